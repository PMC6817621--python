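item_id,alpha,se_alpha,beta,se_beta,validity_r
A2,1.19,0.41,-4.45,0.48,0.19
B1,1.82,0.20,-1.74,0.15,0.58
B2,1.24,0.14,-0.49,0.10,0.51
B3,1.41,0.15,-0.22,0.10,0.54
B4,1.64,0.18,-1.18,0.12,0.56
B5,1.68,0.17,-0.34,0.11,0.58
C1,0.95,0.12,-1.31,0.11,0.42
C2,1.34,0.14,-0.45,0.10,0.52
C3,0.83,0.10,0.58,0.08,0.39
C4,1.53,0.15,-0.39,0.10,0.53
C5,1.55,0.16,-0.88,0.11,0.53
C6,1.86,0.18,-0.55,0.12,0.58
C7,1.45,0.15,1.22,0.12,0.47
D1,1.14,0.18,-1.53,0.12,0.39
D2,1.11,0.14,-0.16,0.09,0.46
D3,1.47,0.19,-1.10,0.11,0.48
D4,0.96,0.16,-0.85,0.10,0.39
D5,1.28,0.17,-0.55,0.10,0.49
E1,0.78,0.30,-3.30,0.21,0.21
F1,1.55,0.26,-2.15,0.17,0.38
F2,1.02,0.16,-0.88,0.11,0.40
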