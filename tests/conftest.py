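import numpy as np
import pytest

from hybridscreen import CohortSpec, gen_study, load_ncsr_bank

#: Printed administration order at the -0.15 cutoff for the shipped bank.
RANKED_ORDER = (
    "C6", "B5", "C4", "B3", "C5", "C2", "D5", "B2", "B4", "D3", "D2",
    "F2", "C7", "D4", "D1", "C1", "B1", "C3", "F1", "E1", "A2",
)


@pytest.fixture(scope="session")
def bank():
    return load_ncsr_bank()


@pytest.fixture(scope="session")
def small_study(bank):
    """One seeded default-size synthetic study shared across tests."""
    return gen_study(CohortSpec(seed=11), bank)


def riemann_eap(responses, bank, prior_mean=0.0, prior_var=1.0, n=1201, span=6.0):
    """Independent fine-grid Riemann-sum oracle for the EAP posterior mean/SD."""
    sd = np.sqrt(prior_var)
    t = np.linspace(prior_mean - span * sd, prior_mean + span * sd, n)
    x = np.asarray(responses, dtype=float)
    seen = ~np.isnan(x)
    logpost = -0.5 * ((t - prior_mean) / sd) ** 2
    for xi, a, b in zip(x[seen], bank.alpha[seen], bank.beta[seen]):
        p = 1.0 / (1.0 + np.exp(-np.clip(a * (t - b), -700, 700)))
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
        logpost += np.log(p) if xi == 1 else np.log1p(-p)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = w @ t
    return mean, np.sqrt(w @ (t - mean) ** 2)
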