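"""End-to-end screening pipeline: the three estimation approaches, adaptive
routing curves, and performance evaluation, from files or in-memory objects.

Approach 1 estimates each latent trait by EAP under N(0, 1) from the 21-item
responses alone; approach 2 classifies narratives by the PSM log-ratio score;
approach 3 fits the latent regression by MCMC and re-estimates each trait
under the text-informed prior. All three are scored against the diagnostic
cutoff and the structured-interview diagnoses.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataio import (
    load_ncsr_bank,
    read_corpus_jsonl,
    read_item_bank,
    read_response_matrix,
    write_posterior_csv,
    write_scores_csv,
)
from .hybrid_bayes import McmcConfig, fit_latent_regression, hybrid_eap
from .irt_core import ItemBank, ResponseMatrix, eap_estimate
from .psm_text import TokenizedDoc, psm_score, standardize_scores, train_psm
from .routing import DEFAULT_CUTOFF, RoutingPlan, items_saved, rank_items, se_curve
from .screening_eval import ConfusionCounts, classify, metrics, validity_coefficients

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "run_pipeline_from_files"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; paths resolve relative to the working directory."""

    bank_path: str | None = None      # None -> shipped NCS-R fixture
    corpus_path: str | None = None
    responses_path: str | None = None
    out_dir: str = "pipeline_out"
    cutoff: float = DEFAULT_CUTOFF
    psm_a: float = 0.5
    psm_b: float = 0.0
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass
class PipelineReport:
    """Structured pipeline output (also serialized to out_dir)."""

    metrics_by_approach: dict[str, dict[str, float]]
    confusion_by_approach: dict[str, dict[str, int]]
    reg: dict[str, float]
    correlations: dict[str, float]
    se_curve_without: list[float]
    se_curve_with: list[float]
    se_curve_uninformative: list[float]
    m_star: int
    items_saved: int
    m_star_uninformative: int
    items_saved_uninformative: int
    ranked_items: list[str]
    validity: dict[str, float]
    run_log: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    docs: list[TokenizedDoc],
    responses: ResponseMatrix,
    truth_positive: np.ndarray,
    bank: ItemBank,
    cfg: RunConfig = RunConfig(),
) -> PipelineReport:
    """Run approaches 1-3, routing and evaluation on in-memory inputs.

    ``truth_positive`` is the structured-interview diagnosis (True = PTSD),
    the reference standard for every metric row.
    """
    truth = np.asarray(truth_positive, dtype=bool)
    n = responses.n_persons
    if len(docs) != n or truth.shape != (n,):
        raise ValueError("docs, responses and truth must cover the same persons")

    with _stage("text scoring"):
        model = train_psm(docs, a=cfg.psm_a, b=cfg.psm_b)
        scores = [psm_score(model, d) for d in docs]
        raw = np.array([s.raw for s in scores])
        y = standardize_scores(raw)
        text_pred = np.array([s.predicted_class == 1 for s in scores])

    with _stage("IRT estimation"):
        post_irt = [eap_estimate(responses.values[i], bank) for i in range(n)]
        theta_irt = np.array([p.theta_hat for p in post_irt])

    with _stage("hybrid estimation"):
        mcmc = fit_latent_regression(responses, bank, y, cfg.mcmc)
        post_hyb = [hybrid_eap(responses.values[i], bank, mcmc.reg, y[i]) for i in range(n)]
        theta_hyb = np.array([p.theta_hat for p in post_hyb])

    with _stage("evaluation"):
        rows, confusion = {}, {}
        for name, pred in (
            ("irt", classify(theta_irt, cfg.cutoff)),
            ("text", text_pred),
            ("hybrid", classify(theta_hyb, cfg.cutoff)),
        ):
            cc = ConfusionCounts.from_labels(truth, pred)
            rows[name] = {k: round(v, 2) for k, v in metrics(cc).items()}
            confusion[name] = {"tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn}
        corr = {
            "irt_text": float(np.corrcoef(theta_irt, y)[0, 1]),
            "irt_hybrid": float(np.corrcoef(theta_irt, theta_hyb)[0, 1]),
            "text_hybrid": float(np.corrcoef(y, theta_hyb)[0, 1]),
        }
        validity = validity_coefficients(responses, theta_irt)

    with _stage("routing"):
        plan = rank_items(bank, cfg.cutoff)
        curve_without = se_curve(responses, bank, plan)
        curve_with = se_curve(responses, bank, plan, reg=mcmc.reg, y=y)
        m_star, saving = items_saved(curve_with, curve_without)
        # reference without any informative prior (near-flat normal), the
        # natural benchmark when the text prior is vaguer than N(0, 1)
        curve_flat = se_curve(responses, bank, plan, prior_var=25.0)
        m_star_flat, saving_flat = items_saved(curve_with, curve_flat)

    run_log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "mcmc": {"n_iter": cfg.mcmc.n_iter, "burn_in": cfg.mcmc.burn_in,
                 "n_chains": cfg.mcmc.n_chains, "seed": cfg.mcmc.seed},
        "cutoff": cfg.cutoff,
        "psm": {"a": cfg.psm_a, "b": cfg.psm_b,
                "vocab_size": len(model.vocab),
                "priors": [model.prior1, model.prior2]},
        "defaults": {
            "log_base": "natural",
            "token_counting": "multiplicity",
            "tie_at_threshold": "class 2",
            "standardization": "cohort mean/SD, n-1 denominator",
            "quadrature": "121 points, prior mean +/- 6 SD",
            "classification_boundary": "theta_hat >= cutoff is positive",
            "ranking_tie_rule": "bank order",
        },
        "rhat": mcmc.rhat,
    }

    return PipelineReport(
        metrics_by_approach=rows,
        confusion_by_approach=confusion,
        reg={"b0": mcmc.reg.b0, "b1": mcmc.reg.b1, "sigma2": mcmc.reg.sigma2},
        correlations=corr,
        se_curve_without=[float(v) for v in curve_without.mean_sd],
        se_curve_with=[float(v) for v in curve_with.mean_sd],
        se_curve_uninformative=[float(v) for v in curve_flat.mean_sd],
        m_star=m_star,
        items_saved=saving,
        m_star_uninformative=m_star_flat,
        items_saved_uninformative=saving_flat,
        ranked_items=list(plan.ranked_items),
        validity=validity,
        run_log=run_log,
    )


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = asdict(report)
    (out_dir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline_from_files(cfg: RunConfig) -> PipelineReport:
    """File-based pipeline entry: read bank/corpus/responses, run, write report.

    The corpus must carry labels (1/2) for every person; persons are matched
    to response rows by id.
    """
    if cfg.corpus_path is None or cfg.responses_path is None:
        raise ValueError("pipeline requires corpus_path and responses_path "
                         "(approach 3 needs text scores)")
    for label, p in (("bank", cfg.bank_path), ("corpus", cfg.corpus_path),
                     ("responses", cfg.responses_path)):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")

    bank = load_ncsr_bank() if cfg.bank_path is None else read_item_bank(cfg.bank_path)
    docs = read_corpus_jsonl(cfg.corpus_path)
    responses = read_response_matrix(cfg.responses_path)
    by_id = {d.id: d for d in docs}
    missing = [p for p in responses.person_ids if p not in by_id]
    if missing:
        raise ValueError(f"corpus is missing narratives for persons {missing[:5]}")
    docs = [by_id[p] for p in responses.person_ids]
    if any(d.label is None for d in docs):
        raise ValueError("pipeline corpus must be fully labeled (1/2)")
    truth = np.array([d.label == 1 for d in docs])

    report = run_pipeline(docs, responses, truth, bank, cfg)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = train_psm(docs, a=cfg.psm_a, b=cfg.psm_b)
    scores = [psm_score(model, d) for d in docs]
    raw = np.array([s.raw for s in scores])
    write_scores_csv(responses.person_ids, raw, standardize_scores(raw),
                     [s.predicted_class for s in scores], out / "scores.csv")
    _write_report(report, out)
    return report
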