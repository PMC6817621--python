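"""Readers and writers for the package's file formats.

Formats are deliberately plain: item bank CSV, response-matrix CSV, narrative
corpus JSONL, score/posterior CSVs, metrics/cutoff JSON. All writers
round-trip losslessly through the matching readers. Unicode minus signs
(U+2212) are normalized on ingest so values transcribed from typeset tables
parse as numbers.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .irt_core import ItemBank, ResponseMatrix
from .psm_text import TokenizedDoc, preprocess

__all__ = [
    "load_ncsr_bank",
    "read_item_bank",
    "write_item_bank",
    "read_response_matrix",
    "write_response_matrix",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_scores_csv",
    "write_scores_csv",
    "write_posterior_csv",
    "read_posterior_csv",
]

_BANK_COLUMNS = ("item_id", "alpha", "se_alpha", "beta", "se_beta", "validity_r")


def _normalize_minus(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: v.replace("−", "-").strip() if isinstance(v, str) else v)


def read_item_bank(path: str | Path) -> ItemBank:
    """Read an item-parameter CSV (item_id, alpha, se_alpha, beta, se_beta,
    validity_r); validates columns, uniqueness and positive discriminations."""
    df = pd.read_csv(path, dtype={"item_id": str})
    missing = [c for c in ("item_id", "alpha", "beta") if c not in df.columns]
    if missing:
        raise ValueError(f"item bank {path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"item bank {path}: no items")
    df = _normalize_minus(df)
    dupes = df["item_id"][df["item_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"item bank {path}: duplicate item ids {sorted(set(dupes))}")
    alpha = pd.to_numeric(df["alpha"]).to_numpy()
    bad = df["item_id"][alpha <= 0].tolist()
    if bad:
        raise ValueError(f"item bank {path}: non-positive discrimination for {bad}")

    def opt(col):
        return pd.to_numeric(df[col]).to_numpy() if col in df.columns else None

    return ItemBank(
        tuple(df["item_id"]),
        alpha,
        pd.to_numeric(df["beta"]).to_numpy(),
        opt("se_alpha"), opt("se_beta"), opt("validity_r"),
    )


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    data = {"item_id": bank.item_ids, "alpha": bank.alpha, "beta": bank.beta}
    for col, v in (("se_alpha", bank.se_alpha), ("se_beta", bank.se_beta),
                   ("validity_r", bank.validity_r)):
        if v is not None:
            data[col] = v
    pd.DataFrame(data).to_csv(path, index=False)


def load_ncsr_bank() -> ItemBank:
    """The shipped 21-item NCS-R PTSD bank (fixed 2PL calibration)."""
    with resources.as_file(
        resources.files("hybridscreen").joinpath("data/ncsr_table1.csv")
    ) as p:
        return read_item_bank(p)


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    """Read a persons x items 0/1 CSV: person_id column then one column per item."""
    df = pd.read_csv(path, dtype={"person_id": str})
    if "person_id" not in df.columns:
        raise ValueError(f"response matrix {path}: missing person_id column")
    items = tuple(c for c in df.columns if c != "person_id")
    if not items:
        raise ValueError(f"response matrix {path}: no item columns")
    values = df[list(items)].to_numpy(dtype=float)
    return ResponseMatrix(tuple(df["person_id"]), items, values)


def write_response_matrix(rm: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rm.values, columns=rm.item_ids)
    # keep 0/1 cells integral in the file; missing stays blank
    df = df.astype("Int64")
    df.insert(0, "person_id", rm.person_ids)
    df.to_csv(path, index=False)


def read_corpus_jsonl(path: str | Path, tokenized: bool = True) -> list[TokenizedDoc]:
    """Read narrative records {"id", "label", "text"} (label 1, 2 or null),
    preprocessing each text into a TokenizedDoc."""
    docs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        label = rec.get("label")
        docs.append(preprocess(rec["text"], doc_id=str(rec["id"]),
                               label=None if label is None else int(label)))
    return docs


def write_corpus_jsonl(docs: list[TokenizedDoc], path: str | Path) -> None:
    """Write tokenized narratives as JSONL, text = space-joined stems."""
    with open(path, "w") as fh:
        for d in docs:
            fh.write(json.dumps(
                {"id": d.id, "label": d.label, "text": " ".join(d.tokens)}) + "\n")


def write_scores_csv(person_ids, raw, standardized, predicted_class, path) -> None:
    pd.DataFrame({
        "person_id": person_ids,
        "raw": np.asarray(raw, dtype=float),
        "standardized": np.asarray(standardized, dtype=float),
        "predicted_class": np.asarray(predicted_class, dtype=int),
    }).to_csv(path, index=False, float_format="%.10g")


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    need = {"person_id", "raw", "standardized"}
    if not need.issubset(df.columns):
        raise ValueError(f"scores file {path}: needs columns {sorted(need)}")
    return df


def write_posterior_csv(person_ids, posteriors, prior_means, prior_vars, path) -> None:
    """Per-person posterior summaries: theta_hat, post_sd and the prior used."""
    pd.DataFrame({
        "person_id": person_ids,
        "theta_hat": [p.theta_hat for p in posteriors],
        "post_sd": [p.post_sd for p in posteriors],
        "prior_mean": np.asarray(prior_means, dtype=float),
        "prior_var": np.asarray(prior_vars, dtype=float),
    }).to_csv(path, index=False, float_format="%.10g")


def read_posterior_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    need = {"person_id", "theta_hat", "post_sd"}
    if not need.issubset(df.columns):
        raise ValueError(f"posterior file {path}: needs columns {sorted(need)}")
    return df
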