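"""Polygenic and nongenetic risk scores, and the shared 0-10 normalization.

PRS = sum over the panel of log(OR_i) * dosage_i (natural log, the
regression-coefficient convention).  All score types — liability, PRS,
nongenetic, multifactorial — are mapped onto a common 0-10 scale by min-max
normalization, X_N = (X - X_min) / X_range * 10, with the normalization
parameters fitted once on a reference sample and persisted so held-out data
can be scored consistently (out-of-range values clip to [0, 10]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .liability import SnpWeight

__all__ = ["ScoreSet", "compute_prs", "compute_covariate_score", "minmax_normalize"]


@dataclass
class ScoreSet:
    """Raw and 0-10 normalized scores with persisted normalization parameters."""

    raw: pd.Series
    score_type: str
    x_min: float
    x_range: float
    n_clipped: int = 0
    normalized: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.x_range <= 0:
            raise ValueError("normalization range must be > 0")
        scaled = (self.raw - self.x_min) / self.x_range * 10.0
        clipped = scaled.clip(0.0, 10.0)
        self.n_clipped = int((scaled != clipped).sum())
        if self.n_clipped:
            warnings.warn(f"{self.n_clipped} value(s) outside the reference range were clipped",
                          RuntimeWarning, stacklevel=2)
        self.normalized = clipped

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"raw": self.raw, "normalized": self.normalized, "score_type": self.score_type}
        ).to_csv(path, sep="\t", index_label="sample")

    def normalization_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"score_type": self.score_type, "x_min": self.x_min,
                       "x_range": self.x_range}, fh, indent=2)


def compute_prs(dosages: pd.DataFrame, weights: Sequence[SnpWeight]) -> pd.Series:
    """Per-sample polygenic risk score: sum_i ln(OR_i) * x_i.

    ``dosages`` columns are rsIDs; samples with a missing dosage at any panel
    SNP are dropped (complete-case).
    """
    log_ors = {}
    for w in weights:
        if w.per_allele_or <= 0:
            raise ValueError(f"{w.rsid}: OR must be > 0")
        log_ors[w.rsid] = np.log(w.per_allele_or)
    missing = [r for r in log_ors if r not in dosages.columns]
    if missing:
        raise KeyError(f"dosage matrix lacks panel SNPs: {missing[:5]}")
    sub = dosages[list(log_ors)]
    sub = sub.loc[sub.notna().all(axis=1)]
    values = sub.to_numpy(dtype=float) @ np.array(list(log_ors.values()))
    return pd.Series(values, index=sub.index, name="prs")


def compute_covariate_score(categories: pd.DataFrame, schemes) -> pd.Series:
    """Nongenetic analogue of the PRS: sum_j ln(OR of the sample's category)."""
    by_name = {s.name: s for s in schemes}
    missing = [n for n in by_name if n not in categories.columns]
    if missing:
        raise KeyError(f"category table lacks covariates: {missing}")
    sub = categories[list(by_name)]
    sub = sub.loc[sub.notna().all(axis=1)]
    total = np.zeros(len(sub))
    for name, scheme in by_name.items():
        log_or = np.log(np.asarray(scheme.category_ors))
        total += log_or[sub[name].to_numpy(dtype=int)]
    return pd.Series(total, index=sub.index, name="nongenetic_score")


def minmax_normalize(values: pd.Series, reference: pd.Series | None = None,
                     score_type: str = "score") -> ScoreSet:
    """Map scores onto [0, 10] with min-max normalization.

    The affine map sends the reference minimum to 0 and maximum to 10
    (reference defaults to ``values`` itself); values outside the reference
    range are clipped, with the count recorded on the returned ScoreSet.
    Being strictly increasing, the map preserves every rank-based statistic.
    """
    values = pd.Series(values)
    ref = values if reference is None else pd.Series(reference)
    x_min = float(ref.min())
    x_range = float(ref.max() - ref.min())
    if x_range <= 0:
        raise ValueError("reference scores have zero range")
    return ScoreSet(raw=values, score_type=score_type, x_min=x_min, x_range=x_range)
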