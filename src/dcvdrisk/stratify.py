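"""Discrete (cutoff) and quartile risk-group stratification.

The discrete model labels a sample high-risk when its score is at or above a
cutoff ("0.21 or greater" convention: ties go to high risk) and reports
confusion counts, sensitivity, specificity and percent correctly classified.
The quartile model bins scores at the pooled 25/50/75th percentiles and
compares the highest to the lowest quartile with a cross-product OR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import ContingencyTable2x2, OddsRatioResult, odds_ratio_2x2

__all__ = ["ConfusionCounts", "confusion_metrics", "dichotomize", "quartile_assign",
           "youden_cutoff", "QuartileResult"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, percent correct, and the high-vs-low OR
    (flagged unestimable when a cell is zero, as happens when no case falls
    in the low-risk group)."""
    if c.n_cases == 0 or c.n_controls == 0:
        raise ValueError("need both cases and controls")
    oddsratio: OddsRatioResult = odds_ratio_2x2(
        ContingencyTable2x2(a=c.tp, b=c.fn, c=c.fp, d=c.tn))
    return {
        "sensitivity": c.tp / c.n_cases,
        "specificity": c.tn / c.n_controls,
        "percent_correct": (c.tp + c.tn) / c.total,
        "odds_ratio": oddsratio,
    }


def dichotomize(scores, status, cutoff: float) -> tuple[ConfusionCounts, dict]:
    """Classify high risk = score >= cutoff and tally the confusion matrix."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and status must be aligned")
    high = s >= cutoff
    counts = ConfusionCounts(
        tp=int(np.sum(high & (y == 1))),
        fp=int(np.sum(high & (y == 0))),
        tn=int(np.sum(~high & (y == 0))),
        fn=int(np.sum(~high & (y == 1))),
    )
    return counts, confusion_metrics(counts)


@dataclass
class QuartileResult:
    labels: pd.Series                      # Q1 (lowest) .. Q4 (highest)
    boundaries: tuple[float, float, float]
    counts: pd.DataFrame                   # cases/controls per group
    q4_vs_q1: OddsRatioResult | None


def quartile_assign(scores, status=None) -> QuartileResult:
    """Assign pooled-sample risk quartiles Q1 (lowest) .. Q4 (highest).

    Boundaries are the 25/50/75th linear-interpolation percentiles of the
    full sample; scores exactly on a boundary go to the lower group.  With
    ``status`` given, per-group case/control counts and the Q4-vs-Q1 OR are
    computed.
    """
    s = pd.Series(scores, dtype=float)
    if s.nunique() < 4:
        raise ValueError("need at least 4 distinct score values for quartiles")
    q1, q2, q3 = np.percentile(s, [25, 50, 75])
    group_idx = np.searchsorted([q1, q2, q3], s.to_numpy(), side="left")
    labels = pd.Series([f"Q{i + 1}" for i in group_idx], index=s.index, name="quartile")

    counts = None
    q4_vs_q1 = None
    if status is not None:
        y = pd.Series(np.asarray(status, dtype=int), index=s.index)
        counts = (
            pd.crosstab(labels, y)
            .reindex(index=[f"Q{i}" for i in range(1, 5)], columns=[0, 1], fill_value=0)
            .rename(columns={0: "controls", 1: "cases"})
        )
        q4_vs_q1 = odds_ratio_2x2(ContingencyTable2x2(
            a=int(counts.loc["Q4", "cases"]), b=int(counts.loc["Q1", "cases"]),
            c=int(counts.loc["Q4", "controls"]), d=int(counts.loc["Q1", "controls"])))
    return QuartileResult(labels=labels, boundaries=(float(q1), float(q2), float(q3)),
                          counts=counts, q4_vs_q1=q4_vs_q1)


def youden_cutoff(scores, status) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Offered as a labelled extension: how published cutoffs were chosen is a
    separate question, and :func:`dichotomize` always takes the cutoff as an
    input.  Returns (cutoff, J).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=int)
    order = np.argsort(-s)
    s_sorted, y_sorted = s[order], y[order]
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need both cases and controls")
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # candidate cutoffs: each distinct score treated as the >= threshold
    last = np.r_[np.diff(s_sorted) != 0, True]
    j = tp[last] / n_cases - fp[last] / n_controls
    best = int(np.argmax(j))
    return float(s_sorted[last][best]), float(j[best])
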