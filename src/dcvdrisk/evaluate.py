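"""Predictive-performance metrics for risk models.

Rank-based (Mann-Whitney) AUC with a DeLong-type asymptotic confidence
interval, per-1-point odds ratios on 0-10 normalized scores, continuous net
reclassification improvement, stratified 10-fold cross-validation, and
per-cohort evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .association import fit_logistic
from .scores import minmax_normalize

__all__ = ["EvalReport", "auc_rank", "per_point_or", "continuous_nri",
           "kfold_cv", "per_cohort_eval", "evaluate_scores"]


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------

def _delong_variance(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """DeLong asymptotic variance of the Mann-Whitney AUC via midrank
    structural components."""
    m, n = len(case_scores), len(control_scores)
    all_scores = np.concatenate([case_scores, control_scores])
    r_all = rankdata(all_scores)
    r_case = rankdata(case_scores)
    r_ctrl = rankdata(control_scores)
    v10 = (r_all[:m] - r_case) / n          # per-case components
    v01 = 1.0 - (r_all[m:] - r_ctrl) / m    # per-control components
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_rank(scores, status, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong-type CI.

    Equals the probability that a random case outscores a random control.
    The CI is computed on the AUC scale from the asymptotic variance of the
    rank statistic and truncated to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=int)
    case_scores, control_scores = s[y == 1], s[y == 0]
    m, n = len(case_scores), len(control_scores)
    if m == 0 or n == 0:
        raise ValueError("need both cases and controls for AUC")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n)
    se = np.sqrt(_delong_variance(case_scores, control_scores))
    z = norm.isf((1 - ci_level) / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


# --------------------------------------------------------------------------
# per-point OR and NRI
# --------------------------------------------------------------------------

def per_point_or(normalized_scores, status) -> dict:
    """OR per 1-point increase of a 0-10 normalized score, by univariate
    logistic regression of status on the score."""
    s = pd.Series(normalized_scores, dtype=float).reset_index(drop=True)
    y = pd.Series(np.asarray(status, dtype=int))
    design = pd.DataFrame({"const": 1.0, "score": s})
    fit = fit_logistic(design, y)
    ci = fit.conf_int().loc["score"]
    return {
        "or": float(np.exp(fit.coefficients["score"])),
        "ci_lo": float(ci["ci_lo"]),
        "ci_hi": float(ci["ci_hi"]),
        "p": float(fit.wald_p_values["score"]),
        "converged": fit.converged,
    }


def continuous_nri(risk_old, risk_new, status) -> dict:
    """Continuous net reclassification improvement of new over old risks.

    NRI_e  = P(new > old | case)    - P(new < old | case)
    NRI_ne = P(new < old | control) - P(new > old | control)
    Ties contribute to neither direction; overall = NRI_e + NRI_ne.
    """
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    y = np.asarray(status, dtype=int)
    if not (old.shape == new.shape == y.shape):
        raise ValueError("risk_old, risk_new and status must be aligned")
    up, down = new > old, new < old
    cases, controls = y == 1, y == 0
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need both cases and controls")
    nri_event = (up & cases).sum() / cases.sum() - (down & cases).sum() / cases.sum()
    nri_nonevent = (down & controls).sum() / controls.sum() - (up & controls).sum() / controls.sum()
    return {
        "nri_event": float(nri_event),
        "nri_nonevent": float(nri_nonevent),
        "nri_overall": float(nri_event + nri_nonevent),
    }


# --------------------------------------------------------------------------
# reports, cross-validation, per-cohort
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    n_cases: int
    n_controls: int
    per_point: dict | None = None
    nri: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        if self.per_point is not None:
            out["per_point_or"] = self.per_point
        if self.nri is not None:
            out["nri"] = self.nri
        out.update(self.extra)
        return out


def evaluate_scores(raw_scores, status, normalized_scores=None) -> EvalReport:
    """AUC (+CI) on the raw scores and, when a normalized version is given,
    the per-1-point OR."""
    y = np.asarray(status, dtype=int)
    auc, ci = auc_rank(raw_scores, y)
    pp = per_point_or(normalized_scores, y) if normalized_scores is not None else None
    return EvalReport(auc=auc, auc_ci=ci, n_cases=int(y.sum()),
                      n_controls=int((1 - y).sum()), per_point=pp)


def kfold_cv(raw_scores, status, k: int = 10, seed: int = 0) -> dict:
    """Stratified k-fold evaluation of a score.

    Folds preserve the case/control ratio (within one sample).  Per fold,
    the 0-10 normalization is fitted on the training portion only and the
    held-out samples are scored with those persisted parameters before the
    fold AUC and per-point OR are computed.  Deterministic under a fixed
    seed.
    """
    s = pd.Series(raw_scores, dtype=float).reset_index(drop=True)
    y = pd.Series(np.asarray(status, dtype=int))
    if y.value_counts().min() < k:
        raise ValueError(f"smallest class has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train, test) in enumerate(skf.split(s, y)):
        ref = s.iloc[train]
        held = minmax_normalize(s.iloc[test], reference=ref)
        auc, ci = auc_rank(s.iloc[test], y.iloc[test])
        fold = {"fold": i, "n_test": len(test), "auc": auc, "auc_ci": list(ci),
                "n_clipped": held.n_clipped}
        try:
            fold["per_point_or"] = per_point_or(held.normalized, y.iloc[test])["or"]
        except ValueError:
            fold["per_point_or"] = np.nan
        folds.append(fold)
    aucs = np.array([f["auc"] for f in folds])
    return {
        "folds": folds,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)),
        "k": k,
        "seed": seed,
    }


def per_cohort_eval(scores, status, cohort_labels, normalized_scores=None) -> pd.DataFrame:
    """AUC and per-point OR within each cohort label.

    Cohorts containing a single outcome class are skipped, with the reason
    recorded in the returned table.
    """
    s = pd.Series(scores, dtype=float).reset_index(drop=True)
    y = pd.Series(np.asarray(status, dtype=int))
    labels = pd.Series(np.asarray(cohort_labels))
    nrm = (pd.Series(normalized_scores, dtype=float).reset_index(drop=True)
           if normalized_scores is not None else None)
    rows = []
    for label in sorted(labels.unique()):
        mask = (labels == label).to_numpy()
        y_c = y[mask]
        row = {"cohort": label, "n": int(mask.sum()),
               "n_cases": int(y_c.sum()), "n_controls": int((1 - y_c).sum())}
        if y_c.nunique() < 2:
            row.update(auc=np.nan, auc_lo=np.nan, auc_hi=np.nan,
                       skipped="single outcome class")
            rows.append(row)
            continue
        auc, (lo, hi) = auc_rank(s[mask], y_c)
        row.update(auc=auc, auc_lo=lo, auc_hi=hi, skipped="")
        if nrm is not None:
            try:
                row["per_point_or"] = per_point_or(nrm[mask], y_c)["or"]
            except ValueError:
                row["per_point_or"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
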