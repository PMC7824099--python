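"""Case-control association statistics for nongenetic risk factors.

2x2 odds ratios with Wald confidence intervals, multivariable logistic
regression (via statsmodels, complete-case), and backward stepwise
elimination at a Wald-p threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "LogisticFit",
    "odds_ratio_2x2",
    "fit_logistic",
    "backward_eliminate",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x status counts: a = exposed cases, b = reference cases,
    c = exposed controls, d = reference controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def swapped(self) -> "ContingencyTable2x2":
        """Swap exposed and reference categories."""
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_lo: float
    ci_hi: float
    p: float
    estimable: bool = True


def odds_ratio_2x2(t: ContingencyTable2x2, ci_level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with Wald CI and p-value.

    OR = (a*d)/(b*c); CI = exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    A zero cell makes the Wald estimate unavailable; the result is returned
    flagged ``estimable=False`` (this is how a risk group containing no cases
    is reported, rather than as an error).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return OddsRatioResult(np.nan, np.nan, np.nan, np.nan, estimable=False)
    log_or = np.log(t.a * t.d / (t.b * t.c))
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = norm.isf((1 - ci_level) / 2)
    p = 2 * norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        oddsratio=float(np.exp(log_or)),
        ci_lo=float(np.exp(log_or - z * se)),
        ci_hi=float(np.exp(log_or + z * se)),
        p=float(p),
    )


@dataclass
class LogisticFit:
    """Coefficients (log-odds per term), Wald inference, and bookkeeping."""

    coefficients: pd.Series
    standard_errors: pd.Series
    wald_p_values: pd.Series
    converged: bool
    n_used: int

    def __post_init__(self) -> None:
        if not (len(self.coefficients) == len(self.standard_errors) == len(self.wald_p_values)):
            raise ValueError("inconsistent term lengths")

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def conf_int(self, ci_level: float = 0.95) -> pd.DataFrame:
        z = norm.isf((1 - ci_level) / 2)
        return pd.DataFrame(
            {
                "ci_lo": np.exp(self.coefficients - z * self.standard_errors),
                "ci_hi": np.exp(self.coefficients + z * self.standard_errors),
            }
        )


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton IRLS, tol 1e-8,
    max 100 iterations), complete-case.

    ``design`` must already contain the intercept column (conventionally
    ``const``).  Rows with any missing value in design or outcome are
    dropped and ``n_used`` reports what remained.  Perfect separation is
    flagged ``converged=False`` with a warning rather than raised.
    """
    design = pd.DataFrame(design).astype(float)
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index)
    keep = design.notna().all(axis=1) & y.notna()
    X, y = design.loc[keep], y.loc[keep]
    n_used = len(y)
    if n_used <= X.shape[1]:
        raise ValueError(f"too few complete cases ({n_used}) for {X.shape[1]} terms")
    if y.nunique() < 2:
        raise ValueError("outcome is constant (no events or no non-events)")
    non_const = [c for c in X.columns if X[c].nunique() == 1 and c != "const"
                 and not np.allclose(X[c], 1.0)]
    if non_const:
        raise ValueError(f"constant non-intercept column(s): {non_const}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError):
            warnings.warn("perfect separation: coefficients unreliable",
                          RuntimeWarning, stacklevel=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
            converged = False
    return LogisticFit(
        coefficients=res.params,
        standard_errors=res.bse,
        wald_p_values=res.pvalues,
        converged=converged,
        n_used=n_used,
    )


def backward_eliminate(design: pd.DataFrame, outcome, alpha: float = 0.05,
                       ) -> tuple[list[str], LogisticFit]:
    """Backward stepwise elimination on Wald p-values.

    Repeatedly drops the non-intercept term with the largest p >= ``alpha``
    and refits, until every remaining term has p < ``alpha`` (possibly the
    intercept-only model).  Ties on p are broken by earlier column position,
    so the procedure is deterministic given input order.
    """
    design = pd.DataFrame(design)
    terms = [c for c in design.columns if c != "const"]
    if "const" not in design.columns:
        raise ValueError("design must contain an intercept column named 'const'")
    while True:
        fit = fit_logistic(design[["const"] + terms], outcome)
        if not terms:
            break
        pvals = fit.wald_p_values.drop("const")
        worst_p = pvals.max()
        if worst_p < alpha:
            break
        # ties: keep input order, drop the earliest of the tied worst terms
        tied = [t for t in terms if pvals[t] == worst_p]
        terms.remove(tied[0])
    return terms, fit
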