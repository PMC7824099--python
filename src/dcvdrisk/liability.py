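"""Liability-threshold (probit) machinery for disease risk modelling.

The liability-threshold model treats disease as the visible tail of a latent,
standard-normally distributed *liability*: an individual develops disease when
their liability exceeds the threshold ``T = Phi^-1(1 - K)`` fixed by the
population prevalence ``K``.  Measured risk factors (SNP genotypes, categorical
covariates) shift the mean of an individual's liability; the residual term
``e`` carries everything unmeasured, with variance ``1 - V`` where ``V`` is the
variance explained by the measured factors, so that total liability stays
N(0, 1) marginally.

This module converts published per-allele odds ratios (or genotypic risk
ratios) and risk-allele frequencies into per-genotype liability shifts,
aggregates them into a per-sample measured liability, conditions on family
history, maps liability to posterior disease risk, and cumulates risk over an
age/sex life table into an incidence-based lifetime risk that accounts for
disease-free mortality as a competing event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SnpWeight",
    "CovariateScheme",
    "LocusEffects",
    "LiabilityModel",
    "LifeTable",
    "ModelSpecificationError",
    "threshold_from_prevalence",
    "genotype_frequencies",
    "locus_effects",
    "covariate_effects",
    "build_model",
    "measured_liability",
    "family_history_update",
    "posterior_risk",
    "lifetime_risk",
    "liability_distribution",
    "predicted_auc",
    "read_weights",
    "write_weights",
    "dosages_from_vcf",
]


class ModelSpecificationError(ValueError):
    """Raised when supplied effects are incompatible with the threshold model
    (e.g. implied penetrance >= 1, or total variance explained >= 1)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpWeight:
    """Published per-SNP weight: risk allele, its population frequency and
    per-allele effect size (odds ratio by convention)."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    nonrisk_allele: str
    raf: float
    per_allele_or: float

    def __post_init__(self) -> None:
        if not 0.0 < self.raf < 1.0:
            raise ValueError(f"{self.rsid}: risk-allele frequency must be in (0,1), got {self.raf}")
        if self.per_allele_or <= 0.0:
            raise ValueError(f"{self.rsid}: per-allele OR must be > 0, got {self.per_allele_or}")

    @property
    def is_ambiguous(self) -> bool:
        """A/T or C/G SNPs cannot be disambiguated by strand flipping."""
        return _COMPLEMENT.get(self.risk_allele) == self.nonrisk_allele


@dataclass(frozen=True)
class CovariateScheme:
    """Categorical (0/1 or 0/1/2) coding of a nongenetic risk factor, with
    category frequencies and category odds ratios (reference category OR=1)."""

    name: str
    category_frequencies: tuple[float, ...]
    category_ors: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.category_frequencies, dtype=float)
        o = np.asarray(self.category_ors, dtype=float)
        if f.size != o.size or f.size < 2:
            raise ValueError(f"{self.name}: need matching frequencies/ORs for >= 2 categories")
        if not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{self.name}: category frequencies must sum to 1 (got {f.sum()})")
        if np.any(f <= 0.0):
            raise ValueError(f"{self.name}: every category must have positive frequency")
        if not np.isclose(o[0], 1.0):
            raise ValueError(f"{self.name}: reference category OR must be 1")
        if np.any(o <= 0.0):
            raise ValueError(f"{self.name}: category ORs must be > 0")

    @property
    def n_categories(self) -> int:
        return len(self.category_frequencies)


@dataclass(frozen=True)
class LocusEffects:
    """Centered per-category liability mean shifts and the variance they
    explain, plus the implied per-category penetrances."""

    shifts: tuple[float, ...]
    variance: float
    penetrances: tuple[float, ...]
    frequencies: tuple[float, ...]


@dataclass
class LiabilityModel:
    """A fitted liability-threshold model: threshold, per-locus and
    per-covariate shifts, and the variance decomposition."""

    prevalence: float
    heritability: float
    threshold: float
    locus_shifts: dict[str, LocusEffects] = field(default_factory=dict)
    covariate_shifts: dict[str, LocusEffects] = field(default_factory=dict)

    @property
    def variance_genetic(self) -> float:
        return float(sum(e.variance for e in self.locus_shifts.values()))

    @property
    def variance_covariate(self) -> float:
        return float(sum(e.variance for e in self.covariate_shifts.values()))

    @property
    def variance_explained(self) -> float:
        return self.variance_genetic + self.variance_covariate

    @property
    def fh_correlation(self) -> float:
        """Liability correlation with one first-degree relative: 0.5 * h2."""
        return 0.5 * self.heritability


class LifeTable:
    """Age-band x sex table of disease incidence (events per 1000 person-years)
    and disease-free mortality (deaths per 10,000 person-years).

    Bands must be contiguous and non-overlapping within each sex.
    """

    COLUMNS = ("age_lo", "age_hi", "sex", "incidence_per_1000py", "mortality_per_10000py")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        table = table.sort_values(["sex", "age_lo"]).reset_index(drop=True)
        if (table["incidence_per_1000py"] < 0).any() or (table["mortality_per_10000py"] < 0).any():
            raise ValueError("life-table rates must be non-negative")
        for _, grp in table.groupby("sex"):
            ages = grp[["age_lo", "age_hi"]].to_numpy(dtype=float)
            if np.any(ages[:, 1] <= ages[:, 0]):
                raise ValueError("age bands must have age_hi > age_lo")
            if np.any(ages[1:, 0] != ages[:-1, 1]):
                raise ValueError("age bands must be contiguous within sex")
        self.table = table

    def for_sex(self, sex: str) -> pd.DataFrame:
        out = self.table[self.table["sex"] == sex]
        if out.empty:
            raise ValueError(f"life table has no rows for sex {sex!r}")
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other) -> bool:
        return isinstance(other, LifeTable) and self.table.equals(other.table)


# --------------------------------------------------------------------------
# threshold and per-term liability shifts
# --------------------------------------------------------------------------

def threshold_from_prevalence(prevalence: float) -> float:
    """Liability threshold ``T = Phi^-1(1 - K)`` for prevalence ``K``."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    return float(norm.isf(prevalence))


def genotype_frequencies(raf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) for
    risk-allele dosage 0/1/2."""
    if not 0.0 < raf < 1.0:
        raise ValueError(f"risk-allele frequency must be in (0,1), got {raf}")
    p = raf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _penetrances(freqs: np.ndarray, multipliers: np.ndarray, prevalence: float,
                 effect_scale: str) -> np.ndarray:
    """Per-category penetrances f_g constrained to sum(P_g * f_g) = K.

    ``multipliers`` act on the odds scale (``effect_scale="or"``) or directly
    on the risk scale (``effect_scale="rr"``).
    """
    K = prevalence
    if effect_scale == "rr":
        f0 = K / float(freqs @ multipliers)
        f = f0 * multipliers
        if np.any(f >= 1.0):
            raise ModelSpecificationError(
                "risk-ratio effects imply penetrance >= 1 at this prevalence")
        return f
    if effect_scale != "or":
        raise ValueError(f"effect_scale must be 'or' or 'rr', got {effect_scale!r}")

    def excess(log_odds0: float) -> float:
        odds = np.exp(log_odds0) * multipliers
        return float(freqs @ (odds / (1.0 + odds))) - K

    lo, hi = -40.0, 40.0
    if excess(lo) > 0 or excess(hi) < 0:  # pragma: no cover - unreachable for valid input
        raise ModelSpecificationError("cannot match prevalence with supplied odds ratios")
    log_odds0 = brentq(excess, lo, hi, xtol=1e-12)
    odds = np.exp(log_odds0) * multipliers
    return odds / (1.0 + odds)


def _shifts_from_penetrances(freqs: np.ndarray, penetrances: np.ndarray,
                             threshold: float) -> tuple[np.ndarray, float]:
    """Solve the per-category mean liability shifts mu_g and the variance v
    they explain.

    Each shift satisfies ``1 - Phi((T - mu_g)/sqrt(1 - v)) = f_g``; since v
    depends on the shifts, the map mu -> v is iterated to a fixed point
    (damped by 0.5 if it oscillates).  Each mu_g is found by bracketed
    root-finding on [-8, 8] liability units (tolerance 1e-10).
    """
    v = 0.0
    mus = np.zeros_like(freqs)
    prev_step = None
    for _ in range(100):
        scale = np.sqrt(1.0 - v)

        def solve_mu(f_g: float) -> float:
            def h(mu: float) -> float:
                return norm.sf((threshold - mu) / scale) - f_g
            return brentq(h, -8.0, 8.0, xtol=1e-10)

        mus = np.array([solve_mu(f) for f in penetrances])
        centered = mus - freqs @ mus
        v_new = float(freqs @ centered**2)
        if v_new >= 1.0:
            raise ModelSpecificationError("effect too large: variance explained >= 1")
        step = v_new - v
        if prev_step is not None and step * prev_step < 0:  # oscillating: damp
            v_new = v + 0.5 * step
        prev_step = step
        if abs(v_new - v) < 1e-10:
            v = v_new
            break
        v = v_new
    else:
        raise ModelSpecificationError("liability-shift fixed point did not converge")
    scale = np.sqrt(1.0 - v)
    mus = threshold - scale * norm.isf(penetrances)
    centered = mus - freqs @ mus
    return centered, v


def locus_effects(weight: SnpWeight, prevalence: float,
                  effect_scale: str = "or") -> LocusEffects:
    """Per-genotype liability shifts for one SNP.

    The per-allele effect is expanded multiplicatively over genotypes
    (1, OR, OR^2), converted to penetrances under the prevalence constraint,
    and mapped to centered liability mean shifts.
    """
    freqs = genotype_frequencies(weight.raf)
    mult = np.array([1.0, weight.per_allele_or, weight.per_allele_or**2])
    return _category_effects(freqs, mult, prevalence, effect_scale)


def covariate_effects(scheme: CovariateScheme, prevalence: float,
                      effect_scale: str = "or") -> LocusEffects:
    """Per-category liability shifts for a categorical nongenetic factor
    (same machinery as :func:`locus_effects`)."""
    freqs = np.asarray(scheme.category_frequencies, dtype=float)
    mult = np.asarray(scheme.category_ors, dtype=float)
    return _category_effects(freqs, mult, prevalence, effect_scale)


def _category_effects(freqs: np.ndarray, multipliers: np.ndarray,
                      prevalence: float, effect_scale: str) -> LocusEffects:
    T = threshold_from_prevalence(prevalence)
    if np.allclose(multipliers, 1.0):
        f = np.full_like(freqs, prevalence)
        return LocusEffects(tuple(np.zeros_like(freqs)), 0.0, tuple(f), tuple(freqs))
    f = _penetrances(freqs, multipliers, prevalence, effect_scale)
    shifts, v = _shifts_from_penetrances(freqs, f, T)
    return LocusEffects(tuple(shifts), v, tuple(f), tuple(freqs))


def build_model(weights: Sequence[SnpWeight],
                schemes: Sequence[CovariateScheme] = (),
                prevalence: float = 0.17,
                heritability: float = 0.5,
                effect_scale: str = "or") -> LiabilityModel:
    """Assemble a :class:`LiabilityModel` from SNP weights and covariate
    schemes, checking the total variance explained stays below 1."""
    if not 0.0 <= heritability <= 1.0:
        raise ValueError(f"heritability must be in [0,1], got {heritability}")
    model = LiabilityModel(
        prevalence=prevalence,
        heritability=heritability,
        threshold=threshold_from_prevalence(prevalence),
    )
    for w in weights:
        model.locus_shifts[w.rsid] = locus_effects(w, prevalence, effect_scale)
    for s in schemes:
        model.covariate_shifts[s.name] = covariate_effects(s, prevalence, effect_scale)
    if model.variance_explained >= 1.0:
        raise ModelSpecificationError(
            f"total variance explained {model.variance_explained:.3f} >= 1")
    return model


# --------------------------------------------------------------------------
# per-sample liability and risk
# --------------------------------------------------------------------------

def measured_liability(model: LiabilityModel,
                       dosages: pd.DataFrame | None = None,
                       categories: pd.DataFrame | None = None) -> pd.Series:
    """Measured liability L = sum of per-genotype shifts + per-category shifts.

    ``dosages`` columns are rsIDs with values 0/1/2 (NaN = missing);
    ``categories`` columns are covariate-scheme names.  Samples missing any
    required input are dropped (complete-case) and reported via the returned
    index.  Passing only one of the two tables scores the genetic-only or
    nongenetic-only model.
    """
    if dosages is None and categories is None:
        raise ValueError("need dosages and/or categories")
    parts: list[pd.Series] = []
    if dosages is not None:
        for rsid in dosages.columns:
            if rsid not in model.locus_shifts:
                raise KeyError(f"no liability shifts for SNP {rsid!r}")
        mask = dosages.notna().all(axis=1)
        total = np.zeros(int(mask.sum()))
        sub = dosages.loc[mask]
        for rsid in dosages.columns:
            shifts = np.asarray(model.locus_shifts[rsid].shifts)
            total += shifts[sub[rsid].to_numpy(dtype=int)]
        parts.append(pd.Series(total, index=sub.index))
    if categories is not None:
        for name in categories.columns:
            if name not in model.covariate_shifts:
                raise KeyError(f"no liability shifts for covariate {name!r}")
        mask = categories.notna().all(axis=1)
        total = np.zeros(int(mask.sum()))
        sub = categories.loc[mask]
        for name in categories.columns:
            shifts = np.asarray(model.covariate_shifts[name].shifts)
            total += shifts[sub[name].to_numpy(dtype=int)]
        parts.append(pd.Series(total, index=sub.index))
    if len(parts) == 1:
        return parts[0]
    idx = parts[0].index.intersection(parts[1].index)
    return parts[0].loc[idx] + parts[1].loc[idx]


def family_history_update(liability, model: LiabilityModel, fh) -> np.ndarray | float:
    """Condition measured liability on family history of disease.

    With one affected first-degree relative (``fh=1``), the unmeasured
    polygenic liability (variance ``h2 - V_g``) has conditional mean

        delta = 0.5 * (h2 - V_g) * phi(T) / K

    since relative liabilities correlate at 0.5*h2 and the mean liability of
    an affected relative is phi(T)/K.  ``fh=0`` (or unknown, coded 0) leaves
    the liability unchanged.
    """
    resid_genetic = max(model.heritability - model.variance_genetic, 0.0)
    delta = 0.5 * resid_genetic * norm.pdf(model.threshold) / model.prevalence
    fh_arr = np.nan_to_num(np.asarray(fh, dtype=float), nan=0.0)
    out = np.asarray(liability, dtype=float) + delta * fh_arr
    if np.isscalar(liability) or np.ndim(liability) == 0:
        return float(out)
    if isinstance(liability, pd.Series):
        return pd.Series(out, index=liability.index)
    return out


def posterior_risk(liability, variance_explained: float, prevalence: float):
    """Posterior disease probability 1 - Phi((T - L)/sqrt(1 - V)).

    Strictly increasing in L; with L=0, V=0 it returns the prevalence.
    """
    if not 0.0 <= variance_explained < 1.0:
        raise ValueError(f"variance explained must be in [0,1), got {variance_explained}")
    T = threshold_from_prevalence(prevalence)
    L = np.asarray(liability, dtype=float)
    risk = norm.sf((T - L) / np.sqrt(1.0 - variance_explained))
    if np.isscalar(liability) or np.ndim(liability) == 0:
        return float(risk)
    if isinstance(liability, pd.Series):
        return pd.Series(risk, index=liability.index)
    return risk


def lifetime_risk(risk_ratio: float, table: LifeTable, sex: str,
                  start_age: float) -> float:
    """Incidence-based lifetime risk with disease-free mortality competing.

    Walks the life-table bands from ``start_age``; in each band the
    individual hazard is ``risk_ratio`` x the band incidence (per person-year)
    and disease-free survival is decremented by both that hazard and the
    disease-free mortality.  The lifetime risk is the sum over bands of
    hazard x band-entry survival x band width, capped at 1.
    """
    if risk_ratio < 0:
        raise ValueError("risk ratio must be >= 0")
    rows = table.for_sex(sex)
    if start_age < rows["age_lo"].min() or start_age >= rows["age_hi"].max():
        raise ValueError(f"start age {start_age} outside life-table coverage")
    survival = 1.0
    total = 0.0
    for row in rows.itertuples(index=False):
        if row.age_hi <= start_age:
            continue
        lo = max(float(row.age_lo), start_age)
        width = float(row.age_hi) - lo
        hazard = risk_ratio * float(row.incidence_per_1000py) / 1000.0
        mort = float(row.mortality_per_10000py) / 10000.0
        band_prob = hazard * width
        if band_prob > 1.0:
            warnings.warn("band hazard exceeds 1; capping", RuntimeWarning, stacklevel=2)
            band_prob = 1.0
        total += band_prob * survival
        survival *= np.exp(-(hazard + mort) * width)
    return float(min(total, 1.0))


def liability_distribution(model: LiabilityModel, step: float = 2e-4,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of measured liability L on a uniform grid.

    L is a finite sum of independent discrete terms (one per locus, one per
    covariate scheme), so its distribution is obtained by convolving the
    per-term shift atoms; atoms are snapped to a grid of spacing ``step``.
    Returns (grid values, probabilities).
    """
    terms = list(model.locus_shifts.values()) + list(model.covariate_shifts.values())
    lo = sum(min(t.shifts) for t in terms) if terms else 0.0
    hi = sum(max(t.shifts) for t in terms) if terms else 0.0
    n = int(np.ceil((hi - lo) / step)) + 1
    probs = np.zeros(n)
    probs[int(round(-lo / step))] = 1.0  # start: point mass at 0
    for t in terms:
        new = np.zeros(n)
        for shift, freq in zip(t.shifts, t.frequencies):
            k = int(round(shift / step))
            if k >= 0:
                new[k:] += freq * probs[:n - k]
            else:
                new[:k] += freq * probs[-k:]
        probs = new
    values = lo + step * np.arange(n)
    keep = probs > 0
    return values[keep], probs[keep]


def predicted_auc(model: LiabilityModel, method: str = "exact",
                  n_grid: int = 4001) -> float:
    """Model-implied AUC of measured liability against disease status.

    ``method="exact"`` convolves the per-term shift distributions and pair-
    counts cases against controls (ties at 1/2) over the resulting discrete
    liability distribution.  ``method="binormal"`` approximates L as
    N(0, V) and integrates the tilted normal mixture; slightly biased when
    the discrete sum is skewed.
    """
    V = model.variance_explained
    K = model.prevalence
    if V <= 0.0:
        return 0.5
    if method == "exact":
        values, probs = liability_distribution(model)
        risk = norm.sf((model.threshold - values) / np.sqrt(1.0 - V))
        f_case = probs * risk
        f_ctrl = probs * (1.0 - risk)
        f_case /= f_case.sum()
        f_ctrl /= f_ctrl.sum()
        F_ctrl_below = np.concatenate([[0.0], np.cumsum(f_ctrl)[:-1]])
        return float(np.sum(f_case * (F_ctrl_below + 0.5 * f_ctrl)))
    if method != "binormal":
        raise ValueError(f"method must be 'exact' or 'binormal', got {method!r}")
    grid = np.linspace(-8 * np.sqrt(V), 8 * np.sqrt(V), n_grid)
    dens = norm.pdf(grid, scale=np.sqrt(V))
    risk = posterior_risk(grid, V, K)
    f_case = dens * risk
    f_ctrl = dens * (1.0 - risk)
    f_case /= np.trapezoid(f_case, grid)
    f_ctrl /= np.trapezoid(f_ctrl, grid)
    # P(case > control) = int F_ctrl(l) f_case(l) dl
    from scipy.integrate import cumulative_trapezoid

    F_ctrl = cumulative_trapezoid(f_ctrl, grid, initial=0.0)
    return float(np.trapezoid(F_ctrl * f_case, grid))


# --------------------------------------------------------------------------
# weight-table and genotype I/O
# --------------------------------------------------------------------------

_WEIGHT_COLUMNS = ("rsid", "chrom", "pos", "risk_allele", "nonrisk_allele", "raf", "or")


def write_weights(weights: Iterable[SnpWeight], path) -> None:
    rows = [(w.rsid, w.chrom, w.pos, w.risk_allele, w.nonrisk_allele, w.raf, w.per_allele_or)
            for w in weights]
    pd.DataFrame(rows, columns=list(_WEIGHT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_weights(path) -> list[SnpWeight]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    return [
        SnpWeight(row["rsid"], str(row["chrom"]), int(row["pos"]), row["risk_allele"],
                  row["nonrisk_allele"], float(row["raf"]), float(row["or"]))
        for _, row in df.iterrows()
    ]


def dosages_from_vcf(path, weights: Sequence[SnpWeight]) -> pd.DataFrame:
    """Risk-allele dosage matrix (samples x rsID) from a VCF.

    Alleles are matched exactly against REF/ALT; the dosage is flipped when
    the risk allele is REF.  Strand flips are rejected: a record whose alleles
    only match after complementing is an error, and A/T or C/G SNPs require
    an exact allele match by construction.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    by_rsid = {w.rsid: w for w in weights}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        w = by_rsid.get(variant.ID)
        if w is None:
            continue
        ref, alts = variant.REF, variant.ALT
        if len(alts) != 1:
            raise ValueError(f"{w.rsid}: multi-allelic records are not supported")
        alt = alts[0]
        alt_dosage = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unk,3 hom-alt
        dose = np.where(alt_dosage == 3, 2.0, np.where(alt_dosage == 2, np.nan, alt_dosage))
        if (ref, alt) == (w.nonrisk_allele, w.risk_allele):
            data[w.rsid] = dose
        elif (ref, alt) == (w.risk_allele, w.nonrisk_allele):
            data[w.rsid] = 2.0 - dose
        else:
            flipped = (_COMPLEMENT.get(ref), _COMPLEMENT.get(alt))
            if flipped in {(w.nonrisk_allele, w.risk_allele), (w.risk_allele, w.nonrisk_allele)}:
                raise ValueError(f"{w.rsid}: strand flip detected ({ref}/{alt}); refusing to guess")
            raise ValueError(f"{w.rsid}: alleles {ref}/{alt} do not match weight table "
                             f"{w.nonrisk_allele}/{w.risk_allele}")
    absent = [w.rsid for w in weights if w.rsid not in data]
    if absent:
        raise ValueError(f"VCF lacks records for: {absent[:5]}{'...' if len(absent) > 5 else ''}")
    return pd.DataFrame(data, index=samples, columns=[w.rsid for w in weights])
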