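"""Synthetic cohorts with the statistical structure the risk models assume.

Generates Hardy-Weinberg genotypes at given risk-allele frequencies, draws
disease status from an additive liability-threshold model (total liability
N(0,1), threshold set by prevalence), simulates family history through one
first-degree relative with correlated liability, assigns multi-cohort labels,
and builds fixture life tables.  A bundled 47-SNP diabetic-CVD susceptibility
panel (control risk-allele frequencies and per-allele odds ratios from a
published Korean T2D case-control study) provides realistic weights.

The study conditions emulated by the defaults: 17% CVD prevalence among
adults with type 2 diabetes, liability heritability 0.5, four population
cohorts, ages 40-69.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import lognorm, truncnorm

from .liability import (
    CovariateScheme,
    LiabilityModel,
    LifeTable,
    SnpWeight,
    build_model,
    measured_liability,
)

__all__ = [
    "SimulationSpec",
    "CohortTable",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_logistic_covariates",
    "make_life_tables",
    "dcvd_panel_15",
    "dcvd_panel_47",
    "default_covariate_schemes",
]


# --------------------------------------------------------------------------
# bundled SNP panel and covariate schemes
# --------------------------------------------------------------------------

# (rsid, chrom, nonrisk, risk, control RAF, per-allele OR).  The first 15 rows
# are previously reported CVD SNPs replicated in the source study; the rest
# reached p < 1e-4 there.  Genomic positions were not published; placeholder
# positions (1-based, synthetic) are assigned so the records remain valid.
_PANEL_47 = (
    ("rs4621553", "5", "A", "G", 0.05, 1.05),
    ("rs9818870", "3", "C", "T", 0.01, 1.08),
    ("rs599839", "1", "A", "G", 0.06, 1.04),
    ("rs16893526", "6", "G", "A", 0.11, 1.03),
    ("rs879324", "16", "A", "G", 0.62, 1.02),
    ("rs1333042", "9", "A", "G", 0.65, 1.02),
    ("rs11610422", "12", "A", "G", 0.05, 1.04),
    ("rs17035270", "4", "C", "T", 0.04, 1.04),
    ("rs16851055", "3", "G", "A", 0.18, 1.02),
    ("rs2814993", "6", "G", "A", 0.01, 1.07),
    ("rs7865618", "9", "G", "A", 0.86, 1.02),
    ("rs12801636", "11", "A", "G", 0.49, 1.02),
    ("rs6706785", "2", "G", "T", 0.27, 1.02),
    ("rs17006292", "2", "C", "A", 0.03, 1.05),
    ("rs3782889", "12", "G", "A", 0.83, 1.02),
    ("rs4538911", "8", "C", "G", 0.06, 1.08),
    ("rs9982069", "21", "G", "A", 0.38, 1.04),
    ("rs17465734", "16", "T", "A", 0.01, 1.14),
    ("rs7946015", "11", "A", "T", 0.17, 1.04),
    ("rs5768165", "22", "G", "T", 0.05, 1.07),
    ("rs2338258", "22", "T", "C", 0.07, 1.06),
    ("rs5768143", "22", "C", "T", 0.07, 1.05),
    ("rs17072597", "4", "C", "T", 0.14, 1.05),
    ("rs16864293", "2", "T", "A", 0.04, 1.08),
    ("rs1053226", "5", "C", "T", 0.02, 1.11),
    ("rs41326844", "2", "T", "C", 0.36, 1.03),
    ("rs6555242", "5", "T", "G", 0.03, 1.09),
    ("rs16956185", "18", "G", "A", 0.08, 1.06),
    ("rs1503908", "10", "A", "G", 0.12, 1.05),
    ("rs319025", "11", "T", "C", 0.56, 1.03),
    ("rs6893667", "5", "C", "T", 0.02, 1.10),
    ("rs877455", "14", "G", "A", 0.05, 1.07),
    ("rs1001715", "11", "G", "A", 0.33, 1.03),
    ("rs12276510", "11", "G", "A", 0.33, 1.03),
    ("rs2450153", "8", "G", "A", 0.52, 1.03),
    ("rs3843918", "8", "T", "C", 0.44, 1.03),
    ("rs1872125", "19", "T", "C", 0.16, 1.04),
    ("rs9506827", "13", "T", "C", 0.20, 1.04),
    ("rs8016145", "14", "G", "A", 0.04, 1.08),
    ("rs349083", "11", "G", "A", 0.36, 1.03),
    ("rs10968749", "9", "A", "G", 0.12, 1.04),
    ("rs9586032", "13", "G", "A", 0.15, 1.04),
    ("rs2825256", "21", "T", "A", 0.55, 1.03),
    ("rs2913472", "5", "A", "C", 0.02, 1.11),
    ("rs4575680", "2", "G", "C", 0.04, 1.07),
    ("rs10501726", "11", "A", "T", 0.04, 1.08),
    ("rs767164", "10", "T", "A", 0.21, 1.04),
)


def dcvd_panel_47() -> list[SnpWeight]:
    """The bundled 47-SNP diabetic-CVD panel (control RAFs, per-allele ORs)."""
    return [
        SnpWeight(rsid, chrom, 1_000_000 * (i + 1), risk, nonrisk, raf, oddsratio)
        for i, (rsid, chrom, nonrisk, risk, raf, oddsratio) in enumerate(_PANEL_47)
    ]


def dcvd_panel_15() -> list[SnpWeight]:
    """The 15 previously reported SNPs in the bundled panel."""
    return dcvd_panel_47()[:15]


# Raw-value distributions behind the default categorical covariates.  Tertile
# cut points sit at the distribution's 1/3 and 2/3 quantiles so the stated
# category frequencies hold exactly.  Category ORs approximate published
# per-unit effects (per-year age OR 1.06, per-kg/m2 BMI OR 1.09, per-mg/dL
# creatinine OR 2.02, male sex OR 1.07) applied over the between-tertile gap.
_AGE_DIST = truncnorm((40 - 57) / 9, (69 - 57) / 9, loc=57, scale=9)
_BMI_DIST = lognorm(s=0.12, scale=25.0)
_CREAT_DIST = lognorm(s=0.25, scale=0.88)
_COVARIATE_DISTS = {"age": _AGE_DIST, "bmi": _BMI_DIST, "creatinine": _CREAT_DIST}

_TERTILE = (1 / 3, 1 / 3, 1 / 3)


def default_covariate_schemes() -> list[CovariateScheme]:
    """Age/sex/BMI/creatinine schemes matching the nongenetic risk model."""
    return [
        CovariateScheme("age", _TERTILE, (1.0, 1.7, 2.9)),
        CovariateScheme("sex", (0.48, 0.52), (1.0, 1.07)),
        CovariateScheme("bmi", _TERTILE, (1.0, 1.35, 1.8)),
        CovariateScheme("creatinine", _TERTILE, (1.0, 1.2, 1.45)),
    ]


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Conditions for one simulated cohort.

    Defaults are the study conditions the models assume: prevalence 0.17,
    heritability 0.5, the bundled 47-SNP panel, the four-factor nongenetic
    scheme, four cohorts.
    """

    n_samples: int = 2378
    snp_weights: Sequence[SnpWeight] = field(default_factory=dcvd_panel_47)
    covariate_schemes: Sequence[CovariateScheme] = field(default_factory=default_covariate_schemes)
    prevalence: float = 0.17
    heritability: float = 0.5
    fh_relative_correlation: float | None = None  # default 0.5 * h2
    n_cohorts: int = 4
    seed: int = 0
    effect_scale: str = "or"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError(f"heritability must be in [0,1], got {self.heritability}")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")

    @property
    def relative_correlation(self) -> float:
        if self.fh_relative_correlation is not None:
            return self.fh_relative_correlation
        return 0.5 * self.heritability


@dataclass
class CohortTable:
    """One simulated (or loaded) cohort: genotype dosages, covariates and
    their 0/1/2 category codes, disease status, family history, cohort label,
    and — when simulated — the true total liability."""

    genotypes: pd.DataFrame
    categories: pd.DataFrame
    covariates: pd.DataFrame
    status: pd.Series
    family_history: pd.Series
    cohort: pd.Series
    liability: pd.Series | None = None
    model: LiabilityModel | None = None

    @property
    def n(self) -> int:
        return len(self.status)

    @property
    def samples(self) -> pd.Index:
        return self.status.index

    def measured_liability(self) -> pd.Series:
        """Measured (genetic + covariate) liability under the generating
        model; only available on simulated cohorts that carry their model."""
        if self.model is None:
            raise ValueError("cohort has no attached liability model")
        return measured_liability(
            self.model,
            dosages=self.genotypes if not self.genotypes.empty else None,
            categories=self.categories if not self.categories.empty else None,
        )

    def write(self, prefix: str) -> None:
        """Write dosages and sample table as TSV (``{prefix}.dosages.tsv``,
        ``{prefix}.samples.tsv``)."""
        self.genotypes.to_csv(f"{prefix}.dosages.tsv", sep="\t", index_label="sample")
        samp = pd.concat(
            [
                self.status.rename("status"),
                self.family_history.rename("family_history"),
                self.cohort.rename("cohort"),
                self.covariates,
                self.categories.add_prefix("cat_"),
            ],
            axis=1,
        )
        if self.liability is not None:
            samp["liability"] = self.liability
        samp.to_csv(f"{prefix}.samples.tsv", sep="\t", index_label="sample")

    @classmethod
    def read(cls, prefix: str) -> "CohortTable":
        geno = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col="sample")
        samp = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample")
        cat_cols = [c for c in samp.columns if c.startswith("cat_")]
        categories = samp[cat_cols].rename(columns=lambda c: c[4:])
        cov_cols = [c for c in samp.columns
                    if c not in {"status", "family_history", "cohort", "liability"}
                    and not c.startswith("cat_")]
        liab = samp["liability"] if "liability" in samp.columns else None
        return cls(
            genotypes=geno,
            categories=categories,
            covariates=samp[cov_cols],
            status=samp["status"],
            family_history=samp["family_history"],
            cohort=samp["cohort"],
            liability=liab,
        )

    def write_vcf(self, path, weights: Sequence[SnpWeight]) -> None:
        """Minimal VCF (GT only; REF = non-risk allele, ALT = risk allele)."""
        by_rsid = {w.rsid: w for w in weights}
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(w.chrom for w in weights):
                fh.write(f"##contig=<ID={chrom}>\n")
            cols = "\t".join(self.samples)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            for rsid in self.genotypes.columns:
                w = by_rsid[rsid]
                gts = "\t".join(gt_map.get(int(d), "./.") if not np.isnan(d) else "./."
                                for d in self.genotypes[rsid].to_numpy(dtype=float))
                fh.write(f"{w.chrom}\t{w.pos}\t{w.rsid}\t{w.nonrisk_allele}\t"
                         f"{w.risk_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_genotypes(rafs, n: int, seed) -> np.ndarray:
    """HWE genotype dosages: column j ~ Binomial(2, raf_j) i.i.d. over samples.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rafs = np.asarray(rafs, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any((rafs <= 0.0) | (rafs >= 1.0)):
        raise ValueError("risk-allele frequencies must be in (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, rafs, size=(n, rafs.size)).astype(np.int8)


def _raw_from_category(name: str, cats: np.ndarray, scheme: CovariateScheme,
                       rng: np.random.Generator) -> np.ndarray | None:
    """Raw covariate values consistent with the drawn category, for covariates
    with a registered marginal distribution (inverse-CDF within the category's
    quantile band)."""
    if name == "sex":
        return cats.astype(int)
    dist = _COVARIATE_DISTS.get(name)
    if dist is None or scheme.n_categories != 3:
        return None
    bounds = np.concatenate([[0.0], np.cumsum(scheme.category_frequencies)])
    u = rng.uniform(bounds[cats], bounds[cats + 1])
    return dist.ppf(u)


def simulate_cohort(spec: SimulationSpec) -> CohortTable:
    """Draw a cohort from the liability-threshold model.

    Total liability = genetic shifts + covariate shifts + N(0, 1 - V)
    residual; disease iff liability > threshold; family history from one
    first-degree relative whose liability correlates at ``0.5 * h2`` and who
    is affected iff their own liability exceeds the threshold; cohort labels
    uniform.
    """
    rng = np.random.default_rng(spec.seed)
    model = build_model(spec.snp_weights, spec.covariate_schemes,
                        spec.prevalence, spec.heritability, spec.effect_scale)
    n = spec.n_samples
    samples = pd.Index([f"S{i:06d}" for i in range(n)], name="sample")

    rafs = [w.raf for w in spec.snp_weights]
    geno = simulate_genotypes(rafs, n, rng) if spec.snp_weights else np.empty((n, 0), dtype=np.int8)
    genotypes = pd.DataFrame(geno, index=samples,
                             columns=[w.rsid for w in spec.snp_weights])

    cat_data, raw_data = {}, {}
    for scheme in spec.covariate_schemes:
        cats = rng.choice(scheme.n_categories, size=n,
                          p=np.asarray(scheme.category_frequencies))
        cat_data[scheme.name] = cats
        raw = _raw_from_category(scheme.name, cats, scheme, rng)
        if raw is not None:
            raw_data[scheme.name] = raw
    categories = pd.DataFrame(cat_data, index=samples, dtype=int)
    covariates = pd.DataFrame(raw_data, index=samples)

    if spec.snp_weights or spec.covariate_schemes:
        L = measured_liability(
            model,
            dosages=genotypes if spec.snp_weights else None,
            categories=categories if spec.covariate_schemes else None,
        )
    else:
        L = pd.Series(0.0, index=samples)
    V = model.variance_explained
    liability = L + rng.normal(0.0, np.sqrt(1.0 - V), n)
    status = (liability > model.threshold).astype(int)

    rho = spec.relative_correlation
    rel_liability = rho * liability + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    family_history = (rel_liability > model.threshold).astype(int)

    cohort = pd.Series(
        [f"cohort{i + 1}" for i in rng.integers(0, spec.n_cohorts, size=n)],
        index=samples, name="cohort",
    )
    return CohortTable(
        genotypes=genotypes,
        categories=categories,
        covariates=covariates,
        status=pd.Series(status, index=samples, name="status"),
        family_history=pd.Series(family_history, index=samples, name="family_history"),
        cohort=cohort,
        liability=pd.Series(liability, index=samples, name="liability"),
        model=model,
    )


def simulate_logistic_covariates(n: int, effects: Sequence[tuple[str, float, float, float]],
                                 prevalence: float = 0.17, seed: int = 0,
                                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Continuous covariates with a logistic outcome, for association testing.

    ``effects`` is a sequence of (name, mean, sd, per_unit_or); the intercept
    is set so the outcome probability at the covariate means equals
    ``prevalence``.  Returns (design with 'const' column, outcome).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({name: rng.normal(mean, sd, n) for name, mean, sd, _ in effects})
    betas = np.array([np.log(o) for *_, o in effects])
    means = np.array([m for _, m, _, _ in effects])
    alpha = np.log(prevalence / (1 - prevalence)) - betas @ means
    eta = alpha + X.to_numpy() @ betas
    y = pd.Series(rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))), name="status")
    X.insert(0, "const", 1.0)
    return X, y


# --------------------------------------------------------------------------
# fixture life tables
# --------------------------------------------------------------------------

def make_life_tables(base_ir_female: float = 15.67, base_ir_male: float = 13.47,
                     mort_male: float = 19.5, mort_female: float = 7.3,
                     age_bands: Sequence[tuple[float, float]] | None = None) -> LifeTable:
    """Fixture life table with constant sex-specific rates across age bands.

    Default rates are the published sex-aggregate summaries: DCVD incidence
    15.67 (women) and 13.47 (men) per 1000 person-years; disease-free
    mortality 19.5 (men) and 7.3 (women) per 10,000 people.  Default bands:
    5-year bands covering ages 40-70.
    """
    for rate in (base_ir_female, base_ir_male, mort_male, mort_female):
        if rate < 0:
            raise ValueError("rates must be non-negative")
    if age_bands is None:
        age_bands = [(a, a + 5) for a in range(40, 70, 5)]
    rows = []
    for lo, hi in age_bands:
        rows.append((lo, hi, "F", base_ir_female, mort_female))
        rows.append((lo, hi, "M", base_ir_male, mort_male))
    return LifeTable(pd.DataFrame(rows, columns=list(LifeTable.COLUMNS)))
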