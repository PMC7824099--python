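"""End-to-end orchestration: simulate -> score -> stratify -> evaluate.

One config drives a full run producing, per SNP panel, the six model
variants — nongenetic liability (nGLT) and risk score (nGRS), genetic
liability (GLT) and polygenic risk score (PRS), multifactorial liability
(MLT) and risk score (MRS) — each liability model additionally with the
family-history update applied.  Outputs land in a run directory as TSV/JSON
together with a machine-readable manifest (config hash, seed, versions).

The multifactorial combinations: MLT sums the genetic and nongenetic
liability shifts before the posterior-risk mapping (exact on the liability
scale); MRS averages the 0-10 normalized PRS and nongenetic score, the
minimal combination on their common scale (recorded in output metadata).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import continuous_nri, evaluate_scores, kfold_cv, per_cohort_eval
from .liability import (
    build_model,
    family_history_update,
    lifetime_risk,
    measured_liability,
    posterior_risk,
    read_weights,
)
from .scores import compute_covariate_score, compute_prs, minmax_normalize
from .stratify import dichotomize, quartile_assign
from .synthetic import (
    SimulationSpec,
    dcvd_panel_47,
    default_covariate_schemes,
    make_life_tables,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; all randomness flows from ``seed``."""

    n_samples: int = 2378
    prevalence: float = 0.17
    heritability: float = 0.5
    seed: int = 0
    n_cohorts: int = 4
    effect_scale: str = "or"
    weights_path: str | None = None          # default: bundled 47-SNP panel
    panels: dict = field(default_factory=lambda: {"47": 47})  # name -> size or rsid list
    family_history: str = "conditional"      # conditional | off
    cutoffs: dict = field(default_factory=dict)  # model name -> score cutoff
    k_folds: int = 10
    start_age: float = 40.0
    out_dir: str = "dcvdrisk_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0,1]")
        if self.family_history not in {"conditional", "off"}:
            raise ValueError("family_history must be 'conditional' or 'off'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _logistic_risk(score: pd.Series, status: pd.Series) -> pd.Series:
    """In-sample predicted probabilities from a univariate logistic fit,
    used to place score-based models on the risk scale for NRI."""
    from .association import fit_logistic

    design = pd.DataFrame({"const": 1.0, "score": score})
    fit = fit_logistic(design, status)
    eta = fit.coefficients["const"] + fit.coefficients["score"] * score
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=score.index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis under one config and write the run directory.

    Returns the results dict that is also written as ``results.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    weights = read_weights(config.weights_path) if config.weights_path else dcvd_panel_47()
    schemes = default_covariate_schemes()
    spec = SimulationSpec(
        n_samples=config.n_samples,
        snp_weights=weights,
        covariate_schemes=schemes,
        prevalence=config.prevalence,
        heritability=config.heritability,
        n_cohorts=config.n_cohorts,
        seed=config.seed,
        effect_scale=config.effect_scale,
    )
    cohort = simulate_cohort(spec)
    status = cohort.status
    life = make_life_tables()

    # per-panel sub-models (marginal per-locus shifts, panel-specific V)
    panels: dict[str, list] = {}
    for name, sel in config.panels.items():
        if isinstance(sel, int):
            panels[name] = weights[:sel]
        else:
            by_rsid = {w.rsid: w for w in weights}
            panels[name] = [by_rsid[r] for r in sel]

    ng_model = build_model([], schemes, config.prevalence, config.heritability,
                           config.effect_scale)
    raw: dict[str, pd.Series] = {}
    variance: dict[str, float] = {}
    lt_models: dict[str, object] = {}

    raw["nGLT"] = measured_liability(ng_model, categories=cohort.categories)
    variance["nGLT"] = ng_model.variance_covariate
    lt_models["nGLT"] = ng_model
    raw["nGRS"] = compute_covariate_score(cohort.categories, schemes)

    for name, pw in panels.items():
        g_model = build_model(pw, [], config.prevalence, config.heritability,
                              config.effect_scale)
        m_model = build_model(pw, schemes, config.prevalence, config.heritability,
                              config.effect_scale)
        rsids = [w.rsid for w in pw]
        raw[f"GLT_{name}"] = measured_liability(g_model, dosages=cohort.genotypes[rsids])
        variance[f"GLT_{name}"] = g_model.variance_genetic
        lt_models[f"GLT_{name}"] = g_model
        raw[f"MLT_{name}"] = measured_liability(
            m_model, dosages=cohort.genotypes[rsids], categories=cohort.categories)
        variance[f"MLT_{name}"] = m_model.variance_explained
        lt_models[f"MLT_{name}"] = m_model
        raw[f"PRS_{name}"] = compute_prs(cohort.genotypes, pw)

    # family-history variants of the liability models
    if config.family_history == "conditional":
        for model_name in list(lt_models):
            L = raw[model_name]
            raw[f"{model_name}_fh"] = pd.Series(
                family_history_update(L, lt_models[model_name],
                                      cohort.family_history.loc[L.index]),
                index=L.index,
            )
            variance[f"{model_name}_fh"] = variance[model_name]

    # normalized scores (reference = full analysis sample) and MRS averages;
    # constant scores (e.g. a null panel) cannot be min-max normalized and
    # are carried through as degenerate
    normalized = {name: (minmax_normalize(s, score_type=name) if s.nunique() > 1 else None)
                  for name, s in raw.items()}
    for name in panels:
        if normalized[f"PRS_{name}"] is None or normalized["nGRS"] is None:
            continue
        mrs = (normalized[f"PRS_{name}"].normalized + normalized["nGRS"].normalized) / 2.0
        raw[f"MRS_{name}"] = mrs
        normalized[f"MRS_{name}"] = minmax_normalize(mrs, score_type=f"MRS_{name}")

    results: dict = {"models": {}, "nri": {}, "metadata": {
        "mrs_rule": "mean of 0-10 normalized PRS and nongenetic score",
        "quartile_reference": "pooled sample",
        "family_history": config.family_history,
    }}
    for name, series in raw.items():
        y = status.loc[series.index]
        norm_values = normalized[name].normalized if normalized[name] is not None else None
        report = evaluate_scores(series, y, norm_values)
        quart = None
        if norm_values is None:
            report.extra["degenerate"] = "constant score"
        else:
            report.extra["cv"] = kfold_cv(series, y, k=config.k_folds, seed=config.seed)
            report.extra["per_cohort"] = per_cohort_eval(
                series, y, cohort.cohort.loc[series.index],
                norm_values).to_dict(orient="records")
            quart = quartile_assign(series, y)
            report.extra["quartiles"] = {
                "boundaries": list(quart.boundaries),
                "counts": quart.counts.to_dict(),
                "q4_vs_q1_or": (quart.q4_vs_q1.oddsratio if quart.q4_vs_q1.estimable else None),
            }
        if name in config.cutoffs:
            counts, metrics = dichotomize(series, y, config.cutoffs[name])
            report.extra["discrete"] = {
                "cutoff": config.cutoffs[name],
                "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
                "sensitivity": metrics["sensitivity"],
                "specificity": metrics["specificity"],
                "percent_correct": metrics["percent_correct"],
            }
        results["models"][name] = report.to_dict()

        table = pd.DataFrame({"raw": series, "status": y})
        if norm_values is not None:
            table["normalized"] = norm_values
            table["quartile"] = quart.labels
        if name in variance:  # liability models: risk scale + lifetime risk
            post = posterior_risk(series, variance[name], config.prevalence)
            table["posterior_risk"] = post
            sex = cohort.covariates["sex"].loc[series.index] if "sex" in cohort.covariates else 0
            ratio = post / config.prevalence
            table["lifetime_risk"] = [
                lifetime_risk(r, life, "M" if s == 1 else "F", config.start_age)
                for r, s in zip(ratio, np.broadcast_to(np.asarray(sex), post.shape))
            ]
        table.to_csv(out / f"scores_{name}.tsv", sep="\t", index_label="sample")

    # NRI: effect of adding genetic information to the nongenetic model
    for name in panels:
        for base, new, kind in (("nGLT", f"MLT_{name}", "lt"),
                                ("nGRS", f"MRS_{name}", "rs")):
            if base not in raw or new not in raw:
                continue
            idx = raw[base].index.intersection(raw[new].index)
            y = status.loc[idx]
            if kind == "lt":
                r_old = posterior_risk(raw[base].loc[idx], variance[base], config.prevalence)
                r_new = posterior_risk(raw[new].loc[idx], variance[new], config.prevalence)
            else:
                r_old = _logistic_risk(normalized[base].normalized.loc[idx], y)
                r_new = _logistic_risk(normalized[new].normalized.loc[idx], y)
            results["nri"][f"{base}_to_{new}"] = continuous_nri(r_old, r_new, y)

    cohort.write(str(out / "cohort"))
    life.to_tsv(out / "life_table.tsv")
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "dcvdrisk_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results
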