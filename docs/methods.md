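# Methods

## The liability-threshold model

Disease status is modelled as the visible tail of a latent liability that is
standard normal in the population: an individual is affected when their
liability exceeds `T = Φ⁻¹(1 − K)`, where `K` is the disease prevalence
(default 0.17, the CVD prevalence among Korean adults with type 2 diabetes;
`T ≈ 0.9542`). Measured risk factors shift the liability mean; the residual
`e ~ N(0, 1 − V)` carries everything unmeasured, so total liability remains
N(0, 1) marginally and the threshold reproduces the prevalence exactly.

### From published effect sizes to liability shifts

Each SNP enters with a risk-allele frequency `p` (Hardy–Weinberg genotype
frequencies `(1−p)², 2p(1−p), p²`) and a per-allele odds ratio expanded
multiplicatively over genotypes as `(1, OR, OR²)`. Genotype penetrances
`f_g` are solved under the prevalence constraint `Σ P(g)·f_g = K`:
on the odds scale by bracketed root-finding on the baseline log-odds
(`brentq`, tolerance 1e−12), or directly on the risk scale when effects are
supplied as genotypic risk ratios (`effect_scale="rr"`). Whether published
per-SNP coefficients are odds ratios or another scale is often ambiguous;
the engine treats them as per-allele ORs by default and exposes the
risk-ratio alternative.

The per-genotype mean shifts `μ_g` then satisfy
`1 − Φ((T − μ_g)/√(1 − v)) = f_g`, where `v = Σ P(g)(μ_g − μ̄)²` is the
variance the locus explains. Because `v` depends on the shifts, the map
`μ → v` is iterated to a fixed point (tolerance 1e−10, damping 0.5 on
oscillation, 100-iteration cap); each `μ_g` is found by bracketed
root-finding on `[−8, 8]` liability units (tolerance 1e−10). Shifts are
returned centered (`Σ P(g)·μ_g = 0` to machine precision). Categorical
covariates (coded 0/1 or 0/1/2) use the identical machinery with category
frequencies and category ORs. Variances add over independent terms;
a total `V ≥ 1` raises a model-misspecification error.

Degenerate inputs: a unit odds ratio short-circuits to zero shifts; a zero
category frequency, a RAF outside (0, 1), or an effect implying penetrance
≥ 1 at the given prevalence are rejected with explicit errors.

### Family history

Family history is a conditional-liability update, not an extra covariate:
relative liabilities correlate at `ρ = 0.5·h²` (first-degree kinship), and
the mean liability of an affected relative is `φ(T)/K`, so one affected
first-degree relative adds `Δ = 0.5·(h² − V_g)·φ(T)/K` to the *unmeasured*
polygenic part (variance `h² − V_g`, clamped at 0 when the measured panel
already captures more than `h²`). Missing family-history data is treated as
absent (`fh = 0`), matching how such models are reported with family history
as a toggle.

### Posterior and lifetime risk

Posterior disease probability is `1 − Φ((T − L)/√(1 − V))`, strictly
increasing in `L`, equal to `K` at `L = 0, V = 0`, and integrating back to
`K` over the population (verified by simulation). Lifetime risk walks an
age×sex life table from a start age: per band, the individual hazard is
(posterior risk / K) × band incidence per person-year, disease-free survival
decays as `exp(−(hazard + mortality)·width)`, and the risk accumulates as
hazard × band-entry survival × width (left-rectangle cumulation; exact as
band width → 0, and within 2% of the closed-form `1 − e^(−λT)` for 1-year
bands at realistic rates). Band probabilities above 1 are capped with a
warning, the cumulative risk at 1.

The model-implied AUC of measured liability is computed exactly by
convolving the per-term shift atoms onto a fine grid (step 2e−4 liability
units) and pair-counting the risk-tilted case and control distributions
(ties at 1/2). A binormal `N(0, V)` approximation is also available; it is
visibly biased (~0.002 here) because the discrete liability sum is slightly
skewed, which is why the exact form is the default and the cross-module
consistency test compares the exact form against the empirical rank AUC.

## Scores, stratification, evaluation

- **PRS** uses natural-log odds ratios (the regression-coefficient
  convention): `Σ ln(ORᵢ)·xᵢ`, complete-case over the panel.
- **Min-max normalization** to 0–10 is fitted once on the full analysis
  sample and its `(x_min, x_range)` persisted; held-out values outside the
  reference range clip to [0, 10] with a recorded count. The map is strictly
  increasing, so all rank statistics (AUC) are unchanged.
- **Discrete models** classify high risk as score ≥ cutoff ("0.21 or
  greater" convention). A risk group with no cases yields an unestimable
  odds ratio, reported as a flag rather than an error. How a published
  cutoff was chosen is generally unstated; the cutoff is therefore an input,
  with a clearly labelled Youden-J search offered as an extension.
- **Quartiles** are cut at the pooled-sample 25/50/75th percentiles (linear
  interpolation); boundary ties go to the lower group. Pooling cases and
  controls is the conservative default when the reference population is
  unspecified, and is recorded in output metadata.
- **AUC** is the Mann–Whitney statistic with ties at 1/2; its CI is
  DeLong-type (midrank structural components), chosen for determinism. The
  implementation was cross-checked to 10 decimals against R `pROC`'s DeLong
  interval on a frozen fixture.
- **Continuous NRI**: `NRI_e = P(new>old|case) − P(new<old|case)`,
  `NRI_ne = P(new<old|control) − P(new>old|control)`, ties contributing to
  neither (the standard convention), overall = sum. Score-based models are
  placed on the risk scale via an in-sample univariate logistic fit before
  NRI comparison; liability models use their posterior risks.
- **Cross-validation** uses stratified folds (with ~7% cases, unstratified
  10-fold splits would risk case-free folds); normalization parameters are
  refitted on training folds only. **Per-cohort** evaluation skips strata
  with a single outcome class, logging the reason.
- **Logistic regression** is Newton IRLS (statsmodels; tolerance 1e−8, max
  100 iterations), complete-case with `n_used` reported, Wald CIs and
  p-values (their magnitudes match published univariate tables, verified on
  the drinking/smoking rows). Perfect separation is flagged
  `converged=False` with a warning instead of raising. Backward stepwise
  elimination drops the worst Wald p ≥ α (default 0.05) one term at a time,
  ties broken toward the earlier column, making the path deterministic.

## The synthetic cohort generator

The generator defines the study conditions everything downstream is tested
under; its defaults are fixed, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| prevalence `K` | 0.17 | CVD prevalence in Korean adults with T2D |
| heritability `h²` | 0.5 | reported liability heritability for CVD |
| SNP panel | bundled 47-SNP DCVD panel | published control RAFs and per-allele ORs (1.02–1.14) |
| covariates | age, sex, BMI, creatinine | the factors retained by multivariate selection |
| relative correlation | `0.5·h²` | first-degree polygenic kinship |
| cohorts | 4, uniform | supports per-cohort evaluation without cohort effects |
| n (pipeline default) | 2378 | the source study's analysis sample |

Genotypes are i.i.d. `Binomial(2, p)` per locus (exact Hardy–Weinberg).
Disease status thresholds the total liability (measured shifts + N(0, 1−V)
residual). Family history: one relative with liability `ρ·L + √(1−ρ²)·z`,
affected iff above `T`. Covariate categories are drawn from their scheme
frequencies; raw age/BMI/creatinine values are back-filled by inverse-CDF
sampling within the drawn tertile band (age truncated-normal(57, 9) on
[40, 69]; BMI and creatinine lognormal around the published means), and the
tertile ORs approximate the published per-unit ORs (1.06/year,
1.09/kg·m⁻², 2.02/mg·dL⁻¹, male 1.07) applied over the between-tertile gap.
The fixture life table carries the published sex-aggregate summary rates
(incidence 15.67/13.47 per 1000 person-years for women/men; disease-free
mortality 19.5/7.3 per 10,000 for men/women) held constant across 5-year
bands from 40 to 70 — the underlying age-resolved national tables are not
public, so absolute lifetime-risk values are illustrative.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium between loci, population
stratification or cohort-specific effects, genotyping error and
missingness patterns, covariate measurement error, and real covariate
correlation structure. Tests against it validate the *statistical
machinery* (calibration, recovery, invariances), not real-data predictive
performance; in particular, headline real-data AUC/NRI figures from
restricted cohort data (e.g. AUC 0.99 with a 231-SNP panel, which the
original authors themselves flag as likely overfitting) are out of scope,
and under honest published effect sizes the bundled panel supports only a
modest genetic AUC (~0.52–0.55 at n≈2400).

## Pipeline and problem sizes

`run_pipeline` builds, per configured panel, the six model variants (nGLT,
nGRS, GLT, PRS, MLT, MRS) plus family-history variants of the liability
models. MLT sums genetic and nongenetic liability shifts before the
posterior-risk mapping (exact on the liability scale, verified to 1e−10);
MRS averages the two 0–10 normalized scores — the published combination
rule for score-based multifactorial models is unstated, and averaging on
the common scale is the minimal choice, recorded in output metadata.
Constant (degenerate) scores — e.g. a deliberately null panel — skip
normalization, quartiles and CV, and are flagged. Every output directory
carries a manifest with the config hash, seed, and package/library
versions; reruns from the same config are byte-identical.

The test suite simulates cohorts of 200,000 (calibration at 3-SE
tolerances), 4,000 (rank statistics), and ~1,200–2,400 (pipeline and power
checks); the acceptance script uses 200,000 for calibration and 10⁶ draws
for the single-locus Monte-Carlo penetrance oracle. These sizes put
Monte-Carlo error comfortably inside the stated tolerances while keeping a
full run in tens of seconds.

## Known limitations

- Additive liability only: no dominance, epistasis, or LD-aware adjustment;
  per-SNP weights are inputs, never re-estimated from cohort data.
- The odds→penetrance conversion assumes multiplicative genotypic odds; true
  genotypic risk patterns that deviate from this are mis-specified unless
  supplied as risk ratios.
- Lifetime-risk scaling multiplies band incidence by the posterior risk
  ratio (how published "incidence-based" rankings combine the two is not
  fully specified); a posterior-only ranking can be assembled from the same
  primitives.
- Wald inference throughout; profile-likelihood or bootstrap intervals are
  not implemented (DeLong covers the AUC case deterministically).
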