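"""Liability-threshold engine: threshold, shifts, risk, lifetime risk."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dcvdrisk import (
    CovariateScheme,
    LifeTable,
    ModelSpecificationError,
    SnpWeight,
    build_model,
    covariate_effects,
    family_history_update,
    lifetime_risk,
    locus_effects,
    make_life_tables,
    measured_liability,
    posterior_risk,
    predicted_auc,
    read_weights,
    threshold_from_prevalence,
    write_weights,
)
from dcvdrisk.synthetic import dcvd_panel_47


def _weight(raf, oddsratio, rsid="rsX"):
    return SnpWeight(rsid, "1", 1, "G", "A", raf, oddsratio)


class TestThreshold:
    @pytest.mark.parametrize(
        "prevalence, expected, decimals",
        [(0.5, 0.0, 10), (0.17, 0.9542, 4), (norm.sf(3), 3.0, 6)],
    )
    def test_known_quantiles(self, prevalence, expected, decimals):
        assert threshold_from_prevalence(prevalence) == pytest.approx(
            expected, abs=10.0 ** -decimals)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prevalence(self, bad):
        with pytest.raises(ValueError):
            threshold_from_prevalence(bad)


class TestLocusEffects:
    def test_null_locus_has_no_shifts(self):
        eff = locus_effects(_weight(0.3, 1.0), 0.17)
        assert eff.shifts == (0.0, 0.0, 0.0)
        assert eff.variance == 0.0

    @pytest.mark.parametrize("raf, oddsratio, prevalence",
                             [(0.27, 1.5, 0.17), (0.05, 1.14, 0.17),
                              (0.62, 1.02, 0.17), (0.3, 2.0, 0.05)])
    def test_centering_and_prevalence_constraints(self, raf, oddsratio, prevalence):
        """Shifts are mean-zero and penetrances average back to the prevalence."""
        eff = locus_effects(_weight(raf, oddsratio), prevalence)
        freqs = np.asarray(eff.frequencies)
        assert abs(freqs @ np.asarray(eff.shifts)) < 1e-10
        assert freqs @ np.asarray(eff.penetrances) == pytest.approx(prevalence, abs=1e-8)
        assert eff.variance > 0

    def test_monte_carlo_penetrance_ratio(self, rng):
        """Simulating genotype shifts + residual reproduces the input genotypic
        risk ratios (1, 1.5, 2.25) within 2%."""
        eff = locus_effects(_weight(0.27, 1.5), 0.17, effect_scale="rr")
        g = rng.binomial(2, 0.27, 1_000_000)
        liab = np.asarray(eff.shifts)[g] + rng.normal(0, np.sqrt(1 - eff.variance), g.size)
        affected = liab > threshold_from_prevalence(0.17)
        f = np.array([affected[g == k].mean() for k in range(3)])
        assert f[1] / f[0] == pytest.approx(1.5, rel=0.02)
        assert f[2] / f[0] == pytest.approx(2.25, rel=0.02)

    def test_variance_additive_over_independent_loci(self):
        eff = locus_effects(_weight(0.27, 1.5), 0.17)
        model = build_model([_weight(0.27, 1.5, "rs1"), _weight(0.27, 1.5, "rs2")],
                            prevalence=0.17)
        assert model.variance_genetic == pytest.approx(2 * eff.variance, rel=1e-9)

    def test_effect_too_large_raises(self):
        with pytest.raises(ModelSpecificationError):
            locus_effects(_weight(0.5, 50.0), 0.17, effect_scale="rr")


class TestCovariateEffects:
    def test_null_scheme(self):
        eff = covariate_effects(
            CovariateScheme("x", (0.5, 0.5), (1.0, 1.0)), 0.17)
        assert eff.shifts == (0.0, 0.0)

    def test_ordinal_scheme_penetrances_increase(self):
        eff = covariate_effects(
            CovariateScheme("x", (0.25, 0.5, 0.25), (1.0, 2.0, 4.0)), 0.17)
        pen = np.asarray(eff.penetrances)
        assert np.all(np.diff(pen) > 0)
        assert np.asarray(eff.frequencies) @ pen == pytest.approx(0.17, abs=1e-8)

    def test_zero_frequency_category_rejected(self):
        with pytest.raises(ValueError):
            CovariateScheme("x", (0.0, 0.5, 0.5), (1.0, 2.0, 4.0))


class TestMeasuredLiability:
    def test_modal_category_null_model_is_zero(self):
        model = build_model([_weight(0.3, 1.0, "rs1")], prevalence=0.17)
        dosages = pd.DataFrame({"rs1": [0, 1, 2]})
        L = measured_liability(model, dosages=dosages)
        assert (L == 0).all()

    def test_additive_over_terms(self):
        w1, w2 = _weight(0.3, 1.3, "rs1"), _weight(0.1, 1.8, "rs2")
        model = build_model([w1, w2], prevalence=0.17)
        d = pd.DataFrame({"rs1": [2], "rs2": [1]})
        L = measured_liability(model, dosages=d)
        L1 = measured_liability(model, dosages=d[["rs1"]])
        L2 = measured_liability(model, dosages=d[["rs2"]])
        assert L.iloc[0] == pytest.approx(L1.iloc[0] + L2.iloc[0], abs=1e-12)

    def test_null_panel_padding_changes_nothing(self, rng):
        """Adding OR=1 loci to the panel leaves every liability unchanged."""
        active = [_weight(0.3, 1.4, "rs1")]
        nulls = [_weight(0.2, 1.0, f"null{i}") for i in range(5)]
        d = pd.DataFrame({"rs1": rng.integers(0, 3, 50)} |
                         {f"null{i}": rng.integers(0, 3, 50) for i in range(5)})
        L_small = measured_liability(build_model(active, prevalence=0.17),
                                     dosages=d[["rs1"]])
        L_padded = measured_liability(build_model(active + nulls, prevalence=0.17),
                                      dosages=d)
        assert np.array_equal(L_small.to_numpy(), L_padded.to_numpy())

    def test_population_moments(self, large_cohort):
        """Measured liability is mean-zero with variance V over a cohort."""
        c = large_cohort
        L = measured_liability(c.model, dosages=c.genotypes, categories=c.categories)
        V = c.model.variance_explained
        assert L.mean() == pytest.approx(0.0, abs=4 * np.sqrt(V / c.n))
        assert L.var() == pytest.approx(V, rel=0.05)

    def test_complete_case_exclusion(self):
        model = build_model([_weight(0.3, 1.3, "rs1")], prevalence=0.17)
        d = pd.DataFrame({"rs1": [0.0, np.nan, 2.0]})
        L = measured_liability(model, dosages=d)
        assert list(L.index) == [0, 2]

    def test_unknown_rsid_raises(self):
        model = build_model([_weight(0.3, 1.3, "rs1")], prevalence=0.17)
        with pytest.raises(KeyError):
            measured_liability(model, dosages=pd.DataFrame({"rsZ": [1]}))


class TestFamilyHistory:
    def test_no_history_is_identity(self):
        model = build_model([], prevalence=0.17, heritability=0.5)
        assert family_history_update(1.3, model, 0) == 1.3

    def test_zero_heritability_no_shift(self):
        model = build_model([], prevalence=0.17, heritability=0.0)
        assert family_history_update(0.2, model, 1) == 0.2

    def test_conditional_shift_matches_bivariate_simulation(self, rng):
        """With h2=0.5 and no measured genetics, the family-history shift is
        the mean liability of people with an affected first-degree relative
        (bivariate normal, correlation 0.25)."""
        model = build_model([], prevalence=0.17, heritability=0.5)
        delta = family_history_update(0.0, model, 1)
        rho, n = 0.25, 1_000_000
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        sim = x[y > threshold_from_prevalence(0.17)].mean()
        assert delta == pytest.approx(sim, rel=0.05)


class TestPosteriorRisk:
    def test_population_baseline(self):
        assert posterior_risk(0.0, 0.0, 0.17) == pytest.approx(0.17)

    def test_at_threshold_is_half(self):
        T = threshold_from_prevalence(0.17)
        for V in (0.0, 0.3, 0.8):
            assert posterior_risk(T, V, 0.17) == pytest.approx(0.5)

    def test_monotone_in_liability(self):
        L = np.linspace(-3, 3, 50)
        risk = posterior_risk(L, 0.2, 0.17)
        assert np.all(np.diff(risk) > 0)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            posterior_risk(0.0, 1.0, 0.17)

    def test_mean_posterior_risk_is_prevalence(self, large_cohort):
        """Law of total probability: E[posterior risk] = K."""
        c = large_cohort
        L = measured_liability(c.model, dosages=c.genotypes, categories=c.categories)
        risk = posterior_risk(L, c.model.variance_explained, 0.17)
        se = np.sqrt(0.17 * 0.83 / c.n)
        assert risk.mean() == pytest.approx(0.17, abs=3 * se)

    def test_calibration_within_liability_bins(self, large_cohort):
        """Posterior risk matches the simulated disease rate bin by bin."""
        c = large_cohort
        L = measured_liability(c.model, dosages=c.genotypes, categories=c.categories)
        risk = posterior_risk(L, c.model.variance_explained, 0.17)
        bins = pd.qcut(L, 10, labels=False, duplicates="drop")
        for b in np.unique(bins):
            mask = bins == b
            observed = c.status[mask].mean()
            expected = risk[mask].mean()
            se = np.sqrt(expected * (1 - expected) / mask.sum())
            assert observed == pytest.approx(expected, abs=3.5 * se)


class TestLifetimeRisk:
    def test_zero_incidence_zero_risk(self):
        table = make_life_tables(0.0, 0.0, 19.5, 7.3)
        assert lifetime_risk(1.0, table, "M", 40) == 0.0

    def test_constant_hazard_matches_exponential(self):
        """lambda=0.01/year, no mortality, 30 years: 1 - exp(-0.3) up to
        band-discretization error."""
        bands = [(a, a + 1) for a in range(40, 70)]
        table = make_life_tables(10.0, 10.0, 0.0, 0.0, age_bands=bands)
        risk = lifetime_risk(1.0, table, "F", 40)
        assert risk == pytest.approx(1 - np.exp(-0.3), rel=0.02)

    def test_mortality_reduces_lifetime_risk(self):
        risks = [lifetime_risk(1.0, make_life_tables(15.67, 13.47, m, m), "F", 40)
                 for m in (0.0, 50.0, 200.0, 1000.0)]
        assert np.all(np.diff(risks) < 0)

    def test_extreme_ratio_capped_with_warning(self):
        table = make_life_tables(500.0, 500.0, 0.0, 0.0)
        with pytest.warns(RuntimeWarning):
            risk = lifetime_risk(10.0, table, "M", 40)
        assert risk == 1.0

    def test_start_age_outside_table(self):
        with pytest.raises(ValueError):
            lifetime_risk(1.0, make_life_tables(), "M", 80)


class TestModelImpliedAuc:
    def test_predicted_auc_matches_empirical(self, large_cohort):
        """The numeric-integration AUC from the liability model agrees with
        the rank AUC of the simulated cohort within Monte-Carlo error."""
        from dcvdrisk import auc_rank

        c = large_cohort
        L = c.measured_liability()
        auc, (lo, hi) = auc_rank(L, c.status)
        se = (hi - lo) / (2 * 1.96)
        assert predicted_auc(c.model) == pytest.approx(auc, abs=3 * se)

    def test_binormal_approximation_close_to_exact(self, large_cohort):
        model = large_cohort.model
        assert predicted_auc(model, method="binormal") == pytest.approx(
            predicted_auc(model), abs=0.01)

    def test_no_signal_is_half(self):
        model = build_model([], prevalence=0.17)
        assert predicted_auc(model) == 0.5


class TestWeightIO:
    def test_roundtrip(self, tmp_path):
        panel = dcvd_panel_47()
        path = tmp_path / "weights.tsv"
        write_weights(panel, path)
        assert read_weights(path) == panel

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            SnpWeight("rs1", "1", 1, "A", "G", 1.2, 1.1)
        with pytest.raises(ValueError):
            SnpWeight("rs1", "1", 1, "A", "G", 0.3, -1.0)


class TestLifeTableValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            make_life_tables(-1.0, 10.0, 5.0, 5.0)

    def test_non_contiguous_bands_rejected(self):
        df = make_life_tables().table.copy()
        df.loc[df.index[0], "age_hi"] = 44
        with pytest.raises(ValueError):
            LifeTable(df)
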