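import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from minmet import diffexp
from minmet.diffexp import ModeratedANOVA
from minmet.io import EffectTable, IntensityMatrix, StudyDesign, ValidationError
from minmet.preprocess import preprocess_tissue
from minmet.simulate import simulate_cohort
from tests.conftest import make_matrix


def design_n(n_per_cell):
    samples, mice, geno, diet = [], [], [], []
    i = 0
    for g in ("WT", "MU"):
        for d in ("LF", "HF"):
            for _ in range(n_per_cell):
                samples.append(f"s{i}")
                mice.append(f"m{i}")
                geno.append(g)
                diet.append(d)
                i += 1
    return StudyDesign(samples, mice, geno, diet, ["PLA"] * i)


class TestAnovaFit:
    def test_cell_mean_algebra(self):
        """Cell means (WT-LF, WT-HF, MU-LF, MU-HF) = (0, 1, 0, 3) give
        mu = 1, beta_G = 0.5, beta_D = 1, beta_GD = 0.5 and logFCs 1/2/2."""
        design = design_n(2)
        y = np.array([[0, 0, 1, 1, 0, 0, 3, 3]], dtype=float)
        m = make_matrix(y, sample_ids=design.sample_ids)
        fit = diffexp.fit_anova_models(m, design)
        assert np.allclose(fit.coefficients[0], [1.0, 0.5, 1.0, 0.5])
        assert fit.contrast_estimates["genotype"][0] == pytest.approx(1.0)
        assert fit.contrast_estimates["diet"][0] == pytest.approx(2.0)
        assert fit.contrast_estimates["interaction"][0] == pytest.approx(2.0)
        assert fit.s2[0] == pytest.approx(0.0)
        assert fit.df_residual == 4

    def test_constant_metabolite(self):
        design = design_n(2)
        m = make_matrix(np.full((1, 8), 3.3), sample_ids=design.sample_ids)
        fit = diffexp.fit_anova_models(m, design)
        assert np.allclose(fit.coefficients[0][1:], 0.0)
        assert fit.s2[0] == pytest.approx(0.0)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        design = design_n(5)
        y = rng.normal(0, 1, (30, 20))
        m = make_matrix(y, sample_ids=design.sample_ids)
        fit = diffexp.fit_anova_models(m, design)
        x = diffexp.design_matrix(design)
        beta_ref, *_ = np.linalg.lstsq(x, y.T, rcond=None)
        assert np.allclose(fit.coefficients, beta_ref.T, atol=1e-10)

    def test_empty_cell_rejected(self):
        design = StudyDesign([f"s{i}" for i in range(6)],
                             [f"m{i}" for i in range(6)],
                             ["WT"] * 3 + ["MU"] * 3,
                             ["LF"] * 6, ["PLA"] * 6)
        m = make_matrix(np.ones((1, 6)), sample_ids=design.sample_ids)
        with pytest.raises(ValidationError, match="rank"):
            diffexp.fit_anova_models(m, design)


class TestModeration:
    def test_shrinkage_hand_example(self):
        s2_post = diffexp.squeeze_variances(np.array([1.0]), 4, 4.0, 1.0)
        assert s2_post[0] == pytest.approx(1.0)
        t = 1.0 / np.sqrt(s2_post[0] * 0.2)
        assert t == pytest.approx(2.2361, abs=1e-4)

    def test_zero_prior_df_recovers_classical_t(self):
        """With the prior df forced to 0 the moderated t equals the
        classical per-metabolite OLS t statistic."""
        rng = np.random.default_rng(1)
        design = design_n(5)
        y = rng.normal(0, 1, (40, 20))
        m = make_matrix(y, sample_ids=design.sample_ids)
        fit = diffexp.fit_anova_models(m, design)
        _, tables = diffexp.moderate_statistics(fit, d0_override=0.0)
        x = diffexp.design_matrix(design)
        for j in range(8):
            res = sm.OLS(y[j], x).fit()
            assert tables["genotype"].frame.set_index("metabolite_id").loc[
                m.metabolite_ids[j], "t"] == pytest.approx(res.tvalues[1],
                                                           abs=1e-8)

    def test_infinite_prior_df_gives_complete_shrinkage(self):
        rng = np.random.default_rng(2)
        design = design_n(5)
        y = rng.normal(0, 1, (40, 20))
        m = make_matrix(y, sample_ids=design.sample_ids)
        fit = diffexp.fit_anova_models(m, design)
        _, s02 = diffexp.estimate_prior(fit.s2, fit.df_residual)
        squeezed = diffexp.squeeze_variances(fit.s2, fit.df_residual,
                                             np.inf, s02)
        assert np.allclose(squeezed, s02)

    def test_posterior_variance_between_extremes(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 100) / 4
        d0, s02 = diffexp.estimate_prior(s2, 16)
        post = diffexp.squeeze_variances(s2, 16, d0, s02)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_permutation_equivariance_of_pvalues(self):
        rng = np.random.default_rng(4)
        design = design_n(5)
        y = rng.normal(0, 1, (40, 20))
        m = make_matrix(y, sample_ids=design.sample_ids)
        _, tables = diffexp.moderate_statistics(
            diffexp.fit_anova_models(m, design))
        perm = rng.permutation(40)
        m2 = IntensityMatrix(y[perm], np.zeros((40, 20), bool),
                             [m.metabolite_ids[i] for i in perm],
                             list(design.sample_ids),
                             scale_tag="regularized")
        _, tables2 = diffexp.moderate_statistics(
            diffexp.fit_anova_models(m2, design))
        for name in tables:
            a = tables[name].frame.set_index("metabolite_id")["p_raw"]
            b = tables2[name].frame.set_index("metabolite_id")["p_raw"]
            assert np.allclose(a.sort_index(), b.sort_index())

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for x in (0.01, 0.5, 2.0, 50.0):
            y = diffexp.trigamma_inverse(x)
            assert polygamma(1, y) == pytest.approx(x, rel=1e-8)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError, match="jitter"):
            diffexp.estimate_prior(np.zeros(20), 4)


class TestReports:
    @staticmethod
    def table(qs, fcs):
        import pandas as pd
        frame = pd.DataFrame({
            "metabolite_id": [f"M{i}" for i in range(len(qs))],
            "logFC": fcs, "t": fcs, "B": fcs,
            "p_raw": qs, "p_adj": qs,
        })
        return EffectTable(frame)

    def test_up_down_counting(self):
        tables = {"genotype": self.table([0.01, 0.2, 0.04], [1.0, -1.0, -1.0])}
        rep = diffexp.effect_tables(tables, threshold=0.05)
        info = rep["contrasts"]["genotype"]
        assert info["n_up"] == 1 and info["n_down"] == 1

    def test_identical_sets_intersect_fully(self):
        t = self.table([0.01, 0.01], [1.0, 1.0])
        tables = {"genotype": t, "diet": t, "interaction": t}
        rep = diffexp.effect_tables(tables, threshold=0.05)
        assert rep["venn"]["genotype&diet&interaction"] == 2


def test_null_cohort_pvalues_uniform(null_config):
    """With no planted effects the pooled raw p-values are uniform."""
    pooled = []
    for seed in range(10):
        cohort = simulate_cohort(null_config, seed=400 + seed)
        pla = cohort.design.subset_tissue("PLA")
        reg, _ = preprocess_tissue(cohort.intensity["PLA"], pla)
        res = ModeratedANOVA(reg, pla).fit()
        pooled.append(res.tables["genotype"].frame["p_raw"].to_numpy())
    stat = kstest(np.concatenate(pooled), "uniform").statistic
    assert stat < 0.05


def test_planted_effects_are_recovered(preprocessed_cohort):
    """Most strongly planted genotype metabolites are called significant."""
    cohort, pla, reg, _ = preprocessed_cohort
    res = ModeratedANOVA(reg, pla).fit()
    table = res.tables["genotype"].frame.set_index("metabolite_id")
    ids = cohort.intensity["PLA"].metabolite_ids
    strong = [ids[j] for j, e in cohort.truth.genotype_effects.items()
              if abs(e) >= 1.0 and ids[j] in table.index]
    called = (table.loc[strong, "p_adj"] <= 0.05).mean()
    assert called > 0.8


def test_summary_mentions_prior_and_counts(preprocessed_cohort):
    _, pla, reg, _ = preprocessed_cohort
    res = ModeratedANOVA(reg, pla).fit()
    text = res.summary()
    assert "prior df" in text and "genotype" in text
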