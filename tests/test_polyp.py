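import numpy as np
import pytest
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)

from minmet import polyp
from minmet.io import PolypCounts, StudyDesign, ValidationError
from minmet.polyp import DegenerateMarginError, ZeroInflatedNB


def mouse_design(genotypes, diets):
    n = len(genotypes)
    return StudyDesign([f"m{i}" for i in range(n)],
                       [f"m{i}" for i in range(n)],
                       list(genotypes), list(diets), ["PLA"] * n)


class TestLoglik:
    def test_poisson_limit_hand_value(self):
        """counts [0, 2], pi = 0.5, mean 1 in the Poisson limit:
        ln(0.5 (1 + e^-1)) + ln(0.5 e^-1 / 2) = -2.7662."""
        ll = polyp.zinb_loglik(np.array([0, 2]), np.ones((2, 1)),
                               np.array([0.0]), 0.0, 1e9)
        assert ll == pytest.approx(-2.7662, abs=1e-4)

    def test_pi_zero_collapses_to_negative_binomial(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, 50)
        x = np.column_stack([np.ones(50), rng.normal(0, 1, 50)])
        beta = np.array([1.0, 0.3])
        theta = 2.5
        ll = polyp.zinb_loglik(counts, x, beta, -1e3, theta)
        mean = np.exp(x @ beta)
        ref = polyp._nb_logpmf(counts, mean, theta).sum()
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_pi_one_with_positive_count_impossible(self):
        ll = polyp.zinb_loglik(np.array([0, 2]), np.ones((2, 1)),
                               np.array([0.0]), np.inf, 2.0)
        assert ll == -np.inf

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            polyp.zinb_loglik(np.array([0.5]), np.ones((1, 1)),
                              np.array([0.0]), 0.0, 1.0)

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4.0, 30)
        x = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
        beta = np.array([1.2, -0.2])
        perm = rng.permutation(30)
        assert polyp.zinb_loglik(counts, x, beta, -0.4, 3.0) == pytest.approx(
            polyp.zinb_loglik(counts[perm], x[perm], beta, -0.4, 3.0))

    def test_large_counts_no_underflow(self):
        ll = polyp.zinb_loglik(np.array([10 ** 6]), np.ones((1, 1)),
                               np.array([10.0]), -2.0, 5.0)
        assert np.isfinite(ll)


class TestFit:
    def test_matches_statsmodels_zinb_oracle(self):
        rng = np.random.default_rng(7)
        n = 500
        g = rng.integers(0, 2, n).astype(float)
        d = rng.integers(0, 2, n).astype(float)
        y = rng.normal(0, 1, n)
        x = np.column_stack([np.ones(n), g, d, g * d * y])
        mu = np.exp(x @ np.array([2.0, 0.5, 1.0, 0.8]))
        counts = rng.negative_binomial(4.0, 4.0 / (4.0 + mu))
        counts[rng.random(n) < 0.2] = 0
        mine = polyp.fit_zinb_design(counts, x)
        oracle = ZeroInflatedNegativeBinomialP(
            counts, x, exog_infl=np.ones((n, 1)), p=2).fit(disp=0,
                                                           maxiter=500)
        assert np.allclose(mine.beta, oracle.params[1:5], atol=1e-3)
        assert mine.loglik == pytest.approx(oracle.llf, abs=1e-3)
        se_mine = np.sqrt(np.diag(mine.cov)[:4])
        assert np.allclose(se_mine, oracle.bse[1:5], atol=1e-3)

    def test_no_zero_inflation_matches_nb_oracle(self):
        """pi = 0 data (all counts positive): count coefficients agree with
        a plain negative-binomial ML fit."""
        rng = np.random.default_rng(8)
        n = 400
        x = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        mu = np.exp(x @ np.array([1.5, 0.5]))
        counts = rng.negative_binomial(5.0, 5.0 / (5.0 + mu)) + 1
        mine = polyp.fit_zinb_design(counts, x)
        import statsmodels.api as sm
        oracle = sm.NegativeBinomial(counts, x).fit(disp=0)
        assert np.allclose(mine.beta[:2], oracle.params[:2], atol=2e-3)

    def test_poisson_limit_matches_zip_oracle(self):
        """theta forced to 1e6: the fit agrees with a zero-inflated
        Poisson oracle."""
        rng = np.random.default_rng(9)
        n = 300
        x = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        counts = rng.poisson(np.exp(x @ np.array([1.0, 0.6])))
        counts[rng.random(n) < 0.25] = 0
        mine = polyp.fit_zinb_design(counts, x, fixed_theta=1e6)
        oracle = ZeroInflatedPoisson(counts, x,
                                     exog_infl=np.ones((n, 1))).fit(disp=0)
        assert np.allclose(mine.beta[:2], oracle.params[1:3], atol=1e-3)

    def test_ascent_from_starting_values(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            n = 40
            x = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
            counts = rng.negative_binomial(2.0, 0.3, n)
            counts[rng.random(n) < 0.3] = 0
            m = polyp.fit_zinb_design(counts.astype(float), x)
            assert m.loglik >= m.start_loglik - 1e-8

    def test_all_zero_counts_boundary_not_crash(self):
        design = mouse_design(["WT"] * 4 + ["MU"] * 4,
                              ["LF", "HF"] * 4)
        counts = PolypCounts([f"m{i}" for i in range(8)], np.zeros(8, int))
        model = polyp.fit_zinb(counts, design, np.zeros(8))
        assert model.boundary_flag
        assert model.pi > 0.99 or np.exp(model.beta[0]) < 1e-6

    def test_model_results_interface(self, default_cohort):
        pla = default_cohort.design.subset_tissue("PLA")
        y = default_cohort.truth.driver_z
        model = ZeroInflatedNB.from_cohort(default_cohort.polyps,
                                           pla, y)
        res = model.fit()
        z, p = res.wald(3)
        assert np.isfinite(p)
        lo, hi = res.conf_int(3)
        assert lo < res.beta[3] < hi
        assert "theta" in res.summary()


class TestAssociation:
    def test_permuted_labels_break_association(self, preprocessed_cohort):
        """Permuting the mouse labels of the driver metabolite's values
        destroys its association with polyp counts."""
        cohort, pla, reg, _ = preprocessed_cohort
        mouse = polyp._mouse_level_design(pla)
        counts = cohort.polyps.aligned_to(mouse.sample_ids)
        driver_id = cohort.intensity["PLA"].metabolite_ids[
            cohort.truth.driver_index]
        j = reg.metabolite_ids.index(driver_id)
        y = reg.values[j]
        _, p_true = polyp.fit_zinb_design(
            counts, polyp.build_count_design(mouse, y)).wald(3)
        rng = np.random.default_rng(0)
        p_perm = []
        for _ in range(30):
            _, p = polyp.fit_zinb_design(
                counts,
                polyp.build_count_design(mouse, rng.permutation(y))).wald(3)
            p_perm.append(p)
        assert p_true < 0.01
        assert np.median(p_perm) > 0.1

    def test_driver_found_significant(self, preprocessed_cohort):
        cohort, pla, reg, _ = preprocessed_cohort
        table, diag = polyp.associate_metabolites(cohort.polyps, pla, reg)
        driver_id = cohort.intensity["PLA"].metabolite_ids[
            cohort.truth.driver_index]
        frame = table.frame.set_index("metabolite_id")
        assert frame.loc[driver_id, "p_adj"] <= 0.05
        assert diag["n_nonconverged"] < 0.5 * len(frame)


class TestGroupCorrelations:
    def test_constant_counts_undefined_rho_zero_r2(self):
        design = mouse_design(["WT"] * 3, ["LF"] * 3)
        counts = PolypCounts(["m0", "m1", "m2"], np.zeros(3, int))
        out = polyp.group_correlations(counts, np.array([1.0, 2.0, 3.0]),
                                       design)
        assert np.isnan(out["WT-LF"]["rho"])
        assert out["WT-LF"]["r2"] == 0.0

    def test_perfect_lines(self):
        design = mouse_design(["MU"] * 3, ["HF"] * 3)
        up = polyp.group_correlations(
            PolypCounts(["m0", "m1", "m2"], np.array([2, 4, 6])),
            np.array([1.0, 2.0, 3.0]), design)["MU-HF"]
        assert up["rho"] == pytest.approx(1.0)
        assert up["r2"] == pytest.approx(1.0)
        down = polyp.group_correlations(
            PolypCounts(["m0", "m1", "m2"], np.array([6, 4, 2])),
            np.array([1.0, 2.0, 3.0]), design)["MU-HF"]
        assert down["rho"] == pytest.approx(-1.0)
        assert down["r2"] == pytest.approx(1.0)

    def test_small_group_gives_sentinels(self):
        design = mouse_design(["WT"], ["LF"])
        out = polyp.group_correlations(PolypCounts(["m0"], np.array([3])),
                                       np.array([1.0]), design)
        assert np.isnan(out["WT-LF"]["rho"])
        assert np.isnan(out["WT-LF"]["r2"])


class TestChiSquare:
    def test_diagonal_table(self):
        stat, df, p = polyp.chisq_independence([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_independence(self):
        stat, _, p = polyp.chisq_independence([[5, 5], [5, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateMarginError, match="row"):
            polyp.chisq_independence([[0, 0], [51, 273]])

    def test_mutant_share(self):
        assert polyp.mutant_polyp_share([[0, 0], [51, 273]]) == 100.0
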