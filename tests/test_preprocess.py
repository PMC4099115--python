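import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from minmet import preprocess as pre
from minmet.io import IntensityMatrix, ValidationError
from tests.conftest import design_two_groups, make_matrix


def matrix_with_missing(miss_counts, n=10, scale_tag="raw"):
    p = len(miss_counts)
    values = np.ones((p, n)) * 2.0
    mask = np.zeros((p, n), dtype=bool)
    for j, c in enumerate(miss_counts):
        mask[j, :c] = True
    return make_matrix(values, mask, scale_tag=scale_tag)


def brute_force_nu(miss_counts, n, min_group):
    """Exhaustive reference for the threshold rule: every feasible integer
    is scored; the reported nu is the largest observed-count maximiser
    (0 always eligible; the bound itself when nothing observed is feasible)."""
    import math
    nu_hi = int(math.ceil(n - min_group / 2.0)) - 1
    miss = np.asarray(miss_counts)
    j = {nu: int((miss <= nu).sum() - miss[miss <= nu].sum())
         for nu in range(nu_hi + 1)}
    observed = sorted({int(c) for c in miss if c <= nu_hi})
    candidates = sorted({0, *observed}) if observed else [0, nu_hi]
    best = max(j[nu] for nu in candidates)
    nu = max(nu for nu in candidates if j[nu] == best)
    return nu, [i for i, c in enumerate(miss_counts) if c <= nu], j


class TestMissingnessThreshold:
    def test_no_missing_retains_everything(self):
        m = matrix_with_missing([0, 0, 0])
        res = pre.select_missingness_threshold(m, design_two_groups(10))
        assert res.nu == 0
        assert res.retained_ids == m.metabolite_ids

    def test_tradeoff_example(self):
        m = matrix_with_missing([0, 0, 1, 5, 9])
        res = pre.select_missingness_threshold(m, design_two_groups(10))
        assert res.nu == 1
        assert len(res.retained_ids) == 3
        assert res.objective_trace[0][2] == 2
        assert res.objective_trace[1][2] == 2
        assert res.objective_trace[5][2] == -2

    def test_nothing_feasible_reports_bound(self):
        m = matrix_with_missing([8, 8])
        res = pre.select_missingness_threshold(m, design_two_groups(10))
        assert res.nu == 7
        assert res.retained_ids == []

    def test_objective_attains_exhaustive_maximum(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = int(rng.integers(1, 51))
            n = int(rng.integers(4, 21))
            miss = rng.integers(0, n + 1, p)
            m = matrix_with_missing(list(miss), n=n)
            design = design_two_groups(n)
            res = pre.select_missingness_threshold(m, design)
            nu, retained_idx, trace = brute_force_nu(miss, n,
                                                     min(design.group_sizes()
                                                         .values()))
            assert res.nu == nu
            assert res.retained_ids == [m.metabolite_ids[i]
                                        for i in retained_idx]
            assert res.objective_trace[res.nu][2] == max(trace.values())

    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=1,
                    max_size=50),
           st.integers(min_value=4, max_value=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_threshold_matches_brute_force(self, miss, n):
        miss = [min(c, n) for c in miss]
        m = matrix_with_missing(miss, n=n)
        design = design_two_groups(n)
        res = pre.select_missingness_threshold(m, design)
        nu, retained_idx, _ = brute_force_nu(
            miss, n, min(design.group_sizes().values()))
        assert res.nu == nu
        assert res.retained_ids == [m.metabolite_ids[i] for i in retained_idx]

    def test_empty_matrix_rejected(self):
        m = make_matrix(np.ones((0, 4)))
        with pytest.raises(ValidationError):
            pre.select_missingness_threshold(m, design_two_groups(4))


class TestImputation:
    def test_no_missing_is_identity(self):
        m = make_matrix(np.arange(8.0).reshape(2, 4) + 1, scale_tag="log2")
        out = pre.impute_missing(m, design_two_groups(4))
        assert np.array_equal(out.values, m.values)

    def test_truncated_normal_expectation(self):
        """Neighbours {5,6,7} and detection limit 5: E[Y|Y<5] under
        N(6,1) is 6 - phi(-1)/Phi(-1) = 4.4749, cross-checked by numeric
        integration."""
        values = np.array([[5.0, 6.0, 7.0, 1.0, 5.0, 9.0, 9.0, 9.0]])
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 3] = True
        design = design_two_groups(8)
        m = make_matrix(values, mask, scale_tag="log2")
        out = pre.impute_missing(m, design)
        num = integrate.quad(
            lambda y: y * stats.norm.pdf(y, 6, 1), -np.inf, 5)[0]
        den = stats.norm.cdf(5, 6, 1)
        assert out.values[0, 3] == pytest.approx(num / den, abs=1e-6)
        assert out.values[0, 3] == pytest.approx(4.4749, abs=1e-4)

    def test_whole_group_missing_gets_background(self):
        values = np.array([[3.0, 4.0, 1.0, 1.0],
                           [5.0, 6.0, 7.0, 8.0]])
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 2] = mask[0, 3] = True
        m = make_matrix(values, mask, scale_tag="log2")
        out = pre.impute_missing(m, design_two_groups(4))
        assert out.values[0, 2] == out.values[0, 3] == 3.0 - 1.0

    def test_imputed_values_below_detection_limit(self, preprocessed_cohort):
        cohort, pla, _, _ = preprocessed_cohort
        matrix = cohort.intensity["PLA"]
        logged = pre.log2_transform(matrix)
        imputed = pre.impute_missing(logged, pla)
        groups = np.array(pla.group_labels())
        for j in range(matrix.n_metabolites):
            row_mask = matrix.missing_mask[j]
            if not row_mask.any() or row_mask.all():
                continue
            c_j = logged.values[j][~row_mask].min()
            for i in np.nonzero(row_mask)[0]:
                neighbors = (~row_mask) & (groups == groups[i])
                if neighbors.sum() >= 2:
                    assert imputed.values[j, i] < c_j

    def test_observed_cells_unchanged(self, default_cohort):
        pla = default_cohort.design.subset_tissue("PLA")
        matrix = default_cohort.intensity["PLA"]
        logged = pre.log2_transform(matrix)
        imputed = pre.impute_missing(logged, pla)
        keep = ~matrix.missing_mask
        assert np.array_equal(imputed.values[keep], logged.values[keep])

    def test_requires_log_scale(self):
        m = make_matrix(np.ones((1, 4)), scale_tag="raw")
        with pytest.raises(ValidationError):
            pre.impute_missing(m, design_two_groups(4))


class TestRegularization:
    def test_constant_sd_scales_centred_values_globally(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 12)
        values = np.array([5.0 + 2.0 * base, 9.0 + 2.0 * base])
        m = make_matrix(values, scale_tag="log2")
        out = pre.log_transform_regularize(m)
        centred_in = values - values.mean(axis=1, keepdims=True)
        centred_out = out.values - out.values.mean(axis=1, keepdims=True)
        ratio = centred_out / centred_in
        assert np.allclose(ratio, ratio.flat[0])

    def test_variance_mean_trend_removed(self, preprocessed_cohort):
        _, _, reg, _ = preprocessed_cohort
        m = reg.values.mean(axis=1)
        s2 = reg.values.var(axis=1, ddof=1)
        rho = stats.spearmanr(np.argsort(np.argsort(m)), s2).statistic
        assert abs(rho) < 0.1

    def test_group_variance_ratio_decreases(self, preprocessed_cohort):
        cohort, pla, reg, filt = preprocessed_cohort
        raw = pre.log2_transform(
            cohort.intensity["PLA"].subset_metabolites(filt.retained_ids))
        raw = pre.impute_missing(raw, pla)
        groups = np.array(pla.group_labels())

        def median_ratio(matrix):
            ratios = []
            for j in range(matrix.n_metabolites):
                var = [matrix.values[j][groups == g].var(ddof=1)
                       for g in sorted(set(groups))]
                if min(var) > 0:
                    ratios.append(max(var) / min(var))
            return np.median(ratios)

        assert median_ratio(reg) <= median_ratio(raw)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 2, (30, 10)) * 1.0
        m = make_matrix(values, scale_tag="log2")
        out = pre.log_transform_regularize(m)
        perm = rng.permutation(30)
        m_perm = IntensityMatrix(values[perm],
                                 np.zeros_like(values[perm], dtype=bool),
                                 [m.metabolite_ids[i] for i in perm],
                                 list(m.sample_ids), scale_tag="log2")
        out_perm = pre.log_transform_regularize(m_perm)
        assert np.allclose(out.values[perm], out_perm.values)

    def test_non_positive_raw_rejected(self):
        values = np.array([[1.0, 0.0]])
        m = IntensityMatrix(values, np.array([[False, True]]), ["A"],
                            ["s1", "s2"], scale_tag="raw")
        m.values[0, 1] = 0.0
        m.missing_mask[0, 1] = False
        with pytest.raises(ValidationError):
            pre.log2_transform(m)
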