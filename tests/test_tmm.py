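"""TMM: reference selection, doubly trimmed mean, adjustment, CPM."""

import numpy as np
import pytest

from countnorm import (
    AUTO_UPPER_QUARTILE,
    CountMatrix,
    TMMOptions,
    adjust_to_unit_product,
    geometric_mean,
    library_sizes,
    pre_normalize,
    select_reference,
    tmm_cpm,
    tmm_effective_library_sizes,
    tmm_factors,
    tmm_relative_factors,
)
from countnorm.synthetic import SimulationConfig, simulate_counts

from conftest import random_matrix


class TestSelectReference:
    def test_explicit_index_passes_through(self, toy_matrix):
        Y = pre_normalize(toy_matrix)
        assert select_reference(Y, TMMOptions(reference=0)) == 0
        with pytest.raises(IndexError):
            select_reference(Y, TMMOptions(reference=5))

    def test_identical_columns_tie_break_to_lowest_index(self, toy_matrix):
        Y = pre_normalize(toy_matrix)  # proportional columns -> identical Y
        assert select_reference(Y, TMMOptions()) == 0

    def test_picks_sample_closest_to_mean_upper_quartile(self):
        # three columns engineered so the per-column 75th percentiles of
        # pre-normalized values are distinct and the middle one is closest
        # to their mean
        rng = np.random.default_rng(3)
        cm = random_matrix(rng, n_genes=101, n_samples=3)
        Y = pre_normalize(cm)
        uq = np.quantile(Y.values, 0.75, axis=0)
        expected = int(np.argmin(np.abs(uq - uq.mean())))
        assert select_reference(Y, TMMOptions()) == expected


class TestRelativeFactors:
    def test_proportional_columns_give_unit_factors(self, toy_matrix):
        tau, usable = tmm_relative_factors(toy_matrix, TMMOptions(reference=0))
        np.testing.assert_allclose(tau, 1.0, atol=1e-14)
        assert usable.tolist() == [3, 3]

    def test_median_mode_on_toy(self, toy_matrix):
        tau, _ = tmm_relative_factors(
            toy_matrix, TMMOptions(reference=0, m_trim=0.5, a_trim=0.0))
        assert tau.tolist() == [1.0, 1.0]

    def test_reference_factor_is_exactly_one(self):
        cm = simulate_counts(SimulationConfig(
            n_genes=500, de_fraction=0.3, de_up_share=1.0, seed=5))
        tau, _ = tmm_relative_factors(cm, TMMOptions(reference=2))
        assert tau[2] == 1.0

    def test_ratio_and_log2_scales_coincide_at_median_trim(self):
        # with a 50% M-trim both scales reduce to the median of ratios;
        # odd valid-gene count keeps the median on a data point
        cm = random_matrix(np.random.default_rng(11), n_genes=101, n_samples=4)
        opts = dict(reference=0, m_trim=0.5, a_trim=0.0)
        tau_r, _ = tmm_relative_factors(cm, TMMOptions(**opts, mean_scale="ratio"))
        tau_l, _ = tmm_relative_factors(cm, TMMOptions(**opts, mean_scale="log2"))
        np.testing.assert_allclose(tau_r, tau_l, rtol=1e-12)

    def test_double_trim_matches_loop_oracle(self):
        """Rank-trim of each M and A tail + intersection, checked gene by
        gene against a pure-Python reimplementation."""
        rng = np.random.default_rng(17)
        cm = random_matrix(rng, n_genes=60, n_samples=3, zeros=0.1)
        opts = TMMOptions(reference=0, m_trim=0.3, a_trim=0.05)
        tau, _ = tmm_relative_factors(cm, opts)

        Y = pre_normalize(cm).values
        for s in (1, 2):
            pairs = [(g, np.log2(Y[g, s] / Y[g, 0]),
                      0.5 * np.log2(Y[g, s] * Y[g, 0]))
                     for g in range(cm.n_genes) if Y[g, s] > 0 and Y[g, 0] > 0]
            n = len(pairs)
            km, ka = int(0.3 * n), int(0.05 * n)
            by_m = sorted(range(n), key=lambda i: (pairs[i][1], i))
            by_a = sorted(range(n), key=lambda i: (pairs[i][2], i))
            keep = (set(by_m[km:n - km] if km else by_m)
                    & set(by_a[ka:n - ka] if ka else by_a))
            ratios = [Y[pairs[i][0], s] / Y[pairs[i][0], 0] for i in sorted(keep)]
            assert tau[s] == pytest.approx(np.mean(ratios), rel=1e-12)

    def test_empty_survivor_set_raises(self):
        cm = CountMatrix(np.array([[1.0, 5.0], [9.0, 5.0]]),
                         ["g1", "g2"], ["s1", "s2"], ["a", "b"])
        with pytest.raises(ValueError, match="no usable genes"):
            tmm_relative_factors(cm, TMMOptions(reference=0, m_trim=0.5, a_trim=0.5))


class TestAdjustmentAndDownstream:
    def test_adjust_examples(self):
        np.testing.assert_allclose(adjust_to_unit_product([1.0, 4.0]), [0.5, 2.0])
        np.testing.assert_allclose(adjust_to_unit_product([1, 1, 1]), 1.0)

    def test_adjusted_product_is_one(self):
        rng = np.random.default_rng(0)
        tau = rng.lognormal(0, 0.5, size=9)
        assert np.prod(adjust_to_unit_product(tau)) == pytest.approx(1.0, abs=1e-10)

    def test_effective_library_sizes(self):
        np.testing.assert_allclose(
            tmm_effective_library_sizes(np.array([0.5, 2.0]),
                                        np.array([100.0, 100.0])),
            [50.0, 200.0])

    def test_cpm_column_sums_to_million_when_e_equals_n(self, toy_matrix):
        N = library_sizes(toy_matrix)
        Z = tmm_cpm(toy_matrix, N)
        np.testing.assert_allclose(Z.sum(axis=0), 1e6, rtol=1e-12)
        assert Z[toy_matrix.counts == 0].size == 0  # no zeros in toy

    def test_cpm_invariant_to_joint_depth_scaling(self, toy_matrix):
        res = tmm_factors(toy_matrix, TMMOptions(reference=0))
        Z1 = tmm_cpm(toy_matrix, res.effective_library_sizes)
        scaled = CountMatrix(toy_matrix.counts * 10, toy_matrix.gene_ids,
                             toy_matrix.sample_ids, toy_matrix.conditions)
        res10 = tmm_factors(scaled, TMMOptions(reference=0))
        Z10 = tmm_cpm(scaled, res10.effective_library_sizes)
        np.testing.assert_allclose(Z1, Z10, rtol=1e-12)


class TestFullPipeline:
    def test_size_factors_scale_invariant_and_unit_product(self):
        cm = random_matrix(np.random.default_rng(23), n_genes=80, n_samples=5)
        res = tmm_factors(cm, TMMOptions())
        assert geometric_mean(res.adjusted_factors) == pytest.approx(1.0, abs=1e-10)
        scaled = CountMatrix(cm.counts * 3, cm.gene_ids, cm.sample_ids,
                             cm.conditions)
        res3 = tmm_factors(scaled, TMMOptions())
        np.testing.assert_allclose(res.size_factors, res3.size_factors, rtol=1e-12)

    def test_factors_near_one_despite_varying_depths_without_bias(self):
        """No composition bias: TMM factors stay ~1 while depths vary 10x."""
        N = np.array([2e5, 5e5, 1e6, 2e6, 4e6, 2e5])
        cm = simulate_counts(SimulationConfig(
            n_genes=2000, n_conditions=2, n_replicates=3, de_fraction=0.0,
            dispersion=0.05, library_sizes=N, seed=9))
        res = tmm_factors(cm, TMMOptions())
        np.testing.assert_allclose(res.size_factors, 1.0, atol=0.05)

    def test_settings_recorded(self, toy_matrix):
        res = tmm_factors(toy_matrix, TMMOptions(reference=0, m_trim=0.2))
        assert res.settings["m_trim"] == 0.2
        assert res.method == "TMM"
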