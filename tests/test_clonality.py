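"""Clonality statistics: VAF, abundance, diversity, bandwidth, weighted KDE."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import nl_weighted_kde
from omiclone.clonality import (
    MIN_BANDWIDTH,
    abundance,
    berger_parker_dominance,
    calculate_metrics,
    compute_vaf,
    default_grid,
    kde_modes,
    plugin_bandwidth,
    shannon_diversity,
    silverman_bandwidth,
    simpson_diversity,
    weighted_kde,
)
from omiclone.fixtures import example_case_bundle, key_genes_of
from omiclone.integration import distinct_mutations, integrate

SQRT_2PI = math.sqrt(2 * math.pi)

# abundances VAF*DP*CN of the worked presentation case's five key genes
TABLE1_ABUNDANCES = [17 * 82 * 1, 31 * 207 * 3, 24 * 94 * 1, 24 * 117 * 3, 14 * 244 * 3]


class TestVafAndAbundance:
    @pytest.mark.parametrize("trv,trr,expected", [(0, 50, 0.0), (50, 50, 50.0), (31, 69, 31.0), (25, 75, 25.0)])
    def test_vaf_formula(self, trv, trr, expected):
        assert compute_vaf(trv, trr) == pytest.approx(expected)

    def test_vaf_undefined_without_reads(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_vaf(0, 0)

    def test_abundance_product(self):
        assert abundance(0, 100, 2) == 0.0
        assert abundance(31, 207, 3) == 19251.0  # amplified MYC-like case
        assert abundance(10, 50, None) == abundance(10, 50, 2)  # null CN is diploid


class TestShannonDiversity:
    def test_single_clone_is_zero(self):
        assert shannon_diversity([123.4]) == pytest.approx(0.0, abs=1e-15)

    def test_uniform_maximizes_at_log_n(self):
        assert shannon_diversity([5.0] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_zero_abundances_contribute_nothing(self):
        assert shannon_diversity([1, 0, 1, 0]) == pytest.approx(math.log(2), abs=1e-12)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            shannon_diversity([0.0, 0.0])

    def test_worked_case_matches_direct_summation_oracle(self):
        # independent oracle: exact rational shares, direct -sum p ln p
        total = sum(TABLE1_ABUNDANCES)
        expected = -sum(
            float(Fraction(a, total)) * math.log(Fraction(a, total)) for a in TABLE1_ABUNDANCES
        )
        assert shannon_diversity(TABLE1_ABUNDANCES) == pytest.approx(expected, rel=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=1, max_size=30),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounds_and_scale_invariance(self, abundances, scale):
        sdi = shannon_diversity(abundances)
        assert -1e-12 <= sdi <= math.log(len(abundances)) + 1e-12
        assert shannon_diversity([a * scale for a in abundances]) == pytest.approx(sdi, abs=1e-9)

    def test_permutation_invariance(self):
        a = [3.0, 1.0, 4.0, 1.5]
        assert shannon_diversity(a) == pytest.approx(shannon_diversity(a[::-1]), abs=1e-15)

    def test_optional_indices(self):
        assert simpson_diversity([1, 1]) == pytest.approx(0.5)
        assert berger_parker_dominance([3, 1]) == pytest.approx(0.75)


class TestPluginBandwidth:
    # reference values computed with an independent implementation of the
    # two-stage direct plug-in selector (R KernSmooth::dpik, scalest="minim",
    # level 2, normal kernel, fine binning) on the same frozen samples
    def test_matches_independent_reference_standard_normal_n200(self):
        rng = np.random.default_rng(12345)
        x = rng.standard_normal(200)
        assert plugin_bandwidth(x) == pytest.approx(0.3261816614, rel=5e-3)

    def test_matches_independent_reference_vaf_scale(self):
        rng = np.random.default_rng(12345)
        rng.standard_normal(200)  # advance to the second frozen sample
        x = rng.normal(40, 8, 300)
        assert plugin_bandwidth(x) == pytest.approx(2.4957727587, rel=5e-3)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(30, 6, 120)
        assert plugin_bandwidth(x + 17.3) == pytest.approx(plugin_bandwidth(x), rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 150)
        h = plugin_bandwidth(x)
        for c in (0.5, 3.0, 12.0):
            assert plugin_bandwidth(c * x) == pytest.approx(c * h, rel=1e-10)

    def test_degenerate_inputs_fall_back_without_crashing(self):
        assert plugin_bandwidth([42.0, 42.0, 42.0]) == MIN_BANDWIDTH
        assert plugin_bandwidth([1.0, 2.0]) >= MIN_BANDWIDTH
        assert silverman_bandwidth([5.0]) == MIN_BANDWIDTH

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plugin_bandwidth([])


class TestWeightedKde:
    def test_single_point_closed_form(self):
        h = 2.5
        curve = weighted_kde([40.0], [1.0], h=h, grid=np.array([40.0]))
        assert curve.density[0] == pytest.approx(1.0 / (h * SQRT_2PI), rel=1e-12)

    def test_equal_weights_cancel(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(5, 95, 60)
        grid = default_grid()
        h = 3.0
        weighted = weighted_kde(x, np.full(60, 7.0), h=h, grid=grid)
        unweighted = (np.exp(-0.5 * ((x[:, None] - grid[None, :]) / h) ** 2) / SQRT_2PI).sum(0) / (
            len(x) * h
        )  # plain estimator, all mutations weighted equally
        np.testing.assert_allclose(weighted.density, unweighted, rtol=1e-12)
        assert weighted.weights_used is False or np.ptp(np.full(60, 7.0)) == 0

    def test_pointwise_agreement_with_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 99, 40)
        w = rng.integers(1, 5, 40).astype(float)
        h = 2.2
        grid = np.linspace(0, 100, 101)
        curve = weighted_kde(x, w, h=h, grid=grid)
        oracle = nl_weighted_kde(list(x), list(w), h, list(grid))
        np.testing.assert_allclose(curve.density, oracle, rtol=1e-12)

    def test_grid_integral_near_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(45, 8, 200).clip(1, 99)
        w = rng.integers(1, 4, 200).astype(float)
        curve = weighted_kde(x, w)
        assert 0.98 <= curve.integral() <= 1.02

    def test_convex_combination_density_bound(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(10, 90, 50)
        w = rng.integers(1, 6, 50).astype(float)
        h = 1.7
        curve = weighted_kde(x, w, h=h)
        assert curve.density.max() <= 1.0 / (h * SQRT_2PI) + 1e-12
        assert (curve.density >= 0).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            weighted_kde([1.0, 2.0], [1.0], h=1.0)

    def test_two_separated_clones_recovered_as_two_modes(self):
        """Planted clusters >= 6 sd apart yield exactly 2 modes near the centers."""
        rng = np.random.default_rng(20)
        centers = (25.0, 61.0)
        sd = 3.0
        x = np.concatenate([rng.normal(c, sd, 150) for c in centers]).clip(0.5, 99.5)
        w = rng.integers(1, 4, x.size).astype(float)
        curve = weighted_kde(x, w, h=plugin_bandwidth(x))
        modes = kde_modes(curve)
        assert len(modes) == 2
        for c, m in zip(centers, sorted(modes)):
            assert abs(m - c) <= 2.0


class TestMetrics:
    def test_worked_presentation_case(self):
        bundle = example_case_bundle("presentation")
        w_hat = distinct_mutations(integrate(bundle))
        m = calculate_metrics(w_hat, key_genes_of(bundle.key_genes))
        assert m.n_mutations == 5
        assert m.n_key_genes == 5
        expected_sdi = shannon_diversity(TABLE1_ABUNDANCES)
        assert m.sdi == pytest.approx(expected_sdi, rel=1e-12)

    def test_empty_relation_is_an_error(self, presentation):
        w_hat = distinct_mutations(integrate(presentation)).iloc[0:0]
        with pytest.raises(ValueError):
            calculate_metrics(w_hat)

    def test_metrics_report_shape(self, presentation):
        w_hat = distinct_mutations(integrate(presentation))
        report = calculate_metrics(w_hat).to_json()
        assert '"N": 5' in report and '"SDI"' in report
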