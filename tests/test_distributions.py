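"""Distribution constructions: printed stimulus statistics and invariants."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from notchrdk import (
    ConfigurationError,
    DiscreteDistribution,
    ExperimentConfig,
    InfeasibleConstraintError,
    build_bandwidth_family,
    build_constant_distance_notched,
    build_direction_gapped,
    build_mean_targeted_notched,
    build_symmetric_notched,
    build_uniform,
    make_conditions,
    moments,
    solve_band_tilt,
    validate_matched,
)


def brute_mean(dist):
    """Independent oracle: direct weighted average over the support."""
    return sum(x * p for x, p in zip(dist.support, dist.probabilities))


class TestBuildUniform:
    @pytest.mark.parametrize(
        "lo, hi, interval, n_points, mean",
        [
            (0.4, 23.6, 1.0, 24, 12.0),  # reference standard: mean 12 deg/s
            (1.2, 8.0, 0.4, 18, 4.6),  # slow-range standard
            (17.2, 24.0, 0.4, 18, 20.6),  # fast-range standard
        ],
    )
    def test_printed_standards(self, lo, hi, interval, n_points, mean):
        d = build_uniform(lo, hi, interval)
        assert d.n_points == n_points
        assert moments(d).global_mean == pytest.approx(mean, abs=1e-9)
        assert d.support[0] == pytest.approx(lo) and d.support[-1] == pytest.approx(hi)

    def test_degenerate_single_point(self):
        d = build_uniform(5.0, 5.0, 1.0)
        assert d.n_points == 1
        assert moments(d).global_mean == 5.0
        assert moments(d).span == 0.0

    def test_equiprobable(self):
        d = build_uniform(0.4, 23.6, 1.0)
        assert np.allclose(d.probabilities, 1 / 24)

    def test_bad_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            build_uniform(0.0, 10.0, -1.0)


class TestSymmetricNotched:
    def test_wide_notch_band_contents(self):
        d = build_symmetric_notched(0.4, 23.6, 19.0, 1.0)
        np.testing.assert_allclose(
            d.support, [0.4, 1.4, 2.4, 21.6, 22.6, 23.6], atol=1e-12
        )
        assert moments(d).global_mean == pytest.approx(12.0, abs=1e-9)

    def test_zero_notch_equals_uniform(self):
        a = build_symmetric_notched(0.4, 23.6, 0.0, 1.0)
        b = build_uniform(0.4, 23.6, 1.0)
        np.testing.assert_array_equal(a.support, b.support)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_band_means_against_brute_force(self):
        # oracle: enumerate the two band grids directly
        lower = np.arange(0.4, 8.5, 1.0)
        upper = 23.6 - np.arange(8.0, -1.0, -1.0)
        d = build_symmetric_notched(0.4, 23.6, 7.0, 1.0)
        m = moments(d)
        assert m.band_means[0] == pytest.approx(lower.mean(), abs=1e-9)
        assert m.band_means[1] == pytest.approx(upper.mean(), abs=1e-9)
        assert m.mean_distance == pytest.approx(15.2, abs=1e-9)

    def test_overwide_notch_rejected(self):
        with pytest.raises(ConfigurationError):
            build_symmetric_notched(0.4, 23.6, 23.2, 1.0)

    @pytest.mark.parametrize("width", [1.0, 4.0, 7.0, 10.0, 13.0, 16.0, 19.0])
    def test_mean_preserved_at_every_notch(self, width):
        d = build_symmetric_notched(0.4, 23.6, width, 1.0)
        assert brute_mean(d) == pytest.approx(12.0, abs=1e-9)


class TestBandTilt:
    BAND = np.arange(0.4, 8.5, 1.0)  # 0.4 .. 8.4

    def test_target_at_unweighted_mean_is_uniform(self):
        w = solve_band_tilt(self.BAND, float(self.BAND.mean()))
        np.testing.assert_allclose(w, 1.0 / self.BAND.size)

    def test_target_hit_exactly(self):
        w = solve_band_tilt(self.BAND, 6.0)
        assert w @ self.BAND == pytest.approx(6.0, abs=1e-6)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w > 0)

    def test_target_below_support_rejected(self):
        with pytest.raises(InfeasibleConstraintError):
            solve_band_tilt(self.BAND, 0.3)

    def test_monotone_weights_when_tilted_up(self):
        # lambda > 0 => weights increase with the support value
        w = solve_band_tilt(self.BAND, 6.0)
        assert np.all(np.diff(w) > 0)

    @given(
        n=st.integers(4, 40),
        lo=st.floats(0.1, 20.0),
        step=st.floats(0.1, 2.0),
        frac=st.floats(0.02, 0.98),
    )
    def test_tilt_solves_any_interior_target(self, n, lo, step, frac):
        band = lo + step * np.arange(n)
        target = band.min() + frac * (band.max() - band.min())
        if not band.min() < target < band.max():
            return
        w = solve_band_tilt(band, float(target))
        assert w @ band == pytest.approx(target, abs=1e-6)

    def test_lambda_monotone_in_target(self):
        # recover lambda from consecutive weight ratios on an even grid
        lams = []
        for target in (3.0, 4.4, 6.0, 7.5):
            w = solve_band_tilt(self.BAND, target)
            lams.append(np.log(w[1] / w[0]))  # = lambda * step (step 1)
        assert np.all(np.diff(lams) > 0)
        assert lams[1] == pytest.approx(0.0, abs=1e-9)  # target = unweighted mean


class TestMeanTargeted:
    def test_untilted_geometry(self):
        d = build_mean_targeted_notched(interval=1.0)  # no tilt
        m = moments(d)
        assert d.range_lo == pytest.approx(0.4) and d.range_hi == pytest.approx(23.6)
        # brute-force oracle on the anchored band grids
        lower = np.arange(0.4, 8.5, 1.0)
        assert m.band_means[0] == pytest.approx(lower.mean(), abs=1e-9)
        assert m.mean_distance == pytest.approx(15.2, abs=1e-9)

    def test_targeted_distance_13(self):
        d = build_mean_targeted_notched(target_mean_distance=13.0, interval=0.2)
        m = moments(d)
        assert m.band_means[0] == pytest.approx(5.5, abs=1e-6)
        assert m.band_means[1] == pytest.approx(18.5, abs=1e-6)
        assert m.global_mean == pytest.approx(12.0, abs=1e-6)

    def test_total_span_is_bands_plus_notch(self):
        d = build_mean_targeted_notched(target_mean_distance=15.0, interval=0.2)
        assert moments(d).span == pytest.approx(2 * 8.1 + 7.0, abs=1e-9)

    def test_impossible_distance_rejected(self):
        with pytest.raises(InfeasibleConstraintError):
            build_mean_targeted_notched(target_mean_distance=40.0, interval=0.2)


class TestBandwidthFamily:
    def test_span_20(self):
        std, cmp_ = build_bandwidth_family(20.0, interval=1.0)
        assert (std.range_lo, std.range_hi) == (2.0, 22.0)
        assert cmp_.support.min() == 2.0 and cmp_.support.max() == 22.0
        assert cmp_.support[cmp_.support <= 12].max() == pytest.approx(8.0)
        assert cmp_.support[cmp_.support > 12].min() == pytest.approx(16.0)
        assert moments(std).global_mean == pytest.approx(moments(cmp_).global_mean)

    def test_narrow_span_fine_grid(self):
        std, cmp_ = build_bandwidth_family(8.0, interval=0.2)
        m = moments(cmp_)
        assert m.global_mean == pytest.approx(12.0, abs=1e-9)
        # bands are only 0.5 deg/s wide
        assert np.ptp(cmp_.support[cmp_.support <= 12]) == pytest.approx(0.4, abs=1e-9)

    def test_span_equal_notch_rejected(self):
        with pytest.raises(ConfigurationError):
            build_bandwidth_family(7.0, interval=1.0)


class TestConstantDistance:
    @pytest.mark.parametrize("speed_range, gmean", [((1.2, 8.0), 4.6), ((17.2, 24.0), 20.6)])
    def test_global_means(self, speed_range, gmean):
        for w in (1.2, 2.0, 3.6, 5.2):
            d = build_constant_distance_notched(*speed_range, w, 6.0, 0.4)
            assert moments(d).global_mean == pytest.approx(gmean, abs=1e-6)

    def test_distance_identical_across_notch_widths(self):
        dists = [
            moments(build_constant_distance_notched(1.2, 8.0, w, 6.0, 0.4)).mean_distance
            for w in (1.2, 2.0, 3.6, 5.2)
        ]
        assert np.ptp(dists) < 1e-6
        assert dists[0] == pytest.approx(6.0, abs=1e-6)

    def test_band_means_against_dot_product_oracle(self):
        d = build_constant_distance_notched(1.2, 8.0, 5.2, 6.0, 0.4)
        lower = d.support <= 4.6
        p = d.probabilities
        assert p[lower] @ d.support[lower] / p[lower].sum() == pytest.approx(1.6, abs=1e-6)

    def test_infeasible_distance_rejected(self):
        with pytest.raises(InfeasibleConstraintError):
            build_constant_distance_notched(1.2, 8.0, 5.2, 7.0, 0.4)

    def test_distance_below_notch_rejected(self):
        with pytest.raises(InfeasibleConstraintError):
            build_constant_distance_notched(1.2, 8.0, 5.2, 4.0, 0.4)


class TestDirectionGapped:
    def test_standard_is_uniform_59_points(self):
        d = build_direction_gapped(58.0, 30.0, 0.0, 1.0)
        assert d.kind == "direction"
        np.testing.assert_allclose(d.support, np.arange(1.0, 60.0))
        assert moments(d).global_mean == pytest.approx(30.0, abs=1e-9)

    def test_widest_gap_bands(self):
        d = build_direction_gapped(58.0, 30.0, 50.0, 1.0)
        np.testing.assert_allclose(d.support, [1, 2, 3, 4, 5, 55, 56, 57, 58, 59])
        assert moments(d).global_mean == pytest.approx(30.0, abs=1e-9)

    @pytest.mark.parametrize("gap", [2.0, 10.0, 18.0, 26.0, 34.0, 42.0, 50.0])
    def test_mean_direction_preserved(self, gap):
        d = build_direction_gapped(58.0, 30.0, gap, 1.0)
        assert moments(d).global_mean == pytest.approx(30.0, abs=1e-9)

    def test_gap_equal_span_rejected(self):
        with pytest.raises(ConfigurationError):
            build_direction_gapped(58.0, 30.0, 58.0, 1.0)


def all_catalogue_conditions():
    return (
        make_conditions(1)
        + make_conditions(2)
        + make_conditions(2, variant="bandwidth")
        + make_conditions(3)
        + make_conditions(3, speed_range="fast")
        + make_conditions(4)
    )


class TestMatchedConstraints:
    def test_every_catalogued_pair_is_matched(self):
        for cond in all_catalogue_conditions():
            report = validate_matched(cond.standard, cond.comparison, tol=1e-6)
            assert report.passed, (cond.label, report.violations)

    def test_reflexive(self):
        d = build_uniform(0.4, 23.6, 1.0)
        assert validate_matched(d, d).passed

    def test_disjoint_ranges_fail_on_endpoints_and_mean(self):
        slow = build_uniform(1.2, 8.0, 0.4)
        fast = build_symmetric_notched(17.2, 24.0, 2.0, 0.4)
        report = validate_matched(slow, fast)
        names = {name for name, _ in report.violations}
        assert not report.passed
        assert {"range_lo", "range_hi", "global_mean"} <= names

    def test_kind_mismatch_is_usage_error(self):
        with pytest.raises(ConfigurationError):
            validate_matched(build_uniform(1.2, 8.0, 0.4), build_direction_gapped())

    def test_probabilities_and_notch_exclusion_everywhere(self):
        for cond in all_catalogue_conditions():
            for d in (cond.standard, cond.comparison):
                assert abs(d.probabilities.sum() - 1.0) < 1e-9
                assert np.all(d.probabilities >= 0)
                if d.notch is not None:
                    lo, hi = d.notch
                    inside = (d.support > lo + 1e-9) & (d.support < hi - 1e-9)
                    assert not inside.any()


class TestSerialization:
    def test_round_trip(self, tmp_path):
        d = build_symmetric_notched(0.4, 23.6, 7.0, 1.0)
        path = tmp_path / "dist.json"
        d.to_json(path)
        loaded = DiscreteDistribution.from_json(path)
        np.testing.assert_array_equal(loaded.support, d.support)
        np.testing.assert_array_equal(loaded.probabilities, d.probabilities)
        assert loaded.notch == pytest.approx(d.notch)
        payload = json.loads(path.read_text())
        assert set(payload) == {
            "kind", "range", "interval", "notch", "support", "probabilities"
        }


class TestExperimentConfig:
    def test_conditions_counts(self):
        assert len(ExperimentConfig(experiment=1).conditions()) == 7
        assert len(ExperimentConfig(experiment=2).conditions()) == 5
        assert len(ExperimentConfig(experiment=4).conditions()) == 21

    def test_uncatalogued_value_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(experiment=1, notch_widths=(2.5,))

    def test_custom_value_allowed_when_not_strict(self):
        cfg = ExperimentConfig(experiment=1, notch_widths=(2.5,), strict=False)
        assert cfg.conditions()[0].param == 2.5
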