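"""Count-trace and PSD estimators: B, delay, window, d90 and G."""

import numpy as np
import pytest
from dataclasses import replace

from xtalkin import secondary, simulate
from xtalkin.errors import InsufficientDataError, InvalidArgumentError
from xtalkin.secondary import PSD_BIN_EDGES


def make_counts(times, counts, calibration=100.0, S=1.1):
    return secondary.CountSeries(
        vial_id="v1",
        supersaturation=S,
        times=np.asarray(times, dtype=float),
        counts=np.asarray(counts, dtype=float),
        calibration_factor=calibration,
    )


def brute_force_d90(sizes, quantile=0.9):
    """Per-particle volume-weighted d90: sort and accumulate L^3."""
    sizes = np.sort(np.asarray(sizes, dtype=float))
    cum = np.cumsum(sizes**3)
    cum = cum / cum[-1]
    return sizes[np.searchsorted(cum, quantile)]


class TestCountsToDensity:
    def test_zero_count_zero_density(self):
        cs = make_counts([0, 1, 2], [0, 0, 0])
        _, dens = secondary.counts_to_density(cs)
        assert np.all(dens == 0)

    def test_linear_calibration(self):
        cs = make_counts([0, 1], [50, 60], calibration=100.0)
        _, dens = secondary.counts_to_density(cs)
        assert dens[0] == 5000.0

    def test_simulator_round_trip_with_shared_factor(self):
        cfg = simulate.SimulationConfig(
            B_true=5000.0, delay_true=5.0, noise=False, seed=0
        )
        cs = simulate.simulate_seeded_counts(cfg, 30.0)
        _, dens = secondary.counts_to_density(cs)
        expected = cfg.B_true * np.maximum(cs.times - cfg.delay_true, 0.0)
        np.testing.assert_allclose(dens, expected, rtol=1e-12)

    def test_non_positive_factor_rejected(self):
        cs = make_counts([0, 1], [1, 2], calibration=100.0)
        cs.calibration_factor = 0.0
        with pytest.raises(InvalidArgumentError):
            secondary.counts_to_density(cs)


class TestDetectDelayTime:
    def test_first_crossing(self):
        cs = make_counts([0, 2, 4, 6], [0, 3, 12, 30])
        assert secondary.detect_delay_time(cs, threshold=10) == 4.0

    def test_all_zero_not_detected(self):
        cs = make_counts([0, 1, 2], [0, 0, 0])
        assert secondary.detect_delay_time(cs) is None

    def test_immediate_crossing(self):
        cs = make_counts([0, 1], [1, 5])
        assert secondary.detect_delay_time(cs, threshold=1) == 0.0


class TestSelectWindow:
    def test_monotone_trace_spans_count_bounds(self):
        times = np.arange(0.0, 21.0)
        counts = 10.0 * times  # 0 .. 200
        cs = make_counts(times, counts)
        t0, t1 = secondary.select_window(cs, 10, 160)
        assert counts[int(t0)] >= 10
        assert counts[int(t1)] <= 160
        assert counts[int(t1) + 1] > 160

    def test_capped_trace_ends_at_last_frame(self):
        times = np.arange(0.0, 10.0)
        counts = np.minimum(10.0 * times, 50.0)
        cs = make_counts(times, counts)
        _, t1 = secondary.select_window(cs, 10, 160)
        assert t1 == times[-1]

    def test_degenerate_jump_rejected(self):
        cs = make_counts([0, 1, 2], [5, 300, 400])
        with pytest.raises(InsufficientDataError):
            secondary.select_window(cs, 10, 160)


class TestEstimateSecondaryRate:
    def test_exact_line(self):
        times = np.arange(5.0, 20.0)
        dens = 5000.0 * (times - 5.0)
        est = secondary.estimate_secondary_rate(
            times, dens, (times[0], times[-1])
        )
        assert est.value == pytest.approx(5000.0, rel=1e-12)
        assert est.quality_warning is None

    def test_constant_density_zero_rate(self):
        times = np.arange(0.0, 10.0)
        est = secondary.estimate_secondary_rate(
            times, np.full_like(times, 800.0), (0.0, 9.0)
        )
        assert est.value == 0.0

    def test_negative_slope_flagged(self):
        times = np.arange(0.0, 5.0)
        est = secondary.estimate_secondary_rate(
            times, 100.0 - 10.0 * times, (0.0, 4.0)
        )
        assert est.quality_warning is not None

    def test_mean_over_noisy_replicates_recovers_truth(self):
        B_true = 2000.0
        estimates = []
        for i in range(200):
            cfg = simulate.SimulationConfig(
                B_true=B_true, delay_true=5.0, noise=True, seed=7000 + i
            )
            cs = simulate.simulate_seeded_counts(cfg, 30.0)
            window = secondary.select_window(cs)
            t, dens = secondary.counts_to_density(cs)
            estimates.append(
                secondary.estimate_secondary_rate(t, dens, window).value
            )
        assert np.mean(estimates) == pytest.approx(B_true, rel=0.05)

    def test_calibration_consistency_doubles_exactly(self):
        cfg = simulate.SimulationConfig(B_true=3000.0, noise=True, seed=5)
        cs = simulate.simulate_seeded_counts(cfg, 30.0)
        window = secondary.select_window(cs)
        t, dens = secondary.counts_to_density(cs)
        B1 = secondary.estimate_secondary_rate(t, dens, window).value
        cs2 = replace(cs, calibration_factor=cs.calibration_factor * 2)
        _, dens2 = secondary.counts_to_density(cs2)
        B2 = secondary.estimate_secondary_rate(t, dens2, window).value
        assert B2 == pytest.approx(2.0 * B1, rel=1e-12)


class TestD90:
    def test_single_bin_containment(self):
        hist = np.zeros(99)
        j = np.searchsorted(PSD_BIN_EDGES, 60.0) - 1
        hist[j] = 25
        d90 = secondary.d90_from_histogram(hist)
        assert PSD_BIN_EDGES[j] <= d90 <= PSD_BIN_EDGES[j + 1]

    def test_equal_volume_bins_put_d90_in_upper(self):
        hist = np.zeros(99)
        mids = 0.5 * (PSD_BIN_EDGES[:-1] + PSD_BIN_EDGES[1:])
        lo, hi = 10, 40
        hist[lo] = 1000.0
        hist[hi] = 1000.0 * mids[lo] ** 3 / mids[hi] ** 3
        d90 = secondary.d90_from_histogram(hist)
        assert PSD_BIN_EDGES[hi] <= d90 <= PSD_BIN_EDGES[hi + 1]

    def test_agrees_with_brute_force_particle_oracle(self, rng):
        bin_width = PSD_BIN_EDGES[1] - PSD_BIN_EDGES[0]
        for _ in range(100):
            n = rng.integers(20, 500)
            sizes = rng.uniform(4.0, 290.0, n)
            hist, _ = np.histogram(sizes, bins=PSD_BIN_EDGES)
            d90_hist = secondary.d90_from_histogram(hist)
            d90_exact = brute_force_d90(sizes)
            assert abs(d90_hist - d90_exact) <= bin_width

    def test_d90_at_least_d50(self, rng):
        for _ in range(20):
            hist = rng.integers(0, 50, 99).astype(float)
            if hist.sum() < 1:
                continue
            d90 = secondary.d90_from_histogram(hist, quantile=0.9)
            d50 = secondary.d90_from_histogram(hist, quantile=0.5)
            assert d90 >= d50

    def test_invariant_to_count_scaling(self, rng):
        hist = rng.integers(1, 50, 99).astype(float)
        assert secondary.d90_from_histogram(hist) == pytest.approx(
            secondary.d90_from_histogram(7.0 * hist), rel=1e-12
        )

    def test_sparse_frames_skipped(self):
        times = np.array([0.0, 1.0])
        hists = np.zeros((2, 99))
        hists[1, 30] = 50
        psd = secondary.PSDSeries("v", 1.1, times, hists)
        pts = secondary.d90_series(psd)
        assert [t for t, _ in pts] == [1.0]


class TestEstimateGrowthRate:
    def test_exact_linear_trajectory(self):
        pts = [(t, 30.0 + 12.0 * t) for t in np.arange(0.0, 10.0)]
        est = secondary.estimate_growth_rate(pts, (0.0, 9.0))
        assert est.value == pytest.approx(12.0, rel=1e-12)

    def test_frozen_psd_zero_growth(self):
        cohort = np.full(50, 10.0)
        cfg = simulate.SimulationConfig(B_true=0.0, G_true=0.0, noise=False, seed=0)
        psd = simulate.simulate_psd_series(cfg, 5.0, initial_cohort=cohort)
        pts = secondary.d90_series(psd)
        est = secondary.estimate_growth_rate(pts, (pts[0][0], pts[-1][0]))
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulator_truth_within_ten_percent(self):
        cfg = simulate.SimulationConfig(
            B_true=1000.0, G_true=10.0, delay_true=0.0, noise=True, seed=3
        )
        psd = simulate.simulate_psd_series(cfg, 20.0)
        pts = secondary.d90_series(psd)
        est = secondary.estimate_growth_rate(pts, (pts[0][0], pts[-1][0]))
        assert est.value == pytest.approx(10.0, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            secondary.estimate_growth_rate([(0.0, 5.0), (1.0, 6.0)], (0.0, 1.0))
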