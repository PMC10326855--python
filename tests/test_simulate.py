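"""Statistical and structural properties of the instrument simulator."""

import numpy as np
import pytest
from scipy import stats

from xtalkin import simulate
from xtalkin.errors import InvalidArgumentError


class TestInductionSimulator:
    def test_zero_rate_all_censored(self):
        cfg = simulate.SimulationConfig(J_true=0.0, seed=1)
        ds = simulate.simulate_induction_times(cfg, 50)
        assert ds.n_nucleated == 0
        assert ds.n_censored == 50

    def test_huge_rate_offset_dominates(self):
        cfg = simulate.SimulationConfig(J_true=1e3, V=3.0, t_g_true=37.0, seed=2)
        ds = simulate.simulate_induction_times(cfg, 100)
        assert np.all(np.abs(ds.times - 37.0) < 0.1)

    def test_nucleated_fraction_matches_exponential_cdf(self):
        # truth: fraction = 1 - exp(-J*V*(censor - t_g))
        cfg = simulate.SimulationConfig(
            J_true=1.3e-3, V=3.0, t_g_true=37.0, censor_time=240.0, seed=42
        )
        n = 100_000
        ds = simulate.simulate_induction_times(cfg, n)
        p = 1.0 - np.exp(-1.3e-3 * 3.0 * (240.0 - 37.0))
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(ds.n_nucleated / n - p) < 3 * sigma

    def test_uncensored_waiting_times_pass_ks(self):
        cfg = simulate.SimulationConfig(
            J_true=2e-3, V=3.0, t_g_true=0.0, censor_time=1e9, seed=5
        )
        ds = simulate.simulate_induction_times(cfg, 100_000)
        res = stats.kstest(ds.times, "expon", args=(0.0, 1.0 / (2e-3 * 3.0)))
        # 1% critical value of the KS statistic for large n
        assert res.statistic < 1.63 / np.sqrt(100_000)

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = simulate.SimulationConfig(seed=9)
        a = simulate.simulate_induction_times(cfg, 100)
        b = simulate.simulate_induction_times(cfg, 100)
        np.testing.assert_array_equal(a.times, b.times)


class TestSeededCountSimulator:
    def test_zero_rate_gives_flat_zero_trace(self):
        cfg = simulate.SimulationConfig(B_true=0.0, delay_true=5.0, seed=1)
        cs = simulate.simulate_seeded_counts(cfg, 30.0)
        assert np.all(cs.counts == 0)

    def test_deterministic_mode_exactly_linear_after_delay(self):
        cfg = simulate.SimulationConfig(
            B_true=5000.0, delay_true=5.0, noise=False, seed=1
        )
        cs = simulate.simulate_seeded_counts(cfg, 30.0)
        expected = 5000.0 * np.maximum(cs.times - 5.0, 0.0) / cfg.calibration_factor
        np.testing.assert_allclose(cs.counts, expected, rtol=1e-12)

    def test_noisy_counts_are_non_negative_integers(self):
        cfg = simulate.SimulationConfig(B_true=5000.0, noise=True, seed=4)
        cs = simulate.simulate_seeded_counts(cfg, 30.0)
        assert np.all(cs.counts >= 0)
        assert np.all(cs.counts == np.round(cs.counts))

    def test_mean_fitted_slope_tracks_generating_rate(self):
        from xtalkin import secondary

        slopes = []
        for i in range(200):
            # frame interval chosen to resolve the 10-160 count window,
            # which spans only ~3 min at this nucleation rate
            cfg = simulate.SimulationConfig(
                B_true=5000.0, delay_true=5.0, noise=True, seed=100 + i,
                time_step=0.1,
            )
            cs = simulate.simulate_seeded_counts(cfg, 30.0)
            window = secondary.select_window(cs)
            t, dens = secondary.counts_to_density(cs)
            slopes.append(secondary.estimate_secondary_rate(t, dens, window).value)
        assert np.mean(slopes) == pytest.approx(5000.0, rel=0.02)

    def test_duration_must_exceed_delay(self):
        cfg = simulate.SimulationConfig(delay_true=10.0)
        with pytest.raises(InvalidArgumentError):
            simulate.simulate_seeded_counts(cfg, 5.0)


class TestPsdSimulator:
    def test_frozen_system_frames_identical(self):
        cfg = simulate.SimulationConfig(B_true=0.0, G_true=0.0, noise=False, seed=1)
        psd = simulate.simulate_psd_series(
            cfg, 5.0, initial_cohort=np.full(30, 10.0)
        )
        for frame in psd.histograms[1:]:
            np.testing.assert_array_equal(frame, psd.histograms[0])

    def test_single_particle_crosses_one_bin_per_bin_width_time(self):
        # bin width 3 um at G = 2 um/min -> one bin crossing per 1.5 min
        cfg = simulate.SimulationConfig(
            B_true=0.0, G_true=2.0, noise=False, time_step=1.5, seed=1
        )
        psd = simulate.simulate_psd_series(
            cfg, 15.0, initial_cohort=np.array([10.5])
        )
        bins = [int(np.argmax(h)) for h in psd.histograms]
        assert np.all(np.diff(bins) == 1)

    def test_particle_conservation_with_fixed_cohort(self):
        # 50 particles at 10 um growing at 30 um/min: all visible until
        # they cross the 300 um ceiling, then they leave the histogram
        cfg = simulate.SimulationConfig(
            B_true=0.0, G_true=30.0, noise=False, seed=8
        )
        psd = simulate.simulate_psd_series(
            cfg, 15.0, initial_cohort=np.full(50, 10.0)
        )
        sizes = 10.0 + 30.0 * psd.times
        for frame, size in zip(psd.histograms, sizes):
            assert frame.sum() == (50 if size <= 300.0 else 0)

    def test_histogram_counts_bounded_by_births(self):
        cfg = simulate.SimulationConfig(
            B_true=500.0, G_true=5.0, delay_true=0.0, noise=True, seed=8
        )
        psd = simulate.simulate_psd_series(cfg, 20.0)
        totals = psd.histograms.sum(axis=1)
        # all sizes stay below 300 um here, so visibility only grows as
        # particles cross the 3 um floor: frame totals are non-decreasing
        assert np.all(np.diff(totals) >= 0)

    def test_d90_slope_recovers_growth_rate(self):
        from xtalkin import secondary

        cfg = simulate.SimulationConfig(
            B_true=1000.0, G_true=10.0, delay_true=0.0, noise=True, seed=3
        )
        psd = simulate.simulate_psd_series(cfg, 20.0)
        pts = secondary.d90_series(psd)
        est = secondary.estimate_growth_rate(pts, (pts[0][0], pts[-1][0]))
        assert est.value == pytest.approx(10.0, rel=0.10)

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = simulate.SimulationConfig(B_true=500.0, seed=12)
        a = simulate.simulate_psd_series(cfg, 10.0)
        b = simulate.simulate_psd_series(cfg, 10.0)
        np.testing.assert_array_equal(a.histograms, b.histograms)


class TestWorkflowSuite:
    def test_cardinality_matches_supersaturations(self, kinetic_laws):
        cfg = simulate.SimulationConfig(seed=3)
        S = [1.06 + 0.02 * i for i in range(7)]
        suite = simulate.simulate_workflow_suite(
            kinetic_laws["growth"],
            kinetic_laws["secondary"],
            kinetic_laws["primary"],
            S,
            cfg,
            n_vials=5,
            n_seeded=2,
        )
        assert len(suite.induction) == 7
        assert all(len(v) == 2 for v in suite.counts.values())
        assert suite.truth["per_S"][S[0]]["G"] > 0

    def test_empty_supersaturation_list_rejected(self, kinetic_laws):
        with pytest.raises(InvalidArgumentError):
            simulate.simulate_workflow_suite(
                kinetic_laws["growth"],
                kinetic_laws["secondary"],
                kinetic_laws["primary"],
                [],
                simulate.SimulationConfig(),
            )

    def test_saturated_solution_rejected(self, kinetic_laws):
        with pytest.raises(InvalidArgumentError):
            simulate.simulate_workflow_suite(
                kinetic_laws["growth"],
                kinetic_laws["secondary"],
                kinetic_laws["primary"],
                [1.0],
                simulate.SimulationConfig(),
            )
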