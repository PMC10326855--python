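"""Monte-Carlo simulator of the instrument-level datasets.

Generates the three data streams the estimators consume, with the
statistical structure the analysis assumes:

* unseeded induction times: a single primary nucleation event per vial at
  an exponential waiting time with rate J*V, plus a deterministic growth
  offset t_g, censored at the end of the isothermal hold;
* seeded count traces: zero before the secondary-nucleation delay, then a
  linearly rising particle number density B*(t - delay) converted to
  counts per image through the calibration factor, optionally with
  Poisson detection noise per frame;
* PSD series: secondary nuclei born at rate B*V below the 3-um detection
  floor, all growing at the prevailing rate G, histogrammed each frame
  into the instrument's 99 linear bins over 3-300 um.

Solute depletion is neglected (concentration changes < 1% over the
measurement window) and all crystals share a single growth rate; growth
rate dispersion between individuals is a known simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from xtalkin.core import PowerLawFit, evaluate_power_law
from xtalkin.errors import InvalidArgumentError
from xtalkin.induction import InductionDataset
from xtalkin.secondary import (
    CountSeries,
    PSDSeries,
    PSD_BIN_EDGES,
    DEFAULT_CALIBRATION,
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters and detection geometry for the simulator.

    Rates and scales default to the magnitudes typical of glycine/water
    vial experiments at 25 degC: J of order 1e-3 nuclei/(mL min) in 3 mL
    vials with tens-of-minutes growth offsets, seeded secondary
    nucleation of order 1e3-1e4 particles/(mL min) after a ~5 min delay,
    and growth rates of order 10 um/min.
    """

    J_true: float = 1.3e-3  # nuclei/(mL min)
    V: float = 3.0  # mL
    t_g_true: float = 37.0  # min
    censor_time: float = 240.0  # min
    B_true: float = 5000.0  # particles/(mL min)
    delay_true: float = 5.0  # min
    G_true: float = 10.0  # um/min
    calibration_factor: float = DEFAULT_CALIBRATION  # (particles/mL)/(count/image)
    initial_size_um: float = 1.0  # birth size of secondary nuclei
    bin_edges: np.ndarray = field(
        default_factory=lambda: PSD_BIN_EDGES.copy()
    )
    time_step: float = 1.0  # min between frames
    noise: bool = True  # Poisson detection noise on count frames
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.J_true, self.t_g_true, self.B_true, self.G_true) < 0:
            raise InvalidArgumentError("rates and offsets must be non-negative")
        if self.V <= 0 or self.censor_time <= 0 or self.time_step <= 0:
            raise InvalidArgumentError("V, censor_time, time_step must be positive")
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size != 100 or np.any(np.diff(edges) <= 0):
            raise InvalidArgumentError("bin_edges must be 100 increasing edges")
        self.bin_edges = edges

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass
class WorkflowSuite:
    """Bundle of simulated datasets across supersaturations, with truth."""

    S_values: list[float]
    induction: dict[float, InductionDataset]
    counts: dict[float, list[CountSeries]]
    psd: dict[float, list[PSDSeries]]
    truth: dict


def simulate_induction_times(
    config: SimulationConfig, n_vials: int
) -> InductionDataset:
    """Simulate one censored induction-time ensemble.

    Each vial nucleates after an exponential waiting time with per-vial
    rate J*V; the recorded induction time adds the growth offset t_g.
    Times beyond the censor time are recorded as censored.  J = 0 yields
    an all-censored (still valid) dataset.
    """
    if n_vials < 1:
        raise InvalidArgumentError("need at least one vial")
    rng = config.rng(stream=1)
    rate = config.J_true * config.V
    if rate > 0:
        waiting = rng.exponential(scale=1.0 / rate, size=n_vials)
    else:
        waiting = np.full(n_vials, np.inf)
    induction = waiting + config.t_g_true
    observed = induction[induction <= config.censor_time]
    n_censored = int(n_vials - observed.size)
    return InductionDataset(
        supersaturation=float("nan"),
        times=observed,
        n_censored=n_censored,
        volume_mL=config.V,
        censor_time=config.censor_time,
    )


def simulate_seeded_counts(
    config: SimulationConfig, duration: float, vial_id: str = "sim"
) -> CountSeries:
    """Simulate a seeded particle-count trace.

    Counts are zero before the delay; afterwards the expected number
    density rises linearly at B_true, converted to counts per image via
    the calibration factor.  With ``config.noise`` each frame is a
    Poisson draw around the expectation (integer counts); in
    deterministic mode the trace is exactly linear.
    """
    if duration <= config.delay_true:
        raise InvalidArgumentError("duration must exceed the delay time")
    rng = config.rng(stream=2)
    times = np.arange(0.0, duration + 1e-9, config.time_step)
    expected_density = config.B_true * np.maximum(times - config.delay_true, 0.0)
    expected_counts = expected_density / config.calibration_factor
    if config.noise:
        counts = rng.poisson(expected_counts).astype(float)
    else:
        counts = expected_counts
    return CountSeries(
        vial_id=vial_id,
        supersaturation=float("nan"),
        times=times,
        counts=counts,
        calibration_factor=config.calibration_factor,
    )


def simulate_psd_series(
    config: SimulationConfig,
    duration: float,
    vial_id: str = "sim",
    initial_cohort: np.ndarray | None = None,
) -> PSDSeries:
    """Simulate the evolving number-weighted PSD under constant growth.

    Particles are born at rate B_true*V (Poisson per frame interval, or
    the rounded expectation in deterministic mode) at ``initial_size_um``
    below the 3-um detection floor, starting after the secondary
    nucleation delay (``delay_true``, consistent with the count traces),
    and every particle grows linearly at G_true.  Each frame histograms
    the live sizes into the instrument bins; particles outside 3-300 um
    are invisible to the camera.

    ``initial_cohort`` optionally places particles of given sizes (um) in
    the vial at t = 0 in addition to (or, with B_true = 0, instead of)
    the nucleation stream.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = config.rng(stream=3)
    times = np.arange(0.0, duration + 1e-9, config.time_step)
    births_per_step = config.B_true * config.V * config.time_step
    birth_times: list[np.ndarray] = []
    birth_sizes: list[np.ndarray] = []
    if initial_cohort is not None:
        cohort = np.asarray(initial_cohort, dtype=float)
        birth_times.append(np.zeros(cohort.size))
        birth_sizes.append(cohort)
    # births attributed to the start of each inter-frame interval, once
    # the secondary-nucleation delay has elapsed
    for t0 in times[:-1]:
        if t0 < config.delay_true:
            continue
        n = (
            rng.poisson(births_per_step)
            if config.noise
            else int(round(births_per_step))
        )
        if n > 0:
            birth_times.append(np.full(n, t0))
            birth_sizes.append(np.full(n, config.initial_size_um))
    if birth_times:
        bt = np.concatenate(birth_times)
        bs = np.concatenate(birth_sizes)
    else:
        bt = np.empty(0)
        bs = np.empty(0)
    hists = np.zeros((times.size, 99))
    for i, t in enumerate(times):
        alive = bt <= t
        sizes = bs[alive] + config.G_true * (t - bt[alive])
        hists[i], _ = np.histogram(sizes, bins=config.bin_edges)
    return PSDSeries(
        vial_id=vial_id,
        supersaturation=float("nan"),
        times=times,
        histograms=hists,
    )


def simulate_workflow_suite(
    growth_law: PowerLawFit,
    secondary_law: PowerLawFit,
    primary_law: PowerLawFit,
    S_values: list[float],
    config: SimulationConfig,
    n_vials: int = 25,
    n_seeded: int = 3,
    offset_size_um: float | None = None,
    count_duration: float | None = None,
    psd_duration: float | None = None,
) -> WorkflowSuite:
    """Simulate the full rapid-assessment study across supersaturations.

    For each S, the ground-truth rates J, B, G are evaluated from the
    supplied power laws; the induction offset t_g is set to
    ``offset_size_um / G(S)`` when an offset size is given (emulating a
    fixed minimum crystal size to initiate detectable secondary
    nucleation), else to ``config.t_g_true``.  Each S yields one
    induction ensemble, ``n_seeded`` seeded count traces and PSD series.
    Truth parameters are embedded in the bundle for test harnesses.

    Unless explicit durations are given, the frame interval and trace
    duration at each S are chosen so that the 10-160 count window is
    resolved by at least a dozen frames and the trace runs just past the
    count saturating 160, mirroring how measurement times scale with the
    secondary nucleation rate.
    """
    if not S_values:
        raise InvalidArgumentError("need at least one supersaturation")
    if any(S <= 1.0 for S in S_values):
        raise InvalidArgumentError("all supersaturations must exceed 1")
    induction: dict[float, InductionDataset] = {}
    counts: dict[float, list[CountSeries]] = {}
    psd: dict[float, list[PSDSeries]] = {}
    truth: dict = {
        "growth": {"k": growth_law.prefactor, "n": growth_law.exponent},
        "secondary": {"k": secondary_law.prefactor, "n": secondary_law.exponent},
        "primary": {"k": primary_law.prefactor, "n": primary_law.exponent},
        "offset_size_um": offset_size_um,
        "per_S": {},
    }
    for i, S in enumerate(S_values):
        G = float(evaluate_power_law(growth_law, S))
        B = float(evaluate_power_law(secondary_law, S))
        J = float(evaluate_power_law(primary_law, S))
        t_g = offset_size_um / G if offset_size_um is not None else config.t_g_true
        # times (min) at which the expected count crosses the imaging window
        t_low = config.delay_true + 10.0 * config.calibration_factor / B
        t_high = config.delay_true + 160.0 * config.calibration_factor / B
        window_span = t_high - t_low
        step = min(config.time_step, window_span / 12.0)
        dur_counts = (
            count_duration
            if count_duration is not None
            else t_high + max(2.0 * step, 0.1 * window_span)
        )
        dur_psd = psd_duration if psd_duration is not None else dur_counts
        local = replace(
            config,
            J_true=J,
            B_true=B,
            G_true=G,
            t_g_true=t_g,
            time_step=step,
            seed=config.seed + 1000 * (i + 1),
        )
        ds = simulate_induction_times(local, n_vials)
        ds.supersaturation = S
        induction[S] = ds
        cs_list, ps_list = [], []
        for j in range(n_seeded):
            vial_cfg = replace(local, seed=local.seed + j + 1)
            cs = simulate_seeded_counts(
                vial_cfg, dur_counts, vial_id=f"S{S:.3f}-seed{j}"
            )
            cs.supersaturation = S
            cs_list.append(cs)
            ps = simulate_psd_series(
                vial_cfg, dur_psd, vial_id=f"S{S:.3f}-seed{j}"
            )
            ps.supersaturation = S
            ps_list.append(ps)
        counts[S] = cs_list
        psd[S] = ps_list
        truth["per_S"][S] = {"J": J, "B": B, "G": G, "t_g": t_g}
    return WorkflowSuite(
        S_values=list(S_values),
        induction=induction,
        counts=counts,
        psd=psd,
        truth=truth,
    )
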