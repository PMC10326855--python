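"""Secondary nucleation and growth rates from in-situ imaging data.

A single large seed crystal added to a supersaturated, agitated solution
produces a burst of secondary nuclei after a short delay.  The instrument
camera reports (a) a particle count per image over time and (b) a
number-weighted particle size distribution (PSD) histogrammed into 99
linear bins spanning 3-300 um.  From these two streams this module
estimates:

* the secondary nucleation rate B, as the slope of particle number density
  (counts converted to particles/mL via a calibration factor) against
  time, within the window where the image count rises from 10 to 160 --
  below 10 counts are background-dominated, above ~160 particles overlap
  and the count saturates;
* the delay time between seed addition and detectable secondary
  nucleation, as the first threshold crossing of the count trace;
* the crystal growth rate G, as the slope of the volume-weighted d90
  against time, d90 tracking the largest (earliest-born) crystals and so
  being insensitive to ongoing nucleation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from xtalkin.errors import InsufficientDataError, InvalidArgumentError

PSD_N_BINS = 99
PSD_MIN_UM = 3.0
PSD_MAX_UM = 300.0
#: Linear bin edges of the instrument PSD histogram (100 edges, 99 bins).
PSD_BIN_EDGES = np.linspace(PSD_MIN_UM, PSD_MAX_UM, PSD_N_BINS + 1)

DEFAULT_WINDOW_LOW = 10
DEFAULT_WINDOW_HIGH = 160
DEFAULT_CALIBRATION = 100.0
#: Frames with fewer particles than this are background and skipped for d90.
D90_MIN_COUNT = 10

#: Sentinel returned when a count trace never reaches the delay threshold.
NOT_DETECTED = None


@dataclass
class CountSeries:
    """Particle count per image over time for one vial.

    ``calibration_factor`` converts count/image to particles/mL.  The seed
    crystal itself (nominal 2500 +/- 1000 um) is too large for the imaging
    optics and does not appear in the counts.
    """

    vial_id: str
    supersaturation: float
    times: np.ndarray
    counts: np.ndarray
    calibration_factor: float = DEFAULT_CALIBRATION
    seed_size_um: float = 2500.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise InvalidArgumentError("times and counts must align")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")


@dataclass
class PSDSeries:
    """Time-stamped number-weighted PSD histograms (99 bins, 3-300 um)."""

    vial_id: str
    supersaturation: float
    times: np.ndarray
    histograms: np.ndarray  # shape (n_frames, 99)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.histograms = np.asarray(self.histograms, dtype=float)
        if self.histograms.ndim != 2 or self.histograms.shape[1] != PSD_N_BINS:
            raise InvalidArgumentError(
                f"histograms must have {PSD_N_BINS} bins per frame"
            )
        if self.histograms.shape[0] != self.times.size:
            raise InvalidArgumentError("times and histograms must align")
        if np.any(self.histograms < 0):
            raise InvalidArgumentError("histogram counts must be non-negative")


@dataclass
class RateEstimate:
    """A slope-derived rate (B or G) with its fitting window and diagnostics."""

    value: float
    stderr: float
    window: tuple[float, float]
    n_frames: int
    r_squared: float
    kind: str  # "secondary_nucleation" or "growth"
    quality_warning: str | None = None
    supersaturation: float = float("nan")


def counts_to_density(series: CountSeries) -> tuple[np.ndarray, np.ndarray]:
    """Convert a count trace to particle number density (particles/mL).

    The instrument calibration is modelled as a linear factor:
    density = count * calibration_factor, applied frame-wise.
    Returns (times, densities).
    """
    if series.calibration_factor <= 0:
        raise InvalidArgumentError("calibration factor must be positive")
    return series.times.copy(), series.counts * series.calibration_factor


def detect_delay_time(
    series: CountSeries, threshold: float = DEFAULT_WINDOW_LOW
) -> float | None:
    """Delay from seed addition (t = 0) to the count reaching ``threshold``.

    Returns the first frame time at which count >= threshold, or ``None``
    (not detected) if the trace never reaches it.
    """
    if threshold < 1:
        raise InvalidArgumentError("threshold must be >= 1")
    idx = np.nonzero(series.counts >= threshold)[0]
    if idx.size == 0:
        return NOT_DETECTED
    return float(series.times[idx[0]])


def select_window(
    series: CountSeries,
    low: float = DEFAULT_WINDOW_LOW,
    high: float = DEFAULT_WINDOW_HIGH,
) -> tuple[float, float]:
    """Imaging validity window for slope fits.

    Spans from the first frame with count >= ``low`` through the last
    frame with count <= ``high`` before the trace first exceeds ``high``
    (or the final frame if it never does).  Requires at least 3 frames in
    the window.
    """
    if low >= high:
        raise InvalidArgumentError("window low must be below high")
    start_idx = np.nonzero(series.counts >= low)[0]
    if start_idx.size == 0:
        raise InsufficientDataError(f"count never reaches window low ({low})")
    i0 = int(start_idx[0])
    over = np.nonzero(series.counts > high)[0]
    i1 = int(over[0]) - 1 if over.size else series.counts.size - 1
    # step back over any frames above high just before saturation
    while i1 >= i0 and series.counts[i1] > high:
        i1 -= 1
    if i1 - i0 + 1 < 3:
        raise InsufficientDataError(
            "fewer than 3 frames inside the count window"
        )
    return float(series.times[i0]), float(series.times[i1])


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times <= window[1])


def estimate_secondary_rate(
    times: np.ndarray,
    densities: np.ndarray,
    window: tuple[float, float],
    supersaturation: float = float("nan"),
) -> RateEstimate:
    """Secondary nucleation rate B as the OLS slope of density vs time.

    ``densities`` in particles/mL, times in min, within ``window``.  A
    negative fitted slope is reported with a quality warning rather than
    silently clipped.
    """
    times = np.asarray(times, dtype=float)
    densities = np.asarray(densities, dtype=float)
    mask = _window_mask(times, window)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 frames in fitting window")
    res = stats.linregress(times[mask], densities[mask])
    warning = "negative fitted slope" if res.slope < 0 else None
    return RateEstimate(
        value=float(res.slope),
        stderr=float(res.stderr),
        window=window,
        n_frames=int(mask.sum()),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        kind="secondary_nucleation",
        quality_warning=warning,
        supersaturation=supersaturation,
    )


def d90_from_histogram(
    histogram: np.ndarray,
    bin_edges: np.ndarray = PSD_BIN_EDGES,
    quantile: float = 0.9,
) -> float:
    """Volume-weighted d90 of one number-weighted histogram frame.

    Volume weight per bin is count * midpoint**3 (the shape factor cancels
    in the volume fraction); d90 is the size at which the cumulative
    volume fraction reaches 0.90, linearly interpolated within the
    containing bin.  Other volume quantiles (e.g. d50) are available via
    ``quantile``.
    """
    if not 0.0 < quantile < 1.0:
        raise InvalidArgumentError("quantile must lie in (0, 1)")
    histogram = np.asarray(histogram, dtype=float)
    total = histogram.sum()
    if total < 1:
        raise InsufficientDataError("empty histogram frame")
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    vol = histogram * mids**3
    cum = np.cumsum(vol) / vol.sum()
    j = int(np.searchsorted(cum, quantile))
    frac_below = cum[j - 1] if j > 0 else 0.0
    frac_in_bin = cum[j] - frac_below
    width = bin_edges[j + 1] - bin_edges[j]
    return float(bin_edges[j] + (quantile - frac_below) / frac_in_bin * width)


def d90_series(
    psd: PSDSeries, min_count: int = D90_MIN_COUNT
) -> list[tuple[float, float]]:
    """Per-frame (time, d90) trajectory, skipping sparse frames.

    Frames with fewer than ``min_count`` total particles are dominated by
    background and excluded.
    """
    out: list[tuple[float, float]] = []
    for t, hist in zip(psd.times, psd.histograms):
        if hist.sum() < min_count:
            continue
        out.append((float(t), d90_from_histogram(hist)))
    return out


def estimate_growth_rate(
    d90_points: list[tuple[float, float]],
    window: tuple[float, float],
    supersaturation: float = float("nan"),
) -> RateEstimate:
    """Crystal growth rate G (um/min) as the OLS slope of d90 vs time."""
    if not d90_points:
        raise InsufficientDataError("no d90 points supplied")
    times = np.array([p[0] for p in d90_points])
    sizes = np.array([p[1] for p in d90_points])
    mask = _window_mask(times, window)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 d90 points in window")
    res = stats.linregress(times[mask], sizes[mask])
    return RateEstimate(
        value=float(res.slope),
        stderr=float(res.stderr),
        window=window,
        n_frames=int(mask.sum()),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        kind="growth",
        supersaturation=supersaturation,
    )
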