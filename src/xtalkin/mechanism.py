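"""Single-nucleus-mechanism syntheses across supersaturations.

Under the single-nucleus mechanism, the primary nucleus in an unseeded
vial must grow to a minimum size L_sn before secondary nucleation becomes
fast enough to detect, so the induction-time offset (minimum induction
time, or the fitted growth time t_g) is L_sn / G(S).  Plotting the offset
against 1/G and fitting a line through the origin therefore estimates
L_sn, independent of supersaturation.

In seeded experiments the analogous plot of mean delay time against 1/G
has a free intercept: the intercept is the minimum delay for secondary
nucleation to start once a seed is immersed (boundary-layer development),
and the slope is the size new nuclei must reach to be detected by the
imaging optics.

The behavior-assessment table aligns growth, secondary-nucleation and
primary-nucleation rates at shared supersaturations to expose their
relative magnitudes (secondary rates per seed exceed primary rates per
vial by many orders of magnitude in glycine/water).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from xtalkin.core import PowerLawFit, evaluate_power_law
from xtalkin.errors import InsufficientDataError, InvalidArgumentError
from xtalkin.induction import InductionFit
from xtalkin.secondary import RateEstimate


@dataclass(frozen=True)
class OffsetPoint:
    """One (offset, 1/G) pair for the through-origin minimum-size fit."""

    supersaturation: float
    offset_min: float  # MIT or fitted t_g, minutes
    inverse_growth: float  # min/um, from the growth power law at this S

    def __post_init__(self) -> None:
        if self.offset_min <= 0 or self.inverse_growth <= 0:
            raise InvalidArgumentError("offset and 1/G must be positive")


@dataclass
class MechanismSummary:
    """Mechanistic sizes and delays synthesised from the rate estimates.

    ``L_sn_mit`` / ``L_sn_tg`` are the minimum crystal sizes (um) to
    initiate detectable secondary nucleation, from the MIT-based and
    t_g-based offset fits respectively; ``t_min_delay`` (min) is the
    seeded-delay intercept and ``L_det`` (um) the detectable-size slope.
    """

    L_sn_mit: float | None = None
    L_sn_tg: float | None = None
    t_min_delay: float | None = None
    L_det: float | None = None
    diagnostics: dict | None = None


def offset_fit_through_origin(points: list[OffsetPoint]) -> float:
    """Minimum size L_sn (um) from a through-origin fit of offset vs 1/G.

    Least-squares slope constrained through the origin,
    slope = sum(x*y) / sum(x*x); the slope carries units of um since the
    abscissa is min/um and the ordinate min.
    """
    if len(points) < 2:
        raise InsufficientDataError("through-origin fit needs >=2 points")
    x = np.array([p.inverse_growth for p in points])
    y = np.array([p.offset_min for p in points])
    return float(np.sum(x * y) / np.sum(x * x))


def delay_fit_free_intercept(
    points: list[tuple[float, float]]
) -> tuple[float, float]:
    """Fit mean seeded delay vs 1/G with a free intercept.

    ``points`` are (1/G in min/um, mean delay in min).  Returns
    (t_min_delay, L_det): the intercept is the minimum delay (min) in the
    fast-growth limit and the slope the detectable crystal size (um).
    """
    if len(points) < 3:
        raise InsufficientDataError("delay fit needs >=3 points")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.ptp(x) == 0:
        # degenerate abscissa: slope indeterminate, report the mean delay
        return float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope)


def predicted_growth_time(
    L_sn: float, growth_fit: PowerLawFit, S: float
) -> float:
    """Theoretical growth time t_g(S) = L_sn / G(S), minutes.

    The time for a fresh nucleus to reach the minimum size L_sn at the
    power-law growth rate; strictly decreasing in S.
    """
    if S <= 1.0:
        raise InvalidArgumentError("supersaturation must exceed 1")
    if L_sn <= 0:
        raise InvalidArgumentError("minimum size must be positive")
    return L_sn / float(evaluate_power_law(growth_fit, S))


def behavior_table(
    induction_fits: list[InductionFit],
    secondary_rates: list[RateEstimate],
    growth_fit: PowerLawFit,
) -> list[dict]:
    """Crystallization-behavior assessment rows (S, G, B, J*V).

    Aligns primary-nucleation fits (J*V per vial, 1/min) and seeded
    secondary rates (per single seed in the vial volume, particles/(mL
    min)) on their supersaturations, with G evaluated from the growth
    power law.  Rows are emitted for every S that has at least one rate;
    missing quantities are None.
    """
    S_primary = {round(f.supersaturation, 6): f for f in induction_fits}
    S_secondary: dict[float, list[RateEstimate]] = {}
    for r in secondary_rates:
        S_secondary.setdefault(round(r.supersaturation, 6), []).append(r)
    all_S = sorted(set(S_primary) | set(S_secondary))
    if not all_S:
        raise InsufficientDataError("no rate estimates to tabulate")
    rows = []
    for S in all_S:
        ind = S_primary.get(S)
        secs = S_secondary.get(S, [])
        rows.append(
            {
                "S": S,
                "G_um_per_min": float(evaluate_power_law(growth_fit, S)),
                "B_per_mL_min": (
                    float(np.mean([r.value for r in secs])) if secs else None
                ),
                "JV_per_min": ind.JV if ind else None,
                "J_per_mL_min": ind.J if ind else None,
            }
        )
    return rows
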