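"""Shared domain types, supersaturation arithmetic and power-law kinetics.

Supersaturation is the ratio S = C / C_s of solution concentration to the
equilibrium solubility at the working temperature; both are expressed as
solute mass per solvent mass (mg per g of water).  Crystal growth rates G
and secondary nucleation rates B both follow empirical power laws in the
driving force, rate = k * (S - 1)**n, which this module fits in log-log
space and inverts to find the supersaturation required for a target rate.

Solubility itself is estimated from clear-point temperatures measured at
several heating rates and extrapolated to zero heating rate (dissolution is
kinetically limited, so the intercept is the equilibrium value), then
summarised by a van't Hoff model ln C = a - b / T(K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from xtalkin.errors import InsufficientDataError, InvalidArgumentError

#: Equilibrium solubility of alpha-glycine in water at 25 degC, mg per g of
#: water.  Used as the default reference when computing supersaturation.
DEFAULT_SOLUBILITY_MG_PER_G = 249.52

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class SupersaturationSpec:
    """Solution state from which supersaturation is computed.

    Parameters
    ----------
    concentration : float
        Solute concentration, mg per g of water.
    solubility_ref : float
        Equilibrium solubility at ``temperature``, mg per g of water.
    temperature : float
        Working temperature, degC.
    """

    concentration: float
    solubility_ref: float = DEFAULT_SOLUBILITY_MG_PER_G
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.solubility_ref <= 0:
            raise InvalidArgumentError(
                "concentration and solubility_ref must be positive"
            )

    @property
    def S(self) -> float:
        return self.concentration / self.solubility_ref


@dataclass
class ClearPointTable:
    """Clear-point temperatures for one concentration at several heating rates.

    ``rows`` holds (heating_rate degC/min, clear_point degC, replicate id).
    """

    concentration: float
    rows: list[tuple[float, float, int]]

    def __post_init__(self) -> None:
        for rate, _, _ in self.rows:
            if rate <= 0:
                raise InvalidArgumentError("heating rates must be positive")

    @property
    def heating_rates(self) -> np.ndarray:
        return np.array([r[0] for r in self.rows], dtype=float)

    @property
    def clear_points(self) -> np.ndarray:
        return np.array([r[1] for r in self.rows], dtype=float)


@dataclass
class SolubilityModel:
    """Van't Hoff solubility model ln C = a - b / T with T in kelvin.

    ``intercept`` is the dimensionless a, ``slope_K`` the b in kelvin;
    ``b > 0`` means solubility increases with temperature, as it does for
    glycine in water.
    """

    intercept: float
    slope_K: float
    temperature_range_C: tuple[float, float] = (0.0, 100.0)
    concentration_range: tuple[float, float] | None = None

    def solubility(self, temperature_C: float | np.ndarray) -> float | np.ndarray:
        """Predicted solubility (mg/g) at ``temperature_C``."""
        T = np.asarray(temperature_C, dtype=float) + KELVIN_OFFSET
        out = np.exp(self.intercept - self.slope_K / T)
        return float(out) if out.ndim == 0 else out


@dataclass
class PowerLawFit:
    """Power-law kinetics rate = k * (S - 1)**n fitted in log-log space.

    ``prefactor`` k is the rate at S - 1 = 1 in the units of the fitted
    rate (um/min for growth, particles/(mL min) for nucleation);
    ``exponent`` n is dimensionless.
    """

    prefactor: float
    exponent: float
    rate_kind: str = "growth"
    r_squared: float = float("nan")
    n_points: int = 0
    se_log_prefactor: float = float("nan")
    se_exponent: float = float("nan")

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise InvalidArgumentError("power-law prefactor must be positive")

    def evaluate(self, S: float | np.ndarray) -> float | np.ndarray:
        return evaluate_power_law(self, S)

    def invert(self, target_rate: float) -> float:
        return invert_power_law(self, target_rate)


def supersaturation(concentration: float, solubility_ref: float) -> float:
    """Supersaturation ratio S = C / C_s.

    Both arguments are in mg solute per g of water (any shared mass basis
    cancels).  Raises :class:`InvalidArgumentError` on non-positive input.
    """
    if concentration <= 0 or solubility_ref <= 0:
        raise InvalidArgumentError(
            f"concentration ({concentration}) and solubility_ref "
            f"({solubility_ref}) must be positive"
        )
    return concentration / solubility_ref


def extrapolate_clear_point(
    table: ClearPointTable,
) -> tuple[float, tuple[float, float]]:
    """Equilibrium solubility temperature by zero-heating-rate extrapolation.

    Fits an ordinary least-squares line of clear point (degC) against
    heating rate (degC/min) and returns ``(intercept, (lo, hi))`` where the
    interval is intercept +/- 1.96 standard errors.  With only two distinct
    heating rates the line is exact and the interval degenerate.
    """
    rates = table.heating_rates
    temps = table.clear_points
    if len(np.unique(rates)) < 2:
        raise InsufficientDataError(
            "need clear points at >=2 distinct heating rates to extrapolate"
        )
    res = stats.linregress(rates, temps)
    se = res.intercept_stderr if np.isfinite(res.intercept_stderr) else 0.0
    return res.intercept, (res.intercept - 1.96 * se, res.intercept + 1.96 * se)


def fit_vant_hoff(points: list[tuple[float, float]]) -> SolubilityModel:
    """Fit ln C = a - b / T(K) to (temperature degC, solubility mg/g) points.

    Ordinary least squares on the log-transformed data; with exactly two
    points the parameters interpolate exactly.
    """
    if len(points) < 2:
        raise InsufficientDataError("van't Hoff fit needs >=2 points")
    temps_C = np.array([p[0] for p in points], dtype=float)
    concs = np.array([p[1] for p in points], dtype=float)
    if np.any(concs <= 0):
        raise InvalidArgumentError("solubility values must be positive")
    inv_T = 1.0 / (temps_C + KELVIN_OFFSET)
    if len(np.unique(inv_T)) < 2:
        raise InsufficientDataError("temperatures must span a nonzero range")
    res = stats.linregress(inv_T, np.log(concs))
    # ln C = intercept + slope/T  ->  a = intercept, b = -slope
    return SolubilityModel(
        intercept=res.intercept,
        slope_K=-res.slope,
        temperature_range_C=(float(temps_C.min()), float(temps_C.max())),
        concentration_range=(float(concs.min()), float(concs.max())),
    )


def fit_power_law(
    points: list[tuple[float, float]], rate_kind: str = "growth"
) -> PowerLawFit:
    """Fit rate = k * (S - 1)**n by OLS of ln(rate) on ln(S - 1).

    All points must have S > 1 and rate > 0.  Returns a
    :class:`PowerLawFit` with k = exp(intercept) and n = slope, plus the
    log-space R-squared and standard errors.
    """
    if len(points) < 2:
        raise InsufficientDataError("power-law fit needs >=2 points")
    S = np.array([p[0] for p in points], dtype=float)
    rate = np.array([p[1] for p in points], dtype=float)
    if np.any(S <= 1.0):
        raise InvalidArgumentError("all supersaturations must exceed 1")
    if np.any(rate <= 0.0):
        raise InvalidArgumentError("all rates must be positive")
    x = np.log(S - 1.0)
    y = np.log(rate)
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("supersaturations must span a nonzero range")
    res = stats.linregress(x, y)
    return PowerLawFit(
        prefactor=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        rate_kind=rate_kind,
        r_squared=float(res.rvalue**2),
        n_points=len(points),
        se_log_prefactor=float(res.intercept_stderr),
        se_exponent=float(res.stderr),
    )


def evaluate_power_law(
    fit: PowerLawFit, S: float | np.ndarray
) -> float | np.ndarray:
    """Rate predicted by the power law at supersaturation ``S`` (> 1)."""
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr <= 1.0):
        raise InvalidArgumentError("supersaturation must exceed 1")
    out = fit.prefactor * (S_arr - 1.0) ** fit.exponent
    return float(out) if out.ndim == 0 else out


def invert_power_law(fit: PowerLawFit, target_rate: float) -> float:
    """Supersaturation at which the power law reaches ``target_rate``.

    Closed form: S = 1 + (rate / k)**(1/n).  Round-trips with
    :func:`evaluate_power_law` to floating-point precision.
    """
    if target_rate <= 0:
        raise InvalidArgumentError("target rate must be positive")
    if fit.exponent == 0:
        raise InvalidArgumentError("cannot invert a zero-exponent power law")
    return 1.0 + (target_rate / fit.prefactor) ** (1.0 / fit.exponent)
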