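"""Primary nucleation rate estimation from censored induction-time ensembles.

Isothermal induction times in small stirred vials are stochastic: under the
single-nucleus mechanism each vial nucleates once, at an exponentially
distributed waiting time with rate J*V (J the primary nucleation rate per
volume, V the solution volume), and the event only becomes detectable after
a deterministic growth time t_g during which the nucleus grows large enough
to trigger detectable secondary nucleation.  The cumulative probability of
observing an induction time at or before t is therefore

    P(t) = 1 - exp(-J * V * (t - t_g))    for t > t_g,  else 0.

The empirical distribution is M+(t) / M, where M is the total number of
vials (censored ones included) and M+(t) the number nucleated by time t.
Fitting the model to the empirical steps by Levenberg-Marquardt least
squares yields J and t_g with standard errors.  Censoring at the end of the
isothermal hold (4 h by default) enters only through the denominator M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from xtalkin.errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
)

DEFAULT_CENSOR_MIN = 240.0
DEFAULT_VOLUME_ML = 3.0
#: Minimum number of nucleated vials required before attempting a fit.
MIN_NUCLEATED_FOR_FIT = 5


@dataclass
class InductionDataset:
    """A censored ensemble of induction times at one supersaturation.

    ``times`` holds the observed induction times (min) of nucleated vials;
    ``n_censored`` the number of vials that never nucleated within
    ``censor_time``.  M = len(times) + n_censored is the full ensemble
    size that normalises the empirical distribution.
    """

    supersaturation: float
    times: np.ndarray
    n_censored: int = 0
    volume_mL: float = DEFAULT_VOLUME_ML
    censor_time: float = DEFAULT_CENSOR_MIN
    vial_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.n_censored < 0:
            raise InvalidArgumentError("n_censored must be non-negative")
        if self.times.size and (
            np.any(self.times <= 0) or np.any(self.times > self.censor_time)
        ):
            raise InvalidArgumentError(
                "observed induction times must lie in (0, censor_time]"
            )
        if self.M < 1:
            raise InsufficientDataError("dataset contains no vials")

    @property
    def M(self) -> int:
        """Total number of experiments, censored vials included."""
        return int(self.times.size) + self.n_censored

    @property
    def n_nucleated(self) -> int:
        return int(self.times.size)


@dataclass
class InductionFit:
    """Estimated primary nucleation rate and growth-time offset.

    J in nuclei/(mL min), t_g in min; standard errors from the Jacobian at
    the least-squares optimum.
    """

    J: float
    J_stderr: float
    t_g: float
    t_g_stderr: float
    volume_mL: float
    n_nucleated: int
    M: int
    residual_norm: float
    supersaturation: float = float("nan")

    @property
    def JV(self) -> float:
        """Primary nucleation rate per vial, 1/min."""
        return self.J * self.volume_mL


def empirical_cdf(dataset: InductionDataset) -> list[tuple[float, float]]:
    """Empirical cumulative induction-time distribution M+(t) / M.

    Returns sorted (t, P) steps at each distinct observed induction time,
    ties merged; censored vials contribute to the denominator only.  The
    step values are non-decreasing and bounded by n_nucleated / M.
    """
    if dataset.M < 1:
        raise InsufficientDataError("empty induction dataset")
    if dataset.n_nucleated == 0:
        return []
    times = np.sort(dataset.times)
    uniq, counts = np.unique(times, return_counts=True)
    cum = np.cumsum(counts)
    return [(float(t), float(c) / dataset.M) for t, c in zip(uniq, cum)]


def induction_probability(
    J: float, V: float, t_g: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Model cumulative probability of an induction time at or before t.

    P = 1 - exp(-J*V*(t - t_g)) for t > t_g, zero at or below the offset.
    """
    if J < 0 or V < 0 or t_g < 0:
        raise InvalidArgumentError("J, V and t_g must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidArgumentError("time must be non-negative")
    out = np.where(t_arr > t_g, 1.0 - np.exp(-J * V * np.maximum(t_arr - t_g, 0.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def minimum_induction_time(dataset: InductionDataset) -> float:
    """Smallest observed induction time (MIT), a proxy for the offset t_g."""
    if dataset.n_nucleated == 0:
        raise InsufficientDataError("all vials censored; no induction observed")
    return float(dataset.times.min())


def _initial_guess(
    t: np.ndarray, P: np.ndarray, V: float, M: int
) -> tuple[float, float]:
    """Data-driven starting point: t_g at the MIT, J from the CDF shape.

    J is seeded from the time at which the empirical distribution crosses
    63% of its final level — the 1/e point of the exponential, where
    J*V*(t - t_g) = 1.  The final step itself can sit at P = 1 (every
    vial nucleated), where the log-transform diverges, so it is clipped
    to 1 - 1/(2M) when used.
    """
    t_g0 = float(t.min())
    P_max = min(float(P.max()), 1.0 - 1.0 / (2 * M))
    i63 = min(int(np.searchsorted(P, 0.632 * float(P.max()))), t.size - 1)
    span63 = max(float(t[i63]) - t_g0, 1e-6)
    span_last = max(float(t.max()) - t_g0, 1e-6)
    # two scale readings: the 1/e crossing and the final step
    J0_63 = 1.0 / (V * span63)
    J0_last = math.log(1.0 / (1.0 - P_max)) / (V * span_last)
    J0 = math.sqrt(J0_63 * J0_last)
    return max(J0, 1e-12), t_g0


def fit_induction_model(
    dataset: InductionDataset,
    min_nucleated: int = MIN_NUCLEATED_FOR_FIT,
    n_restarts: int = 5,
) -> InductionFit:
    """Fit (J, t_g) to the empirical induction-time distribution.

    Nonlinear least squares (Levenberg-Marquardt) of the exponential
    model against the empirical steps, both parameters bounded below by
    zero and t_g bounded above by the minimum observed induction time.
    On failure to converge, up to ``n_restarts`` jittered restarts are
    attempted before raising :class:`FitFailureError`.
    """
    if dataset.n_nucleated < min_nucleated:
        raise InsufficientDataError(
            f"need >={min_nucleated} nucleated vials, got {dataset.n_nucleated}"
        )
    steps = empirical_cdf(dataset)
    t = np.array([s[0] for s in steps])
    P = np.array([s[1] for s in steps])
    V = dataset.volume_mL
    J0, t_g0 = _initial_guess(t, P, V, dataset.M)
    mit = float(t.min())

    def residual(params: lmfit.Parameters) -> np.ndarray:
        J = params["J"].value
        t_g = params["t_g"].value
        model = np.where(
            t > t_g, 1.0 - np.exp(-J * V * np.maximum(t - t_g, 0.0)), 0.0
        )
        return model - P

    # the saturated-model corner (J huge, t_g at the MIT) is a flat local
    # minimum LM can stall in, so several starts are always tried and the
    # lowest residual norm wins
    rng = np.random.default_rng(0)
    starts = [(J0, t_g0), (J0 / 4.0, 0.5 * t_g0), (4.0 * J0, t_g0)]
    starts += [
        (J0 * rng.uniform(0.1, 10.0), t_g0 * rng.uniform(0.0, 1.0))
        for _ in range(n_restarts)
    ]
    best = None
    last_exc: Exception | None = None
    for J_start, tg_start in starts:
        params = lmfit.Parameters()
        params.add("J", value=max(J_start, 1e-12), min=0.0)
        params.add("t_g", value=min(tg_start, mit), min=0.0, max=mit)
        try:
            result = lmfit.minimize(residual, params, method="leastsq")
        except Exception as exc:  # pragma: no cover - lmfit internal failure
            last_exc = exc
            continue
        if not result.success:
            continue
        norm = float(np.sqrt(np.sum(result.residual**2)))
        if best is None or norm < best[0]:
            best = (norm, result)
    if best is None:
        raise FitFailureError(
            "induction-time fit did not converge",
            diagnostics={
                "n_starts": len(starts),
                "last_exception": repr(last_exc),
            },
        )
    norm, result = best
    pJ = result.params["J"]
    ptg = result.params["t_g"]
    return InductionFit(
        J=float(pJ.value),
        J_stderr=float(pJ.stderr) if pJ.stderr else float("nan"),
        t_g=float(ptg.value),
        t_g_stderr=float(ptg.stderr) if ptg.stderr else float("nan"),
        volume_mL=V,
        n_nucleated=dataset.n_nucleated,
        M=dataset.M,
        residual_norm=norm,
        supersaturation=dataset.supersaturation,
    )


def censored_exponential_mle(dataset: InductionDataset, t_g: float) -> float:
    """Maximum-likelihood J for the censored exponential at a fixed offset.

    Optional cross-check for the least-squares route: with waiting times
    w_i = t_i - t_g for nucleated vials and censored exposure
    c = censor_time - t_g per censored vial, the MLE of the per-vial rate
    is n_nucleated / (sum(w_i) + n_censored * c), divided by V to give J.
    """
    if dataset.n_nucleated == 0:
        raise InsufficientDataError("no nucleated vials for MLE")
    w = dataset.times - t_g
    if np.any(w < 0):
        raise InvalidArgumentError("t_g exceeds an observed induction time")
    exposure = float(w.sum()) + dataset.n_censored * (dataset.censor_time - t_g)
    return dataset.n_nucleated / exposure / dataset.volume_mL
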