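"""Growth-curve fitness proxies.

Turns OD600 time series into the quantities the screens are built on:
baseline-corrected curves, empirical area under the growth curve (AUC),
logistic fits, and population doublings.

The AUC of the baseline-corrected curve is the primary fitness proxy: it
integrates both how fast and how far a culture grows over the assay window,
and is robust to the lag/exponential/stationary phase boundaries that make
single-parameter summaries (mu_max, lag time) fragile on non-model anaerobes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "GrowthSummary",
    "baseline_correct",
    "auc_trapezoid",
    "fit_logistic",
    "doublings",
    "logistic_od",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series.

    Parameters
    ----------
    plate_id, well, strain_id, replicate
        Provenance metadata carried through the pipeline.
    times
        Sampling times in hours, strictly increasing, length >= 2.
    od
        OD600 readings, same length as ``times``, all finite.
    """

    plate_id: str
    well: str
    strain_id: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or times.size != od.size:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a growth curve needs at least 2 time points")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(od)):
            raise ValueError("times and od must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class LogisticFit:
    """Parameters of a logistic growth fit N(t) = K / (1 + ((K-N0)/N0) e^(-rt))."""

    carrying_capacity: float
    rate: float
    initial_size: float
    auc_fit: float
    converged: bool


@dataclass(frozen=True)
class GrowthSummary:
    """Per-well fitness summary: empirical AUC and population doublings."""

    raw_auc: float
    doublings: float


def logistic_od(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth model evaluated at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def baseline_correct(curve: GrowthCurve) -> GrowthCurve:
    """Shift the curve so its minimum OD is zero.

    Idempotent; preserves shape (``od_out = od - min(od)``).
    """
    return replace(curve, od=curve.od - curve.od.min())


def auc_trapezoid(curve: GrowthCurve) -> float:
    """Trapezoidal integral of OD over time (OD600 * hours).

    Exact for piecewise-linear signals on the observed time stamps; no
    resampling is performed. Expects a baseline-corrected curve, in which
    case the result is nonnegative.
    """
    return float(np.trapezoid(curve.od, curve.times))


def doublings(curve: GrowthCurve, floor: float = 0.01) -> float:
    """Population doublings G = log2(od_final / od_initial), clamped at 0.

    Computed on absolute (baseline-uncorrected) OD; both endpoints are
    floored at ``floor`` so near-zero blank readings do not explode the log.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    od0 = max(float(curve.od[0]), floor)
    od1 = max(float(curve.od[-1]), floor)
    return max(0.0, float(np.log2(od1 / od0)))


def fit_logistic(curve: GrowthCurve, dynamic_range_floor: float = 0.05) -> LogisticFit:
    """Least-squares logistic fit of a growth curve.

    Initial guesses are deterministic: N0 = first OD, K = max OD, and
    r = 4 / (time of half-maximum). Curves whose dynamic range
    (max - min OD) falls below ``dynamic_range_floor``, or for which the
    optimizer fails, are returned with ``converged=False`` rather than
    raising. ``auc_fit`` is the numerical integral of the fitted model over
    the observed time window.
    """
    t, od = curve.times, curve.od
    if t.size < 5:
        raise ValueError("logistic fit requires at least 5 time points")
    dyn = float(od.max() - od.min())
    if dyn < dynamic_range_floor:
        return LogisticFit(float(od.max()), 0.0, float(max(od[0], 1e-12)), 0.0, False)

    n0_guess = max(float(od[0]), 1e-6)
    k_guess = max(float(od.max()), n0_guess * 1.01)
    half = od.min() + dyn / 2.0
    i_half = int(np.argmax(od >= half))
    t_half = float(t[i_half]) if t[i_half] > 0 else float(t[1])
    r_guess = 4.0 / t_half

    try:
        popt, _ = optimize.curve_fit(
            logistic_od,
            t,
            od,
            p0=[k_guess, r_guess, n0_guess],
            bounds=([1e-9, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return LogisticFit(k_guess, 0.0, n0_guess, 0.0, False)

    K, r, N0 = (float(v) for v in popt)
    auc_fit, _ = integrate.quad(lambda x: logistic_od(x, K, r, N0), t[0], t[-1])
    return LogisticFit(K, r, N0, float(auc_fit), True)


def summarize(curve: GrowthCurve, floor: float = 0.01) -> GrowthSummary:
    """Baseline-corrected AUC plus doublings for one well."""
    return GrowthSummary(
        raw_auc=auc_trapezoid(baseline_correct(curve)),
        doublings=doublings(curve, floor=floor),
    )
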