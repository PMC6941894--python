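"""Growth-rate estimation from turbidostat traces and plate-reader curves.

A turbidostat holds a culture in exponential growth by diluting it back to a
target optical density at fixed intervals.  Between consecutive dilutions the
OD rises exponentially, so each dilution cycle yields one specific growth
rate ``ln(OD_end / OD_start) / (t_end - t_start)`` in h^-1.  Averaging the
per-cycle rates over a day gives the mean rate ``mu_bar`` and the number of
generations per day ``g = 24 * mu_bar / ln 2``.

Batch growth curves from a plate reader are summarised with the modified
Gompertz model (Zwietering parameterisation)::

    y(t) = A * exp(-exp((mu_max * e / A) * (lag - t) + 1))

whose parameters are the maximum specific growth rate ``mu_max`` (h^-1), the
lag time ``lag`` (h) and the maximum growth ``A`` (baseline-subtracted OD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ODTrace",
    "GrowthEstimate",
    "GompertzFit",
    "GompertzFitError",
    "detect_dilutions",
    "per_cycle_rates",
    "summarize_day",
    "gompertz",
    "subtract_baseline",
    "fit_gompertz",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ODTrace:
    """A time-stamped optical-density series with dilution-cycle boundaries.

    Parameters
    ----------
    times:
        Reading times in hours, strictly increasing.
    od:
        Optical densities, strictly positive.
    dilution_marks:
        Indices ``i`` such that reading ``i`` is the first reading of a new
        cycle (the reading right after a dilution).  Each mark must coincide
        with a drop in OD relative to the preceding reading.
    """

    times: np.ndarray
    od: np.ndarray
    dilution_marks: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "dilution_marks", tuple(int(i) for i in self.dilution_marks))
        if times.ndim != 1 or od.shape != times.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a trace needs at least two readings")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(od > 0):
            raise ValueError("od must be positive everywhere")
        n_no_drop = 0
        for i in self.dilution_marks:
            if not 1 <= i < times.size:
                raise ValueError(f"dilution mark {i} out of range")
            if od[i] >= od[i - 1]:
                n_no_drop += 1
        if n_no_drop:
            # reading noise can mask small dilution drops (a 60 s cycle grows
            # the OD < 1%), so a missing drop is suspicious, not fatal
            logger.warning(
                "%d of %d dilution marks do not coincide with an OD drop",
                n_no_drop, len(self.dilution_marks),
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class GrowthEstimate:
    """Daily summary of per-cycle growth rates."""

    mu_bar: float
    n_cycles: int
    generations_per_day: float
    per_cycle_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_cycles != len(self.per_cycle_rates):
            raise ValueError("n_cycles must equal len(per_cycle_rates)")


@dataclass(frozen=True)
class GompertzFit:
    """Result of a modified-Gompertz fit.

    ``mu_max`` in h^-1, ``lag`` in hours, ``a_max`` in (baseline-subtracted)
    OD units, ``rss`` the residual sum of squares of the fit.
    """

    mu_max: float
    lag: float
    a_max: float
    rss: float

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")


class GompertzFitError(RuntimeError):
    """Raised when the Gompertz optimiser fails; carries the best iterate."""

    def __init__(self, message: str, best: GompertzFit | None = None):
        super().__init__(message)
        self.best = best


def detect_dilutions(od: np.ndarray, rel_threshold: float = 0.02) -> tuple[int, ...]:
    """Indices where OD drops by more than ``rel_threshold`` relative to the
    previous reading — used to segment a trace into dilution cycles when no
    explicit marks were recorded."""
    od = np.asarray(od, dtype=float)
    drops = np.flatnonzero(od[1:] < od[:-1] * (1.0 - rel_threshold)) + 1
    return tuple(int(i) for i in drops)


def _cycles(trace: ODTrace, rel_threshold: float) -> list[tuple[int, int]]:
    """(start, stop) index pairs, stop exclusive, one per dilution cycle."""
    marks = trace.dilution_marks or detect_dilutions(trace.od, rel_threshold)
    bounds = [0, *marks, len(trace)]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]


def per_cycle_rates(
    trace: ODTrace,
    rel_threshold: float = 0.02,
    outlier_z: float | None = 4.0,
) -> list[float]:
    """Specific growth rate of every dilution cycle, in h^-1.

    Each cycle contributes ``ln(N_t1 / N_t0) / (t1 - t0)`` where ``N_t0`` is
    the OD right after the dilution and ``N_t1`` the OD right before the
    next.  Cycles whose rate lies more than ``outlier_z`` robust z-scores
    from the day's distribution are dropped with a log message (pass
    ``outlier_z=None`` to keep everything).
    """
    rates: list[float] = []
    for start, stop in _cycles(trace, rel_threshold):
        t0, t1 = trace.times[start], trace.times[stop - 1]
        n0, n1 = trace.od[start], trace.od[stop - 1]
        if t1 <= t0:
            raise ValueError(f"cycle starting at index {start} has zero duration")
        if n0 <= 0 or n1 <= 0:
            raise ValueError(f"cycle starting at index {start} has nonpositive OD")
        rates.append(math.log(n1 / n0) / (t1 - t0))
    if outlier_z is not None and len(rates) >= 4:
        arr = np.asarray(rates)
        mu, sd = arr.mean(), arr.std(ddof=1)
        if sd > 0:
            keep = np.abs(arr - mu) <= outlier_z * sd
            n_drop = int((~keep).sum())
            if n_drop:
                logger.info("per_cycle_rates: dropped %d outlier cycle(s) (|z| > %g)", n_drop, outlier_z)
                rates = [r for r, k in zip(rates, keep) if k]
    return rates


def summarize_day(rates: list[float] | np.ndarray) -> GrowthEstimate:
    """Mean growth rate and generations per day from per-cycle rates.

    ``g = 24 * mu_bar / ln 2`` — at ``mu_bar = ln 2`` per hour (doubling time
    one hour) this is exactly 24 generations per day.
    """
    rates = [float(r) for r in np.asarray(rates, dtype=float).ravel()]
    if not rates:
        raise ValueError("cannot summarise an empty rate list")
    mu_bar = float(np.mean(rates))
    return GrowthEstimate(
        mu_bar=mu_bar,
        n_cycles=len(rates),
        generations_per_day=24.0 * mu_bar / LN2,
        per_cycle_rates=tuple(rates),
    )


def gompertz(t: np.ndarray, mu_max: float, lag: float, a_max: float) -> np.ndarray:
    """Modified Gompertz curve ``A*exp(-exp((mu_max*e/A)*(lag-t)+1))``."""
    t = np.asarray(t, dtype=float)
    return a_max * np.exp(-np.exp((mu_max * math.e / a_max) * (lag - t) + 1.0))


def subtract_baseline(od: np.ndarray, baseline_points: int = 5, smooth_width: int = 3) -> np.ndarray:
    """Subtract the pre-growth baseline: a moving average of width
    ``smooth_width`` is applied and the mean of the first ``baseline_points``
    smoothed readings is removed from the raw curve."""
    od = np.asarray(od, dtype=float)
    if baseline_points < 1:
        raise ValueError("baseline_points must be >= 1")
    kernel = np.ones(smooth_width) / smooth_width
    # same-length smoothing with edge padding
    padded = np.pad(od, (smooth_width // 2, smooth_width - 1 - smooth_width // 2), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    baseline = float(smoothed[:baseline_points].mean())
    return od - baseline


def _gompertz_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = float(max(y.max(), 1e-6))
    pos = y > a0 * 1e-3
    mu0 = 0.1
    if pos.sum() >= 3:
        logs = np.log(y[pos])
        slopes = np.diff(logs) / np.diff(t[pos])
        if slopes.size and np.isfinite(slopes).any():
            mu0 = float(np.nanmax(np.where(np.isfinite(slopes), slopes, np.nan)))
            mu0 = max(mu0, 1e-3)
    d2 = np.gradient(np.gradient(y, t), t)
    lag0 = float(t[int(np.argmax(d2))])
    return mu0, max(lag0, 0.0), a0


def fit_gompertz(
    times: np.ndarray,
    od: np.ndarray,
    baseline_points: int | None = 5,
    smooth_width: int = 3,
) -> GompertzFit:
    """Least-squares fit of the modified Gompertz model to a growth curve.

    When ``baseline_points`` is given the pre-growth baseline is subtracted
    first (see :func:`subtract_baseline`); pass ``None`` for data that is
    already baseline-corrected.  Parameters are bounded below by zero;
    initial guesses come from the max slope of log OD (``mu_max``), the max
    OD (``A``) and the time of maximum curvature (``lag``).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size or t.size < 8:
        raise ValueError("need >= 8 (time, od) points spanning lag and growth")
    if baseline_points is not None:
        y = subtract_baseline(y, baseline_points, smooth_width)
    y = np.clip(y, 0.0, None)
    p0 = _gompertz_guess(t, y)
    try:
        popt, _ = curve_fit(
            gompertz, t, y, p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        yhat = gompertz(t, *p0)
        best = GompertzFit(*p0, rss=float(np.sum((y - yhat) ** 2)))
        raise GompertzFitError(f"Gompertz fit did not converge: {exc}", best=best) from exc
    rss = float(np.sum((y - gompertz(t, *popt)) ** 2))
    fit = GompertzFit(mu_max=float(popt[0]), lag=float(popt[1]), a_max=float(popt[2]), rss=rss)
    if fit.mu_max <= 0 or fit.a_max <= 0:
        logger.warning("fit_gompertz: nonpositive parameter estimate %s", fit)
    return fit
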