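"""Trajectory filtering, averaging, normalization and model fitting.

Two gene-expression models are fitted to fluorescence trajectories:

* **Fluorophore maturation** after a translation block (cycloheximide
  chase).  With production halted, the pre-existing immature pool converts
  to the fluorescent form at a single rate a, so the normalized population
  fluorescence follows ``F(t) = 1 - exp(-a t)`` with time measured from the
  block; the rate is reported as a half-time ``T_1/2 = ln(2) / a``.

* **Logistic induction** for sigmoid turn-on of expression,
  ``F(t) = A + (B - A) / (1 + exp(-beta (t - t0)))`` with lower/upper
  asymptotes A and B, maximal rate parameter beta (1/min) and half-rise
  time t0 (where ``F(t0) = (A + B)/2``).

Before fitting, trajectories shorter than a minimum number of time points
(default 50, about 250 min at 5-min sampling) are discarded, remaining
cells are averaged per time point, and the average is normalized to [0, 1]
by first subtracting its minimum and then dividing by the maximum of the
shifted curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .tracking import CellTrajectory

__all__ = [
    "MaturationFit",
    "LogisticFit",
    "filter_trajectories",
    "population_average",
    "normalize01",
    "fit_maturation",
    "fit_logistic",
    "summarize",
    "memory_ratios",
    "maturation_model",
    "logistic_model",
]

MIN_TRAJECTORY_POINTS = 50


class ConstantTrajectoryError(ValueError):
    """The trajectory has zero range; normalization is undefined."""


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass(frozen=True)
class MaturationFit:
    """Single-rate maturation fit."""

    a: float  # maturation rate, 1/min
    rss: float

    @property
    def half_time(self) -> float:
        """T_1/2 = ln(2)/a, minutes."""
        return math.log(2.0) / self.a


@dataclass(frozen=True)
class LogisticFit:
    """Four-parameter logistic induction fit."""

    A: float  # lower asymptote, a.u.
    B: float  # upper asymptote, a.u.
    beta: float  # maximal rate parameter, 1/min
    t0: float  # half-rise time, min
    rss: float

    def __call__(self, t):
        return logistic_model(np.asarray(t, dtype=float), self.A, self.B, self.beta, self.t0)


def maturation_model(t: np.ndarray, a: float) -> np.ndarray:
    """Normalized post-chase maturation curve F(t) = 1 - exp(-a t)."""
    return 1.0 - np.exp(-a * t)


def logistic_model(t: np.ndarray, A: float, B: float, beta: float, t0: float) -> np.ndarray:
    """Logistic induction F(t) = A + (B - A)/(1 + exp(-beta (t - t0)))."""
    return A + (B - A) / (1.0 + np.exp(-beta * (t - t0)))


def filter_trajectories(
    trajectories: Iterable[CellTrajectory], min_points: int = MIN_TRAJECTORY_POINTS
) -> list[CellTrajectory]:
    """Keep only cells present for at least ``min_points`` time points."""
    return [tr for tr in trajectories if tr.n_points >= min_points]


def population_average(
    trajectories: Sequence[CellTrajectory], background_subtract: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Mean fluorescence over cells present at each acquisition time point.

    Returns ``(times, means)`` over the union of time points; at each time
    the mean runs over the cells recorded there.
    """
    if len(trajectories) == 0:
        raise ValueError("population_average needs at least one trajectory")
    sums: dict[float, float] = {}
    counts: dict[float, int] = {}
    for tr in trajectories:
        vals = tr.fluorescence_bgsub if background_subtract else tr.fluorescence
        for t, v in zip(tr.times, vals):
            sums[t] = sums.get(t, 0.0) + float(v)
            counts[t] = counts.get(t, 0) + 1
    times = np.array(sorted(sums))
    means = np.array([sums[t] / counts[t] for t in times])
    return times, means


def normalize01(values: Sequence[float]) -> np.ndarray:
    """Normalize a curve to [0, 1]: subtract the minimum, then divide by
    the maximum of the shifted curve (in that order)."""
    v = np.asarray(values, dtype=np.float64)
    shifted = v - v.min()
    peak = shifted.max()
    if peak == 0.0:
        raise ConstantTrajectoryError("cannot normalize a constant trajectory")
    return shifted / peak


def fit_maturation(times: Sequence[float], values: Sequence[float]) -> MaturationFit:
    """Least-squares fit of the maturation model to a normalized curve.

    ``times`` are minutes since the translation block; ``values`` should be
    normalized to [0, 1].  Needs at least 5 points at t >= 0.
    """
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    keep = t >= 0
    t, y = t[keep], y[keep]
    if t.size < 5:
        raise ValueError("fit_maturation needs >= 5 time points at t >= 0")
    # initial rate from the time the curve first crosses 1/2
    above = np.nonzero(y >= 0.5)[0]
    t_half0 = t[above[0]] if above.size and t[above[0]] > 0 else max(t[-1] / 2.0, 1e-6)
    a0 = math.log(2.0) / t_half0
    try:
        popt, _ = curve_fit(maturation_model, t, y, p0=[a0], maxfev=10000)
    except RuntimeError as e:  # pragma: no cover - defensive
        raise FitConvergenceError(f"maturation fit failed: {e}") from e
    a = float(popt[0])
    if a <= 0:
        raise FitConvergenceError(f"maturation fit returned non-positive rate a={a}")
    rss = float(np.sum((y - maturation_model(t, a)) ** 2))
    return MaturationFit(a=a, rss=rss)


def fit_logistic(times: Sequence[float], values: Sequence[float]) -> LogisticFit:
    """Least-squares fit of the 4-parameter logistic to a trajectory.

    Initial values come from the data (A = min, B = max, t0 = time of
    half-rise, beta from the maximal finite-difference slope); a few
    perturbed restarts guard against bad local minima.  Needs >= 6 points
    and a non-constant trajectory.
    """
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    if t.size < 6:
        raise ValueError("fit_logistic needs >= 6 time points")
    if np.ptp(y) == 0:
        raise ConstantTrajectoryError("cannot fit a logistic to a constant trajectory")
    A0, B0 = float(y.min()), float(y.max())
    half = 0.5 * (A0 + B0)
    above = np.nonzero(y >= half)[0]
    t00 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.diff(y) / np.diff(t)
    max_slope = float(np.nanmax(np.abs(slopes))) if slopes.size else 0.0
    beta0 = 4.0 * max_slope / (B0 - A0) if max_slope > 0 else 1.0 / max(np.ptp(t), 1.0)

    span = float(np.ptp(t))
    starts = [
        (A0, B0, beta0, t00),
        (A0, B0, beta0 * 0.3, t00),
        (A0, B0, beta0 * 3.0, t00 + 0.1 * span),
        (A0, B0, beta0, t00 - 0.1 * span),
    ]
    best: LogisticFit | None = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(logistic_model, t, y, p0=list(p0), maxfev=20000)
        except RuntimeError:
            continue
        A, B, beta, t0 = (float(v) for v in popt)
        if beta < 0:  # equivalent curve with swapped asymptotes
            A, B, beta = B, A, -beta
        rss = float(np.sum((y - logistic_model(t, A, B, beta, t0)) ** 2))
        if best is None or rss < best.rss:
            best = LogisticFit(A=A, B=B, beta=beta, t0=t0, rss=rss)
    if best is None or best.B <= best.A:
        raise FitConvergenceError("logistic fit failed to converge to a rising sigmoid")
    return best


def chase_half_time(
    trajectories: Iterable[CellTrajectory],
    t_origin_min: float,
    min_points: int = MIN_TRAJECTORY_POINTS,
) -> MaturationFit:
    """Full maturation analysis of a cycloheximide-chase experiment.

    Filters short trajectories, averages the background-subtracted
    fluorescence per time point, normalizes the post-block portion of the
    average to [0, 1] and fits the maturation model with time measured
    from ``t_origin_min`` (the translation-block time).
    """
    kept = filter_trajectories(trajectories, min_points)
    if not kept:
        raise ValueError(f"no trajectory has >= {min_points} time points")
    times, means = population_average(kept)
    mask = times >= t_origin_min - 1e-9
    if mask.sum() < 5:
        raise ValueError("fewer than 5 time points after the translation block")
    norm = normalize01(means[mask])
    return fit_maturation(np.asarray(times)[mask] - t_origin_min, norm)


def summarize(values: Sequence[float]) -> dict[str, float]:
    """Mean, SEM and CV of replicate values.

    SEM is the sample standard deviation (n-1 denominator) over sqrt(n);
    CV is the sample standard deviation over the mean.  With fewer than two
    values SEM and CV are NaN.
    """
    v = np.asarray(values, dtype=np.float64)
    mean = float(v.mean())
    if v.size < 2:
        return {"mean": mean, "sem": float("nan"), "cv": float("nan")}
    sd = float(v.std(ddof=1))
    return {"mean": mean, "sem": sd / math.sqrt(v.size), "cv": sd / mean}


def memory_ratios(
    first_fits: Sequence[LogisticFit], second_fits: Sequence[LogisticFit]
) -> tuple[float, float]:
    """Transcriptional-memory ratios between two induction rounds.

    Returns ``(delay_ratio, rate_ratio)`` where
    ``delay_ratio = mean(t0 first) / mean(t0 second)`` (how much faster the
    re-induction starts) and ``rate_ratio = mean(beta second) /
    mean(beta first)`` (how much faster fluorescence rises).
    """
    if not first_fits or not second_fits:
        raise ValueError("memory_ratios needs non-empty fit sets")
    t0_first = float(np.mean([f.t0 for f in first_fits]))
    t0_second = float(np.mean([f.t0 for f in second_fits]))
    b_first = float(np.mean([f.beta for f in first_fits]))
    b_second = float(np.mean([f.beta for f in second_fits]))
    if t0_second == 0 or b_first == 0:
        raise ZeroDivisionError("memory ratio denominator is zero")
    return t0_first / t0_second, b_second / b_first
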