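"""Acquisition latency model and minimum-time-resolution planning.

Every step of an acquisition cycle costs time: autofocusing (t_AF), stage
moves (t_mot(x), a function of travel distance x), filter-wheel moves
(t_filt(k), a function of slot distance k), exposures (t_exp per channel),
and — when images are processed in the control loop — segmentation (t_seg),
frame-to-frame mapping (t_map(n)) and feature extraction (t_ext(n)), the
latter two functions of the cell count n.  The shortest feasible acquisition
period for N fields of view and P channels is

    dt_min  = n_AF * t_AF
              + sum_{i=1..N} [ t_mot(x_i) + sum_{p=1..P} (t_filt(k_p) + t_exp_p) ]

    dt~_min = dt_min + N * (t_seg + t_map + t_ext)        (adaptive mode)

where 0 <= n_AF <= N is the number of FOVs autofocused each cycle and x_i
are consecutive travel distances along the route (closing the loop back to
the first FOV).  Each term is a low-order polynomial fitted to benchmark
timings; planning uses constants t_seg = 1.15 s and the n = 40-cell values
t_map = 3.74 s, t_ext = 0.53 s so that the chosen period stays feasible for
at least one population doubling after FOVs are seeded with <= 20 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fov_select import FieldOfView, order_route

__all__ = [
    "Channel",
    "LatencyModel",
    "LatencyFitError",
    "fit_latency_model",
    "fit_polynomial_term",
    "min_resolution",
    "min_resolution_adaptive",
    "rescale_on_drop",
]

#: planning constants, seconds (t_map/t_ext at the 40-cell operating point)
T_SEG_DEFAULT = 1.15
T_MAP_DEFAULT = 3.74
T_EXT_DEFAULT = 0.53
PLANNING_CELL_COUNT = 40

#: maximum polynomial degree per term (lowest degree with R^2 > 0.9 wins)
_DEGREE_CAP = {"t_af": 2, "t_map": 2, "t_mot": 1, "t_filt": 1, "t_ext": 1}


@dataclass(frozen=True)
class Channel:
    """One acquisition channel: a filter slot and an exposure."""

    name: str
    filter_slot: int
    exposure_ms: float

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms / 1000.0


@dataclass(frozen=True)
class LatencyModel:
    """Polynomial latency terms of one hardware + software configuration.

    Coefficients are in ascending order (numpy.polynomial convention).
    ``t_af_coeffs`` is a polynomial in image pixel count; the phase-contrast
    exposure used during focusing enters as an additive offset
    (``af_exposure_s``), and the pixel count is fixed per experiment, so
    the planner treats t_AF as a per-cycle constant.
    """

    t_af_coeffs: tuple[float, ...] = (4.0,)
    af_pixel_count: float = 0.0
    af_exposure_s: float = 0.0
    t_mot_coeffs: tuple[float, ...] = (0.18, 4.5e-4)
    t_filt_coeffs: tuple[float, ...] = (0.2, 0.05)
    t_seg: float = T_SEG_DEFAULT
    t_map_coeffs: tuple[float, ...] = (T_MAP_DEFAULT,)
    t_ext_coeffs: tuple[float, ...] = (T_EXT_DEFAULT,)
    planning_n_cells: int = PLANNING_CELL_COUNT

    def t_af(self) -> float:
        """Autofocus latency per focused FOV (s)."""
        return float(np.polynomial.polynomial.polyval(self.af_pixel_count, self.t_af_coeffs)) + self.af_exposure_s

    def t_mot(self, x_um: float) -> float:
        """Stage-move latency for a travel of ``x_um`` micrometres (s)."""
        return max(0.0, float(np.polynomial.polynomial.polyval(x_um, self.t_mot_coeffs)))

    def t_filt(self, k: int) -> float:
        """Filter-wheel latency for a ``k``-slot move (s); free when k = 0."""
        if k == 0:
            return 0.0
        return max(0.0, float(np.polynomial.polynomial.polyval(abs(k), self.t_filt_coeffs)))

    def t_map(self, n: int | None = None) -> float:
        """Cell-mapping latency for ``n`` cells (default: planning constant)."""
        n = self.planning_n_cells if n is None else n
        return max(0.0, float(np.polynomial.polynomial.polyval(n, self.t_map_coeffs)))

    def t_ext(self, n: int | None = None) -> float:
        """Feature-extraction latency for ``n`` cells (default: planning constant)."""
        n = self.planning_n_cells if n is None else n
        return max(0.0, float(np.polynomial.polynomial.polyval(n, self.t_ext_coeffs)))

    def processing_per_fov(self, n: int | None = None) -> float:
        """t_seg + t_map + t_ext, the adaptive-mode per-FOV overhead (s)."""
        return self.t_seg + self.t_map(n) + self.t_ext(n)

    def to_dict(self) -> dict:
        return {
            "t_af_coeffs": list(self.t_af_coeffs),
            "af_pixel_count": self.af_pixel_count,
            "af_exposure_s": self.af_exposure_s,
            "t_mot_coeffs": list(self.t_mot_coeffs),
            "t_filt_coeffs": list(self.t_filt_coeffs),
            "t_seg": self.t_seg,
            "t_map_coeffs": list(self.t_map_coeffs),
            "t_ext_coeffs": list(self.t_ext_coeffs),
            "planning_n_cells": self.planning_n_cells,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LatencyModel":
        kwargs = dict(d)
        for key in ("t_af_coeffs", "t_mot_coeffs", "t_filt_coeffs", "t_map_coeffs", "t_ext_coeffs"):
            if key in kwargs:
                kwargs[key] = tuple(float(c) for c in kwargs[key])
        return cls(**kwargs)


class LatencyFitError(RuntimeError):
    """No polynomial within the degree cap reached R^2 > 0.9."""

    def __init__(self, term: str, best_coeffs: tuple[float, ...], best_r2: float):
        self.term = term
        self.best_coeffs = best_coeffs
        self.best_r2 = best_r2
        super().__init__(
            f"latency term {term!r}: best fit (degree {len(best_coeffs) - 1}) "
            f"has R^2 = {best_r2:.4f} <= 0.9"
        )


def fit_polynomial_term(
    x: Sequence[float],
    y: Sequence[float],
    max_degree: int,
    r2_min: float = 0.9,
) -> tuple[tuple[float, ...], int, float]:
    """Least-squares fit of the lowest-order polynomial with R^2 > ``r2_min``.

    Returns ``(coeffs ascending, degree, r2)``.  Degenerate (constant) data
    fits degree 0 with R^2 defined as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 benchmark samples per term")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best: tuple[tuple[float, ...], int, float] | None = None
    for deg in range(0, max_degree + 1):
        coeffs = np.polynomial.polynomial.polyfit(x, y, deg)
        resid = y - np.polynomial.polynomial.polyval(x, coeffs)
        ss_res = float(np.sum(resid**2))
        r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        cand = (tuple(float(c) for c in coeffs), deg, r2)
        if best is None or r2 > best[2]:
            best = cand
        if r2 > r2_min:
            return cand
    assert best is not None
    raise LatencyFitError("<term>", best[0], best[2])


def fit_latency_model(
    benchmarks: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    r2_min: float = 0.9,
    **fixed,
) -> LatencyModel:
    """Fit a :class:`LatencyModel` from benchmark tables.

    Parameters
    ----------
    benchmarks
        Maps term names (``t_af``, ``t_mot``, ``t_filt``, ``t_map``,
        ``t_ext``) to ``(predictor, seconds)`` sample arrays.  ``t_seg``
        may map to a 1-D array of seconds, averaged to a constant.
    fixed
        Extra :class:`LatencyModel` fields (e.g. ``af_pixel_count``).

    For each term, polynomials of increasing degree are fitted and the
    lowest degree with R^2 > 0.9 is kept; degree caps reflect the physics
    (autofocus and mapping at most quadratic; motion, filter, extraction at
    most linear).  Failure to reach R^2 > 0.9 raises
    :class:`LatencyFitError` carrying the best attempt.
    """
    kwargs: dict = dict(fixed)
    for term, data in benchmarks.items():
        if term == "t_seg":
            arr = np.asarray(data, dtype=float).ravel()
            kwargs["t_seg"] = float(arr.mean())
            continue
        if term not in _DEGREE_CAP:
            raise ValueError(f"unknown latency term {term!r}")
        x, y = data
        try:
            coeffs, _deg, _r2 = fit_polynomial_term(x, y, _DEGREE_CAP[term], r2_min)
        except LatencyFitError as e:
            raise LatencyFitError(term, e.best_coeffs, e.best_r2) from None
        kwargs[f"{term}_coeffs"] = coeffs
    return LatencyModel(**kwargs)


def _travel_distances(fovs: Sequence[FieldOfView]) -> list[float]:
    """Consecutive x-y travel distances along the route, closing the loop."""
    n = len(fovs)
    return [
        math.hypot(fovs[(i + 1) % n].x - fovs[i].x, fovs[(i + 1) % n].y - fovs[i].y)
        for i in range(n)
    ]


def _filter_moves(channels: Sequence[Channel]) -> list[int]:
    """Slot distances per channel change within one FOV visit.

    The wheel arrives at channel 1 from the previous FOV's last channel,
    then steps through the channel order.
    """
    slots = [c.filter_slot for c in channels]
    prev = slots[-1]
    moves = []
    for s in slots:
        moves.append(abs(s - prev))
        prev = s
    return moves


def min_resolution(
    model: LatencyModel,
    fovs: Sequence[FieldOfView],
    channels: Sequence[Channel],
    n_af: int,
) -> float:
    """Minimum acquisition period dt_min (seconds) without live processing.

    Sums autofocus time for ``n_af`` FOVs, stage travel along the route
    (loop-closed), and per-FOV filter moves and exposures for each channel.
    """
    n = len(fovs)
    if not 0 <= n_af <= n:
        raise ValueError(f"n_af must satisfy 0 <= n_af <= {n}, got {n_af}")
    if n == 0:
        return 0.0
    per_fov_channels = sum(
        model.t_filt(k) + c.exposure_s for k, c in zip(_filter_moves(channels), channels)
    )
    travel = sum(model.t_mot(x) for x in _travel_distances(fovs))
    return n_af * model.t_af() + travel + n * per_fov_channels


def min_resolution_adaptive(
    model: LatencyModel,
    fovs: Sequence[FieldOfView],
    channels: Sequence[Channel],
    n_af: int,
    n_cells: int | None = None,
) -> float:
    """Minimum adaptive-mode period dt~_min (seconds).

    Adds the per-FOV image-processing overhead t_seg + t_map + t_ext to
    :func:`min_resolution`; by default the planning constants (40-cell
    operating point) are used rather than live cell counts.
    """
    base = min_resolution(model, fovs, channels, n_af)
    return base + len(fovs) * model.processing_per_fov(n_cells)


def rescale_on_drop(
    model: LatencyModel,
    fovs_retained: Sequence[FieldOfView],
    channels: Sequence[Channel],
    n_af: int | str = "all",
) -> tuple[float, list[FieldOfView]]:
    """Recompute dt~_min after FOVs are dropped mid-experiment.

    The retained FOVs are re-routed (a shorter tour is usually possible)
    and the adaptive minimum period recomputed.  ``n_af="all"`` autofocuses
    every retained FOV; an integer is clamped to the new FOV count.

    Returns ``(dt~_min seconds, re-routed retained FOVs)``.  An empty
    retained set is an error: the experiment cannot continue.
    """
    if len(fovs_retained) == 0:
        raise ValueError("no FOVs retained: experiment cannot continue")
    order = order_route([(f.x, f.y) for f in fovs_retained])
    routed = [replace(fovs_retained[i], retained=True) for i in order]
    eff_n_af = len(routed) if n_af == "all" else min(int(n_af), len(routed))
    return min_resolution_adaptive(model, routed, channels, eff_n_af), routed
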