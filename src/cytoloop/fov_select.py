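"""Scan planning, field-of-view selection and stage routing.

A scan region is specified by three corners (top-left, top-right,
bottom-right), each with its own z, so that the focal surface is a tilted
plane interpolated during the scan instead of autofocusing at every grid
position.  Grid steps equal the camera sensor size in object space
(physical sensor size / magnification); candidate FOVs are counted, the
best N are kept (at least one cell but fewer than a crowding threshold,
sorted by decreasing count), and the retained positions are reordered to
shorten the stage tour (nearest-neighbour construction + 2-opt refinement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FieldOfView",
    "ScanPlan",
    "CollinearCornersError",
    "plane_z",
    "plan_scan",
    "select_fovs",
    "order_route",
    "route_length",
]


@dataclass(frozen=True)
class FieldOfView:
    """A stage position with an associated cell count.

    Coordinates are stage micrometres; ``fov_id`` is assigned in scan order
    and is stable for the lifetime of an experiment.
    """

    x: float
    y: float
    z: float
    cell_count: int = 0
    retained: bool = True
    fov_id: int = -1


@dataclass(frozen=True)
class ScanPlan:
    """A serpentine raster over a 3-corner region."""

    corners: tuple[tuple[float, float, float], ...]
    step_x: float
    step_y: float
    n_cols: int
    n_rows: int
    positions: tuple[FieldOfView, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.positions)


class CollinearCornersError(ValueError):
    """The three region corners do not define a plane in (x, y)."""


def plane_z(
    corners: Sequence[Sequence[float]], x: float, y: float
) -> float:
    """z of the plane through three (x, y, z) corners, evaluated at (x, y).

    Raises :class:`CollinearCornersError` when the corners are collinear in
    the (x, y) projection.
    """
    (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = (tuple(map(float, c)) for c in corners)
    # z = z0 + s*(z1-z0) + t*(z2-z0) with (x,y) barycentric in the corner triangle
    det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    if abs(det) < 1e-12 * max(1.0, abs(x1 - x0), abs(y2 - y0)):
        raise CollinearCornersError(f"corners {corners!r} are collinear in (x, y)")
    s = ((x - x0) * (y2 - y0) - (x2 - x0) * (y - y0)) / det
    t = ((x1 - x0) * (y - y0) - (x - x0) * (y1 - y0)) / det
    return z0 + s * (z1 - z0) + t * (z2 - z0)


def plan_scan(
    corners: Sequence[Sequence[float]],
    sensor_px: tuple[int, int],
    pixel_size_um: float,
    magnification: float,
    binning: int = 1,
) -> ScanPlan:
    """Plan a serpentine raster scan covering a 3-corner region.

    Parameters
    ----------
    corners
        (top-left, top-right, bottom-right) as (x, y, z) in um.
    sensor_px
        Sensor resolution (width, height) in physical pixels.
    pixel_size_um
        Physical pixel pitch of the sensor, um.
    magnification
        Objective magnification (> 0).
    binning
        CCD pixel binning.  Binning changes image pixel counts, not the
        physical sensor extent, so it does not affect the grid.

    Notes
    -----
    The grid step is the sensor size in object space,
    ``step = sensor_px * pixel_size_um / magnification``; grid dimensions
    are ``floor(extent / step)`` per axis (at least 1).  With a 3000x3000 um
    region, a 1392x1040 sensor, 6.45 um pixels and a 63x objective this
    yields 21 x 28 = 588 positions.
    """
    if magnification <= 0:
        raise ValueError("magnification must be > 0")
    w, h = sensor_px
    if w < 1 or h < 1:
        raise ValueError("sensor dimensions must be >= 1 pixel")
    del binning  # object-space FOV size depends on physical sensor size only

    step_x = w * pixel_size_um / magnification
    step_y = h * pixel_size_um / magnification

    (tl, tr, br) = (tuple(map(float, c)) for c in corners)
    extent_x = math.hypot(tr[0] - tl[0], tr[1] - tl[1])
    extent_y = math.hypot(br[0] - tr[0], br[1] - tr[1])
    n_cols = max(1, math.floor(extent_x / step_x))
    n_rows = max(1, math.floor(extent_y / step_y))

    # unit vectors along the top edge (columns) and right edge (rows)
    ux = ((tr[0] - tl[0]) / extent_x, (tr[1] - tl[1]) / extent_x)
    uy = ((br[0] - tr[0]) / extent_y, (br[1] - tr[1]) / extent_y)

    positions: list[FieldOfView] = []
    fid = 0
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        for c in cols:
            # centre of grid cell (c, r), offset half a step from the corner
            dx = (c + 0.5) * step_x
            dy = (r + 0.5) * step_y
            x = tl[0] + ux[0] * dx + uy[0] * dy
            y = tl[1] + ux[1] * dx + uy[1] * dy
            z = plane_z(corners, x, y)
            positions.append(FieldOfView(x=x, y=y, z=z, fov_id=fid))
            fid += 1
    return ScanPlan(
        corners=(tl, tr, br),
        step_x=step_x,
        step_y=step_y,
        n_cols=n_cols,
        n_rows=n_rows,
        positions=tuple(positions),
    )


def select_fovs(
    candidates: Sequence[FieldOfView],
    n_keep: int,
    max_cells: int = 20,
    route: bool = True,
) -> list[FieldOfView]:
    """Keep the N most-populated usable FOVs and route-order them.

    A candidate is usable when ``1 <= cell_count < max_cells`` (empty FOVs
    carry no information; crowded ones become unsegmentable as cells grow).
    Usable candidates are sorted by decreasing count (ties keep scan order),
    truncated to ``n_keep`` and reordered into a short stage tour.

    An empty result (no usable candidate) is returned with a warning rather
    than an error.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    valid = [f for f in candidates if 1 <= f.cell_count < max_cells]
    if not valid:
        warnings.warn("no candidate FOV has 1 <= cell_count < max_cells", stacklevel=2)
        return []
    # stable sort keeps scan order among equal counts
    ranked = sorted(valid, key=lambda f: -f.cell_count)
    kept = [replace(f, retained=True) for f in ranked[:n_keep]]
    if route and len(kept) > 1:
        kept = [kept[i] for i in order_route([(f.x, f.y) for f in kept])]
    return kept


def route_length(points: Sequence[tuple[float, float]], order: Sequence[int] | None = None) -> float:
    """Total open-path Euclidean length of ``points`` visited in ``order``."""
    idx = list(order) if order is not None else list(range(len(points)))
    return float(
        sum(
            math.dist(points[idx[i]], points[idx[i + 1]])
            for i in range(len(idx) - 1)
        )
    )


def order_route(points: Sequence[tuple[float, float]]) -> list[int]:
    """Short stage tour over ``points``: nearest-neighbour then 2-opt.

    Returns a permutation of indices whose open-path length is never worse
    than the input order, and which admits no improving 2-opt segment
    reversal.  Starts from the first point (the stage is already there).
    """
    n = len(points)
    if n == 0:
        raise ValueError("order_route needs at least one position")
    if n == 1:
        return [0]
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)

    def _nn(start: int) -> list[int]:
        order = [start]
        free = set(range(n)) - {start}
        while free:
            last = order[-1]
            nxt = min(free, key=lambda j: (d[last, j], j))
            order.append(nxt)
            free.remove(nxt)
        return order

    def _length(order: list[int]) -> float:
        return float(d[order[:-1], order[1:]].sum())

    def _two_opt(order: list[int]) -> list[int]:
        # open-path 2-opt; i == -1 reverses the prefix (free left endpoint)
        improved = True
        while improved:
            improved = False
            for i in range(-1, n - 2):
                a = order[i] if i >= 0 else None
                for j in range(i + 2, n):
                    b, c = order[i + 1], order[j]
                    dn = order[j + 1] if j + 1 < n else None
                    old = (d[a, b] if a is not None else 0.0) + (
                        d[c, dn] if dn is not None else 0.0
                    )
                    new = (d[a, c] if a is not None else 0.0) + (
                        d[b, dn] if dn is not None else 0.0
                    )
                    if new < old - 1e-12:
                        order[i + 1 : j + 1] = reversed(order[i + 1 : j + 1])
                        improved = True
        return order

    # stage starts at point 0, so try that first; other constructions are
    # accepted only on strict improvement (keeps ties deterministic)
    best = _two_opt(_nn(0))
    best_len = _length(best)
    for start in range(1, n):
        cand = _two_opt(_nn(start))
        if _length(cand) < best_len - 1e-12:
            best, best_len = cand, _length(cand)
    if best_len > route_length(points) + 1e-12:
        best = _two_opt(list(range(n)))  # never worse than the input order
    return best
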