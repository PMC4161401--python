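"""Overlap-based cell tracking and feature extraction.

Cells move little between frames relative to their size, so identity is
assigned by pixel overlap: the overlap of two regions is the ratio of the
intersection of their pixels to their union (the Jaccard index).  Each cell
in the current frame claims the previous-frame cell it overlaps most,
greedily in descending overlap, one claim per previous cell; unclaimed
current cells (overlap below threshold, or their best match already taken —
typically a bud still overlapping its mother) are births.

Per-cell features are the pixel area of the label region and the raw mean
fluorescence under it; the fluorescence background (border-pixel median) is
reported separately so downstream criteria can background-subtract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .segmentation import LabeledImage

__all__ = [
    "CellRecord",
    "CellTrajectory",
    "Tracker",
    "overlap",
    "overlap_matrix",
    "map_cells",
    "extract_features",
]

#: minimum Jaccard overlap for frame-to-frame identity (below = birth)
OVERLAP_THRESHOLD = 0.3


class EmptyRegionsError(ValueError):
    """Both pixel sets are empty; overlap is undefined."""


class ShapeMismatchError(ValueError):
    """Label/fluorescence images must share a shape."""


def overlap(region_a: Iterable[tuple[int, int]], region_b: Iterable[tuple[int, int]]) -> float:
    """Jaccard overlap |A intersect B| / |A union B| of two pixel sets."""
    a, b = set(region_a), set(region_b)
    if not a and not b:
        raise EmptyRegionsError("overlap of two empty pixel sets is undefined")
    return len(a & b) / len(a | b)


def overlap_matrix(labels_now: LabeledImage, labels_prev: LabeledImage) -> np.ndarray:
    """Jaccard overlap of every (current, previous) label pair.

    Returns an array of shape ``(n_now + 1, n_prev + 1)`` indexed by label
    (row 0 / column 0 correspond to background and are zeroed).
    """
    now, prev = labels_now.labels, labels_prev.labels
    if now.shape != prev.shape:
        raise ShapeMismatchError(f"label shapes differ: {now.shape} vs {prev.shape}")
    n_now, n_prev = labels_now.n_cells, labels_prev.n_cells
    pair = now.astype(np.int64) * (n_prev + 1) + prev.astype(np.int64)
    inter = np.bincount(pair.ravel(), minlength=(n_now + 1) * (n_prev + 1)).reshape(
        n_now + 1, n_prev + 1
    )
    area_now = np.bincount(now.ravel(), minlength=n_now + 1).astype(np.float64)
    area_prev = np.bincount(prev.ravel(), minlength=n_prev + 1).astype(np.float64)
    union = area_now[:, None] + area_prev[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    jac[0, :] = 0.0
    jac[:, 0] = 0.0
    return jac


def map_cells(
    labels_now: LabeledImage,
    labels_prev: LabeledImage,
    threshold: float = OVERLAP_THRESHOLD,
) -> dict[int, int | None]:
    """Map current labels to previous labels by greedy maximal overlap.

    Returns ``{current_label: previous_label or None}``; ``None`` flags a
    birth.  Assignment is greedy in descending overlap (ties: lower current
    label first), each previous label claimed at most once, and any pair
    below ``threshold`` is rejected — a budding daughter overlapping its
    already-claimed mother therefore registers as a birth.
    """
    jac = overlap_matrix(labels_now, labels_prev)
    n_now, n_prev = labels_now.n_cells, labels_prev.n_cells
    mapping: dict[int, int | None] = {c: None for c in range(1, n_now + 1)}
    if n_now == 0 or n_prev == 0:
        return mapping
    pairs = [
        (jac[c, p], c, p)
        for c in range(1, n_now + 1)
        for p in range(1, n_prev + 1)
        if jac[c, p] >= threshold
    ]
    # descending overlap; ties resolved toward lower current then prev label
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_prev: set[int] = set()
    assigned: set[int] = set()
    for ov, c, p in pairs:
        if c in assigned or p in used_prev:
            continue
        mapping[c] = p
        assigned.add(c)
        used_prev.add(p)
    return mapping


def extract_features(
    labels: LabeledImage, fluorescence: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell (area, mean fluorescence) plus the image background level.

    Returns ``(areas, means, background)`` where ``areas[k-1]`` and
    ``means[k-1]`` belong to label k, and ``background`` is the median of
    the fluorescence image's border pixels.  Fluorescence means are raw
    (not background-subtracted).
    """
    fl = np.asarray(fluorescence, dtype=np.float64)
    if fl.shape != labels.labels.shape:
        raise ShapeMismatchError(
            f"fluorescence shape {fl.shape} != labels shape {labels.labels.shape}"
        )
    n = labels.n_cells
    lab = labels.labels
    areas = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    sums = np.bincount(lab.ravel(), weights=fl.ravel(), minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        means = np.where(areas > 0, sums / np.maximum(areas, 1), np.nan)
    border = np.concatenate([fl[0, :], fl[-1, :], fl[1:-1, 0], fl[1:-1, -1]])
    return areas, means, float(np.median(border))


@dataclass
class CellRecord:
    """One cell at one acquired frame."""

    t_min: float
    frame: int
    area_px: int
    mean_fluor: float
    background: float
    fov_id: int


@dataclass
class CellTrajectory:
    """A single cell's time-indexed identity, size and fluorescence."""

    cell_id: int
    fov_id: int
    records: list[CellRecord] = field(default_factory=list)
    mother_id: int | None = None

    @property
    def n_points(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.t_min for r in self.records])

    @property
    def fluorescence(self) -> np.ndarray:
        """Raw mean fluorescence per record."""
        return np.array([r.mean_fluor for r in self.records])

    @property
    def fluorescence_bgsub(self) -> np.ndarray:
        """Background-subtracted mean fluorescence per record."""
        return np.array([r.mean_fluor - r.background for r in self.records])

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.area_px for r in self.records])


class Tracker:
    """Accumulates stable cell identities for one field of view.

    Feed one segmented frame (plus its fluorescence image) per acquisition
    cycle; the tracker links labels to the previous frame by overlap and
    maintains :class:`CellTrajectory` objects keyed by stable ids (unique
    within the tracker; offset by FOV externally if needed).
    """

    def __init__(self, fov_id: int = 0, threshold: float = OVERLAP_THRESHOLD):
        self.fov_id = fov_id
        self.threshold = threshold
        self.trajectories: dict[int, CellTrajectory] = {}
        self._prev_labels: LabeledImage | None = None
        self._prev_ids: dict[int, int] = {}  # prev frame label -> stable id
        self._next_id = 1
        self._frame = 0

    def add_frame(
        self, labels: LabeledImage, fluorescence: np.ndarray, t_min: float
    ) -> dict[int, int]:
        """Ingest one frame; returns {label -> stable cell id} for it."""
        areas, means, bg = extract_features(labels, fluorescence)
        if self._prev_labels is None:
            mapping: dict[int, int | None] = {c: None for c in range(1, labels.n_cells + 1)}
        else:
            mapping = map_cells(labels, self._prev_labels, self.threshold)
        ids: dict[int, int] = {}
        for label in range(1, labels.n_cells + 1):
            prev_label = mapping[label]
            if prev_label is not None and prev_label in self._prev_ids:
                cid = self._prev_ids[prev_label]
            else:
                cid = self._next_id
                self._next_id += 1
                self.trajectories[cid] = CellTrajectory(cell_id=cid, fov_id=self.fov_id)
            ids[label] = cid
            self.trajectories[cid].records.append(
                CellRecord(
                    t_min=t_min,
                    frame=self._frame,
                    area_px=int(areas[label - 1]),
                    mean_fluor=float(means[label - 1]),
                    background=bg,
                    fov_id=self.fov_id,
                )
            )
        self._prev_labels = labels
        self._prev_ids = ids
        self._frame += 1
        return ids
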