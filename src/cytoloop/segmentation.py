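"""Phase-contrast cell segmentation.

Yeast in phase contrast appear as dark interiors ringed by bright halos on a
mid-grey background, so cell interiors are regional minima of the image.
The pipeline:

1. flood-fill every regional minimum not connected to the image border
   (fills the interiors of cell groups up to their pour level);
2. estimate the background as the median of the border pixels;
3. scan the histogram of the filled image for intensity levels brighter
   than background that occur more often than the minimum cell area — each
   group of cells floods to its own slightly different level, and only
   levels with enough pixels can be cell groups;
4. keep pixels at those levels that were actually raised by the fill (plus
   enclosed holes), and discard components that are too small to be cells;
5. separate touching cells by cutting the thin necks between them with an
   erosion, label the pieces, and restore each cell to its original extent
   with a label-preserving dilation (a pixel joins its nearest label, ties
   to the lower label).

Defaults follow a minimum cell area of 200 px at 63x magnification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, reconstruction

__all__ = [
    "SegmentationParams",
    "LabeledImage",
    "fill_and_threshold",
    "split_and_label",
    "segment",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    min_area
        Minimum cell area in pixels (component filter and histogram
        frequency threshold); 200 px suits yeast at 63x.
    cleanup_radius
        Disk radius (px) of the debris-removal erosion applied when sizing
        components in :func:`fill_and_threshold`.
    neck_radius
        Disk radius (px) of the erosion that cuts necks between touching
        cells; also the radius of the restoring dilation.
    dilation_radius
        Radius of the restoring dilation; ``None`` means equal to
        ``neck_radius``.
    n_bins
        Histogram bins used for floating-point images (integer images use
        unit-width bins).
    """

    min_area: int = 200
    cleanup_radius: int = 1
    neck_radius: int = 3
    dilation_radius: int | None = None
    n_bins: int = 256

    def __post_init__(self):
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.cleanup_radius < 1 or self.neck_radius < 1:
            raise ValueError("erosion radii must be >= 1")

    @property
    def restore_radius(self) -> int:
        return self.neck_radius if self.dilation_radius is None else self.dilation_radius


@dataclass(frozen=True)
class LabeledImage:
    """Integer label mask: 0 = background, k in 1..n_cells = cell k."""

    labels: np.ndarray
    n_cells: int

    def __post_init__(self):
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")

    def pixel_set(self, label: int) -> set[tuple[int, int]]:
        """Pixels of one label as a set of (row, col) tuples."""
        rows, cols = np.nonzero(self.labels == label)
        return set(zip(rows.tolist(), cols.tolist()))

    def areas(self) -> np.ndarray:
        """Pixel count per label, index 0 unused (areas[k] = area of cell k)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)


def _fill_minima(image: np.ndarray) -> np.ndarray:
    """Flood-fill regional minima not connected to the image border.

    Morphological reconstruction by erosion from a border-anchored seed:
    interior minima are filled to their pour level, border-connected ones
    are left alone.
    """
    seed = np.full_like(image, image.max())
    seed[0, :] = image[0, :]
    seed[-1, :] = image[-1, :]
    seed[:, 0] = image[:, 0]
    seed[:, -1] = image[:, -1]
    return reconstruction(seed, image, method="erosion")


def _border_median(image: np.ndarray) -> float:
    border = np.concatenate(
        [image[0, :], image[-1, :], image[1:-1, 0], image[1:-1, -1]]
    )
    return float(np.median(border))


def fill_and_threshold(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of cell groups from a phase-contrast image.

    Implements steps 1-4 of the module pipeline (see module docstring):
    fill interior minima, find histogram levels above the border-median
    background with frequency above the minimum cell area, keep fill-raised
    pixels at those levels plus enclosed holes, and drop components whose
    area after a cleanup erosion falls below the minimum cell area.

    Returns a boolean mask; an image with no candidate level yields an
    empty mask (not an error).
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    filled = _fill_minima(img)
    background = _border_median(img)

    # histogram of the filled image: unit bins for integer data, n_bins else
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        lo, hi = int(filled.min()), int(np.ceil(filled.max()))
        edges = np.arange(lo, hi + 2) - 0.5
    else:
        lo, hi = float(filled.min()), float(filled.max())
        if hi <= lo:
            return np.zeros(img.shape, dtype=bool)
        edges = np.linspace(lo, hi, params.n_bins + 1)
    counts, edges = np.histogram(filled, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    candidate = (centers > background) & (counts > params.min_area)
    if not candidate.any():
        return np.zeros(img.shape, dtype=bool)

    bin_idx = np.clip(np.digitize(filled, edges) - 1, 0, len(counts) - 1)
    raised = filled > img + 1e-12  # pixels actually changed by the fill
    mask = candidate[bin_idx] & raised
    mask = ndi.binary_fill_holes(mask)

    # size filter: a component must keep >= min_area pixels after a cleanup
    # erosion (removes debris and thin bridges of barely-raised pixels)
    eroded = ndi.binary_erosion(mask, structure=disk(params.cleanup_radius))
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    surviving = np.bincount((lab * eroded).ravel(), minlength=n + 1)
    keep = surviving >= params.min_area
    keep[0] = False
    return keep[lab]


def _label_preserving_dilation(labels: np.ndarray, radius: int) -> np.ndarray:
    """Grow every label by ``radius`` without merging regions.

    Iterated 8-neighbour accretion: each round, an unlabeled pixel adjacent
    to labeled pixels joins the smallest neighbouring label.  This realizes
    nearest-label assignment in the chamfer metric with deterministic
    ties-to-lower-label behaviour.
    """
    out = labels.copy()
    big = np.iinfo(out.dtype).max
    footprint = np.ones((3, 3), dtype=bool)
    for _ in range(radius):
        grown = np.where(out == 0, big, out)
        nearest = ndi.minimum_filter(grown, footprint=footprint)
        newly = (out == 0) & (nearest != big)
        out[newly] = nearest[newly]
    return out


def split_and_label(mask: np.ndarray, params: SegmentationParams | None = None) -> LabeledImage:
    """Separate touching cells in a group mask and label them.

    Erodes by the neck-cut radius (severing the thin necks between touching
    cells), labels the remaining components in raster-scan order, then
    restores each cell toward its original size with a label-preserving
    dilation clipped to the input mask.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    cut = ndi.binary_erosion(mask, structure=disk(params.neck_radius))
    lab, n = ndi.label(cut)
    if n == 0:
        return LabeledImage(labels=np.zeros(mask.shape, dtype=np.int32), n_cells=0)
    lab = _label_preserving_dilation(lab.astype(np.int32), params.restore_radius)
    lab[~mask] = 0  # never grow beyond the detected cell-group mask
    # relabel 1..n in raster order of first appearance (erosion can delete
    # components entirely)
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    uniq, first = np.unique(flat[nz], return_index=True)
    order = np.argsort(first, kind="stable")
    remap = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    remap[uniq[order]] = np.arange(1, len(uniq) + 1, dtype=np.int32)
    return LabeledImage(labels=remap[lab], n_cells=int(len(uniq)))


def segment(image: np.ndarray, params: SegmentationParams | None = None) -> LabeledImage:
    """Full phase-contrast segmentation: fill/threshold then split/label."""
    params = params or SegmentationParams()
    return split_and_label(fill_and_threshold(image, params), params)
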