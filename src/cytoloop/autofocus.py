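"""Contrast-based software autofocus.

Best focus is found from image content alone: a scalar contrast metric is
evaluated on images snapped at a handful of z positions, and the stage moves
to the plane that maximizes it.  The metric is the two-term autocorrelation
difference (Vollath's F4),

    C = sum_xy I(x, y) * I(x+1, y)  -  sum_xy I(x, y) * I(x+2, y),

which peaks sharply at focus for phase-contrast images because defocus blur
suppresses the short-range autocorrelation difference.  The search is a
two-pass grid: five planes 2 um apart centred on the current z, then five
planes 0.3 um apart centred on the coarse winner — exactly 10 images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["ContrastValue", "contrast", "focus_search", "COARSE_STEP_UM", "FINE_STEP_UM"]

#: z spacing of the first (coarse) 5-plane pass, in micrometres.
COARSE_STEP_UM = 2.0
#: z spacing of the second (fine) 5-plane pass, in micrometres.
FINE_STEP_UM = 0.3


@dataclass(frozen=True)
class ContrastValue:
    """Autocorrelation contrast of one image plane."""

    C: float
    shape: tuple[int, int]

    def __float__(self) -> float:  # allows max()/argmax on the dataclass
        return self.C


class ImageTooNarrowError(ValueError):
    """Image has fewer than 3 pixels along the correlation axis."""


def contrast(image: np.ndarray, direction: str = "x") -> ContrastValue:
    """Autocorrelation contrast metric of a 2-D image.

    Parameters
    ----------
    image
        2-D grayscale array.  Any real dtype.
    direction
        ``"x"`` correlates along rows (shifts in the column index, the
        default), ``"y"`` along columns, ``"symmetric"`` averages the two.

    Returns
    -------
    ContrastValue
        ``C = sum I(x,y) I(x+1,y) - sum I(x,y) I(x+2,y)`` with sums over all
        valid index pairs.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"contrast expects a 2-D image, got shape {img.shape}")

    def _along_axis(a: np.ndarray, axis: int) -> float:
        if a.shape[axis] < 3:
            raise ImageTooNarrowError(
                f"image must span at least 3 pixels along axis {axis}, "
                f"got {a.shape[axis]}"
            )
        sl1_a = [slice(None)] * 2
        sl1_b = [slice(None)] * 2
        sl2_a = [slice(None)] * 2
        sl2_b = [slice(None)] * 2
        sl1_a[axis], sl1_b[axis] = slice(0, -1), slice(1, None)
        sl2_a[axis], sl2_b[axis] = slice(0, -2), slice(2, None)
        lag1 = float(np.sum(a[tuple(sl1_a)] * a[tuple(sl1_b)]))
        lag2 = float(np.sum(a[tuple(sl2_a)] * a[tuple(sl2_b)]))
        return lag1 - lag2

    # image axis 1 (columns) is x
    if direction == "x":
        c = _along_axis(img, 1)
    elif direction == "y":
        c = _along_axis(img, 0)
    elif direction == "symmetric":
        c = 0.5 * (_along_axis(img, 1) + _along_axis(img, 0))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ContrastValue(C=c, shape=(img.shape[0], img.shape[1]))


def _argmax_lowest(zs: Sequence[float], cs: Sequence[float]) -> float:
    """Return the z of maximal contrast; ties go to the lowest z."""
    order = np.argsort(zs, kind="stable")
    zs_sorted = np.asarray(zs)[order]
    cs_sorted = np.asarray(cs)[order]
    return float(zs_sorted[int(np.argmax(cs_sorted))])  # argmax takes first max


def focus_search(
    image_source: Callable[[float], np.ndarray],
    z0: float,
    direction: str = "x",
) -> float:
    """Two-pass 5-plane autofocus around ``z0``.

    Pass 1 snaps images at ``{z0-4, z0-2, z0, z0+2, z0+4}`` um and moves to
    the contrast argmax ``z1``; pass 2 refines over
    ``{z1-0.6, z1-0.3, z1, z1+0.3, z1+0.6}``.  Exactly 10 images are
    acquired.  Contrast ties resolve to the lowest z.

    Parameters
    ----------
    image_source
        Callable mapping a commanded z (um) to a 2-D image, e.g. a bound
        microscope snap.
    z0
        Starting z position (um).

    Returns
    -------
    float
        The refined best-focus z (um).
    """
    coarse = [z0 + k * COARSE_STEP_UM for k in (-2, -1, 0, 1, 2)]
    c_coarse = [contrast(image_source(z), direction).C for z in coarse]
    z1 = _argmax_lowest(coarse, c_coarse)

    fine = [z1 + k * FINE_STEP_UM for k in (-2, -1, 0, 1, 2)]
    c_fine = [contrast(image_source(z), direction).C for z in fine]
    return _argmax_lowest(fine, c_fine)
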