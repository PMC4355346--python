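"""Morphological primitives and the field-of-view mask recipe.

Structuring elements are explicit boolean footprints with the origin at the
centre cell.  Discs contain exactly the lattice offsets at Euclidean
distance <= r from the origin (library disc definitions differ; this one is
fixed here).  Lines contain exactly L cells rasterised through the origin
at a given angle, measured counterclockwise from the +col axis.

Border conventions: erosion treats out-of-image cells as foreground (the
field of view is not eaten away at the frame), dilation treats them as
background.  Greyscale erosion/dilation are the per-pixel min/max over the
footprint with the matching +inf/-inf padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import EmptyFovError
from .thresholding import iterative_threshold

_CROSS4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_BOX8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True, eq=False)
class StructuringElement:
    """A binary footprint with its origin at the centre of an odd-sized box."""

    footprint: np.ndarray
    descriptor: str

    @property
    def origin(self) -> tuple[int, int]:
        return (self.footprint.shape[0] // 2, self.footprint.shape[1] // 2)

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of (row, col) offsets of the true cells."""
        oy, ox = self.origin
        rows, cols = np.nonzero(self.footprint)
        return np.stack([rows - oy, cols - ox], axis=1)


def make_disc(radius: int) -> StructuringElement:
    """Disc of all lattice offsets with Euclidean distance <= radius."""
    if int(radius) != radius or radius < 1:
        raise ValueError(f"disc radius must be a positive integer, got {radius}")
    radius = int(radius)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    fp = (yy * yy + xx * xx) <= radius * radius
    return StructuringElement(footprint=fp, descriptor=f"disc(r={radius})")


def make_line(length: int, angle_deg: float) -> StructuringElement:
    """Line of exactly `length` cells through the origin at `angle_deg`.

    The angle is measured counterclockwise from the +col axis (so 180 deg
    is horizontal and 90 deg vertical); the segment is rasterised one cell
    per step of its major axis, which keeps the cells 8-connected and
    collinear to within half a pixel.
    """
    if int(length) != length or length < 1:
        raise ValueError(f"line length must be a positive integer, got {length}")
    length = int(length)
    theta = np.deg2rad(angle_deg)
    ks = np.arange(length) - length // 2
    if abs(np.cos(theta)) >= abs(np.sin(theta)):
        cols = ks
        rows = np.rint(-np.tan(theta) * ks).astype(int)
    else:
        rows = ks
        cols = np.rint(-ks / np.tan(theta)).astype(int)
    half_r = int(np.abs(rows).max())
    half_c = int(np.abs(cols).max())
    fp = np.zeros((2 * half_r + 1, 2 * half_c + 1), dtype=bool)
    fp[rows + half_r, cols + half_c] = True
    return StructuringElement(footprint=fp, descriptor=f"line(L={length}, angle={angle_deg}deg)")


def _footprint(se: StructuringElement | np.ndarray) -> np.ndarray:
    fp = se.footprint if isinstance(se, StructuringElement) else np.asarray(se, dtype=bool)
    if fp.ndim != 2 or not fp.any():
        raise ValueError("structuring element must be a non-empty 2-D footprint")
    return fp


def erode(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion: binary subset test / greyscale minimum over the footprint."""
    fp = _footprint(se)
    image = np.asarray(image)
    if image.dtype == bool:
        return ndimage.binary_erosion(image, structure=fp, border_value=1)
    return ndimage.grey_erosion(image.astype(float), footprint=fp, mode="constant", cval=np.inf)


def dilate(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation: Minkowski sum (reflected-hit test) / greyscale maximum."""
    fp = _footprint(se)
    image = np.asarray(image)
    if image.dtype == bool:
        return ndimage.binary_dilation(image, structure=fp, border_value=0)
    return ndimage.grey_dilation(image.astype(float), footprint=fp, mode="constant", cval=-np.inf)


def opening(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation; anti-extensive and idempotent."""
    return dilate(erode(image, se), se)


def clear_border_structures(image: np.ndarray) -> np.ndarray:
    """Remove structures 4-connected to the image border.

    Binary masks: every foreground component touching the border is
    removed.  Greyscale: bright border-connected structures are flattened
    by subtracting the morphological reconstruction (by dilation, 4-connected)
    of the image from a border marker; interior bright structures survive on
    a zeroed background.
    """
    image = np.asarray(image)
    if image.dtype == bool:
        labels, n = ndimage.label(image, structure=_CROSS4)
        if n == 0:
            return image.copy()
        border = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
        border = border[border != 0]
        if border.size == 0:
            return image.copy()
        return image & ~np.isin(labels, border)
    from skimage.morphology import reconstruction

    arr = image.astype(float)
    marker = np.full_like(arr, arr.min())
    marker[0, :] = arr[0, :]
    marker[-1, :] = arr[-1, :]
    marker[:, 0] = arr[:, 0]
    marker[:, -1] = arr[:, -1]
    rec = reconstruction(marker, arr, method="dilation", footprint=_CROSS4)
    return arr - rec


def remove_small_components(mask: np.ndarray, min_size: int, connectivity: int = 8) -> np.ndarray:
    """Drop connected components with fewer than `min_size` pixels.

    Components with exactly `min_size` pixels are kept ("fewer than" is
    strict).  Connectivity is 4 or 8 (default 8: vessels are thin diagonal
    structures that 4-connectivity would fragment).
    """
    if int(min_size) != min_size or min_size < 1:
        raise ValueError(f"min_size must be a positive integer, got {min_size}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    structure = _BOX8 if connectivity == 8 else _CROSS4
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


class FovMasks(NamedTuple):
    """The field-of-view mask and its dilated/eroded companions."""

    fov: np.ndarray
    dilated: np.ndarray  # used to gate optic-disc candidates
    eroded: np.ndarray   # used to trim the vessel map away from the FOV rim


def build_fov_mask(
    green: np.ndarray,
    *,
    green_threshold=10,
    open_radius: int = 1,
    dilate_radius: int = 15,
    erode_radius: int = 10,
    fill: bool = True,
    t0: float = 15.0,
    tol: float = 0.5,
) -> FovMasks:
    """Construct the circular field-of-view mask from the green channel.

    Pixels above `green_threshold` (or an automatically estimated threshold
    when ``green_threshold="auto"``) form the raw mask, which is then opened
    with a radius-1 disc to shed speckle, cleared of border-connected
    structures, and (by default) hole-filled so vessel shadows do not punch
    holes in it.  The dilated companion (radius 15) gates optic-disc
    candidates; the eroded companion (radius 10) removes the bright outer
    rim from the vessel map.

    Raises :class:`EmptyFovError` when no pixel exceeds the threshold.
    """
    arr = np.asarray(green, dtype=float)
    if green_threshold == "auto":
        thr = iterative_threshold(arr, t0=t0, tol=tol).threshold
    else:
        thr = float(green_threshold)
    raw = arr > thr
    if not raw.any():
        raise EmptyFovError(f"no pixel above the FOV threshold {thr:g}; image appears all-dark")
    mask = opening(raw, make_disc(open_radius))
    mask = clear_border_structures(mask)
    if fill:
        mask = fill_holes(mask)
    if not mask.any():
        raise EmptyFovError("field of view vanished during mask cleanup")
    return FovMasks(
        fov=mask,
        dilated=dilate(mask, make_disc(dilate_radius)),
        eroded=erode(mask, make_disc(erode_radius)),
    )
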