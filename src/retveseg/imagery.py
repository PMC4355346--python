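"""Fundus image and mask I/O, channel extraction, and dataset readers.

Conventions used throughout the package: an RGB fundus photograph is an
``(H, W, 3)`` uint8 array, a single channel is a 2-D array (integer on
load, float during processing), and a mask is a 2-D boolean array.  All
rasters are row-major with the origin at the top-left corner and 0-based
``(row, col)`` indexing.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

CHANNELS = {"red": 0, "green": 1, "blue": 2}

#: Default file layouts of the two public benchmarks.  Each entry is a list
#: of candidate path patterns relative to the dataset root; ``{id}`` is the
#: case identifier.  The first pattern that exists on disk wins, so a single
#: layout covers both the training and test halves of DRIVE.
DRIVE_LAYOUT = {
    "image": ["images/{id}_training.tif", "images/{id}_test.tif"],
    "truth": ["1st_manual/{id}_manual1.gif"],
    "fov": ["mask/{id}_training_mask.gif", "mask/{id}_test_mask.gif"],
}
STARE_LAYOUT = {
    "image": ["im{id}.ppm"],
    "truth": ["labels-ah/im{id}.ah.ppm"],
    "fov": [],
}

_LAYOUTS = {"drive": DRIVE_LAYOUT, "stare": STARE_LAYOUT}


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB image as an ``(H, W, 3)`` uint8 array.

    Greyscale inputs are replicated to three channels; an alpha channel is
    dropped.  Raises :class:`FileNotFoundError` for a missing file and
    :class:`FormatError` for anything that does not decode to 8-bit pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # decoder errors vary wildly per plugin
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 4:  # animated container: use the first frame
        arr = arr[0]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"{path}: expected a 2-D or RGB(A) raster, got shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype} (expected 8 bits per plane)")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise FormatError(f"{path}: image must be at least 3x3, got {arr.shape[:2]}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an image (2-D channel or ``(H, W, 3)`` RGB) losslessly.

    Float channels are clipped to [0, 255] and rounded; no re-compression of
    JPEG sources ever occurs because outputs are always fresh PNG/TIFF/PPM.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def extract_channel(image: np.ndarray, channel: str) -> np.ndarray:
    """Return one colour plane of an RGB image, unchanged."""
    try:
        idx = CHANNELS[str(channel).lower()]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}; expected one of {sorted(CHANNELS)}") from None
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    return image[..., idx]


def read_mask(path) -> np.ndarray:
    """Read a binary mask: any pixel with intensity > 0 becomes True.

    DRIVE/STARE manual labels are stored as 0/255 rasters, so this
    binarisation is exact for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"cannot decode mask {path}: {exc}") from exc
    if arr.ndim == 4:
        arr = arr[0]
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 image (round-trips through read_mask)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def load_dataset_case(root, layout: str, case_id: str, layout_map: dict | None = None):
    """Load one case from a DRIVE/STARE-style directory.

    Returns ``(image, truth, fov)`` where ``truth`` (manual vessel labels)
    and ``fov`` are None when the corresponding files are absent.  A missing
    image file raises :class:`FileNotFoundError` naming the paths searched.
    ``layout_map`` overrides individual pattern lists of the built-in layout
    (keys ``image``, ``truth``, ``fov``).
    """
    root = Path(root)
    try:
        patterns = dict(_LAYOUTS[str(layout).lower()])
    except KeyError:
        raise ValueError(f"unknown dataset layout {layout!r}; expected 'drive' or 'stare'") from None
    if layout_map:
        patterns.update(layout_map)

    def _find(kind):
        for pat in patterns.get(kind, []):
            candidate = root / pat.format(id=case_id)
            if candidate.exists():
                return candidate
        return None

    image_path = _find("image")
    if image_path is None:
        tried = [str(root / p.format(id=case_id)) for p in patterns["image"]]
        raise FileNotFoundError(f"no image for case {case_id!r}; looked for: {', '.join(tried)}")
    image = read_image(image_path)
    truth_path = _find("truth")
    fov_path = _find("fov")
    truth = read_mask(truth_path) if truth_path else None
    fov = read_mask(fov_path) if fov_path else None
    return image, truth, fov
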