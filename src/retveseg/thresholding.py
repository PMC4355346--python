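"""Iterative mean-split (isodata-style) thresholding.

Starting from an initial guess T0, the image is split into the pixels above
T and those at or below it, and T is replaced by the midpoint of the two
group means, ``T = (mean1 + mean2) / 2``, until successive thresholds differ
by less than a tolerance.  The same routine serves two stages of the
pipeline: separating the optic disc from the diffused red channel and
separating vessels from background in the maximum-response image.

The split is strict on the upper side: group 1 is ``values > T``, group 2 is
``values <= T``.  If either group empties, its mean is taken as the current
T, which freezes the iteration and guarantees termination on near-constant
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ThresholdState:
    """Bookkeeping of one thresholding run (useful for run manifests)."""

    t0: float
    t: float
    mean1: float
    mean2: float
    tol: float
    iterations_run: int
    converged: bool
    degenerate: bool  # constant input: threshold equals the constant


@dataclass
class ThresholdResult:
    threshold: float
    mask: np.ndarray  # image > threshold
    state: ThresholdState


def iterative_threshold(
    image: np.ndarray,
    t0: float = 15.0,
    tol: float = 0.5,
    *,
    within: np.ndarray | None = None,
    max_iter: int = 100,
) -> ThresholdResult:
    """Threshold an image by iterated mean splitting.

    Parameters
    ----------
    image
        2-D intensity raster (any real dtype).
    t0
        Initial threshold guess, clamped into the observed value range.
    tol
        Convergence tolerance on successive thresholds, in grey levels.
    within
        Optional boolean mask restricting the pixels from which the
        threshold is *estimated* (e.g. the field of view).  The returned
        mask is always full-frame ``image > T``.
    max_iter
        Safety cap; the isodata iteration is monotone-bracketed and
        terminates long before this on 8-bit data.

    A constant input returns that constant as the threshold with an
    all-false mask and ``state.degenerate`` set, rather than raising.
    """
    arr = np.asarray(image, dtype=float)
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if within is not None:
        values = arr[np.asarray(within, dtype=bool)]
    else:
        values = arr.ravel()
    if values.size == 0:
        raise ValueError("no pixels available to estimate a threshold")

    vmin, vmax = float(values.min()), float(values.max())
    t = float(np.clip(t0, vmin, vmax))
    if vmin == vmax:
        state = ThresholdState(t0=float(t0), t=vmin, mean1=vmin, mean2=vmin, tol=tol,
                               iterations_run=1, converged=True, degenerate=True)
        return ThresholdResult(threshold=vmin, mask=arr > vmin, state=state)

    mean1 = mean2 = t
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        upper = values > t
        mean1 = float(values[upper].mean()) if upper.any() else t
        mean2 = float(values[~upper].mean()) if (~upper).any() else t
        t_new = 0.5 * (mean1 + mean2)
        delta = abs(t_new - t)
        t = t_new
        if delta < tol:
            converged = True
            break

    state = ThresholdState(t0=float(t0), t=t, mean1=mean1, mean2=mean2, tol=tol,
                           iterations_run=iterations, converged=converged, degenerate=False)
    return ThresholdResult(threshold=t, mask=arr > t, state=state)
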