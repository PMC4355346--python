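"""Independent brute-force reference implementations.

Deliberately written as plain double loops / set operations over
coordinates, sharing no code with the package, so each oracle is an
independent statement of the operation's definition.
"""

from __future__ import annotations

import numpy as np

_DIRS8 = [(-1, 0), (1, 0), (0, 1), (0, -1), (-1, 1), (-1, -1), (1, 1), (1, -1)]


def diffuse_reference(image, psi, kappa, iterations):
    """Explicit eight-direction diffusion, pixel by pixel, edge-replicated."""
    img = np.asarray(image, dtype=float).copy()
    h, w = img.shape
    for _ in range(iterations):
        out = img.copy()
        for r in range(h):
            for c in range(w):
                centre = img[r, c]
                acc = 0.0
                for dr, dc in _DIRS8:
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    g = img[rr, cc] - centre
                    acc += g / (1.0 + (g / kappa) ** 2)
                out[r, c] = centre + psi * acc
        img = out
    return img


def isodata_reference(values, t0, tol, max_iter=100):
    """Mean-split threshold recomputed from the full integer histogram.

    `values` must be non-negative integers; returns (threshold, iterations).
    """
    values = np.asarray(values).ravel()
    hist = np.bincount(values.astype(int))
    levels = np.arange(hist.size, dtype=float)
    vmin = values.min()
    vmax = values.max()
    t = float(np.clip(t0, vmin, vmax))
    if vmin == vmax:
        return float(vmin), 1
    for it in range(1, max_iter + 1):
        upper = levels > t
        n1 = hist[upper].sum()
        n2 = hist[~upper].sum()
        mean1 = (hist[upper] * levels[upper]).sum() / n1 if n1 else t
        mean2 = (hist[~upper] * levels[~upper]).sum() / n2 if n2 else t
        t_new = 0.5 * (mean1 + mean2)
        delta = abs(t_new - t)
        t = t_new
        if delta < tol:
            break
    return t, it


def erode_reference(mask, footprint):
    """Binary erosion by subset test; out-of-image cells count as foreground."""
    mask = np.asarray(mask, dtype=bool)
    fp = np.asarray(footprint, dtype=bool)
    oy, ox = fp.shape[0] // 2, fp.shape[1] // 2
    offs = [(r - oy, c - ox) for r, c in zip(*np.nonzero(fp))]
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilate_reference(mask, footprint):
    """Binary dilation as the Minkowski sum (stamp the footprint on each hit)."""
    mask = np.asarray(mask, dtype=bool)
    fp = np.asarray(footprint, dtype=bool)
    oy, ox = fp.shape[0] // 2, fp.shape[1] // 2
    offs = [(r - oy, c - ox) for r, c in zip(*np.nonzero(fp))]
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
    return out


def clear_border_reference(mask):
    """Flood fill from every border foreground pixel, 4-connected."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    stack = [(r, c) for r in range(h) for c in (0, w - 1) if mask[r, c]]
    stack += [(r, c) for c in range(w) for r in (0, h - 1) if mask[r, c]]
    while stack:
        r, c = stack.pop()
        if not (0 <= r < h and 0 <= c < w) or seen[r, c] or not mask[r, c]:
            continue
        seen[r, c] = True
        stack.extend([(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)])
    return mask & ~seen


def component_sizes_reference(mask, connectivity=8):
    """Label by flood fill; returns a same-shape array of component sizes."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    dirs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        dirs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    labels = np.zeros((h, w), dtype=int)
    sizes = [0]
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                count = 0
                while stack:
                    r, c = stack.pop()
                    if not (0 <= r < h and 0 <= c < w) or not mask[r, c] or labels[r, c]:
                        continue
                    labels[r, c] = nxt
                    count += 1
                    stack.extend((r + dr, c + dc) for dr, dc in dirs)
                sizes.append(count)
    return np.asarray(sizes)[labels]


def confusion_reference(pred, truth, fov=None):
    """Four-way per-pixel tally; returns (tp, fp, tn, fn)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = fp = tn = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            if fov is not None and not fov[r, c]:
                continue
            if pred[r, c] and truth[r, c]:
                tp += 1
            elif pred[r, c]:
                fp += 1
            elif truth[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
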