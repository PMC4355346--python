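"""Seeded synthetic fundus phantom with exact ground-truth masks.

The phantom reproduces the structure the segmentation pipeline relies on:
a bright circular field of view on a dark camera surround, a bright
circular optic disc (brightest in the red channel, with a Gaussian-blurred
edge), and a dark branching vessel tree grown by a seeded random walk from
points on the disc rim outward (highest contrast in the green channel),
plus additive Gaussian noise.  Ground-truth vessel/disc/FOV masks are
rendered before noise and without anti-aliasing; the intensity image gets a
1-pixel linear coverage ramp at vessel edges.

One pseudo-random stream per sample, consumed in a fixed order — optic-disc
placement (only when not pinned), then tree growth, then noise — so
changing the noise level never reshuffles the tree geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, photometry and randomness of one synthetic fundus image.

    Intensities are grey levels in [0, 255].  ``od_center`` of None places
    the disc at a seed-dependent position drawn uniformly inside the field
    of view (with a margin keeping the whole disc inside); a fixed (row,
    col) pins it.  ``vessel_margin_frac`` confines the vessel walk to that
    fraction of the FOV radius, emulating the fading of vessels below
    camera resolution toward the periphery.
    """

    height: int = 256
    width: int = 256
    fov_radius_frac: float = 0.47
    od_center: tuple | None = None
    od_radius: float = 18.0
    od_red: float = 230.0
    od_green: float = 180.0
    bg_red: float = 90.0
    bg_green: float = 70.0
    bg_blue: float = 25.0
    outside: tuple = (6.0, 4.0, 3.0)
    n_roots: int = 6
    branch_prob: float = 0.02
    step: float = 3.0
    init_width: float = 4.0
    width_decay: float = 0.7
    min_width: float = 1.0
    vessel_green_contrast: float = 45.0
    vessel_red_contrast: float = 10.0
    vessel_blue_contrast: float = 5.0
    vessel_margin_frac: float = 0.92
    angle_jitter: float = 0.12   # radians per step of the random walk
    od_edge_sigma: float = 2.0   # Gaussian blur of the disc edge, px
    rim_sigma: float = 1.0       # Gaussian softening of the FOV rim, px
    noise_sigma: float = 3.0
    seed: int = 0


@dataclass(frozen=True, eq=False)
class PhantomSample:
    """A rendered phantom with its exact ground-truth masks."""

    image: np.ndarray          # (H, W, 3) uint8
    vessel_truth: np.ndarray   # bool
    od_truth: np.ndarray       # bool
    fov_truth: np.ndarray      # bool
    spec: PhantomSpec


def _paint_capsule(truth, coverage, p0, p1, width, yy, xx):
    """Rasterise one vessel segment as a round-capped stroke.

    ``truth`` gets the exact set of pixels within width/2 of the segment;
    ``coverage`` accumulates (by max) a 1-px linear edge ramp used for the
    anti-aliased intensity rendering.
    """
    half = width / 2.0
    r0 = max(int(math.floor(min(p0[0], p1[0]) - half - 1)), 0)
    r1 = min(int(math.ceil(max(p0[0], p1[0]) + half + 2)), truth.shape[0])
    c0 = max(int(math.floor(min(p0[1], p1[1]) - half - 1)), 0)
    c1 = min(int(math.ceil(max(p0[1], p1[1]) + half + 2)), truth.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    y = yy[r0:r1, c0:c1]
    x = xx[r0:r1, c0:c1]
    vy, vx = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = vy * vy + vx * vx
    if seg_len2 == 0:
        d = np.hypot(y - p0[0], x - p0[1])
    else:
        t = np.clip(((y - p0[0]) * vy + (x - p0[1]) * vx) / seg_len2, 0.0, 1.0)
        d = np.hypot(y - (p0[0] + t * vy), x - (p0[1] + t * vx))
    truth[r0:r1, c0:c1] |= d <= half
    np.maximum(coverage[r0:r1, c0:c1],
               np.clip(0.5 + (half - d), 0.0, 1.0),
               out=coverage[r0:r1, c0:c1])


def _grow_tree(rng, spec, od_center, fov_center, fov_radius):
    """Random-walk vessel tree; returns a list of (p0, p1, width) segments."""
    limit = spec.vessel_margin_frac * fov_radius
    segments = []
    stack = []
    for k in range(spec.n_roots):
        ang = 2.0 * math.pi * k / max(spec.n_roots, 1) + rng.normal(0.0, 0.3)
        pos = (od_center[0] + spec.od_radius * math.sin(ang),
               od_center[1] + spec.od_radius * math.cos(ang))
        stack.append((pos, ang, spec.init_width))
    max_walks = 48
    walks = 0
    while stack and walks < max_walks:
        pos, ang, width = stack.pop()
        walks += 1
        for _ in range(200):
            ang += rng.normal(0.0, spec.angle_jitter)
            new = (pos[0] + spec.step * math.sin(ang),
                   pos[1] + spec.step * math.cos(ang))
            if math.hypot(new[0] - fov_center[0], new[1] - fov_center[1]) > limit:
                break
            segments.append((pos, new, width))
            pos = new
            if rng.random() < spec.branch_prob and len(stack) + walks < max_walks:
                child = max(width * spec.width_decay, spec.min_width)
                side = 1.0 if rng.random() < 0.5 else -1.0
                stack.append((pos, ang + side * rng.uniform(0.35, 0.9), child))
                width = child
    return segments


def generate(spec: PhantomSpec | None = None) -> PhantomSample:
    """Render one phantom; same spec (incl. seed) is bit-identical."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov_radius = spec.fov_radius_frac * min(h, w)

    if spec.od_center is None:
        rmax = fov_radius - spec.od_radius - 6.0
        if rmax <= 0:
            raise ValueError("optic disc does not fit inside the field of view")
        rad = rmax * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        od_center = (cy + rad * math.sin(theta), cx + rad * math.cos(theta))
    else:
        od_center = (float(spec.od_center[0]), float(spec.od_center[1]))
        od_dist = math.hypot(od_center[0] - cy, od_center[1] - cx)
        if od_dist + spec.od_radius > fov_radius:
            raise ValueError(
                f"optic disc at {od_center} (radius {spec.od_radius}) lies outside "
                f"the field of view (radius {fov_radius:.1f})")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    fov_truth = np.hypot(yy - cy, xx - cx) <= fov_radius
    od_truth = np.hypot(yy - od_center[0], xx - od_center[1]) <= spec.od_radius

    truth = np.zeros((h, w), dtype=bool)
    coverage = np.zeros((h, w), dtype=float)
    for p0, p1, width in _grow_tree(rng, spec, od_center, (cy, cx), fov_radius):
        _paint_capsule(truth, coverage, p0, p1, width, yy, xx)
    vessel_truth = truth & fov_truth
    coverage *= fov_truth

    fov_soft = gaussian_filter(fov_truth.astype(float), spec.rim_sigma)
    od_soft = gaussian_filter(od_truth.astype(float), spec.od_edge_sigma)

    channels = []
    for outside, bg, od_level, contrast in (
        (spec.outside[0], spec.bg_red, spec.od_red, spec.vessel_red_contrast),
        (spec.outside[1], spec.bg_green, spec.od_green, spec.vessel_green_contrast),
        (spec.outside[2], spec.bg_blue, spec.bg_blue, spec.vessel_blue_contrast),
    ):
        chan = outside + fov_soft * (bg - outside) + od_soft * (od_level - bg)
        chan -= contrast * coverage
        channels.append(chan)

    if spec.noise_sigma > 0:
        for chan in channels:
            chan += rng.normal(0.0, spec.noise_sigma, size=(h, w))

    image = np.clip(np.rint(np.stack(channels, axis=-1)), 0, 255).astype(np.uint8)
    return PhantomSample(image=image, vessel_truth=vessel_truth,
                         od_truth=od_truth, fov_truth=fov_truth, spec=spec)


def generate_suite(n: int, base_seed: int, spec: PhantomSpec | None = None) -> list[PhantomSample]:
    """Generate `n` phantoms with seeds ``base_seed .. base_seed + n - 1``.

    With the default (unpinned) ``od_center``, disc positions vary per
    sample.  Regeneration with the same arguments is bit-identical.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    base = spec or PhantomSpec()
    return [generate(replace(base, seed=base_seed + i)) for i in range(int(n))]
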