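"""Vessel detection: oriented line openings, maximum response, extraction.

Vessels are dark, thin, locally straight structures in the green channel.
After the optic disc is blanked out, the channel is inverted (openings
preserve *bright* structures) and opened with a bank of 12 line structuring
elements, 10 pixels long, at 15 degree increments from 15 to 180 degrees.
A locally straight vessel survives the opening at the orientation matching
its direction and is erased at the others, so the pixelwise maximum over
the bank enhances vessels regardless of direction.  The maximum-response
image is thresholded by iterated mean splitting, the resulting binary map
is cleaned with a disc top-hat (removing bulk regions wider than the disc
while keeping thin structures), trimmed to the eroded field of view,
stripped of components below 50 pixels, and finally the optic-disc region
is excluded.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import resolve_config
from .diffusion import DiffusionParams
from .errors import RetvesegError
from .imagery import extract_channel
from .morphology import (
    FovMasks,
    StructuringElement,
    build_fov_mask,
    dilate,
    erode,
    make_disc,
    make_line,
    opening,
    remove_small_components,
)
from .od_segment import ODResult, eliminate_od, segment_od
from .thresholding import iterative_threshold

#: The 12 template orientations, degrees counterclockwise from the +col
#: axis; 180 is horizontal, so the bank samples orientation space at 15
#: degree resolution.
ANGLES_DEG = tuple(range(15, 181, 15))


@dataclass(frozen=True, eq=False)
class OrientationBank:
    """The 12 oriented line structuring elements used for enhancement."""

    angles: tuple
    length: int
    elements: tuple


def make_orientation_bank(length: int = 10, angles=ANGLES_DEG) -> OrientationBank:
    """Build line structuring elements of `length` cells at each angle."""
    elements = tuple(make_line(length, a) for a in angles)
    return OrientationBank(angles=tuple(angles), length=length, elements=elements)


def orientation_responses(
    green_no_od: np.ndarray,
    bank: OrientationBank,
    domain: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Open the inverted green channel with each oriented line.

    The working image is ``255 - green`` (vessels become bright) restricted
    to ``domain`` (outside pixels set to 0).  The domain should exclude the
    blanked optic-disc region as well as the image surround: both are
    artefacts of elimination, not vessel candidates.  Each response is
    pixelwise <= the working image (openings are anti-extensive).
    """
    v = 255.0 - np.asarray(green_no_od, dtype=float)
    if domain is not None:
        v = np.where(np.asarray(domain, dtype=bool), v, 0.0)
    return [opening(v, se) for se in bank.elements]


def maximum_response(responses) -> np.ndarray:
    """Pixelwise maximum over the per-orientation responses."""
    responses = [np.asarray(r, dtype=float) for r in responses]
    if not responses:
        raise ValueError("no responses given")
    shape = responses[0].shape
    if any(r.shape != shape for r in responses):
        raise ValueError("orientation responses must share one shape")
    return np.maximum.reduce(responses)


@dataclass
class VesselResult:
    """Vessel extraction output with every intermediate retained."""

    threshold: float
    g_mask: np.ndarray        # thresholded maximum response (G)
    raw: np.ndarray           # after the disc top-hat of G
    trimmed: np.ndarray       # restricted to the eroded FOV
    denoised: np.ndarray      # small components removed
    vessel_mask: np.ndarray   # optic-disc region excluded
    empty: bool = False       # True when thresholding produced no pixels


def extract_vessels(
    max_response: np.ndarray,
    fov_eroded: np.ndarray,
    od_mask: np.ndarray | None = None,
    *,
    s_size: int = 15,
    min_component: int = 50,
    connectivity: int = 8,
    t0: float = 15.0,
    tol: float = 0.5,
    eq10: str = "tophat",
    threshold_domain: np.ndarray | None = None,
) -> VesselResult:
    """Extract the binary vessel map from the maximum-response image.

    The threshold is estimated over ``threshold_domain`` (default: the
    eroded FOV minus the optic disc) so the dark surround cannot drag the
    class means down.  ``eq10`` selects the cleanup of the thresholded map
    G: ``"tophat"`` computes ``G - open(G, disc(s_size))``, which removes
    regions thick enough to contain the disc while keeping thin vessels;
    ``"literal"`` applies the plain erosion ``G - (G - erode(G, disc))``
    reduces to, kept only for auditing (it erases every structure thinner
    than the disc, vessels included).
    """
    max_response = np.asarray(max_response, dtype=float)
    fov_eroded = np.asarray(fov_eroded, dtype=bool)
    if max_response.shape != fov_eroded.shape:
        raise ValueError("max_response and fov_eroded must share one shape")
    if od_mask is not None:
        od_mask = np.asarray(od_mask, dtype=bool)
        if od_mask.shape != max_response.shape:
            raise ValueError("od_mask shape does not match max_response")

    if threshold_domain is None:
        threshold_domain = fov_eroded & ~od_mask if od_mask is not None else fov_eroded
    thr = iterative_threshold(max_response, t0=t0, tol=tol, within=threshold_domain)
    g = thr.mask

    disc = make_disc(s_size)
    if eq10 == "tophat":
        raw = g & ~opening(g, disc)
    elif eq10 == "literal":
        raw = erode(g, disc)
    else:
        raise ValueError(f"unknown eq10 mode {eq10!r}; expected 'tophat' or 'literal'")

    trimmed = raw & fov_eroded
    denoised = remove_small_components(trimmed, min_component, connectivity)
    vessel_mask = denoised & ~od_mask if od_mask is not None else denoised
    return VesselResult(
        threshold=thr.threshold,
        g_mask=g,
        raw=raw,
        trimmed=trimmed,
        denoised=denoised,
        vessel_mask=vessel_mask,
        empty=not g.any(),
    )


@dataclass
class PipelineResult:
    """End-to-end segmentation output with every stage retrievable."""

    vessel: VesselResult
    od: ODResult
    fov: FovMasks
    green_no_od: np.ndarray
    max_response: np.ndarray
    responses: list = field(repr=False, default_factory=list)
    config: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.vessel.vessel_mask


def _stage(name: str):
    """Context manager re-raising stage errors with the stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (RetvesegError, ValueError)):
                exc.args = (f"[{name}] {exc}",)
            return False

    return _Ctx()


def segment(
    image: np.ndarray,
    cfg: dict | None = None,
    fov_provided: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full vessel segmentation pipeline on one RGB fundus image.

    The composition is deterministic (no randomness anywhere): channel
    extraction -> FOV masks -> optic-disc segmentation (diffusion +
    thresholding) -> disc elimination -> 12-orientation line opening ->
    maximum response -> thresholding, top-hat, trimming, small-component
    removal, disc exclusion.  ``cfg`` is a (possibly partial) config dict as
    produced by :func:`retveseg.config.load_config`.  When
    ``mask.source == "provided"`` and ``fov_provided`` is given, that mask
    replaces the computed field of view (its dilated/eroded companions are
    still derived here).
    """
    cfg = resolve_config(cfg)
    image = np.asarray(image)
    timings: dict[str, float] = {}

    def tick(name, t_start):
        timings[name] = time.perf_counter() - t_start

    t = time.perf_counter()
    with _stage("channels"):
        green = extract_channel(image, "green").astype(float)
    tick("channels", t)

    t = time.perf_counter()
    with _stage("fov_mask"):
        m = cfg["mask"]
        if m["source"] == "provided" and fov_provided is not None:
            base = np.asarray(fov_provided, dtype=bool)
            fov = FovMasks(
                fov=base,
                dilated=dilate(base, make_disc(m["dilate_radius"])),
                eroded=erode(base, make_disc(m["erode_radius"])),
            )
        else:
            fov = build_fov_mask(
                green,
                green_threshold=m["green_threshold"],
                open_radius=m["open_radius"],
                dilate_radius=m["dilate_radius"],
                erode_radius=m["erode_radius"],
                fill=m["fill_holes"],
                t0=cfg["threshold"]["t0"],
                tol=cfg["threshold"]["tol"],
            )
    tick("fov_mask", t)

    t = time.perf_counter()
    with _stage("od_segment"):
        od = segment_od(
            image,
            fov.fov,
            DiffusionParams(**cfg["diffusion"]),
            channel=cfg["od"]["channel"],
            tol=cfg["threshold"]["tol"],
            dilate_radius=cfg["mask"]["dilate_radius"],
        )
    tick("od_segment", t)

    t = time.perf_counter()
    with _stage("od_eliminate"):
        if cfg["vessel"]["source"] == "od_eliminated":
            green_no_od = eliminate_od(green, od, fill=cfg["od"]["fill"], fov=fov.fov)
        else:
            green_no_od = green.copy()
    tick("od_eliminate", t)

    t = time.perf_counter()
    with _stage("orientation_bank"):
        bank = make_orientation_bank(cfg["vessel"]["line_length"])
        domain = fov.fov & ~od.od_mask
        responses = orientation_responses(green_no_od, bank, domain=domain)
        mr = maximum_response(responses)
    tick("orientation_bank", t)

    t = time.perf_counter()
    with _stage("extract_vessels"):
        pp = cfg["postprocess"]
        # Threshold histogram: keep clear of the blanked disc by the line
        # half-length, where openings are dragged down by the zero fill.
        if od.od_mask.any():
            pad = dilate(od.od_mask, make_disc(cfg["vessel"]["line_length"] // 2 + 1))
            thr_domain = fov.eroded & ~pad
        else:
            thr_domain = fov.eroded
        vessel = extract_vessels(
            mr,
            fov.eroded,
            od.od_mask,
            threshold_domain=thr_domain,
            s_size=pp["s_size"],
            min_component=pp["min_component"],
            connectivity=pp["connectivity"],
            t0=cfg["threshold"]["t0"],
            tol=cfg["threshold"]["tol"],
            eq10=pp["eq10"],
        )
    tick("extract_vessels", t)

    return PipelineResult(
        vessel=vessel,
        od=od,
        fov=fov,
        green_no_od=green_no_od,
        max_response=mr,
        responses=responses,
        config=cfg,
        timings=timings,
    )
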