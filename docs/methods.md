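# Methods

This note records the model underlying `retveseg`, the parameter choices
that matter, the numerical conventions, and what the synthetic phantom
does and does not establish.

## Anisotropic diffusion (optic-disc stage)

The red channel is smoothed with the explicit eight-neighbour
Perona–Malik scheme

    I_{t+1}(p) = I_t(p) + ψ · Σ_dir C(∇_dir I(p)) · ∇_dir I(p),

where `∇_dir I(p) = I(neighbour) − I(p)` for the eight compass neighbours
and the diffusivity is the rational form `C(g) = 1 / (1 + (g/k_a)²)` —
no exponential variant is offered. Diagonal neighbours carry the same
unit weight as axial ones (the eight difference templates are uniform).
Borders are edge-replicated, so gradients across the frame vanish; a
consequence worth knowing is that the scheme conserves the global
intensity sum exactly (opposite-direction fluxes cancel pairwise), which
the tests assert to 1e-9.

Defaults: **ψ = 1/8** (with eight neighbours and C ≤ 1 this makes every
update a convex-bounded perturbation, hence the discrete maximum
principle holds and the explicit scheme is stable), **k_a = 30 grey
levels** (on 8-bit data this passes vessel-scale contrast (~20–50) as
"edge-ish" while flattening noise; the disc edge, at 100+ grey levels, is
fully preserved), **15 iterations** (enough to flatten vessel texture
inside the disc at these settings). All three are config keys
(`diffusion.psi`, `diffusion.kappa`, `diffusion.iterations`). Arithmetic
is double precision throughout; quantisation to 8 bits happens only at
image export.

## Iterative mean-split thresholding

Both binarisation stages use the isodata-style iteration: split at T,
compute the two class means, move T to their midpoint, stop when the
step falls below `threshold.tol` (default 0.5 grey levels) or after 100
iterations (a safety cap; the sequence is monotone-bracketed and
terminates far earlier on 8-bit data). The split is strict: group 1 is
`> T`, group 2 is `≤ T`. If a group empties, its mean is defined as the
current T, which freezes the iteration — this makes near-constant inputs
well-behaved, and exactly constant inputs return the constant with an
all-false mask and a `degenerate` flag.

Two choices here were genuinely open:

- **Threshold domain.** The iteration is estimated over the field of view
  only (and, in the vessel stage, additionally away from the eliminated
  disc — see below). Estimated over the full frame, the dark camera
  surround (roughly half the pixels) becomes one of the two dominant
  modes and the iteration converges to a surround/retina split instead of
  the intended retina-internal split. The returned mask is always
  full-frame `image > T`.
- **Initialisation.** The mean-split iteration has one stable fixed point
  per pair of adjacent intensity modes, and the start value selects the
  basin. For the *vessel* stage the default start is 15 grey levels
  (range-clamped); from there the iteration climbs through the background
  mode and settles on the background/vessel split, which the phantom
  tests confirm. For the *optic-disc* stage a low start settles between
  the vessels and the background — the wrong basin, since the disc is only
  ~2% of the FOV — so `segment_od` starts at the midpoint of the
  FOV-restricted dynamic range of the diffused channel, which reliably
  selects the bright-disc basin. This mid-range start is the package's
  choice; classical descriptions of the method treat the start as
  arbitrary, which holds only for cleanly bimodal data.

## Morphology conventions

- Discs contain exactly the lattice offsets with Euclidean distance ≤ r;
  radius 1 is the 5-cell plus shape, radius 2 has 13 cells.
- Lines have exactly L cells, rasterised one cell per major-axis step
  through the origin, angle counterclockwise from the +col axis. Even
  lengths (the default bank uses L = 10) are necessarily half-a-cell
  asymmetric; openings are translation-invariant in the structuring
  element, so this has no effect on results.
- Erosion treats out-of-image cells as foreground and dilation as
  background, so the FOV is not eroded from the frame inward and nothing
  is dilated in from outside. Greyscale erosion/dilation are min/max with
  ±inf padding accordingly.
- Connected-component removal is strict ("fewer than 50 pixels"):
  components of exactly 50 pixels survive. Connectivity defaults to 8,
  because vessels are thin, frequently diagonal structures that
  4-connectivity fragments into sub-50-pixel pieces.

## FOV mask

`fov = fill_holes(clear_border(open(green > 10, disc(1))))`. The
published recipe phrases this via a double inversion (zero the bright
pixels, invert, open, border-clear, invert); for binary masks the direct
form is equivalent and is what is implemented and tested. Hole filling is
an addition (config-disableable, `mask.fill_holes`): dark vessel shadows
otherwise punch holes into the mask. The fixed threshold 10 is the
default; `mask.green_threshold = "auto"` runs the mean-split iteration
instead. When a dataset ships FOV masks, `mask.source = "provided"` uses
them; the dilated/eroded companions are always derived internally.

## Optic-disc stage details

After thresholding the diffused red channel, candidates are intersected
with the dilated FOV (removing bright rim artefacts hugging the FOV
boundary) and the largest 8-connected component is taken as the disc.
The largest-component rule is an addition: the thresholded image may
retain small bright interior regions, and the disc is the dominant bright
blob by construction. Disc elimination fills with zero by default
(`od.fill = "mean"` is available; zero fill creates an artificial edge,
which the pipeline neutralises by masking the disc region out of the
vessel-stage working image and the final map).

## Vessel stage details

The working image is `255 − green_no_od`, restricted to the FOV *minus
the disc region*: the blanked disc is an elimination artefact, not vessel
evidence, so it is set to 0 in the working image rather than left at the
inverted-zero value 255. For the same reason the vessel-stage threshold
histogram excludes a disc neighbourhood widened by the line half-length
(5+1 px): within that band, openings are dragged down by the zeroed disc,
and those artefact values would anchor the lower class mean and collapse
the threshold below the background mode.

The binary cleanup of the thresholded map G is the top-hat
`G − open(G, disc(15))`, which removes any region that can contain a
radius-15 disc and keeps everything thinner — vessels included. The
printed form of this step, `G − (G − G⊖s)`, algebraically reduces to
plain erosion by the disc, which would erase every vessel (all are far
thinner than 15 px); that literal reduction is kept available as
`postprocess.eq10 = "literal"` for auditing, and the tests document that
it empties vessel-like structures while a radius-25 bulk region erodes
to a non-empty core.

## Evaluation

Vessel = positive class. Counts are FOV-restricted by default
(`evaluation.fov_only`); counting the trivially-correct surround inflates
specificity and accuracy, and the choice materially shifts both. Zero
denominators flag the metric as undefined (NaN) instead of raising.
Dataset averages are unweighted per-image (macro) means, matching the
usual per-image benchmark tables.

## The phantom

The generator emulates exactly the structure the pipeline assumes:
256×256, FOV radius 0.47 × 256 ≈ 120 px, a radius-18 disc (red 230 /
green 180 over background red 90 / green 70) with a σ = 2 px blurred
edge, and a vessel tree of 6 random-walk roots leaving the disc rim
outward (step 3 px, direction jitter σ = 0.12 rad per step, branch
probability 0.02 per step, initial width 4 px decaying ×0.7 per branch
down to 1 px, green contrast −45 grey levels, weaker in red/blue), plus
additive Gaussian noise σ = 3. Ground-truth masks are rendered exactly
(no anti-aliasing); the intensity image gets a 1-px linear coverage ramp
at vessel edges. One random stream per sample, consumed in a fixed order
(disc placement when unpinned, then tree, then noise), so changing the
noise level never reshuffles the geometry. Walks are confined to 92% of
the FOV radius: peripheral capillaries fall below camera resolution in
real fundus images, and the outermost ~10 px band is in any case outside
the method's output domain (the vessel map is trimmed to the
radius-10-eroded FOV).

With the default spec the tree covers 3–8% of the FOV (measured over
seeds 1–20 and frozen into the tests). What passing the phantom suite
shows: the stages compose correctly, the disc is localised to sub-pixel
median error, and vessels of width 1–4 px with 45-grey-level contrast are
recovered at Se ≈ 0.95 / Sp ≈ 0.99 inside the FOV. What it does not
show: robustness to lesions, illumination gradients, JPEG artefacts,
central reflexes, or low-contrast capillaries — i.e. clinical-grade
performance. Benchmarks on real data require the public datasets and the
`retveseg dataset` harness.

## Degenerate inputs and error behaviour

All-dark images raise an empty-FOV error (exit code 4 at the CLI); a flat
red channel yields an empty disc result (area 0), not an error; an empty
thresholded vessel map yields an empty result with a flag. Pipeline
errors name their stage. The pipeline contains no randomness: repeated
runs are bit-identical.

## Problem sizes used in the test suite

Oracle-equivalence tests run on ≤16×16 rasters (100 instances per
primitive) against double-loop references; threshold convergence is
checked on 1000 random 8-bit histograms; the end-to-end suite uses 50
phantoms at 256×256. These sizes make every oracle comparison exhaustive
yet keep the whole suite in the tens of seconds.
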