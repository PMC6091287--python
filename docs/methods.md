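# Methods

## Problem and model

The task is 2-D affine registration of a floating ultrasound-like image
`I_F` onto a fixed CT-like reference `I_R` of the same cardiac scene. The
obstacle is the modality gap: the same tissue class maps to unrelated gray
levels in the two images (chambers filled with contrast agent are bright on
CT, anechoic on echo), so intensity-similarity objectives computed on the
raw images can be weak or misleading.

The method composes two transforms conceptually but estimates one: a coarse
affine `T_basic` solved in closed form from three valve landmark pairs, and
a fine affine `T_final` obtained by maximizing normalized mutual
information (NMI) between *probability maps* of the two images, with the
optimizer initialized at `T_basic`. The warm start is initialization only —
`T_final` is a complete transform, not a correction composed onto
`T_basic`; the final result is `S_final = T_final · I_F`.

All transforms map moving-image `(x, y)` coordinates (x = column, y = row,
0-based, pixel centers on the integer grid) to fixed-image coordinates;
images are resampled by pulling through the inverse, which cannot leave
holes. Pixels whose pull-back source falls outside the moving footprint are
zero-filled and excluded from every similarity computation through an
explicit validity mask: fill values would otherwise fabricate correlation.

## Coarse stage

Three non-collinear point pairs determine a planar affine uniquely, so the
solve is two 3×3 linear systems (one per output coordinate). Triplets with
doubled triangle area ≤ 1e-6 px² are rejected as collinear; the solved
transform must map the landmarks with ≤ 1e-6 px residual or a geometry
error is raised. A least-squares extension to more than three pairs would
be straightforward but is deliberately not the default: three valve points
are the method's interface.

Conditioning matters more than count: the landmark triangle's area controls
how operator click error amplifies into the affine. The phantom places its
three anchors on two different valves (two endpoints of one, midpoint of
the other) for a well-spread triangle, mirroring how an operator would pick
distinct valve structures rather than three points along one thin leaflet.

## Probability maps

For each modality, with image `I`, foreground mask `G` and enhancement
level `L` (defaults `N = 80` reference, `M = 100` floating — empirical
values tied to typical ROI mean intensities):

1. `V = L · 1[G]`, `I_h = I + V` (enhancement; pixelwise, never clipped at
   255 — clipping would merge enhanced foreground bins back into bright
   background bins and destroy the separation the next step depends on; the
   working intensity domain is therefore [0, 255 + L]).
2. `f(i) =` fraction of pixels of (rounded) integer intensity `i` that lie
   in `G`; probabilities are stored as fractions in [0, 1].
3. `P(x) = f(I_h(x))`; intensities never observed at fit time map to 0.

The numerator of `f` counts ROI pixels of intensity `i` — equivalently the
foreground-restricted enhanced segmentation — so `f(i)` is exactly the
conditional probability of ROI membership given the observed intensity.
If enhancement makes foreground and background bins disjoint, the map
reduces to the mask indicator (an assertable special case); with
overlapping bins it gives graded membership. Enhancement is applied to the
segmented foreground mask, not any rectangular selection box around it:
only the former changes foreground/background contrast. Pixel positions are
never mixed, so the maps inherit the images' spatial structure exactly.

The moving map is built once in native moving space and warped during
optimization rather than being rebuilt per trial transform: density
estimation is intensity-based and would otherwise absorb resampling noise.

## Fine stage

NMI is Studholme's normalization `(H(A) + H(B)) / H(A, B)`, computed from a
`bins × bins` joint histogram (default 64) over the valid-overlap pixels,
each marginal spanning that input's observed range. The value is 2 for
identical non-constant inputs and tends to 1 for independent ones; constant
input over the overlap is a degenerate-input error, and invalid trial
transforms (near-singular, tiny or degenerate overlap) score the floor 1.0.

Optimization is Powell's direction-set method (no gradients, Brent line
searches) over a parameter vector decomposed about the fixed-image center:
translation in px, rotation, scales and shear. Rotation is expressed in
radians × 100 and scales/shear × 100 so that one line-search step is
commensurate across parameters. Two models are provided: `affine6`
(default, matching the coarse stage) and `rigid_scale4`. Termination is by
parameter change (`powell_xtol`, default 1e-4) or iteration cap (default
100). The returned transform is never worse than its start: if the final
polish dips below the warm-start NMI (line-search round-off can do this by
~1e-10), the warm start is returned. Trial warps use bilinear interpolation
for speed; only the final resample is cubic.

## Numerical choices

- Resampling uses scipy's prefiltered cubic B-spline (order 3), which
  interpolates exactly at pixel centers; negative ringing is clamped to 0.
  Interpolation coordinates are edge-clamped and the zero fill is applied
  from the validity mask afterwards, so sub-ulp round-off in a solved
  transform cannot blank boundary pixels.
- Validity bounds carry a 1e-6 px tolerance for the same reason.
- Density binning rounds to nearest integer — a no-op for 8-bit ingest plus
  integer enhancement levels.
- Mask warping for Dice is nearest-neighbor (threshold 0.5).
- Between 32 and 128 NMI bins the recovered transform moves by ~0.6 px at
  the image corners on the clean phantom (the binning of bilinearly
  interpolated map values shifts the flat optimum slightly); the suite
  asserts sub-pixel (< 1 px) agreement.

## Evaluation

- Dice `2|A∩B|/(|A|+|B|)` between the moving-side ROI warped into fixed
  space by the estimated and by the reference transform (error if both
  empty).
- TRE: every ROI pixel is mapped by both transforms; displacements are
  converted to mm per axis with the fixed-image pixel spacing (CT default
  0.32 mm, TEE 0.224 mm, phantom 1.0 mm) before the RMS. A clinical bronze
  standard can be supplied as the reference; for phantoms the generating
  transform is the reference.

## Synthetic phantom

The generator emulates the features that make CT/TEE registration hard and
is a pure function of `(seed, params)`:

- A "heart" of three overlapping elliptical chambers plus two thin bright
  valves, laid out analytically so the moving image is rendered by
  evaluating the same geometry at forward-mapped coordinates — the ground
  truth contains no interpolation error.
- Modality gap: chambers are bright on the pseudo-CT (150/110/180) and
  near-background dark on the pseudo-TEE (30/38/26 vs background 25), as
  anechoic blood pools are; valves stay bright in both. This per-structure
  level table is the generator's intensity remap and deliberately makes raw
  intensity a poor registration signal while leaving the probability maps
  intact; `remap="identity"` disables it for monomodal controls.
- Noise: additive Gaussian (sd 3) on the pseudo-CT; multiplicative
  unit-mean Rayleigh speckle (strength 0.3) on the pseudo-TEE — the
  standard first-order ultrasound texture model.
- A fan/sector footprint clips the pseudo-TEE, and the moving canvas
  (240×320 vs 320×320 fixed) exercises unequal image sizes.
- Deformations: rotation ±10°, translation ±20 px, per-axis scale 0.9–1.1,
  shear ±0.05 — a large-displacement but still affine setting; landmark
  click error is i.i.d. Gaussian with sd 2 px.

Problem sizes are chosen so a full 10-seed two-mode benchmark runs in
minutes on one CPU; the 320×320 canvas is a desk-scale stand-in for
clinical 1024×1024 / 600×800 rasters.

What passing phantom tests do **not** show: robustness to non-affine
cardiac deformation, to segmentation errors (phantom masks are exact by
construction — real grab-cut masks are not), to genuinely 3-D anatomy
projected into mismatched slice planes, or to clinical speckle statistics
beyond the first-order model.

## Observed behavior worth knowing

- With masks of this quality the probability maps are near-binary, so the
  fine stage effectively aligns segmentations; its accuracy is nearly
  independent of speckle strength. The raw-intensity ablation (VMI) is
  *not* monotonically degraded by speckle either — warm-started NMI is
  empirically robust to unit-mean multiplicative noise — its deficit is
  driven by gray-level confusability between chambers and background.
- Both failure modes of the whole pipeline trace to the warm start: a badly
  conditioned or badly perturbed landmark triplet can put Powell in the
  wrong basin, and nothing downstream recovers from that.

## Known limitations

- 2-D affine only; no deformable model, no multi-resolution pyramid.
- Segmentation is consumed, not produced: any segmenter can be plugged in
  upstream, but mask quality bounds probability-map quality.
- The density table conditions on intensity alone; images whose foreground
  and background share identical intensity distributions yield a flat map
  (the mixing fraction everywhere) and no fine-stage signal.
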