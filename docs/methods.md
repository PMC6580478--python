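# Methods

## Problem and evaluation protocol

The package evaluates closed-set ear identification: every probe image
has exactly one mate in the gallery (the same subject photographed at a
different visit). For one capture condition, visit-1 images form the
gallery and visit-2 images are probes, then the roles are swapped; the
reported top-1 and top-10 rates are 100 × the mean of the two
directional hit proportions, printed to one decimal place. Top-10 is
clamped to min(10, gallery size) so small cohorts remain meaningful.
Per-direction integer counts are always retained alongside the averaged
percentage, since an averaged rate alone does not determine them.
Verification metrics (false accept/reject at a score threshold) are out
of scope; the protocol is identification only.

## Synthetic cohort generator

No image data accompanies the study design this package addresses, so
the cohort is synthetic: N subjects × 2 visits × 2 capture conditions,
4 images per subject. The generator's purpose is not photorealism but a
faithful *noise model of capture*: images whose high-contrast structure
is subject-specific, degraded by exactly the nuisances that differ
between a standardized and an unstandardized capture.

**Ear rendering.** Each subject's ear is procedural: an outer-helix
ellipse ridge (semi-axes ~112–148 × 72–100 px in a 480×360 frame), an
antihelix arc displaced inward, a concha bowl with a bright rim, a
tragus bump and a lobe blob, plus a subject-specific smooth texture
field (Gaussian-filtered noise keyed by a per-subject seed, coarse
σ=3 at amplitude 0.10 and fine σ=1 at 0.04, confined to the ear). A
smooth pseudo-relief (ridges high, concha low) supports the
out-of-plane model below. Shape parameters are drawn per subject from
ranges wide enough that inter-subject differences dominate capture
noise under standardized conditions — the premise the study tests.

**Capture conditions.** A `CaptureModel` holds uniform ranges for each
nuisance; one value per nuisance is drawn per (subject, visit,
condition) from a dedicated seeded stream, so the whole cohort is a
pure function of (n_subjects, models, cohort_seed) and regenerates
byte-identically.

| nuisance | standardized ("donut") | freehand | units |
|---|---|---|---|
| in-plane rotation | 0 | ±15 | degrees |
| translation | 0 | ±15% | fraction of frame per axis |
| scale | 1 | 0.75–1.30 | multiplier |
| out-of-plane tilt | 0 | 0–40 | degrees |
| illumination gradient | 0 | 0–0.40 | fraction of dynamic range |
| gamma | 0.97–1.03 | 0.70–1.40 | exponent |
| hair occlusion | 0 | 0–25% | fraction of ear area |
| aperture ring | yes | no | — |
| sensor noise sd | 0.01 | 0.01 | intensity |

Nuisances apply in order: tilt (depth parallax from the relief, 14 px
maximum displacement, plus cos-tilt foreshortening along a random
azimuth), then the similarity transform (scale, rotation, translation),
background clutter, the illumination ramp with relief shading tied to
its drawn strength, gamma, occlusion strokes, the aperture ring, and
additive sensor noise. Rationale for the three model components beyond
the obvious ones:

- *Out-of-plane tilt.* A local-feature matcher is invariant by design
  to similarity transforms and monotone tone maps, so those nuisances
  alone barely reduce accuracy. What collapses field performance is
  viewpoint: a tilted 3-D ear suffers anisotropic foreshortening and
  depth parallax that no similarity-invariant descriptor compensates.
  The device physically fixes the camera axis, so tilt is zero in the
  standardized condition.
- *Background clutter.* Field captures image the ear against head,
  hair and scene, which change between visits; the device encloses the
  ear, so clutter is rendered only for captures without the ring.
- *Strand-textured hair.* Occlusion strokes carry elongated noise:
  hair both hides ear structure and adds capture-specific
  high-contrast detail.

The standardized pair of a subject differs only by sensor noise and the
small per-visit gamma offset (mean absolute pixel difference below
5 × noise sd); the freehand pair redraws every nuisance. With these
defaults a 50-subject study yields ~100% standardized vs ~40–50%
freehand top-1 — the qualitative contrast of the field data, though not
its exact rates, which depended on real ears and real scenes. Passing
tests on this cohort therefore show that the *pipeline* behaves as the
study describes under this noise model; they do not certify accuracy on
real photographs.

**Aperture ring.** The device leaves a dark annulus (interior radius
165 px, edge ramp 1.5 px, intensity 0.04) centered in the frame. The
auto-crop detector thresholds pixels below 0.25 × frame mean, takes the
largest connected dark component, requires it to enclose a hole
(annular topology), keeps the largest hole (noise speckles inside the
ring also register as holes), and crops its bounding box — within ±2 px
of the generator's ground truth on seeded cohorts. On an
already-cropped image the residual dark corner arcs no longer enclose
the center; that signature makes the operation idempotent rather than
an error.

## Preprocessing

Grayscale conversion uses ITU-R BT.601 weights (0.299, 0.587, 0.114) by
default; single-channel input passes through. Fixed crops are
length × width windows centered on the frame (the fallback for
unstandardized captures, default 340 × 260 px ≈ nominal ear + margin);
no resampling. Resizing preserves aspect ratio, bilinear, anti-aliased
on downscale, long side 256 px by default — small enough to keep
extraction well under a second per image, large enough to retain the
texture the descriptors need.

## Feature extraction

Native implementation of the canonical scale-invariant feature
transform: 4 octaves × 3 scales, base σ 1.6 over an assumed input blur
of 0.5, no initial upsampling (octave 0 is input resolution).
Difference-of-Gaussian extrema over 3×3×3 neighborhoods are refined by
an iterated quadratic fit (up to 3 moves, offsets beyond 1.5 rejected);
contrast threshold 0.03 on [0,1] intensities applied per layer as
0.03/3; edge responses rejected when tr²/det of the spatial Hessian
exceeds (r+1)²/r with r = 10. Orientations come from a twice-smoothed
36-bin gradient histogram weighted by a 1.5σ Gaussian; secondary peaks
≥ 80% of the maximum duplicate the keypoint. Descriptors are 4×4
spatial × 8 orientation bins of Gaussian-weighted gradients sampled in
the keypoint's scale- and orientation-aligned frame, trilinearly
distributed, clamped at 0.2, renormalized to unit norm. Keypoints whose
sampling window leaves the octave image are dropped and counted in the
log. Extraction is deterministic.

A "reference" backend dispatches to scikit-image's extractor with
matched parameters. It serves as an independent audit (≥ 60% of native
keypoints must coincide within 2 px on fixtures; observed ~97%), never
as the pipeline default, so the implementation and its check stay on
separate code paths.

## Matching and ranking

Pair score = number of accepted one-to-one correspondences under the
ratio test (threshold 0.75). The test is directional; both
gallery/probe directions are evaluated explicitly. When an image is
scored against itself, the second-nearest distance excludes the
identical-index descriptor so the self-match ceiling (score = descriptor
count) is well defined. Ranking is by descending count with ties broken
on ascending (subject, visit), making the result independent of gallery
input order. No geometric verification is applied — the scored count is
the raw correspondence count. Degenerate cases: empty feature sets score
0; a single-descriptor gallery has no second neighbor and its lone
candidate is accepted.

## Crop sensitivity

Top-1 accuracy is recomputed over a strictly increasing grid of crop
values for one dimension, the other held fixed; sensitivity is the
finite-difference slope in percentage points per pixel, with |slope| > 1
flagged as sensitive (the threshold is configurable; percentage points
per pixel is the literal reading of an accuracy-vs-pixels curve). The
shipped study design sweeps both dimensions over the same 180–360 px
range on a 24-subject freehand cohort: because the rendered ear is
taller (~224–296 px) than wide (~144–200 px), equal crop values cut
anatomy along the length much sooner than along the width, so length
slopes exceed width slopes — the asymmetry the protocol is designed to
expose. At materially smaller cohorts (≈16 subjects) the per-point
rates are quantized coarsely enough that the ordering can flip by
counting noise; 24 subjects × 4 points is the smallest design we found
stable. Standardized-condition sweeps are flat at 100% over this range
(near-identical visit pairs match from any window) and carry no slope
signal.

## Study statistics

- `chi2_uncorrected`: Pearson chi-squared on a 2×2 table via the closed
  form N(ad−bc)²/(r₁r₂c₁c₂), 1 df, upper-tail p; zero margins raise.
  Arm counts for published percentages are reconstructed by rounding
  rate × N (e.g. 95.9% of 194 → 186/8, 24.1% → 47/147).
- `two_proportion_sample_size`: pooled-under-H0 / unpooled-under-H1
  normal approximation, z-quantiles from the inverse normal CDF,
  rounded up. For (0.80, 0.90, α = 0.05, power = 0.80) it returns 199,
  read as a per-group size.
- `pugh_score`: totals = Σ weight × mark per concept; linear in marks
  and order-invariant. The shipped lighting chart (criteria Shadow
  weight 2, Power/Shape/Buy-Make/Price weight 1) scores the three
  candidate designs 0 / 0 / +3 against the diffused-plate baseline.

## Numerical and design choices

- Coordinates are row/col, 0-based, origin top-left, everywhere.
- All randomness flows from a single cohort seed through named
  per-image streams; extraction and matching have none.
- Reports and score matrices are CSV with the run-config hash embedded;
  rerunning an identical config reproduces every artifact
  byte-for-byte (timestamps live only in the run log).
- Features are re-extracted per sweep point rather than cached: a crop
  change invalidates them anyway, and at these problem sizes
  re-extraction is cheaper than cache bookkeeping. `FeatureSet` still
  serializes to a columnar text format for callers who want caching.
- Problem sizes shipped in tests and the acceptance script — 50
  subjects for the headline study, 24 for the sweep — were chosen as
  the smallest cohorts whose binomial counting noise does not obscure
  the effects being demonstrated.

## Known limitations

- The renderer is a noise model, not an ear: absolute identification
  rates on real photographs cannot be inferred from it.
- The freehand nuisance magnitudes are stand-ins; no quantitative field
  measurements of lighting/angle spread inform them.
- Descriptor parameters replicate the canonical published algorithm;
  equivalence with any particular historical implementation is claimed
  only in kind, via the reference-backend audit.
- The sensitivity-slope ordering is a statistical effect; on very small
  cohorts or unlucky seeds it can flip by counting noise.
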