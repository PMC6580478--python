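# earident

Ear-biometric identification with standardized vs. field image capture.

In settings without reliable identifiers, the outer ear is an attractive
biometric: it is easy to photograph, stable, and as distinctive as a
fingerprint. But identification pipelines built on local image features
degrade badly when capture conditions — distance, angle, rotation,
lighting, centering, hair — vary between visits. This package implements
a closed-set ear identification pipeline and a synthetic paired-capture
cohort generator that contrasts two conditions: **standardized** capture
through an internally lit aperture device that fixes the nuisances, and
**freehand** field capture that randomizes them. It is written for
researchers studying how capture standardization affects biometric
matching, with no external image data required.

## The method

Each ear image is converted to single-precision grayscale, cropped
(automatically, from the dark aperture annulus the device leaves in the
frame, or by a fixed window otherwise), and resized. Scale-invariant
local features are extracted natively: a Gaussian scale-space pyramid,
difference-of-Gaussian extrema detected over 3×3×3 neighborhoods, refined
to sub-pixel position, filtered by contrast and principal-curvature
ratio, assigned orientations from a 36-bin gradient histogram, and
described by 4×4×8 Gaussian-weighted gradient-orientation histograms
(128-d, clamped at 0.2, unit-normalized).

A probe image is scored against each gallery image by the number of
accepted descriptor correspondences: nearest-neighbor in descriptor
space, accepted when d₁/d₂ < 0.75 (Lowe ratio test), made one-to-one
greedily by ascending distance. With visit-1 images as the gallery and
visit-2 images as probes, a probe is *top-1 correct* when the rank-1
gallery subject is the probe's subject and *top-10 correct* when the
subject appears within the first min(10, gallery) ranks; the roles are
then swapped and the two directional proportions averaged:

    top-k rate = 100 × ½ (k-hit proportion with gallery=visit1
                          + k-hit proportion with gallery=visit2)

Crop sensitivity is the finite-difference slope of top-1 accuracy in
percentage points per pixel of crop length or width. The study
statistics are the uncorrected Pearson chi-squared on the 2×2
success/failure table of the two capture arms, the classical
two-proportion sample-size formula

    n = (z₁₋α/2 √(2 p̄(1−p̄)) + z₁₋β √(p₁(1−p₁)+p₂(1−p₂)))² / (p₁−p₂)²,

and weighted Pugh-chart scoring of design concepts.

## Worked example

```python
from earident import generate_cohort, identification_report

manifest = generate_cohort(n_subjects=15, cohort_seed=3, out_dir="cohort")
for condition in ("donut", "freehand"):
    report, _ = identification_report(manifest, condition, crop="auto")
    print(condition, report.top1_rate, report.top10_rate)
```

prints

```
donut 100.0 100.0
freehand 73.3 100.0
```

Under standardized capture every one of the 15 subjects is identified at
rank 1 in both directions (top-1 = top-10 = 100%); freehand capture
drops to 73.3% top-1 on this small gallery and degrades further as the
gallery grows (41% at 50 subjects). At the matching level the margin is
stark — for one typical standardized pair, the same ear across visits
yields 218 accepted correspondences against 1 for an impostor pair
(`examples/02_features_and_matching.py`).

The `examples/` directory holds one short script per capability:
cohort generation, feature matching, identification rates, the crop
sensitivity sweep, and the study statistics. A thin CLI mirrors them
(`earident generate|identify|sensitivity|stats|report`).

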