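"""Extract scale-invariant features from two captures and score the pair.

Shows the core of the identification engine: keypoint + 128-d descriptor
extraction, and the ratio-test match count that scores how likely two
images show the same ear.
"""

from earident import extract, match_descriptors, resize, auto_crop_aperture
from earident.cohort import (
    default_donut_model,
    render_capture,
    sample_ear_shape,
)

shape_a = sample_ear_shape(1, cohort_seed=7)
shape_b = sample_ear_shape(2, cohort_seed=7)
model = default_donut_model()

# two visits of subject 1 and one visit of subject 2
img_a1 = resize(auto_crop_aperture(render_capture(shape_a, model, 1, 7)), 256)
img_a2 = resize(auto_crop_aperture(render_capture(shape_a, model, 2, 7)), 256)
img_b1 = resize(auto_crop_aperture(render_capture(shape_b, model, 1, 7)), 256)

fs_a1, fs_a2, fs_b1 = (extract(im) for im in (img_a1, img_a2, img_b1))
print(f"keypoints: a1={len(fs_a1)} a2={len(fs_a2)} b1={len(fs_b1)}")

same = match_descriptors(fs_a2, fs_a1, ratio_threshold=0.75)
diff = match_descriptors(fs_a2, fs_b1, ratio_threshold=0.75)
print(f"same subject across visits: {same.n_matches} accepted matches")
print(f"different subjects:         {diff.n_matches} accepted matches")
# The same-subject count should dwarf the impostor count: that margin is
# what makes rank-1 identification work.
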