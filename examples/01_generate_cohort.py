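"""Generate a small synthetic paired-capture ear cohort.

Each subject contributes four PNG images: two "visits" captured through
the standardizing aperture device ("donut") and two captured freehand,
with rotation, framing, distance, out-of-plane angle, lighting and hair
occlusion all varying between captures.
"""

from pathlib import Path

from earident import generate_cohort

out = Path("example_cohort")
manifest = generate_cohort(n_subjects=4, cohort_seed=42, out_dir=out)

print(f"wrote {len(manifest.records)} images under {out}/")
for sid, visit, condition, fname in manifest.records:
    print(f"  subject {sid} visit {visit} [{condition:8s}] {fname}")
# 4 records per subject: the two capture conditions of the two visits.
# Re-running with the same seed rewrites byte-identical files.
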