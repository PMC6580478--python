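"""Synthetic cohort generator: determinism, subject separability, and the
contrast between standardized and unstandardized capture."""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pytest

import earident.cohort as cohort_mod
from earident.cohort import (
    CaptureModel,
    CohortManifest,
    InvalidCaptureModelError,
    default_donut_model,
    default_freehand_model,
    generate_cohort,
    render_capture,
    sample_ear_shape,
)


class TestEarShape:
    def test_deterministic_under_fixed_seed(self):
        assert sample_ear_shape(1, 42) == sample_ear_shape(1, 42)

    def test_distinct_subjects_differ(self):
        s1, s2 = sample_ear_shape(1, 42), sample_ear_shape(2, 42)
        assert s1 != s2

    def test_fifty_subjects_pairwise_distinct(self):
        shapes = [sample_ear_shape(i, 7) for i in range(1, 51)]
        vectors = [
            (*s.helix_axes, s.antihelix_offset, *s.concha_center,
             s.concha_radius, s.lobe_extent, s.tragus_size)
            for s in shapes
        ]
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                assert vectors[i] != vectors[j]

    def test_invalid_subject_rejected(self):
        with pytest.raises(ValueError):
            sample_ear_shape(0, 42)

    def test_shape_invariants(self):
        for sid in range(1, 21):
            s = sample_ear_shape(sid, 3)
            assert s.antihelix_offset < min(s.helix_axes)
            assert all(v > 0 for v in (*s.helix_axes, s.concha_radius,
                                       s.lobe_extent, s.tragus_size))


class TestRenderCapture:
    def test_reproducible(self, donut_pair):
        shape = sample_ear_shape(3, 77)
        again = render_capture(shape, default_donut_model(), 1, 77)
        np.testing.assert_array_equal(donut_pair[0].pixels, again.pixels)

    def test_donut_visits_differ_only_by_noise_and_offset(self, donut_pair):
        v1, v2 = donut_pair
        model = default_donut_model()
        mad = np.abs(v1.pixels - v2.pixels).mean()
        # sensor noise (two independent draws) plus the small per-visit
        # gamma offset bound the expected difference
        assert mad < 5 * model.sensor_noise_sd
        p1, p2 = v1.meta["capture_params"], v2.meta["capture_params"]
        for key in ("scale", "rotation_deg", "translation", "tilt_deg",
                    "occlusion_fraction"):
            assert p1[key] == p2[key]

    def test_freehand_nuisances_redrawn_per_visit(self, freehand_pair):
        p1 = freehand_pair[0].meta["capture_params"]
        p2 = freehand_pair[1].meta["capture_params"]
        assert p1["scale"] != p2["scale"]
        assert p1["rotation_deg"] != p2["rotation_deg"]
        assert p1["translation"] != p2["translation"]

    def test_standardized_pairs_more_similar_for_every_subject(self):
        donut, freehand = default_donut_model(), default_freehand_model()
        for sid in range(1, 13):
            shape = sample_ear_shape(sid, 55)
            d = [render_capture(shape, donut, v, 55) for v in (1, 2)]
            f = [render_capture(shape, freehand, v, 55) for v in (1, 2)]
            mad_d = np.abs(d[0].pixels - d[1].pixels).mean()
            mad_f = np.abs(f[0].pixels - f[1].pixels).mean()
            assert mad_d < mad_f

    def test_raw_pixel_nearest_neighbor_separability(self):
        """Under standardized capture, visit-2 images are closest in raw
        pixel distance to the same subject's visit-1 image — the premise
        that makes identification possible at all."""
        donut = default_donut_model()
        n = 20
        shapes = [sample_ear_shape(i, 13) for i in range(1, n + 1)]
        v1 = np.stack([render_capture(s, donut, 1, 13).pixels for s in shapes])
        v2 = np.stack([render_capture(s, donut, 2, 13).pixels for s in shapes])
        hits = 0
        for i in range(n):
            dists = np.abs(v1 - v2[i]).mean(axis=(1, 2))
            hits += int(np.argmin(dists) == i)
        assert hits >= 0.9 * n

    def test_zero_occlusion_range_is_identity(self, monkeypatch):
        shape = sample_ear_shape(4, 9)
        model = replace(default_freehand_model(),
                        occlusion_fraction_range=(0.0, 0.0))
        with_hook = render_capture(shape, model, 1, 9)
        monkeypatch.setattr(cohort_mod, "_draw_occlusion",
                            lambda img, mask, frac, rng: img)
        disabled = render_capture(shape, model, 1, 9)
        np.testing.assert_array_equal(with_hook.pixels, disabled.pixels)

    def test_runaway_translation_rejected(self):
        shape = sample_ear_shape(1, 1)
        model = CaptureModel(condition_name="bad",
                             translation_range=(-0.6, 0.6))
        with pytest.raises(InvalidCaptureModelError):
            render_capture(shape, model, 1, 1)

    def test_invalid_visit_rejected(self):
        with pytest.raises(ValueError):
            render_capture(sample_ear_shape(1, 1), default_donut_model(), 3, 1)

    def test_model_range_validation(self):
        with pytest.raises(InvalidCaptureModelError):
            CaptureModel(condition_name="x", scale_range=(1.2, 0.8))
        with pytest.raises(InvalidCaptureModelError):
            CaptureModel(condition_name="x",
                         occlusion_fraction_range=(0.0, 1.5))


class TestGenerateCohort:
    def test_manifest_counts(self, cohort12):
        assert len(cohort12.records) == 48
        for sid in cohort12.subjects():
            n = sum(1 for s, *_ in cohort12.records if s == sid)
            assert n == 4

    def test_regeneration_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_cohort(3, cohort_seed=5, out_dir=a)
        generate_cohort(3, cohort_seed=5, out_dir=b)
        for f in sorted(a.glob("*.png")):
            assert f.read_bytes() == (b / f.name).read_bytes()

    def test_minimum_cohort_size(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(1, cohort_seed=0, out_dir=tmp_path)

    def test_study_sized_manifest_has_776_records(self):
        """194 enrolled subjects x 2 visits x 2 conditions = 776 images."""
        records = [
            (sid, v, c, f"s{sid}_{v}_{c}.png")
            for sid in range(1, 195)
            for c in ("donut", "freehand")
            for v in (1, 2)
        ]
        manifest = CohortManifest(records=records, cohort_seed=0)
        manifest.validate()
        assert len(manifest.records) == 776

    def test_duplicate_triple_rejected(self):
        records = [(1, 1, "donut", "x.png"), (1, 1, "donut", "y.png")]
        with pytest.raises(ValueError, match="duplicate"):
            CohortManifest(records=records, cohort_seed=0).validate()
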