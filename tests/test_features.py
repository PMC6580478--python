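"""Feature extraction: scale-space construction, keypoint detection,
descriptor invariances, and the independent reference-backend audit."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from earident.features import (
    ConfigurationError,
    FeatureSet,
    SiftParams,
    build_scale_space,
    compute_descriptors,
    detect_keypoints,
    extract,
)
from earident.preprocess import EarImage


def _positions(fs: FeatureSet) -> np.ndarray:
    return np.array([[k.row, k.col] for k in fs.keypoints]).reshape(-1, 2)


class TestScaleSpace:
    def test_constant_image_gives_zero_dog(self):
        img = EarImage(np.full((96, 96), 0.5, dtype=np.float32))
        space = build_scale_space(img)
        for dog in space.dogs:
            np.testing.assert_allclose(dog, 0.0, atol=1e-7)

    def test_plane_counts(self):
        img = EarImage(np.random.default_rng(0).random((128, 96)).astype(np.float32))
        space = build_scale_space(img, n_octaves=3, scales_per_octave=3)
        assert len(space.dogs) == 3
        for g, d in zip(space.gaussians, space.dogs):
            assert g.shape[0] == 3 + 3
            assert d.shape[0] == 3 + 2

    def test_too_small_image_rejected(self):
        img = EarImage(np.zeros((40, 40), dtype=np.float32))
        with pytest.raises(ConfigurationError):
            build_scale_space(img, n_octaves=4)

    def test_bright_dot_yields_extremum_at_dot(self):
        px = np.zeros((96, 96), dtype=np.float32)
        px[48, 40] = 1.0
        space = build_scale_space(EarImage(px))
        # brute-force: strongest |DoG| response over the whole pyramid
        best = None
        for o, dog in enumerate(space.dogs):
            idx = np.unravel_index(np.argmax(np.abs(dog)), dog.shape)
            val = abs(dog[idx])
            if best is None or val > best[0]:
                best = (val, o, idx)
        _, o, (j, y, x) = best
        assert abs(y * 2 ** o - 48) <= 2 and abs(x * 2 ** o - 40) <= 2

    def test_doubling_base_sigma_shifts_octave_down(self):
        # a blob of fixed radius peaks one octave earlier when the base
        # blur doubles (same absolute scale, half the octave index)
        rr, cc = np.mgrid[:128, :128]
        blob = np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * 8.0 ** 2))
        img = EarImage(blob.astype(np.float32))

        def peak_octave(base_sigma: float) -> int:
            space = build_scale_space(img, base_sigma=base_sigma)
            best = (0.0, 0)
            for o, dog in enumerate(space.dogs):
                v = float(np.abs(dog).max())
                if v > best[0]:
                    best = (v, o)
            return best[1]

        assert peak_octave(3.2) == peak_octave(1.6) - 1


class TestKeypoints:
    def test_constant_image_has_no_keypoints(self):
        img = EarImage(np.full((96, 96), 0.25, dtype=np.float32))
        assert detect_keypoints(build_scale_space(img)) == []

    def test_step_edge_filtered_by_curvature_test(self):
        px = np.zeros((96, 96), dtype=np.float32)
        px[:, 48:] = 1.0
        px = ndimage.gaussian_filter(px, 1.0)
        kps = detect_keypoints(build_scale_space(EarImage(px)))
        # responses along a straight edge fail the principal-curvature test
        assert len(kps) == 0

    def test_rotation_covariance(self, textured_image):
        fs = extract(textured_image)
        rot = EarImage(np.rot90(textured_image.pixels).copy())
        fs_rot = extract(rot)
        assert len(fs) > 30
        assert abs(len(fs) - len(fs_rot)) <= 0.15 * len(fs)
        H, W = textured_image.pixels.shape
        mapped = np.array([[W - 1 - k.col, k.row] for k in fs.keypoints])
        dist, idx = cKDTree(_positions(fs_rot)).query(mapped)
        frac = (dist <= 1.0).mean()
        assert frac >= 0.85
        close = dist <= 1.0
        desc_d = np.linalg.norm(
            fs.descriptors[close] - fs_rot.descriptors[idx[close]], axis=1)
        assert np.median(desc_d) <= 0.35

    def test_detection_is_deterministic(self, textured_image):
        a = extract(textured_image)
        b = extract(textured_image)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)
        assert [(k.row, k.col) for k in a.keypoints] == \
               [(k.row, k.col) for k in b.keypoints]


class TestDescriptors:
    def test_length_and_unit_norm(self, textured_image):
        fs = extract(textured_image)
        assert fs.descriptors.shape[1] == 128
        norms = np.linalg.norm(fs.descriptors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-5)
        assert (fs.descriptors >= 0).all()

    def test_photometric_gain_invariance(self, textured_image):
        fs = extract(textured_image)
        scaled = EarImage((textured_image.pixels * 0.6).astype(np.float32))
        fs2 = extract(scaled)

        def keyed(f):
            return {(round(k.row, 2), round(k.col, 2), round(k.orientation, 1)): i
                    for i, k in enumerate(f.keypoints)}

        k1, k2 = keyed(fs), keyed(fs2)
        common = set(k1) & set(k2)
        assert len(common) >= 0.7 * len(fs)
        for key in common:
            d = np.linalg.norm(fs.descriptors[k1[key]] - fs2.descriptors[k2[key]])
            assert d < 1e-3

    def test_serialization_round_trip(self, textured_image):
        fs = extract(textured_image)
        back = FeatureSet.from_text(fs.to_text(), image_key=fs.image_key)
        assert len(back) == len(fs)
        np.testing.assert_allclose(back.descriptors, fs.descriptors, atol=1e-5)
        np.testing.assert_allclose(
            [k.row for k in back.keypoints], [k.row for k in fs.keypoints],
            atol=1e-3)


class TestExtractDispatch:
    def test_blank_image_both_backends_empty(self):
        blank = EarImage(np.full((128, 128), 0.5, dtype=np.float32))
        for backend in ("native", "reference"):
            fs = extract(blank, backend=backend)
            assert len(fs) == 0
            assert fs.descriptors.shape == (0, 128)

    def test_unknown_backend_rejected(self, textured_image):
        with pytest.raises(ValueError):
            extract(textured_image, backend="opencv")

    def test_native_matches_reference_backend(self, textured_image, donut_pair):
        """Independent audit: most native keypoints coincide with the
        external reference extractor's, within 2 px."""
        from earident.preprocess import auto_crop_aperture, resize

        images = [textured_image] + [
            resize(auto_crop_aperture(img), 256) for img in donut_pair
        ]
        for img in images:
            native = extract(img, backend="native")
            ref = extract(img, backend="reference")
            assert len(native) > 20 and len(ref) > 20
            dist, _ = cKDTree(_positions(ref)).query(_positions(native))
            assert (dist <= 2.0).mean() >= 0.60
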