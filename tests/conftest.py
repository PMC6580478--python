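from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from earident.cohort import (
    default_donut_model,
    default_freehand_model,
    generate_cohort,
    render_capture,
    sample_ear_shape,
)
from earident.preprocess import EarImage


@pytest.fixture(scope="session")
def cohort12(tmp_path_factory):
    """A 12-subject paired cohort on disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort12")
    manifest = generate_cohort(12, cohort_seed=101, out_dir=out)
    return manifest


@pytest.fixture(scope="session")
def donut_pair():
    """One subject's two standardized-visit captures."""
    shape = sample_ear_shape(3, 77)
    model = default_donut_model()
    return (render_capture(shape, model, 1, 77),
            render_capture(shape, model, 2, 77))


@pytest.fixture(scope="session")
def freehand_pair():
    shape = sample_ear_shape(3, 77)
    model = default_freehand_model()
    return (render_capture(shape, model, 1, 77),
            render_capture(shape, model, 2, 77))


@pytest.fixture(scope="session")
def textured_image():
    """A deterministic textured fixture rich in blob-like features."""
    rng = np.random.default_rng(2024)
    field = ndimage.gaussian_filter(rng.standard_normal((192, 160)), 2.5)
    field = (field - field.min()) / (field.max() - field.min())
    return EarImage((0.1 + 0.8 * field).astype(np.float32))


@pytest.fixture(scope="session")
def unit_descriptors():
    """Factory for random unit-norm descriptor arrays."""
    def make(n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        d = np.abs(rng.standard_normal((n, 128))).astype(np.float32)
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.maximum(norms, 1e-12)
    return make
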