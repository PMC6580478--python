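"""Manifest and image IO.

The cohort manifest is a plain CSV with header
``subject_id,visit,condition,file_path``; images are 8-bit grayscale PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .cohort import CohortManifest
from .preprocess import EarImage, to_grayscale_single

MANIFEST_COLUMNS = ["subject_id", "visit", "condition", "file_path"]


class ManifestError(ValueError):
    """Manifest file is malformed or violates cohort invariants."""


def write_manifest(manifest: CohortManifest, path: Path | str) -> None:
    df = pd.DataFrame(manifest.records, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path: Path | str) -> CohortManifest:
    """Read and validate a manifest CSV.

    Raises :class:`ManifestError` on missing columns, duplicate
    (subject, visit, condition) triples, or subjects that do not have
    exactly 4 records.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    records = [
        (int(r.subject_id), int(r.visit), str(r.condition), str(r.file_path))
        for r in df.itertuples()
    ]
    manifest = CohortManifest(records=records, cohort_seed=0,
                              root=str(Path(path).parent))
    try:
        manifest.validate()
    except ValueError as exc:
        raise ManifestError(str(exc)) from exc
    return manifest


def load_image(path: Path | str, *, subject_id: int = 0, visit: int = 1,
               condition_name: str = "") -> EarImage:
    """Load a PNG as a single-precision grayscale image in [0, 1]."""
    with PILImage.open(path) as im:
        arr = np.asarray(im)
    return to_grayscale_single(arr, subject_id=subject_id, visit=visit,
                               condition_name=condition_name)


def load_manifest_images(manifest: CohortManifest, condition: str,
                         root: Path | str | None = None) -> dict:
    """Load all images of one condition, keyed by (subject_id, visit)."""
    images = {}
    base = root if root is not None else manifest.root
    for sid, visit, cond, fp in manifest.records:
        if cond != condition:
            continue
        p = Path(fp)
        if base is not None and not p.is_absolute():
            p = Path(base) / p
        if not p.exists():
            raise ManifestError(f"image listed in manifest not found: {p}")
        images[(sid, visit)] = load_image(p, subject_id=sid, visit=visit,
                                          condition_name=cond)
    return images
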