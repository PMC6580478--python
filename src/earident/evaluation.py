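"""Closed-set identification evaluation and crop-sensitivity analysis.

For one capture condition, visit-1 images form the gallery and visit-2
images are probes (top-1 correct when the rank-1 gallery subject equals
the probe subject; top-10 correct when the probe's subject appears within
the first min(10, gallery size) ranks), then the roles are swapped and
the two directional proportions are averaged into the reported top-1 and
top-10 identification rates, as percentages.

Crop sensitivity re-runs the top-1 evaluation over a grid of crop lengths
(or widths) with the other dimension fixed, and quantifies sensitivity as
the finite-difference slope of accuracy (percentage points) per pixel of
crop; |slope| > 1 flags a sensitive operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CohortManifest
from .features import FeatureSet, SiftParams, extract
from .io import load_manifest_images
from .matching import DEFAULT_RATIO, rank_gallery
from .preprocess import (
    CropSpec,
    EarImage,
    RingDetectionError,
    auto_crop_aperture,
    fixed_crop,
    resize,
)

TOP_K = 10
DEFAULT_TARGET_LONG_SIDE = 256
#: Fallback window when aperture detection fails under "auto" cropping,
#: sized to hold the nominal ear with margin.
DEFAULT_FALLBACK_CROP = CropSpec(length=340, width=260)
SENSITIVE_SLOPE = 1.0  # percentage points of accuracy per pixel of crop


class ManifestInconsistency(ValueError):
    """Probe/gallery subject sets disagree or images are missing."""


@dataclass
class DirectionResult:
    gallery_visit: int
    n_probes: int
    top1_correct: int
    top10_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.top1_correct <= self.top10_correct <= self.n_probes):
            raise ValueError(
                "need 0 <= top1_correct <= top10_correct <= n_probes"
            )

    @property
    def top1_proportion(self) -> float:
        return self.top1_correct / self.n_probes

    @property
    def top10_proportion(self) -> float:
        return self.top10_correct / self.n_probes


@dataclass
class IdentificationReport:
    """Bidirectional identification rates for one capture condition.

    ``top1_rate``/``top10_rate`` are percentages: 100 x the mean of the
    two directional proportions, reported to one decimal place.
    """

    condition_name: str
    direction_results: Tuple[DirectionResult, DirectionResult]
    provenance: Dict = field(default_factory=dict)

    @property
    def top1_rate(self) -> float:
        return round(100.0 * float(np.mean(
            [d.top1_proportion for d in self.direction_results])), 1)

    @property
    def top10_rate(self) -> float:
        return round(100.0 * float(np.mean(
            [d.top10_proportion for d in self.direction_results])), 1)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition_name,
             "gallery_visit": d.gallery_visit, "n_probes": d.n_probes,
             "top1_correct": d.top1_correct, "top10_correct": d.top10_correct}
            for d in self.direction_results
        ]
        df = pd.DataFrame(rows)
        df["top1_rate_pct"] = self.top1_rate
        df["top10_rate_pct"] = self.top10_rate
        return df


@dataclass
class SensitivityCurve:
    swept_dimension: str                 # "length" or "width"
    points: List[Tuple[int, float]]      # (crop_value px, top1_rate pct)

    @property
    def slopes(self) -> List[float]:
        """Finite-difference slope (pct points / px) between consecutive points."""
        return [
            (r1 - r0) / (v1 - v0)
            for (v0, r0), (v1, r1) in zip(self.points, self.points[1:])
        ]

    @property
    def sensitive_flags(self) -> List[bool]:
        return [abs(s) > SENSITIVE_SLOPE for s in self.slopes]

    def as_frame(self) -> pd.DataFrame:
        slopes = [np.nan] + self.slopes
        return pd.DataFrame({
            "crop_value": [v for v, _ in self.points],
            "top1_rate_pct": [r for _, r in self.points],
            "slope_pct_per_px": slopes,
        })


def score_matrix(
    probes: Dict[int, FeatureSet],
    gallery: Dict[int, FeatureSet],
    ratio_threshold: float = DEFAULT_RATIO,
) -> pd.DataFrame:
    """Integer match-count matrix, probe subjects as rows, gallery as columns."""
    g_list = [gallery[s] for s in sorted(gallery)]
    rows = {}
    for ps in sorted(probes):
        ranked = rank_gallery(probes[ps], g_list, ratio_threshold)
        by_key = {k: n for k, n in ranked.ranking}
        rows[ps] = [by_key[gallery[s].image_key] for s in sorted(gallery)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=sorted(gallery)).rename_axis("probe_subject")


def identify_direction(
    gallery: Dict[int, FeatureSet],
    probes: Dict[int, FeatureSet],
    ratio_threshold: float = DEFAULT_RATIO,
    gallery_visit: int = 1,
) -> Tuple[DirectionResult, pd.DataFrame]:
    """Run one gallery/probe direction; returns the result and the score matrix.

    ``gallery`` and ``probes`` map subject_id -> FeatureSet, one image per
    subject on each side.
    """
    missing = set(probes) - set(gallery)
    if missing:
        raise ManifestInconsistency(
            f"probe subjects absent from gallery: {sorted(missing)}")
    g_list = [gallery[s] for s in sorted(gallery)]
    k = min(TOP_K, len(g_list))
    top1 = top10 = 0
    mat_rows: Dict[int, List[int]] = {}
    for ps in sorted(probes):
        ranked = rank_gallery(probes[ps], g_list, ratio_threshold)
        subjects_in_order = [key[0] for key, _ in ranked.ranking]
        if subjects_in_order[0] == ps:
            top1 += 1
        if ps in subjects_in_order[:k]:
            top10 += 1
        by_key = {key: n for key, n in ranked.ranking}
        mat_rows[ps] = [by_key[gallery[s].image_key] for s in sorted(gallery)]
    result = DirectionResult(gallery_visit=gallery_visit, n_probes=len(probes),
                             top1_correct=top1, top10_correct=top10)
    mat = pd.DataFrame.from_dict(
        mat_rows, orient="index", columns=sorted(gallery)
    ).rename_axis("probe_subject")
    return result, mat


def preprocess_for_matching(
    image: EarImage,
    crop: "CropSpec | str" = "auto",
    target_long_side: int = DEFAULT_TARGET_LONG_SIDE,
    fallback: CropSpec = DEFAULT_FALLBACK_CROP,
) -> EarImage:
    """Crop (aperture-based when ``crop="auto"``, fixed otherwise) and resize.

    With ``crop="auto"`` the aperture detector is tried first; when no ring
    is found (unstandardized captures) the fixed fallback window is used,
    mirroring the study's fallback to manually chosen crop dimensions.
    """
    if isinstance(crop, str) and crop == "auto":
        try:
            cropped = auto_crop_aperture(image)
        except RingDetectionError:
            spec = CropSpec(length=min(fallback.length, image.height),
                            width=min(fallback.width, image.width),
                            anchor=fallback.anchor)
            cropped = fixed_crop(image, spec)
    else:
        cropped = fixed_crop(image, crop)
    return resize(cropped, target_long_side)


def _condition_features(
    manifest: CohortManifest,
    condition_name: str,
    crop: "CropSpec | str",
    target_long_side: int,
    sift_params: Optional[SiftParams],
    backend: str,
    root=None,
) -> Dict[int, Dict[int, FeatureSet]]:
    """Features per visit: {visit: {subject_id: FeatureSet}}."""
    images = load_manifest_images(manifest, condition_name, root=root)
    out: Dict[int, Dict[int, FeatureSet]] = {1: {}, 2: {}}
    for (sid, visit), img in sorted(images.items()):
        pre = preprocess_for_matching(img, crop=crop,
                                      target_long_side=target_long_side)
        out[visit][sid] = extract(pre, backend=backend, params=sift_params)
    if set(out[1]) != set(out[2]):
        raise ManifestInconsistency(
            f"visit subject sets differ for condition {condition_name!r}")
    return out


def identification_report(
    manifest: CohortManifest,
    condition_name: str,
    crop: "CropSpec | str" = "auto",
    target_long_side: int = DEFAULT_TARGET_LONG_SIDE,
    ratio_threshold: float = DEFAULT_RATIO,
    sift_params: Optional[SiftParams] = None,
    backend: str = "native",
    root=None,
    features: Optional[Dict[int, Dict[int, FeatureSet]]] = None,
) -> Tuple[IdentificationReport, Dict[int, pd.DataFrame]]:
    """Bidirectional identification for one condition.

    Runs preprocess -> features -> matching with visit 1 as gallery and
    visit 2 as probes, then swapped, and averages the two directions.
    Returns the report and the two score matrices keyed by gallery visit.
    Precomputed ``features`` (as from the sweep's cache) bypass extraction.
    """
    feats = features if features is not None else _condition_features(
        manifest, condition_name, crop, target_long_side, sift_params,
        backend, root)
    d1, m1 = identify_direction(feats[1], feats[2], ratio_threshold,
                                gallery_visit=1)
    d2, m2 = identify_direction(feats[2], feats[1], ratio_threshold,
                                gallery_visit=2)
    report = IdentificationReport(
        condition_name=condition_name,
        direction_results=(d1, d2),
        provenance={
            "crop": str(crop), "target_long_side": target_long_side,
            "ratio_threshold": ratio_threshold, "backend": backend,
            "cohort_seed": manifest.cohort_seed,
            "n_subjects": len(manifest.subjects()),
        },
    )
    return report, {1: m1, 2: m2}


def sensitivity_sweep(
    manifest: CohortManifest,
    condition_name: str,
    dimension: str,
    values: Sequence[int],
    fixed_other: int,
    target_long_side: int = DEFAULT_TARGET_LONG_SIDE,
    ratio_threshold: float = DEFAULT_RATIO,
    sift_params: Optional[SiftParams] = None,
    backend: str = "native",
    root=None,
) -> SensitivityCurve:
    """Top-1 accuracy as a function of one crop dimension.

    ``values`` must be strictly increasing crop sizes in pixels for the
    swept dimension; the other dimension is held at ``fixed_other``.
    """
    if dimension not in ("length", "width"):
        raise ValueError('dimension must be "length" or "width"')
    if len(values) < 2 or any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("values must be >= 2 and strictly increasing")
    points = []
    for v in values:
        spec = (CropSpec(length=v, width=fixed_other) if dimension == "length"
                else CropSpec(length=fixed_other, width=v))
        report, _ = identification_report(
            manifest, condition_name, crop=spec,
            target_long_side=target_long_side,
            ratio_threshold=ratio_threshold, sift_params=sift_params,
            backend=backend, root=root)
        points.append((int(v), report.top1_rate))
    return SensitivityCurve(swept_dimension=dimension, points=points)
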