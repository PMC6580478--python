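"""Synthetic paired-capture ear cohort generator.

Emulates the study design: a cohort of subjects, each contributing two
"visit" images per capture condition. The standardized condition ("donut")
models capture through an internally lit aperture device that fixes
distance, in-plane rotation, centering, lighting and keeps hair out of the
frame; the unstandardized condition ("freehand") randomizes all of those
nuisances per capture.

Ears are rendered procedurally: an outer-helix ellipse ridge, an antihelix
arc, a concha bowl with rim, a tragus bump and a lobe blob, overlaid with a
subject-specific smooth texture field. The rendering is not photorealistic;
it only needs to give the feature extractor high-contrast structure that is
subject-specific, which is the premise the study tests.

Everything is a pure function of (n_subjects, capture models, cohort_seed):
per-image random streams are derived from the (subject, visit, condition)
triple so regeneration is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

from .preprocess import EarImage

# Nominal capture frame (rows x cols) and device-aperture interior radius.
FRAME_SHAPE: Tuple[int, int] = (480, 360)
APERTURE_RADIUS = 165
_BACKGROUND = 0.55

DONUT = "donut"
FREEHAND = "freehand"


class InvalidCaptureModelError(ValueError):
    """Capture model parameters are inconsistent or could lose the ear."""


@dataclass(frozen=True)
class EarShape:
    """Per-subject anatomical parameters of the procedural ear, in pixels
    of the canonical (unit-scale) frame."""

    subject_id: int
    helix_axes: Tuple[float, float]      # (row, col) semi-axes of the outer helix
    antihelix_offset: float              # inward displacement of the antihelix arc
    concha_center: Tuple[float, float]   # (row, col)
    concha_radius: float
    lobe_extent: float
    tragus_size: float
    texture_seed: int

    def __post_init__(self) -> None:
        lengths = (*self.helix_axes, self.antihelix_offset, self.concha_radius,
                   self.lobe_extent, self.tragus_size)
        if any(v <= 0 for v in lengths):
            raise ValueError("all EarShape lengths must be strictly positive")
        if self.antihelix_offset >= min(self.helix_axes):
            raise ValueError("antihelix_offset must be smaller than the helix axes")


@dataclass(frozen=True)
class CaptureModel:
    """Nuisance-parameter distributions defining a capture condition.

    All ranges are (min, max); per-capture values are drawn uniformly.
    Translation is a fraction of the frame size per axis; the illumination
    gradient strength is a fraction of the dynamic range; occlusion covers
    the drawn fraction of the ear area with dark hair-like strokes.
    """

    condition_name: str
    rotation_range: Tuple[float, float] = (0.0, 0.0)          # degrees
    translation_range: Tuple[float, float] = (0.0, 0.0)       # fraction of frame
    scale_range: Tuple[float, float] = (1.0, 1.0)
    illumination_gradient_strength: Tuple[float, float] = (0.0, 0.0)
    gamma_range: Tuple[float, float] = (1.0, 1.0)
    occlusion_fraction_range: Tuple[float, float] = (0.0, 0.0)
    tilt_range: Tuple[float, float] = (0.0, 0.0)  # out-of-plane camera angle, degrees
    aperture_ring: bool = False
    sensor_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("rotation_range", "translation_range", "scale_range",
                     "illumination_gradient_strength", "gamma_range",
                     "occlusion_fraction_range", "tilt_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidCaptureModelError(f"{name} must be ordered (min <= max)")
        for name in ("illumination_gradient_strength", "occlusion_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise InvalidCaptureModelError(f"{name} fractions must lie in [0, 1]")
        if self.sensor_noise_sd < 0:
            raise InvalidCaptureModelError("sensor_noise_sd must be non-negative")


def default_donut_model() -> CaptureModel:
    """Standardized capture: the device freezes geometry and lighting; only
    sensor noise and a small per-visit illumination (gamma) offset remain."""
    return CaptureModel(
        condition_name=DONUT,
        gamma_range=(0.97, 1.03),
        aperture_ring=True,
    )


def default_freehand_model() -> CaptureModel:
    """Unstandardized field capture: rotation, framing, distance, ambient
    lighting and hair occlusion all vary between captures."""
    return CaptureModel(
        condition_name=FREEHAND,
        rotation_range=(-15.0, 15.0),
        translation_range=(-0.15, 0.15),
        scale_range=(0.75, 1.30),
        illumination_gradient_strength=(0.0, 0.40),
        gamma_range=(0.70, 1.40),
        occlusion_fraction_range=(0.0, 0.25),
        tilt_range=(0.0, 40.0),
        aperture_ring=False,
    )


@dataclass
class CohortManifest:
    """Index of generated images: one record per (subject, visit, condition)."""

    records: List[Tuple[int, int, str, str]]  # (subject_id, visit, condition, file_path)
    cohort_seed: int
    root: "str | None" = None  # directory file_path entries are relative to

    def validate(self) -> None:
        triples = [(s, v, c) for s, v, c, _ in self.records]
        if len(set(triples)) != len(triples):
            dupes = sorted({t for t in triples if triples.count(t) > 1})
            raise ValueError(f"duplicate (subject, visit, condition) triples: {dupes}")
        by_subject: dict = {}
        for s, v, c, _ in self.records:
            by_subject.setdefault(s, []).append((v, c))
        bad = {s: sorted(vc) for s, vc in by_subject.items() if len(vc) != 4}
        if bad:
            raise ValueError(f"subjects without exactly 4 records: {bad}")

    def subjects(self) -> List[int]:
        return sorted({s for s, _, _, _ in self.records})

    def path_for(self, subject_id: int, visit: int, condition: str) -> str:
        for s, v, c, p in self.records:
            if (s, v, c) == (subject_id, visit, condition):
                return p
        raise KeyError((subject_id, visit, condition))


def _condition_code(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def _stream(cohort_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([cohort_seed & 0x7FFFFFFF, *tags])


def sample_ear_shape(subject_id: int, cohort_seed: int) -> EarShape:
    """Draw a subject's ear-shape parameters; deterministic in the pair.

    Ranges are wide enough that inter-subject differences (geometry plus
    the texture field keyed by ``texture_seed``) dominate intra-subject
    capture noise under standardized conditions.
    """
    if subject_id < 1:
        raise ValueError("subject_id must be >= 1")
    rng = _stream(cohort_seed, 0, subject_id)
    cy, cx = FRAME_SHAPE[0] / 2.0, FRAME_SHAPE[1] / 2.0
    a_row = rng.uniform(112.0, 148.0)
    a_col = rng.uniform(72.0, 100.0)
    return EarShape(
        subject_id=subject_id,
        helix_axes=(a_row, a_col),
        antihelix_offset=rng.uniform(18.0, 40.0),
        concha_center=(cy + rng.uniform(-12, 12), cx + rng.uniform(-12, 12)),
        concha_radius=rng.uniform(16.0, 28.0),
        lobe_extent=rng.uniform(24.0, 44.0),
        tragus_size=rng.uniform(10.0, 20.0),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _render_canonical(shape: EarShape) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the ear at unit scale into the nominal frame.

    Returns (image, ear_mask, height). ``height`` is a smooth pseudo-relief
    of the ear (ridges high, concha low, unit std inside the ear) used to
    model out-of-plane parallax and directional shading. Pure function of
    the shape.
    """
    h, w = FRAME_SHAPE
    cy, cx = h / 2.0, w / 2.0
    rr, cc = np.mgrid[:h, :w].astype(np.float64)
    a, b = shape.helix_axes

    img = np.full((h, w), _BACKGROUND)

    rho = np.sqrt(((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2)
    scale_px = np.sqrt(a * b)
    d = (rho - 1.0) * scale_px  # approx pixel distance to the helix ellipse

    # Outer helix: bright ridge with a darker rim just outside it.
    img += 0.30 * np.exp(-(d ** 2) / (2 * 6.0 ** 2))
    img -= 0.18 * np.exp(-((d - 11.0) ** 2) / (2 * 5.0 ** 2))

    # Antihelix: inner arc over the upper/rear part of the ear.
    a2, b2 = a - shape.antihelix_offset, b - shape.antihelix_offset
    rho2 = np.sqrt(((rr - cy) / a2) ** 2 + ((cc - cx) / b2) ** 2)
    d2 = (rho2 - 1.0) * np.sqrt(a2 * b2)
    theta = np.arctan2(cc - cx, -(rr - cy))  # 0 at top, +pi/2 toward +col
    arc = (theta > -2.4) & (theta < 1.9)
    img += 0.22 * np.exp(-(d2 ** 2) / (2 * 4.5 ** 2)) * arc

    # Concha: dark bowl with a bright rim.
    qy, qx = shape.concha_center
    dc = np.sqrt((rr - qy) ** 2 + (cc - qx) ** 2)
    img -= 0.25 * np.exp(-((dc / shape.concha_radius) ** 4))
    img += 0.18 * np.exp(-((dc - 1.35 * shape.concha_radius) ** 2) / (2 * 3.5 ** 2))

    # Tragus: bump forward of the concha (toward smaller col).
    ty, tx = qy + 0.2 * shape.concha_radius, qx - 1.9 * shape.concha_radius
    dt = np.sqrt((rr - ty) ** 2 + (cc - tx) ** 2)
    img += 0.24 * np.exp(-((dt / shape.tragus_size) ** 2))

    # Lobe: soft blob in the lower part of the ear.
    ly, lx = cy + 0.72 * a, cx - 0.18 * b
    dl = np.sqrt((rr - ly) ** 2 + (cc - lx) ** 2)
    img += 0.15 * np.exp(-((dl / shape.lobe_extent) ** 2))

    ear_mask = rho <= 1.10

    # Pseudo-relief from the structural components rendered so far:
    # bright ridges (helix, antihelix, tragus) sit high, the concha bowl
    # sits low. Smooth it so parallax displacements stay gentle.
    height = ndimage.gaussian_filter(img - _BACKGROUND, 5.0)
    height = height * ear_mask
    height /= max(height[ear_mask].std(), 1e-9) if ear_mask.any() else 1.0

    # Subject-specific texture: a smooth random field plus fine grain,
    # confined to the ear and tapered at its boundary.
    trng = np.random.default_rng(shape.texture_seed)
    coarse = ndimage.gaussian_filter(trng.standard_normal((h, w)), 3.0)
    coarse /= max(coarse.std(), 1e-9)
    fine = ndimage.gaussian_filter(trng.standard_normal((h, w)), 1.0)
    fine /= max(fine.std(), 1e-9)
    taper = np.clip((1.10 - rho) * scale_px / 12.0, 0.0, 1.0)
    img += (0.10 * coarse + 0.04 * fine) * taper

    return np.clip(img, 0.03, 0.97), ear_mask, height


def _draw_occlusion(img: np.ndarray, ear_mask: np.ndarray, fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Overlay hair-like strokes until they cover ``fraction`` of the ear
    area. Strokes are straight bands of dark, strand-textured hair: they
    both hide the covered ear structure and introduce capture-specific
    high-contrast detail, as loose hair does in field images."""
    if fraction <= 0 or not ear_mask.any():
        return img
    h, w = img.shape
    rows = np.any(ear_mask, axis=1).nonzero()[0]
    cols = np.any(ear_mask, axis=0).nonzero()[0]
    rr, cc = np.mgrid[:h, :w].astype(np.float64)
    strokes = np.zeros((h, w), dtype=bool)
    ear_area = float(ear_mask.sum())
    for _ in range(40):
        py = rng.uniform(rows[0], rows[-1])
        px = rng.uniform(cols[0], cols[-1])
        ang = rng.uniform(0, np.pi)
        width = rng.uniform(2.5, 7.0)
        # signed distance to the infinite line through (py, px) at angle ang
        dist = np.abs(-(rr - py) * np.sin(ang) + (cc - px) * np.cos(ang))
        strokes |= dist < width
        if (strokes & ear_mask).sum() / ear_area >= fraction:
            break
    # elongated noise emulating individual strands within the strokes
    strands = ndimage.gaussian_filter(rng.standard_normal((h, w)), (0.8, 5.0))
    strands /= max(strands.std(), 1e-9)
    hair = np.clip(0.10 + 0.16 * strands, 0.02, 0.55)
    alpha = np.clip(ndimage.gaussian_filter(strokes.astype(np.float64), 1.0), 0, 1)
    return img * (1 - alpha) + hair * alpha


def _background_clutter(shape_hw: Tuple[int, int],
                        rng: np.random.Generator) -> np.ndarray:
    """A capture-specific textured background field (head, hair, scene).

    Field captures image the ear against whatever surrounds it; that
    backdrop changes between visits and is rich in high-contrast detail.
    The aperture device standardizes it away by enclosing the ear, so
    clutter is rendered only for captures without the ring.
    """
    h, w = shape_hw
    coarse = ndimage.gaussian_filter(rng.standard_normal((h, w)), 5.0)
    coarse /= max(coarse.std(), 1e-9)
    fine = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.2)
    fine /= max(fine.std(), 1e-9)
    return 0.12 * coarse + 0.06 * fine


def render_capture(shape: EarShape, model: CaptureModel, visit: int,
                   cohort_seed: int) -> EarImage:
    """Render one capture of ``shape`` under ``model`` for the given visit.

    Nuisances are applied in order: scale, rotation, translation (one draw
    each per (subject, visit, condition)), illumination gradient with a
    random direction, gamma jitter, occlusion strokes, the aperture ring if
    the model carries one, and finally additive sensor noise. Fully
    reproducible from (shape, model, visit, cohort_seed).
    """
    if visit not in (1, 2):
        raise ValueError("visit must be 1 or 2")
    if max(abs(model.translation_range[0]), abs(model.translation_range[1])) >= 0.5:
        raise InvalidCaptureModelError(
            "translation_range could move the ear entirely out of frame"
        )
    h, w = FRAME_SHAPE
    cy, cx = h / 2.0, w / 2.0
    code = _condition_code(model.condition_name)
    rng = _stream(cohort_seed, 1, shape.subject_id, visit, code)
    occ_rng = _stream(cohort_seed, 2, shape.subject_id, visit, code)
    noise_rng = _stream(cohort_seed, 3, shape.subject_id, visit, code)

    s = rng.uniform(*model.scale_range)
    rot = rng.uniform(*model.rotation_range)
    t_r = rng.uniform(*model.translation_range) * h
    t_c = rng.uniform(*model.translation_range) * w
    grad = rng.uniform(*model.illumination_gradient_strength)
    grad_dir = rng.uniform(0, 2 * np.pi)
    gamma = rng.uniform(*model.gamma_range)
    occ_frac = rng.uniform(*model.occlusion_fraction_range)
    tilt = rng.uniform(*model.tilt_range)
    tilt_dir = rng.uniform(0, 2 * np.pi)

    canonical, ear_mask, height = _render_canonical(shape)
    mask_f = ear_mask.astype(np.float64)

    if tilt > 0:
        # out-of-plane camera angle: depth parallax shifts structures by
        # their relief along the tilt azimuth (a non-rigid warp)
        tau = np.deg2rad(tilt)
        depth_px = 14.0
        disp = np.sin(tau) * depth_px * height
        rr, cc = np.mgrid[:h, :w].astype(np.float64)
        coords = (rr + disp * np.cos(tilt_dir), cc + disp * np.sin(tilt_dir))
        canonical = ndimage.map_coordinates(canonical, coords, order=1,
                                            cval=_BACKGROUND)
        mask_f = ndimage.map_coordinates(mask_f, coords, order=1, cval=0.0)
        height = ndimage.map_coordinates(height, coords, order=1, cval=0.0)

    theta = np.deg2rad(rot)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    # foreshortening: compression by cos(tilt) along the tilt azimuth
    u_vec = np.array([np.cos(tilt_dir), np.sin(tilt_dir)])
    F = np.eye(2) - (1.0 - np.cos(np.deg2rad(tilt))) * np.outer(u_vec, u_vec)
    fwd = s * (R @ F)
    inv = np.linalg.inv(fwd)
    center = np.array([cy, cx])
    offset = center - inv @ (center + np.array([t_r, t_c]))
    img = ndimage.affine_transform(canonical, inv, offset=offset, order=1,
                                   cval=_BACKGROUND)
    mask = ndimage.affine_transform(mask_f, inv, offset=offset, order=1,
                                    cval=0.0) > 0.5
    height_w = ndimage.affine_transform(height, inv, offset=offset, order=1,
                                        cval=0.0)

    if not model.aperture_ring:
        bg_rng = _stream(cohort_seed, 4, shape.subject_id, visit, code)
        soft = np.clip(ndimage.gaussian_filter(mask.astype(np.float64), 4.0), 0, 1)
        img = img + _background_clutter((h, w), bg_rng) * (1.0 - soft)

    if grad > 0:
        rr, cc = np.mgrid[:h, :w].astype(np.float64)
        u = ((rr - cy) * np.cos(grad_dir) + (cc - cx) * np.sin(grad_dir))
        u /= np.hypot(h, w)
        img = img + grad * u
        # directional relief shading: ridges facing away from the light
        # darken, flanks facing it brighten; scales with the drawn
        # ambient-gradient strength and vanishes under the device's
        # uniform internal lighting
        gr, gc = np.gradient(height_w)
        dh = gr * np.cos(grad_dir) + gc * np.sin(grad_dir)
        sd = dh[mask].std() if mask.any() else 0.0
        if sd > 1e-9:
            img = img + 0.8 * grad * (dh / sd) * 0.12
    img = np.clip(img, 0.0, 1.0) ** gamma
    img = _draw_occlusion(img, mask, occ_frac, occ_rng)

    meta = {
        "capture_params": {
            "scale": s, "rotation_deg": rot, "translation": (t_r, t_c),
            "gradient": grad, "gradient_dir": grad_dir, "gamma": gamma,
            "occlusion_fraction": occ_frac, "tilt_deg": tilt,
            "tilt_dir": tilt_dir,
        },
    }
    if mask.any():
        mr = np.any(mask, axis=1).nonzero()[0]
        mc = np.any(mask, axis=0).nonzero()[0]
        meta["ear_bbox"] = (int(mr[0]), int(mr[-1]) + 1, int(mc[0]), int(mc[-1]) + 1)

    if model.aperture_ring:
        rr, cc = np.mgrid[:h, :w].astype(np.float64)
        rad = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        ring_alpha = np.clip((rad - APERTURE_RADIUS) / 1.5, 0.0, 1.0)
        img = img * (1 - ring_alpha) + 0.04 * ring_alpha
        meta["aperture_interior"] = (
            int(np.ceil(cy - APERTURE_RADIUS)), int(np.floor(cy + APERTURE_RADIUS)) + 1,
            int(np.ceil(cx - APERTURE_RADIUS)), int(np.floor(cx + APERTURE_RADIUS)) + 1,
        )

    if model.sensor_noise_sd > 0:
        img = img + noise_rng.normal(0.0, model.sensor_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return EarImage(img, subject_id=shape.subject_id, visit=visit,
                    condition_name=model.condition_name, meta=meta)


def save_png(image: EarImage, path: Path) -> None:
    """Write an 8-bit grayscale PNG."""
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)


def generate_cohort(
    n_subjects: int,
    donut_model: CaptureModel | None = None,
    freehand_model: CaptureModel | None = None,
    cohort_seed: int = 0,
    out_dir: Path | str = ".",
) -> CohortManifest:
    """Generate the full paired cohort: 4 PNG images per subject (2 visits x
    2 conditions) plus a ``manifest.csv``; returns the manifest.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    donut_model = donut_model or default_donut_model()
    freehand_model = freehand_model or default_freehand_model()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: List[Tuple[int, int, str, str]] = []
    for sid in range(1, n_subjects + 1):
        shape = sample_ear_shape(sid, cohort_seed)
        for model in (donut_model, freehand_model):
            for visit in (1, 2):
                img = render_capture(shape, model, visit, cohort_seed)
                fname = f"s{sid:04d}_v{visit}_{model.condition_name}.png"
                save_png(img, out_dir / fname)
                records.append((sid, visit, model.condition_name, fname))
    manifest = CohortManifest(records=records, cohort_seed=cohort_seed,
                              root=str(out_dir))
    manifest.validate()
    from .io import write_manifest  # local import avoids a cycle
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
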