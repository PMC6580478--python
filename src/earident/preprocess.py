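"""Image preprocessing: grayscale conversion, auto/fixed cropping, resizing.

All images flowing through the pipeline are single-precision grayscale
arrays with intensities in [0, 1], row/col indexed, origin at the top-left.
Standardized captures carry a dark device-aperture annulus whose interior
is recovered by :func:`auto_crop_aperture`; unstandardized captures fall
back to a fixed window (:func:`fixed_crop`) because the ear's position in
the frame is not controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

#: ITU-R BT.601 luma weights, the conventional RGB -> gray projection.
BT601_WEIGHTS: Tuple[float, float, float] = (0.299, 0.587, 0.114)

MIN_IMAGE_SIDE = 32


class FormatError(ValueError):
    """Raster has an unsupported channel layout."""


class RingDetectionError(RuntimeError):
    """No device-aperture annulus could be located in the image."""


class InvalidCropError(ValueError):
    """Requested crop window does not fit inside the image."""


@dataclass
class EarImage:
    """A grayscale ear capture plus its identity/visit/condition metadata.

    ``pixels`` is a float32 array with values in [0, 1]. ``meta`` carries
    optional generator ground truth (aperture geometry, ear bounding box,
    drawn nuisance parameters) used by tests and audits, never by the
    matching pipeline itself.
    """

    pixels: np.ndarray
    subject_id: int = 0
    visit: int = 1
    condition_name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2:
            raise FormatError(f"EarImage pixels must be 2-D, got shape {px.shape}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def key(self) -> Tuple[int, int, str]:
        return (self.subject_id, self.visit, self.condition_name)


@dataclass(frozen=True)
class CropSpec:
    """A fixed crop window: vertical ``length`` (ear length) by horizontal
    ``width`` (ear width), centered on ``anchor`` (row, col) or the frame
    center when anchor is "auto"."""

    length: int
    width: int
    anchor: object = "auto"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise InvalidCropError("crop length and width must be strictly positive")


def to_grayscale_single(
    raster: np.ndarray,
    channel_weights: Tuple[float, float, float] = BT601_WEIGHTS,
    *,
    subject_id: int = 0,
    visit: int = 1,
    condition_name: str = "",
) -> EarImage:
    """Convert a 1- or 3-channel raster to a single-precision gray image in [0, 1].

    Integer rasters are rescaled by their dtype maximum; float rasters are
    assumed to already live in [0, 1] and are clipped. Single-channel input
    passes through without applying ``channel_weights``.
    """
    arr = np.asarray(raster)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 2:
        gray = arr.astype(np.float64)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(channel_weights, dtype=np.float64)
        gray = arr.astype(np.float64) @ w
    else:
        raise FormatError(f"unsupported raster shape {arr.shape}; need 1 or 3 channels")
    if np.issubdtype(arr.dtype, np.integer):
        gray = gray / float(np.iinfo(arr.dtype).max)
    gray = np.clip(gray, 0.0, 1.0)
    return EarImage(gray.astype(np.float32), subject_id=subject_id, visit=visit,
                    condition_name=condition_name)


def _inscribed_disc_mask(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = min(h, w) / 2.0
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r


def auto_crop_aperture(
    image: EarImage,
    dark_fraction: float = 0.25,
    min_interior_fraction: float = 0.05,
) -> EarImage:
    """Crop to the interior of the dark device-aperture annulus.

    The detector thresholds pixels darker than ``dark_fraction`` of the
    frame mean, takes the largest connected dark component, and requires it
    to enclose a hole (annular topology). The returned image is the
    bounding box of that hole. A second application returns its input
    unchanged: after cropping, the residual dark corner arcs no longer
    enclose the frame center, which is the already-cropped signature.

    Raises :class:`RingDetectionError` when no annulus is found and the
    image does not look already cropped.
    """
    px = image.pixels
    thresh = dark_fraction * float(px.mean())
    dark = px < thresh
    labels, n = ndimage.label(dark)
    if n > 0:
        sizes = ndimage.sum_labels(np.ones_like(px), labels, index=np.arange(1, n + 1))
        comp = labels == (1 + int(np.argmax(sizes)))
        filled = ndimage.binary_fill_holes(comp)
        hole = filled & ~comp
        # keep only the largest hole: sensor-noise speckles inside the ring
        # also register as (tiny) holes and must not widen the box
        hlab, hn = ndimage.label(hole)
        if hn > 0:
            hsizes = ndimage.sum_labels(np.ones_like(px), hlab,
                                        index=np.arange(1, hn + 1))
            hole = hlab == (1 + int(np.argmax(hsizes)))
        if hole.sum() >= min_interior_fraction * px.size:
            rows = np.any(hole, axis=1).nonzero()[0]
            cols = np.any(hole, axis=0).nonzero()[0]
            r0, r1 = int(rows[0]), int(rows[-1]) + 1
            c0, c1 = int(cols[0]), int(cols[-1]) + 1
            out = replace(image, pixels=px[r0:r1, c0:c1].copy())
            out.meta = dict(image.meta)
            out.meta["crop_origin"] = (r0, c0)
            return out
    # Already-cropped signature: frame corners (outside the inscribed disc)
    # are predominantly dark ring remnants while the disc itself is not.
    disc = _inscribed_disc_mask(px.shape)
    corners = ~disc
    if corners.any() and disc.any():
        if float(px[corners].mean()) < dark_fraction * 1.6 * float(px[disc].mean()):
            return image
    raise RingDetectionError(
        "no aperture annulus detected; image was likely captured without the device"
    )


def fixed_crop(image: EarImage, spec: CropSpec) -> EarImage:
    """Extract the ``spec.length`` x ``spec.width`` window centered at the
    anchor (frame center when anchor="auto"). No resampling is done."""
    h, w = image.pixels.shape
    if spec.length > h or spec.width > w:
        raise InvalidCropError(
            f"crop {spec.length}x{spec.width} exceeds image {h}x{w}"
        )
    if isinstance(spec.anchor, str) and spec.anchor == "auto":
        ar, ac = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        ar, ac = float(spec.anchor[0]), float(spec.anchor[1])
    r0 = int(round(ar - spec.length / 2.0))
    c0 = int(round(ac - spec.width / 2.0))
    r0 = min(max(r0, 0), h - spec.length)
    c0 = min(max(c0, 0), w - spec.width)
    out = replace(image, pixels=image.pixels[r0:r0 + spec.length, c0:c0 + spec.width].copy())
    out.meta = dict(image.meta)
    out.meta["crop_origin"] = (r0, c0)
    return out


def resize(image: EarImage, target_long_side: int) -> EarImage:
    """Resize so the long side equals ``target_long_side``, preserving the
    aspect ratio, with bilinear interpolation (anti-aliased on downscale)."""
    if target_long_side < MIN_IMAGE_SIDE:
        raise ValueError(f"target_long_side must be >= {MIN_IMAGE_SIDE}")
    h, w = image.pixels.shape
    long_side = max(h, w)
    if long_side == target_long_side:
        return image
    scale = target_long_side / long_side
    new_h = target_long_side if h >= w else max(1, int(round(h * scale)))
    new_w = target_long_side if w > h else max(1, int(round(w * scale)))
    px = _sk_resize(
        image.pixels, (new_h, new_w), order=1,
        anti_aliasing=scale < 1.0, preserve_range=True,
    )
    out = replace(image, pixels=np.clip(px, 0.0, 1.0).astype(np.float32))
    out.meta = dict(image.meta)
    out.meta["resize_scale"] = scale
    return out
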