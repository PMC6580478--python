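"""Scale-invariant local features (keypoints + 128-d descriptors).

A native implementation of the classic difference-of-Gaussian / gradient-
orientation-histogram feature transform: Gaussian scale-space pyramid,
3x3x3 DoG extremum detection with sub-pixel refinement, contrast and
edge-response (principal-curvature ratio) filtering, orientation
assignment from a 36-bin gradient histogram, and 4x4x8 Gaussian-weighted
descriptors clamped at 0.2 and renormalized to unit length.

Extraction is deterministic: no randomness anywhere. A "reference"
backend dispatches to scikit-image's extractor with matched parameters
and is used as an independent audit of the native detector, never as the
pipeline default.

Coordinates are row/col in the input image frame, 0-based, sub-pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import EarImage

logger = logging.getLogger(__name__)

DESCRIPTOR_SIZE = 128
_DESC_WIDTH = 4     # spatial grid
_DESC_BINS = 8      # orientation bins
_ORI_BINS = 36
_ORI_SIGMA_FACTOR = 1.5
_ORI_PEAK_RATIO = 0.8


class ConfigurationError(ValueError):
    """Scale-space request inconsistent with the image size."""


@dataclass(frozen=True)
class SiftParams:
    """Tunable extraction parameters (octave 0 is the input resolution)."""

    n_octaves: int = 4
    scales_per_octave: int = 3
    base_sigma: float = 1.6
    assumed_blur: float = 0.5        # blur already present in the input
    contrast_threshold: float = 0.03  # on [0,1] intensities, per Lowe's convention
    edge_ratio: float = 10.0
    descriptor_clamp: float = 0.2
    refine: bool = True               # sub-pixel quadratic refinement of extrema


@dataclass
class Keypoint:
    row: float
    col: float
    scale: float          # absolute Gaussian sigma in input pixels
    orientation: float    # degrees in [0, 360)
    response: float = 0.0
    octave: int = 0
    layer: int = 0
    octave_row: float = 0.0
    octave_col: float = 0.0
    octave_sigma: float = 0.0


@dataclass
class FeatureSet:
    """Parallel keypoint/descriptor lists for one image."""

    image_key: Tuple[int, int, str]
    keypoints: List[Keypoint]
    descriptors: np.ndarray  # (n, 128) float32, unit rows

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float32)
        if self.descriptors.size == 0:
            self.descriptors = self.descriptors.reshape(0, DESCRIPTOR_SIZE)
        if len(self.keypoints) != self.descriptors.shape[0]:
            raise ValueError("keypoints and descriptors must be parallel")

    def __len__(self) -> int:
        return len(self.keypoints)

    def to_text(self) -> str:
        """One row per keypoint: row,col,scale,orientation,128 values."""
        lines = []
        for kp, d in zip(self.keypoints, self.descriptors):
            head = f"{kp.row:.4f},{kp.col:.4f},{kp.scale:.4f},{kp.orientation:.4f}"
            lines.append(head + "," + ",".join(f"{v:.6f}" for v in d))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str, image_key=(0, 1, "")) -> "FeatureSet":
        kps, descs = [], []
        for line in text.splitlines():
            if not line.strip():
                continue
            vals = [float(v) for v in line.split(",")]
            kps.append(Keypoint(row=vals[0], col=vals[1], scale=vals[2],
                                orientation=vals[3]))
            descs.append(vals[4:])
        arr = np.asarray(descs, dtype=np.float32).reshape(len(kps), DESCRIPTOR_SIZE)
        return cls(image_key=image_key, keypoints=kps, descriptors=arr)


@dataclass
class ScaleSpace:
    gaussians: List[np.ndarray]   # per octave: (s+3, H, W)
    dogs: List[np.ndarray]        # per octave: (s+2, H, W)
    params: SiftParams

    @property
    def n_octaves(self) -> int:
        return len(self.gaussians)


def build_scale_space(image: EarImage | np.ndarray,
                      n_octaves: int = 4,
                      scales_per_octave: int = 3,
                      base_sigma: float = 1.6,
                      assumed_blur: float = 0.5) -> ScaleSpace:
    """Build the Gaussian and difference-of-Gaussian pyramids.

    Each octave holds ``scales_per_octave + 3`` Gaussian planes (sigmas
    ``base_sigma * 2**(i/s)``) and ``scales_per_octave + 2`` DoG planes
    from adjacent subtraction; octaves downsample by 2.
    """
    px = image.pixels if isinstance(image, EarImage) else np.asarray(image)
    px = px.astype(np.float32)
    if max(px.shape) < 32:
        raise ConfigurationError("image long side must be >= 32")
    if min(px.shape) < 2 ** (n_octaves - 1) * 8:
        raise ConfigurationError(
            f"image {px.shape} too small for {n_octaves} octaves"
        )
    s = scales_per_octave
    k = 2.0 ** (1.0 / s)
    sigmas = base_sigma * k ** np.arange(s + 3)
    # incremental blurs within an octave
    increments = np.sqrt(np.maximum(sigmas[1:] ** 2 - sigmas[:-1] ** 2, 0.0))

    base = px
    if base_sigma > assumed_blur:
        base = ndimage.gaussian_filter(
            base, np.sqrt(base_sigma ** 2 - assumed_blur ** 2))
    gaussians, dogs = [], []
    for o in range(n_octaves):
        levels = [base]
        for inc in increments:
            levels.append(ndimage.gaussian_filter(levels[-1], inc))
        g = np.stack(levels)
        gaussians.append(g)
        dogs.append(g[1:] - g[:-1])
        # level s has sigma 2*base_sigma: the next octave's base
        base = g[s][::2, ::2]
    params = SiftParams(n_octaves=n_octaves, scales_per_octave=s,
                        base_sigma=base_sigma, assumed_blur=assumed_blur)
    return ScaleSpace(gaussians=gaussians, dogs=dogs, params=params)


def _octave_gradients(g_level: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    dr = np.zeros_like(g_level)
    dc = np.zeros_like(g_level)
    dr[1:-1, :] = 0.5 * (g_level[2:, :] - g_level[:-2, :])
    dc[:, 1:-1] = 0.5 * (g_level[:, 2:] - g_level[:, :-2])
    mag = np.sqrt(dr ** 2 + dc ** 2)
    ang = np.arctan2(dr, dc)  # angle of the gradient in row/col frame
    return mag, ang


def _refine_extrema(D: np.ndarray, j: np.ndarray, y: np.ndarray, x: np.ndarray,
                    n_iter: int = 3):
    """Vectorized quadratic refinement of DoG extrema.

    Returns (j, y, x, offsets(n,3), value_at_peak, keep_mask). Offsets are
    in (scale, row, col) order.
    """
    n_layers, H, W = D.shape
    keep = np.ones(len(j), dtype=bool)
    off = np.zeros((len(j), 3))
    val = np.zeros(len(j))
    for it in range(n_iter):
        g_s = 0.5 * (D[j + 1, y, x] - D[j - 1, y, x])
        g_y = 0.5 * (D[j, y + 1, x] - D[j, y - 1, x])
        g_x = 0.5 * (D[j, y, x + 1] - D[j, y, x - 1])
        c = D[j, y, x]
        h_ss = D[j + 1, y, x] + D[j - 1, y, x] - 2 * c
        h_yy = D[j, y + 1, x] + D[j, y - 1, x] - 2 * c
        h_xx = D[j, y, x + 1] + D[j, y, x - 1] - 2 * c
        h_sy = 0.25 * (D[j + 1, y + 1, x] - D[j + 1, y - 1, x]
                       - D[j - 1, y + 1, x] + D[j - 1, y - 1, x])
        h_sx = 0.25 * (D[j + 1, y, x + 1] - D[j + 1, y, x - 1]
                       - D[j - 1, y, x + 1] + D[j - 1, y, x - 1])
        h_yx = 0.25 * (D[j, y + 1, x + 1] - D[j, y + 1, x - 1]
                       - D[j, y - 1, x + 1] + D[j, y - 1, x - 1])
        A = np.empty((len(j), 3, 3))
        A[:, 0, 0], A[:, 0, 1], A[:, 0, 2] = h_ss, h_sy, h_sx
        A[:, 1, 0], A[:, 1, 1], A[:, 1, 2] = h_sy, h_yy, h_yx
        A[:, 2, 0], A[:, 2, 1], A[:, 2, 2] = h_sx, h_yx, h_xx
        b = -np.stack([g_s, g_y, g_x], axis=1)
        det = np.linalg.det(A)
        ok = np.abs(det) > 1e-12
        off = np.zeros_like(b)
        if ok.any():
            off[ok] = np.linalg.solve(A[ok], b[ok, :, None])[:, :, 0]
        keep &= ok
        val = c - 0.5 * (b * off).sum(axis=1)  # c + 0.5 * gradient . offset
        moved = (np.abs(off) > 0.6).any(axis=1) & keep
        if it == n_iter - 1 or not moved.any():
            break
        j = np.where(moved, np.clip(j + np.round(off[:, 0]).astype(int),
                                    1, n_layers - 2), j)
        y = np.where(moved, np.clip(y + np.round(off[:, 1]).astype(int),
                                    1, H - 2), y)
        x = np.where(moved, np.clip(x + np.round(off[:, 2]).astype(int),
                                    1, W - 2), x)
    keep &= (np.abs(off) < 1.5).all(axis=1)
    return j, y, x, off, val, keep


def detect_keypoints(space: ScaleSpace,
                     contrast_threshold: float = 0.03,
                     edge_ratio: float = 10.0,
                     refine: bool = True) -> List[Keypoint]:
    """Find scale-space extrema and assign orientations.

    Extrema are 3x3x3 local max/min of the DoG stack, refined to sub-pixel
    position, kept when the interpolated |DoG| exceeds the per-layer
    contrast threshold and the principal-curvature ratio test passes.
    Secondary orientation peaks >= 80% of the dominant one duplicate the
    keypoint.
    """
    s = space.params.scales_per_octave
    k = 2.0 ** (1.0 / s)
    base_sigma = space.params.base_sigma
    # Lowe applies 0.03 assuming s=3 spacing; scale per-layer like OpenCV
    layer_thresh = contrast_threshold / s
    edge_limit = (edge_ratio + 1.0) ** 2 / edge_ratio

    keypoints: List[Keypoint] = []
    for o, D in enumerate(space.dogs):
        n_layers, H, W = D.shape
        if H < 8 or W < 8:
            continue
        interior = D[1:-1]
        maxf = ndimage.maximum_filter(D, size=3, mode="nearest")[1:-1]
        minf = ndimage.minimum_filter(D, size=3, mode="nearest")[1:-1]
        pre = 0.5 * layer_thresh
        cand = ((interior >= maxf) & (interior > pre)) | \
               ((interior <= minf) & (interior < -pre))
        cand[:, :1, :] = cand[:, -1:, :] = False
        cand[:, :, :1] = cand[:, :, -1:] = False
        jj, yy, xx = np.nonzero(cand)
        if len(jj) == 0:
            continue
        jj = jj + 1
        if refine:
            jj, yy, xx, off, val, keep = _refine_extrema(D, jj, yy, xx)
        else:
            off = np.zeros((len(jj), 3))
            val = D[jj, yy, xx]
            keep = np.ones(len(jj), dtype=bool)
        keep &= np.abs(val) >= layer_thresh
        # edge response on the 2x2 spatial Hessian
        c = D[jj, yy, xx]
        h_yy = D[jj, yy + 1, xx] + D[jj, yy - 1, xx] - 2 * c
        h_xx = D[jj, yy, xx + 1] + D[jj, yy, xx - 1] - 2 * c
        h_yx = 0.25 * (D[jj, yy + 1, xx + 1] - D[jj, yy + 1, xx - 1]
                       - D[jj, yy - 1, xx + 1] + D[jj, yy - 1, xx - 1])
        tr = h_yy + h_xx
        det = h_yy * h_xx - h_yx ** 2
        keep &= (det > 0) & (tr ** 2 / np.where(det > 0, det, 1.0) < edge_limit)

        jj, yy, xx, off, val = jj[keep], yy[keep], xx[keep], off[keep], val[keep]
        scale_px = float(2 ** o)
        grads = {}
        for i in range(len(jj)):
            layer = int(jj[i])
            sig_oct = base_sigma * k ** (jj[i] + off[i, 0])
            r_oct = yy[i] + off[i, 1]
            c_oct = xx[i] + off[i, 2]
            if layer not in grads:
                grads[layer] = _octave_gradients(space.gaussians[o][layer])
            mag, ang = grads[layer]
            oris = _orientation_peaks(mag, ang, r_oct, c_oct, sig_oct)
            for ori in oris:
                keypoints.append(Keypoint(
                    row=r_oct * scale_px, col=c_oct * scale_px,
                    scale=sig_oct * scale_px, orientation=ori,
                    response=float(abs(val[i])), octave=o, layer=layer,
                    octave_row=r_oct, octave_col=c_oct, octave_sigma=sig_oct,
                ))
    keypoints.sort(key=lambda kp: (kp.row, kp.col, kp.scale, kp.orientation))
    return keypoints


def _orientation_peaks(mag: np.ndarray, ang: np.ndarray, r: float, c: float,
                       sigma_oct: float) -> List[float]:
    H, W = mag.shape
    sig = _ORI_SIGMA_FACTOR * sigma_oct
    radius = int(round(3.0 * sig))
    r0, r1 = int(round(r)) - radius, int(round(r)) + radius + 1
    c0, c1 = int(round(c)) - radius, int(round(c)) + radius + 1
    r0c, r1c = max(r0, 1), min(r1, H - 1)
    c0c, c1c = max(c0, 1), min(c1, W - 1)
    if r0c >= r1c or c0c >= c1c:
        return []
    m = mag[r0c:r1c, c0c:c1c]
    a = ang[r0c:r1c, c0c:c1c]
    ys, xs = np.mgrid[r0c:r1c, c0c:c1c]
    w = np.exp(-((ys - r) ** 2 + (xs - c) ** 2) / (2 * sig ** 2))
    bins = np.floor((a + np.pi) / (2 * np.pi) * _ORI_BINS).astype(int) % _ORI_BINS
    hist = np.bincount(bins.ravel(), weights=(m * w).ravel(), minlength=_ORI_BINS)
    # circular smoothing, twice
    for _ in range(2):
        hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
    peak = hist.max()
    if peak <= 0:
        return []
    oris = []
    for b in range(_ORI_BINS):
        prev_, next_ = hist[(b - 1) % _ORI_BINS], hist[(b + 1) % _ORI_BINS]
        if hist[b] > prev_ and hist[b] > next_ and hist[b] >= _ORI_PEAK_RATIO * peak:
            denom = prev_ - 2 * hist[b] + next_
            interp = b + (0.5 * (prev_ - next_) / denom if denom != 0 else 0.0)
            # bin center -> angle: bin b spans [-pi + b*2pi/36, ...)
            theta = (interp + 0.5) / _ORI_BINS * 360.0
            oris.append(float(theta % 360.0))
    return oris


def compute_descriptors(space: ScaleSpace, keypoints: Sequence[Keypoint],
                        image_key: Tuple[int, int, str] = (0, 1, ""),
                        clamp: float = 0.2) -> FeatureSet:
    """Build 4x4x8 gradient-orientation descriptors for the keypoints.

    Samples Gaussian-weighted gradients in the keypoint's scale- and
    orientation-aligned frame, distributes them trilinearly over the
    spatial/orientation grid, clamps entries at ``clamp`` and renormalizes
    to unit Euclidean norm. Keypoints whose sampling window leaves the
    octave image are dropped (and counted in the log), not an error.
    """
    d, nb = _DESC_WIDTH, _DESC_BINS
    kept: List[Keypoint] = []
    descs: List[np.ndarray] = []
    grads: dict = {}
    dropped = 0
    for kp in keypoints:
        o, layer = kp.octave, kp.layer
        key = (o, layer)
        if key not in grads:
            grads[key] = _octave_gradients(space.gaussians[o][layer])
        mag, ang = grads[key]
        H, W = mag.shape
        hist_width = 3.0 * kp.octave_sigma
        radius = int(round(hist_width * np.sqrt(2) * (d + 1) * 0.5))
        r, c = kp.octave_row, kp.octave_col
        ri, ci = int(round(r)), int(round(c))
        if ri - radius < 1 or ri + radius >= H - 1 or \
           ci - radius < 1 or ci + radius >= W - 1:
            dropped += 1
            continue
        ys, xs = np.mgrid[ri - radius:ri + radius + 1,
                          ci - radius:ci + radius + 1]
        dy = ys - r
        dx = xs - c
        theta = np.deg2rad(kp.orientation)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        # rotate into the keypoint frame (row/col): orientation angle is the
        # gradient angle measured from +col toward +row
        rot_r = (-sin_t * dx + cos_t * dy) / hist_width
        rot_c = (cos_t * dx + sin_t * dy) / hist_width
        rbin = rot_r + d / 2 - 0.5
        cbin = rot_c + d / 2 - 0.5
        inside = (rbin > -1) & (rbin < d) & (cbin > -1) & (cbin < d)
        if not inside.any():
            dropped += 1
            continue
        m = mag[ys, xs][inside]
        a = ang[ys, xs][inside]
        rbin, cbin = rbin[inside], cbin[inside]
        w = np.exp(-(rot_r[inside] ** 2 + rot_c[inside] ** 2) / (0.5 * d ** 2))
        obin = ((a - theta) / (2 * np.pi) * nb) % nb
        hist = np.zeros((d + 2, d + 2, nb))
        r0 = np.floor(rbin).astype(int)
        c0 = np.floor(cbin).astype(int)
        o0 = np.floor(obin).astype(int)
        fr, fc, fo = rbin - r0, cbin - c0, obin - o0
        wm = m * w
        for dr_ in (0, 1):
            wr = wm * (fr if dr_ else 1 - fr)
            for dc_ in (0, 1):
                wc = wr * (fc if dc_ else 1 - fc)
                for do_ in (0, 1):
                    wo = wc * (fo if do_ else 1 - fo)
                    np.add.at(hist, (r0 + dr_ + 1, c0 + dc_ + 1,
                                     (o0 + do_) % nb), wo)
        vec = hist[1:-1, 1:-1, :].ravel()
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            dropped += 1
            continue
        vec = np.minimum(vec / norm, clamp)
        vec /= max(np.linalg.norm(vec), 1e-12)
        kept.append(kp)
        descs.append(vec.astype(np.float32))
    if dropped:
        logger.debug("dropped %d keypoints too close to the border", dropped)
    arr = np.asarray(descs, dtype=np.float32).reshape(len(kept), DESCRIPTOR_SIZE)
    fs = FeatureSet(image_key=image_key, keypoints=kept, descriptors=arr)
    fs.dropped_keypoints = dropped
    return fs


def _extract_native(image: EarImage, params: SiftParams) -> FeatureSet:
    space = build_scale_space(image, params.n_octaves, params.scales_per_octave,
                              params.base_sigma, params.assumed_blur)
    kps = detect_keypoints(space, params.contrast_threshold, params.edge_ratio,
                           params.refine)
    return compute_descriptors(space, kps, image_key=image.key,
                               clamp=params.descriptor_clamp)


def _extract_reference(image: EarImage, params: SiftParams) -> FeatureSet:
    from skimage.feature import SIFT as _SkSIFT

    det = _SkSIFT(
        upsampling=1,
        n_octaves=params.n_octaves,
        n_scales=params.scales_per_octave,
        sigma_min=params.base_sigma,
        sigma_in=params.assumed_blur,
        c_dog=params.contrast_threshold / params.scales_per_octave,
        c_edge=params.edge_ratio,
    )
    try:
        det.detect_and_extract(image.pixels.astype(np.float64))
    except RuntimeError:
        return FeatureSet(image.key, [], np.zeros((0, DESCRIPTOR_SIZE)))
    kps = [
        Keypoint(row=float(p[0]), col=float(p[1]), scale=float(s),
                 orientation=float(np.degrees(o) % 360.0))
        for p, s, o in zip(det.positions, det.sigmas, det.orientations)
    ]
    desc = det.descriptors.astype(np.float32)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    desc = desc / np.maximum(norms, 1e-12)
    return FeatureSet(image.key, kps, desc)


def extract(image: EarImage, backend: str = "native",
            params: Optional[SiftParams] = None) -> FeatureSet:
    """Extract a :class:`FeatureSet` with the chosen backend.

    ``backend`` is "native" (this module's implementation, the pipeline
    default) or "reference" (scikit-image, for independent auditing).
    """
    params = params or SiftParams()
    if backend == "native":
        return _extract_native(image, params)
    if backend == "reference":
        return _extract_reference(image, params)
    raise ValueError(f"unknown backend {backend!r}; use 'native' or 'reference'")
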