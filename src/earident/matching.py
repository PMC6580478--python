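"""Descriptor matching and gallery ranking.

An image pair is scored by the number of accepted descriptor
correspondences: each probe descriptor is matched to its nearest gallery
descriptor by Euclidean distance, accepted when the Lowe ratio
(nearest / second-nearest) falls below the threshold, and correspondences
are made one-to-one by greedy acceptance in ascending nearest-distance
order. A probe identifies against a gallery by ranking gallery images by
this match count, descending; ties break on ascending (subject_id, visit)
so the ranking is independent of gallery input order.

The ratio test is directional — score(probe, gallery) need not equal
score(gallery, probe); the evaluation layer runs both directions
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .features import FeatureSet

DEFAULT_RATIO = 0.75

ImageKey = Tuple[int, int, str]


@dataclass(frozen=True)
class PairScore:
    probe_key: ImageKey
    gallery_key: ImageKey
    n_matches: int


@dataclass
class RankedMatches:
    """Full descending ranking of the gallery for one probe."""

    probe_key: ImageKey
    ranking: List[Tuple[ImageKey, int]]  # (gallery_key, n_matches), descending

    def top(self, k: int) -> List[Tuple[ImageKey, int]]:
        return self.ranking[:k]

    @property
    def best(self) -> Tuple[ImageKey, int]:
        return self.ranking[0]


def _accepted_correspondences(
    probe_desc: np.ndarray,
    gallery_desc: np.ndarray,
    ratio_threshold: float,
    same_image: bool,
) -> List[Tuple[int, int, float]]:
    """Candidate (probe_idx, gallery_idx, distance) triples passing the
    ratio test, before one-to-one enforcement."""
    n_p, n_g = len(probe_desc), len(gallery_desc)
    if n_p == 0 or n_g == 0:
        return []
    # squared Euclidean distances; unit descriptors keep values well-scaled
    d2 = (
        np.sum(probe_desc ** 2, axis=1)[:, None]
        + np.sum(gallery_desc ** 2, axis=1)[None, :]
        - 2.0 * probe_desc @ gallery_desc.T
    )
    np.maximum(d2, 0.0, out=d2)
    if not same_image:
        nn = np.argmin(d2, axis=1)
        d1 = np.sqrt(d2[np.arange(n_p), nn])
        if n_g == 1:
            # no second neighbor exists; the single candidate is accepted
            return [(i, int(nn[i]), float(d1[i])) for i in range(n_p)]
        two = np.sqrt(np.partition(d2, 1, axis=1)[:, :2])
        d2nd = two[:, 1]
        ok = np.where(d2nd > 0.0, d1 < ratio_threshold * d2nd, d1 <= 0.0)
        return [(i, int(nn[i]), float(d1[i])) for i in np.nonzero(ok)[0]]
    cand: List[Tuple[int, int, float]] = []
    for i in range(n_p):
        row = d2[i]
        nn_i = int(np.argmin(row))
        d1_i = float(np.sqrt(row[nn_i]))
        # second nearest; for a self-comparison, exclude the identical index
        # so the ratio at the duplicate descriptor stays well-defined
        mask_idx = {nn_i, i}
        if n_g <= len(mask_idx):
            cand.append((i, nn_i, d1_i))  # single usable candidate: accept
            continue
        row2 = row.copy()
        row2[nn_i] = np.inf
        row2[i] = np.inf
        d2nd = float(np.sqrt(row2.min()))
        if d2nd <= 0.0:
            if d1_i <= 0.0:
                cand.append((i, nn_i, d1_i))
            continue
        if d1_i / d2nd < ratio_threshold:
            cand.append((i, nn_i, d1_i))
    return cand


def match_descriptors(
    probe: FeatureSet,
    gallery_image: FeatureSet,
    ratio_threshold: float = DEFAULT_RATIO,
) -> PairScore:
    """Count accepted one-to-one descriptor correspondences.

    Empty feature sets yield zero. When probe and gallery are the same
    image, the second-nearest distance excludes the identical-index
    descriptor, so self-matching scores the full descriptor count.
    """
    if not (0.0 < ratio_threshold < 1.0):
        raise ValueError("ratio_threshold must lie in (0, 1)")
    same = probe.image_key == gallery_image.image_key and \
        len(probe) == len(gallery_image)
    cand = _accepted_correspondences(
        probe.descriptors, gallery_image.descriptors, ratio_threshold, same)
    cand.sort(key=lambda t: (t[2], t[0], t[1]))
    used_p, used_g = set(), set()
    n = 0
    for pi, gi, _ in cand:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        n += 1
    return PairScore(probe_key=probe.image_key,
                     gallery_key=gallery_image.image_key, n_matches=n)


def rank_gallery(
    probe: FeatureSet,
    gallery: Sequence[FeatureSet],
    ratio_threshold: float = DEFAULT_RATIO,
) -> RankedMatches:
    """Score the probe against every gallery image and rank descending.

    Ties break on ascending (subject_id, visit) of the gallery key, so the
    result does not depend on gallery input order. Duplicate gallery keys
    are a malformed gallery.
    """
    if len(gallery) == 0:
        raise ValueError("gallery must be non-empty")
    keys = [g.image_key for g in gallery]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate gallery keys: gallery is malformed")
    scores = [match_descriptors(probe, g, ratio_threshold) for g in gallery]
    order = sorted(scores, key=lambda s: (-s.n_matches, s.gallery_key))
    return RankedMatches(probe_key=probe.image_key,
                         ranking=[(s.gallery_key, s.n_matches) for s in order])
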