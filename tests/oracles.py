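"""Independent brute-force oracles used by the tests.

Deliberately naive re-implementations (explicit loops, explicit sorts)
of the matching/ranking/identification rules, kept free of any code
shared with the package so they can audit it.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np


def brute_match_count(probe: np.ndarray, gallery: np.ndarray,
                      ratio: float, same_image: bool = False) -> int:
    """Accepted one-to-one correspondences, counted the slow way."""
    n_p, n_g = len(probe), len(gallery)
    if n_p == 0 or n_g == 0:
        return 0
    accepted: List[Tuple[float, int, int]] = []
    for i in range(n_p):
        dists = sorted(
            (math.dist(probe[i], gallery[j]), j) for j in range(n_g)
        )
        d1, j1 = dists[0]
        rest = [d for d, j in dists[1:] if not (same_image and j == i)]
        if not rest:
            accepted.append((d1, i, j1))
            continue
        d2 = rest[0]
        if d2 <= 0.0:
            if d1 <= 0.0:
                accepted.append((d1, i, j1))
            continue
        if d1 / d2 < ratio:
            accepted.append((d1, i, j1))
    accepted.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p, used_g = set(), set()
    count = 0
    for _, i, j in accepted:
        if i not in used_p and j not in used_g:
            used_p.add(i)
            used_g.add(j)
            count += 1
    return count


def brute_ranking(probe_desc: np.ndarray,
                  gallery: Sequence[Tuple[tuple, np.ndarray]],
                  ratio: float) -> List[Tuple[tuple, int]]:
    """Full descending ranking with (count desc, key asc) ordering."""
    scored = [(key, brute_match_count(probe_desc, desc, ratio))
              for key, desc in gallery]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def rates_from_score_matrix(matrix: "np.ndarray | object",
                            probe_subjects: Sequence[int],
                            gallery_subjects: Sequence[int],
                            k: int = 10) -> Tuple[int, int]:
    """(top1_correct, topk_correct) recomputed by re-sorting score rows.

    Ties break on ascending gallery subject id, mirroring the published
    deterministic rule.
    """
    mat = np.asarray(matrix)
    k = min(k, len(gallery_subjects))
    top1 = topk = 0
    for r, ps in enumerate(probe_subjects):
        order = sorted(range(len(gallery_subjects)),
                       key=lambda c: (-mat[r, c], gallery_subjects[c]))
        ranked_subjects = [gallery_subjects[c] for c in order]
        if ranked_subjects[0] == ps:
            top1 += 1
        if ps in ranked_subjects[:k]:
            topk += 1
    return top1, topk
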