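"""Similarity reduction over fixed-length windows at a 40% identity threshold.

Windows are already positionally registered on the central cysteine, so
identity is the ungapped fraction of matching positions — no pairwise
alignment is performed.  The retention rule is class-asymmetric: when a
positive window conflicts with a negative one, the negative is discarded;
conflicts within a class are resolved at random (seeded).
"""

from __future__ import annotations

import numpy as np

from .dataio import Segment


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions (gaps included) at which two windows agree."""
    if len(a) != len(b):
        raise ValueError(f"window lengths differ: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _window_matrix(segments: list[Segment]) -> np.ndarray:
    return np.frombuffer(
        "".join(s.window for s in segments).encode("ascii"), dtype=np.uint8
    ).reshape(len(segments), -1)


def reduce_redundancy(
    positives: list[Segment],
    negatives: list[Segment],
    threshold: float = 0.40,
    seed: int = 0,
) -> tuple[list[Segment], list[Segment]]:
    """Greedy removal so that no surviving pair exceeds ``threshold`` identity.

    Segments are scanned positives-first; a segment is kept iff its identity
    with every previously kept segment is <= threshold (strictly greater
    removes).  Scanning positives before negatives guarantees a cross-class
    conflict always drops the negative.  Within each class the scan order is
    a seeded permutation of a canonical sort, so the surviving member of a
    within-class conflict is random yet reproducible and independent of the
    input order.
    """
    lengths = {len(s.window) for s in positives + negatives}
    if len(lengths) > 1:
        raise ValueError(f"windows have mixed lengths: {sorted(lengths)}")
    rng = np.random.default_rng(seed)

    def seeded_order(cls: list[Segment]) -> list[Segment]:
        canonical = sorted(cls, key=lambda s: (s.window, s.protein_id, s.center_position))
        return [canonical[i] for i in rng.permutation(len(canonical))]

    kept_pos: list[Segment] = []
    kept_neg: list[Segment] = []
    n_total = len(positives) + len(negatives)
    L = next(iter(lengths)) if lengths else 0
    kept_buf = np.empty((n_total, L), dtype=np.uint8)
    n_kept = 0

    for cls, kept in ((seeded_order(positives), kept_pos), (seeded_order(negatives), kept_neg)):
        if not cls:
            continue
        cand_mat = _window_matrix(cls)
        for i, seg in enumerate(cls):
            if n_kept:
                ident = (kept_buf[:n_kept] == cand_mat[i]).mean(axis=1)
                if (ident > threshold).any():
                    continue
            kept.append(seg)
            kept_buf[n_kept] = cand_mat[i]
            n_kept += 1
    return kept_pos, kept_neg
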