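"""Match-score evaluation of found against hidden (planted) biclusters.

MS(B, H) = (1/|B|) * sum over (I1,J1) in B of max over (I2,J2) in H of the
Jaccard similarity |I1 ∩ I2| / |I1 ∪ I2| of the row sets.  MS(B, H) reads
as correctness of the found solution, MS(H, B) as completeness (how well
each hidden bicluster is recovered).  ``area`` mode replaces the row-set
Jaccard by a Jaccard over cell sets for diagnostics.
"""

from __future__ import annotations

from .matrix import BiclusterSet


def _row_jaccard(a, b) -> float:
    inter = len(a.rows & b.rows)
    union = len(a.rows | b.rows)
    return inter / union if union else 0.0


def _area_jaccard(a, b) -> float:
    inter = len(a.rows & b.rows) * len(a.cols & b.cols)
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def match_score(found: BiclusterSet, hidden: BiclusterSet, mode: str = "rows") -> float:
    """Average best-match Jaccard of ``found`` against ``hidden`` in [0, 1]."""
    if len(found) == 0 or len(hidden) == 0:
        raise ValueError("match score is undefined for empty bicluster sets")
    if mode == "rows":
        sim = _row_jaccard
    elif mode == "area":
        sim = _area_jaccard
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    for b in found:
        total += max(sim(b, h) for h in hidden)
    return total / len(found)
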