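"""Agreement between two PRS sets for the same samples.

Used to quantify how well scores computed from imputed exomes track the
scores from directly sequenced genomes: Spearman rank correlation, a
10x10 decile cross-classification matrix (each score set binned by its
own decile boundaries), the percentage of extreme-decile (top/bottom)
samples assigned to the same extreme decile by both sets, and the
percentage landing in the same or an adjacent decile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceReport:
    spearman_rho: float
    spearman_p: float
    decile_agreement: np.ndarray      # 10x10 counts, rows = set A deciles
    extreme_overlap_pct: float        # joint top+bottom overlap
    top_overlap_pct: float
    bottom_overlap_pct: float
    adjacent_pct: float
    n: int

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "decile_agreement": self.decile_agreement.tolist(),
            "extreme_overlap_pct": self.extreme_overlap_pct,
            "top_overlap_pct": self.top_overlap_pct,
            "bottom_overlap_pct": self.bottom_overlap_pct,
            "adjacent_pct": self.adjacent_pct,
            "n": self.n,
        }


def _own_deciles(scores: np.ndarray) -> np.ndarray:
    """Decile index per sample from the score set's own boundaries
    (left-open right-closed intervals)."""
    bounds = np.quantile(scores, np.arange(0.1, 1.0, 0.1))
    return np.searchsorted(bounds, scores, side="left")


def compare_scores(scores_a, scores_b) -> ConcordanceReport:
    """Concordance of two score sets over the same samples (paired order).

    Spearman uses average ranks for ties.  The extreme-decile overlap is
    computed over the union of set A's top and bottom deciles: the share of
    those samples placed in the same extreme decile by set B.  Top and
    bottom overlaps are also reported separately.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConcordanceError("score sets must be 1-D and of equal length")
    if len(a) < 3:
        raise ConcordanceError("need at least 3 paired samples")

    rho, p = stats.spearmanr(a, b)
    dec_a = _own_deciles(a)
    dec_b = _own_deciles(b)
    matrix = np.zeros((10, 10), dtype=int)
    np.add.at(matrix, (dec_a, dec_b), 1)

    top_a, bot_a = dec_a == 9, dec_a == 0
    top_hits = int(np.sum(top_a & (dec_b == 9)))
    bot_hits = int(np.sum(bot_a & (dec_b == 0)))
    n_top, n_bot = int(top_a.sum()), int(bot_a.sum())

    def pct(hits, n):
        return 100.0 * hits / n if n else float("nan")

    adjacent = np.abs(dec_a - dec_b) <= 1
    return ConcordanceReport(
        spearman_rho=float(rho),
        spearman_p=float(p),
        decile_agreement=matrix,
        extreme_overlap_pct=pct(top_hits + bot_hits, n_top + n_bot),
        top_overlap_pct=pct(top_hits, n_top),
        bottom_overlap_pct=pct(bot_hits, n_bot),
        adjacent_pct=pct(int(adjacent.sum()), len(a)),
        n=len(a),
    )
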