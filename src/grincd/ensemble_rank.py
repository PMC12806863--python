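"""Borda-style ensembling of the linear and nonlinear pipelines.

The two pipelines emit propensity matrices on different raw scales
(their HSIC statistics are not comparable), so before the lambda-weighted
vote each matrix is normalized.  The default ``rank`` normalization is a
true Borda count: centered average ranks over all admissible entries of
one matrix.  It is a globally monotone transform, so a single-pipeline
limit (lambda -> 0 or 1) reproduces that pipeline's ranking exactly and
the combination is invariant to any strictly monotone rescaling of
either input.  ``rank-block`` ranks the TF-TF and TF-TG blocks
separately; within the TF-TF block the score multiset is symmetric
around zero (antisymmetry), so the per-block centered ranks are an odd
transform there and the combined matrix keeps exact TF-TF antisymmetry,
at the price of re-calibrating the two blocks against each other.
``minmax`` and ``none`` reproduce a literal weighted sum of (rescaled)
raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .causal_anm import PropensityMatrix
from .core_io import GeneRoster, RankedEdgeList

__all__ = [
    "EnsembleConfig",
    "normalize_propensity",
    "ensemble",
    "rank_edges",
    "topk_intersection",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Weight of the linear pipeline and the pre-combination normalization."""

    lambda_: float = 0.5
    normalization: str = "rank"  # rank | rank-block | minmax | none

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_ < 1.0:
            raise ValueError("lambda must lie strictly inside (0, 1)")
        if self.normalization not in ("rank", "rank-block", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _admissible_mask(roster: GeneRoster) -> np.ndarray:
    mask = np.ones((roster.n_tfs, roster.n_genes), dtype=bool)
    for i in range(roster.n_tfs):
        mask[i, i] = False  # self-pairs
    return mask


def normalize_propensity(W: PropensityMatrix, mode: str) -> np.ndarray:
    """Return normalized score values (same shape), diagonal kept at zero."""
    values = W.values.copy()
    roster = W.roster
    n_tfs = roster.n_tfs
    if mode == "none":
        return values
    if mode == "minmax":
        mask = _admissible_mask(roster)
        lo, hi = values[mask].min(), values[mask].max()
        span = hi - lo if hi > lo else 1.0
        out = (values - lo) / span
        out[~mask] = 0.0
        return out
    if mode == "rank":
        # centered average ranks in (-1/2, 1/2) over all admissible entries
        mask = _admissible_mask(roster)
        out = np.zeros_like(values)
        vals = values[mask]
        r = rankdata(vals, method="average")
        out[mask] = (r - (vals.size + 1) / 2.0) / vals.size
        return out
    if mode == "rank-block":
        out = np.zeros_like(values)
        # per-block centered average ranks; odd on the TF-TF block because
        # its antisymmetric value multiset is symmetric around zero
        tf_mask = _admissible_mask(roster)[:, :n_tfs]
        blocks = [(np.s_[:, :n_tfs], tf_mask)]
        if roster.n_genes > n_tfs:
            tg_mask = np.ones((n_tfs, roster.n_genes - n_tfs), dtype=bool)
            blocks.append((np.s_[:, n_tfs:], tg_mask))
        for sl, mask in blocks:
            vals = values[sl][mask]
            if vals.size == 0:
                continue
            r = rankdata(vals, method="average")
            centered = (r - (vals.size + 1) / 2.0) / vals.size
            block = np.zeros_like(values[sl])
            block[mask] = centered
            out[sl] = block
        return out
    raise ValueError(f"unknown normalization {mode!r}")


def ensemble(
    w_linear: PropensityMatrix,
    w_nonlinear: PropensityMatrix,
    cfg: EnsembleConfig = EnsembleConfig(),
) -> PropensityMatrix:
    """lambda * norm(W_linear) + (1 - lambda) * norm(W_nonlinear)."""
    if w_linear.roster != w_nonlinear.roster:
        raise ValueError("pipelines were scored over different rosters")
    a = normalize_propensity(w_linear, cfg.normalization)
    b = normalize_propensity(w_nonlinear, cfg.normalization)
    combined = cfg.lambda_ * a + (1.0 - cfg.lambda_) * b
    for i in range(w_linear.roster.n_tfs):
        combined[i, i] = 0.0
    return PropensityMatrix(values=combined, roster=w_linear.roster)


def rank_edges(W: PropensityMatrix) -> RankedEdgeList:
    """All admissible pairs sorted by descending score.

    Ties break lexicographically on (regulator, target) so output files
    are byte-reproducible.
    """
    roster = W.roster
    rows = []
    for i, tf in enumerate(roster.tfs):
        for j, gene in enumerate(roster.all_genes):
            if gene == tf:
                continue
            rows.append((tf, gene, float(W.values[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return RankedEdgeList(rows=tuple(rows))


def topk_intersection(
    list_a: RankedEdgeList, list_b: RankedEdgeList, k: int
) -> int:
    """Size of the intersection of the two top-k (regulator, target) sets."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(len(list_a), len(list_b)):
        raise ValueError("k exceeds a list length")
    return len(list_a.top_k_pairs(k) & list_b.top_k_pairs(k))
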