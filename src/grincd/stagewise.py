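"""Stage-wise monotonicity screen and driver-TF ranking.

Given per-stage propensity matrices inferred independently for an
ordered sequence of biological conditions (for example normal ->
inflammation -> adenoma -> carcinoma), a regulatory relation is flagged
*monotonically increasing* when its normalized score never drops between
consecutive stages and its total change reaches a threshold (default
0.15); decreasing is symmetric.  Raw HSIC-difference scores are not
comparable across datasets, so before screening all stages are mapped
onto one [0, 1] scale.  The default is a min-max rescaling with the
range *pooled over all stages*: a per-stage scale would let one
strengthening relation shrink everyone else's scores, and a rank
transform (available as ``normalize="rank"``, pooled likewise) amplifies
estimator noise among the many near-zero non-edge scores, where ranks
are nearly tied.  ``normalize="none"`` screens raw scores.

Transcription factors are then ranked by how many monotone relations
they regulate — regulators of many progression-coupled relations are
candidate drivers of the disease transition.  Differential-expression
prefiltering of the gene universe happens upstream; this module accepts
whatever roster it is given.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .causal_anm import PropensityMatrix
from .core_io import GeneRoster

__all__ = [
    "StageScores",
    "MonotoneRelation",
    "monotone_screen",
    "driver_tf_ranking",
]

DEFAULT_MONOTONICITY_THRESHOLD = 0.15


@dataclass(frozen=True)
class StageScores:
    """Per-stage propensity scores over a shared roster, in stage order."""

    stage_labels: tuple[str, ...]
    matrices: tuple[PropensityMatrix, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_labels", tuple(self.stage_labels))
        object.__setattr__(self, "matrices", tuple(self.matrices))
        if len(self.stage_labels) != len(self.matrices):
            raise ValueError("one label per stage matrix is required")
        if len(self.matrices) < 2:
            raise ValueError("need at least two stages")
        roster = self.matrices[0].roster
        for mat in self.matrices[1:]:
            if mat.roster != roster:
                raise ValueError("all stages must share one roster")

    @property
    def roster(self) -> GeneRoster:
        return self.matrices[0].roster

    def reversed(self) -> "StageScores":
        return StageScores(
            stage_labels=tuple(reversed(self.stage_labels)),
            matrices=tuple(reversed(self.matrices)),
        )


@dataclass(frozen=True)
class MonotoneRelation:
    """One regulation whose strength changes monotonically across stages."""

    regulator: str
    target: str
    direction: str  # "increasing" | "decreasing"
    magnitude: float  # |last - first| on the screened scale

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


def _normalized_stage_values(scores: StageScores, normalize: str) -> list[np.ndarray]:
    """Per-stage score arrays on a common scale; diagonal excluded later."""
    roster = scores.roster
    n_tfs = roster.n_tfs
    mask = np.ones((n_tfs, roster.n_genes), dtype=bool)
    for i in range(n_tfs):
        mask[i, i] = False
    stacked = [mat.values[mask] for mat in scores.matrices]
    if normalize == "minmax":
        # one scale pooled over all stages: a per-stage scale would let a
        # single strengthening relation shrink everyone else's scores
        pooled = np.concatenate(stacked)
        lo, hi = pooled.min(), pooled.max()
        span = hi - lo if hi > lo else 1.0
        scaled = [(flat - lo) / span for flat in stacked]
    elif normalize == "rank":
        pooled = np.concatenate(stacked)
        r = rankdata(pooled, method="average")
        r = (r - 1) / (pooled.size - 1) if pooled.size > 1 else np.zeros_like(r)
        splits = np.cumsum([flat.size for flat in stacked])[:-1]
        scaled = np.split(r, splits)
    elif normalize == "none":
        scaled = stacked
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    out = []
    for mat, flat in zip(scores.matrices, scaled):
        vals = np.zeros_like(mat.values)
        vals[mask] = flat
        out.append(vals)
    return out


def monotone_screen(
    scores: StageScores,
    threshold: float = DEFAULT_MONOTONICITY_THRESHOLD,
    normalize: str = "minmax",
) -> list[MonotoneRelation]:
    """Flag relations whose score sequence is monotone with enough change.

    A relation is *increasing* iff every consecutive difference is >= 0
    and the total change (last minus first) is >= ``threshold``;
    *decreasing* is symmetric.  With a positive threshold the two sets
    are disjoint and constant sequences are never flagged.
    """
    if len(scores.matrices) < 3:
        raise ValueError("monotonicity needs at least 3 stages")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    stage_vals = _normalized_stage_values(scores, normalize)
    roster = scores.roster
    relations: list[MonotoneRelation] = []
    for i, tf in enumerate(roster.tfs):
        for j, gene in enumerate(roster.all_genes):
            if gene == tf:
                continue
            seq = np.array([vals[i, j] for vals in stage_vals])
            diffs = np.diff(seq)
            total = seq[-1] - seq[0]
            if np.all(diffs >= 0) and total >= threshold:
                relations.append(
                    MonotoneRelation(tf, gene, "increasing", float(total))
                )
            elif np.all(diffs <= 0) and -total >= threshold:
                relations.append(
                    MonotoneRelation(tf, gene, "decreasing", float(-total))
                )
    return relations


def driver_tf_ranking(
    relations: list[MonotoneRelation],
) -> list[tuple[str, int]]:
    """TFs sorted by how many monotone relations they regulate.

    Ties break lexicographically on the TF identifier.
    """
    if not relations:
        raise ValueError("no monotone relations to rank")
    counts = Counter(rel.regulator for rel in relations)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
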