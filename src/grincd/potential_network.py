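"""Candidate co-expression networks guiding representation learning.

Two flavors of undirected "potential" networks are built from the
standardized expression matrix: a *linear* one from Pearson correlation
and a *nonlinear* one from a binned plug-in mutual-information estimate.
Thresholding the score matrix yields a sparse 0/1 adjacency that the
embedding stage samples links from.  The potential network is scaffolding
only — the framework's output is a directed ranking, never this graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix

__all__ = [
    "PotentialNetwork",
    "pearson_matrix",
    "mutual_information_matrix",
    "threshold_network",
    "write_network_edges",
]


@dataclass(frozen=True)
class PotentialNetwork:
    """Symmetric 0/1 adjacency over all genes with the threshold that made it."""

    adjacency: np.ndarray
    gene_ids: tuple[str, ...]
    threshold: float
    flavor: str  # "linear" | "nonlinear"

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        object.__setattr__(self, "adjacency", adj.astype(bool))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if adj.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency size does not match gene_ids")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency diagonal must be zero (no self-edges)")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if self.flavor not in ("linear", "nonlinear"):
            raise ValueError(f"unknown flavor {self.flavor!r}")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def pearson_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation between all gene pairs (columns of ``matrix``).

    Requires every column to have nonzero variance — guaranteed for
    z-scored input.
    """
    sd = matrix.values.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = [matrix.gene_ids[j] for j in zero[:5]]
        raise ValueError(f"zero-variance column(s) have undefined correlation: {names}")
    r = np.corrcoef(matrix.values, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def _bin_columns(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of every column into integer codes 0..n_bins-1."""
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    codes = np.floor((values - lo) / span * n_bins).astype(np.int64)
    return np.clip(codes, 0, n_bins - 1)


def mutual_information_matrix(
    matrix: ExpressionMatrix, n_bins: int | None = None
) -> np.ndarray:
    """Plug-in mutual information (nats) between all gene pairs.

    Each gene is discretized into ``n_bins`` equal-width bins (default
    ``ceil(sqrt(m))``) and MI is computed from the joint histogram.  The
    diagonal carries each gene's marginal entropy (its self-MI); network
    thresholding ignores the diagonal.
    """
    m, n = matrix.values.shape
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(m)))
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if n_bins > m:
        raise ValueError(f"n_bins={n_bins} exceeds the sample count m={m}")

    codes = _bin_columns(matrix.values, n_bins)
    # marginal entropies
    marg = np.zeros(n)
    counts = np.zeros((n, n_bins))
    for j in range(n):
        c = np.bincount(codes[:, j], minlength=n_bins).astype(float)
        counts[j] = c
        p = c[c > 0] / m
        marg[j] = -np.sum(p * np.log(p))

    mi = np.zeros((n, n))
    for i in range(n):
        ci = codes[:, i]
        for j in range(i + 1, n):
            joint = np.bincount(ci * n_bins + codes[:, j], minlength=n_bins * n_bins)
            p = joint[joint > 0] / m
            h_joint = -np.sum(p * np.log(p))
            mi_ij = marg[i] + marg[j] - h_joint
            mi[i, j] = mi[j, i] = max(mi_ij, 0.0)
    np.fill_diagonal(mi, marg)
    return mi


def threshold_network(
    score_matrix: np.ndarray,
    threshold: float,
    gene_ids: tuple[str, ...] | list[str],
    flavor: str,
    use_absolute: bool | None = None,
) -> PotentialNetwork:
    """Binarize a symmetric score matrix into a potential network.

    An edge (i, j), i != j, exists iff its score is >= ``threshold``.
    For the linear flavor the score is |Pearson r| by default, because
    co-expression strength is sign-agnostic (negative regulation is
    real); set ``use_absolute=False`` to threshold the signed value.
    For the nonlinear flavor the raw MI (nats) is used.
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("score matrix must be square")
    if not np.allclose(scores, scores.T, atol=1e-12):
        raise ValueError("score matrix must be symmetric")
    if use_absolute is None:
        use_absolute = flavor == "linear"
    effective = np.abs(scores) if use_absolute else scores
    adj = effective >= threshold
    np.fill_diagonal(adj, False)
    adj = adj | adj.T  # guard against asymmetric float edge cases
    if not adj.any():
        raise ValueError(
            f"threshold {threshold} leaves the {flavor} potential network "
            "with zero edges; lower the threshold"
        )
    return PotentialNetwork(
        adjacency=adj, gene_ids=tuple(gene_ids), threshold=float(threshold),
        flavor=flavor,
    )


def write_network_edges(network: PotentialNetwork, path) -> None:
    """Export undirected edges as ``geneA<TAB>geneB`` with a < b index order."""
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{network.gene_ids[i]}\t{network.gene_ids[j]}\n")
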