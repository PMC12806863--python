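"""System-aware gene representations from a two-layer GraphSAGE encoder.

Isolated pairwise expression ignores the rest of the regulatory system,
so each gene is re-represented by aggregating information from its
co-expression neighborhood.  Positive training links are edges visited
by uniform random walks over the potential network; negative links are
non-edges whose endpoints are drawn from the degree (unigram)
distribution; the two classes are balanced.  A two-layer mean-aggregator
GraphSAGE encoder feeds a logistic link classifier (Hadamard product of
the endpoint embeddings followed by an affine map), trained with Adam on
the binary cross-entropy.  The encoder is considered well trained when
the link classifier reaches high held-out accuracy; the trained
second-layer activations are the gene embeddings.

Implemented directly on numpy: the graphs here are small enough
(hundreds to a few thousand genes) that full-batch dense linear algebra
is faster than any GPU framework round-trip, and it keeps the package
dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix
from .potential_network import PotentialNetwork

__all__ = [
    "SageConfig",
    "LinkSample",
    "EmbeddingMatrix",
    "TrainReport",
    "sample_positive_links",
    "sample_negative_links",
    "sage_layer",
    "train_embedding",
]


@dataclass(frozen=True)
class SageConfig:
    """Hyperparameters of the link sampler, encoder and training loop.

    All stochastic draws (walks, negative sampling, neighbor sampling,
    weight initialization, holdout split) are driven by ``seed``.
    """

    hidden_dims: tuple[int, int] = (64, 32)
    neighbor_samples: tuple[int, int] = (10, 5)
    walk_length: int = 5
    walks_per_node: int = 10
    epochs: int = 100
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != 2 or any(d < 1 for d in self.hidden_dims):
            raise ValueError("hidden_dims must be two positive integers")
        if len(self.neighbor_samples) != 2 or any(s < 1 for s in self.neighbor_samples):
            raise ValueError("neighbor_samples must be two positive integers")
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ValueError("walk parameters must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")


@dataclass(frozen=True)
class LinkSample:
    """Balanced positive/negative link pairs with labels."""

    pairs: tuple[tuple[int, int], ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if len(self.pairs) != labels.size:
            raise ValueError("pairs and labels must have equal length")
        if labels.sum() * 2 != labels.size:
            raise ValueError("positive and negative links must be balanced")
        pos = {frozenset(p) for p, l in zip(self.pairs, labels) if l == 1}
        neg = {frozenset(p) for p, l in zip(self.pairs, labels) if l == 0}
        if pos & neg:
            raise ValueError("a pair cannot be both positive and negative")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """n genes x d learned representations, row order matching gene_ids.

    When produced by :func:`train_embedding` the trained link-classifier
    head (``link_w``, ``link_b``) rides along, so the probability that
    any gene pair is a system link can be scored after training.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    source_flavor: str
    link_w: np.ndarray | None = None
    link_b: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if values.ndim != 2 or values.shape[0] != len(self.gene_ids):
            raise ValueError("embedding shape does not match gene_ids")
        if values.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("embedding contains non-finite values")
        if self.link_w is not None:
            w = np.asarray(self.link_w, dtype=float)
            object.__setattr__(self, "link_w", w)
            if w.shape != (values.shape[1],):
                raise ValueError("link head dimension does not match embedding")

    def link_probability_matrix(self) -> np.ndarray:
        """Symmetric n x n matrix of predicted link probabilities."""
        if self.link_w is None:
            raise ValueError("embedding carries no trained link classifier")
        logits = (self.values * self.link_w) @ self.values.T + self.link_b
        return _sigmoid(logits)

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"no embedding for gene {gene!r}") from None
        return self.values[i]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {g: self.values[i] for i, g in enumerate(self.gene_ids)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, g in enumerate(self.gene_ids):
                cols = "\t".join(f"{v:.17g}" for v in self.values[i])
                fh.write(f"{g}\t{cols}\n")


@dataclass(frozen=True)
class TrainReport:
    """Diagnostics of one embedding run."""

    first_epoch_loss: float
    final_loss: float
    train_accuracy: float
    holdout_accuracy: float
    n_links: int


# ---------------------------------------------------------------------------
# Link sampling


def sample_positive_links(
    network: PotentialNetwork, cfg: SageConfig, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Edges traversed by uniform random walks, deduplicated.

    ``walks_per_node`` walks of ``walk_length`` steps start from every
    non-isolated node; every traversed edge becomes a positive pair.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adj = network.adjacency
    n = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]
    starts = [i for i in range(n) if neighbors[i].size]
    if not starts:
        raise ValueError("potential network has only isolated nodes")
    seen: set[frozenset] = set()
    pairs: list[tuple[int, int]] = []
    for start in starts:
        for _ in range(cfg.walks_per_node):
            node = start
            for _ in range(cfg.walk_length):
                nbrs = neighbors[node]
                if nbrs.size == 0:
                    break
                nxt = int(nbrs[rng.integers(nbrs.size)])
                key = frozenset((node, nxt))
                if key not in seen:
                    seen.add(key)
                    pairs.append((min(node, nxt), max(node, nxt)))
                node = nxt
    return pairs


def sample_negative_links(
    network: PotentialNetwork,
    count: int,
    cfg: SageConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """``count`` unique non-edges with endpoints drawn by degree.

    Endpoint draws follow the unigram (degree) distribution of the
    network; self-pairs and existing edges are rejected.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adj = network.adjacency
    n = adj.shape[0]
    n_non_edges = n * (n - 1) // 2 - network.n_edges
    if count > n_non_edges:
        raise ValueError(
            f"{count} negative links requested but only {n_non_edges} non-edges exist"
        )
    deg = network.degrees().astype(float)
    if deg.sum() == 0:
        raise ValueError("potential network has no edges")
    probs = deg / deg.sum()
    chosen: set[frozenset] = set()
    pairs: list[tuple[int, int]] = []
    max_tries = 1000 * max(count, 1)
    tries = 0
    while len(pairs) < count:
        tries += 1
        if tries > max_tries:  # fall back to exhaustive listing of non-edges
            pairs.extend(_exhaustive_negatives(adj, count - len(pairs), chosen, rng))
            break
        a, b = rng.choice(n, size=2, p=probs)
        if a == b or adj[a, b]:
            continue
        key = frozenset((int(a), int(b)))
        if key in chosen:
            continue
        chosen.add(key)
        pairs.append((min(int(a), int(b)), max(int(a), int(b))))
    return pairs


def _exhaustive_negatives(adj, needed, chosen, rng):
    cand = [
        (i, j)
        for i in range(adj.shape[0])
        for j in range(i + 1, adj.shape[0])
        if not adj[i, j] and frozenset((i, j)) not in chosen
    ]
    idx = rng.choice(len(cand), size=needed, replace=False)
    return [cand[k] for k in idx]


def make_link_sample(
    network: PotentialNetwork, cfg: SageConfig, rng: np.random.Generator | None = None
) -> LinkSample:
    """Balanced positive (walk-visited edges) and negative link sample."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = sample_positive_links(network, cfg, rng)
    n = network.adjacency.shape[0]
    n_non_edges = n * (n - 1) // 2 - network.n_edges
    if len(pos) > n_non_edges:  # cannot balance: trim positives
        keep = rng.choice(len(pos), size=n_non_edges, replace=False)
        pos = [pos[k] for k in sorted(keep)]
    neg = sample_negative_links(network, len(pos), cfg, rng)
    pairs = tuple(pos + neg)
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LinkSample(pairs=pairs, labels=labels)


# ---------------------------------------------------------------------------
# Encoder


def _sample_aggregator(
    adj: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Row-stochastic mean-aggregation matrix over sampled neighbor sets.

    Each node samples exactly ``size`` neighbors, bootstrapping (drawing
    with replacement) whenever its degree is below the sampling size.  A
    node with no neighbors aggregates over itself, keeping every gene
    embeddable.
    """
    n = adj.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size == 0:
            A[i, i] = 1.0
            continue
        picked = rng.choice(nbrs, size=size, replace=True)
        counts = np.bincount(picked, minlength=n)
        A[i] = counts / size
    return A


def sage_layer(
    h_prev: np.ndarray,
    network: PotentialNetwork,
    theta: np.ndarray,
    *,
    sample_size: int,
    rng: np.random.Generator,
    activation: str = "relu",
) -> np.ndarray:
    """One GraphSAGE mean-aggregation layer.

    ``h_g = sigma(theta^T . concat(h_g, mean of sampled neighbors))``;
    ``theta`` has shape (2 * d_prev, d_out).
    """
    A = _sample_aggregator(network.adjacency, sample_size, rng)
    z = np.hstack([h_prev, A @ h_prev]) @ theta
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "identity":
        return z
    raise ValueError(f"unknown activation {activation!r}")


class _Adam:
    """Plain Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward(X, A1, A2, W1, W2):
    C1 = np.hstack([X, A1 @ X])
    Z1 = C1 @ W1
    H1 = np.maximum(Z1, 0.0)
    C2 = np.hstack([H1, A2 @ H1])
    H2 = C2 @ W2  # identity activation on the output layer
    return C1, Z1, H1, C2, H2


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_embedding(
    network: PotentialNetwork,
    matrix: ExpressionMatrix,
    cfg: SageConfig,
) -> tuple[EmbeddingMatrix, TrainReport]:
    """Train the encoder + link classifier; return embeddings and diagnostics.

    Node input features are the genes' standardized expression vectors.
    With ``epochs=0`` the returned embedding is the untrained (seeded)
    forward pass.  Training aborts on a non-finite loss.
    """
    if tuple(network.gene_ids) != tuple(matrix.gene_ids):
        raise ValueError("network and expression matrix gene orders differ")
    rng = np.random.default_rng(cfg.seed)
    X = matrix.values.T  # n genes x m features
    n, m = X.shape
    d1, d2 = cfg.hidden_dims

    sample = make_link_sample(network, cfg, rng)
    idx = rng.permutation(len(sample.pairs))
    n_hold = int(round(cfg.holdout_fraction * len(idx)))
    hold_idx, train_idx = idx[:n_hold], idx[n_hold:]
    pairs = np.asarray(sample.pairs)
    labels = sample.labels.astype(float)

    # Glorot-style initialization, seeded
    def init(shape):
        limit = np.sqrt(6.0 / sum(shape))
        return rng.uniform(-limit, limit, size=shape)

    W1 = init((2 * m, d1))
    W2 = init((2 * d1, d2))
    w = init((d2,))
    b = np.zeros(1)
    params = [W1, W2, w, b]
    opt = _Adam(params, cfg.learning_rate)

    ta = pairs[train_idx, 0]
    tb = pairs[train_idx, 1]
    ty = labels[train_idx]
    first_loss = final_loss = float("nan")

    for epoch in range(cfg.epochs):
        A1 = _sample_aggregator(network.adjacency, cfg.neighbor_samples[0], rng)
        A2 = _sample_aggregator(network.adjacency, cfg.neighbor_samples[1], rng)
        C1, Z1, H1, C2, H2 = _forward(X, A1, A2, W1, W2)

        ha, hb = H2[ta], H2[tb]
        logits = (ha * hb) @ w + b[0]
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(ty * np.log(p + eps) + (1 - ty) * np.log(1 - p + eps))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; "
                "lower the learning rate"
            )
        if epoch == 0:
            first_loss = float(loss)
        final_loss = float(loss)

        # backprop
        dlogit = (p - ty) / ty.size
        dw = (ha * hb).T @ dlogit
        db = np.array([dlogit.sum()])
        dH2 = np.zeros_like(H2)
        np.add.at(dH2, ta, dlogit[:, None] * (w[None, :] * hb))
        np.add.at(dH2, tb, dlogit[:, None] * (w[None, :] * ha))
        dW2 = C2.T @ dH2
        dC2 = dH2 @ W2.T
        dH1 = dC2[:, :d1] + A2.T @ dC2[:, d1:]
        dZ1 = dH1 * (Z1 > 0)
        dW1 = C1.T @ dZ1
        opt.step(params, [dW1, dW2, dw, db])

    # final deterministic forward pass for the reported embedding
    eval_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                            spawn_key=(911,)))
    A1 = _sample_aggregator(network.adjacency, cfg.neighbor_samples[0], eval_rng)
    A2 = _sample_aggregator(network.adjacency, cfg.neighbor_samples[1], eval_rng)
    _, _, _, _, H2 = _forward(X, A1, A2, W1, W2)

    def accuracy(which: np.ndarray) -> float:
        if which.size == 0:
            return float("nan")
        pa, pb = pairs[which, 0], pairs[which, 1]
        logits = (H2[pa] * H2[pb]) @ w + b[0]
        pred = (logits > 0).astype(float)
        return float(np.mean(pred == labels[which]))

    report = TrainReport(
        first_epoch_loss=first_loss,
        final_loss=final_loss,
        train_accuracy=accuracy(train_idx),
        holdout_accuracy=accuracy(hold_idx),
        n_links=len(sample.pairs),
    )
    emb = EmbeddingMatrix(
        values=H2, gene_ids=matrix.gene_ids, source_flavor=network.flavor,
        link_w=w.copy(), link_b=float(b[0]),
    )
    return emb, report
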