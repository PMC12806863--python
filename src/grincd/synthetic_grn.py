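"""Synthetic GRNs with additive-noise expression mechanisms.

Generates a planted directed TF->gene network together with expression
data drawn from the same generative family the causal scorer assumes:
every regulated gene is a sum of nonlinear functions of its regulators
plus independent Gaussian noise.  Root genes (no regulators) are
standard normal.  The planted edges double as a gold standard, so every
pipeline stage and the end-to-end ranking are testable without any
external download.

TF-TF edges respect a random topological order over the TFs, so
generation is a DAG; the inference side never uses or assumes this
ordering.  Every edge's function output is standardized to zero mean and
unit variance before entering its target's sum, so ``noise_sd`` is the
per-edge noise-to-signal ratio, an edge amplitude directly controls that
edge's strength, and deep TF chains cannot blow up numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, GeneRoster, GoldStandard

__all__ = ["SyntheticSpec", "simulate_grn", "simulate_stage_series"]

_FAMILIES = ("quadratic", "sigmoid", "mixed")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted GRN and its expression mechanism.

    Defaults describe a desk-scale benchmark: 20 TFs, 80 targets, 150
    directed edges, 300 samples, mixed quadratic/sigmoid regulatory
    functions, noise at 0.3 of the signal's standard deviation.
    """

    n_tfs: int = 20
    n_tgs: int = 80
    n_edges: int = 150
    n_samples: int = 300
    function_family: str = "mixed"
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_tgs < 0:
            raise ValueError("need at least one TF and non-negative TG count")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.function_family not in _FAMILIES:
            raise ValueError(f"function_family must be one of {_FAMILIES}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        max_edges = self.n_tfs * (self.n_tfs - 1) // 2 + self.n_tfs * self.n_tgs
        if self.n_edges > max_edges:
            raise ValueError(
                f"{self.n_edges} edges requested but only {max_edges} admissible "
                "DAG pairs exist"
            )

    def roster(self) -> GeneRoster:
        tfs = tuple(f"TF{i + 1}" for i in range(self.n_tfs))
        tgs = tuple(f"G{i + 1}" for i in range(self.n_tgs))
        return GeneRoster(tfs=tfs, targets=tgs)


def _draw_function(rng: np.random.Generator, family: str):
    """A random bounded-coefficient regulatory function x -> f(x).

    Coefficient magnitudes stay >= 0.5 so planted edges remain detectable
    at desk-scale sample sizes.
    """
    if family == "mixed":
        family = rng.choice(("quadratic", "sigmoid"))
    sign = rng.choice((-1.0, 1.0))
    a = sign * rng.uniform(0.5, 1.5)
    b = rng.uniform(-1.0, 1.0)
    if family == "quadratic":
        return lambda x: a * (x + b) ** 2
    c = rng.choice((-1.0, 1.0)) * rng.uniform(1.0, 3.0)
    return lambda x: a * np.tanh(c * x + b)


def _planted_edges(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample ``n_edges`` admissible (regulator, target) index pairs.

    Gene indices run over F then G.  TF-TF edges point from earlier to
    later in a random topological permutation of the TFs, keeping the
    generative graph acyclic.
    """
    order = rng.permutation(spec.n_tfs)
    topo_pos = np.empty(spec.n_tfs, dtype=int)
    topo_pos[order] = np.arange(spec.n_tfs)
    admissible = []
    for i in range(spec.n_tfs):
        for j in range(spec.n_tfs):
            if i != j and topo_pos[i] < topo_pos[j]:
                admissible.append((i, j))
        for j in range(spec.n_tgs):
            admissible.append((i, spec.n_tfs + j))
    idx = rng.choice(len(admissible), size=spec.n_edges, replace=False)
    return [admissible[k] for k in idx]


def _simulate_expression(
    spec: SyntheticSpec,
    edges: list[tuple[int, int]],
    functions: dict[tuple[int, int], object],
    rng: np.random.Generator,
    amplitudes: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Sample an m x n matrix from the additive-noise mechanism."""
    n = spec.n_tfs + spec.n_tgs
    m = spec.n_samples
    parents: dict[int, list[tuple[int, int]]] = {j: [] for j in range(n)}
    for (i, j) in edges:
        parents[j].append((i, j))

    # generation order: TFs in topological order (parents always precede
    # children because TF-TF edges follow the permutation), then TGs
    order = _generation_order(spec, edges)
    values = np.empty((m, n))
    for j in order:
        if not parents[j]:
            values[:, j] = rng.standard_normal(m)
            continue
        signal = np.zeros(m)
        for edge in parents[j]:
            amp = 1.0 if amplitudes is None else amplitudes.get(edge, 1.0)
            contrib = functions[edge](values[:, edge[0]])
            sd = contrib.std()
            if sd > 0:  # unit-variance per-edge contribution, so the
                contrib = (contrib - contrib.mean()) / sd
            signal += amp * contrib  # amplitude is the edge's SNR knob
        values[:, j] = signal + rng.normal(0.0, spec.noise_sd, m)
    return values


def _generation_order(spec: SyntheticSpec, edges: list[tuple[int, int]]) -> list[int]:
    """Topological order of gene indices implied by the planted DAG."""
    n = spec.n_tfs + spec.n_tgs
    children: dict[int, list[int]] = {j: [] for j in range(n)}
    indeg = [0] * n
    for (i, j) in edges:
        children[i].append(j)
        indeg[j] += 1
    queue = sorted(j for j in range(n) if indeg[j] == 0)
    order = []
    while queue:
        j = queue.pop(0)
        order.append(j)
        for c in children[j]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise RuntimeError("planted graph is not acyclic")  # pragma: no cover
    return order


def simulate_grn(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, GoldStandard, GeneRoster]:
    """Simulate a planted GRN and ANM-mechanism expression data.

    Returns the expression matrix, the planted edges as a gold standard,
    and the roster.  Fully reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    roster = spec.roster()
    edges = _planted_edges(spec, rng)
    functions = {e: _draw_function(rng, spec.function_family) for e in edges}
    values = _simulate_expression(spec, edges, functions, rng)
    genes = roster.all_genes
    matrix = ExpressionMatrix(
        values=values,
        sample_ids=tuple(f"S{i + 1}" for i in range(spec.n_samples)),
        gene_ids=genes,
    )
    gold = GoldStandard(
        roster=roster,
        positives=frozenset((genes[i], genes[j]) for i, j in edges),
    )
    return matrix, gold, roster


def simulate_stage_series(
    spec: SyntheticSpec,
    n_stages: int,
    drift: float,
    n_drift_increasing: int = 2,
    n_drift_decreasing: int = 2,
) -> tuple[list[ExpressionMatrix], list[tuple[str, str, str]], GoldStandard]:
    """Expression matrices for ordered stages with planted amplitude drift.

    A fixed planted network is shared by all stages; a designated subset
    of edges has its regulatory-function amplitude grow (or shrink)
    linearly with the stage index at rate ``drift`` per stage, emulating
    regulations that strengthen or weaken along disease progression.
    All other edges keep constant amplitude; stages are otherwise
    independent re-draws.

    ``drift = 0`` yields i.i.d. stages with an empty planted monotone
    set.  Returns (matrices, planted, gold) where ``planted`` lists
    (regulator, target, "increasing"|"decreasing").
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if drift < 0:
        raise ValueError("drift must be non-negative")
    rng = np.random.default_rng(spec.seed)
    roster = spec.roster()
    genes = roster.all_genes
    edges = _planted_edges(spec, rng)
    functions = {e: _draw_function(rng, spec.function_family) for e in edges}

    planted: list[tuple[str, str, str]] = []
    drifting: dict[tuple[int, int], str] = {}
    if drift > 0:
        n_drift = n_drift_increasing + n_drift_decreasing
        if n_drift > len(edges):
            raise ValueError("more drifting edges requested than planted edges")
        # Prefer TF->TG edges whose target has no other regulator and whose
        # regulator has no TF-TF edges: drifting one input of a
        # multi-regulator target shifts its sibling relations too, a TF-TF
        # drift would flag its antisymmetric mirror pair, and a regulator
        # correlated with other TFs (through TF-TF edges) drags their
        # relations along.  Only isolated mechanisms yield a cleanly
        # attributable monotone set.
        indeg: dict[int, int] = {}
        tf_coupled: set[int] = set()
        for (i, j) in edges:
            indeg[j] = indeg.get(j, 0) + 1
            if j < spec.n_tfs:
                tf_coupled.update((i, j))
        preferred = [
            k for k, (i, j) in enumerate(edges)
            if j >= spec.n_tfs and indeg[j] == 1 and i not in tf_coupled
        ]
        if len(preferred) < n_drift:
            raise ValueError(
                "not enough isolated TF->TG edges to plant drift on; "
                "use a larger or sparser network"
            )
        chosen = rng.choice(preferred, size=n_drift, replace=False)
        for pos, k in enumerate(chosen):
            direction = "increasing" if pos < n_drift_increasing else "decreasing"
            drifting[edges[k]] = direction
            planted.append((genes[edges[k][0]], genes[edges[k][1]], direction))
            # Drifting edges get a near-symmetric quadratic mechanism — the
            # regime where the ANM scorer responds most strongly to
            # amplitude, so the planted drift is visible at every stage
            # and the screen tests monotonicity detection, not the
            # identifiability of an unlucky mechanism draw.
            b = rng.uniform(-0.3, 0.3)
            functions[edges[k]] = (lambda bb: lambda x: (x + bb) ** 2)(b)

    matrices = []
    for t in range(n_stages):
        amplitudes = {}
        for edge, direction in drifting.items():
            if direction == "increasing":
                # weak at the first stage, strong at the last
                amplitudes[edge] = 0.1 + drift * t
            else:
                amplitudes[edge] = max(0.1, 0.1 + drift * (n_stages - 1 - t))
        stage_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(t + 1,))
        )
        values = _simulate_expression(spec, edges, functions, stage_rng, amplitudes)
        matrices.append(
            ExpressionMatrix(
                values=values,
                sample_ids=tuple(f"S{i + 1}" for i in range(spec.n_samples)),
                gene_ids=genes,
            )
        )
    gold = GoldStandard(
        roster=roster,
        positives=frozenset((genes[i], genes[j]) for i, j in edges),
    )
    return matrices, planted, gold
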