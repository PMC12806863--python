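"""Domain types and DREAM5-style file I/O.

The framework operates on four core objects:

* :class:`ExpressionMatrix` — an ``m`` samples x ``n`` genes real matrix.
* :class:`GeneRoster` — the ordered split of genes into transcription
  factors (TFs, the admissible regulators) and target genes (TGs).
* :class:`GoldStandard` — a set of experimentally supported directed
  regulatory edges used only for evaluation.
* :class:`RankedEdgeList` — the framework's output: directed
  (regulator, target, score) triples sorted by decreasing confidence.

File dialects follow the DREAM5 network-inference challenge: expression
as a TSV with a header row of gene identifiers and one sample per row, a
TF list with one identifier per line, gold standards and predictions as
three-column TSVs.  Gene identifiers are opaque, case-sensitive strings
and matching across files is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneRoster",
    "GoldStandard",
    "RankedEdgeList",
    "read_expression",
    "write_expression",
    "read_tf_list",
    "write_tf_list",
    "read_gold_standard",
    "write_gold_standard",
    "read_ranked_edges",
    "write_ranked_edges",
    "zscore_normalize",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes expression values with identifiers.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in sample
    ``sample_ids[i]``.  Values must be finite; at least two samples and
    two genes are required for any downstream statistic to be defined.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        m, n = values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 samples and 2 genes, got {m}x{n}")
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match row count")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene identifiers must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene identifier: {gene!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class GeneRoster:
    """Ordered TF set F and target set G fixing matrix row/column semantics.

    A gene is either a TF (admissible regulator, may also be regulated by
    other TFs) or a target gene (regulated only).  ``all_genes`` is the
    concatenation F then G and defines the column order of propensity
    matrices.
    """

    tfs: tuple[str, ...]
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tfs", tuple(self.tfs))
        object.__setattr__(self, "targets", tuple(self.targets))
        if len(set(self.tfs)) != len(self.tfs):
            raise ValueError("duplicate TF identifiers")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate target identifiers")
        if set(self.tfs) & set(self.targets):
            raise ValueError("TF and target sets must be disjoint")
        if not self.tfs:
            raise ValueError("roster needs at least one TF")

    @classmethod
    def from_tf_list(cls, gene_ids: Sequence[str], tfs: Iterable[str]) -> "GeneRoster":
        """Split ``gene_ids`` into (TFs, targets) given the TF identifiers.

        TF order follows ``gene_ids``; TFs absent from ``gene_ids`` raise.
        """
        tf_set = set(tfs)
        missing = tf_set - set(gene_ids)
        if missing:
            raise ValueError(f"TFs not present in expression matrix: {sorted(missing)}")
        tf_ordered = tuple(g for g in gene_ids if g in tf_set)
        targets = tuple(g for g in gene_ids if g not in tf_set)
        return cls(tfs=tf_ordered, targets=targets)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.tfs + self.targets

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def n_genes(self) -> int:
        return len(self.tfs) + len(self.targets)

    @property
    def n_admissible_pairs(self) -> int:
        """|F| * (|F| + |G| - 1): all TF->gene ordered pairs minus self-pairs."""
        return self.n_tfs * (self.n_genes - 1)

    def admissible_pairs(self) -> Iterator[tuple[str, str]]:
        """All directed (TF, gene) pairs excluding self-regulation.

        TG->anything pairs never appear: targets cannot regulate.
        """
        for tf in self.tfs:
            for gene in self.all_genes:
                if gene != tf:
                    yield (tf, gene)

    def is_admissible(self, regulator: str, target: str) -> bool:
        return (
            regulator in set(self.tfs)
            and regulator != target
            and target in set(self.all_genes)
        )


@dataclass(frozen=True)
class GoldStandard:
    """Directed reference edges over a roster's admissible pair universe.

    ``positives`` are the supported regulator->target edges.  Pairs
    explicitly labelled 0 in the source file are kept in ``negatives``;
    any admissible pair not listed as positive counts as a negative for
    evaluation (DREAM convention).  The universe size ``T`` is the number
    of admissible ordered pairs: no self-pairs, no TG->TG pairs.
    """

    roster: GeneRoster
    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        tf_set = set(self.roster.tfs)
        gene_set = set(self.roster.all_genes)
        for reg, tgt in self.positives | self.negatives:
            if reg == tgt:
                raise ValueError(f"self-pair in gold standard: {reg!r}")
            if reg not in tf_set:
                raise ValueError(f"gold-standard regulator is not a TF: {reg!r}")
            if tgt not in gene_set:
                raise ValueError(f"gold-standard target not in roster: {tgt!r}")
        if self.positives & self.negatives:
            raise ValueError("pairs labelled both positive and negative")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def universe_size(self) -> int:
        return self.roster.n_admissible_pairs

    @property
    def n_negatives(self) -> int:
        return self.universe_size - self.n_positives


@dataclass(frozen=True)
class RankedEdgeList:
    """Directed (regulator, target, score) triples, scores non-increasing."""

    rows: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        rows = tuple((str(r), str(t), float(s)) for r, t, s in self.rows)
        object.__setattr__(self, "rows", rows)
        scores = [s for _, _, s in rows]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")
        pairs = [(r, t) for r, t, _ in rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (regulator, target) pairs")
        if any(r == t for r, t in pairs):
            raise ValueError("self-pairs are not admissible")

    def __len__(self) -> int:
        return len(self.rows)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.rows]

    def top_k_pairs(self, k: int) -> set[tuple[str, str]]:
        if k <= 0:
            raise ValueError("k must be positive")
        return {(r, t) for r, t, _ in self.rows[:k]}


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a DREAM5-style expression TSV.

    First row holds gene identifiers, each subsequent row one sample.
    ``transpose=True`` instead reads a genes-in-rows layout: first column
    gene identifiers, first row sample identifiers (row label cell first).
    """
    path = Path(path)
    if transpose:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise FormatError(f"{path}: missing values after transpose-load")
        try:
            values = df.to_numpy(dtype=float).T
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell: {exc}") from None
        return ExpressionMatrix(
            values=values,
            sample_ids=tuple(str(c) for c in df.columns),
            gene_ids=tuple(str(g) for g in df.index),
        )
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file or missing header")
        gene_ids = header.split("\t")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(gene_ids):
                raise FormatError(
                    f"{path}: row {lineno} has {len(cells)} fields, "
                    f"expected {len(gene_ids)}"
                )
            parsed = []
            for col, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at row {lineno}, "
                        f"column {col}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    values = np.asarray(rows, dtype=float)
    sample_ids = tuple(f"S{i + 1}" for i in range(values.shape[0]))
    return ExpressionMatrix(values=values, sample_ids=sample_ids, gene_ids=tuple(gene_ids))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the DREAM5 TSV dialect (header + rows)."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=list(matrix.gene_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tf_list(path: str | Path) -> tuple[str, ...]:
    """Read a TF list: one identifier per line, blanks ignored."""
    path = Path(path)
    tfs = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(tfs)) != len(tfs):
        raise FormatError(f"{path}: duplicate TF identifiers")
    return tuple(tfs)


def write_tf_list(tfs: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{tf}\n" for tf in tfs))


def read_gold_standard(path: str | Path, roster: GeneRoster) -> GoldStandard:
    """Read a gold standard TSV: ``regulator<TAB>target<TAB>{0,1}``."""
    path = Path(path)
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: row {lineno} must have 3 fields")
            reg, tgt, label = cells
            if label not in ("0", "1"):
                raise FormatError(f"{path}: row {lineno} label must be 0 or 1")
            (positives if label == "1" else negatives).add((reg, tgt))
    return GoldStandard(roster=roster, positives=frozenset(positives),
                        negatives=frozenset(negatives))


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for reg, tgt in sorted(gold.positives):
            fh.write(f"{reg}\t{tgt}\t1\n")
        for reg, tgt in sorted(gold.negatives):
            fh.write(f"{reg}\t{tgt}\t0\n")


def read_ranked_edges(path: str | Path) -> RankedEdgeList:
    """Read a prediction TSV: ``regulator<TAB>target<TAB>score``, descending."""
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise FormatError(f"{path}: row {lineno} must have 3 fields")
            try:
                score = float(cells[2])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric score at row {lineno}"
                ) from None
            rows.append((cells[0], cells[1], score))
    return RankedEdgeList(rows=tuple(rows))


def write_ranked_edges(edges: RankedEdgeList, path: str | Path) -> None:
    """Write one ``regulator<TAB>target<TAB>score`` line per edge, in order."""
    with Path(path).open("w") as fh:
        for reg, tgt, score in edges.rows:
            fh.write(f"{reg}\t{tgt}\t{score!r}\n")  # shortest lossless repr


# ---------------------------------------------------------------------------
# Standardization


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every gene column to mean 0, population sd 1.

    The population standard deviation (denominator ``m``, not ``m - 1``)
    is used.  A constant gene column has no finite z-score and raises,
    naming the offending gene.
    """
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd, ddof=0
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = [matrix.gene_ids[j] for j in zero[:5]]
        raise ValueError(
            f"constant expression column(s) cannot be standardized: {names}"
        )
    return ExpressionMatrix(
        values=(values - mean) / sd,
        sample_ids=matrix.sample_ids,
        gene_ids=matrix.gene_ids,
    )
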