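import numpy as np
import pytest

from grincd.core_io import ExpressionMatrix, GeneRoster, GoldStandard
from grincd.synthetic_grn import SyntheticSpec, simulate_grn


@pytest.fixture(scope="session")
def small_grn():
    """A small planted GRN shared by cheap end-to-end tests."""
    spec = SyntheticSpec(n_tfs=5, n_tgs=10, n_edges=18, n_samples=120, seed=42)
    matrix, gold, roster = simulate_grn(spec)
    return matrix, gold, roster


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_roster():
    return GeneRoster(tfs=("A", "B"), targets=("C", "D"))


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(30, 4))
    return ExpressionMatrix(
        values=values,
        sample_ids=tuple(f"S{i}" for i in range(30)),
        gene_ids=("A", "B", "C", "D"),
    )


@pytest.fixture()
def toy_gold(toy_roster):
    return GoldStandard(
        roster=toy_roster,
        positives=frozenset({("A", "C"), ("B", "D"), ("A", "B")}),
    )
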