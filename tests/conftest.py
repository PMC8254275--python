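import numpy as np
import pytest

from anmda.data_model import AssociationMatrix, TreeNumberTable
from anmda.disease_semantics import combined_semantic_similarity


@pytest.fixture
def toy_tree() -> TreeNumberTable:
    """Four-disease hierarchy: A at the root, B above C, E a sibling leaf.

    DAG census: A appears in all four DAGs, B in two (B, C), C and E only in
    their own — the worked fixture for both semantic-value models.
    """
    return TreeNumberTable(
        {
            "A": {"C01"},
            "B": {"C01.100"},
            "C": {"C01.100.200"},
            "E": {"C01.900"},
        }
    )


@pytest.fixture
def toy_combined_ss(toy_tree):
    return combined_semantic_similarity(toy_tree, delta=0.5)


@pytest.fixture
def identity_assoc() -> AssociationMatrix:
    """Two miRNAs, two diseases, diagonal associations."""
    return AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.eye(2, dtype=int))


def random_association_matrix(rng: np.random.Generator, n_m=None, n_d=None):
    """Small random association matrix with at least one positive."""
    n_m = n_m or int(rng.integers(2, 7))
    n_d = n_d or int(rng.integers(2, 7))
    adj = (rng.random((n_m, n_d)) < 0.4).astype(int)
    if adj.sum() == 0:
        adj[rng.integers(n_m), rng.integers(n_d)] = 1
    return AssociationMatrix(
        [f"m{i}" for i in range(n_m)], [f"d{j}" for j in range(n_d)], adj
    )
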