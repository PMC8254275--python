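"""Disease semantic similarity over hierarchy DAGs.

Each disease's tree numbers place it in a hierarchical vocabulary; the
whole-segment prefixes of its codes identify ancestor headings. The disease
plus all ancestors present in the table form its DAG, over which two
semantic-value models are computed:

* model 1 — a decaying-contribution recursion: the disease itself
  contributes 1 and each step up the hierarchy multiplies the contribution
  by a semantic contribution factor ``delta`` (default 0.5), taking the max
  over descent paths;
* model 2 — an information-content value ``-log(N_d / N)`` where ``N_d``
  counts how many diseases' DAGs contain ``d`` and ``N`` is the number of
  diseases in the table, so ubiquitous headings contribute nothing.

The pairwise similarity is the shared semantic mass divided by the total
semantic values of the two diseases; the final score averages the two models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_model import SimilarityMatrix, TreeNumberTable

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5


@dataclass
class DiseaseDAG:
    """A disease, its ancestor vertices, and the directed hierarchy edges.

    Edges point parent -> child (toward the target disease); every vertex
    can reach the target.
    """

    target: str
    vertices: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.target not in self.vertices:
            raise ValueError(f"target {self.target!r} missing from its own DAG")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"DAG for {self.target!r} contains a cycle")
        for v in self.vertices:
            if v != self.target and not nx.has_path(g, v, self.target):
                raise ValueError(f"vertex {v!r} cannot reach target {self.target!r}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def children_of(self, vertex: str) -> set[str]:
        return {c for p, c in self.edges if p == vertex}


@dataclass
class SemanticValueMap:
    """Per-vertex semantic contributions to one target disease and their sum."""

    target: str
    contributions: dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.contributions.values()):
            raise ValueError("semantic contributions must be non-negative")
        self.total = float(sum(self.contributions.values()))


def _prefix_chain(code: str) -> list[str]:
    """All whole-segment prefixes of a tree number, shortest first, code last."""
    segments = code.split(".")
    return [".".join(segments[: i + 1]) for i in range(len(segments))]


def build_dags(table: TreeNumberTable) -> dict[str, DiseaseDAG]:
    """Build every disease's ancestor DAG from the tree-number table.

    A disease ``a`` is a vertex of DAG(t) iff some code of ``a`` is a
    whole-segment prefix of some code of ``t``. Edges follow immediate-prefix
    parenthood; when the table lacks the heading for an intermediate prefix,
    the hole is skipped and the nearest existing ancestor connects directly
    to the nearest existing descendant, preserving reachability.
    """
    code_owner: dict[str, list[str]] = {}
    for disease, codes in table.codes.items():
        for code in codes:
            code_owner.setdefault(code, []).append(disease)

    dags: dict[str, DiseaseDAG] = {}
    for disease, codes in table.codes.items():
        vertices: set[str] = {disease}
        edges: set[tuple[str, str]] = set()
        for code in codes:
            chain = _prefix_chain(code)
            missing = [c for c in chain if c not in code_owner]
            if missing:
                logger.debug(
                    "DAG(%s): %d ancestor code(s) of %s map to no disease; skipped",
                    disease, len(missing), code,
                )
            # diseases owning each existing prefix level, shallow -> deep
            levels = [code_owner[c] for c in chain if c in code_owner]
            if not levels or disease not in levels[-1]:
                levels.append([disease])
            for owners in levels:
                vertices.update(owners)
            for parents, children in zip(levels, levels[1:]):
                for p in parents:
                    for c in children:
                        if p != c:
                            edges.add((p, c))
        dags[disease] = DiseaseDAG(disease, vertices, edges)
    return dags


def dag_census(dags: dict[str, DiseaseDAG]) -> dict[str, int]:
    """For each disease, how many DAGs (over all diseases) contain it."""
    census: dict[str, int] = {}
    for dag in dags.values():
        for v in dag.vertices:
            census[v] = census.get(v, 0) + 1
    return census


def semantic_values_model1(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> SemanticValueMap:
    """Decaying-contribution semantic values via reverse topological sweep.

    D(target) = 1; for any other vertex, D(d) = max over children d' of d
    inside the DAG of delta * D(d').
    """
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    g = dag.graph()
    contributions: dict[str, float] = {dag.target: 1.0}
    # walk vertices from closest-to-target outward: reverse topological order
    for vertex in reversed(list(nx.topological_sort(g))):
        if vertex in contributions:
            continue
        children = dag.children_of(vertex)
        known = [contributions[c] for c in children if c in contributions]
        if not known:
            raise ValueError(
                f"vertex {vertex!r} has no evaluated child in DAG({dag.target!r})"
            )
        contributions[vertex] = delta * max(known)
    return SemanticValueMap(dag.target, contributions)


def semantic_values_model2(
    dag: DiseaseDAG, census: dict[str, int], n_total: int
) -> SemanticValueMap:
    """Information-content semantic values: D(d) = -log(N_d / N), natural log."""
    contributions: dict[str, float] = {}
    for vertex in dag.vertices:
        n_d = census.get(vertex, 0)
        if n_d < 1:
            raise ValueError(f"disease {vertex!r} appears in no DAG (census 0)")
        if n_d > n_total:
            raise ValueError(f"census {n_d} for {vertex!r} exceeds total {n_total}")
        contributions[vertex] = -float(np.log(n_d / n_total))
    return SemanticValueMap(dag.target, contributions)


def semantic_similarity(values_i: SemanticValueMap, values_j: SemanticValueMap) -> float:
    """Shared semantic mass normalised by total semantic values.

    Returns 0 for an empty vertex intersection, and 0 for the degenerate
    case of both totals vanishing (possible under model 2 when every vertex
    is ubiquitous).
    """
    shared = values_i.contributions.keys() & values_j.contributions.keys()
    denom = values_i.total + values_j.total
    if not shared or denom == 0.0:
        return 0.0
    num = sum(values_i.contributions[d] + values_j.contributions[d] for d in shared)
    return float(num / denom)


def combined_semantic_similarity(
    table: TreeNumberTable, delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Full disease-by-disease semantic similarity, averaging the two models.

    Covers exactly the diseases in the tree-number table; diseases absent
    from the table get no row here and fall back to the interaction-profile
    kernel downstream.
    """
    dags = build_dags(table)
    census = dag_census(dags)
    n_total = len(table)
    diseases = list(table.codes)
    maps1 = {d: semantic_values_model1(dags[d], delta) for d in diseases}
    maps2 = {d: semantic_values_model2(dags[d], census, n_total) for d in diseases}
    n = len(diseases)
    values = np.zeros((n, n), dtype=float)
    for i, di in enumerate(diseases):
        for j in range(i, n):
            dj = diseases[j]
            ss1 = semantic_similarity(maps1[di], maps1[dj])
            ss2 = semantic_similarity(maps2[di], maps2[dj])
            values[i, j] = values[j, i] = 0.5 * (ss1 + ss2)
    return SimilarityMatrix(diseases, np.clip(values, 0.0, 1.0))
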