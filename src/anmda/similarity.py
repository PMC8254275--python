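"""miRNA functional similarity, Gaussian interaction-profile kernels, and
integrated similarities.

The interaction profile of an entity is its binary row (miRNA) or column
(disease) of the association matrix; the Gaussian interaction-profile (GIP)
kernel turns the squared distance between two profiles into a similarity
``exp(-gamma * ||IP_i - IP_j||^2)`` with the bandwidth normalised by the
mean squared profile norm. Functional similarity between two miRNAs is the
best-match average of the semantic similarities of their associated disease
sets. Integrated similarity averages the semantic/functional value with the
GIP value where the former exists, else falls back to GIP alone.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_model import (
    AssociationMatrix,
    PairDataset,
    PairIndex,
    POSITIVE,
    NEGATIVE,
    SimilarityMatrix,
    normalize_id,
)

DEFAULT_GAMMA_PRIME = 1.0


def gip_similarity(
    a: AssociationMatrix, axis: str, gamma_prime: float = DEFAULT_GAMMA_PRIME
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one axis of the association matrix.

    Parameters
    ----------
    a : AssociationMatrix
    axis : ``"mirna"`` or ``"disease"``
        Which entities to compare; profiles are the corresponding rows or
        columns of the adjacency.
    gamma_prime : float
        Raw bandwidth, normalised by the mean squared profile norm.
    """
    if axis == "mirna":
        profiles = a.adjacency.astype(float)
        labels = a.mirna_ids
    elif axis == "disease":
        profiles = a.adjacency.T.astype(float)
        labels = a.disease_ids
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    mean_sq_norm = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValueError("all interaction profiles are zero; kernel bandwidth undefined")
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(labels), values)


def mirna_functional_similarity(
    a: AssociationMatrix, ss: SimilarityMatrix
) -> SimilarityMatrix:
    """Best-match-average functional similarity between miRNAs.

    For miRNAs ``m_i``, ``m_j`` with associated disease sets ``MD_i``,
    ``MD_j`` (restricted to diseases carrying a semantic row), the score is

        [sum_{d in MD_j} S(d, MD_i) + sum_{d in MD_i} S(d, MD_j)] / (n_i + n_j)

    where ``S(d, MD)`` is the maximum semantic similarity between ``d`` and
    any disease of ``MD``. Entries are NaN (missing, not 0) for miRNAs with
    no associations or none of whose diseases have semantic rows.
    """
    ss_index = {normalize_id(lab): k for k, lab in enumerate(ss.labels)}
    # column index in adjacency -> row in the semantic matrix (or None)
    col_to_ss = [ss_index.get(normalize_id(d)) for d in a.disease_ids]

    disease_sets: list[np.ndarray | None] = []
    for i in range(a.n_mirnas):
        cols = np.nonzero(a.adjacency[i])[0]
        rows = [col_to_ss[c] for c in cols if col_to_ss[c] is not None]
        disease_sets.append(np.asarray(rows, dtype=int) if rows else None)

    n = a.n_mirnas
    values = np.full((n, n), np.nan)
    for i in range(n):
        mdi = disease_sets[i]
        if mdi is None:
            continue
        for j in range(i, n):
            mdj = disease_sets[j]
            if mdj is None:
                continue
            block = ss.values[np.ix_(mdi, mdj)]
            # best match of each disease of MD_i in MD_j, and vice versa
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(mdi) + len(mdj)
            )
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(list(a.mirna_ids), values, allow_missing=True)


def _integrate(partial: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Average partial similarity with GIP where defined, else GIP alone."""
    gip_key = {normalize_id(lab): k for k, lab in enumerate(gip.labels)}
    values = gip.values.copy()
    part_idx = []
    for k, lab in enumerate(partial.labels):
        key = normalize_id(lab)
        if key in gip_key:
            part_idx.append((k, gip_key[key]))
    for pi, gi in part_idx:
        for pj, gj in part_idx:
            v = partial.values[pi, pj]
            if np.isfinite(v):
                values[gi, gj] = 0.5 * (gip.values[gi, gj] + v)
    return SimilarityMatrix(list(gip.labels), values)


def integrate_disease_similarity(
    ss: SimilarityMatrix, gs_d: SimilarityMatrix
) -> SimilarityMatrix:
    """Combine semantic similarity with the disease GIP kernel.

    Entry (i, j) is the average of the two where the semantic value exists
    (both diseases in the tree-number table), otherwise the GIP value alone.
    ``gs_d`` must cover every disease.
    """
    return _integrate(ss, gs_d)


def integrate_mirna_similarity(
    fsm: SimilarityMatrix, gs_m: SimilarityMatrix
) -> SimilarityMatrix:
    """Combine functional similarity with the miRNA GIP kernel (same fallback)."""
    return _integrate(fsm, gs_m)


def build_pair_features(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    pairs: PairIndex,
) -> PairDataset:
    """Feature vectors for pairs: miRNA similarity row, then disease row.

    The feature vector of pair (m_i, d_j) is the concatenation of row i of
    the integrated miRNA similarity (length n_m) and row j of the integrated
    disease similarity (length n_d).
    """
    n_m, n_d = sm.n, sd.n
    pairs.validate_bounds(n_m, n_d)
    idx = np.asarray(pairs.pairs, dtype=int).reshape(-1, 2)
    X = np.hstack([sm.values[idx[:, 0]], sd.values[idx[:, 1]]]) if len(pairs) else \
        np.empty((0, n_m + n_d))
    label_value = {POSITIVE: 1, NEGATIVE: 0}.get(pairs.label, -1)
    y = np.full(len(pairs), label_value, dtype=int)
    return PairDataset(list(pairs.pairs), X, y)
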