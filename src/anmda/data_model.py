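"""Core domain types and TSV readers/writers.

The association matrix is the single source of truth for the pair universe:
positives are the recorded (miRNA, disease) associations, and every other
cell is an *undetected* pair — the pool that negative sampling draws from
and in which label noise (future true positives) hides.

Identifiers are case-preserved for display but matched case-insensitively
after whitespace trimming, because curated disease vocabularies mix
capitalisations of the same heading.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")

#: Pair-label vocabulary used throughout the package.
POSITIVE = "positive"
NEGATIVE = "negative"
UNDETECTED = "undetected"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_id(identifier: str) -> str:
    """Canonical comparison key for an identifier: trimmed, lower-cased."""
    return identifier.strip().lower()


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency with ordered identifier lists.

    ``adjacency[i, j] == 1`` iff miRNA ``mirna_ids[i]`` is a verified
    association partner of disease ``disease_ids[j]``.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n_m, n_d = len(self.mirna_ids), len(self.disease_ids)
        if n_m < 1 or n_d < 1:
            raise ValueError("association matrix needs at least one miRNA and one disease")
        if self.adjacency.shape != (n_m, n_d):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"({n_m} miRNAs, {n_d} diseases)"
            )
        for ids, what in ((self.mirna_ids, "miRNA"), (self.disease_ids, "disease")):
            keys = [normalize_id(x) for x in ids]
            if len(set(keys)) != len(keys):
                raise ValueError(f"duplicate {what} identifiers (case-insensitive)")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.adjacency.sum())

    def positive_pairs(self) -> "PairIndex":
        rows, cols = np.nonzero(self.adjacency)
        return PairIndex(list(zip(rows.tolist(), cols.tolist())), label=POSITIVE)


@dataclass
class TreeNumberTable:
    """Mapping disease id -> non-empty set of hierarchical tree-number codes.

    A tree number is a dot-separated code (e.g. ``C04.588.322``); whole-segment
    prefixes of a code identify its hierarchy ancestors.
    """

    codes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for disease, numbers in self.codes.items():
            if not numbers:
                raise ValueError(f"disease {disease!r} has no tree numbers")
            for num in numbers:
                if not _TREE_NUMBER_RE.match(num):
                    raise ValueError(f"invalid tree number {num!r} for disease {disease!r}")

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.codes

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class SimilarityMatrix:
    """Square, symmetric, labeled matrix of similarities in [0, 1].

    Partial matrices (``allow_missing=True``) mark undefined entries as NaN;
    0 is a legal similarity value and is never used to encode absence.
    """

    labels: list[str]
    values: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match {n} labels")
        keys = [normalize_id(x) for x in self.labels]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate labels")
        finite = np.isfinite(self.values)
        if not self.allow_missing and not finite.all():
            raise ValueError("non-finite entries in a complete similarity matrix")
        vals = self.values[finite]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        asym = np.nanmax(np.abs(self.values - self.values.T)) if n else 0.0
        if n and not np.isnan(asym) and asym > 1e-12:
            raise ValueError(f"matrix is asymmetric (max deviation {asym:.3g})")
        # NaN pattern must be symmetric too for a partial matrix
        if self.allow_missing and not (finite == finite.T).all():
            raise ValueError("missing-entry pattern is asymmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        key = normalize_id(label)
        for i, lab in enumerate(self.labels):
            if normalize_id(lab) == key:
                return i
        raise KeyError(label)

    def get(self, label_i: str, label_j: str) -> float:
        return float(self.values[self.index_of(label_i), self.index_of(label_j)])


@dataclass
class PairIndex:
    """List of (mirna_index, disease_index) pairs carrying one shared label."""

    pairs: list[tuple[int, int]]
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE, UNDETECTED):
            raise ValueError(f"unknown pair label {self.label!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def validate_bounds(self, n_m: int, n_d: int) -> None:
        for i, j in self.pairs:
            if not (0 <= i < n_m and 0 <= j < n_d):
                raise IndexError(f"pair ({i}, {j}) out of bounds for {n_m}x{n_d}")


@dataclass
class PairDataset:
    """Feature vectors and labels for (miRNA, disease) pairs.

    ``y`` uses 1 for positive, 0 for negative and -1 for undetected (unlabeled).
    """

    pairs: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.pairs) or self.y.shape[0] != len(self.pairs):
            raise ValueError("pairs, X and y must have equal first dimension")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: Sequence[int]) -> "PairDataset":
        idx = np.asarray(indices, dtype=int)
        return PairDataset([self.pairs[i] for i in idx], self.X[idx], self.y[idx])


def concat_datasets(parts: Iterable[PairDataset]) -> PairDataset:
    parts = list(parts)
    return PairDataset(
        [p for part in parts for p in part.pairs],
        np.vstack([part.X for part in parts]),
        np.concatenate([part.y for part in parts]),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (miRNA id, disease id) TSV into an association matrix.

    Identifier order follows first appearance; duplicate pairs collapse to a
    single association with a logged warning. A header line is tolerated if
    its pair repeats nowhere (standard curated lists have none).
    """
    path = Path(path)
    mirna_order: dict[str, str] = {}
    disease_order: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    n_dupes = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            m_raw, d_raw = fields[0].strip(), fields[1].strip()
            if not m_raw or not d_raw:
                raise FormatError(f"{path}:{lineno}: empty identifier")
            if lineno == 1 and normalize_id(m_raw) in {"mirna", "mirna_id", "microrna"}:
                continue  # header row
            mk, dk = normalize_id(m_raw), normalize_id(d_raw)
            mirna_order.setdefault(mk, m_raw)
            disease_order.setdefault(dk, d_raw)
            if (mk, dk) in seen:
                n_dupes += 1
                continue
            seen.add((mk, dk))
            pairs.append((mk, dk))
    if not pairs:
        raise FormatError(f"{path}: no associations found")
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate association(s)", path, n_dupes)
    mirna_ids = list(mirna_order.values())
    disease_ids = list(disease_order.values())
    m_pos = {k: i for i, k in enumerate(mirna_order)}
    d_pos = {k: i for i, k in enumerate(disease_order)}
    adjacency = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for mk, dk in pairs:
        adjacency[m_pos[mk], d_pos[dk]] = 1
    return AssociationMatrix(mirna_ids, disease_ids, adjacency)


def write_associations(a: AssociationMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, j in a.positive_pairs():
            fh.write(f"{a.mirna_ids[i]}\t{a.disease_ids[j]}\n")


def read_tree_numbers(path: str | Path) -> TreeNumberTable:
    """Read a two-column (disease id, semicolon-joined tree numbers) TSV."""
    path = Path(path)
    codes: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            disease = fields[0].strip()
            numbers = {c.strip() for c in fields[1].split(";") if c.strip()}
            if not disease or not numbers:
                raise FormatError(f"{path}:{lineno}: empty disease or tree-number field")
            codes.setdefault(disease, set()).update(numbers)
    if not codes:
        raise FormatError(f"{path}: no tree numbers found")
    return TreeNumberTable(codes)


def write_tree_numbers(t: TreeNumberTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for disease in t.codes:
            fh.write(f"{disease}\t{';'.join(sorted(t.codes[disease]))}\n")


def write_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    """Serialize a labeled square matrix as TSV.

    Header row of labels with a leading empty cell, then one row per label.
    Floats carry 17 significant digits so the round trip is lossless.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t" + "\t".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            cells = "\t".join("%.17g" % v for v in row)
            fh.write(f"{label}\t{cells}\n")


def read_matrix(path: str | Path, allow_missing: bool = False) -> SimilarityMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[0].strip():
        raise FormatError(f"{path}: header must start with an empty cell")
    labels = [h.strip() for h in header[1:]]
    n = len(labels)
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: {len(lines) - 1} data rows for {n} labels (non-square)")
    values = np.empty((n, n), dtype=float)
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise FormatError(f"{path}: row {i + 1} has {len(fields) - 1} cells, expected {n}")
        if normalize_id(fields[0]) != normalize_id(labels[i]):
            raise FormatError(
                f"{path}: row label {fields[0]!r} does not match column label {labels[i]!r}"
            )
        values[i] = [float(x) for x in fields[1:]]
    return SimilarityMatrix(labels, values, allow_missing=allow_missing)


def undetected_pairs(a: AssociationMatrix) -> PairIndex:
    """All pairs without a recorded association, in row-major (miRNA-major) order."""
    rows, cols = np.nonzero(a.adjacency == 0)
    return PairIndex(list(zip(rows.tolist(), cols.tolist())), label=UNDETECTED)


def write_ranking(rows: Iterable[tuple[str, str, float, int]], path: str | Path) -> None:
    """Write a (mirna_id, disease_id, score, rank) ranking TSV with header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("mirna_id\tdisease_id\tscore\trank\n")
        for m, d, score, rank in rows:
            fh.write(f"{m}\t{d}\t{score:.10g}\t{rank}\n")
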