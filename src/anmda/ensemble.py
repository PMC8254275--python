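"""The anti-noise learner: bootstrap-subsampled base models with averaged
predictions, plus novel-pair ranking.

Hidden positives mislabelled as negatives act as label noise. Drawing
several bootstrap subsets spreads that noise thinly across subsets; training
one base learner per subset and averaging the predicted probabilities (soft
voting) then dilutes each noisy point's influence on the final score. The
default base learner is a gradient-boosted tree model (LightGBM), whose
stage-wise residual fitting is itself comparatively noise-tolerant;
k-nearest-neighbour, multilayer-perceptron and logistic-regression learners
are available for the smoothing comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .data_model import (
    AssociationMatrix,
    PairDataset,
    SimilarityMatrix,
    undetected_pairs,
    write_ranking,
)
from .similarity import build_pair_features

DEFAULT_N_SUBSETS = 10

LEARNER_KINDS = ("gbm", "knn", "mlp", "logreg")


@dataclass
class SubsampleSpec:
    """Bootstrap design: number of subsets, subset size, seed.

    ``subset_size=None`` means the classic bootstrap (subsets as large as the
    training set); sampling is always with replacement.
    """

    n_subsets: int = DEFAULT_N_SUBSETS
    subset_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("need at least one subset")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


def make_learner(kind: str, params: dict[str, Any] | None = None, seed: int = 0):
    """Instantiate a base learner by kind with sensible defaults."""
    params = dict(params or {})
    if kind == "gbm":
        import lightgbm

        params.setdefault("n_estimators", 100)
        params.setdefault("num_leaves", 31)
        params.setdefault("learning_rate", 0.1)
        params.setdefault("verbose", -1)
        # small synthetic training sets need permissive leaf constraints
        params.setdefault("min_child_samples", 5)
        return lightgbm.LGBMClassifier(random_state=seed, **params)
    if kind == "knn":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if kind == "mlp":
        params.setdefault("hidden_layer_sizes", (32,))
        params.setdefault("max_iter", 300)
        return MLPClassifier(random_state=seed, **params)
    if kind == "logreg":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(f"unknown learner kind {kind!r}; choose from {LEARNER_KINDS}")


@dataclass
class EnsembleModel:
    """Fitted base learners plus the metadata to reproduce their training."""

    members: list[Any]
    learner_kind: str
    spec: SubsampleSpec
    n_features: int
    subset_indices: list[np.ndarray] = field(default_factory=list)
    learner_params: dict[str, Any] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit(
    train: PairDataset,
    spec: SubsampleSpec | None = None,
    learner_kind: str = "gbm",
    learner_params: dict[str, Any] | None = None,
) -> EnsembleModel:
    """Train the subsampled ensemble on a labeled pair dataset.

    Draws ``spec.n_subsets`` bootstrap subsets (seeded, with replacement),
    fits one base learner per subset. Raises if the training data carries a
    single class — every member needs both labels to estimate probabilities.
    """
    spec = spec or SubsampleSpec()
    X, y = train.X, train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    n = len(train)
    size = spec.subset_size if spec.subset_size is not None else n
    rng = np.random.default_rng(spec.seed)
    members: list[Any] = []
    subset_indices: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny subsets
        for s in range(spec.n_subsets):
            # resample until both classes present (bootstrap can drop one on tiny data)
            for _ in range(100):
                idx = rng.integers(0, n, size=size)
                if len(np.unique(y[idx])) == 2:
                    break
            else:
                raise ValueError("could not draw a two-class bootstrap subset")
            learner = make_learner(learner_kind, learner_params, seed=spec.seed + s)
            learner.fit(X[idx], y[idx])
            members.append(learner)
            subset_indices.append(idx)
    return EnsembleModel(
        members=members,
        learner_kind=learner_kind,
        spec=spec,
        n_features=train.n_features,
        subset_indices=subset_indices,
        learner_params=dict(learner_params or {}),
    )


def predict_proba(model: EnsembleModel, pairs: PairDataset | np.ndarray) -> np.ndarray:
    """Ensemble score: mean positive-class probability across members."""
    X = pairs.X if isinstance(pairs, PairDataset) else np.asarray(pairs, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    scores = np.zeros(X.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lightgbm feature-name chatter
        for member in model.members:
            proba = member.predict_proba(X)
            positive_col = int(np.nonzero(member.classes_ == 1)[0][0])
            scores += proba[:, positive_col]
    return scores / model.n_members


def rank_novel_pairs(
    model: EnsembleModel,
    a: AssociationMatrix,
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    top_n: int | None = None,
    per_disease: int | None = None,
) -> list[tuple[str, str, float, int]]:
    """Score and rank every undetected pair, highest score first.

    Ties break on (mirna_id, disease_id) lexicographic order. ``top_n``
    truncates the global list; ``per_disease`` instead keeps the top-N
    candidates for each disease (ranks restart per disease).
    """
    pool = undetected_pairs(a)
    feats = build_pair_features(sm, sd, pool)
    scores = predict_proba(model, feats)
    rows = [
        (a.mirna_ids[i], a.disease_ids[j], float(s))
        for (i, j), s in zip(pool.pairs, scores)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if per_disease is not None:
        out: list[tuple[str, str, float, int]] = []
        for disease in a.disease_ids:
            kept = [r for r in rows if r[1] == disease][:per_disease]
            out.extend((m, d, s, rank) for rank, (m, d, s) in enumerate(kept, start=1))
        return out
    if top_n is not None:
        rows = rows[:top_n]
    return [(m, d, s, rank) for rank, (m, d, s) in enumerate(rows, start=1)]


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist the fitted ensemble plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "format_version": 1,
        "learner_kind": model.learner_kind,
        "learner_params": model.learner_params,
        "n_members": model.n_members,
        "n_features": model.n_features,
        "subsample": {
            "n_subsets": model.spec.n_subsets,
            "subset_size": model.spec.subset_size,
            "seed": model.spec.seed,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> EnsembleModel:
    return joblib.load(path)
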