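"""Repeated cross-validation, ranking metrics, and the label-noise experiments.

The evaluation protocol is repeated stratified k-fold cross-validation
(default 5 folds, 100 repeats). Each repeat reshuffles with a derived seed,
pools the out-of-fold predictions, and computes AUROC, AUPR, precision,
recall and F1 (threshold 0.5 on the averaged probability); the report
carries the mean and sample standard deviation across repeats.

Two experiment harnesses accompany the protocol: a label-flip experiment
that contrasts a noise-free arm with an arm whose positives were partly
mislabelled (keeping both arms balanced at the same size), and a
train/test smoothing comparison that measures what bootstrap-subsampled
averaging buys a given base learner on noisy labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from . import ensemble as ens
from .data_model import AssociationMatrix, PairDataset, SimilarityMatrix
from .similarity import gip_similarity, integrate_disease_similarity, integrate_mirna_similarity

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auroc", "aupr", "precision", "recall", "f1")

DEFAULT_THRESHOLD = 0.5

#: MLP configuration for the smoothing comparison: a lightly trained,
#: high-variance net, so that subsample averaging has variance to remove.
NOISE_EXPERIMENT_MLP_PARAMS = {
    "hidden_layer_sizes": (32,),
    "max_iter": 60,
    "learning_rate_init": 0.05,
}


@dataclass
class CVProtocol:
    """Repeated k-fold design: folds, repeats, stratification, master seed."""

    n_folds: int = 5
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class MetricReport:
    """Per-repeat metric table plus mean ± std aggregates."""

    per_repeat: pd.DataFrame
    mean: pd.Series = field(init=False)
    std: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_repeat.mean()
        # sample std across repeats (ddof=1); 0 for a single repeat
        n = len(self.per_repeat)
        self.std = self.per_repeat.std(ddof=1) if n > 1 else self.per_repeat.std(ddof=0)

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": float(self.mean[m]), "std": float(self.std[m])}
            for m in self.per_repeat.columns
        }


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> dict[str, float]:
    """AUROC, AUPR and thresholded precision/recall/F1 for one score vector."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_hat = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(y_true, scores)),
        "aupr": float(average_precision_score(y_true, scores)),
        "precision": float(precision_score(y_true, y_hat, zero_division=0)),
        "recall": float(recall_score(y_true, y_hat, zero_division=0)),
        "f1": float(f1_score(y_true, y_hat, zero_division=0)),
    }


def _fold_splitter(protocol: CVProtocol, repeat_seed: int):
    cls = StratifiedKFold if protocol.stratified else KFold
    return cls(n_splits=protocol.n_folds, shuffle=True, random_state=repeat_seed)


def cross_validate(
    data: PairDataset,
    protocol: CVProtocol,
    model_factory: Callable[[int], Any] | None = None,
    spec: ens.SubsampleSpec | None = None,
    learner_kind: str = "gbm",
    learner_params: dict[str, Any] | None = None,
) -> MetricReport:
    """Repeated k-fold CV of the subsampled ensemble (or a custom factory).

    ``model_factory(seed)`` may supply any object with fit/predict_proba;
    otherwise an anti-noise ensemble with the given spec and learner kind is
    trained per fold. Per-repeat metrics are computed on the pooled
    out-of-fold predictions.
    """
    X, y = data.X, data.y
    if len(data) < protocol.n_folds:
        raise ValueError("fewer samples than folds")
    rows = []
    for repeat in range(protocol.n_repeats):
        repeat_seed = int((protocol.seed * 100003 + repeat) % (2**31 - 1))
        splitter = _fold_splitter(protocol, repeat_seed)
        pooled_scores = np.empty(len(y))
        for train_idx, test_idx in splitter.split(X, y):
            if model_factory is not None:
                model = model_factory(repeat_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X[train_idx], y[train_idx])
                    proba = model.predict_proba(X[test_idx])
                col = int(np.nonzero(model.classes_ == 1)[0][0])
                pooled_scores[test_idx] = proba[:, col]
            else:
                fold_spec = ens.SubsampleSpec(
                    n_subsets=(spec or ens.SubsampleSpec()).n_subsets,
                    subset_size=(spec or ens.SubsampleSpec()).subset_size,
                    seed=repeat_seed,
                )
                model = ens.fit(data.subset(train_idx), fold_spec, learner_kind, learner_params)
                pooled_scores[test_idx] = ens.predict_proba(model, X[test_idx])
        rows.append(compute_metrics(y, pooled_scores))
    return MetricReport(pd.DataFrame(rows, columns=list(METRIC_NAMES)))


# ---------------------------------------------------------------------------
# Label-noise experiments
# ---------------------------------------------------------------------------

def inject_label_noise(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    n_per_class: int,
    n_flip: int,
    seed: int = 0,
) -> tuple[PairDataset, PairDataset]:
    """Build matched noise-free and noisy arms from positive/negative pools.

    The noise-free arm takes ``n_per_class`` of each class. The noisy arm
    flips ``n_flip`` of those positives to negative labels, drops ``n_flip``
    original negatives and promotes ``n_flip`` reserve positives (kept
    correctly labeled), so both arms stay balanced at ``n_per_class`` per
    class and differ only by the mislabelled points.
    """
    if n_flip < 0:
        raise ValueError("n_flip must be >= 0")
    if len(X_pos) < n_per_class + n_flip:
        raise ValueError(
            f"need {n_per_class + n_flip} positives ({n_per_class} + {n_flip} reserve), "
            f"got {len(X_pos)}"
        )
    if len(X_neg) < n_per_class:
        raise ValueError(f"need {n_per_class} negatives, got {len(X_neg)}")
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(len(X_pos))
    neg_idx = rng.permutation(len(X_neg))
    pos = X_pos[pos_idx[:n_per_class]]
    reserve = X_pos[pos_idx[n_per_class : n_per_class + n_flip]]
    neg = X_neg[neg_idx[:n_per_class]]

    def _dataset(X: np.ndarray, y: np.ndarray) -> PairDataset:
        return PairDataset([(i, 0) for i in range(len(y))], X, y)

    clean = _dataset(
        np.vstack([pos, neg]),
        np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)]),
    )
    if n_flip == 0:
        return clean, clean
    flipped = pos[:n_flip]  # true positives carrying negative labels: the noise
    kept_pos = pos[n_flip:]
    kept_neg = neg[n_flip:]
    noisy = _dataset(
        np.vstack([kept_pos, reserve, flipped, kept_neg]),
        np.concatenate(
            [
                np.ones(n_per_class - n_flip, int),
                np.ones(n_flip, int),
                np.zeros(n_flip, int),
                np.zeros(n_per_class - n_flip, int),
            ]
        ),
    )
    return clean, noisy


def label_noise_experiment(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    n_flip: int,
    model_kinds: list[str],
    protocol: CVProtocol,
    n_per_class: int = 200,
    smooth: bool = False,
    n_subsets: int = ens.DEFAULT_N_SUBSETS,
    learner_params: dict[str, Any] | None = None,
    seed: int = 0,
) -> dict[str, dict[str, Any]]:
    """Evaluate model kinds on matched noise-free vs noisy arms.

    Returns, per kind, the two MetricReports and the noisy-minus-clean
    metric deltas. ``smooth=True`` wraps each kind in the subsampled
    ensemble; otherwise a single model per fold is trained.
    """
    clean, noisy = inject_label_noise(X_pos, X_neg, n_per_class, n_flip, seed=seed)
    results: dict[str, dict[str, Any]] = {}
    for kind in model_kinds:
        reports = {}
        for arm_name, arm in (("clean", clean), ("noisy", noisy)):
            if smooth:
                report = cross_validate(
                    arm, protocol,
                    spec=ens.SubsampleSpec(n_subsets=n_subsets, seed=protocol.seed),
                    learner_kind=kind, learner_params=learner_params,
                )
            else:
                report = cross_validate(
                    arm, protocol,
                    model_factory=lambda s, k=kind: ens.make_learner(k, learner_params, seed=s),
                )
            reports[arm_name] = report
        delta = {
            m: float(reports["noisy"].mean[m] - reports["clean"].mean[m])
            for m in METRIC_NAMES
        }
        results[kind] = {"clean": reports["clean"], "noisy": reports["noisy"], "delta": delta}
    return results


def smoothing_comparison(
    data: PairDataset,
    learner_kind: str,
    n_subsets: int = ens.DEFAULT_N_SUBSETS,
    test_fraction: float = 0.3,
    learner_params: dict[str, Any] | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Test AUROC of the S-subset ensemble vs the single model, one split.

    Returns ``(ensemble_auroc, single_auroc)`` on a stratified held-out
    fraction; the single model trains on the full training split.
    """
    idx = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=data.y, random_state=seed
    )
    train, test = data.subset(train_idx), data.subset(test_idx)
    model = ens.fit(
        train, ens.SubsampleSpec(n_subsets=n_subsets, seed=seed),
        learner_kind, learner_params,
    )
    ens_scores = ens.predict_proba(model, test.X)
    single = ens.make_learner(learner_kind, learner_params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single.fit(train.X, train.y)
        proba = single.predict_proba(test.X)
    col = int(np.nonzero(single.classes_ == 1)[0][0])
    return (
        float(roc_auc_score(test.y, ens_scores)),
        float(roc_auc_score(test.y, proba[:, col])),
    )


# ---------------------------------------------------------------------------
# Interaction-profile kernel leakage control
# ---------------------------------------------------------------------------

def gip_matrices(
    a: AssociationMatrix,
    mode: str = "full",
    held_out_pairs: list[tuple[int, int]] | None = None,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Compute (miRNA, disease) GIP kernels under a leakage policy.

    ``full`` uses the complete association matrix — the conventional choice,
    but test-fold associations then inform the features of test pairs.
    ``fold_safe`` zeroes the held-out pairs' cells first, so the kernel never
    sees the associations being predicted.
    """
    if mode not in ("full", "fold_safe"):
        raise ValueError(f"mode must be 'full' or 'fold_safe', got {mode!r}")
    if mode == "full":
        if held_out_pairs:
            logger.warning(
                "gip mode 'full': %d held-out association(s) still inform the kernel",
                len(held_out_pairs),
            )
        source = a
    else:
        adjacency = a.adjacency.copy()
        for i, j in held_out_pairs or []:
            adjacency[i, j] = 0
        source = AssociationMatrix(list(a.mirna_ids), list(a.disease_ids), adjacency)
    return (
        gip_similarity(source, "mirna", gamma_prime),
        gip_similarity(source, "disease", gamma_prime),
    )


def integrated_similarities(
    a: AssociationMatrix,
    ss: SimilarityMatrix,
    fsm: SimilarityMatrix,
    mode: str = "full",
    held_out_pairs: list[tuple[int, int]] | None = None,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated (miRNA, disease) similarity matrices under a GIP mode."""
    gs_m, gs_d = gip_matrices(a, mode, held_out_pairs, gamma_prime)
    return (
        integrate_mirna_similarity(fsm, gs_m),
        integrate_disease_similarity(ss, gs_d),
    )
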