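"""ROC / precision-recall curve helpers for the evaluation reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_roc_pr(
    y_true: np.ndarray,
    scores_by_label: dict[str, np.ndarray],
    out_path: str | Path | None = None,
):
    """Plot ROC and PR curves for one or more score vectors on shared axes.

    Returns the matplotlib figure; saves a PNG when ``out_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import precision_recall_curve, roc_curve, auc

    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4.2))
    for label, scores in scores_by_label.items():
        fpr, tpr, _ = roc_curve(y_true, scores)
        prec, rec, _ = precision_recall_curve(y_true, scores)
        ax_roc.plot(fpr, tpr, label=f"{label} (AUROC={auc(fpr, tpr):.3f})")
        ax_pr.plot(rec, prec, label=label)
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax_roc.set(xlabel="False positive rate", ylabel="True positive rate", title="ROC")
    ax_pr.set(xlabel="Recall", ylabel="Precision", title="Precision-Recall")
    for ax in (ax_roc, ax_pr):
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
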