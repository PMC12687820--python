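"""Cross-validated evaluation of the fused pipeline.

The harness follows the leakage-safe protocol: folds are stratified so
each validation split preserves the class balance; within every fold the
visual vocabulary, the standardizer and the classifier are refit from
training rows only, while the topological block — unsupervised and
strictly per-image — is computed once up front.  Reported metrics treat
the disease class (label 1) as positive; hard labels are the argmax of
the 2-class softmax.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from . import betti, bovw, fusion
from .model import TopoBowNetConfig, train

logger = logging.getLogger("topobow")

METRICS = ("precision", "recall", "f1", "accuracy", "auc")

#: the five named feature blocks of the fused vector (half-open ranges)
NAMED_BLOCKS = {
    "gray_tda": (0, 200),
    "red_tda": (200, 400),
    "green_tda": (400, 600),
    "blue_tda": (600, 800),
    "bovw": (800, 950),
}


def stratified_folds(labels, k: int = 20, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) per sample; stratified and seeded.

    Validation sets are disjoint, cover every sample, and keep per-fold
    class proportions within one sample of the global proportions.
    """
    labels = np.asarray(labels)
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < k:
            raise ValueError(
                f"class {cls} has only {count} samples, fewer than k={k} "
                f"folds; use a smaller k"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[val_idx] = fold
    return assignment


def compute_metrics(truth, predictions, scores) -> dict:
    """Standard binary metrics plus confusion matrix and ROC points.

    ``scores`` are positive-class probabilities.  With single-class truth
    the AUC is undefined and reported as None (never coerced to 0).
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    scores = np.asarray(scores, dtype=float)
    if not (len(truth) == len(predictions) == len(scores)):
        raise ValueError("truth, predictions and scores must share length")
    out = {
        "precision": float(precision_score(truth, predictions, zero_division=0)),
        "recall": float(recall_score(truth, predictions, zero_division=0)),
        "f1": float(f1_score(truth, predictions, zero_division=0)),
        "accuracy": float(accuracy_score(truth, predictions)),
        "confusion": confusion_matrix(truth, predictions, labels=[0, 1]),
    }
    if len(np.unique(truth)) < 2:
        out["auc"] = None
        out["roc"] = None
    else:
        out["auc"] = float(roc_auc_score(truth, scores))
        fpr, tpr, thr = roc_curve(truth, scores)
        out["roc"] = np.column_stack([fpr, tpr, thr])
    return out


@dataclass
class FoldReport:
    """Predictions and metrics of one validation fold."""

    fold: int
    sample_ids: list
    truth: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    metrics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": self.fold, "id": self.sample_ids, "truth": self.truth,
            "prediction": self.predictions, "score": self.scores,
        })


@dataclass
class CvSummary:
    """Across-fold mean and sd per metric, plus pooled predictions."""

    mean: dict
    sd: dict
    fold_reports: list
    pooled_roc: np.ndarray | None = None

    def __str__(self) -> str:
        parts = [
            f"{m}={self.mean[m]:.3f} (+/-{self.sd[m]:.3f})"
            for m in METRICS if self.mean.get(m) is not None
        ]
        return "CV summary: " + ", ".join(parts)


def summarize(fold_reports: list) -> CvSummary:
    mean, sd = {}, {}
    for m in METRICS:
        vals = [r.metrics[m] for r in fold_reports if r.metrics.get(m) is not None]
        mean[m] = float(np.mean(vals)) if vals else None
        sd[m] = float(np.std(vals)) if vals else None
    truth = np.concatenate([r.truth for r in fold_reports])
    scores = np.concatenate([r.scores for r in fold_reports])
    pooled = compute_metrics(truth, (scores >= 0.5).astype(int), scores)
    return CvSummary(mean=mean, sd=sd, fold_reports=fold_reports,
                     pooled_roc=pooled["roc"])


def extract_features(records, threshold: float = bovw.DOH_THRESHOLD):
    """Per-image TDA blocks and descriptor sets (fold-independent work)."""
    tda_blocks, descriptor_sets = [], []
    for rec in records:
        tda_blocks.append(betti.tda_features(rec))
        descriptor_sets.append(bovw.detect_and_describe(rec, threshold=threshold))
    return tda_blocks, descriptor_sets


def cross_validate(records=None, k: int = 20, seed: int = 0,
                   feature_set: str = "fused",
                   net_config: TopoBowNetConfig | None = None,
                   tda_blocks=None, descriptor_sets=None,
                   labels=None) -> CvSummary:
    """Run the full leakage-safe k-fold evaluation of the pipeline.

    ``feature_set`` selects the representation: ``fused`` (950), ``tda``
    (800) or ``bovw`` (150) — the two ablations reuse the same protocol.
    Precomputed ``tda_blocks``/``descriptor_sets`` may be passed to avoid
    repeating per-image feature extraction across runs.
    """
    if feature_set not in ("fused", "tda", "bovw"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    if records is not None:
        labels = np.array([r.label for r in records])
        ids = [r.id for r in records]
        if tda_blocks is None or descriptor_sets is None:
            tda_blocks, descriptor_sets = extract_features(records)
    else:
        labels = np.asarray(labels)
        ids = [ds.image_id for ds in descriptor_sets]
    n = len(labels)
    folds = stratified_folds(labels, k=k, seed=seed)
    tda_matrix = np.vstack([b.values for b in tda_blocks])

    reports = []
    for fold in range(k):
        t0 = time.time()
        val = folds == fold
        train_idx, val_idx = np.flatnonzero(~val), np.flatnonzero(val)

        if feature_set in ("fused", "bovw"):
            vocab = bovw.fit_vocabulary(
                [descriptor_sets[i] for i in train_idx], seed=seed)
            hist = np.vstack([
                bovw.encode_histogram(ds, vocab).values for ds in descriptor_sets
            ])
        if feature_set == "fused":
            X = np.hstack([tda_matrix, hist])
        elif feature_set == "tda":
            X = tda_matrix
        else:
            X = hist

        std = fusion.Standardizer(val_fold=fold)
        std.fit(X[train_idx], row_folds=folds[train_idx])
        Z = std.transform(X)

        cfg = net_config or TopoBowNetConfig()
        if cfg.input_dim != X.shape[1]:
            import dataclasses
            cfg = dataclasses.replace(cfg, input_dim=X.shape[1])
        trained = train(Z[train_idx], labels[train_idx],
                        Z[val_idx], labels[val_idx], config=cfg)
        proba = trained.predict_proba(Z[val_idx])
        scores = proba[:, 1]
        preds = proba.argmax(axis=1)
        rep = FoldReport(
            fold=fold, sample_ids=[ids[i] for i in val_idx],
            truth=labels[val_idx], predictions=preds, scores=scores,
        )
        rep.metrics = compute_metrics(rep.truth, rep.predictions, rep.scores)
        reports.append(rep)
        logger.info("fold %d/%d: acc=%.3f (%.1fs)", fold + 1, k,
                    rep.metrics["accuracy"], time.time() - t0)
    return summarize(reports)


def plot_block_summary(summary: pd.DataFrame, path) -> None:
    """Bar chart of class-wise block means with sd whiskers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    blocks = list(NAMED_BLOCKS)
    x = np.arange(len(blocks))
    for cls, offset, color in ((0, -0.18, "tab:blue"), (1, 0.18, "tab:red")):
        sel = summary[summary["class"] == cls].set_index("block")
        ax.bar(x + offset, sel.loc[blocks, "mean"], width=0.34,
               yerr=sel.loc[blocks, "sd"], color=color, capsize=3,
               label=f"class {cls}")
    ax.set_xticks(x, blocks)
    ax.set_ylabel("standardized mean")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_attention_heatmap(segment_scores: np.ndarray, path) -> None:
    """Heatmap of per-sample attention mass over the 5 feature segments."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.atleast_2d(segment_scores)
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(scores) + 1.5))
    im = ax.imshow(scores, cmap="viridis", aspect="auto")
    ax.set_xlabel("feature segment")
    ax.set_ylabel("sample")
    ax.set_xticks(range(scores.shape[1]))
    fig.colorbar(im, ax=ax, label="attention mass")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def feature_block_summary(features: np.ndarray, labels) -> pd.DataFrame:
    """Class-wise mean/sd per named feature block of a (n, 950) matrix."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[1] != fusion.FUSED_DIM:
        raise ValueError(f"expected {fusion.FUSED_DIM} features, "
                         f"got {features.shape[1]}")
    rows = []
    for cls in (0, 1):
        sel = features[labels == cls]
        if len(sel) == 0:
            raise ValueError(f"class {cls} is empty")
        for name, (lo, hi) in NAMED_BLOCKS.items():
            block = sel[:, lo:hi]
            rows.append({"block": name, "class": cls,
                         "mean": float(block.mean()),
                         "sd": float(block.std())})
    return pd.DataFrame(rows)
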