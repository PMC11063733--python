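"""Cross-validation harness and metric suite.

Global LOOCV withholds each known association once, reruns propagation and
projection, and ranks the held-out score against the scores of all pairs
that are never known.  Leave-one-entity-out simulates new miRNAs / isolated
diseases by blanking a whole row or column.  Metrics: ROC AUC, AUPR, and
thresholded ACC / MCC / F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from scplpa.core_io import (
    AssociationMatrix,
    DiseaseDAGSet,
    SCPLPAConfig,
    SimilarityMatrix,
)
from scplpa.projection import build_networks, score_networks

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "pr_aupr",
    "threshold_metrics",
    "loocv",
    "leave_one_entity_out",
    "parameter_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    auc: float
    aupr: float
    acc: float
    mcc: float
    f1: float
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_points: tuple[np.ndarray, np.ndarray]  # (recall, precision)
    threshold: float
    fold_count: int
    confusion: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("auc", self.auc),
            ("aupr", self.aupr),
            ("acc", self.acc),
            ("mcc", self.mcc),
            ("f1", self.f1),
            ("threshold", self.threshold),
            ("fold_count", self.fold_count),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    return scores, labels


def roc_auc(scores, labels) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Trapezoidal area under the ROC curve; equal scores share a threshold."""
    scores, labels = _as_arrays(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), (fpr, tpr)


def pr_aupr(scores, labels) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Area under the precision-recall curve via step interpolation."""
    scores, labels = _as_arrays(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positive labels")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns points from high threshold to low;
    # step-area = sum (R_k - R_{k-1}) * P_k, identical to average precision.
    area = float(-np.sum(np.diff(recall) * precision[:-1]))
    return area, (recall[::-1], precision[::-1])


def threshold_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Confusion-matrix metrics at ``score >= threshold``.

    MCC and F1 fall back to 0 when a denominator factor vanishes.
    """
    scores, labels = _as_arrays(scores, labels)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_denom) if mcc_denom > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "acc": float(acc),
        "mcc": float(mcc),
        "f1": float(f1),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def _youden_threshold(scores, labels) -> float:
    fpr, tpr, thresholds = roc_curve(labels, scores)
    # the first ROC point is a sentinel at threshold +inf; skip it
    j = (tpr - fpr)[1:]
    if j.size == 0:
        return float(np.max(scores))
    return float(thresholds[1:][int(np.argmax(j))])


def _pooled_report(scores, labels, config: SCPLPAConfig, fold_count: int) -> EvaluationReport:
    auc_val, roc_pts = roc_auc(scores, labels)
    aupr_val, pr_pts = pr_aupr(scores, labels)
    if isinstance(config.threshold_mode, (int, float)) and not isinstance(
        config.threshold_mode, bool
    ):
        threshold = float(config.threshold_mode)
    elif config.threshold_mode == "youden":
        threshold = _youden_threshold(scores, labels)
    else:
        raise ValueError(f"unknown threshold_mode {config.threshold_mode!r}")
    tm = threshold_metrics(scores, labels, threshold)
    return EvaluationReport(
        auc=auc_val,
        aupr=aupr_val,
        acc=tm["acc"],
        mcc=tm["mcc"],
        f1=tm["f1"],
        roc_points=roc_pts,
        pr_points=pr_pts,
        threshold=threshold,
        fold_count=fold_count,
        confusion={k: tm[k] for k in ("tp", "fp", "tn", "fn")},
    )


def _fold_networks(assoc, md, dags, dd, mm, config, base_nets):
    """Networks for one fold: reuse the full-data networks unless refreshing."""
    if not config.refresh_gip_per_fold:
        return base_nets
    fold_assoc = assoc.with_values(md)
    return build_networks(fold_assoc, dags=dags, dd=dd, mm=mm, config=config)


def loocv(
    assoc: AssociationMatrix,
    dags: DiseaseDAGSet | None = None,
    dd: SimilarityMatrix | None = None,
    mm: SimilarityMatrix | None = None,
    config: SCPLPAConfig | None = None,
) -> EvaluationReport:
    """Global leave-one-out cross-validation over known associations.

    Each known pair is zeroed in turn and rescored by the pipeline; its
    held-out score is a positive.  Negatives are the scores of all pairs
    unknown in the full data, taken from the full-data run.  By default the
    data-derived similarities are built once from the full matrix
    (``refresh_gip_per_fold`` recomputes them inside every fold).
    """
    config = config or SCPLPAConfig()
    known = np.argwhere(assoc.values == 1)
    if len(known) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    base_nets = build_networks(assoc, dags=dags, dd=dd, mm=mm, config=config)
    full_bundle = score_networks(base_nets, assoc.values, assoc, config)
    pos_scores = np.empty(len(known))
    for k, (i, j) in enumerate(known):
        md = assoc.values.copy()
        md[i, j] = 0.0
        try:
            nets = _fold_networks(assoc, md, dags, dd, mm, config, base_nets)
            bundle = score_networks(nets, md, assoc, config)
        except Exception as exc:
            raise RuntimeError(
                f"LOOCV fold failed for pair ({assoc.mirna_names[i]}, "
                f"{assoc.disease_names[j]}): {exc}"
            ) from exc
        pos_scores[k] = bundle.md_star[i, j]
    neg_scores = full_bundle.md_star[assoc.values == 0]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    return _pooled_report(scores, labels, config, fold_count=len(known))


def leave_one_entity_out(
    assoc: AssociationMatrix,
    dags: DiseaseDAGSet | None = None,
    dd: SimilarityMatrix | None = None,
    mm: SimilarityMatrix | None = None,
    config: SCPLPAConfig | None = None,
    axis: str = "mirna",
) -> EvaluationReport:
    """Cold-start cross-validation: blank one entity's row/column per fold.

    ``axis='mirna'`` simulates new miRNAs (row blanked), ``axis='disease'``
    isolated diseases (column blanked).  Per fold, the entity's true
    associations are ranked against its non-associations; the pooled scores
    give the report.  Entities with no associations are skipped and logged.
    """
    config = config or SCPLPAConfig()
    if axis not in ("mirna", "disease"):
        raise ValueError("axis must be 'mirna' or 'disease'")
    n_entities = assoc.nm if axis == "mirna" else assoc.nd
    if n_entities < 2:
        raise ValueError("need at least two entities on the chosen axis")
    base_nets = build_networks(assoc, dags=dags, dd=dd, mm=mm, config=config)
    names = assoc.mirna_names if axis == "mirna" else assoc.disease_names
    scores_pool: list[np.ndarray] = []
    labels_pool: list[np.ndarray] = []
    folds = 0
    for e in range(n_entities):
        truth = assoc.values[e] if axis == "mirna" else assoc.values[:, e]
        if truth.sum() == 0:
            logger.info("skipping %s %r: no known associations", axis, names[e])
            continue
        md = assoc.values.copy()
        if axis == "mirna":
            md[e, :] = 0.0
        else:
            md[:, e] = 0.0
        nets = _fold_networks(assoc, md, dags, dd, mm, config, base_nets)
        bundle = score_networks(nets, md, assoc, config)
        entity_scores = bundle.md_star[e] if axis == "mirna" else bundle.md_star[:, e]
        scores_pool.append(entity_scores)
        labels_pool.append(truth)
        folds += 1
    if folds == 0:
        raise ValueError("no entity on the chosen axis has any association")
    scores = np.concatenate(scores_pool)
    labels = np.concatenate(labels_pool)
    return _pooled_report(scores, labels, config, fold_count=folds)


def parameter_sweep(
    assoc: AssociationMatrix,
    dags: DiseaseDAGSet | None = None,
    dd: SimilarityMatrix | None = None,
    mm: SimilarityMatrix | None = None,
    config: SCPLPAConfig | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sequential conditional sweep of (alpha=beta, delta, epsilon) by LOOCV AUC.

    Stage 1 fixes delta = epsilon = 0.5 and sweeps alpha = beta over the
    grid; stage 2 fixes the best alpha and sweeps delta (epsilon = 0.5);
    stage 3 fixes the best delta and sweeps epsilon.  Returns one row per
    grid point with the stage label and the AUC.
    """
    config = config or SCPLPAConfig()
    if grid is None:
        grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("parameter grid must be nonempty")

    rows = []

    def _auc_for(cfg: SCPLPAConfig) -> float:
        return loocv(assoc, dags=dags, dd=dd, mm=mm, config=cfg).auc

    best_alpha = None
    for a in grid:
        cfg = config.updated(alpha=float(a), beta=float(a), delta=0.5, epsilon=0.5)
        rows.append(("alpha", float(a), cfg.alpha, cfg.delta, cfg.epsilon, _auc_for(cfg)))
    stage = [r for r in rows if r[0] == "alpha"]
    best_alpha = max(stage, key=lambda r: r[5])[1]

    for dlt in grid:
        cfg = config.updated(alpha=best_alpha, beta=best_alpha, delta=float(dlt), epsilon=0.5)
        rows.append(("delta", float(dlt), cfg.alpha, cfg.delta, cfg.epsilon, _auc_for(cfg)))
    stage = [r for r in rows if r[0] == "delta"]
    best_delta = max(stage, key=lambda r: r[5])[1]

    for eps in grid:
        cfg = config.updated(
            alpha=best_alpha, beta=best_alpha, delta=best_delta, epsilon=float(eps)
        )
        rows.append(("epsilon", float(eps), cfg.alpha, cfg.delta, cfg.epsilon, _auc_for(cfg)))

    return pd.DataFrame(
        rows, columns=["stage", "value", "alpha", "delta", "epsilon", "auc"]
    )
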