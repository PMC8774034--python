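"""Metrics, fixed-specificity operating points, and the cross-validation harness."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DataError
from .graph import normalize_adjacency
from .model import Hyperparams, train
from .pipeline import SideInformation, build_similarities
from .types import AssociationMatrix

__all__ = [
    "MetricReport",
    "FoldResult",
    "CVResult",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "sensitivity_at_specificity",
    "five_fold_cv",
    "hyperparameter_sweep",
]


@dataclass
class MetricReport:
    sen: float
    spec: float
    acc: float
    pre: float
    f1: float
    mcc: float
    threshold: float
    auroc: float | None = None
    aupr: float | None = None


def _as_arrays(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise DataError("labels and scores must be 1-d and the same length")
    if labels.min(initial=1) < 0 or labels.max(initial=0) > 1:
        raise DataError("labels must be binary")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DataError("both classes must be present")
    return labels, scores


def confusion_metrics(labels, scores, threshold: float) -> MetricReport:
    """Threshold at ``score >= threshold`` and evaluate all six summary metrics.

    The Matthews coefficient returns 0 when its denominator vanishes.
    """
    labels, scores = _as_arrays(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sen = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tn + tp) / (tn + tp + fn + fp)
    pre = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * pre * sen / (pre + sen) if (pre + sen) > 0 else 0.0
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricReport(
        sen=sen, spec=spec, acc=acc, pre=pre, f1=f1, mcc=mcc, threshold=threshold
    )


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + P(tie)/2."""
    labels, scores = _as_arrays(labels, scores)
    return float(roc_auc_score(labels, scores))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    labels, scores = _as_arrays(labels, scores)
    return float(average_precision_score(labels, scores))


def sensitivity_at_specificity(
    labels, scores, target_spec: float = 0.99
) -> MetricReport:
    """Metrics at the smallest threshold whose specificity reaches the target."""
    labels, scores = _as_arrays(labels, scores)
    n_neg = int(np.sum(labels == 0))
    if n_neg * (1.0 - target_spec) < 1.0:
        raise DataError(
            f"{n_neg} negatives cannot resolve specificity {target_spec}; "
            f"need at least {math.ceil(1.0 / (1.0 - target_spec))}"
        )
    neg_scores = np.sort(scores[labels == 0])
    for t in np.unique(scores):
        # specificity at threshold t: negatives strictly below t
        spec = np.searchsorted(neg_scores, t, side="left") / n_neg
        if spec >= target_spec:
            report = confusion_metrics(labels, scores, t)
            report.auroc = roc_auc(labels, scores)
            report.aupr = pr_auc(labels, scores)
            return report
    # threshold above the top score: all-negative prediction, specificity 1
    top = float(scores.max())
    report = confusion_metrics(labels, scores, np.nextafter(top, np.inf))
    report.auroc = roc_auc(labels, scores)
    report.aupr = pr_auc(labels, scores)
    return report


@dataclass
class FoldResult:
    repeat: int
    fold: int
    auroc: float
    aupr: float
    fixed_spec: MetricReport | None
    n_test_positives: int
    epochs_run: int


@dataclass
class CVResult:
    folds: list[FoldResult]
    mean_auroc: float = field(init=False)
    std_auroc: float = field(init=False)
    mean_aupr: float = field(init=False)
    std_aupr: float = field(init=False)

    def __post_init__(self) -> None:
        aurocs = np.array([f.auroc for f in self.folds])
        auprs = np.array([f.aupr for f in self.folds])
        self.mean_auroc = float(aurocs.mean())
        self.std_auroc = float(aurocs.std())
        self.mean_aupr = float(auprs.mean())
        self.std_aupr = float(auprs.std())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {
                "repeat": f.repeat,
                "fold": f.fold,
                "auroc": f.auroc,
                "aupr": f.aupr,
                "n_test_positives": f.n_test_positives,
                "epochs_run": f.epochs_run,
            }
            if f.fixed_spec is not None:
                row.update(
                    sen_at_spec=f.fixed_spec.sen,
                    acc_at_spec=f.fixed_spec.acc,
                    pre_at_spec=f.fixed_spec.pre,
                    f1_at_spec=f.fixed_spec.f1,
                    mcc_at_spec=f.fixed_spec.mcc,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _fold_partition(
    n_positives: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    perm = rng.permutation(n_positives)
    return np.array_split(perm, n_folds)


def five_fold_cv(
    Y: AssociationMatrix,
    hp: Hyperparams,
    side: SideInformation | None = None,
    n_folds: int = 5,
    n_repeats: int = 1,
    target_spec: float = 0.99,
) -> CVResult:
    """Leak-free cross-validation over the known positive entries.

    Per fold the held-out positives are zeroed in the training copy of Y and
    every Y-derived quantity (Gaussian kernels, fused similarities,
    normalized graphs) is recomputed from that training matrix. Held-out
    positives are scored against all pairs that are zero in the full matrix.
    """
    side = side or SideInformation()
    positives = np.argwhere(Y.values == 1)
    if len(positives) < n_folds:
        raise DataError(f"need at least {n_folds} positive entries, got {len(positives)}")
    negatives_mask = Y.values == 0
    neg_idx = np.where(negatives_mask.ravel())[0]
    rng = np.random.default_rng(hp.seed)
    folds: list[FoldResult] = []
    for repeat in range(n_repeats):
        for fold, test_ids in enumerate(_fold_partition(len(positives), n_folds, rng)):
            if len(test_ids) == 0:
                raise DataError("empty test fold")
            test_pairs = positives[test_ids]
            Y_train = Y.copy()
            Y_train.values[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
            Sm, Sd = build_similarities(Y_train, side)
            Am, Ad = normalize_adjacency(Sm), normalize_adjacency(Sd)
            fold_hp = replace(hp, seed=hp.seed + 7919 * repeat + 104729 * fold)
            bundle, losses, _ = train(Y_train, Am, Ad, fold_hp)
            flat = bundle.F.ravel()
            scores = np.concatenate(
                [bundle.F[test_pairs[:, 0], test_pairs[:, 1]], flat[neg_idx]]
            )
            labels = np.concatenate(
                [np.ones(len(test_pairs), dtype=int), np.zeros(len(neg_idx), dtype=int)]
            )
            fixed = None
            try:
                fixed = sensitivity_at_specificity(labels, scores, target_spec)
            except DataError:
                pass  # too few negatives at this scale; AUROC/AUPR still valid
            folds.append(
                FoldResult(
                    repeat=repeat,
                    fold=fold,
                    auroc=roc_auc(labels, scores),
                    aupr=pr_auc(labels, scores),
                    fixed_spec=fixed,
                    n_test_positives=len(test_pairs),
                    epochs_run=len(losses),
                )
            )
    return CVResult(folds)


def hyperparameter_sweep(
    Y: AssociationMatrix,
    base_hp: Hyperparams,
    grid: dict[str, list],
    side: SideInformation | None = None,
    n_folds: int = 5,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Cross-validate every point of a cartesian hyperparameter grid."""
    import itertools

    names = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[name] for name in names)):
        hp = replace(base_hp, **dict(zip(names, combo)))
        result = five_fold_cv(Y, hp, side=side, n_folds=n_folds, n_repeats=n_repeats)
        row = dict(zip(names, combo))
        row.update(
            mean_auroc=result.mean_auroc,
            std_auroc=result.std_auroc,
            mean_aupr=result.mean_aupr,
            std_aupr=result.std_aupr,
        )
        rows.append(row)
    return pd.DataFrame(rows)
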