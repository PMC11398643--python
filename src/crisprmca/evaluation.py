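"""Cross-validation harness and imbalance-aware metrics.

Evaluation follows the protocol standard for heavily imbalanced off-target
data: stratified 5-fold cross-validation reporting Recall (at a 0.5
probability threshold), ROC-AUC, and PR-AUC, with PR-AUC preferred as the
headline metric under imbalance.  Within each fold, 10% of the validation
records are split off as a tuning subset used for early stopping; metrics
are reported on the remaining 90%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

from .encodings import encode_dataset
from .errors import ConfigurationError, UndefinedMetricError
from .pairs import GuideTargetPair

METRIC_NAMES = ("recall", "roc_auc", "pr_auc")


@dataclass(frozen=True)
class FoldAssignment:
    """Index sets for one CV fold.

    ``val_idx`` is the full held-out fold; ``tune_idx`` is the 10% tuning
    subset of it and ``eval_idx`` the remaining 90% on which metrics are
    reported.
    """

    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    tune_idx: np.ndarray
    eval_idx: np.ndarray


def kfold_split(
    labels: np.ndarray | list[int],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
    groups: np.ndarray | list | None = None,
    tune_fraction: float = 0.1,
) -> list[FoldAssignment]:
    """Partition record indices into k folds with a per-fold tuning subset.

    Stratified by label by default so rare positives appear in every fold;
    falls back (with a warning) to plain shuffled K-fold when a class has
    fewer than k members.  Passing ``groups`` (e.g. the guide sequence of
    each record) switches to group-wise splitting instead.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < k:
        raise ConfigurationError(f"dataset of size {n} cannot be split into {k} folds")
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        split_iter = splitter.split(np.zeros(n), labels, groups=np.asarray(groups))
    elif stratified and np.bincount(labels, minlength=2).min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        if stratified:
            warnings.warn(
                "fewer members of a class than folds; falling back to non-stratified K-fold"
            )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    rng = np.random.default_rng(seed)
    folds = []
    for i, (train_idx, val_idx) in enumerate(split_iter):
        n_tune = max(1, int(round(tune_fraction * len(val_idx))))
        perm = rng.permutation(len(val_idx))
        tune_idx = np.sort(val_idx[perm[:n_tune]])
        eval_idx = np.sort(val_idx[perm[n_tune:]])
        folds.append(
            FoldAssignment(
                fold=i,
                train_idx=np.sort(train_idx),
                val_idx=np.sort(val_idx),
                tune_idx=tune_idx,
                eval_idx=eval_idx,
            )
        )
    return folds


def compute_metrics(
    labels: np.ndarray | list[int],
    scores: np.ndarray | list[float],
    threshold: float = 0.5,
) -> dict[str, float]:
    """Recall at ``threshold``, ROC-AUC (trapezoid), PR-AUC (step integral).

    PR-AUC is the non-interpolated step integral over the precision-recall
    curve, sum_n (R_n - R_{n-1}) P_n.  Single-class label vectors make the
    ranking metrics undefined and raise
    :class:`~crisprmca.errors.UndefinedMetricError`.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ConfigurationError("labels and scores must have matching shapes")
    if not np.isin(labels, (0, 1)).all():
        raise ConfigurationError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "ROC-AUC and PR-AUC are undefined for single-class label vectors"
        )
    pred = scores >= threshold
    n_pos = int(labels.sum())
    recall = float((pred & (labels == 1)).sum() / n_pos)
    return {
        "recall": recall,
        "roc_auc": float(roc_auc_score(labels, scores)),
        "pr_auc": float(average_precision_score(labels, scores)),
    }


@dataclass
class CVResult:
    """Per-fold metrics with means and standard deviations."""

    folds: pd.DataFrame
    fold_assignments: list[FoldAssignment]
    seed: int

    @property
    def means(self) -> pd.Series:
        return self.folds[list(METRIC_NAMES)].mean()

    @property
    def sds(self) -> pd.Series:
        return self.folds[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> str:
        lines = [f"{len(self.folds)}-fold cross-validation (seed {self.seed})"]
        for m in METRIC_NAMES:
            lines.append(f"  {m:8s} {self.means[m]:.3f} ± {self.sds[m]:.3f}")
        return "\n".join(lines)


def cross_validate(
    pairs: list[GuideTargetPair],
    model_factory,
    k: int = 5,
    seed: int = 0,
    scheme: str = "C3_24x7",
    augment=None,
    threshold: float = 0.5,
    stratified: bool = True,
    groups=None,
) -> CVResult:
    """k-fold cross-validation of a classifier over a pair dataset.

    ``model_factory(X, y, seed)`` must return an object whose ``fit(X_tune,
    y_tune)`` returns a results object with ``predict_proba``; a fresh model
    is built per fold.  ``augment(train_pairs, heldout_pairs)``, if given,
    is applied to the training-fold records only (the held-out fold is
    passed solely so leakage rules can be enforced) and must return the
    augmented list of pairs — this is where ESB rebalancing plugs in.
    """
    labels = np.array([p.label for p in pairs], dtype=int)
    folds = kfold_split(labels, k=k, seed=seed, stratified=stratified, groups=groups)
    rows = []
    for fa in folds:
        train_pairs = [pairs[i] for i in fa.train_idx]
        heldout_pairs = [pairs[i] for i in fa.val_idx]
        if augment is not None:
            train_pairs = augment(train_pairs, heldout_pairs)
        X_train = encode_dataset(train_pairs, scheme)
        y_train = np.array([p.label for p in train_pairs], dtype=int)
        X_tune = encode_dataset([pairs[i] for i in fa.tune_idx], scheme)
        y_tune = labels[fa.tune_idx]
        X_eval = encode_dataset([pairs[i] for i in fa.eval_idx], scheme)
        y_eval = labels[fa.eval_idx]
        fold_seed = (seed * 1000 + fa.fold) % (2**31 - 1)
        model = model_factory(X_train, y_train, fold_seed)
        result = model.fit(X_tune, y_tune)
        scores = result.predict_proba(X_eval)[:, 1]
        metrics = compute_metrics(y_eval, scores, threshold=threshold)
        rows.append({"fold": fa.fold, "n_train": len(y_train), **metrics})
    return CVResult(folds=pd.DataFrame(rows), fold_assignments=folds, seed=seed)
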