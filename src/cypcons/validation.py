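"""Confusion-matrix metrics and the repeated tenfold cross-validation harness.

The potent class is positive throughout.  Cross-validation follows the
leave-10%-out scheme: each repeat shuffles the compounds into k equal
portions, each portion is held out in turn, the classifier is retrained
from scratch on the rest (no information carry-over), and the metrics are
averaged separately over the 90% training fits ("split") and the held-out
evaluations ("CV").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    correct_classification: float
    type_i_error: float
    type_ii_error: float
    sd: dict = field(default_factory=dict)  # over CV repeats, when aggregated
    flags: list[str] = field(default_factory=list)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity and accuracy; undefined ratios are flagged NaN."""
    flags = []
    pos, neg = c.tp + c.fn, c.tn + c.fp
    total = pos + neg
    if total == 0:
        raise ValueError("empty confusion matrix")
    if pos > 0:
        sens = c.tp / pos
    else:
        sens, flags = float("nan"), flags + ["no positives: sensitivity undefined"]
    if neg > 0:
        spec = c.tn / neg
    else:
        spec, flags = float("nan"), flags + ["no negatives: specificity undefined"]
    correct = (c.tp + c.tn) / total
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        correct_classification=correct,
        type_i_error=1.0 - spec,
        type_ii_error=1.0 - sens,
        flags=flags,
    )


def confusion_from_calls(truth: Sequence[str], calls: Sequence[str]) -> ConfusionCounts:
    t = np.asarray([str(v).upper() in ("P", "POTENT", "1", "TRUE") for v in truth])
    c = np.asarray([str(v).upper() in ("P", "POTENT", "1", "TRUE") for v in calls])
    return ConfusionCounts(
        tp=int((t & c).sum()), fp=int((~t & c).sum()), tn=int((~t & ~c).sum()), fn=int((t & ~c).sum())
    )


Trainer = Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], Sequence[str]]]
"""A trainer takes (features, boolean-ish labels) and returns a predictor
mapping a feature table to per-compound 'P'/'W' calls."""


def _fold_indices(n: int, k: int, rng: np.random.Generator, stratified: bool, y: np.ndarray) -> list[np.ndarray]:
    if stratified:
        folds: list[list[int]] = [[] for _ in range(k)]
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for i, j in enumerate(idx):
                folds[i % k].append(j)
        return [np.sort(np.array(f)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def kfold_cv(
    trainer: Trainer,
    data: pd.DataFrame,
    labels,
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[MetricsReport, MetricsReport]:
    """Repeated k-fold cross-validation; returns (split-training, held-out) reports.

    A fold whose training part lacks a class is redrawn once; a second
    failure is an error.  With a fixed seed the partitions and the reports
    are fully deterministic (given a deterministic trainer).
    """
    y = np.asarray([1 if str(v).upper() in ("P", "POTENT", "1", "TRUE") else 0 for v in np.asarray(labels)])
    n = len(y)
    if k > n:
        raise ValueError("k cannot exceed the number of compounds")
    rng = np.random.default_rng(seed)
    split_rows, cv_rows = [], []
    for _ in range(repeats):
        def _complete(fs):
            return all(len(np.unique(y[np.setdiff1d(np.arange(n), f)])) == 2 for f in fs)

        folds = _fold_indices(n, k, rng, stratified, y)
        if not _complete(folds):
            folds = _fold_indices(n, k, rng, stratified, y)  # resample once
            if not _complete(folds):
                raise ValueError("a training fold lacked one class even after resampling")
        for fold in folds:
            train_idx = np.setdiff1d(np.arange(n), fold)
            predictor = trainer(data.iloc[train_idx], y[train_idx])
            truth_tr = np.where(y[train_idx] == 1, "P", "W")
            truth_te = np.where(y[fold] == 1, "P", "W")
            split_rows.append(metrics(confusion_from_calls(truth_tr, predictor(data.iloc[train_idx]))))
            cv_rows.append(metrics(confusion_from_calls(truth_te, predictor(data.iloc[fold]))))
    return _aggregate(split_rows), _aggregate(cv_rows)


_FIELDS = ("sensitivity", "specificity", "correct_classification", "type_i_error", "type_ii_error")


def _aggregate(reports: list[MetricsReport]) -> MetricsReport:
    vals = {f: np.array([getattr(r, f) for r in reports], dtype=float) for f in _FIELDS}
    means = {f: float(np.nanmean(v)) for f, v in vals.items()}
    sds = {f: float(np.nanstd(v, ddof=1)) if np.isfinite(v).sum() > 1 else float("nan") for f, v in vals.items()}
    flags = sorted({fl for r in reports for fl in r.flags})
    return MetricsReport(sd=sds, flags=flags, **means)
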