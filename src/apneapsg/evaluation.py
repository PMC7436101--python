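"""SVM evaluation stage: under-sampled, cross-validated kernel grid and the
cumulative class hill-climb.

Within every training fold the majority class is randomly under-sampled to
the minority count (the test fold is never touched), features are z-scored
with training-fold statistics, and a soft-margin SVM is fitted.  Kernels:
linear x.y, inhomogeneous polynomial (x.y + 1)^d, and RBF
exp(-||x-y||^2 / (2 sigma^2)); the regularization constant is written R.
Fold metrics are sensitivity, specificity, accuracy and AUC on the 0-100
scale (apnea is the positive class).

The hill-climb evaluates the cumulative class sets A, AB, ..., ABCDE
against every grid configuration and keeps the set with the greatest mean
accuracy across configurations; ties go to the smaller accuracy spread,
then to the smaller (earlier) set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import CLASS_ORDER, SelectionResult

log = logging.getLogger(__name__)

DEFAULT_K = 10
POSITIVE_LABEL = "A"


@dataclass(frozen=True)
class KernelConfig:
    kernel: str  # linear | poly | rbf
    R: float
    d: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.kernel == "poly" and not self.d:
            raise ValueError("poly kernel needs a degree")
        if self.kernel == "rbf" and not self.sigma:
            raise ValueError("rbf kernel needs a width")

    @property
    def name(self) -> str:
        if self.kernel == "poly":
            return f"poly d={self.d} R={self.R:g}"
        if self.kernel == "rbf":
            return f"rbf sigma={self.sigma:g} R={self.R:g}"
        return f"linear R={self.R:g}"


def default_grid(r_values=(0.2, 1.0, 10.0), degrees=(2, 3, 4),
                 sigmas=(1.0, 5.0, 25.0)) -> list[KernelConfig]:
    grid = [KernelConfig("rbf", r, sigma=s) for s, r in product(sigmas, r_values)]
    grid += [KernelConfig("poly", r, d=d) for d, r in product(degrees, r_values)]
    grid += [KernelConfig("linear", r) for r in r_values]
    return grid


@dataclass
class CVEvaluation:
    config: KernelConfig
    class_set: str
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_accuracy: np.ndarray
    fold_auc: np.ndarray

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))


def undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced subset: all minority kept, majority subsampled."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("undersampling needs both labels present")
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if cls != minority and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def make_svm(cfg: KernelConfig) -> SVC:
    if cfg.kernel == "linear":
        return SVC(kernel="linear", C=cfg.R)
    if cfg.kernel == "poly":
        return SVC(kernel="poly", C=cfg.R, degree=cfg.d, gamma=1.0, coef0=1.0)
    return SVC(kernel="rbf", C=cfg.R, gamma=1.0 / (2.0 * cfg.sigma**2))


def train_svm(x: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> SVC:
    """Fit a soft-margin SVM on standardized features; returns the model
    (use ``decision_function`` for signed scores)."""
    model = make_svm(cfg)
    model.fit(x, (np.asarray(y) == POSITIVE_LABEL).astype(int))
    return model


def metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("confusion must contain both true classes")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return sens, spec, acc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC (percent) by the Mann-Whitney identity; ties get half credit."""
    y = (np.asarray(labels) == POSITIVE_LABEL).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC needs both labels present")
    return 100.0 * float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def kfold_cv(x: np.ndarray, y: np.ndarray, cfg: KernelConfig,
             k: int = DEFAULT_K, seed: int = 0, class_set: str = "") -> CVEvaluation:
    """Stratified k-fold CV with in-fold under-sampling and standardization."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    sens_l, spec_l, acc_l, auc_l = [], [], [], []
    for train_idx, test_idx in skf.split(x, y):
        bal = train_idx[undersample(y[train_idx], rng)]
        scaler = StandardScaler().fit(x[bal])
        model = train_svm(scaler.transform(x[bal]), y[bal], cfg)
        scores = model.decision_function(scaler.transform(x[test_idx]))
        pred = scores > 0
        truth = y[test_idx] == POSITIVE_LABEL
        tp = int(np.sum(pred & truth))
        tn = int(np.sum(~pred & ~truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        sens, spec, acc = metrics(tp, tn, fp, fn)
        sens_l.append(sens)
        spec_l.append(spec)
        acc_l.append(acc)
        auc_l.append(roc_auc(scores, y[test_idx]))
    return CVEvaluation(cfg, class_set, np.array(sens_l), np.array(spec_l),
                        np.array(acc_l), np.array(auc_l))


@dataclass
class HillClimbResult:
    table: pd.DataFrame            # one row per (class set, config)
    chosen_set: str                # e.g. "A" or "AB"
    chosen_features: list[str]
    per_set_mean_acc: dict[str, float] = field(default_factory=dict)


def cumulative_class_sets(sr: SelectionResult) -> dict[str, list[str]]:
    """Cumulative feature lists A, AB, ..., ABCDE (in registry order)."""
    sets: dict[str, list[str]] = {}
    acc: list[str] = []
    for label in CLASS_ORDER:
        acc = acc + sr.class_members(label)
        sets["".join(CLASS_ORDER[: CLASS_ORDER.index(label) + 1])] = list(acc)
    return sets


def hill_climb(features: pd.DataFrame, sr: SelectionResult,
               grid: list[KernelConfig] | None = None,
               k: int = DEFAULT_K, seed: int = 0) -> HillClimbResult:
    """Evaluate cumulative class sets against the kernel grid; keep the set
    with the best mean accuracy across configurations."""
    if grid is None:
        grid = default_grid()
    y = features["label"].to_numpy()
    sets = cumulative_class_sets(sr)
    rows = []
    per_set_acc: dict[str, list[float]] = {}
    per_set_std: dict[str, float] = {}
    for set_name, cols in sets.items():
        if not cols:
            log.info("class set %s is empty; skipped", set_name)
            continue
        x = features[cols].to_numpy(float)
        x = np.nan_to_num(x, nan=0.0)
        accs = []
        for cfg in grid:
            ev = kfold_cv(x, y, cfg, k=k, seed=seed, class_set=set_name)
            accs.append(ev.mean_accuracy)
            rows.append({
                "class_set": set_name, "config": cfg.name,
                "sensitivity": ev.mean_sensitivity,
                "specificity": ev.mean_specificity,
                "accuracy": ev.mean_accuracy, "auc": ev.mean_auc,
                "accuracy_std": float(np.std(ev.fold_accuracy, ddof=1)),
            })
        per_set_acc[set_name] = accs
        per_set_std[set_name] = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    if not per_set_acc:
        raise ValueError("no non-empty class set to evaluate")
    means = {s: float(np.mean(a)) for s, a in per_set_acc.items()}
    # best mean accuracy; ties -> smaller std across configs -> earlier set
    chosen = min(means, key=lambda s: (-round(means[s], 10),
                                       round(per_set_std[s], 10), len(s)))
    return HillClimbResult(pd.DataFrame(rows), chosen, sets[chosen], means)
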