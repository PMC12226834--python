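"""Class-weighted kernel SVMs with exhaustive leave-two-out cross-validation.

The classifier is a soft-margin C-classification SVM. Hyperparameters
(kernel function and cost) are chosen by grid search over a predetermined
range, scored by inner cross-validated accuracy ("model tuning"). Validation
is an exhaustive leave-two-out scheme: every (cub-present, cub-absent) pair
of samples is withheld in turn, the remaining data are standardized, tuned
and fitted, and the two withheld samples are predicted — so every prediction
comes from a model that never saw the predicted sample. Sensitivity is the
proportion of cub-present test predictions that were correct, specificity
the same for cub-absent, accuracy the proportion of all predictions correct.

Class weighting (default: inverse class frequency) keeps the larger class
from dominating the fit when sample sizes are asymmetric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "DEFAULT_KERNELS",
    "DEFAULT_COSTS",
    "SvmConfig",
    "CVReport",
    "train_svm",
    "tune",
    "leave_two_out_cv",
    "classification_metrics",
]

POSITIVE_LABEL = "cub_present"
NEGATIVE_LABEL = "cub_absent"

#: kernel preference order for tie-breaking (and the default tuning set)
DEFAULT_KERNELS = ("linear", "radial", "polynomial", "sigmoid")
#: default cost grid: a superset of typical best-performing values
DEFAULT_COSTS = (0.01, 0.1, 1.0, 3.0, 4.0, 5.0, 10.0, 50.0)

_SKLEARN_KERNEL = {
    "linear": "linear",
    "radial": "rbf",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
}


@dataclass(frozen=True)
class SvmConfig:
    """One point of the hyperparameter grid.

    gamma defaults to 1/n_features; degree/coef0 follow the common
    polynomial-kernel defaults.
    """

    kernel: str = "radial"
    cost: float = 1.0
    gamma: float | str = "auto"  # sklearn 'auto' = 1 / n_features
    degree: int = 3
    coef0: float = 0.0
    class_weights: dict[str, float] | None = None  # None -> inverse frequency

    def __post_init__(self) -> None:
        if self.kernel not in _SKLEARN_KERNEL:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ValueError("class weights must be > 0")


def _weights(labels: np.ndarray, config: SvmConfig) -> dict[str, float]:
    if config.class_weights is not None:
        return dict(config.class_weights)
    classes, counts = np.unique(labels, return_counts=True)
    n = labels.size
    return {c: n / (len(classes) * k) for c, k in zip(classes, counts)}


def train_svm(X, labels, config: SvmConfig) -> SVC:
    """Fit a soft-margin kernel SVM with per-class penalties
    cost * class_weight(label). Deterministic for fixed data and config."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(
        C=config.cost,
        kernel=_SKLEARN_KERNEL[config.kernel],
        gamma=config.gamma,
        degree=config.degree,
        coef0=config.coef0,
        class_weight=_weights(labels, config),
    )
    clf.fit(X, labels)
    return clf


def _inner_cv_accuracy(X, labels, config: SvmConfig, seed: int) -> float:
    """Stratified 10-fold inner-CV accuracy (leave-one-out when the smaller
    class has < 10 samples). Folds are redrawn with stratification by
    construction, so no fold can miss a class under k-fold."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    correct = 0
    total = 0
    for tr, te in splitter.split(X, labels):
        if np.unique(labels[tr]).size < 2:
            # LOO can strand a 1-sample class in the test slot; skip that split
            continue
        clf = train_svm(X[tr], labels[tr], config)
        pred = clf.predict(X[te])
        correct += int((pred == labels[te]).sum())
        total += te.size
    return correct / total if total else 0.0


def tune(
    X,
    labels,
    kernels: tuple[str, ...] = DEFAULT_KERNELS,
    costs: tuple[float, ...] = DEFAULT_COSTS,
    seed: int = 0,
    base_config: SvmConfig = SvmConfig(),
) -> SvmConfig:
    """Grid-search kernel x cost by inner-CV accuracy.

    Ties break toward the smaller cost, then the kernel order
    linear < radial < polynomial < sigmoid. A single-point grid is returned
    directly (no inner CV). Deterministic given ``seed``.
    """
    grid = list(itertools.product(kernels, costs))
    if not grid:
        raise ValueError("empty tuning grid")
    if len(grid) == 1:
        k, c = grid[0]
        return replace(base_config, kernel=k, cost=c)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    best = None
    for k, c in grid:
        cfg = replace(base_config, kernel=k, cost=c)
        acc = _inner_cv_accuracy(X, labels, cfg, seed)
        key = (-acc, c, DEFAULT_KERNELS.index(k))
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1]


@dataclass
class CVReport:
    """Results of an exhaustive leave-two-out cross-validation."""

    predictions: pd.DataFrame = field(repr=False)
    sensitivity: float
    specificity: float
    accuracy: float
    n_present: int
    n_absent: int
    tuned_config: SvmConfig | None = None
    fold_configs: list[SvmConfig] | None = field(default=None, repr=False)
    fold_scalers: list | None = field(default=None, repr=False)

    @property
    def n_iterations(self) -> int:
        return self.n_present * self.n_absent

    def summary(self) -> str:
        cfg = self.tuned_config
        lines = [
            "Leave-two-out cross-validation",
            "------------------------------",
            f"n cub-present   {self.n_present:>8d}",
            f"n cub-absent    {self.n_absent:>8d}",
            f"iterations      {self.n_iterations:>8d}",
            f"sensitivity     {self.sensitivity:>8.2f}",
            f"specificity     {self.specificity:>8.2f}",
            f"accuracy        {self.accuracy:>8.2f}",
        ]
        if cfg is not None:
            lines.append(f"tuned kernel/cost  {cfg.kernel}/{cfg.cost:g}")
        return "\n".join(lines)


def classification_metrics(
    predictions: pd.DataFrame,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from a per-prediction table with
    columns ``true`` and ``pred``."""
    if len(predictions) == 0:
        raise ValueError("no predictions")
    true = predictions["true"].to_numpy()
    pred = predictions["pred"].to_numpy()
    pos = true == POSITIVE_LABEL
    sens = float((pred[pos] == POSITIVE_LABEL).mean()) if pos.any() else np.nan
    neg = ~pos
    spec = float((pred[neg] == NEGATIVE_LABEL).mean()) if neg.any() else np.nan
    acc = float((pred == true).mean())
    return sens, spec, acc


def leave_two_out_cv(
    X: pd.DataFrame,
    labels: pd.Series,
    kernels: tuple[str, ...] = DEFAULT_KERNELS,
    costs: tuple[float, ...] = DEFAULT_COSTS,
    seed: int = 0,
    tune_mode: str = "per_fold",
    standardize_reference: str = "training_only",
    base_config: SvmConfig = SvmConfig(),
    record_fold_details: bool = False,
) -> CVReport:
    """Exhaustive leave-two-out cross-validation.

    For every (cub-present i, cub-absent j) pair: withhold both, Z-score the
    remaining samples (``standardize_reference='training_only'``; 'global'
    reproduces the simpler pre-CV standardization), tune on the training fold
    (``tune_mode='per_fold'``; 'once' tunes a single config on the full data
    first), train, and predict the withheld pair. Iteration count is exactly
    n_present * n_absent and every sample is tested once per opposite-class
    sample.

    Deterministic given ``seed``.
    """
    if tune_mode not in ("per_fold", "once"):
        raise ValueError("tune_mode must be 'per_fold' or 'once'")
    if standardize_reference not in ("training_only", "global"):
        raise ValueError("standardize_reference must be 'training_only' or 'global'")
    from .features import Scaler  # local import to avoid cycle

    y = np.asarray(labels)
    present_idx = np.flatnonzero(y == POSITIVE_LABEL)
    absent_idx = np.flatnonzero(y == NEGATIVE_LABEL)
    if present_idx.size < 2 or absent_idx.size < 2:
        raise ValueError("need at least 2 samples in each class")

    global_scaler = Scaler.fit(X)
    tuned_once: SvmConfig | None = None
    if tune_mode == "once":
        Z_all = global_scaler.transform(X).to_numpy()
        tuned_once = tune(
            Z_all, y, kernels=kernels, costs=costs, seed=seed, base_config=base_config
        )

    rows = []
    fold_configs: list[SvmConfig] = []
    fold_scalers: list[Scaler] = []
    rng = np.random.SeedSequence(seed)
    fold_seeds = rng.generate_state(present_idx.size * absent_idx.size) % (2**31)
    it = 0
    for i in present_idx:
        for j in absent_idx:
            train_mask = np.ones(len(X), dtype=bool)
            train_mask[[i, j]] = False
            X_tr = X.iloc[train_mask]
            y_tr = y[train_mask]
            X_te = X.iloc[[i, j]]
            if standardize_reference == "training_only":
                scaler = Scaler.fit(X_tr)
            else:
                scaler = global_scaler
            Z_tr = scaler.transform(X_tr).to_numpy()
            Z_te = scaler.transform(X_te).to_numpy()
            cfg = tuned_once
            if cfg is None:
                cfg = tune(
                    Z_tr,
                    y_tr,
                    kernels=kernels,
                    costs=costs,
                    seed=int(fold_seeds[it]),
                    base_config=base_config,
                )
            clf = train_svm(Z_tr, y_tr, cfg)
            pred = clf.predict(Z_te)
            rows.append(
                {
                    "iteration": it,
                    "sample_id": X.index[i],
                    "true": POSITIVE_LABEL,
                    "pred": pred[0],
                }
            )
            rows.append(
                {
                    "iteration": it,
                    "sample_id": X.index[j],
                    "true": NEGATIVE_LABEL,
                    "pred": pred[1],
                }
            )
            if record_fold_details:
                fold_configs.append(cfg)
                fold_scalers.append(scaler)
            it += 1

    predictions = pd.DataFrame(rows)
    sens, spec, acc = classification_metrics(predictions)
    return CVReport(
        predictions=predictions,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n_present=present_idx.size,
        n_absent=absent_idx.size,
        tuned_config=tuned_once,
        fold_configs=fold_configs if record_fold_details else None,
        fold_scalers=fold_scalers if record_fold_details else None,
    )
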