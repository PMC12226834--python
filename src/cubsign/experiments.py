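"""Evaluation designs: full-data tables, sample-size and period-length
subsampling experiments, and the early-departure holdout test.

All designs run on any cohort (synthetic or real) that has been
preprocessed (filtered, departure-detected, clipped) and standardized to a
regular-interval track per bear-year. Subsampling designs draw balanced
random subsets without replacement, seeded per (experiment seed, cell
index, iteration index) so partial re-runs are reproducible, and report
median sensitivity/specificity/accuracy over iterations.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_COSTS,
    DEFAULT_KERNELS,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    SvmConfig,
    leave_two_out_cv,
    train_svm,
    tune,
)
from .ctcrw import StandardTrack, standardize_bear_year
from .features import PERIODS, Scaler, build_feature_matrix
from .preprocess import BearYear

__all__ = [
    "standardize_cohort",
    "eligible_subset",
    "run_full_data",
    "run_sample_size",
    "run_period_length",
    "run_early_departure",
]


def standardize_cohort(
    bear_years: Iterable[BearYear],
    interval: float = 24.0,
    horizon_days: int = 60,
) -> dict[str, StandardTrack]:
    """Fit a CTCRW per bear-year and predict its standardized track out to
    ``horizon_days`` (keep this at the longest period you will analyse)."""
    tracks: dict[str, StandardTrack] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign extrapolation warnings at the tail
        for b in bear_years:
            track, _ = standardize_bear_year(
                b, interval=interval, period_days=horizon_days
            )
            tracks[b.key] = track
    return tracks


def eligible_subset(bear_years: Sequence[BearYear], period: int) -> list[BearYear]:
    """Bear-years passing the 75% data-coverage rule for ``period`` days."""
    return [b for b in bear_years if b.eligible(period)]


def _cv_kwargs(kw: dict) -> dict:
    out = {
        "kernels": kw.get("kernels", DEFAULT_KERNELS),
        "costs": kw.get("costs", DEFAULT_COSTS),
        "tune_mode": kw.get("tune_mode", "once"),
        "standardize_reference": kw.get("standardize_reference", "training_only"),
        "base_config": kw.get("base_config", SvmConfig()),
    }
    return out


def run_full_data(
    bear_years: Sequence[BearYear],
    tracks: dict[str, StandardTrack],
    periods: Sequence[int] = PERIODS,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """One leave-two-out CV per period on all eligible bear-years.

    Returns a table with one row per period: period, n_present, n_absent,
    tuned kernel and cost (tuned on the full eligible data for the row),
    sensitivity, specificity, accuracy. Periods with fewer than two samples
    in either class are marked not estimable (NaN metrics).
    """
    kw = _cv_kwargs(cv_kwargs)
    rows = []
    for p_idx, period in enumerate(periods):
        elig = eligible_subset(bear_years, period)
        n_p = sum(b.label == POSITIVE_LABEL for b in elig)
        n_a = sum(b.label == NEGATIVE_LABEL for b in elig)
        row = {"period": period, "n_present": n_p, "n_absent": n_a}
        if n_p < 2 or n_a < 2:
            row.update(
                kernel=None, cost=np.nan, sensitivity=np.nan,
                specificity=np.nan, accuracy=np.nan, estimable=False,
            )
        else:
            X, y = build_feature_matrix(elig, tracks, period, populations=populations)
            rep = leave_two_out_cv(X, y, seed=seed + p_idx, **kw)
            cfg = rep.tuned_config
            if cfg is None:  # per-fold tuning: report a full-data tuned config
                scaler = Scaler.fit(X)
                cfg = tune(
                    scaler.transform(X).to_numpy(),
                    y.to_numpy(),
                    kernels=kw["kernels"],
                    costs=kw["costs"],
                    seed=seed + p_idx,
                    base_config=kw["base_config"],
                )
            row.update(
                kernel=cfg.kernel,
                cost=cfg.cost,
                sensitivity=rep.sensitivity,
                specificity=rep.specificity,
                accuracy=rep.accuracy,
                estimable=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _subsample_cv(
    bear_years: Sequence[BearYear],
    tracks: dict[str, StandardTrack],
    period: int,
    n_per_class: int,
    rng: np.random.Generator,
    seed: int,
    populations: tuple[str, ...] | None,
    kw: dict,
):
    present = [b for b in bear_years if b.label == POSITIVE_LABEL]
    absent = [b for b in bear_years if b.label == NEGATIVE_LABEL]
    pick_p = rng.choice(len(present), size=n_per_class, replace=False)
    pick_a = rng.choice(len(absent), size=n_per_class, replace=False)
    subset = [present[i] for i in pick_p] + [absent[i] for i in pick_a]
    X, y = build_feature_matrix(subset, tracks, period, populations=populations)
    return leave_two_out_cv(X, y, seed=seed, **kw)


def _check_pool(pool: Sequence[BearYear], n_per_class: int, what: str) -> None:
    n_p = sum(b.label == POSITIVE_LABEL for b in pool)
    n_a = sum(b.label == NEGATIVE_LABEL for b in pool)
    if n_p < n_per_class or n_a < n_per_class:
        raise ValueError(
            f"{what}: need {n_per_class} eligible bear-years per class, "
            f"have {n_p} cub-present / {n_a} cub-absent"
        )


def run_sample_size(
    bear_years: Sequence[BearYear],
    tracks: dict[str, StandardTrack],
    period: int = 30,
    sizes: Sequence[int] = (10, 20, 30, 40, 50),
    n_iter: int = 100,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-size experiment at a fixed period (default 30 days).

    For each total size s (split equally among classes), draw ``n_iter``
    random balanced subsets of eligible bear-years, run leave-two-out CV on
    each, and report per-size medians plus the full per-iteration table.
    """
    kw = _cv_kwargs(cv_kwargs)
    pool = eligible_subset(bear_years, period)
    per_iter = []
    for s_idx, size in enumerate(sizes):
        if size % 2:
            raise ValueError("sizes must split evenly between classes")
        n_half = size // 2
        _check_pool(pool, n_half, f"sample-size experiment, n={size}")
        for it in range(n_iter):
            ss = np.random.SeedSequence([seed, s_idx, it])
            rng = np.random.default_rng(ss)
            rep = _subsample_cv(
                pool, tracks, period, n_half, rng,
                int(ss.generate_state(1)[0] % (2**31)), populations, kw,
            )
            per_iter.append(
                {
                    "size": size, "iteration": it,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                }
            )
    per_iter = pd.DataFrame(per_iter)
    medians = (
        per_iter.groupby("size")[["sensitivity", "specificity", "accuracy"]]
        .median()
        .reset_index()
    )
    return medians, per_iter


def run_period_length(
    bear_years: Sequence[BearYear],
    tracks: dict[str, StandardTrack],
    n_per_class: int = 15,
    periods: Sequence[int] = PERIODS,
    n_iter: int = 100,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Period-length experiment at fixed class sizes (default 15 + 15).

    A fresh balanced subset is drawn per period per iteration from the
    bear-years eligible at that period.
    """
    kw = _cv_kwargs(cv_kwargs)
    per_iter = []
    for p_idx, period in enumerate(periods):
        pool = eligible_subset(bear_years, period)
        _check_pool(pool, n_per_class, f"period-length experiment, {period} d")
        for it in range(n_iter):
            ss = np.random.SeedSequence([seed, p_idx, it])
            rng = np.random.default_rng(ss)
            rep = _subsample_cv(
                pool, tracks, period, n_per_class, rng,
                int(ss.generate_state(1)[0] % (2**31)), populations, kw,
            )
            per_iter.append(
                {
                    "period": period, "iteration": it,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                }
            )
    per_iter = pd.DataFrame(per_iter)
    medians = (
        per_iter.groupby("period")[["sensitivity", "specificity", "accuracy"]]
        .median()
        .reset_index()
    )
    return medians, per_iter


def run_early_departure(
    train_bear_years: Sequence[BearYear],
    train_tracks: dict[str, StandardTrack],
    holdout_bear_years: Sequence[BearYear],
    holdout_tracks: dict[str, StandardTrack],
    periods: Sequence[int] = (5, 10, 20),
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Holdout evaluation mirroring the early-(January-)departure test.

    Per period: standardize and tune on the full training cohort, train one
    SVM, and predict every eligible holdout bear. Returns a bear x period
    label matrix (None where a holdout bear is ineligible for the period).
    The holdout must be disjoint from the training cohort.
    """
    kw = _cv_kwargs(cv_kwargs)
    train_keys = {b.key for b in train_bear_years}
    overlap = train_keys & {b.key for b in holdout_bear_years}
    if overlap:
        raise ValueError(f"holdout overlaps training cohort: {sorted(overlap)}")
    if populations is None:
        populations = tuple(
            sorted(
                {b.population for b in train_bear_years}
                | {b.population for b in holdout_bear_years}
            )
        )
    out: dict[int, dict[str, str | None]] = {}
    for p_idx, period in enumerate(periods):
        elig = eligible_subset(train_bear_years, period)
        X, y = build_feature_matrix(elig, tracks=train_tracks, period=period,
                                    populations=populations)
        scaler = Scaler.fit(X)
        Z = scaler.transform(X).to_numpy()
        cfg = tune(
            Z, y.to_numpy(), kernels=kw["kernels"], costs=kw["costs"],
            seed=seed + p_idx, base_config=kw["base_config"],
        )
        clf = train_svm(Z, y.to_numpy(), cfg)
        col: dict[str, str | None] = {}
        for b in holdout_bear_years:
            if not b.eligible(period):
                col[b.key] = None
                continue
            Xh, _ = build_feature_matrix(
                [b], holdout_tracks, period, populations=populations
            )
            col[b.key] = str(clf.predict(scaler.transform(Xh).to_numpy())[0])
        out[period] = col
    return pd.DataFrame(out)
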