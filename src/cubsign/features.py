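"""Movement metrics and nested-period feature assembly.

Six movement metrics are computed from each standardized track over nested
post-departure periods (5, 10, 20, 30, 40, 50, 60 days):

* cumulative daily net displacement (km),
* number of days with daily net displacement below a low threshold, above a
  mid threshold and above a high threshold (1/2/5 km for grizzly bears,
  5/10/25 km for polar bears; strict inequalities),
* maximum net-squared displacement (km^2): the square of the largest
  Euclidean distance of any grid location from the departure location,
* mean resultant length of step headings (tortuosity, in [0, 1]).

The feature vector for period P stacks the metrics for every period <= P
("nested"), prefixed by a one-hot (sub)population encoding and the departure
date as a Julian day. All predictors are Z-scored with the sample SD before
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctcrw import StandardTrack
from .preprocess import BearYear

__all__ = [
    "PERIODS",
    "DND_THRESHOLDS_KM",
    "PeriodMetrics",
    "step_displacements",
    "daily_net_displacement",
    "period_metrics",
    "build_feature_matrix",
    "Scaler",
    "standardize",
]

#: Post-departure period lengths (days) analysed, shortest to longest.
PERIODS = (5, 10, 20, 30, 40, 50, 60)

#: (low, mid, high) daily-net-displacement thresholds (km) per species.
DND_THRESHOLDS_KM = {"grizzly": (1.0, 2.0, 5.0), "polar": (5.0, 10.0, 25.0)}


@dataclass(frozen=True)
class PeriodMetrics:
    period: int
    cum_dnd: float
    days_below_low: int
    days_above_mid: int
    days_above_high: int
    max_nsd: float
    mean_resultant_length: float


def step_displacements(track: StandardTrack) -> np.ndarray:
    """Euclidean distances (km) between consecutive standardized positions."""
    if len(track) < 2:
        raise ValueError("need at least 2 positions")
    d = np.diff(track.xy, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def daily_net_displacement(track: StandardTrack) -> np.ndarray:
    """Per-day displacement series (km).

    For 24-h tracks this is simply the distance between consecutive daily
    locations. For finer intervals the daily value is the *sum* of the
    within-day step lengths (the day's path length), which keeps the metric
    comparable across standardization intervals; note that a zig-zag day
    therefore scores its full path length even if the net daily motion is
    zero.
    """
    steps = step_displacements(track)
    spd = int(round(24.0 / track.interval))
    if abs(24.0 / track.interval - spd) > 1e-9 or spd < 1:
        raise ValueError("track interval must divide 24 h")
    n_days = steps.size // spd
    if n_days < 1:
        raise ValueError("track must cover at least one full day")
    return steps[: n_days * spd].reshape(n_days, spd).sum(axis=1)


def period_metrics(track: StandardTrack, species: str, period: int) -> PeriodMetrics:
    """The six movement metrics over the first ``period`` days of a track.

    Threshold-day counts use strict inequalities; a day at exactly the
    threshold counts for neither side. The mean resultant length is
    R = sqrt((sum cos h_i)^2 + (sum sin h_i)^2) / m over the m nonzero-length
    steps' absolute headings h_i within the period (0 if every step has zero
    length).
    """
    low, mid, high = DND_THRESHOLDS_KM[species]
    daily = daily_net_displacement(track)
    if daily.size < period:
        raise ValueError(
            f"track covers {daily.size} full days; {period} required"
        )
    daily = daily[:period]
    spd = int(round(24.0 / track.interval))
    n_pos = period * spd + 1
    xy = track.xy[:n_pos]
    d2 = (xy[:, 0] - xy[0, 0]) ** 2 + (xy[:, 1] - xy[0, 1]) ** 2
    steps = np.diff(xy, axis=0)
    lens = np.hypot(steps[:, 0], steps[:, 1])
    nz = lens > 0
    if nz.any():
        headings = np.arctan2(steps[nz, 1], steps[nz, 0])
        rbar = float(
            np.hypot(np.cos(headings).sum(), np.sin(headings).sum()) / nz.sum()
        )
    else:
        rbar = 0.0
    return PeriodMetrics(
        period=period,
        cum_dnd=float(daily.sum()),
        days_below_low=int((daily < low).sum()),
        days_above_mid=int((daily > mid).sum()),
        days_above_high=int((daily > high).sum()),
        max_nsd=float(d2.max()),
        mean_resultant_length=min(rbar, 1.0),
    )


_METRIC_NAMES = (
    "cum_dnd",
    "days_below_low",
    "days_above_mid",
    "days_above_high",
    "max_nsd",
    "mean_resultant_length",
)


def build_feature_matrix(
    bear_years: list[BearYear],
    tracks: dict[str, StandardTrack],
    period: int,
    populations: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the nested feature matrix for one period.

    Returns ``(X, y)``: X indexed by bear-year key with columns
    ``pop_<name>`` one-hots, ``julian_departure``, then for every analysis
    period p <= ``period`` (ascending) the six metrics ``p<p>d_<metric>``;
    y holds the labels. For the j-th period (1-based among the seven) the
    column count is ``n_populations + 1 + 6*j``.

    All bear-years must share one species (thresholds are species-specific).
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}")
    species = {b.species for b in bear_years}
    if len(species) > 1:
        raise ValueError(f"mixed species in one matrix: {sorted(species)}")
    sp = species.pop()
    if populations is None:
        populations = tuple(sorted({b.population for b in bear_years}))
    nested = [p for p in PERIODS if p <= period]
    rows = []
    labels = []
    index = []
    for b in bear_years:
        track = tracks[b.key]
        row: dict[str, float] = {
            f"pop_{p}": float(b.population == p) for p in populations
        }
        row["julian_departure"] = float(b.departure_time.dayofyear)
        for p in nested:
            m = period_metrics(track, sp, p)
            for name in _METRIC_NAMES:
                row[f"p{p}d_{name}"] = float(getattr(m, name))
        rows.append(row)
        labels.append(b.label)
        index.append(b.key)
    X = pd.DataFrame(rows, index=index)
    y = pd.Series(labels, index=index, name="label")
    return X, y


@dataclass
class Scaler:
    """Column-wise Z-score transform using the sample SD (ddof=1).

    Zero-variance columns are flagged and transformed to exactly 0 (with a
    warning at fit time) rather than dividing by zero.
    """

    mean_: pd.Series
    sd_: pd.Series
    zero_variance: list[str]

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Scaler":
        if len(X) < 2:
            raise ValueError("need at least 2 samples to standardize")
        mean = X.mean()
        sd = X.std(ddof=1)
        zero = sd.index[(sd == 0) | sd.isna()].tolist()
        if zero:
            warnings.warn(
                f"zero-variance column(s) passed through as 0: {zero}", stacklevel=2
            )
        sd = sd.replace(0.0, np.nan)
        return cls(mean_=mean, sd_=sd, zero_variance=zero)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X - self.mean_) / self.sd_
        if self.zero_variance:
            Z[self.zero_variance] = 0.0
        return Z


def standardize(
    X: pd.DataFrame, reference: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, Scaler]:
    """Z-score ``X``; the mean/SD come from ``reference`` when given
    (training-fold standardization), else from ``X`` itself (the
    'global', pre-CV variant)."""
    scaler = Scaler.fit(X if reference is None else reference)
    return scaler.transform(X), scaler
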