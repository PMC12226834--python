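"""Fix-quality filtering, den-departure detection and bear-year assembly.

A *bear-year* is one adult female's location series for one season, running
from den departure to 60 days after departure. This module applies the
quality screens to raw collar fixes, detects den departure with
species-specific distance/no-return rules, clips the series to the analysis
window, and enforces the 75%-of-days data-coverage rule that decides which
post-departure period lengths a bear-year is eligible for.

Fix tables are pandas DataFrames in the standard layout (see
:mod:`cubsign.io`): columns ``animal_id, timestamp, x_km, y_km, source,
argos_class, horiz_error_m, pdop``, time-sorted, coordinates in a planar km
frame (for real data: an azimuthal-equidistant projection centred on the
den).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BearYear",
    "BearYearRejected",
    "IneligibleForPeriod",
    "DepartureNotFound",
    "MAX_GPS_HORIZ_ERROR_M",
    "MAX_PDOP",
    "MAX_SPEED_KMH",
    "DEPARTURE_THRESHOLD_KM",
    "filter_fixes",
    "detect_departure",
    "assemble_bear_year",
    "coverage_fraction",
]

#: GPS fixes with horizontal error strictly above this are removed (m).
MAX_GPS_HORIZ_ERROR_M = 125.0
#: GPS fixes with PDOP strictly above this are removed, where the rule applies.
MAX_PDOP = 10.0
#: fixes implying sustained travel strictly faster than this are removed (km/h).
MAX_SPEED_KMH = 25.0
#: den-departure distance threshold by species (km).
DEPARTURE_THRESHOLD_KM = {"grizzly": 0.25, "polar": 3.0}
#: number of subsequent records that must not return within threshold.
_NO_RETURN_RECORDS = 10

ANALYSIS_WINDOW_DAYS = 60
MIN_COVERAGE = 0.75


class BearYearRejected(ValueError):
    """Bear-year cannot enter the analysis at all (e.g. unknown label)."""


class IneligibleForPeriod(ValueError):
    """Bear-year fails the 75% data-coverage rule for a requested period."""


class DepartureNotFound(ValueError):
    """No sustained movement away from the den was found."""


@dataclass
class BearYear:
    """One animal-year of telemetry plus its metadata.

    ``fixes`` are time-sorted and, after :func:`assemble_bear_year`, clipped
    to the 60-day post-departure window (and, for grizzly cub-present
    samples, truncated at the last observation confirming cubs).
    """

    animal_id: str
    year: int
    species: str  # 'grizzly' | 'polar'
    population: str
    label: str  # 'cub_present' | 'cub_absent' | 'unknown'
    den_xy: tuple[float, float]
    fixes: pd.DataFrame = field(repr=False)
    departure_time: pd.Timestamp | None = None
    last_confirmed_time: pd.Timestamp | None = None
    #: simulator ground truth, for validation only
    true_departure_time: pd.Timestamp | None = None
    denned: bool = True

    @property
    def key(self) -> str:
        return f"{self.animal_id}-{self.year}"

    def coverage(self, period_days: int) -> float:
        """Fraction of the first ``period_days`` post-departure days with
        at least one retained fix."""
        if self.departure_time is None:
            raise ValueError("departure_time not set")
        return coverage_fraction(self.fixes, self.departure_time, period_days)

    def eligible(self, period_days: int) -> bool:
        """75% data-coverage rule, plus: a grizzly cub-present series
        truncated at the last cub-confirming observation is ineligible for
        any period extending past the truncation (the label itself is
        unverified beyond that day, whatever the fix coverage)."""
        if (
            self.species == "grizzly"
            and self.label == "cub_present"
            and self.last_confirmed_time is not None
            and self.departure_time is not None
            and self.last_confirmed_time
            < self.departure_time + pd.Timedelta(days=period_days)
        ):
            return False
        return self.coverage(period_days) >= MIN_COVERAGE


def _require_sorted(fixes: pd.DataFrame) -> None:
    ts = fixes["timestamp"].to_numpy()
    if ts.size > 1 and (np.diff(ts.astype("datetime64[ns]").astype(np.int64)) < 0).any():
        raise ValueError("fixes must be sorted by timestamp")


def filter_fixes(
    fixes: pd.DataFrame, species: str, pdop_filter: bool = False
) -> pd.DataFrame:
    """Apply the fix-quality screens; returns a new, filtered DataFrame.

    Removes, in order: GPS fixes with horizontal error > 125 m; GPS fixes
    with PDOP > 10 when ``pdop_filter`` is set (the PDOP rule applies to one
    grizzly study ecosystem only); then any fix whose implied speed from the
    previously *retained* fix exceeds 25 km/h, in a single forward pass so
    that removing a bad fix re-links its neighbours. All bounds are strict
    inequalities: a fix at exactly 125 m, PDOP 10 or 25 km/h is retained.

    Idempotent; never mutates or reorders the input.
    """
    _require_sorted(fixes)
    df = fixes.copy()
    is_gps = df["source"].to_numpy() == "GPS"
    herr = pd.to_numeric(df["horiz_error_m"], errors="coerce").to_numpy()
    keep = ~(is_gps & (herr > MAX_GPS_HORIZ_ERROR_M))
    if pdop_filter:
        pdop = pd.to_numeric(df["pdop"], errors="coerce").to_numpy()
        keep &= ~(is_gps & (pdop > MAX_PDOP))
    df = df.loc[keep]

    t = df["timestamp"].astype("datetime64[ns]").astype(np.int64).to_numpy() / 3.6e12
    x = df["x_km"].to_numpy()
    y = df["y_km"].to_numpy()
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        j = kept[-1]
        dt = t[i] - t[j]
        dist = float(np.hypot(x[i] - x[j], y[i] - y[j]))
        if dt <= 0:
            # coincident timestamps: keep unless they imply a jump
            if dist > 0:
                continue
            kept.append(i)
            continue
        if dist / dt > MAX_SPEED_KMH:
            continue
        kept.append(i)
    return df.iloc[kept].reset_index(drop=True)


def detect_departure(
    fixes: pd.DataFrame, den_xy: tuple[float, float], species: str
) -> pd.Timestamp:
    """Timestamp of den departure.

    Departure is the first fix farther than the species threshold from the
    den (0.25 km grizzly, 3 km polar — twice the assumed error of the lowest
    Argos quality used) such that none of the following 10 records falls back
    within the threshold. If fewer than 10 records remain after a candidate,
    the no-return test is applied to all remaining records.

    Raises :class:`DepartureNotFound` if no fix qualifies.
    """
    if species not in DEPARTURE_THRESHOLD_KM:
        raise ValueError(f"unknown species {species!r}")
    if len(fixes) < _NO_RETURN_RECORDS + 1:
        raise ValueError("need at least 11 fixes to detect departure")
    _require_sorted(fixes)
    thr = DEPARTURE_THRESHOLD_KM[species]
    d = np.hypot(
        fixes["x_km"].to_numpy() - den_xy[0], fixes["y_km"].to_numpy() - den_xy[1]
    )
    far = d > thr
    for i in np.flatnonzero(far):
        window = far[i + 1 : i + 1 + _NO_RETURN_RECORDS]
        if window.all():
            return pd.Timestamp(fixes["timestamp"].iloc[int(i)])
    raise DepartureNotFound(f"no sustained movement > {thr} km from den")


def coverage_fraction(
    fixes: pd.DataFrame, departure: pd.Timestamp, period_days: int
) -> float:
    """Fraction of days k = 0..period-1 (day k = [departure + 24k h,
    departure + 24(k+1) h)) containing at least one fix.

    The denominator is always the full ``period_days``, so a series
    truncated before the period's end is penalised accordingly.
    """
    if period_days <= 0:
        raise ValueError("period_days must be > 0")
    rel_h = (
        fixes["timestamp"] - departure
    ).dt.total_seconds().to_numpy() / 3600.0
    days = np.floor(rel_h / 24.0).astype(int)
    days = days[(days >= 0) & (days < period_days)]
    return np.unique(days).size / period_days


def assemble_bear_year(
    fixes: pd.DataFrame,
    metadata: dict,
    period_days: int | None = None,
    allow_unknown_label: bool = False,
) -> BearYear:
    """Clip a filtered fix series to the analysis window and build a BearYear.

    ``metadata`` must provide ``animal_id, year, species, population, label,
    den_xy, departure_time`` and may provide ``last_confirmed_time``,
    ``true_departure_time`` and ``denned``. Fixes are clipped to
    [departure, departure + 60 d]; grizzly cub-present series are further
    truncated at ``last_confirmed_time`` (the litter could have been lost
    after the last confirming observation). If ``period_days`` is given, the
    75% coverage rule for that period is enforced.

    Raises :class:`BearYearRejected` for an unknown label (unless
    ``allow_unknown_label``) and :class:`IneligibleForPeriod` when coverage
    falls short.
    """
    label = metadata["label"]
    if label not in ("cub_present", "cub_absent") and not allow_unknown_label:
        raise BearYearRejected(
            f"{metadata['animal_id']}: label {label!r} unusable for training"
        )
    departure = pd.Timestamp(metadata["departure_time"])
    end = departure + pd.Timedelta(days=ANALYSIS_WINDOW_DAYS)
    last_confirmed = metadata.get("last_confirmed_time")
    if (
        metadata["species"] == "grizzly"
        and label == "cub_present"
        and last_confirmed is not None
    ):
        end = min(end, pd.Timestamp(last_confirmed))
    mask = (fixes["timestamp"] >= departure) & (fixes["timestamp"] <= end)
    clipped = fixes.loc[mask].reset_index(drop=True)

    by = BearYear(
        animal_id=metadata["animal_id"],
        year=int(metadata["year"]),
        species=metadata["species"],
        population=metadata["population"],
        label=label,
        den_xy=tuple(metadata["den_xy"]),
        fixes=clipped,
        departure_time=departure,
        last_confirmed_time=(
            pd.Timestamp(last_confirmed) if last_confirmed is not None else None
        ),
        true_departure_time=metadata.get("true_departure_time"),
        denned=bool(metadata.get("denned", True)),
    )
    if period_days is not None and not by.eligible(period_days):
        raise IneligibleForPeriod(
            f"{by.key}: coverage {by.coverage(period_days):.1%} < "
            f"{MIN_COVERAGE:.0%} for {period_days}-day period"
        )
    return by


def preprocess_cohort(
    bears: Iterable[BearYear],
    pdop_populations: tuple[str, ...] = ("GYE",),
    log: list | None = None,
) -> list[BearYear]:
    """Filter fixes, detect departures where unset, clip to the analysis
    window, and drop bear-years whose departure cannot be established.

    ``log`` (optional list) collects ``(key, rule, detail)`` tuples for every
    rejection, for audit.
    """
    out: list[BearYear] = []
    for b in bears:
        filtered = filter_fixes(
            b.fixes, b.species, pdop_filter=b.population in pdop_populations
        )
        dep = b.departure_time
        if dep is None:
            try:
                dep = detect_departure(filtered, b.den_xy, b.species)
            except (DepartureNotFound, ValueError) as exc:
                if log is not None:
                    log.append((b.key, "departure", str(exc)))
                continue
        meta = {
            "animal_id": b.animal_id,
            "year": b.year,
            "species": b.species,
            "population": b.population,
            "label": b.label,
            "den_xy": b.den_xy,
            "departure_time": dep,
            "last_confirmed_time": b.last_confirmed_time,
            "true_departure_time": b.true_departure_time,
            "denned": b.denned,
        }
        try:
            out.append(assemble_bear_year(filtered, meta))
        except BearYearRejected as exc:
            if log is not None:
                log.append((b.key, "label", str(exc)))
    return out
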