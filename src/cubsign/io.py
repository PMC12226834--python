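"""CSV/JSON layouts shared by the pipeline stages.

Fix tables: ``animal_id, timestamp`` (ISO-8601 UTC), ``x_km, y_km, source``
(GPS | ARGOS), ``argos_class`` (0/1/2/3/A/B/Z or empty), ``horiz_error_m,
pdop`` (GPS only, may be empty).

Cohort manifests: one row per bear-year with ``animal_id, year, species,
population, label, den_x_km, den_y_km, departure_time,
true_departure_time, last_confirmed_time, denned``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ctcrw import CTCRWResults, StandardTrack
from .preprocess import BearYear

FIX_COLUMNS = [
    "animal_id",
    "timestamp",
    "x_km",
    "y_km",
    "source",
    "argos_class",
    "horiz_error_m",
    "pdop",
]

MANIFEST_COLUMNS = [
    "animal_id",
    "year",
    "species",
    "population",
    "label",
    "den_x_km",
    "den_y_km",
    "departure_time",
    "true_departure_time",
    "last_confirmed_time",
    "denned",
]


def write_cohort(
    bears: Sequence[BearYear], fixes_path: str | Path, manifest_path: str | Path
) -> None:
    """Write a cohort as a fix CSV plus a manifest CSV."""
    fixes = pd.concat(
        [b.fixes.assign(animal_id=b.animal_id) for b in bears], ignore_index=True
    )[FIX_COLUMNS]
    fixes.to_csv(fixes_path, index=False)
    rows = []
    for b in bears:
        rows.append(
            {
                "animal_id": b.animal_id,
                "year": b.year,
                "species": b.species,
                "population": b.population,
                "label": b.label,
                "den_x_km": b.den_xy[0],
                "den_y_km": b.den_xy[1],
                "departure_time": b.departure_time,
                "true_departure_time": b.true_departure_time,
                "last_confirmed_time": b.last_confirmed_time,
                "denned": b.denned,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)


def _opt_ts(v):
    return None if pd.isna(v) else pd.Timestamp(v)


def read_cohort(fixes_path: str | Path, manifest_path: str | Path) -> list[BearYear]:
    """Read a cohort back from the fix + manifest CSVs."""
    fixes = pd.read_csv(fixes_path, parse_dates=["timestamp"])
    fixes["argos_class"] = fixes["argos_class"].fillna("").astype(str)
    manifest = pd.read_csv(
        manifest_path,
        parse_dates=["departure_time", "true_departure_time", "last_confirmed_time"],
    )
    bears = []
    for _, r in manifest.iterrows():
        fx = (
            fixes[fixes["animal_id"] == r["animal_id"]]
            .sort_values("timestamp", kind="stable")
            .reset_index(drop=True)
        )
        bears.append(
            BearYear(
                animal_id=str(r["animal_id"]),
                year=int(r["year"]),
                species=str(r["species"]),
                population=str(r["population"]),
                label=str(r["label"]),
                den_xy=(float(r["den_x_km"]), float(r["den_y_km"])),
                fixes=fx,
                departure_time=_opt_ts(r["departure_time"]),
                true_departure_time=_opt_ts(r["true_departure_time"]),
                last_confirmed_time=_opt_ts(r["last_confirmed_time"]),
                denned=bool(r["denned"]),
            )
        )
    return bears


def write_tracks(tracks: Iterable[StandardTrack], path: str | Path) -> None:
    """Serialize standardized tracks: bear_year, step_index, time, x_km, y_km."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "bear_year": tr.bear_year_ref,
                    "step_index": range(len(tr)),
                    "time": tr.times,
                    "x_km": tr.xy[:, 0],
                    "y_km": tr.xy[:, 1],
                    "interval_h": tr.interval,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_diagnostics(results: dict[str, CTCRWResults], path: str | Path) -> None:
    """JSON sidecar of fitted CTCRW parameters and diagnostics per bear-year."""
    payload = {
        key: {
            "beta": r.params.beta,
            "sigma": r.params.sigma,
            "llf": r.llf,
            "converged": r.converged,
            "n_fixes": r.n_fixes,
            "low_information": r.low_information,
        }
        for key, r in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cv_report(report, json_path: str | Path, csv_path: str | Path | None = None):
    """CVReport -> JSON summary (+ optional flat per-prediction CSV)."""
    payload = {
        "n_present": report.n_present,
        "n_absent": report.n_absent,
        "iterations": report.n_iterations,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "accuracy": report.accuracy,
        "tuned_config": (
            dataclasses.asdict(report.tuned_config) if report.tuned_config else None
        ),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if csv_path is not None:
        report.predictions.to_csv(csv_path, index=False)
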