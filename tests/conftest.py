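"""Shared fixtures: small synthetic cohorts, standardized once per session."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import cubsign as cs
from cubsign.preprocess import preprocess_cohort


def make_fixes(times_h, xs, ys, source="GPS", herr=10.0, pdop=2.0, argos_class=""):
    """Hand-build a fix table (hours since an arbitrary epoch)."""
    n = len(times_h)
    return pd.DataFrame(
        {
            "animal_id": "T0",
            "timestamp": pd.Timestamp("2021-03-01") + pd.to_timedelta(times_h, "h"),
            "x_km": np.asarray(xs, float),
            "y_km": np.asarray(ys, float),
            "source": [source] * n,
            "argos_class": [argos_class] * n,
            "horiz_error_m": [herr] * n,
            "pdop": [pdop] * n,
        }
    )


@pytest.fixture(scope="session")
def small_profile():
    """Well-separated grizzly-scale cohort, short series for speed."""
    return dataclasses.replace(
        cs.GRIZZLY_PROFILE,
        present=dataclasses.replace(
            cs.GRIZZLY_PROFILE.present, mean_daily_displacement=1.5
        ),
        absent=dataclasses.replace(
            cs.GRIZZLY_PROFILE.absent, mean_daily_displacement=3.5
        ),
        individual_cv=0.1,
        individual_persistence_sd=0.0,
        population_mdd_multipliers=None,
        empirical_departure_days_present=None,
        post_departure_days=13,
    )


@pytest.fixture(scope="session")
def small_cohort(small_profile):
    cohort = cs.generate_cohort(6, 6, small_profile, seed=21)
    return preprocess_cohort(cohort)


@pytest.fixture(scope="session")
def small_tracks(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.standardize_cohort(small_cohort, interval=24.0, horizon_days=10)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_tracks):
    X, y = cs.build_feature_matrix(small_cohort, small_tracks, period=10)
    return X, y


#: single-point tuning grid: keeps combinatoric/orchestration tests fast
FAST_GRID = dict(kernels=("linear",), costs=(1.0,))
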