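"""Assigned location accuracies for collar fixes.

A single per-axis Gaussian SD is assigned per source: 30 m for GPS fixes and
a fixed class-specific magnitude for Argos Doppler fixes. These values are
assigned, not estimated, and are shared by the simulator's observation noise
and the interpolation model's measurement equation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: Per-axis accuracy (m) of each Argos location class.
ARGOS_ACCURACY_M: Mapping[str, float] = {
    "0": 6800.0,
    "1": 2500.0,
    "2": 1000.0,
    "3": 400.0,
    "A": 4100.0,
    "B": 7600.0,
    "Z": 4700.0,
}

#: Per-axis accuracy (m) assigned to GPS fixes.
GPS_ACCURACY_M = 30.0


def fix_error_sd_km(fixes: pd.DataFrame) -> np.ndarray:
    """Per-axis measurement SD in km for every fix in a standard fix table."""
    src = fixes["source"].to_numpy()
    cls = fixes["argos_class"].astype(str).to_numpy()
    sd = np.where(
        src == "GPS",
        GPS_ACCURACY_M,
        [ARGOS_ACCURACY_M.get(c, np.nan) for c in cls],
    ).astype(float)
    if np.isnan(sd).any():
        bad = sorted(set(cls[np.isnan(sd)]))
        raise ValueError(f"unknown Argos class(es): {bad}")
    return sd / 1000.0
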