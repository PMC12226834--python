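"""Synthetic bear-cohort generator.

Simulates labelled bear-years — an adult female's movement from winter den
departure through the following weeks — under a heading-autocorrelated
correlated random walk (CRW), then degrades the true path into irregular,
noisy collar fixes (GPS and/or Argos). The movement model is deliberately a
plain discrete-time CRW rather than the continuous-time model used for track
standardization, so the interpolation stage is never tested against its own
generating process.

All simulation happens in a planar km frame centred on the den; real-data
ingestion is responsible for projection.

Class contrast is encoded as shorter mean daily displacements for females
with cubs-of-the-year than for females without, with polar bears travelling
several times farther per day than grizzly bears at matched reproductive
status.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .location_error import ARGOS_ACCURACY_M, GPS_ACCURACY_M
from .preprocess import BearYear

__all__ = [
    "ClassMovementParams",
    "ObservationModel",
    "TrueTrack",
    "SpeciesProfile",
    "GRIZZLY_PROFILE",
    "POLAR_PROFILE",
    "simulate_true_track",
    "simulate_observations",
    "sample_departure_date",
    "generate_cohort",
]

# radius (km) of the random jitter applied while the bear is den-resident
_DEN_JITTER_KM = 0.05


@dataclass(frozen=True)
class ClassMovementParams:
    """True movement process for one reproductive class.

    Parameters
    ----------
    mean_daily_displacement : float
        Mean summed path length per day, km/day.
    displacement_cv : float
        Day-to-day coefficient of variation of the daily path length.
    directional_persistence : float
        Heading autocorrelation in [0, 1]; 1 = straight-line travel,
        0 = fully random headings each step.
    den_residency_days : float
        Days spent at the den site before departure.
    """

    mean_daily_displacement: float
    displacement_cv: float = 0.5
    directional_persistence: float = 0.5
    den_residency_days: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_daily_displacement < 0:
            raise ValueError("mean_daily_displacement must be >= 0")
        if not 0.0 <= self.directional_persistence <= 1.0:
            raise ValueError("directional_persistence must be in [0, 1]")
        if self.displacement_cv < 0:
            raise ValueError("displacement_cv must be >= 0")
        if self.den_residency_days < 0:
            raise ValueError("den_residency_days must be >= 0")


@dataclass(frozen=True)
class ObservationModel:
    """Collar observation process.

    Noise convention: "accuracy" values are applied as the standard deviation
    of independent Gaussian noise on EACH planar axis, so the RMS 2-D
    positional error of a fix with per-axis SD s is s*sqrt(2). This is a
    convention choice — the accuracy tables the error magnitudes come from do
    not define an RMS — and it is applied consistently here and in the
    measurement model of the interpolation stage.
    """

    gps_sd: float = GPS_ACCURACY_M
    argos_sd_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(ARGOS_ACCURACY_M)
    )
    fix_interval_range: tuple[float, float] = (1.0, 6.0)  # hours
    gap_probability: float = 0.0  # whole-day dropout probability
    argos_fraction: float = 0.0  # probability a fix is Argos rather than GPS
    argos_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.2 for c in "0123A"}
    )

    def __post_init__(self) -> None:
        if self.gps_sd <= 0 or any(v <= 0 for v in self.argos_sd_by_class.values()):
            raise ValueError("all measurement SDs must be > 0")
        lo, hi = self.fix_interval_range
        if not 0 < lo <= hi:
            raise ValueError("fix_interval_range must satisfy 0 < min <= max")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must be in [0, 1]")
        if not 0.0 <= self.argos_fraction <= 1.0:
            raise ValueError("argos_fraction must be in [0, 1]")


@dataclass
class TrueTrack:
    """Noise-free simulated path on a regular step grid (km, hours)."""

    times: np.ndarray  # hours since simulation start, strictly increasing
    xy: np.ndarray  # (n, 2) planar km
    departure_time: float  # hours since simulation start
    den_xy: np.ndarray  # (2,) planar km


def simulate_true_track(
    params: ClassMovementParams,
    n_days: int,
    step_hours: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    den_xy: Sequence[float] = (0.0, 0.0),
) -> TrueTrack:
    """Simulate a den-residency-then-CRW path.

    The bear sits (with metre-scale jitter) at ``den_xy`` for
    ``params.den_residency_days``, then moves by a correlated random walk:
    each day's total path length is Gamma-distributed with mean
    ``mean_daily_displacement`` and CV ``displacement_cv``, split evenly over
    the day's steps; step headings follow a wrapped-normal random walk whose
    turning SD is calibrated so E[cos(turn)] equals
    ``directional_persistence``.

    ``n_days`` counts total simulated days including den residency.
    Deterministic given ``seed``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if step_hours <= 0 or abs(24.0 / step_hours - round(24.0 / step_hours)) > 1e-9:
        raise ValueError("step_hours must be positive and divide 24")
    rng = np.random.default_rng(seed)
    spd = int(round(24.0 / step_hours))
    n_steps = n_days * spd
    times = np.arange(n_steps + 1, dtype=float) * step_hours
    den = np.asarray(den_xy, dtype=float)

    res_steps = min(int(round(params.den_residency_days * spd)), n_steps)
    departure_time = times[res_steps]
    move_days = int(np.ceil((n_steps - res_steps) / spd))

    xy = np.empty((n_steps + 1, 2))
    # residency: bounded jitter inside a small disc around the den
    if res_steps > 0:
        r = rng.uniform(0.0, _DEN_JITTER_KM, size=res_steps)
        phi = rng.uniform(0.0, 2 * np.pi, size=res_steps)
        xy[:res_steps, 0] = den[0] + r * np.cos(phi)
        xy[:res_steps, 1] = den[1] + r * np.sin(phi)
    xy[res_steps] = den  # movement starts from the den itself

    if move_days > 0:
        mdd = params.mean_daily_displacement
        cv = params.displacement_cv
        if mdd == 0.0:
            daily = np.zeros(move_days)
        elif cv == 0.0:
            daily = np.full(move_days, mdd)
        else:
            shape = 1.0 / cv**2
            daily = rng.gamma(shape, mdd * cv**2, size=move_days)
        step_len = np.repeat(daily / spd, spd)[: n_steps - res_steps]

        rho = params.directional_persistence
        n_mv = n_steps - res_steps
        if rho >= 1.0:
            headings = np.full(n_mv, rng.uniform(0.0, 2 * np.pi))
        elif rho <= 0.0:
            headings = rng.uniform(0.0, 2 * np.pi, size=n_mv)
        else:
            # wrapped-normal turn: E[cos(turn)] = exp(-s^2/2) = rho
            s = np.sqrt(-2.0 * np.log(rho))
            turns = rng.normal(0.0, s, size=n_mv)
            turns[0] += rng.uniform(0.0, 2 * np.pi)
            headings = np.cumsum(turns)
        dx = step_len * np.cos(headings)
        dy = step_len * np.sin(headings)
        xy[res_steps + 1 :, 0] = den[0] + np.cumsum(dx)
        xy[res_steps + 1 :, 1] = den[1] + np.cumsum(dy)

    return TrueTrack(times=times, xy=xy, departure_time=departure_time, den_xy=den)


def _interp_position(track: TrueTrack, t: np.ndarray) -> np.ndarray:
    x = np.interp(t, track.times, track.xy[:, 0])
    y = np.interp(t, track.times, track.xy[:, 1])
    return np.column_stack([x, y])


def simulate_observations(
    track: TrueTrack,
    model: ObservationModel,
    seed: int | np.random.SeedSequence = 0,
    animal_id: str = "sim",
    start_time: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Degrade a true track into a collar fix table.

    Fix times walk forward from the track start with i.i.d. uniform intervals
    from ``model.fix_interval_range``; whole calendar days (relative to track
    start) are dropped with probability ``model.gap_probability``; each fix is
    the true position at its time plus isotropic Gaussian noise with the
    per-axis SD of its assigned source/class.

    Returns the fix table in the package's standard layout (see
    :mod:`cubsign.io`). May be empty if every day is gapped.
    """
    if track.times.size == 0:
        raise ValueError("track is empty")
    if start_time is None:
        start_time = pd.Timestamp("2020-01-01 00:00:00")
    rng = np.random.default_rng(seed)
    lo, hi = model.fix_interval_range
    t_end = track.times[-1]
    # upper bound on fix count, then cumulative-sum the intervals
    n_max = int(t_end / lo) + 2
    t = np.cumsum(rng.uniform(lo, hi, size=n_max))
    t = t[t <= t_end]

    n_days = int(np.ceil(t_end / 24.0))
    gapped = rng.random(n_days) < model.gap_probability
    if t.size:
        t = t[~gapped[np.minimum((t // 24.0).astype(int), n_days - 1)]]

    pos = _interp_position(track, t)
    n = t.size
    is_argos = rng.random(n) < model.argos_fraction
    classes = np.array(list(model.argos_class_probs))
    probs = np.array(list(model.argos_class_probs.values()), dtype=float)
    probs = probs / probs.sum()
    argos_class = np.where(is_argos, rng.choice(classes, size=n, p=probs), "")
    sd_m = np.where(
        is_argos,
        np.array([model.argos_sd_by_class.get(c, np.nan) for c in argos_class]),
        model.gps_sd,
    )
    noisy = pos + rng.normal(0.0, 1.0, size=(n, 2)) * (sd_m[:, None] / 1000.0)

    ts = start_time + pd.to_timedelta(t, unit="h")
    df = pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": ts,
            "x_km": noisy[:, 0],
            "y_km": noisy[:, 1],
            "source": np.where(is_argos, "ARGOS", "GPS"),
            "argos_class": argos_class,
            "horiz_error_m": np.where(is_argos, np.nan, rng.rayleigh(20.0, size=n)),
            "pdop": np.where(is_argos, np.nan, rng.uniform(1.0, 6.0, size=n)),
        }
    )
    return df


def sample_departure_date(
    empirical_dates: Sequence[int], seed: int | np.random.SeedSequence = 0
) -> int:
    """Draw one pseudo-departure date (Julian day) uniformly, with
    replacement, from an empirical distribution of observed departure dates.
    """
    if len(empirical_dates) == 0:
        raise ValueError("empirical_dates must be nonempty")
    rng = np.random.default_rng(seed)
    return int(rng.choice(np.asarray(empirical_dates)))


@dataclass(frozen=True)
class SpeciesProfile:
    """Everything needed to generate one species' synthetic cohort."""

    species: str  # 'grizzly' | 'polar'
    populations: tuple[str, ...]
    present: ClassMovementParams
    absent: ClassMovementParams
    observation: ObservationModel = field(default_factory=ObservationModel)
    #: between-individual CV on mean daily displacement (lognormal scatter);
    #: day-to-day variation alone would average out over multi-week periods
    #: and make classes implausibly separable.
    individual_cv: float = 0.35
    #: between-individual SD on directional persistence (truncated normal);
    #: spreads the tortuosity metric within class the same way.
    individual_persistence_sd: float = 0.12
    #: observed den-departure dates (Julian days) to draw calendar anchors
    #: (and non-denner pseudo-departures) from.
    empirical_departure_days: tuple[int, ...] = tuple(range(75, 121, 5))
    #: optional separate date distribution for cub-present females (they
    #: tend to emerge later in spring); None = shared with the absent class.
    empirical_departure_days_present: tuple[int, ...] | None = None
    #: per-population multipliers on mean daily displacement (aligned with
    #: ``populations``): ecosystems differ in baseline movement scale, so the
    #: class contrast lives within, not across, populations.
    population_mdd_multipliers: tuple[float, ...] | None = None
    #: fraction of the cub-absent class simulated as non-denners
    #: (den_residency_days = 0, pseudo-departure date); polar-bear specific.
    nondenning_absent_fraction: float = 0.0
    #: total simulated days of movement after departure
    post_departure_days: int = 66


# Default profiles: movement scales chosen so that every single movement
# metric overlaps substantially between classes (within-class heterogeneity
# from individual scatter and between-ecosystem scale differences) while the
# joint contrast still supports accurate classification at moderate sample
# sizes — the regime the analysis is designed for. Polar travel is several-
# fold grizzly travel at matched status, and the polar cub-absent class is
# non-denning females with pseudo-departure dates.
GRIZZLY_PROFILE = SpeciesProfile(
    species="grizzly",
    populations=("GYE", "NCDE"),
    present=ClassMovementParams(1.8, 0.5, 0.35, den_residency_days=4.0),
    absent=ClassMovementParams(3.1, 0.7, 0.6, den_residency_days=3.0),
    observation=ObservationModel(fix_interval_range=(0.25, 6.0), gap_probability=0.03),
    individual_cv=0.3,
    individual_persistence_sd=0.15,
    population_mdd_multipliers=(0.65, 1.6),
    empirical_departure_days=tuple(range(75, 121, 5)),
    empirical_departure_days_present=tuple(range(85, 131, 5)),
)

POLAR_PROFILE = SpeciesProfile(
    species="polar",
    populations=("SB", "CS"),
    present=ClassMovementParams(12.0, 0.55, 0.9, den_residency_days=4.0),
    absent=ClassMovementParams(16.0, 0.5, 0.75, den_residency_days=0.0),
    observation=ObservationModel(
        fix_interval_range=(1.0, 24.0),
        gap_probability=0.1,
        argos_fraction=0.5,
    ),
    individual_cv=0.3,
    empirical_departure_days=tuple(range(60, 106, 5)),
    nondenning_absent_fraction=1.0,
)


def generate_cohort(
    n_present: int,
    n_absent: int,
    profile: SpeciesProfile = GRIZZLY_PROFILE,
    seed: int | np.random.SeedSequence = 0,
    year: int = 2020,
) -> list[BearYear]:
    """Generate a labelled synthetic cohort of bear-years.

    Each bear gets its own planar frame with the den at the origin, a
    calendar anchor drawn from the profile's empirical departure-date
    distribution, individual movement parameters (lognormal scatter of CV
    ``profile.individual_cv`` around the class mean daily displacement), a
    simulated true track and a degraded fix table. The true departure time is
    recorded on each BearYear for downstream validation; ``departure_time``
    is left unset for denners (detection is the preprocessing stage's job)
    and set to the pseudo-departure for non-denners.

    Reproducible: identical ``seed`` yields an identical cohort.
    """
    if n_present < 0 or n_absent < 0:
        raise ValueError("class sizes must be >= 0")
    root = np.random.SeedSequence(
        seed if isinstance(seed, int) else seed.entropy  # type: ignore[arg-type]
    )
    bears: list[BearYear] = []
    labels = ["cub_present"] * n_present + ["cub_absent"] * n_absent
    children = root.spawn(len(labels))
    for i, (label, ss) in enumerate(zip(labels, children)):
        s_track, s_obs, s_misc = ss.spawn(3)
        rng = np.random.default_rng(s_misc)
        params = profile.present if label == "cub_present" else profile.absent
        non_denner = (
            label == "cub_absent"
            and rng.random() < profile.nondenning_absent_fraction
        )
        if non_denner:
            params = dataclasses.replace(params, den_residency_days=0.0)
        pop_idx = int(rng.integers(len(profile.populations)))
        if profile.population_mdd_multipliers is not None:
            params = dataclasses.replace(
                params,
                mean_daily_displacement=params.mean_daily_displacement
                * profile.population_mdd_multipliers[pop_idx],
            )
        if profile.individual_cv > 0 and params.mean_daily_displacement > 0:
            s_ln = np.sqrt(np.log1p(profile.individual_cv**2))
            mult = rng.lognormal(-0.5 * s_ln**2, s_ln)
            params = dataclasses.replace(
                params, mean_daily_displacement=params.mean_daily_displacement * mult
            )
        if profile.individual_persistence_sd > 0:
            rho_i = float(
                np.clip(
                    params.directional_persistence
                    + rng.normal(0.0, profile.individual_persistence_sd),
                    0.02,
                    0.98,
                )
            )
            params = dataclasses.replace(params, directional_persistence=rho_i)
        dates = profile.empirical_departure_days
        if (
            label == "cub_present"
            and profile.empirical_departure_days_present is not None
        ):
            dates = profile.empirical_departure_days_present
        julian = sample_departure_date(dates, seed=s_misc.spawn(1)[0])
        n_days = int(np.ceil(params.den_residency_days)) + profile.post_departure_days
        track = simulate_true_track(params, n_days=n_days, step_hours=2.0, seed=s_track)
        # anchor the calendar so true departure lands on the sampled Julian day
        start_time = (
            pd.Timestamp(year=year, month=1, day=1)
            + pd.Timedelta(days=julian - 1)
            - pd.Timedelta(hours=track.departure_time)
        )
        fixes = simulate_observations(
            track,
            profile.observation,
            seed=s_obs,
            animal_id=f"{profile.species[0].upper()}{i:03d}",
            start_time=start_time,
        )
        true_dep = start_time + pd.Timedelta(hours=track.departure_time)
        bears.append(
            BearYear(
                animal_id=f"{profile.species[0].upper()}{i:03d}",
                year=year,
                species=profile.species,
                population=profile.populations[pop_idx],
                label=label,
                den_xy=(float(track.den_xy[0]), float(track.den_xy[1])),
                fixes=fixes,
                departure_time=true_dep if non_denner else None,
                true_departure_time=true_dep,
                denned=not non_denner,
            )
        )
    return bears
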