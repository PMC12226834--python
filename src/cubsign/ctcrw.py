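"""Continuous-time correlated random walk (CTCRW) track standardization.

The model is the integrated Ornstein–Uhlenbeck-velocity process: along each
planar axis the velocity follows

    dv = -beta * v dt + sigma * dW,        dx = v dt,

with ``beta`` (1/h) the velocity-autocorrelation decay and ``sigma``
(km/sqrt(h)) the stochastic scale. The x and y axes are independent and share
one (beta, sigma) pair; there is no drift. Fixes observe position with known
per-fix Gaussian SDs (GPS 30 m; Argos class magnitudes), so the exact
likelihood of an irregular, heteroscedastic fix series is available by Kalman
forward filtering, and positions on any regular grid are obtained from the
Rauch–Tung–Striebel smoother — the Gaussian posterior mode, i.e. the
maximum-likelihood location at each grid time.

Exposed statsmodels-style: ``CTCRW`` is the model (data + error SDs),
``CTCRW.fit()`` maximizes the likelihood over log-parameters from a
multi-start grid and returns a :class:`CTCRWResults` carrying estimates,
convergence diagnostics, ``predict()`` and ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .location_error import fix_error_sd_km
from .preprocess import BearYear

__all__ = ["CTCRW", "CTCRWResults", "CtcrwParams", "StandardTrack", "FitFailed"]

_LOG2PI = math.log(2.0 * math.pi)


class FitFailed(RuntimeError):
    """No optimizer start converged to a finite optimum."""


@dataclass(frozen=True)
class CtcrwParams:
    """CTCRW parameters: ``beta`` 1/h, ``sigma`` km/sqrt(h)."""

    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.sigma <= 0:
            raise ValueError("beta and sigma must be > 0")


@dataclass
class StandardTrack:
    """Smoothed locations on an exactly regular grid from departure."""

    bear_year_ref: str
    interval: float  # hours
    times: pd.DatetimeIndex | np.ndarray
    xy: np.ndarray  # (n, 2) km

    def __len__(self) -> int:
        return len(self.xy)


def _transition(beta: float, sig2: float, dt: float):
    """State transition (a, b) and process covariance (qxx, qxv, qvv) for a
    time step dt, state [position, velocity]:  F = [[1, b], [0, a]].
    """
    h = beta * dt
    a = math.exp(-h)
    one_m_a = -math.expm1(-h)
    b = one_m_a / beta
    qvv = sig2 * (1.0 - a * a) / (2.0 * beta)
    qxv = sig2 * one_m_a * one_m_a / (2.0 * beta * beta)
    if h < 1e-4:
        # series form: the closed form cancels catastrophically as h -> 0
        qxx = sig2 / beta**3 * (h**3 / 3.0 - h**4 / 4.0)
    else:
        qxx = sig2 / beta**2 * (dt - 2.0 * b + (1.0 - a * a) / (2.0 * beta))
    return a, b, qxx, qxv, qvv


def simulate_ctcrw_track(
    params: CtcrwParams,
    n_fixes: int,
    dt_hours: float | np.ndarray,
    obs_sd_km: float | np.ndarray,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate observed fixes exactly from the CTCRW state-space model.

    Uses the exact discrete-time transition of the integrated-OU process
    (no Euler error), then adds independent per-axis Gaussian measurement
    noise. Returns ``(times_h, x_km, y_km)``. Intended for parameter-recovery
    and likelihood studies; the bear-cohort simulator deliberately uses a
    different movement model.
    """
    rng = np.random.default_rng(seed)
    dt = np.broadcast_to(np.asarray(dt_hours, dtype=float), (n_fixes - 1,))
    sd = np.broadcast_to(np.asarray(obs_sd_km, dtype=float), (n_fixes,))
    times = np.concatenate([[0.0], np.cumsum(dt)])
    sig2 = params.sigma**2
    state = np.zeros((2, 2))  # rows: axis (x, y); cols: (pos, vel)
    # stationary velocity draw
    state[:, 1] = rng.normal(0.0, math.sqrt(sig2 / (2.0 * params.beta)), size=2)
    true_pos = np.zeros((n_fixes, 2))
    for i, d in enumerate(dt):
        a, b, qxx, qxv, qvv = _transition(params.beta, sig2, d)
        F = np.array([[1.0, b], [0.0, a]])
        Q = np.array([[qxx, qxv], [qxv, qvv]])
        L = np.linalg.cholesky(Q + 1e-30 * np.eye(2))
        state = state @ F.T + rng.normal(size=(2, 2)) @ L.T
        true_pos[i + 1] = state[:, 0]
    obs = true_pos + rng.normal(size=(n_fixes, 2)) * sd[:, None]
    return times, obs[:, 0], obs[:, 1]


class CTCRW:
    """CTCRW model for one bear-year's fix series.

    Parameters
    ----------
    times_h : array
        Fix times in hours (any origin; typically hours since departure).
        Re-sorted internally; duplicate timestamps are allowed and treated as
        repeated measurements of the same state.
    x_km, y_km : array
        Planar fix coordinates.
    sd_km : array
        Known per-axis measurement SD of each fix.
    init_pos_var, init_vel_var : float
        Diffuse prior variances for the initial state (km^2, (km/h)^2); the
        prior mean is the first fix's position with zero velocity.
    """

    def __init__(
        self,
        times_h,
        x_km,
        y_km,
        sd_km,
        init_pos_var: float = 1e4,
        init_vel_var: float = 1e2,
    ) -> None:
        t = np.asarray(times_h, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 fixes to fit a CTCRW")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.x = np.asarray(x_km, dtype=float)[order]
        self.y = np.asarray(y_km, dtype=float)[order]
        self.sd = np.asarray(sd_km, dtype=float)[order]
        if (self.sd <= 0).any():
            raise ValueError("measurement SDs must be > 0")
        self.init_pos_var = float(init_pos_var)
        self.init_vel_var = float(init_vel_var)
        self._dt = np.diff(self.times)
        self._r = self.sd**2

    @classmethod
    def from_bear_year(cls, bear_year: BearYear, **kwargs) -> "CTCRW":
        """Build the model from a preprocessed BearYear, with time measured
        in hours since den departure."""
        if bear_year.departure_time is None:
            raise ValueError("bear-year has no departure_time")
        fx = bear_year.fixes
        t = (
            fx["timestamp"] - bear_year.departure_time
        ).dt.total_seconds().to_numpy() / 3600.0
        return cls(
            t, fx["x_km"].to_numpy(), fx["y_km"].to_numpy(), fix_error_sd_km(fx), **kwargs
        )

    # ---------------------------------------------------------------- loglik

    def loglike(self, params: CtcrwParams | tuple[float, float]) -> float:
        """Exact Gaussian log-likelihood by forward Kalman filtering.

        The x and y axes share the covariance recursion (identical dynamics
        and per-fix variances), so a single pass filters both.
        """
        beta, sigma = (
            (params.beta, params.sigma) if isinstance(params, CtcrwParams) else params
        )
        if beta <= 0 or sigma <= 0:
            raise ValueError("beta and sigma must be > 0")
        sig2 = sigma * sigma
        dt = self._dt
        r = self._r
        xs = self.x
        ys = self.y

        mx_p, mx_v = xs[0], 0.0
        my_p, my_v = ys[0], 0.0
        pxx, pxv, pvv = self.init_pos_var, 0.0, self.init_vel_var
        ll = 0.0
        n = xs.size
        for i in range(n):
            if i > 0:
                d = dt[i - 1]
                if d > 0.0:
                    a, b, qxx, qxv, qvv = _transition(beta, sig2, d)
                    mx_p, mx_v = mx_p + b * mx_v, a * mx_v
                    my_p, my_v = my_p + b * my_v, a * my_v
                    nxx = pxx + 2.0 * b * pxv + b * b * pvv + qxx
                    nxv = a * (pxv + b * pvv) + qxv
                    nvv = a * a * pvv + qvv
                    pxx, pxv, pvv = nxx, nxv, nvv
            s = pxx + r[i]
            if s <= 0 or not math.isfinite(s):
                raise FloatingPointError("ill-conditioned innovation covariance")
            ex = xs[i] - mx_p
            ey = ys[i] - my_p
            ll -= 0.5 * (2.0 * (_LOG2PI + math.log(s)) + (ex * ex + ey * ey) / s)
            kx = pxx / s
            kv = pxv / s
            mx_p += kx * ex
            mx_v += kv * ex
            my_p += kx * ey
            my_v += kv * ey
            pvv -= kv * pxv
            pxv -= kx * pxv
            pxx -= kx * pxx
        return ll

    # ---------------------------------------------------------------- fitting

    def _start_guess(self) -> tuple[float, float]:
        dt = np.maximum(self._dt, 1e-6)
        speeds = np.hypot(np.diff(self.x), np.diff(self.y)) / dt
        v = float(np.median(speeds[speeds > 0])) if (speeds > 0).any() else 0.1
        beta0 = 0.1  # ~10 h velocity correlation
        sigma0 = max(v, 1e-3) * math.sqrt(2.0 * beta0)
        return beta0, sigma0

    def fit(
        self,
        start_multipliers: tuple[float, ...] = (0.2, 1.0, 5.0),
        maxiter: int = 200,
    ) -> "CTCRWResults":
        """Maximize the likelihood over (log beta, log sigma).

        Quasi-Newton (L-BFGS-B) from a multi-start grid of
        ``len(start_multipliers)**2`` points around a moment-based guess.
        Ties are broken by highest log-likelihood, then smallest beta.
        Deterministic. Raises :class:`FitFailed` if every start fails.
        """
        beta0, sigma0 = self._start_guess()

        def nll(z):
            try:
                return -self.loglike((math.exp(z[0]), math.exp(z[1])))
            except FloatingPointError:
                return 1e12

        best = None
        n_converged = 0
        for mb in start_multipliers:
            for ms in start_multipliers:
                z0 = [math.log(beta0 * mb), math.log(sigma0 * ms)]
                res = minimize(
                    nll,
                    z0,
                    method="L-BFGS-B",
                    bounds=[(-12.0, 6.0), (-12.0, 6.0)],
                    options={"maxiter": maxiter},
                )
                if not np.isfinite(res.fun) or res.fun >= 1e11:
                    continue
                n_converged += int(res.success)
                cand = (-res.fun, -math.exp(res.x[0]), res)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            raise FitFailed("CTCRW likelihood optimization failed from all starts")
        llf, _, res = best
        params = CtcrwParams(beta=math.exp(res.x[0]), sigma=math.exp(res.x[1]))
        return CTCRWResults(
            model=self,
            params=params,
            llf=llf,
            converged=n_converged > 0,
            n_fixes=self.times.size,
            low_information=self.times.size < 8,
        )

    # ------------------------------------------------------------- smoothing

    def smooth(
        self, params: CtcrwParams, extra_times: np.ndarray | None = None
    ):
        """Kalman filter + RTS smoother over the union of fix times and
        ``extra_times`` (treated as missing observations).

        Returns ``(times, means, covs)``: smoothed state means of shape
        (n, 2, 2) — axis 1 is (x, y), axis 2 is (position, velocity) — and
        shared state covariances of shape (n, 2, 2).
        """
        t_obs = self.times
        if extra_times is None:
            t_all = t_obs.copy()
            obs_idx = np.arange(t_obs.size)
        else:
            extra = np.asarray(extra_times, dtype=float)
            t_all = np.concatenate([t_obs, extra])
            is_obs = np.concatenate(
                [np.ones(t_obs.size, bool), np.zeros(extra.size, bool)]
            )
            order = np.argsort(t_all, kind="stable")
            t_all = t_all[order]
            is_obs = is_obs[order]
            obs_idx = np.flatnonzero(is_obs)
        beta, sig2 = params.beta, params.sigma**2

        n = t_all.size
        mp = np.zeros((n, 2, 2))  # predicted means per axis
        mf = np.zeros((n, 2, 2))  # filtered means
        Pp = np.zeros((n, 2, 2))  # predicted covariances (shared by axes)
        Pf = np.zeros((n, 2, 2))
        Fs = np.zeros((n, 2, 2))  # transition into step i

        obs_ptr = dict(zip(obs_idx.tolist(), range(obs_idx.size)))
        m = np.array([[self.x[0], 0.0], [self.y[0], 0.0]])
        P = np.diag([self.init_pos_var, self.init_vel_var])
        H = np.array([1.0, 0.0])
        prev_t = t_all[0]
        for i in range(n):
            if i > 0:
                d = t_all[i] - prev_t
                prev_t = t_all[i]
                if d > 0:
                    a, b, qxx, qxv, qvv = _transition(beta, sig2, d)
                    F = np.array([[1.0, b], [0.0, a]])
                    Q = np.array([[qxx, qxv], [qxv, qvv]])
                else:
                    F = np.eye(2)
                    Q = np.zeros((2, 2))
                m = m @ F.T
                P = F @ P @ F.T + Q
                Fs[i] = F
            else:
                Fs[i] = np.eye(2)
            mp[i] = m
            Pp[i] = P
            j = obs_ptr.get(i)
            if j is not None:
                s = P[0, 0] + self._r[j]
                K = P[:, 0] / s
                innov = np.array([self.x[j], self.y[j]]) - m[:, 0]
                m = m + np.outer(innov, K)
                P = P - np.outer(K, P[0, :])
                P = 0.5 * (P + P.T)
            mf[i] = m
            Pf[i] = P

        ms = mf.copy()
        Ps = Pf.copy()
        for i in range(n - 2, -1, -1):
            G = Pf[i] @ Fs[i + 1].T @ np.linalg.inv(Pp[i + 1])
            ms[i] = mf[i] + (ms[i + 1] - mp[i + 1]) @ G.T
            Ps[i] = Pf[i] + G @ (Ps[i + 1] - Pp[i + 1]) @ G.T
        return t_all, ms, Ps


@dataclass
class CTCRWResults:
    """Fitted CTCRW: parameter estimates, diagnostics and prediction."""

    model: CTCRW
    params: CtcrwParams
    llf: float
    converged: bool
    n_fixes: int
    low_information: bool = False

    def predict(
        self,
        interval: float,
        period_days: int,
        departure_h: float = 0.0,
        bear_year_ref: str = "",
        extrapolation_horizon_h: float = 24.0,
        times: pd.DatetimeIndex | None = None,
    ) -> StandardTrack:
        """Smoothed (maximum-likelihood) locations on a regular grid.

        Grid times are ``departure_h + k * interval`` for
        k = 0 .. floor(period_days*24/interval); ``interval`` is 6 or 24 h in
        the analysis. Warns, but still predicts, if the grid extends beyond
        the last fix by more than ``extrapolation_horizon_h``.
        """
        if interval <= 0:
            raise ValueError("interval must be > 0")
        k = int(math.floor(period_days * 24.0 / interval))
        grid = departure_h + np.arange(k + 1) * float(interval)
        overhang = grid[-1] - self.model.times[-1]
        if overhang > extrapolation_horizon_h:
            warnings.warn(
                f"prediction grid extends {overhang:.1f} h beyond the last fix; "
                "smoother is extrapolating",
                stacklevel=2,
            )
        t_all, ms, _ = self.model.smooth(self.params, extra_times=grid)
        # pull grid entries back out (grid times may coincide with fix times)
        pos = np.searchsorted(t_all, grid, side="left")
        xy = ms[pos][:, :, 0]
        if times is None:
            times = grid
        return StandardTrack(
            bear_year_ref=bear_year_ref, interval=float(interval), times=times, xy=xy
        )

    def summary(self) -> str:
        p = self.params
        tau = 1.0 / p.beta
        lines = [
            "CTCRW (integrated OU velocity) fit",
            "----------------------------------",
            f"n fixes            {self.n_fixes:>10d}",
            f"log-likelihood     {self.llf:>10.2f}",
            f"beta  [1/h]        {p.beta:>10.4f}   (velocity autocorr. time {tau:.1f} h)",
            f"sigma [km/sqrt(h)] {p.sigma:>10.4f}",
            f"converged          {str(self.converged):>10s}",
        ]
        if self.low_information:
            lines.append("warning: < 8 fixes; estimates are low-information")
        return "\n".join(lines)


def standardize_bear_year(
    bear_year: BearYear,
    interval: float = 24.0,
    period_days: int = 60,
    **fit_kwargs,
) -> tuple[StandardTrack, CTCRWResults]:
    """Fit a CTCRW to one bear-year and predict its standardized track from
    departure over ``period_days`` at ``interval`` hours."""
    model = CTCRW.from_bear_year(bear_year)
    res = model.fit(**fit_kwargs)
    dep = bear_year.departure_time
    k = int(math.floor(period_days * 24.0 / interval))
    ts = dep + pd.to_timedelta(np.arange(k + 1) * interval, unit="h")
    track = res.predict(
        interval, period_days, departure_h=0.0, bear_year_ref=bear_year.key, times=ts
    )
    return track, res
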