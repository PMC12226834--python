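"""CTCRW filter/smoother correctness, fitting behaviour and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from cubsign.ctcrw import (
    CTCRW,
    CtcrwParams,
    _transition,
    simulate_ctcrw_track,
    standardize_bear_year,
)


def joint_gaussian_oracle(model: CTCRW, params: CtcrwParams):
    """Brute-force reference: stack all states into one Gaussian vector,
    condition on the observed positions by direct matrix algebra.

    Returns (posterior state means x-axis, y-axis, log-likelihood).
    """
    beta, sig2 = params.beta, params.sigma**2
    t = model.times
    n = t.size
    Fs = [np.eye(2)]
    Qs = [np.zeros((2, 2))]
    for d in np.diff(t):
        if d > 0:
            a, b, qxx, qxv, qvv = _transition(beta, sig2, d)
            Fs.append(np.array([[1, b], [0, a]]))
            Qs.append(np.array([[qxx, qxv], [qxv, qvv]]))
        else:
            Fs.append(np.eye(2))
            Qs.append(np.zeros((2, 2)))
    C = np.zeros((2 * n, 2 * n))
    mx = np.zeros(2 * n)
    my = np.zeros(2 * n)
    C[0:2, 0:2] = np.diag([model.init_pos_var, model.init_vel_var])
    mx[0:2] = [model.x[0], 0.0]
    my[0:2] = [model.y[0], 0.0]
    for i in range(1, n):
        mx[2 * i : 2 * i + 2] = Fs[i] @ mx[2 * (i - 1) : 2 * i]
        my[2 * i : 2 * i + 2] = Fs[i] @ my[2 * (i - 1) : 2 * i]
        for j in range(i):
            blk = Fs[i] @ C[2 * (i - 1) : 2 * i, 2 * j : 2 * j + 2]
            C[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = blk
            C[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] = blk.T
        C[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = (
            Fs[i] @ C[2 * (i - 1) : 2 * i, 2 * (i - 1) : 2 * i] @ Fs[i].T + Qs[i]
        )
    H = np.zeros((n, 2 * n))
    H[np.arange(n), 2 * np.arange(n)] = 1.0
    S = H @ C @ H.T + np.diag(model.sd**2)
    Sinv = np.linalg.inv(S)
    gain = C @ H.T @ Sinv
    post_x = mx + gain @ (model.x - H @ mx)
    post_y = my + gain @ (model.y - H @ my)
    ll = multivariate_normal.logpdf(model.x, H @ mx, S) + multivariate_normal.logpdf(
        model.y, H @ my, S
    )
    return post_x, post_y, ll


def toy_model(n=8, seed=42, sd=0.5, beta=0.4, sigma=0.8):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 40, n))
    t[0] = 0.0
    _, x, y = simulate_ctcrw_track(
        CtcrwParams(beta, sigma), n, np.diff(t), sd, seed=seed + 1
    )
    return CTCRW(t, x, y, np.full(n, sd))


class TestLoglik:
    def test_matches_closed_form_marginal(self):
        m = toy_model()
        params = CtcrwParams(0.4, 0.8)
        _, _, ll_oracle = joint_gaussian_oracle(m, params)
        assert m.loglike(params) == pytest.approx(ll_oracle, rel=1e-10)

    def test_sort_invariance(self):
        m = toy_model()
        perm = np.random.default_rng(1).permutation(m.times.size)
        m2 = CTCRW(m.times[perm], m.x[perm], m.y[perm], m.sd[perm])
        p = CtcrwParams(0.3, 1.0)
        assert m2.loglike(p) == pytest.approx(m.loglike(p), rel=1e-12)

    def test_duplicate_timestamp_is_finite(self):
        t = np.array([0.0, 5.0, 5.0, 10.0])
        x = np.array([0.0, 1.0, 1.0, 2.0])
        m = CTCRW(t, x, x, np.full(4, 0.1))
        ll = m.loglike(CtcrwParams(0.5, 0.5))
        assert np.isfinite(ll)

    def test_doubled_error_sds_lower_loglik_on_average(self):
        # data generated at the true SDs should, on average, be less likely
        # under a model that doubles every measurement SD
        true = CtcrwParams(0.3, 0.8)
        diffs = []
        for seed in range(10):
            t, x, y = simulate_ctcrw_track(true, 60, 3.0, 0.5, seed=seed)
            m1 = CTCRW(t, x, y, np.full(60, 0.5))
            m2 = CTCRW(t, x, y, np.full(60, 1.0))
            diffs.append(m1.loglike(true) - m2.loglike(true))
        assert np.mean(diffs) > 0

    def test_invalid_params(self):
        m = toy_model()
        with pytest.raises(ValueError):
            m.loglike((0.0, 1.0))

    def test_too_few_fixes(self):
        with pytest.raises(ValueError, match="4"):
            CTCRW([0, 1, 2], [0, 0, 0], [0, 0, 0], [0.1, 0.1, 0.1])


class TestSmoother:
    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 3), (10, 11)])
    def test_matches_joint_gaussian_conditioning(self, n, seed):
        m = toy_model(n=n, seed=seed)
        params = CtcrwParams(0.4, 0.8)
        px, py, _ = joint_gaussian_oracle(m, params)
        _, ms, _ = m.smooth(params)
        scale = np.maximum(np.abs(px), 1e-6)
        assert np.max(np.abs(ms[:, 0, :].ravel() - px) / scale) < 1e-8
        scale = np.maximum(np.abs(py), 1e-6)
        assert np.max(np.abs(ms[:, 1, :].ravel() - py) / scale) < 1e-8

    def test_translation_equivariance(self):
        m = toy_model()
        params = CtcrwParams(0.3, 0.9)
        shift = np.array([137.0, -42.0])
        m2 = CTCRW(m.times, m.x + shift[0], m.y + shift[1], m.sd)
        _, ms1, _ = m.smooth(params)
        _, ms2, _ = m2.smooth(params)
        assert np.allclose(ms2[:, 0, 0], ms1[:, 0, 0] + shift[0], atol=1e-9)
        assert np.allclose(ms2[:, 1, 0], ms1[:, 1, 0] + shift[1], atol=1e-9)
        assert np.allclose(ms2[:, :, 1], ms1[:, :, 1], atol=1e-9)  # velocities


class TestFit:
    def test_deterministic(self):
        m = toy_model(n=40, seed=5)
        r1 = m.fit()
        r2 = m.fit()
        assert r1.params == r2.params

    def test_parameter_recovery_smoke(self):
        true = CtcrwParams(0.3, 1.0)
        t, x, y = simulate_ctcrw_track(true, 200, 2.0, 0.03, seed=7)
        res = CTCRW(t, x, y, np.full(200, 0.03)).fit()
        assert res.converged
        assert abs(res.params.beta - true.beta) / true.beta < 0.5
        assert abs(res.params.sigma - true.sigma) / true.sigma < 0.2
        assert "beta" in res.summary()

    def test_low_information_flagged(self):
        t = np.array([0.0, 6.0, 12.0, 18.0])
        m = CTCRW(t, [0, 1, 2, 3], [0, 0, 0, 0], np.full(4, 0.1))
        res = m.fit()
        assert res.low_information


class TestPredict:
    def test_grid_length_contract(self):
        m = toy_model(n=40, seed=5, sd=0.1)
        res = m.fit()
        track = res.predict(24.0, 30, extrapolation_horizon_h=1e9)
        assert len(track) == 31

    def test_exact_observation_limit(self):
        # a near-zero-error fix at a grid time pins the smoothed position
        t = np.array([0.0, 24.0, 48.0, 72.0])
        x = np.array([0.0, 3.0, 1.0, 2.0])
        sd = np.array([1e-6, 1e-6, 1e-6, 1e-6])
        m = CTCRW(t, x, x, sd)
        track = m.fit().predict(24.0, 3)
        assert np.allclose(track.xy[:, 0], x, atol=1e-4)

    def test_straight_line_oracle(self):
        # dense noiseless fixes on a constant-velocity path: predictions on
        # the line
        t = np.arange(0.0, 120.0, 2.0)
        x = 0.7 * t
        y = -0.2 * t
        m = CTCRW(t, x, y, np.full(t.size, 1e-5))
        track = m.fit().predict(24.0, 4)
        assert np.allclose(track.xy[:, 0], 0.7 * np.arange(5) * 24.0, atol=1e-2)
        assert np.allclose(track.xy[:, 1], -0.2 * np.arange(5) * 24.0, atol=1e-2)

    def test_extrapolation_warns(self):
        m = toy_model(n=20, seed=2)
        res = m.fit()
        with pytest.warns(UserWarning, match="extrapolat"):
            res.predict(24.0, 30)


def test_standardize_bear_year_grid_from_departure(small_cohort):
    b = small_cohort[0]
    track, res = standardize_bear_year(b, interval=24.0, period_days=10)
    assert len(track) == 11
    assert track.times[0] == b.departure_time
    deltas = np.diff(track.times.asi8) / 3.6e12
    assert np.allclose(deltas, 24.0)
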