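"""Delayed observation structure and Kalman estimation."""

import numpy as np
import pytest

from dyadreach import (
    Condition,
    Geometry,
    ModelParams,
    build_dynamics,
    build_observation,
    compute_kalman_gains,
    get_hypothesis,
    initial_state,
    process_noise_cov,
    solve_gains,
)
from dyadreach.dynamics import BASE_DIM, IX_P1X
from dyadreach.estimation import Estimator


def test_delay_is_eleven_steps_by_default():
    assert ModelParams().delay_steps == 11
    obs = build_observation(ModelParams(), 1)
    assert obs.delay_steps == 11


@pytest.mark.parametrize("player, own_force_col, partner_force_col",
                         [(1, 4, 10), (2, 10, 4)])
def test_observed_channels_exclude_partner_force(player, own_force_col,
                                                 partner_force_col):
    p = ModelParams()
    obs = build_observation(p, player)
    slot = BASE_DIM * p.delay_steps
    read_cols = np.flatnonzero(np.any(obs.C, axis=0))
    assert np.all(read_cols >= slot), "only the oldest slot is observed"
    assert slot + own_force_col in read_cols
    assert slot + partner_force_col not in read_cols
    # 14 channels: own p/v/f, partner p/v, cc, target (x and y each)
    assert obs.C.shape[0] == 14


def test_zero_delay_observation_reads_current_base_block():
    p = ModelParams()
    obs = build_observation(p, 1, delay_steps=0)
    read_cols = np.flatnonzero(np.any(obs.C, axis=0))
    assert np.all(read_cols < BASE_DIM)


def test_gains_vanish_for_uninformative_measurements():
    p = ModelParams(noise_position=2e9, noise_velocity=2e10, noise_force=2e10)
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    K = compute_kalman_gains(dyn, obs, process_noise_cov(p, dyn.n_aug), 30)
    assert np.abs(K).max() < 1e-12


def test_near_exact_measurements_pin_observed_channels():
    """Tiny measurement noise on a zero-delay observer: one update recovers
    the observed channels of the base block almost exactly."""
    p = ModelParams(noise_position=1e-9, noise_velocity=1e-9, noise_force=1e-9)
    dyn = build_dynamics(p)
    obs = build_observation(p, 1, delay_steps=0)
    P0 = 1e-2 * np.eye(dyn.n_aug)
    K = compute_kalman_gains(dyn, obs, process_noise_cov(p, dyn.n_aug), 3,
                             P0=P0)
    # posterior error on observed channels: (I - K C) applied to prior errors
    M = (np.eye(dyn.n_aug) - K[0] @ obs.C)
    assert np.abs(obs.C @ M).max() < 1e-6


def test_gain_recursion_reaches_steady_state():
    """Gains converge: iterating the recursion 10x longer changes nothing."""
    p = ModelParams()
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    W = process_noise_cov(p, dyn.n_aug)
    K_short = compute_kalman_gains(dyn, obs, W, 60)
    K_long = compute_kalman_gains(dyn, obs, W, 600)
    # the forward recursion is a prefix: same gains where horizons overlap
    np.testing.assert_allclose(K_short[59], K_long[59], atol=1e-14)
    # and it settles to a steady state well before 10x the short horizon
    assert np.abs(K_long[599] - K_long[300]).max() < 1e-12
    assert np.abs(K_long[599] - K_long[59]).max() < 1e-2


def test_covariances_stay_symmetric_psd_and_shrink():
    """Posterior covariances are symmetric PSD; with near-noise-free
    measurements and vanishing process noise they are non-increasing."""
    p = ModelParams(noise_position=1e-9, noise_velocity=1e-9,
                    noise_force=1e-9, process_noise=0.0)
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    W = np.zeros((dyn.n_aug, dyn.n_aug))
    _, covs = compute_kalman_gains(dyn, obs, W, 30,
                                   P0=1e-4 * np.eye(dyn.n_aug),
                                   return_covariances=True)
    prev = np.inf
    for P in covs:
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert np.linalg.eigvalsh(P).min() > -1e-12
        trace = np.trace(P)
        assert trace <= prev + 1e-12
        prev = trace


def _closed_loop_errors(params, perturb_mm=5.0):
    """Noise-free closed loop; returns per-step max base-block estimate error."""
    dyn = build_dynamics(params)
    gains = solve_gains(dyn, Condition(True, True),
                        get_hypothesis("rep_weighted"), params)
    W = process_noise_cov(params, dyn.n_aug)
    P0 = 1e-4 * np.eye(dyn.n_aug)
    ests = []
    x = initial_state(params, Geometry())
    for player in (1, 2):
        obs = build_observation(params, player)
        K = compute_kalman_gains(dyn, obs, W, params.horizon_steps, P0=P0)
        ests.append(Estimator(dyn=dyn, obs=obs, K=K, x_hat=x.copy()))
    est1, est2 = ests
    est1.x_hat[IX_P1X] += perturb_mm * 1e-3
    errs = []
    for k in range(params.horizon_steps):
        u1 = -gains.F1[k] @ est1.x_hat
        u2 = -gains.F2[k] @ est2.x_hat
        x = dyn.A @ x + dyn.B1 @ u1 + dyn.B2 @ u2
        est1.step(k, est1.obs.C @ x, u1, -gains.F2[k] @ est1.x_hat)
        est2.step(k, est2.obs.C @ x, -gains.F1[k] @ est2.x_hat, u2)
        errs.append(np.abs(est1.x_hat[:BASE_DIM] - x[:BASE_DIM]).max())
    return np.array(errs)


def test_noise_free_closed_loop_estimate_tracks_truth():
    """A 5 mm initial estimate error vanishes once delayed measurements of
    the start arrive: posterior error < 1e-6 m after 200 ms."""
    p = ModelParams(noise_position=1e-8, noise_velocity=1e-8,
                    noise_force=1e-8, process_noise=1e-6, horizon_steps=60)
    errs = _closed_loop_errors(p)
    assert errs[:11].max() > 1e-3          # error persists within the delay
    assert errs[20:].max() < 1e-6          # gone after 200 ms


def test_innovation_zero_keeps_posterior_at_prior():
    p = ModelParams()
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    K = compute_kalman_gains(dyn, obs, process_noise_cov(p, dyn.n_aug), 2)
    x = initial_state(p, Geometry())
    est = Estimator(dyn=dyn, obs=obs, K=K, x_hat=x.copy())
    u = np.zeros(2)
    prior = est.predict(u, u)
    est.step(0, obs.C @ prior, u, u)       # measurement equals prediction
    np.testing.assert_allclose(est.x_hat, prior, atol=1e-15)


def test_zero_gain_means_pure_prediction():
    p = ModelParams()
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    K = np.zeros((3, dyn.n_aug, 14))
    x = initial_state(p, Geometry())
    est = Estimator(dyn=dyn, obs=obs, K=K, x_hat=x.copy())
    u = np.array([0.3, -0.1])
    for k in range(3):
        prior = est.predict(u, u)
        est.step(k, np.full(14, 9.9), u, u)    # wild measurements, ignored
        np.testing.assert_array_equal(est.x_hat, prior)


def test_dimension_mismatch_rejected():
    p = ModelParams()
    dyn = build_dynamics(p)
    obs = build_observation(p, 1)
    est = Estimator(dyn=dyn, obs=obs, K=np.zeros((1, dyn.n_aug, 14)),
                    x_hat=np.zeros(dyn.n_aug))
    with pytest.raises(ValueError, match="shape"):
        est.step(0, np.zeros(13), np.zeros(2), np.zeros(2))
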