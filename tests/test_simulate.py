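"""Closed-loop trial simulation: jumps, channels, symmetry, determinism."""

import numpy as np
import pytest

from dyadreach import (
    Condition,
    ModelParams,
    build_dynamics,
    get_hypothesis,
    make_trial_spec,
    run_batch,
    simulate_probe,
    simulate_trial,
    solve_gains,
)


@pytest.fixture(scope="module")
def params():
    return ModelParams()


@pytest.fixture(scope="module")
def gains_rel(params):
    dyn = build_dynamics(params)
    return solve_gains(dyn, Condition(True, True),
                       get_hypothesis("rep_weighted"), params)


# --- trial specification ---------------------------------------------------

def test_probe_displacement_profile_is_25_200_25():
    spec = make_trial_spec("pr/sr", "probe", "right")
    d = spec.displacement
    assert d(0.0) == 0.0
    assert d(0.0125) == pytest.approx(0.015)     # mid-ramp
    assert d(0.025) == pytest.approx(0.03)
    assert d(0.125) == pytest.approx(0.03)       # hold
    assert d(0.225) == pytest.approx(0.03)
    assert d(0.2375) == pytest.approx(0.015)     # ramp back
    assert d(0.251) == 0.0
    left = make_trial_spec("pr/sr", "probe", "left")
    assert left.displacement(0.1) == pytest.approx(-0.03)


def test_perturbation_displacement_persists():
    spec = make_trial_spec("pr/sr", "perturbation", "left")
    assert spec.displacement(0.025) == pytest.approx(-0.03)
    assert spec.displacement(5.0) == pytest.approx(-0.03)


def test_null_probe_schedule_is_identically_zero():
    spec = make_trial_spec("pi/si", "null_probe")
    assert all(spec.displacement(t) == 0.0 for t in np.linspace(0, 1, 50))


@pytest.mark.parametrize("ttype, direction", [
    ("non_perturbation", "left"),
    ("null_probe", "right"),
    ("perturbation", "none"),
    ("probe", "none"),
])
def test_invalid_type_direction_combinations_rejected(ttype, direction):
    with pytest.raises(ValueError):
        make_trial_spec("pr/sr", ttype, direction)


def test_onset_threshold_is_quarter_of_reach():
    spec = make_trial_spec("pr/sr", "perturbation", "left")
    assert spec.geometry.onset_threshold == pytest.approx(0.0625)


# --- closed-loop rollouts --------------------------------------------------

def test_noise_free_reach_hits_the_target(gains_rel, params):
    """Both targets relevant: the center cursor ends on the target to <1 mm."""
    rec = simulate_trial(gains_rel, params,
                         make_trial_spec("pr/sr", "non_perturbation"),
                         noise=False)
    assert abs(rec.center_cursor[-1, 0]) < 1e-3
    assert abs(rec.center_cursor[-1, 1] - 0.25) < 2.5e-3


def test_irrelevant_targets_ignore_the_jump(params):
    """With both targets wide nobody corrects for the cursor jump."""
    dyn = build_dynamics(params)
    g = solve_gains(dyn, Condition(False, False),
                    get_hypothesis("rep_weighted"), params)
    rec = simulate_trial(g, params,
                         make_trial_spec("pi/si", "perturbation", "left"),
                         noise=False)
    assert np.abs(rec.hand1[:, 0] - 0.13).max() < 0.005   # << 3 cm jump
    assert np.abs(rec.hand2[:, 0] + 0.13).max() < 0.005


def test_left_right_perturbations_mirror_exactly(gains_rel, params):
    left = simulate_trial(gains_rel, params,
                          make_trial_spec("pr/sr", "perturbation", "left"),
                          noise=False)
    right = simulate_trial(gains_rel, params,
                           make_trial_spec("pr/sr", "perturbation", "right"),
                           noise=False)
    # lateral positions mirror about the start offsets, forward identical
    np.testing.assert_allclose(left.hand1[:, 0] - 0.13,
                               0.13 - right.hand1[:, 0], atol=1e-12)
    np.testing.assert_array_equal(left.hand1[:, 1], right.hand1[:, 1])


def test_probe_channel_pins_lateral_hand_positions(gains_rel, params):
    rec = simulate_probe(gains_rel, params,
                         make_trial_spec("pr/sr", "probe", "left"), seed=5)
    np.testing.assert_array_equal(rec.hand1[:, 0], np.full(len(rec.time), 0.13))
    np.testing.assert_array_equal(rec.hand2[:, 0], np.full(len(rec.time), -0.13))


def test_probe_applied_forces_antisymmetric_noise_free(gains_rel, params):
    left = simulate_probe(gains_rel, params,
                          make_trial_spec("pr/sr", "probe", "left"), noise=False)
    right = simulate_probe(gains_rel, params,
                           make_trial_spec("pr/sr", "probe", "right"),
                           noise=False)
    np.testing.assert_allclose(left.applied_force1, -right.applied_force1,
                               atol=1e-12)


def test_null_probe_forces_vanish_noise_free(gains_rel, params):
    rec = simulate_probe(gains_rel, params,
                         make_trial_spec("pr/sr", "null_probe"), noise=False)
    assert np.abs(rec.applied_force1).max() < 1e-12


def test_simulate_probe_rejects_non_channel_trials(gains_rel, params):
    with pytest.raises(ValueError, match="probe"):
        simulate_probe(gains_rel, params,
                       make_trial_spec("pr/sr", "non_perturbation"))


def test_forward_kinematics_shared_between_probe_and_plain_trial(gains_rel,
                                                                 params):
    """Until (and here, throughout: x/y decouple) the jump, the forward
    reach of a probe trial matches the same-seed non-perturbation trial."""
    probe = simulate_trial(gains_rel, params,
                           make_trial_spec("pr/sr", "probe", "left"), seed=42)
    plain = simulate_trial(gains_rel, params,
                           make_trial_spec("pr/sr", "non_perturbation"),
                           seed=42)
    k = probe.onset_step
    np.testing.assert_array_equal(probe.hand1[:k, 1], plain.hand1[:k, 1])
    np.testing.assert_array_equal(probe.center_cursor[:k, 1],
                                  plain.center_cursor[:k, 1])


def test_displayed_cursor_sits_at_hand_midpoint_even_with_noise(gains_rel,
                                                                params):
    """The center cursor is a computed display quantity: hand midpoint plus
    the jump offset, at every sample of a noisy trial."""
    rec = simulate_trial(gains_rel, params,
                         make_trial_spec("pr/sr", "perturbation", "left"),
                         seed=8)
    mid = 0.5 * (rec.hand1 + rec.hand2)
    np.testing.assert_allclose(rec.center_cursor[:, 1], mid[:, 1], atol=1e-15)
    k = rec.onset_step
    np.testing.assert_allclose(rec.center_cursor[:k, 0], mid[:k, 0],
                               atol=1e-15)
    # after the jump settles, display = midpoint + (-3 cm)
    np.testing.assert_allclose(rec.center_cursor[k + 5:, 0],
                               mid[k + 5:, 0] - 0.03, atol=1e-12)


# --- probe batches ---------------------------------------------------------

def test_batches_are_bitwise_deterministic(params):
    b1 = run_batch("pr/si", "rep_weighted", params, n_trials=6, seed=11)
    b2 = run_batch("pr/si", "rep_weighted", params, n_trials=6, seed=11)
    np.testing.assert_array_equal(b1.vfr_traces, b2.vfr_traces)
    b3 = run_batch("pr/si", "rep_weighted", params, n_trials=6, seed=12)
    assert not np.array_equal(b1.vfr_traces, b3.vfr_traces)


def test_ensemble_spread_shrinks_with_noise_scale(params):
    """Epoch-mean spread scales down with the noise scales and tends to 0."""
    sds = []
    for scale in (1.0, 0.5, 0.1):
        p = params.with_(noise_position=params.noise_position * scale,
                         noise_velocity=params.noise_velocity * scale,
                         noise_force=params.noise_force * scale,
                         process_noise=params.process_noise * scale)
        b = run_batch("pr/sr", "rep_weighted", p, n_trials=16, seed=3)
        sds.append(b.epoch_means().std(ddof=1))
    assert sds[0] > sds[1] > sds[2]
    assert sds[2] < 0.25 * sds[0]


def test_noisy_batch_mean_matches_noise_free_prediction(params):
    noisy = run_batch("pr/si", "rep_weighted", params, n_trials=40, seed=2)
    clean = run_batch("pr/si", "rep_weighted", params, noise=False)
    se = noisy.epoch_means().std(ddof=1) / np.sqrt(len(noisy.epoch_means()))
    assert abs(noisy.involuntary_mean - clean.involuntary_mean) < 4 * se + 0.01
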