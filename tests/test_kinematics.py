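"""Extractor checks against the closed-form minimum-jerk oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trial
from reachkin.errors import (FeatureExtractionError, MissingChannelError,
                             NoMovementError, SequencingError, TooShortError)
from reachkin.kinematics import (MovementUnitConfig, OnsetConfig,
                                 SignalPrepConfig, compute_magnitude_params,
                                 compute_temporal_params, count_sign_crossings,
                                 detect_onset, extract_features,
                                 movement_units, prepare_signals)
from reachkin.minjerk import SubmovementKernel, render_derivatives
from reachkin.synthetic import TrialRecording

NO_FILTER = SignalPrepConfig(lowpass_cutoff=None)
LITERAL_UNITS = MovementUnitConfig(hysteresis_frac=0.0)


# ----------------------------------------------------------------- signals

def test_peak_speed_recovered_from_position_channel(single_reach_trial):
    stack = prepare_signals(single_reach_trial)  # default 10 Hz filter
    assert stack.speed.max() == pytest.approx(1.875 * 0.3, rel=0.01)


def test_constant_position_gives_zero_derivatives():
    t = np.arange(0.0, 2.0, 0.01)
    rec = TrialRecording("s", None, 0, 100.0, t,
                         pos=np.ones((t.size, 3)), acc=None,
                         trigger_time=0.0, end_time=t[-1])
    stack = prepare_signals(rec, NO_FILTER)
    assert np.abs(stack.vel).max() == 0.0
    assert np.abs(stack.acc).max() == 0.0
    assert np.abs(stack.jerk).max() == 0.0


def test_velocity_reconstruction_from_acceleration_only(single_reach_kernel):
    rec = make_trial([single_reach_kernel], drop_pos=True)
    stack = prepare_signals(rec, NO_FILTER)
    t = rec.t
    _, vel_true, _, _ = render_derivatives([single_reach_kernel], t)
    peak = np.abs(vel_true).max()
    assert np.abs(stack.vel - vel_true).max() < 0.02 * peak


def test_signal_prep_errors():
    t = np.arange(0.0, 2.0, 0.01)
    rec = TrialRecording("s", None, 0, 100.0, t, pos=np.zeros((t.size, 3)),
                         acc=None, trigger_time=0.0, end_time=t[-1])
    rec.pos = None
    with pytest.raises(MissingChannelError):
        prepare_signals(rec)
    short = TrialRecording("s", None, 0, 100.0, t[:5],
                           pos=np.zeros((5, 3)), acc=None,
                           trigger_time=0.0, end_time=t[4])
    with pytest.raises(TooShortError):
        prepare_signals(short)


# ------------------------------------------------------------------- onset

def test_onset_on_dual_unit_ramps_is_exactly_20_percent():
    t = np.arange(101) / 100.0
    onset = detect_onset(t.copy(), t.copy(), t, (0.0, 1.0))
    assert onset == pytest.approx(0.20, abs=1e-12)


def test_onset_takes_the_later_of_the_two_conditions():
    t = np.arange(101) / 100.0
    dist = t.copy()                     # crosses 20% at 0.20 s
    acc = (t >= 0.35).astype(float)     # reaches 20% of max only at 0.35 s
    onset = detect_onset(dist, acc, t, (0.0, 1.0))
    assert onset == pytest.approx(0.35, abs=1e-12)


def test_onset_matches_brute_force_scan_on_minjerk_profile():
    k = SubmovementKernel(0.3, 1.0, np.array([0.3, 0.0, 0.0]))
    rec = make_trial([k], trigger=0.0)
    stack = prepare_signals(rec, NO_FILTER)
    rel = np.linalg.norm(stack.pos - stack.pos[0], axis=1)
    onset = detect_onset(rel, stack.acc_mag, rec.t, (0.0, rec.end_time))
    # independent brute-force scan of the analytic profiles
    _, _, acc_true, _ = render_derivatives([k], rec.t)
    tau = np.clip((rec.t - 0.3) / 1.0, 0.0, 1.0)
    d_true = 0.3 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    a_true = np.abs(acc_true[:, 0])
    ok = (d_true >= 0.2 * d_true.max()) & (a_true >= 0.2 * a_true.max())
    expected = rec.t[np.flatnonzero(ok)[0]]
    assert onset == pytest.approx(expected, abs=1e-9)


def test_onset_requires_movement():
    t = np.arange(101) / 100.0
    with pytest.raises(NoMovementError):
        detect_onset(np.zeros_like(t), t.copy(), t, (0.0, 1.0))


# ---------------------------------------------------------------- temporal

def test_temporal_params():
    assert compute_temporal_params(0.4, 0.0, 5.4) == (0.4, 5.0)
    assert compute_temporal_params(0.0, 0.0, 1.0) == (0.0, 1.0)
    with pytest.raises(SequencingError):
        compute_temporal_params(2.0, 0.0, 1.0)


# --------------------------------------------------------------- magnitude

def test_single_reach_magnitude_params(single_reach_trial):
    stack = prepare_signals(single_reach_trial, NO_FILTER)
    p = compute_magnitude_params(stack, 0.0, 1.0)
    assert p["total_distance"] == pytest.approx(0.300, rel=0.01)
    assert p["time_to_peak_velocity"] == pytest.approx(0.50, abs=0.0101)
    assert p["max_velocity"] / p["avg_velocity"] == pytest.approx(1.875, rel=0.02)


def test_out_and_back_distance_exceeds_net_displacement():
    k1 = SubmovementKernel(0.0, 1.0, np.array([0.3, 0.0, 0.0]))
    k2 = SubmovementKernel(1.2, 1.0, np.array([-0.3, 0.0, 0.0]))
    rec = make_trial([k1, k2])
    stack = prepare_signals(rec, NO_FILTER)
    p = compute_magnitude_params(stack, 0.0, rec.end_time)
    assert p["total_distance"] == pytest.approx(0.600, rel=0.01)
    net = np.linalg.norm(stack.pos[-1] - stack.pos[0])
    assert net < 0.01


def test_constant_velocity_segment():
    t = np.arange(0.0, 2.0 + 1e-9, 0.01)
    v = 0.25
    pos = np.column_stack([v * t, np.zeros_like(t), np.zeros_like(t)])
    rec = TrialRecording("s", None, 0, 100.0, t, pos=pos, acc=None,
                         trigger_time=0.0, end_time=t[-1])
    stack = prepare_signals(rec, NO_FILTER)
    p = compute_magnitude_params(stack, 0.0, 2.0)
    assert p["avg_velocity"] == pytest.approx(v, rel=1e-6)
    assert p["max_velocity"] == pytest.approx(v, rel=1e-6)
    assert p["total_distance"] == pytest.approx(2 * v, rel=1e-6)


# ---------------------------------------------------------- zero crossings

def _brute_force_crossings(x):
    s = [np.sign(v) for v in x if v != 0]
    return sum(1 for a, b in zip(s, s[1:]) if a != b)


def test_sign_crossing_examples():
    assert count_sign_crossings(np.array([1.0, -1.0, 1.0, -1.0])) == 3
    assert count_sign_crossings(np.ones(50)) == 0
    assert count_sign_crossings(np.array([])) == 0
    assert count_sign_crossings(np.zeros(10)) == 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e-3, 1e-3, allow_nan=False), min_size=2,
                max_size=200))
def test_sign_crossing_matches_brute_force(xs):
    x = np.asarray(xs)
    assert count_sign_crossings(x, 0.0) == _brute_force_crossings(x)


def test_hysteresis_suppresses_zero_lingering_chatter():
    # excursion to +1, chatter within the band, then excursion to -1
    x = np.array([1.0, 0.02, -0.02, 0.02, -0.02, -1.0, 1.0])
    assert count_sign_crossings(x, 0.05) == 2
    assert count_sign_crossings(x, 0.0) > 2


# ----------------------------------------------------------- movement units

def test_rms_consolidation_examples():
    vel = np.zeros((4, 3))
    # craft per-axis signals with (3, 0, 0) crossings
    vel[:, 0] = [1, -1, 1, -1]
    units = movement_units(vel, np.zeros((4, 3)), np.zeros((4, 3)),
                           LITERAL_UNITS)
    assert units.type1_axes == (3, 0, 0)
    assert units.mu_type1_rms == pytest.approx(np.sqrt(3.0), rel=1e-12)
    sig = np.tile([1.0, -1.0, 1.0], (3, 1)).T
    units_eq = movement_units(sig, sig, sig, LITERAL_UNITS)
    assert units_eq.mu_type1_rms == pytest.approx(2.0, rel=1e-12)
    # root-sum-square mode
    units_sum = movement_units(vel, np.zeros((4, 3)), np.zeros((4, 3)),
                               MovementUnitConfig(hysteresis_frac=0.0,
                                                  rms_divisor="sum"))
    assert units_sum.mu_type1_rms == pytest.approx(3.0, rel=1e-12)


def test_single_minjerk_kernel_unit_counts(single_reach_kernel):
    """Velocity has no interior zero, acceleration one (tau = 1/2), jerk
    two (tau ~ 0.211, 0.789) along x; y and z are silent."""
    t = np.arange(0.0, 1.0 + 1e-9, 0.01)
    _, vel, acc, jerk = render_derivatives([single_reach_kernel], t)
    units = movement_units(vel, acc, jerk, LITERAL_UNITS)
    assert units.type1_axes == (0, 0, 0)
    assert units.type2_axes == (1, 0, 0)
    assert units.type3_axes == (2, 0, 0)
    assert units.mu_type1_rms == 0.0
    assert units.mu_type2_rms == pytest.approx(np.sqrt(1 / 3), rel=1e-9)
    assert units.mu_type3_rms == pytest.approx(np.sqrt(4 / 3), rel=1e-9)


def test_adding_a_corrective_never_decreases_type2_units():
    rng = np.random.default_rng(21)
    primary = SubmovementKernel(0.0, 1.0, np.array([0.3, 0.0, 0.0]))
    t = np.arange(0.0, 2.0, 0.01)
    for _ in range(200):
        c_start = 1.0 * (0.5 + 0.5 * rng.random())
        c_dur = 1.0 * rng.uniform(0.25, 0.45)
        sign = rng.choice([-1.0, 1.0])
        corr = SubmovementKernel(c_start, c_dur,
                                 sign * 0.15 * np.array([0.3, 0.0, 0.0]))
        _, v0, a0, j0 = render_derivatives([primary], t)
        _, v1, a1, j1 = render_derivatives([primary, corr], t)
        u0 = movement_units(v0, a0, j0)
        u1 = movement_units(v1, a1, j1)
        assert u1.mu_type2_rms >= u0.mu_type2_rms


# ------------------------------------------------------------- composition

def test_extract_features_single_block_trial():
    from reachkin.synthetic import Group, default_group_params, simulate_trial
    from dataclasses import replace

    params = replace(default_group_params(Group.TD), corrective_rate=0.0,
                     noise_sd_acc=0.0)
    rec = simulate_trial(params, 1, 100.0, np.random.default_rng(4))
    feats = extract_features(rec, prep_cfg=NO_FILTER)
    # 2-kernel trial: few direction reversals; mu_type1 close to the
    # analytic prediction for a reach-then-place pair
    k = rec.ground_truth.kernels
    t = rec.t
    _, v, a, j = render_derivatives(k, t)
    sl = (t >= feats.onset_time) & (t <= rec.end_time)
    expected = movement_units(v[sl], a[sl], j[sl])
    assert abs(feats.mu_type1_rms - expected.mu_type1_rms) <= 1.0
    assert feats.movement_time > 0
    assert feats.avg_velocity <= feats.max_velocity
    assert feats.time_to_peak_velocity <= feats.movement_time


def test_extraction_error_carries_trial_identity():
    t = np.arange(0.0, 2.0, 0.01)
    rec = TrialRecording("kid42", None, 3, 100.0, t,
                         pos=np.ones((t.size, 3)), acc=None,
                         trigger_time=0.0, end_time=t[-1])
    with pytest.raises(FeatureExtractionError) as exc:
        extract_features(rec)
    assert exc.value.subject_id == "kid42"
    assert exc.value.trial_index == 3


def test_reaction_time_robust_to_small_sensor_noise():
    """Small accelerometer noise shifts the detected onset by at most two
    samples (acceleration-only extraction path)."""
    k = SubmovementKernel(0.5, 1.0, np.array([0.3, 0.0, 0.0]))
    base = make_trial([k], drop_pos=True)
    feats0 = extract_features(base)
    rng = np.random.default_rng(17)
    shifts = []
    for _ in range(50):
        noisy = make_trial([k], drop_pos=True, noise_sd=0.005, rng=rng)
        feats = extract_features(noisy)
        shifts.append(abs(feats.reaction_time - feats0.reaction_time))
    assert max(shifts) <= 2.0 / base.sample_rate + 1e-9


# -------------------------------------------------------------- invariants

def test_magnitude_params_invariant_to_out_of_window_samples(single_reach_kernel):
    rec_short = make_trial([single_reach_kernel], pad=0.2)
    rec_long = make_trial([single_reach_kernel], pad=1.5)
    s1 = prepare_signals(rec_short, NO_FILTER)
    s2 = prepare_signals(rec_long, NO_FILTER)
    p1 = compute_magnitude_params(s1, 0.1, 0.9)
    p2 = compute_magnitude_params(s2, 0.1, 0.9)
    for key in p1:
        assert p1[key] == pytest.approx(p2[key], abs=1e-12)


def test_scale_covariance(single_reach_kernel):
    rec = make_trial([single_reach_kernel])
    k = 3.7
    scaled = make_trial([SubmovementKernel(0.0, 1.0, k * np.array([0.3, 0, 0]))])
    f1 = extract_features(rec, prep_cfg=NO_FILTER, window=(0.0, 1.0))
    f2 = extract_features(scaled, prep_cfg=NO_FILTER, window=(0.0, 1.0))
    for name in ("total_distance", "avg_velocity", "max_velocity",
                 "avg_acceleration", "max_acceleration"):
        assert getattr(f2, name) == pytest.approx(k * getattr(f1, name),
                                                  rel=1e-9)
    for name in ("mu_type1_rms", "mu_type2_rms", "mu_type3_rms",
                 "time_to_peak_velocity", "time_to_peak_acceleration"):
        assert getattr(f2, name) == pytest.approx(getattr(f1, name), abs=1e-12)
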