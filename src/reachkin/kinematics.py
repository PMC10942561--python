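"""Per-trial kinematic feature extraction.

Transforms one wrist-trajectory recording into twelve kinematic
parameters: reaction time, movement time, total distance, average and
maximum velocity, time to peak velocity, average and maximum
acceleration, time to peak acceleration, and the RMS-consolidated counts
of the three movement-unit types (zero crossings of velocity, acceleration
and jerk along each motion axis).

Movement onset follows a dual 20%-of-maximum rule: the earliest instant
at which both the distance travelled from the starting point and the
acceleration magnitude have reached 20% of their respective in-window
maxima.  All magnitude parameters are computed strictly inside the
[onset, end] window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, signal

from .errors import (
    ConfigError,
    FeatureExtractionError,
    MissingChannelError,
    NoMovementError,
    SequencingError,
    TooShortError,
)
from .minjerk import check_uniform_time
from .synthetic import TrialRecording

__all__ = [
    "SignalPrepConfig",
    "OnsetConfig",
    "MovementUnitConfig",
    "SignalStack",
    "KinematicFeatures",
    "MovementUnitCounts",
    "FEATURE_COLUMNS",
    "prepare_signals",
    "detect_onset",
    "compute_temporal_params",
    "compute_magnitude_params",
    "count_sign_crossings",
    "movement_units",
    "extract_features",
    "extract_feature_table",
]

FEATURE_COLUMNS = (
    "reaction_time", "movement_time", "total_distance",
    "avg_velocity", "max_velocity", "time_to_peak_velocity",
    "avg_acceleration", "max_acceleration", "time_to_peak_acceleration",
    "mu_type1_rms", "mu_type2_rms", "mu_type3_rms",
)


@dataclass(frozen=True)
class SignalPrepConfig:
    """Filtering/differentiation settings.

    ``lowpass_cutoff`` (Hz) is applied as a zero-phase (forward-backward)
    Butterworth filter of the given order before differentiation; set it
    to ``None`` to disable filtering (useful on noise-free synthetic
    input).  Derivatives are successive central differences.  When only
    acceleration is recorded, velocity comes from trapezoidal integration
    with optional per-trial linear drift removal.
    """

    lowpass_cutoff: Optional[float] = 10.0
    filter_order: int = 4
    differentiation: str = "central_difference"
    integration_drift: str = "linear_detrend"

    def __post_init__(self):
        if self.lowpass_cutoff is not None and self.lowpass_cutoff <= 0:
            raise ConfigError("lowpass_cutoff must be > 0 or None")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ConfigError("filter_order must be even and >= 2")
        if self.differentiation != "central_difference":
            raise ConfigError("only central_difference differentiation is supported")
        if self.integration_drift not in ("linear_detrend", "none"):
            raise ConfigError("integration_drift must be linear_detrend or none")


@dataclass(frozen=True)
class OnsetConfig:
    """Movement-onset detection settings (dual threshold rule)."""

    threshold_frac: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.threshold_frac < 1.0:
            raise ConfigError("threshold_frac must lie in (0, 1)")


@dataclass(frozen=True)
class MovementUnitConfig:
    """Zero-crossing counting settings.

    ``hysteresis_frac`` scales the in-window absolute maximum of each axis
    signal to form a +/- dead band; a crossing is only counted when the
    signal traverses from beyond one band edge to beyond the other, which
    suppresses noise-driven chatter near zero.  ``hysteresis_frac = 0``
    recovers the literal sign-change count.  ``rms_divisor='mean'``
    consolidates per-axis counts as sqrt((nx^2+ny^2+nz^2)/3);
    ``'sum'`` uses the root-sum-square.
    """

    hysteresis_frac: float = 0.05
    rms_divisor: str = "mean"

    def __post_init__(self):
        if not 0.0 <= self.hysteresis_frac < 1.0:
            raise ConfigError("hysteresis_frac must lie in [0, 1)")
        if self.rms_divisor not in ("mean", "sum"):
            raise ConfigError("rms_divisor must be 'mean' or 'sum'")


@dataclass
class SignalStack:
    """Aligned derivative stack for one trial (all arrays length T)."""

    t: np.ndarray
    pos: np.ndarray      # T x 3, meters
    vel: np.ndarray      # T x 3, m/s
    acc: np.ndarray      # T x 3, m/s^2
    jerk: np.ndarray     # T x 3, m/s^3

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.vel, axis=1)

    @property
    def acc_mag(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)


@dataclass
class MovementUnitCounts:
    """Per-axis zero-crossing counts and their RMS consolidation."""

    type1_axes: tuple
    type2_axes: tuple
    type3_axes: tuple
    mu_type1_rms: float
    mu_type2_rms: float
    mu_type3_rms: float


@dataclass
class KinematicFeatures:
    """The twelve per-trial kinematic parameters (SI units)."""

    reaction_time: float
    movement_time: float
    total_distance: float
    avg_velocity: float
    max_velocity: float
    time_to_peak_velocity: float
    avg_acceleration: float
    max_acceleration: float
    time_to_peak_acceleration: float
    mu_type1_rms: float
    mu_type2_rms: float
    mu_type3_rms: float
    subject_id: Optional[str] = None
    group: Optional[str] = None
    trial_index: Optional[int] = None
    onset_time: Optional[float] = None
    unit_counts: Optional[MovementUnitCounts] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {}
        if self.subject_id is not None:
            d.update(subject_id=self.subject_id, group=self.group,
                     trial_index=self.trial_index)
        d.update({name: getattr(self, name) for name in FEATURE_COLUMNS})
        return d


def _lowpass(x: np.ndarray, fs: float, cfg: SignalPrepConfig) -> np.ndarray:
    if cfg.lowpass_cutoff is None:
        return x
    if cfg.lowpass_cutoff >= fs / 2:
        raise ConfigError("lowpass_cutoff must be below the Nyquist frequency")
    sos = signal.butter(cfg.filter_order, cfg.lowpass_cutoff, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def prepare_signals(rec: TrialRecording,
                    cfg: SignalPrepConfig = SignalPrepConfig()) -> SignalStack:
    """Build the aligned position/velocity/acceleration/jerk stack.

    Position, when available, is the authoritative channel: it is low-pass
    filtered and differentiated by central differences.  With an
    acceleration-only recording, velocity is recovered by trapezoidal
    integration (with optional linear drift removal) and position by a
    second integration.
    """
    t = check_uniform_time(rec.t)
    if t.size < 10:
        raise TooShortError(f"need >= 10 samples, got {t.size}")
    if rec.pos is None and rec.acc is None:
        raise MissingChannelError("recording has neither pos nor acc")
    fs = rec.sample_rate
    dt = 1.0 / fs

    if rec.pos is not None:
        pos = _lowpass(np.asarray(rec.pos, float), fs, cfg)
        vel = np.gradient(pos, dt, axis=0)
        acc = np.gradient(vel, dt, axis=0)
        jerk = np.gradient(acc, dt, axis=0)
    else:
        acc = _lowpass(np.asarray(rec.acc, float), fs, cfg)
        vel = integrate.cumulative_trapezoid(acc, dx=dt, axis=0, initial=0.0)
        if cfg.integration_drift == "linear_detrend":
            # rest-to-rest assumption: any residual end velocity is
            # integration drift (sensor bias/noise); remove it as a ramp
            # so both boundary velocities are zero.
            ramp = (t - t[0]) / (t[-1] - t[0])
            vel = vel - np.outer(ramp, vel[-1])
        pos = integrate.cumulative_trapezoid(vel, dx=dt, axis=0, initial=0.0)
        jerk = np.gradient(acc, dt, axis=0)
    return SignalStack(t=t, pos=pos, vel=vel, acc=acc, jerk=jerk)


def _window_slice(t: np.ndarray, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(t, t0 - 1e-12))
    i1 = int(np.searchsorted(t, t1 + 1e-12))
    return slice(i0, i1)


def detect_onset(pos_mag_rel: np.ndarray, acc_mag: np.ndarray, t: np.ndarray,
                 window: tuple[float, float],
                 cfg: OnsetConfig = OnsetConfig()) -> float:
    """Movement onset: earliest in-window sample at which *both* the
    distance from the starting point and the acceleration magnitude have
    reached ``threshold_frac`` of their in-window maxima."""
    t = np.asarray(t, float)
    sl = _window_slice(t, *window)
    d = np.asarray(pos_mag_rel, float)[sl]
    a = np.asarray(acc_mag, float)[sl]
    if d.size == 0:
        raise NoMovementError("empty onset search window")
    dmax, amax = d.max(), a.max()
    if dmax <= 0 or amax <= 0:
        raise NoMovementError("no movement in the search window")
    ok = (d >= cfg.threshold_frac * dmax) & (a >= cfg.threshold_frac * amax)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise NoMovementError("thresholds never hold simultaneously")
    return float(t[sl][idx[0]])


def compute_temporal_params(onset: float, trigger: float, end: float):
    """``(reaction_time, movement_time)`` from the three event times."""
    if not (trigger <= onset <= end):
        raise SequencingError(
            f"need trigger <= onset <= end, got {trigger}, {onset}, {end}")
    return onset - trigger, end - onset


def compute_magnitude_params(stack: SignalStack, onset: float, end: float) -> dict:
    """Distance, velocity and acceleration parameters over [onset, end].

    Total distance is the summed Euclidean length of consecutive position
    increments; averages are arithmetic means of the magnitude samples;
    time-to-peak values are measured from onset, first occurrence on ties.
    """
    sl = _window_slice(stack.t, onset, end)
    tw = stack.t[sl]
    if tw.size < 2:
        raise NoMovementError("magnitude window holds fewer than 2 samples")
    pos, speed, acc_mag = stack.pos[sl], stack.speed[sl], stack.acc_mag[sl]
    steps = np.diff(pos, axis=0)
    total_distance = float(np.linalg.norm(steps, axis=1).sum())
    i_v = int(np.argmax(speed))
    i_a = int(np.argmax(acc_mag))
    return {
        "total_distance": total_distance,
        "avg_velocity": float(speed.mean()),
        "max_velocity": float(speed[i_v]),
        "time_to_peak_velocity": float(tw[i_v] - onset),
        "avg_acceleration": float(acc_mag.mean()),
        "max_acceleration": float(acc_mag[i_a]),
        "time_to_peak_acceleration": float(tw[i_a] - onset),
    }


def count_sign_crossings(x: np.ndarray, hysteresis_frac: float = 0.0) -> int:
    """Count zero crossings of a 1-D signal.

    With ``hysteresis_frac = 0`` this is the number of strict sign changes
    scanning left to right, ignoring exact zeros.  With a positive
    fraction, the signal must traverse from beyond one edge of the band
    ``+/- hysteresis_frac * max|x|`` to beyond the other for a crossing to
    count, so a signal lingering near zero yields at most one count per
    excursion pair.
    """
    x = np.asarray(x, float)
    if x.size == 0:
        return 0
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    m = np.abs(x).max()
    if m == 0.0:
        return 0
    thr = hysteresis_frac * m
    if thr == 0.0:
        s = np.sign(x)
        s = s[s != 0]
        if s.size < 2:
            return 0
        return int(np.count_nonzero(np.diff(s)))
    state = 0
    count = 0
    for v in x:
        if v >= thr:
            if state == -1:
                count += 1
            state = 1
        elif v <= -thr:
            if state == 1:
                count += 1
            state = -1
    return count


def _rms(counts: Sequence[int], divisor: str) -> float:
    sq = float(sum(c * c for c in counts))
    return float(np.sqrt(sq / 3.0)) if divisor == "mean" else float(np.sqrt(sq))


def movement_units(vel: np.ndarray, acc: np.ndarray, jerk: np.ndarray,
                   cfg: MovementUnitConfig = MovementUnitConfig()) -> MovementUnitCounts:
    """Type 1/2/3 movement units from in-window ``T x 3`` stacks.

    Type 1 counts zero crossings of the velocity components, Type 2 of the
    acceleration components, Type 3 of the jerk components; each type is
    consolidated across the x, y, z axes by the RMS rule.
    """
    out = []
    for arr in (vel, acc, jerk):
        arr = np.asarray(arr, float)
        out.append(tuple(count_sign_crossings(arr[:, ax], cfg.hysteresis_frac)
                         for ax in range(3)))
    t1, t2, t3 = out
    return MovementUnitCounts(
        type1_axes=t1, type2_axes=t2, type3_axes=t3,
        mu_type1_rms=_rms(t1, cfg.rms_divisor),
        mu_type2_rms=_rms(t2, cfg.rms_divisor),
        mu_type3_rms=_rms(t3, cfg.rms_divisor),
    )


def _fallback_end_time(stack: SignalStack, fs: float) -> float:
    """Last sample whose speed stays >= 5% of the max for >= 100 ms."""
    speed = stack.speed
    thr = 0.05 * speed.max()
    above = speed >= thr
    need = max(1, int(round(0.1 * fs)))
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise NoMovementError("no samples above the movement-end threshold")
    # walk runs of consecutive above-threshold samples from the end
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in reversed(runs):
        if run.size >= need:
            return float(stack.t[run[-1]])
    return float(stack.t[idx[-1]])


def extract_features(rec: TrialRecording,
                     prep_cfg: SignalPrepConfig = SignalPrepConfig(),
                     onset_cfg: OnsetConfig = OnsetConfig(),
                     unit_cfg: MovementUnitConfig = MovementUnitConfig(),
                     window: Optional[tuple[float, float]] = None) -> KinematicFeatures:
    """Run the full extraction chain on one recording.

    ``window=(t0, t1)`` bypasses onset detection and the end marker and
    evaluates every parameter over an externally supplied window (used for
    validation against generator ground truth); reaction time is then
    ``t0 - trigger_time``.
    """
    try:
        stack = prepare_signals(rec, prep_cfg)
        if window is not None:
            onset, end = float(window[0]), float(window[1])
        else:
            end = rec.end_time
            if end is None or not np.isfinite(end):
                end = _fallback_end_time(stack, rec.sample_rate)
            trigger = rec.trigger_time
            i0 = int(np.searchsorted(stack.t, trigger - 1e-12))
            pos_rel = np.linalg.norm(stack.pos - stack.pos[i0], axis=1)
            onset = detect_onset(pos_rel, stack.acc_mag, stack.t,
                                 (trigger, end), onset_cfg)
        reaction_time, movement_time = compute_temporal_params(
            onset, rec.trigger_time, end)
        mags = compute_magnitude_params(stack, onset, end)
        sl = _window_slice(stack.t, onset, end)
        units = movement_units(stack.vel[sl], stack.acc[sl], stack.jerk[sl],
                               unit_cfg)
    except FeatureExtractionError:
        raise
    except Exception as exc:
        raise FeatureExtractionError(rec.subject_id, rec.trial_index, exc) from exc

    return KinematicFeatures(
        reaction_time=reaction_time, movement_time=movement_time,
        mu_type1_rms=units.mu_type1_rms, mu_type2_rms=units.mu_type2_rms,
        mu_type3_rms=units.mu_type3_rms,
        subject_id=rec.subject_id,
        group=str(rec.group_label) if rec.group_label is not None else None,
        trial_index=rec.trial_index, onset_time=onset, unit_counts=units,
        **mags,
    )


def extract_feature_table(recordings, manifest: Optional[pd.DataFrame] = None,
                          prep_cfg: SignalPrepConfig = SignalPrepConfig(),
                          onset_cfg: OnsetConfig = OnsetConfig(),
                          unit_cfg: MovementUnitConfig = MovementUnitConfig()
                          ) -> pd.DataFrame:
    """Extract features for every recording into a tidy trials x features
    table, merging adaptive scores from ``manifest`` when provided."""
    rows = [extract_features(r, prep_cfg, onset_cfg, unit_cfg).as_dict()
            for r in recordings]
    table = pd.DataFrame(rows)
    if manifest is not None and len(table):
        score_cols = [c for c in ("vabs_com", "vabs_dl", "vabs_soc")
                      if c in manifest.columns]
        if score_cols:
            table = table.merge(
                manifest[["subject_id", "trial_index", *score_cols]],
                on=["subject_id", "trial_index"], how="left")
    return table
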