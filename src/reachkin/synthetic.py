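"""Synthetic reach-and-place cohort generator.

Emulates the study conditions of a continuous block reach-and-place task:
three groups (adults, typically-developing children, children with ASD),
six trials per participant, a wrist-worn inertial sensor sampling position
and linear acceleration.  Each trial is a superposition of minimum-jerk
submovements: per block one *primary* reach (home/container -> block) and
one *primary* place (block -> container), each followed by a Poisson number
of smaller *corrective* submovements launched in the second half of the
primary.  Ground truth (true onset time, true submovement counts, the
kernel list itself) is attached to every trial so downstream extraction
can be validated without real recordings.

Group parameter defaults are configuration targets chosen so group-level
feature contrasts run in the directions reported for this task family
(children with ASD: larger travelled distance via overshoot and corrective
activity, higher average/peak velocity and acceleration, more Type-2
movement units, slower reaction times; adults: faster reactions, larger
and longer but smoother movements than children).  They are explicitly
not estimates fitted to any real dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .minjerk import SubmovementKernel, render_submovements

__all__ = [
    "Group",
    "GroupParams",
    "ScoreModel",
    "CohortSpec",
    "GroundTruth",
    "TrialRecording",
    "simulate_trial",
    "simulate_cohort",
    "default_group_params",
    "default_cohort_spec",
    "null_cohort_spec",
    "separated_cohort_spec",
    "LARGE_EFFECT_FEATURES",
    "SCORE_COLUMNS",
]


class Group(str, enum.Enum):
    """Cohort group labels."""

    ADULT = "adult"
    TD = "td"
    ASD = "asd"

    def __str__(self) -> str:  # pandas/CSV friendliness
        return self.value


#: Features for which the default group parameters configure a large,
#: sign-definite ASD > TD contrast (the generator's "configured effects").
LARGE_EFFECT_FEATURES = (
    "total_distance",
    "avg_velocity",
    "max_velocity",
    "avg_acceleration",
    "max_acceleration",
    "mu_type2_rms",
)

SCORE_COLUMNS = ("vabs_com", "vabs_dl", "vabs_soc")

#: Order of the per-subject latent tendencies used by the score model.
TENDENCY_NAMES = ("log_rt", "log_dur", "log_amp", "log_rate", "log_speed")


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one group.

    All durations in seconds, amplitudes in meters, noise in m/s^2.
    ``corrective_rate`` is the Poisson mean number of corrective
    submovements per primary; ``peak_speed_scale`` divides the drawn
    primary duration (values > 1 give brisker movements).
    """

    group_label: Group
    reaction_time_mean: float
    reaction_time_sd: float
    primary_duration_mean: float
    primary_duration_sd: float
    reach_amplitude_mean: float
    reach_amplitude_sd: float
    corrective_rate: float
    corrective_amplitude_frac: float
    overshoot_frac: float
    peak_speed_scale: float
    noise_sd_acc: float

    def __post_init__(self):
        if isinstance(self.group_label, str) and not isinstance(self.group_label, Group):
            object.__setattr__(self, "group_label", Group(self.group_label))
        for name in ("reaction_time_sd", "primary_duration_sd", "reach_amplitude_sd",
                     "corrective_rate", "noise_sd_acc"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.overshoot_frac < 1.0:
            raise ConfigError("overshoot_frac must lie in [0, 1)")
        if not 0.0 <= self.corrective_amplitude_frac <= 1.0:
            raise ConfigError("corrective_amplitude_frac must lie in [0, 1]")
        if self.peak_speed_scale <= 0:
            raise ConfigError("peak_speed_scale must be > 0")


_DEFAULT_GROUP_PARAMS = {
    Group.ADULT: GroupParams(
        group_label=Group.ADULT,
        reaction_time_mean=0.28, reaction_time_sd=0.05,
        primary_duration_mean=0.95, primary_duration_sd=0.10,
        reach_amplitude_mean=0.42, reach_amplitude_sd=0.03,
        corrective_rate=0.4, corrective_amplitude_frac=0.12,
        overshoot_frac=0.0, peak_speed_scale=1.0, noise_sd_acc=0.05,
    ),
    Group.TD: GroupParams(
        group_label=Group.TD,
        reaction_time_mean=0.38, reaction_time_sd=0.08,
        primary_duration_mean=0.72, primary_duration_sd=0.09,
        reach_amplitude_mean=0.26, reach_amplitude_sd=0.03,
        corrective_rate=1.2, corrective_amplitude_frac=0.15,
        overshoot_frac=0.02, peak_speed_scale=1.0, noise_sd_acc=0.05,
    ),
    Group.ASD: GroupParams(
        group_label=Group.ASD,
        reaction_time_mean=0.45, reaction_time_sd=0.10,
        primary_duration_mean=0.80, primary_duration_sd=0.12,
        reach_amplitude_mean=0.26, reach_amplitude_sd=0.03,
        corrective_rate=2.6, corrective_amplitude_frac=0.18,
        overshoot_frac=0.14, peak_speed_scale=1.15, noise_sd_acc=0.05,
    ),
}


def default_group_params(group: Group | str) -> GroupParams:
    """Default generative parameters for ``group``."""
    return _DEFAULT_GROUP_PARAMS[Group(group)]


@dataclass(frozen=True)
class ScoreModel:
    """Linear link from per-subject latent tendencies to adaptive scores.

    Scores (communication, daily-living, socialization) are generated as
    ``intercept[group] + coefs[group] @ z + noise`` where ``z`` is the
    subject's standardized latent tendency vector in the order
    ``(log_rt, log_dur, log_amp, log_rate, log_speed)``.  Default
    coefficient signs mirror the reported correlation structure: in TD
    children slower, less smooth movement goes with *lower* daily-living /
    socialization scores, while in children with ASD longer, larger,
    faster movement goes with *higher* communication / socialization
    scores.  Intercepts follow published group norms for the instrument
    (standard scores near 100 for TD, substantially lower for ASD).
    Adults receive no scores (NaN).
    """

    coefs: dict = field(default_factory=lambda: {
        Group.TD: np.array([
            # com                dl                  soc
            [-2.0, -2.0, 0.0, -2.0, 1.0],
            [0.0, -5.0, -2.0, -5.0, 2.0],
            [0.0, -4.0, -1.0, -4.0, 4.0],
        ]),
        Group.ASD: np.array([
            [0.0, 2.0, 3.0, 0.0, 3.0],
            [0.0, 0.0, 1.0, 0.0, 1.0],
            [-1.0, 3.0, 4.0, 2.0, 4.0],
        ]),
    })
    intercepts: dict = field(default_factory=lambda: {
        Group.TD: np.array([103.4, 101.4, 100.2]),
        Group.ASD: np.array([83.2, 80.5, 72.8]),
    })
    noise_sd: float = 5.0

    def scores_for(self, group: Group, z: np.ndarray, rng: np.random.Generator):
        group = Group(group)
        if group not in self.coefs or group not in self.intercepts:
            return np.full(3, np.nan)
        mean = self.intercepts[group] + np.asarray(self.coefs[group]) @ z
        if self.noise_sd > 0:
            mean = mean + rng.normal(0.0, self.noise_sd, size=3)
        return mean


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``groups`` pairs generative parameters with subject counts;
    ``subject_cv`` is the between-subject lognormal coefficient of
    variation applied multiplicatively to reaction time, duration,
    amplitude, corrective rate and speed scale; ``trial_dropout`` drops
    each trial independently with the given probability (emulating
    trial exclusions; default keeps every trial).
    """

    groups: Sequence[tuple[GroupParams, int]]
    trials_per_subject: int = 6
    blocks_per_trial: int = 4
    sample_rate: float = 100.0
    seed: int = 0
    score_model: ScoreModel = field(default_factory=ScoreModel)
    subject_cv: float = 0.08
    trial_dropout: float = 0.0

    def __post_init__(self):
        if len(self.groups) == 0:
            raise ConfigError("CohortSpec requires at least one group")
        if self.trials_per_subject < 1 or self.blocks_per_trial < 1:
            raise ConfigError("trials_per_subject and blocks_per_trial must be >= 1")
        if self.sample_rate < 20.0:
            raise ConfigError("sample_rate must be >= 20 Hz")
        if not 0.0 <= self.trial_dropout < 1.0:
            raise ConfigError("trial_dropout must lie in [0, 1)")


def default_cohort_spec(kind: str = "children", seed: int = 0, **overrides) -> CohortSpec:
    """Default cohort: 15 TD + 26 ASD children (``kind='children'``) or the
    full three-group design with 4 adults (``kind='full'``)."""
    if kind == "children":
        groups = [(default_group_params(Group.TD), 15),
                  (default_group_params(Group.ASD), 26)]
    elif kind == "full":
        groups = [(default_group_params(Group.ADULT), 4),
                  (default_group_params(Group.TD), 15),
                  (default_group_params(Group.ASD), 26)]
    else:
        raise ConfigError(f"unknown cohort kind {kind!r}")
    return CohortSpec(groups=groups, seed=seed, **overrides)


def null_cohort_spec(seed: int = 0, n_per_label=(20, 21), **overrides) -> CohortSpec:
    """A null cohort: both child labels share identical generative
    parameters (TD defaults) and no between-subject heterogeneity, so
    trials are exchangeable across labels.  Label counts are balanced
    (chance level ~0.5) so classifier calibration reads directly against
    the usual chance band; the majority-rate behaviour under class
    imbalance is covered separately by the calibration property tests."""
    td = default_group_params(Group.TD)
    asd_like = replace(td, group_label=Group.ASD)
    overrides.setdefault("subject_cv", 0.0)
    return CohortSpec(groups=[(td, n_per_label[0]), (asd_like, n_per_label[1])],
                      seed=seed, **overrides)


def separated_cohort_spec(factor: float = 2.0, seed: int = 0,
                          n_per_label=(15, 26), **overrides) -> CohortSpec:
    """Child cohort with the configured TD->ASD contrasts amplified by
    ``factor`` in log space (used for classifier calibration checks)."""
    td = default_group_params(Group.TD)
    asd = default_group_params(Group.ASD)

    def stretch(a, b):
        if a <= 0 or b <= 0:
            return b * factor if b != a else b
        return float(a * (b / a) ** factor)

    asd2 = replace(
        asd,
        reaction_time_mean=stretch(td.reaction_time_mean, asd.reaction_time_mean),
        primary_duration_mean=stretch(td.primary_duration_mean, asd.primary_duration_mean),
        corrective_rate=stretch(td.corrective_rate, asd.corrective_rate),
        corrective_amplitude_frac=min(1.0, stretch(td.corrective_amplitude_frac,
                                                   asd.corrective_amplitude_frac)),
        overshoot_frac=min(0.6, asd.overshoot_frac * factor),
        peak_speed_scale=stretch(td.peak_speed_scale, asd.peak_speed_scale),
    )
    return CohortSpec(groups=[(td, n_per_label[0]), (asd2, n_per_label[1])],
                      seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Generator-side truth attached to a synthetic trial."""

    onset_time: float
    submovement_counts: list  # per primary segment: 1 + number of correctives
    kernels: list             # the SubmovementKernel list actually rendered

    @property
    def total_submovements(self) -> int:
        return int(sum(self.submovement_counts))

    @property
    def corrective_count(self) -> int:
        return int(sum(c - 1 for c in self.submovement_counts))


@dataclass
class TrialRecording:
    """One trial's time-stamped 3-axis wrist trajectory with markers."""

    subject_id: str
    group_label: Group
    trial_index: int
    sample_rate: float
    t: np.ndarray
    pos: Optional[np.ndarray]
    acc: Optional[np.ndarray]
    trigger_time: float
    end_time: float
    ground_truth: Optional[GroundTruth] = None

    def validate(self) -> "TrialRecording":
        from .minjerk import check_uniform_time

        t = check_uniform_time(self.t)
        if self.pos is None and self.acc is None:
            raise ConfigError("recording needs at least one of pos/acc")
        for name in ("pos", "acc"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (t.size, 3):
                raise ConfigError(f"{name} must have shape (T, 3) matching t")
        if not (self.trigger_time <= self.end_time):
            raise ConfigError("trigger_time must be <= end_time")
        if self.trigger_time < t[0] - 1e-9 or self.end_time > t[-1] + 1e-9:
            raise ConfigError("trigger/end markers must lie within the recording")
        return self


# fixed task geometry scale: home -> block-circle center distance that the
# per-trial amplitude draw is normalized against (see methods note)
_NOMINAL_REACH = 0.30
_BLOCK_RADIUS = 0.10
_CONTAINER_LATERAL = 0.25


def _segment_targets(n_blocks: int, amplitude: float):
    """Home, per-block positions on a circle, and the container position,
    scaled so the home -> circle-center distance equals ``amplitude``."""
    scale = amplitude / _NOMINAL_REACH
    home = np.zeros(3)
    center = np.array([_NOMINAL_REACH, 0.0, 0.0]) * scale
    angles = -np.pi / 2 + 2.0 * np.pi * np.arange(n_blocks) / max(n_blocks, 1)
    blocks = center + _BLOCK_RADIUS * scale * np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(n_blocks)], axis=1)
    container = center + np.array([0.0, _CONTAINER_LATERAL, 0.0]) * scale
    return home, blocks, container


def simulate_trial(params: GroupParams, blocks_per_trial: int, sample_rate: float,
                   rng: np.random.Generator, *, trigger_time: float = 0.5,
                   subject_id: str = "sim00", trial_index: int = 0) -> TrialRecording:
    """Simulate one continuous reach-and-place trial.

    Per block the hand performs a primary reach to the block then a primary
    place into the container; each primary spawns ``Poisson(corrective_rate)``
    corrective kernels of amplitude ``corrective_amplitude_frac`` times the
    primary, starting uniformly within the primary's second half and
    alternating in direction along the primary axis.  White Gaussian sensor
    noise is added to the acceleration channel only.
    """
    amp = max(0.05, rng.normal(params.reach_amplitude_mean, params.reach_amplitude_sd))
    home, blocks, container = _segment_targets(blocks_per_trial, amp)

    reaction = max(0.05, rng.normal(params.reaction_time_mean, params.reaction_time_sd))
    t0 = trigger_time + reaction
    onset_truth = t0

    kernels: list[SubmovementKernel] = []
    counts: list[int] = []
    cur = home.copy()
    for b in range(blocks_per_trial):
        for target in (blocks[b], container):
            dur = max(0.15, rng.normal(params.primary_duration_mean,
                                       params.primary_duration_sd))
            dur /= params.peak_speed_scale
            primary_disp = (target - cur) * (1.0 + params.overshoot_frac)
            primary = SubmovementKernel(t0, dur, primary_disp)
            kernels.append(primary)
            n_corr = int(rng.poisson(params.corrective_rate))
            p_norm = np.linalg.norm(primary_disp)
            u = primary_disp / p_norm if p_norm > 0 else np.zeros(3)
            moved = primary_disp.copy()
            for j in range(n_corr):
                c_start = t0 + dur * (0.5 + 0.5 * rng.random())
                c_dur = dur * rng.uniform(0.25, 0.45)
                sign = -1.0 if j % 2 == 0 else 1.0
                c_disp = sign * params.corrective_amplitude_frac * p_norm * u
                kernels.append(SubmovementKernel(c_start, c_dur, c_disp))
                moved += c_disp
            counts.append(1 + n_corr)
            cur = cur + moved
            t0 = primary.end_time + rng.uniform(0.08, 0.20)

    last_end = max(k.end_time for k in kernels)
    end_time = last_end + 0.1
    dt = 1.0 / sample_rate
    n = int(np.ceil((end_time + 0.2) / dt)) + 1
    t = np.arange(n) * dt
    pos, acc = render_submovements(kernels, t)
    if params.noise_sd_acc > 0:
        acc = acc + rng.normal(0.0, params.noise_sd_acc, size=acc.shape)

    return TrialRecording(
        subject_id=subject_id, group_label=params.group_label,
        trial_index=trial_index, sample_rate=sample_rate, t=t, pos=pos, acc=acc,
        trigger_time=trigger_time, end_time=end_time,
        ground_truth=GroundTruth(onset_truth, counts, kernels),
    ).validate()


def _subject_params(params: GroupParams, mult: np.ndarray) -> GroupParams:
    """Apply lognormal subject multipliers in TENDENCY_NAMES order."""
    return replace(
        params,
        reaction_time_mean=params.reaction_time_mean * mult[0],
        primary_duration_mean=params.primary_duration_mean * mult[1],
        reach_amplitude_mean=params.reach_amplitude_mean * mult[2],
        corrective_rate=params.corrective_rate * mult[3],
        peak_speed_scale=params.peak_speed_scale * mult[4],
    )


def simulate_cohort(spec: CohortSpec):
    """Simulate a full cohort.

    Returns ``(recordings, manifest)`` where ``manifest`` has one row per
    kept trial with columns ``subject_id, group, trial_index, trigger_time,
    end_time, vabs_com, vabs_dl, vabs_soc`` (scores repeated per trial;
    NaN for adults).  Same spec (including seed) reproduces the cohort
    bit-identically.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[TrialRecording] = []
    rows = []
    for params, n_subjects in spec.groups:
        if n_subjects < 1:
            raise ConfigError("each group needs n_subjects >= 1")
        glabel = Group(params.group_label)
        for i in range(n_subjects):
            sid = f"{glabel.value}{i:03d}"
            if spec.subject_cv > 0:
                z = rng.normal(0.0, spec.subject_cv, size=len(TENDENCY_NAMES))
                zstd = z / spec.subject_cv
            else:
                z = np.zeros(len(TENDENCY_NAMES))
                zstd = z
            sparams = _subject_params(params, np.exp(z))
            scores = spec.score_model.scores_for(glabel, zstd, rng)
            for k in range(spec.trials_per_subject):
                if spec.trial_dropout > 0 and rng.random() < spec.trial_dropout:
                    continue
                rec = simulate_trial(sparams, spec.blocks_per_trial,
                                     spec.sample_rate, rng,
                                     subject_id=sid, trial_index=k)
                recordings.append(rec)
                rows.append({
                    "subject_id": sid, "group": glabel.value, "trial_index": k,
                    "trigger_time": rec.trigger_time, "end_time": rec.end_time,
                    "vabs_com": scores[0], "vabs_dl": scores[1],
                    "vabs_soc": scores[2],
                })
    manifest = pd.DataFrame(rows)
    return recordings, manifest
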