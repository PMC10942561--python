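"""Minimum-jerk submovement primitives.

A point-to-point reach is modelled as a *minimum-jerk* submovement: the
trajectory minimizing the time integral of squared jerk between two rest
states.  Its normalized position profile is

    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5,        tau = (t - t0) / T,

with the bell-shaped normalized speed ``ds/dtau = 30 tau^2 (1 - tau)^2``
peaking at 30/16 = 1.875 at tau = 1/2, so a reach of amplitude D and
duration T has peak speed 1.875 D / T and mean speed D / T.

Continuous reach-and-place trajectories are built by linear superposition
of such kernels (one per primary or corrective submovement).  Because the
polynomial and all of its derivatives are closed-form, position, velocity,
acceleration and jerk are available analytically; these closed forms are
the oracles used throughout the test-suite to validate the numerical
feature extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NonUniformSamplingError

__all__ = [
    "SubmovementKernel",
    "minjerk_pos",
    "minjerk_vel",
    "minjerk_acc",
    "minjerk_jerk",
    "render_submovements",
    "render_derivatives",
    "check_uniform_time",
]


def minjerk_pos(tau):
    """Normalized position ``s(tau)``, clamped to [0, 1] outside the window."""
    tc = np.clip(tau, 0.0, 1.0)
    return tc**3 * (10.0 - 15.0 * tc + 6.0 * tc**2)


def minjerk_vel(tau):
    """Normalized velocity ``ds/dtau = 30 tau^2 (1 - tau)^2`` (0 outside)."""
    tc = np.clip(tau, 0.0, 1.0)
    return 30.0 * tc**2 * (1.0 - tc) ** 2


def minjerk_acc(tau):
    """Normalized acceleration ``d2s/dtau2 = 60 tau (1 - tau)(1 - 2 tau)``."""
    tc = np.clip(tau, 0.0, 1.0)
    return 60.0 * tc * (1.0 - tc) * (1.0 - 2.0 * tc)


def minjerk_jerk(tau):
    """Normalized jerk ``d3s/dtau3 = 60 - 360 tau + 360 tau^2`` (0 outside).

    Unlike the lower derivatives the jerk polynomial is nonzero at the
    window edges, so it is masked (not clamped) outside [0, 1].
    """
    tau = np.asarray(tau, dtype=float)
    inside = (tau >= 0.0) & (tau <= 1.0)
    return np.where(inside, 60.0 - 360.0 * tau + 360.0 * tau**2, 0.0)


def check_uniform_time(t, tol: float = 1e-9) -> np.ndarray:
    """Validate that ``t`` is 1-D, strictly increasing and uniform.

    Returns the validated float array; raises
    :class:`~reachkin.errors.NonUniformSamplingError` otherwise.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise NonUniformSamplingError("time vector must be 1-D with >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0.0) or (dt.max() - dt.min()) > tol:
        raise NonUniformSamplingError(
            f"time vector must be strictly increasing and uniform within {tol} s"
        )
    return t


@dataclass(frozen=True)
class SubmovementKernel:
    """One minimum-jerk submovement.

    Parameters
    ----------
    start_time
        Onset of the submovement, seconds.
    duration
        Duration T > 0, seconds.
    displacement
        3-vector displacement (meters) accumulated over the submovement.
    """

    start_time: float
    duration: float
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        d = np.asarray(self.displacement, dtype=float).reshape(-1)
        if d.shape != (3,):
            raise ValueError("displacement must be a 3-vector")
        object.__setattr__(self, "displacement", d)

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def tau(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.start_time) / self.duration

    def contribution(self, t, order: int = 0) -> np.ndarray:
        """Analytic ``T x 3`` contribution of derivative ``order`` (0..3)."""
        tau = self.tau(t)
        if order == 0:
            prof, scale = minjerk_pos(tau), 1.0
        elif order == 1:
            prof, scale = minjerk_vel(tau), 1.0 / self.duration
        elif order == 2:
            prof, scale = minjerk_acc(tau), 1.0 / self.duration**2
        elif order == 3:
            prof, scale = minjerk_jerk(tau), 1.0 / self.duration**3
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"order must be 0..3, got {order}")
        return np.outer(prof * scale, self.displacement)


def render_derivatives(kernels, t, orders=(0, 1, 2, 3)):
    """Render the requested derivative stacks for superposed kernels.

    All stacks are exact analytic sums (no numerical differentiation).
    Returns a tuple of ``T x 3`` arrays, one per entry of ``orders``
    (default: position, velocity, acceleration, jerk).
    """
    if not kernels:
        raise ValueError("kernels must be non-empty")
    t = check_uniform_time(t)
    stacks = [np.zeros((t.size, 3)) for _ in orders]
    for k in kernels:
        for out, order in zip(stacks, orders):
            out += k.contribution(t, order)
    return tuple(stacks)


def render_submovements(kernels, t):
    """Render ``(pos, acc)`` for a list of kernels on a uniform time grid."""
    pos, acc = render_derivatives(kernels, t, orders=(0, 2))
    return pos, acc
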