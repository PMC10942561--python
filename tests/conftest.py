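import numpy as np
import pytest

from reachkin.minjerk import SubmovementKernel, render_submovements
from reachkin.synthetic import GroundTruth, Group, TrialRecording


def make_trial(kernels, fs=100.0, pad=0.2, trigger=0.0, noise_sd=0.0,
               rng=None, subject="s00", group=Group.TD, trial_index=0,
               drop_pos=False, drop_acc=False):
    """Build a TrialRecording directly from analytic kernels."""
    end = max(k.end_time for k in kernels)
    n = int(np.ceil((end + pad) * fs)) + 1
    t = np.arange(n) / fs
    pos, acc = render_submovements(kernels, t)
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        acc = acc + rng.normal(0.0, noise_sd, acc.shape)
    counts = [len(kernels)]
    return TrialRecording(
        subject_id=subject, group_label=group, trial_index=trial_index,
        sample_rate=fs, t=t,
        pos=None if drop_pos else pos, acc=None if drop_acc else acc,
        trigger_time=trigger, end_time=end,
        ground_truth=GroundTruth(kernels[0].start_time, counts, list(kernels)),
    ).validate()


@pytest.fixture
def single_reach_kernel():
    return SubmovementKernel(0.0, 1.0, np.array([0.3, 0.0, 0.0]))


@pytest.fixture
def single_reach_trial(single_reach_kernel):
    """Noise-free 0.3 m, 1 s reach along x sampled at 100 Hz."""
    return make_trial([single_reach_kernel])
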