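# Methods

`reachkin` is a tested re-implementation of a reach-and-place kinematic
analysis pipeline for wrist-worn inertial sensor data: a synthetic cohort
generator with ground truth, a twelve-parameter kinematic extractor, a
group-statistics battery, and a small MLP classification protocol with
permutation feature importance.  This note records the models, the
defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## Trajectory model

Real recordings of the task (children reaching for blocks and placing
them into a container, one wrist-worn IMU) are not publicly deposited, so
every quantitative check runs on synthetic trajectories with known ground
truth.  Trials are superpositions of **minimum-jerk submovements**: each
submovement contributes `d * s(tau)` to position, with
`s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5` on `tau = (t - t0)/T`, clamped
outside `[0, 1]`.  The choice is deliberate: minimum-jerk kernels are the
standard primitive for goal-directed arm movement, and the quintic gives
closed-form velocity, acceleration and jerk, so the numerical extractor
can be validated against exact oracles (peak speed `1.875 D/T` at the
midpoint, one interior acceleration zero at `tau = 1/2`, jerk zeros at
`tau = 0.211, 0.789`).

A trial consists of `blocks_per_trial` blocks; per block one primary
reach (current position → block) and one primary place (block →
container).  Blocks sit on a 10 cm circle whose center is one reach
amplitude from the home position; the container is 25 cm lateral — a
fixed, configurable layout standing in for the study table.  Each
primary spawns `Poisson(corrective_rate)` **corrective submovements** of
amplitude `corrective_amplitude_frac x |primary|`, starting uniformly in
the primary's second half and alternating in direction along the primary
axis.  `overshoot_frac` inflates each primary beyond its target.  White
Gaussian noise (sd `noise_sd_acc`, default 0.05 m/s²) is added to the
acceleration channel only; the position channel stays noise-free so that
extractor tests can isolate differentiation error from sensor noise.
Sample rate defaults to 100 Hz, a typical wrist-IMU rate.

### Group defaults are configuration targets, not estimates

Three parameter sets (adults, TD children, children with ASD) are tuned
so that the *directions* of the group contrasts match the qualitative
pattern reported for this task family — adults: faster reactions, larger
and longer but smoother movements; ASD vs TD: larger travelled distance
(overshoot + corrective activity), higher average/peak velocity and
acceleration, more Type-2 movement units, slower reactions.  The
constant `LARGE_EFFECT_FEATURES` names the six contrasts the defaults
make large and sign-definite; time-to-peak parameters inherit
movement-time scaling only weakly and are not configured targets.  None
of these values is fitted to real data; passing tests show the pipeline
*recovers configured effects*, not that the generator reproduces real
cohorts.  Real IMU data additionally contain gravity leakage, orientation
drift, grasp-phase dynamics and marker jitter that the generator does not
emulate.

The default child cohort is 15 TD + 26 ASD subjects x 6 trials
(246 trials, 63.4% ASD), matching the study's sizing; a `trial_dropout`
probability can thin this toward the ~221 analysed samples, since no
exclusion rule is documented.  Between-subject heterogeneity is a
lognormal multiplier (CV 0.08) on reaction time, duration, amplitude,
corrective rate and speed; the same latent tendencies feed a linear
score model that generates adaptive-function scores (communication,
daily-living, socialization) with the reported sign structure: in TD
children slower/less-smooth movement links to lower daily-living and
socialization scores, in ASD children longer/larger/faster movement links
to higher communication and socialization scores.

## Kinematic extraction

Position (when present) is the authoritative channel: zero-phase
Butterworth low-pass (default 10 Hz cutoff, order 4, forward-backward)
followed by successive central differences for velocity, acceleration and
jerk.  With acceleration-only input, velocity comes from trapezoidal
integration; residual end-of-trial velocity is treated as integration
drift and removed as a linear ramp (rest-to-rest assumption — a
least-squares detrend would distort genuine bell-shaped velocity
profiles).  No gravity compensation is applied; synthetic accelerations
exclude gravity, and a real-sensor gravity-removal step is out of scope.

**Onset** is the earliest in-window instant at which *both* the distance
from the starting point and the acceleration magnitude have reached 20%
of their in-window maxima (the conjunction is read as "first instant both
thresholds hold simultaneously").  Reaction time is onset minus trigger;
movement time is the experimenter end mark minus onset (fallback when the
mark is absent: last sample whose speed stays above 5% of maximum for
100 ms).  On a continuous multi-reach trial the distance criterion is
relative to the whole-trial maximum, so detected onsets sit later than
the first submovement's start; this is a property of the rule itself and
is preserved faithfully.

All magnitude parameters are computed strictly inside `[onset, end]`:
total distance as summed Euclidean increments, averages as arithmetic
means of magnitude samples (uniform sampling makes time weighting moot),
maxima and first-occurrence argmax times for the peaks.

**Movement units** are zero crossings of velocity (Type 1), acceleration
(Type 2) and jerk (Type 3) along each axis, consolidated as
`sqrt((nx^2 + ny^2 + nz^2)/3)`; "root mean square" is read as dividing by
the number of axes, with root-sum-square available as a config option
since the phrase is ambiguous.  Counting uses a hysteresis band of 5% of
the axis maximum by default so noise chatter near zero counts at most
once per excursion pair; hysteresis 0 recovers the literal sign-change
definition and is what the brute-force oracle tests use.

## Statistics

One-way fixed-effects ANOVA per parameter across groups; Welch
(unequal-variance) post-hoc t-tests only for parameters with ANOVA
p < 0.05; per-group Pearson correlations between parameters and scores,
flagged by Benjamini–Hochberg at q = 0.05 over the whole correlation
table.  Welch rather than pooled t because group sizes differ; BH because
the FDR procedure was unnamed.  Correlations default to trial level
(consistent with the reported degrees of freedom); `subject_level=True`
averages trials within subject first.  Trial-level ANOVA treats trials as
independent; with between-subject heterogeneity this inflates the
false-positive rate, so the null-calibration checks use cohorts with the
subject-level variance set to zero and the power checks rely on effect
sizes large relative to the clustering.

## Classification protocol

Nine features (reaction time, total distance, average/max velocity, time
to peak velocity, average/max acceleration, time to peak acceleration,
Type-2 movement units) are min-max normalized — by default over the whole
dataset before splitting, mirroring the protocol as stated; because that
choice leaks validation information, `per_fold_train` scope is a
first-class alternative and the leakage audit test pins down the
difference.

The network is FC(9→64)–BN–LeakyReLU–FC(64→32)–BN–LeakyReLU–
FC(32→16)–BN–LeakyReLU–FC(16→1)–sigmoid, binary cross-entropy, Adam
(0.9/0.999), initial learning rate 1e-5 dropping permanently to 1e-6 at
the first epoch whose end-of-epoch training accuracy reaches 95%, exactly
200 epochs, threshold 0.5, stratified 10-fold cross-validation (optionally
grouped by subject so one child's trials never straddle a fold).  Hidden
widths, loss, and batch norm placement are package choices where the
protocol is silent.  The implementation is plain NumPy — forward pass,
batch-norm batch/running statistics, backpropagation and Adam are written
out — which keeps every run bit-reproducible from one integer seed.

Two interacting defaults deserve a note.  At learning rate 1e-5 an Adam
step moves each weight by about 1e-5, so 200 full-batch epochs change
weights by ~2e-3 — far too little to rotate a randomly initialized output
layer.  The package therefore (a) trains with mini-batches of 8 (≈28
steps/epoch at n≈221, enough accumulated movement for the 95% switch to
engage on separable data) and (b) initializes the output layer near zero
(sd 1e-2) so the decision direction is learned rather than inherited from
the init.  Both are configurable.

**Permutation importance**: after training, the epoch with the lowest
validation loss is restored; each feature column of the validation set is
shuffled (default 10 independent permutations) and the importance is the
mean permuted loss minus the unpermuted loss.  The validation set is the
held-out CV fold; fold-averaged importances are provided.  Estimates on
small validation sets carry sampling noise of order a few 1e-3 in loss
units, so rank statements are only meaningful for features whose
importance clears that floor.

## Numerical and degenerate-input choices

Uniform time grids are required (tolerance 1e-9 s); argmax ties break to
the first occurrence; exact zeros are ignored by the hysteresis-free
crossing count; constant features normalize to 0.5 and are flagged;
zero within-group variance with distinct means raises a degeneracy error
rather than returning infinite F.  Derived CSV output uses 6 significant
digits; raw trial channels use 10 so a write/read cycle does not perturb
differentiation.  A single global seed is fanned out to stages by fixed
offsets, making each stage independently reproducible; byte-identical
pipeline reruns are asserted in the test-suite.

## Problem sizes

The calibration tests use 100 default cohorts for effect-direction
recovery, 200 null cohorts for the false-positive rate, and 10 seeds each
for the null and label-permuted classifier checks; `scripts/acceptance.py`
re-runs the same measurements at 25/50/3 replicates.  Classifier
calibration uses a balanced-label null cohort (chance = 0.5); behaviour
under the study's 63% class imbalance is asserted separately against the
majority-class rate.

## Known limitations

- Synthetic trajectories have no gravity component, no orientation
  dynamics and no grasp mechanics; acceptance on them validates the
  pipeline's internal consistency, not agreement with real cohorts.
- The reported real-data classification accuracies (~78% ASD vs TD,
  ~98% adult vs child) are not reproduction targets: the underlying
  recordings are unavailable.
- Trial-level analyses ignore within-subject correlation by design
  (mirroring the protocol); subject-grouped folds and subject-level
  statistics are provided as the conservative alternatives.
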