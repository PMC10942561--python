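# reachkin

Quantifying goal-directed arm movement from a single wrist-worn inertial
sensor, and testing whether those kinematics separate groups of movers.
The package targets researchers studying motor control in autism spectrum
disorder (ASD) and motor development: children with ASD tend to show less
smooth, more corrected reaching — more *movement units*, more
overshooting, longer times to peak velocity — and such features are
candidate digital biomarkers.

`reachkin` provides, as one tested pipeline:

1. **`reachkin.synthetic`** — a seeded generator of reach-and-place
   cohorts (adults, typically-developing children, children with ASD)
   built from superposed minimum-jerk submovements
   (`s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`), with ground-truth onsets
   and submovement counts attached to every trial.
2. **`reachkin.kinematics`** — twelve per-trial parameters: reaction
   time, movement time, total distance, average/max velocity, time to
   peak velocity, average/max acceleration, time to peak acceleration,
   and Type 1/2/3 movement units (zero crossings of velocity,
   acceleration and jerk per axis, RMS-consolidated across axes).
   Movement onset is the first instant both relative distance and
   acceleration magnitude reach 20% of their window maxima.
3. **`reachkin.stats`** — one-way ANOVA per parameter, Welch post-hoc
   t-tests for significant parameters, per-group Pearson correlations
   with adaptive-function scores, Benjamini–Hochberg FDR flags.
4. **`reachkin.classifier`** — the MLP protocol in NumPy: min-max
   normalization, FC(9→64)–BN–LeakyReLU ×3 → FC(→1)–sigmoid, Adam with
   learning rate 1e-5 → 1e-6 once training accuracy reaches 95%,
   200 epochs, stratified 10-fold cross-validation, and permutation
   feature importance (loss increase when one feature column is
   shuffled).
5. **`reachkin.cli` / `reachkin.io`** — CSV readers/writers and a
   `reachkin` command with `simulate`, `extract`, `stats`, `train`,
   `importance` and `pipeline` subcommands.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from reachkin import (ClassifierConfig, cross_validate,
                      default_cohort_spec, extract_feature_table,
                      run_battery, simulate_cohort)

recs, manifest = simulate_cohort(default_cohort_spec("children", seed=5))
table = extract_feature_table(recs, manifest)
print(len(table), "trials,",
      f"{100 * (table.group == 'asd').mean():.1f}% ASD")

battery = run_battery(table)
row = battery.anova.set_index("parameter").loc["avg_acceleration"]
print(f"avg_acceleration ANOVA: F={row.F:.1f}, p={row.p:.2e}")

y = (table["group"] == "asd").to_numpy(int)
cv = cross_validate(table, y, ClassifierConfig(seed=5))
print(f"mean 10-fold CV accuracy: {cv.mean_accuracy:.3f}")
```

prints

```
246 trials, 63.4% ASD
avg_acceleration ANOVA: F=134.3, p=4.91e-25
mean 10-fold CV accuracy: 0.871
```

246 trials is 41 children (15 TD + 26 ASD) x 6 trials.  The ANOVA picks
up the configured ASD > TD acceleration contrast at trial level.  The
0.871 is the mean held-out accuracy of the 10 fold models at the default
generator effect sizes; doubling the configured group contrasts
(`separated_cohort_spec(2.0)`) pushes it above 0.9, while a null cohort
with identical group parameters stays at chance.

The same pipeline runs from the shell:

```bash
reachkin pipeline --seed 7 --out runs/demo
```

writing the cohort CSVs, the feature table, `stats/{anova,posthoc,
correlations}.csv`, and per-task `cv_results.csv` / `importance.csv`.

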