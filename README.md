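# copbench

Insole-based center-of-pressure (CoP) analysis for the instrumented
Timed Up and Go (TUG) test, aimed at screening Parkinson's disease (PD)
from postural-sway digital biomarkers.

Pressure-sensing insoles report the CoP — the point of application of
the resultant vertical ground reaction force under each foot — in a
normalized, dimensionless coordinate system (ML axis in [-0.5, 0.5],
AP axis in about [-0.574, 0.426]) at 100 Hz. During a TUG trial
(stand up, walk 3 m, turn, walk back, sit down) the CoP trajectory of
each foot carries information about sway magnitude, speed, spectral
content and stochastic structure that differs between PD patients and
controls. `copbench` packages that analysis end to end for
gait/posturography researchers:

* a **simulator** of two-foot TUG CoP cohorts with controllable group
  effects (sway amplitude ratio, lateralized asymmetry gain,
  low-frequency power shift, complexity reduction), so every stage is
  testable without any data download;
* **sensor I/O**: a CSV trial dialect, CoP from raw 16-sensor force
  frames via the weighted mean `cop = Σ dᵢFᵢ / ΣFᵢ`, and scenario cuts
  (full TUG vs. the 3 m walking segment);
* a frozen **72-feature-per-foot registry** across four domains —
  positional (RMS, ranges, maximal distance, 95% confidence ellipse
  area `χ²₀.₉₅ π √det Σ`, principal sway direction), dynamic (mean and
  peak velocities, sway area per second, phase-plane parameters,
  velocity-based mean frequencies), frequency (Welch PSD mean /
  centroidal / mode / quantile frequencies, band energies ≤0.5 Hz,
  0.5–2 Hz, >2 Hz), and stochastic (stabilogram-diffusion
  coefficients, critical point, scaling exponents, fractal dimension);
* **bilateral aggregation** into 144 scenario features per participant:
  the per-feature average `(L+R)/2` and the asymmetry index
  `|L−R| / (|L|+|R|)` ∈ [0, 1];
* **KDE occupancy maps** per group and foot with a shared, frozen
  bandwidth and grid, so panels are directly comparable;
* a fixed **classification protocol**: one participant-level,
  stratified 80/20 split reused by all models; per-model greedy
  sequential forward selection scored by 5-fold inner-CV F1 with the
  subset size chosen on a grid; a single refit and one evaluation on
  the untouched test set (confusion matrix, accuracy, precision,
  recall/sensitivity, specificity, F1, ROC-AUC, ROC/PR curves); and a
  cross-model consensus-feature report.

See `docs/methods.md` for the full model description, numerical
choices and limitations.

## Worked example

```python
from copbench import SimulationConfig, simulate_cohort, cohort_feature_table
from copbench.bench import (SplitSpec, SelectionConfig, make_split,
                            select_features, evaluate)

cfg = SimulationConfig(n_pd=39, n_control=38, seed=1)   # study-scale cohort
trials, meta = simulate_cohort(cfg)
table = cohort_feature_table(trials, scenario="full_tug")
print(f"cohort: {table.shape[0]} participants x {table.shape[1]-2} features")

train, test = make_split(table, SplitSpec(split_seed=0))
print(f"split: {len(train)} train / {len(test)} test")

sel = select_features(train, "LR", SelectionConfig(k_grid=tuple(range(1, 9))))
rep = evaluate(train, test, "LR", sel)
m = rep.metrics
print(f"LR: k={rep.best_k}  acc={m['accuracy']:.3f}  precision={m['precision']:.3f}  "
      f"recall={m['recall']:.3f}  F1={m['f1']:.3f}  AUC={m['roc_auc']:.3f}")
```

prints

```
cohort: 77 participants x 144 features
split: 61 train / 16 test
LR: k=2  acc=1.000  precision=1.000  recall=1.000  F1=1.000  AUC=1.000
```

The 77 simulated participants (39 PD, 38 control — PD fraction 0.506)
produce 144 features each (72 left/right averages + 72 asymmetry
indices). The stratified 20% split holds out 16 participants (8 per
group). With the simulator's default effect profile the groups are
cleanly separable: forward selection stops at two features and
logistic regression classifies the held-out set perfectly. With
`EffectProfile.zero()` the same pipeline scores at chance — the
null-calibration property exercised by the test suite.

The same flow is scriptable from a shell:

```sh
copbench simulate --n-pd 39 --n-control 38 --seed 1 --out cohort/
copbench extract  --scenario full-tug --in cohort/ --out features.csv
copbench train    --features features.csv --split-seed 0 --out report/
```

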