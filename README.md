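# elwhar

Activity recognition for **electrical line workers (ELWs)** from a single
wrist-worn tri-axial accelerometer sampled at 32 Hz.

Line workers face long shifts, remote sites, and tasks — ladder climbs,
hoists, overhead work — with some of the highest injury rates in the electric
power industry. Monitoring which tasks are performed, how often and for how
long is a prerequisite for risk assessment, and a single wristband is the
least obtrusive instrument that can support it. This package implements the
full analysis chain for classifying ten common ELW tasks (sitting, standing,
walking, hoisting, lifting, pushing, ladder, typing, electrical panel,
overhead work) from windowed acceleration signals, including a synthetic
cohort generator so every stage is testable without human-subject data.

## The method

1. **Windowing.** Annotated signals are cut into non-overlapping windows of
   4 s or 10 s (128 / 320 samples at 32 Hz), anchored at each task interval's
   start; partial windows are dropped so every window carries one label.
2. **Features.** Three per-window feature sets:
   - *time* (27): each axis is low-pass filtered (4th-order Butterworth,
     10 Hz cutoff) and summarized by 9 statistics — mean, RMS, mean absolute
     deviation, σ, min, max, median, 25th/75th percentile;
   - *frequency* (120 / 300): FFT coefficient magnitudes of the raw axis
     signals at frequencies below 10 Hz;
   - *time–frequency* (180 / 216): db4 discrete wavelet transform at maximum
     depth (4 / 5 levels), with entropy, zero- and mean-crossings and the 9
     statistics per coefficient band (cA_L, cD_L … cD_1).
3. **Classification.** k-NN, SVM and random-forest classifiers, tuned by
   10-fold CV grid search, evaluated under an **intra-subject** protocol
   (stratified 80/20 split per subject) and an **inter-subject** protocol
   (5 subject folds; test subjects never seen in training).
4. **Model comparison.** Two-way ANOVA (feature set × classifier, with
   interaction) on the five inter-subject fold accuracies, then Tukey HSD
   for significant main effects.
5. **Interpretation.** Overall random-forest feature importance;
   class-specific importance from a LIME-style weighted local linear
   surrogate averaged over 30 correctly classified windows; and
   reconstruction of the acceleration signal from the top-ranked frequency
   bins (inverse FFT) or wavelet bands (inverse DWT).

## Worked example

```python
import elwhar as e

# a 6-subject synthetic cohort, all ten tasks per subject
config = e.CohortConfig(n_subjects=6, master_seed=3)
cohort = e.simulate_cohort(config)

wcfg = e.WindowingConfig(window_s=10, sampling_rate=32)
windows = [w for rec, track in cohort for w in e.segment(rec, track, wcfg)]
fm = e.build_feature_matrix(windows, "timefreq")
print(fm.values.shape)

cfg = e.ModelConfig(kind="rf", grid={"max_depth": [10, 30], "max_features": [20]},
                    fixed_params={"n_estimators": 50}, seed=0)
intra = e.intra_subject_eval(fm, cfg, split_seed=0)
inter = e.inter_subject_eval(fm, cfg, fold_seed=0)
print(f"intra {intra.accuracy:.3f}  inter {inter.accuracy:.3f} "
      f"(sd {inter.accuracy_sd:.3f})")
```

Output:

```
(936, 216)
intra 1.000  inter 0.971 (sd 0.050)
```

936 windows (156 ten-second windows per subject across the ten tasks), each
described by 216 wavelet-band features. On this synthetic cohort the task
structure — distinct wrist orientations for postures, distinct gait
frequencies for dynamic tasks, high dispersion for hoisting — is strong
enough that the tuned forest recovers every within-subject test window;
inter-subject accuracy is slightly lower (97.1 % averaged over the five
subject folds) because models must generalize across the simulated
between-subject differences in amplitude, cadence, and wrist orientation.

A command-line interface mirrors the pipeline stages:

```bash
elwhar simulate --out cohort/ --seed 3
elwhar validate cohort/S01_recording.csv cohort/S01_annotations.csv
elwhar extract --data-dir cohort/ --domain timefreq --window-s 10 --out features.csv
elwhar evaluate --features features.csv --domain timefreq --window-s 10 \
       --protocol inter --model rf --seed 0 --out report
elwhar explain --features features.csv --domain timefreq --window-s 10 \
       --task electrical_panel --out importance.csv
```

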