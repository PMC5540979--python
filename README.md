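# eegfatigue

Entropy-feature extraction and AdaBoost classification of two-state
(normal vs fatigue) EEG.

Driver fatigue leaves a measurable trace in the EEG: fatigued-state
signals are more regular — less "complex" — than alert-state signals.
This package implements an automated detection pipeline built on that
observation, for researchers working on EEG-based vigilance and
fatigue monitoring:

1. multichannel recordings are band-pass filtered (0.15–45 Hz) and
   sectioned into non-overlapping 1-s single-channel windows
   ("units"), the atomic classification instance;
2. four regularity/complexity statistics are computed per unit —
   fuzzy entropy (FE), sample entropy (SE), approximate entropy (AE)
   and spectral entropy (PE) — and min–max scaled to [−1, 1] within
   each (subject, channel);
3. units are classified normal vs fatigue by a from-scratch AdaBoost
   ensemble over depth-limited decision trees, evaluated by repeated
   stratified 10-fold cross-validation (ERR, Precision, Recall, F1,
   MCC, ROC/AUC, paired t-tests, and parameter/robustness sweeps).

Because no public fatigue-EEG dataset accompanies the method, the
package ships a synthetic-cohort generator (1/f background whose
spectral slope steepens with the fatigue effect size, with an exact
null at effect size 0) and the MIX(p) benchmark process for validating
the entropy estimators.

## The statistics at the core

All four entropies operate on one window `x(1..L)` with embedding
dimension `m = 2`, tolerance `s = 0.2·SD(x)`, and natural logarithms.

**Approximate entropy.** With templates `T_i^m = [x(i),…,x(i+m−1)]`
and Chebyshev distance `d`, let `C_i^m = #{j : d(T_i^m, T_j^m) ≤ s} /
(L−m+1)` (self-match included) and `φ^m = mean_i ln C_i^m`. Then
`AE = φ^m − φ^{m+1}`.

**Sample entropy.** Excluding self-matches and using the `L−m`
templates common to both orders, `B` and `A` are the mean match
fractions at lengths `m` and `m+1`; `SE = ln(B/A) ≥ 0`. Windows with
no surviving matches are flagged undefined and excluded (counted in
the run log).

**Fuzzy entropy.** Templates are baseline-centered; the hard match is
replaced by the membership `D_ij = exp(−d_ij^n / s)` with gradient
`n = 4`; `γ^m` is the double average of `D_ij` over `j ≠ i`, and
`FE = ln γ^m − ln γ^{m+1}`.

**Spectral entropy.** `PE = Σ_i y_i ln(1/y_i)` where `y_i` is the
periodogram power distribution of the mean-removed window.

**AdaBoost.** With labels `y_i ∈ {−1,+1}` (+1 = normal) and uniform
initial weights, round `m` trains a weight-aware Gini tree `D_m`,
computes `e_m = Σ_i W_{m,i} I(D_m(x_i) ≠ y_i)` and
`α_m = ½ ln((1−e_m)/e_m)`, reweights
`W_{m+1,i} ∝ W_{m,i} exp(−α_m y_i D_m(x_i))`, and accumulates
`f_m(x) = f_{m−1}(x) + lr·α_m·D_m(x)`. The decision is `sign(f_M(x))`.
Default operating point: `max_depth = 9`, `lr = 1.0`, `M = 500`.

## Worked example

```python
import eegfatigue as ef

# a small two-state cohort: 4 subjects, 2 channels, 30 s per state
cfg = ef.SynthConfig(n_subjects=4, n_channels=2, fs=128,
                     minutes_per_state=0.5, effect_size=1.0, seed=7)
epochs = ef.assemble_dataset(ef.iter_cohort(cfg))
print(f"{len(epochs)} one-second units")

table = ef.scale_features(ef.extract_features(epochs, feature_set="combined"))
print(table.groupby("state")[["FE", "SE", "AE", "PE"]].mean().round(3))

clf = ef.AdaBoostBinaryClassifier(n_estimators=50, max_depth=3)
report = ef.cross_validate(table, clf, k=10, n_runs=10, seed=1)
print({k: round(v, 3) for k, v in report.as_dict().items()})
```

prints

```
480 one-second units
            FE     SE     AE     PE
state
fatigue -0.857 -0.402  0.099 -0.064
normal   0.560  0.241  0.135  0.557
{'err': 0.0, 'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'mcc': 1.0, 'auc': 1.0}
```

The 480 units are 4 subjects × 2 states × 2 channels × 30 windows.
Fatigue units have markedly lower fuzzy and sample entropy — the
increased regularity the features are designed to capture — and at
this effect size the cross-validated ensemble separates the states
perfectly (ERR 0, AUC 1). At `effect_size=0` the same pipeline yields
chance-level AUC ≈ 0.5.

The same workflow is available from the shell:

```sh
eegfatigue simulate config.yaml   # write a labelled cohort + manifest
eegfatigue extract  config.yaml   # filter, window, features -> CSV
eegfatigue evaluate config.yaml   # cross-validated report + ROC + sweeps
```

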