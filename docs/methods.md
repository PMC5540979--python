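# Methods

This note documents the models, estimators, parameter choices and
numerical conventions of `eegfatigue`, and what the synthetic-data
experiments do and do not demonstrate about real EEG.

## Signal model and preprocessing

A recording is a channels × timepoints matrix of amplitudes at
sampling rate `fs`, carrying a subject id and a binary state label
(`normal` → +1, `fatigue` → −1; the *normal* state is the positive
class everywhere downstream).

Filtering is a zero-phase Butterworth cascade: an order-4 low-pass at
the high corner followed by an order-2 high-pass at the low corner,
each applied forward–backward (`sosfiltfilt`). The default band is
0.15–45 Hz. A monolithic band-pass with a sub-hertz low corner is
numerically ill-conditioned at EEG sampling rates (we measured 2–4 %
stop-band leakage at 100 Hz for fs = 1 kHz); the cascade reaches the
designed attenuation in steady state. The high-pass is padded over
`3·fs/low_hz` samples so its startup transient decays inside the
padding, but an edge transient of roughly `1/low_hz` seconds is
inherent to any zero-phase drift removal — recordings much shorter
than ~30 s are filtered best-effort, and the filter tests assert the
steady-state (central) response.

Windowing cuts each channel into non-overlapping 1-s units of
`L = round(fs · window_s)` samples, half-open ranges
`[kL, (k+1)L)`, discarding a trailing partial window. Unit counts
therefore depend only on duration and window length, not on `fs` or
amplitude — which is what lets the reference design (28 subjects × 2
states × 30 channels × 5 min → 504,000 units) be reproduced at a
reduced sampling rate.

## Entropy estimators

Shared parameters: embedding dimension `m = 2`, tolerance
`s = s_coef · SD(x)` with `s_coef = 0.2` computed from each window's
own SD (per-window stationarity assumption), fuzzy gradient `n = 4`,
natural logarithms for all four statistics. Distances between
templates are Chebyshev (maximum coordinate difference).

* **Approximate entropy** counts template matches *including* the
  self-match, so every count is ≥ 1 and the logarithm is always
  defined; at order `k` all `L−k+1` templates are used and counts are
  normalized by the template count. A strict variant excluding
  self-matches is available (`exclude_self=True`) for study; it can
  produce infinities.
* **Sample entropy** excludes self-matches and uses the standard
  convention: the `L−m` templates common to both orders, each with
  `L−m−1` candidate partners. `SE = ln(B/A)` is non-negative whenever
  defined because a length-`m+1` match implies a length-`m` match.
  Windows with `A = 0` (no matches at the longer length) get an
  undefined-entropy sentinel (`NaN`); feature extraction excludes such
  units and reports their count rather than imputing — at `L = 128`
  and these parameters sentinels are rare, but at `L ≲ 40` they are
  common, which bounds how short a window this feature set tolerates.
* **Fuzzy entropy** centers each template by its own mean before
  measuring distance (hence exact invariance to additive offsets) and
  replaces the hard threshold by the membership
  `D = exp(−d^n / s)`, the canonical fuzzy-entropy form. Note a
  consequence sometimes overlooked: because `d^n` is compared against
  a tolerance *linear* in the SD, fuzzy entropy with `n ≠ 1` is not
  exactly amplitude-scale invariant (the hard-threshold estimators
  are; `n = 1` restores the symmetry). The tests pin down this exact
  behavior.
* **Spectral entropy** is the Shannon entropy of the normalized
  power distribution of a plain rectangular-window periodogram of the
  mean-removed window, over the full post-filter band. Zero-power
  bins contribute nothing; an all-constant window returns 0. No
  division by `ln(n_bins)` is applied by default (a `normalize=True`
  option maps to [0, 1]).

Summation order is fixed (ascending indices, double precision), so
results are bit-reproducible. Each estimator is verified against an
independently coded naive double-loop oracle to 1e−10 on 100 seeded
sequences, and against the MIX(p) complexity ordering (mean AE, SE,
FE strictly increasing in p at L = 1000 over 50 seeds).

Feature tables carry one row per unit with metadata
(subject, channel, epoch_index, state) and the chosen feature columns
(combined set ordered FE, SE, AE, PE). Scaling maps each
(subject, channel, feature) group affinely onto [−1, 1]. The default
mode fits the group extrema on all units before any train/test split,
replicating the conventional whole-dataset normalization; a
`train_only` mode fits on training units only (test values may then
exceed the interval and are clipped by default). Constant groups map
to 0 with a warning.

## Classifier

AdaBoost is implemented from scratch in its discrete form. Sample
weights enter the base trees through the *split criterion* (weighted
Gini impurity), not through resampling, making training fully
deterministic. Tree details: axis-aligned splits at midpoints between
consecutive distinct sorted values; zero-gain splits are allowed (as
in CART — required, e.g., for depth-2 trees to solve XOR-patterned
data); ties broken toward the smallest threshold, then the lowest
feature index; leaves predict the sign of the weighted class sum with
exact ties going to +1.

Boosting round `m`: weighted error `e_m` (misclassification
indicator), learner weight `α_m = ½ ln((1−e_m)/e_m)`, weight update
`W ∝ W·exp(−α_m y D_m(x))` renormalized to sum 1 (checked to 1e−12).
The learning rate shrinks only the accumulated score
`f_m = f_{m−1} + lr·α_m·D_m`, not the weight update. Degenerate
rounds: `e_m = 0` clamps the error to 1e−10, keeps the (perfect)
learner and stops; `e_m ≥ 0.5` discards the learner and stops with a
warning. The decision is the sign of the score with 0 mapped to +1
(configurable only by relabeling). The classic training-error bound
`Π_m 2√(e_m(1−e_m))` is asserted round-by-round in the tests.

Default operating point `max_depth = 9`, `lr = 1.0`, `M = 500`.
Tests and the acceptance script use smaller ensembles (M = 30–50,
depth 2–3) because the desk-scale synthetic cohorts are
low-dimensional (a single FE feature) and saturate well before 500
rounds; the sweep runners expose the full grids.

Baselines (RBF-kernel SVM, Gaussian naive Bayes, single decision
tree) are thin adapters over scikit-learn — except the tree, which
reuses the from-scratch weak learner with uniform weights — exposing a
uniform `fit` / `decision_function` / `predict` surface plus an
optional grid-search hook. Models persist to a versioned JSON document
(thresholds, leaf labels, alphas, lr, M, seed).

## Evaluation

Confusion counts take normal (+1) as positive. ERR uses the full
total `(FP+FN)/(TP+TN+FP+FN)`. Degenerate denominators (no predicted
positives, an empty MCC factor) return 0 with the affected metric
flagged, so sweeps never abort. The ROC sweeps thresholds over unique
scores with tied scores moving as one step (equivalent to the
Mann–Whitney tie convention, verified by exhaustive pair counting up
to n = 50); AUC is trapezoidal.

Cross-validation: stratified shuffled k-fold (fold assignment
delegated to scikit-learn's splitters under a derived per-run seed);
each of the `n_runs` runs re-randomizes folds only — features are
built once. Run metrics are computed on the pooled out-of-fold
predictions; the report carries means and SDs over runs and a mean
ROC obtained by vertical averaging of per-run curves on a fixed
101-point FPR grid. Paired t-tests over matched runs are two-sided;
identical vectors give (t=0, p=1) and a constant nonzero difference
returns an infinite statistic with p = 0 as an explicit sentinel.

Sweep runners reproduce the four experiment designs: tree-depth and
learning-rate grids (repeated k-fold per grid point), test-fraction
robustness (stratified random splits over ratios in (0,1), skipping
ratios that empty either side), and cohort-size robustness (random
subject subsets, 20 repeats by default, k-fold per subset).

## Synthetic cohorts

The generator emulates the reference design — 28 subjects, 30
channels, 5 minutes per state — at a default 250 Hz sampling rate
(1 kHz available; unit counts are unaffected because they depend only
on duration). The background is 1/f-shaped Gaussian noise
(spectral exponent 1.0), band-passed to 0.15–45 Hz, the canonical
coarse model of resting EEG spectra.

The fatigue signature is a steepening of the spectral slope: the
fatigue state draws the same process with exponent
`1.0 + 0.5·δ·g_subject`, where `δ` is the effect size and
`g_subject ~ U(0.8, 1.2)` models between-subject variability. A
steeper slope shifts relative power from fast (beta-band) activity
toward slow/alpha activity — the classic spectral change of fatigue —
and makes windows smoother at the sample scale, lowering FE, SE and
AE monotonically in δ. We deliberately did *not* model fatigue as
*adding* a narrowband alpha oscillation to a fixed background:
measurement shows that any added mid-frequency component (tone or
narrowband noise, at every background slope and sampling rate we
tried) *raises* the match-counting entropies, because the filtered
1/f background is smoother at lag-1 embedding scale than the added
oscillation — the same reason the MIX(p) benchmark interpolates by
*replacing* samples rather than summing components. At `δ = 0` the
two states are draws from the identical process, giving an exact null
for calibration. Subject-level streams are spawned deterministically
from the cohort seed.

MIX(p) is `(1−z_j)·√2·sin(2πj/12) + z_j·V_j` with
`z_j ~ Bernoulli(p)` and `V_j ~ U(−√3, √3)`: unit variance at both
ends, a pure period-12 sinusoid at p = 0 and i.i.d. uniform noise at
p = 1.

What the generator does not emulate: eye-blink/EMG artifacts,
channel covariance and topography, nonstationary drowsiness dynamics,
line noise, or alpha *spindling*. Passing the end-to-end tests
therefore demonstrates that the pipeline detects a regularity
difference of plausible spectral form at honest null calibration —
not that it reaches any particular accuracy on real recordings.

## Problem sizes and calibration choices

The end-to-end tests and the acceptance script use a cohort of 8
subjects × 4 channels × 1 min per state at 128 Hz (3,840 units).
This size is chosen for statistical honesty, not only speed: with few
short recordings, a pooled-unit cross-validation can exploit
per-recording sampling noise as pseudo-signal (each recording's mean
entropy differs by chance, and units from one recording appear in
both train and test folds), inflating the null AUC above 0.55. At 64
recordings × 60 units each the inflation is negligible and the
null-effect AUC lands at ≈ 0.50–0.51. This pseudo-replication effect
is worth keeping in mind when interpreting pooled-unit
cross-validation results on real multi-subject EEG as well. The
design-count computation runs the full 28 × 30 × 5-min cohort at
100 Hz.

## Known limitations

* Undefined sample entropy is excluded, not imputed; on very short
  windows this can bias the retained-unit population.
* The fuzzy-entropy scale sensitivity (above) means FE values are
  comparable only after the per-subject/per-channel scaling step.
* The zero-phase high-pass edge transient makes the first/last few
  seconds of a recording unreliable at the 0.15 Hz corner.
* Subject-level leakage is inherent to the pooled-unit evaluation
  design this package reproduces; a subject-held-out protocol would
  give more conservative estimates and is not implemented.
* The EDF path is read-only and requires the optional mne dependency.
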