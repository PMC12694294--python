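# Methods

## Signal model and derivation

A recording is a single segmented activity trial: tri-axial
acceleration (g), barometric pressure (kPa) and ambient temperature
(°C) sampled at a common rate (201 Hz by default; the rate is inferred
from the time column rather than trusted, and a >1% mismatch against a
declared rate is an error).

Two derived channels drive everything downstream:

* **AVM** — the Euclidean norm of the three acceleration axes,
  orientation-invariant, ≈1 g at rest. AVM is used unfiltered: impact
  spikes are precisely the high-frequency content a low-pass would
  destroy.
* **Barometric altitude** — `h(p,T) = (T+273.15)/0.0065 · (1 −
  (p/p₀)^0.19)` with p₀ = 101.325 kPa. Temperature enters per sample.
  Raw altitude carries decimeter-scale noise, so it is smoothed with a
  Butterworth low-pass applied forward–backward (zero phase). Zero
  phase matters: several features measure *when* the altitude drops,
  and a causal filter would delay that by hundreds of milliseconds.
  Cutoff defaults to 1 Hz and order to 4; both are configurable. The
  filter order is a package choice — voluntary human movement and the
  fall-induced altitude transition live below ~1 Hz in this channel,
  and order 4 gives ≥40 dB of stop-band rejection at 10 Hz without
  numerical trouble at 201 Hz (implemented in second-order sections).
* **Vertical velocity** — central finite differences of the *filtered*
  altitude (differentiating the raw channel would amplify its noise to
  several m/s).

## Features

Features are named `avm_*` / `alt_*` by sensor provenance. Altimeter
statistics are computed on the filtered altitude re-referenced to the
mean of its first second, so "median altitude" means the level change
within the trial, not the altitude of the building floor.

Conventions that change numbers and are therefore pinned:

* Quantiles (median, IQR) use linear interpolation ("type 7").
  Skewness is adjusted Fisher–Pearson, kurtosis is bias-corrected
  excess; both defined as 0 for zero-variance input.
* Jerk is the first difference of AVM scaled by fs (for the altimeter,
  the third difference of altitude scaled by fs³, jerk being the third
  derivative of position). `jerk_variability` uses the population std
  so that rms² = variability² + mean² holds exactly.
* Lag-1 autocorrelation is the normalized form R(1)/R(0) on the
  centered series. The unnormalized lagged product-sum depends on
  amplitude and length, which would make the feature incomparable
  across recordings; normalization preserves exactly the
  rhythmicity-vs-irregularity contrast the feature exists to capture.
* Peak detection (steps, impacts) requires a topographic prominence of
  0.5 g, a height of 0.5 g above the series median, and 0.25 s
  separation — chosen so gait at up to 4 steps/s still resolves
  distinct steps. With <2 peaks the inter-peak interval sentinel is the
  recording duration and the amplitude variability is 0; feature tables
  never contain non-finite entries.
* **Δh**: the series is cut into consecutive non-overlapping
  left-aligned windows (trailing remainder dropped); Δh is the maximum
  drop between consecutive window means. Window w₁ = 1.25 s feeds the
  canonical feature; w₂ = 2.5 s is also computed. Because window
  alignment is arbitrary relative to the fall, a drop of D completed
  within one window yields Δh between D/2 (transition centered in a
  window) and D (transition at a boundary); Δh is a descent-steepness
  *score*, not an unbiased drop estimator.
* Spectra are one-sided power spectra of the mean-removed series, no
  taper (recordings are short single activities; comparability across
  features matters more than leakage suppression; a Hann option
  exists). The DC bin is excluded from all shape features. Dominant
  frequency ties break toward the lower frequency. Band-power ratio
  defaults: AVM low [0.5, 3] Hz vs high (3, 20] Hz (gait vs impact
  energy); altimeter low [0, 0.3] Hz vs high (0.3, 1] Hz (the channel
  is low-passed at 1 Hz). An empty low band with non-empty high band
  maps to the sentinel 1e6.
* Shannon entropy is the amplitude-histogram entropy (16 equal-width
  bins by default), normalized to [0, 1] — a complexity measure
  distinct from spectral entropy. Signal energy is mean squared
  (centered) amplitude, i.e. power per sample, length-invariant.

## Feature selection

Features are z-scored (population σ; σ = 0 columns are flagged and
collapse to zero) with the scaler always fit on training rows only —
inside every CV fold and on the training dataset in cross-dataset
runs — since fitting on test rows would leak distributional
information. Redundancy pruning computes pairwise Spearman |ρ| (rank
based, hence outlier-robust and invariant to the z-scoring) and makes a
greedy keep-first pass in a fixed canonical order (canonical preset
order first, then alphabetical): a feature is dropped iff it correlates
at |ρ| ≥ 0.85 with an already-kept feature. The pass is deterministic,
idempotent, and its report records each drop's partner and ρ so it can
be re-verified from the table. The canonical 27-feature fused preset
(12 AVM + 15 altimeter) is the default benchmark feature set; the
data-driven pruning path is offered alongside it.

## Classifiers and evaluation

Random forest (300 trees), RBF SVM (C = 1, probability outputs),
XGBoost (300 rounds, depth 6, learning rate 0.1), logistic regression
(L2, C = 1), and a majority voter over all four. All hyperparameters
live in the run configuration and are embedded (with the config hash
and seed) in every report. Training rows are sorted into a canonical
lexicographic order before fitting, which makes training invariant to
the caller's row ordering — otherwise seeded bootstrap draws would hit
different rows under permutation. The majority voter takes the modal
label; ties (possible with four voters) break toward the tied class
with the highest mean predicted probability, and the ensemble
probability is the member mean.

Tasks: binary (ADL = {sitting, walking, running, jumping} vs FALL) and
five-class. Metrics: per-class precision/recall/F1 (0/0 defined as 0,
flagged), support-weighted and macro aggregates, stratified 5-fold CV
(fold scores ± sd; dispersion is the sd across folds), and one-vs-rest
ROC with micro (pooled) and macro (unweighted mean) AUC; classes absent
from the test labels are excluded from the macro with a flag rather
than imputed. Cross-dataset evaluation trains on one cohort tag and
tests on the other, both directions, binary task. ANOVA compares
classifier families on per-fold macro-F1 (folds are the only replicate
structure available), with Tukey HSD post hoc at α = 0.05 when the
ANOVA is significant; all-constant score vectors make F undefined and
are flagged degenerate. No class rebalancing is applied — the macro
metrics carry the imbalance information.

## The synthetic-data generator

The generator emulates the *structure* of wearable fall/ADL corpora,
not biomechanics:

* **falls**: pre-fall ≈1 g (1.5–3 s), free-fall dip to 0.4–0.8 g while
  the altitude drops 0.5–1.0 m over 0.3–0.8 s, a half-sine impact spike
  of 3–8 g (60–120 ms) ending the descent, then rest. Ground truth
  (impact sample, drop) is recorded per fall; the impact spike is the
  AVM argmax by construction.
* **sitting**: cosine-ramp descent of 0.4–0.6 m over 1–2 s with an
  acceleration bump below 2 g.
* **walking/running**: AVM sinusoids at 1.6–2.2 Hz / 2.4–3.2 Hz
  (running larger amplitude) with a mild second harmonic; flat
  altitude.
* **jumping**: asymmetric spike/dip cycles at 0.8–1.5 Hz with a ≤0.5 m
  altitude oscillation.

Body-sway fluctuation is band-limited (3 Hz) Gaussian with sd 0.05 g —
white noise at 201 Hz would swamp the jerk features with
differentiated sensor noise, which real (smooth) movement does not do;
a white sensor-noise floor of 0.008 g per axis is added separately.
Altitude noise is white with sd 0.15 m pre-filter, leaving
centimeter-level residual after the 1 Hz low-pass. Pressure is
synthesized by inverting the barometric formula at the simulated
temperature, so preprocessing recovers the constructed altitude exactly
in the noiseless limit.

The default mixture is 600 recordings in the proportions of a heavily
imbalanced sitting/fall corpus (392/178/10/10/10); a balanced preset
exists. Recordings are split across two dataset tags, the second
optionally passing a wrist-placement transform (per-recording AVM
amplitude jitter ×U(0.7, 1.3), doubled sensor noise) — a deliberately
minimal, clearly synthetic stand-in for sensor-placement differences
between cohorts. Sizes were chosen so the full benchmark runs in
minutes on one CPU.

**What passing tests do and do not show.** The generator produces
class-conditional feature separation by construction (fall impacts
dominate jerk energy; gait bands are disjoint), so near-ceiling scores
on it certify that the pipeline extracts and exploits the intended
discriminative structure — not that it would reach those scores on real
falls, where simulated-vs-real intensity differences, soft impacts,
pressure drifts and unmodeled activities all bite. The informative
outputs at desk scale are the orderings (fusion ≥ accelerometer ≥
altimeter), the degradation under placement shift, and the degenerate-
case behaviour, all of which the test suite asserts.

## Known limitations

* The simulator does not model soft/slow falls, recovery movements,
  stair climbing, elevator rides, or weather-driven pressure drift.
* The wrist transform perturbs amplitude and noise only, not the
  frequency content real wrist placement would alter.
* Δh systematically under-reads drops whose transition straddles a
  window center (bounded below by half the drop; see above).
* Holdout/CV protocol choices (80/20 stratified holdout, 5 folds) are
  config-pinned and printed in reports; other protocols change the
  dispersion estimates.
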