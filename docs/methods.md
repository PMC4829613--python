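# Methods

## The problem setting

A laser-evoked-potential (LEP) paradigm delivers brief nociceptive laser
pulses over a ladder of energies while EEG is recorded at the vertex; after
each pulse the participant rates perceived pain on the 0–10 numerical rating
scale (NRS), with NRS 4 the pinprick-pain threshold. Each trial contributes
a pre-stimulus spontaneous segment (−0.5 to 0 s, sEEG) and a post-stimulus
segment (0 to +0.5 s, pEEG) dominated by the Aδ-fiber evoked response (N2
trough near 200 ms, P2 peak near 350 ms at Cz). The package reduces each
segment to its RMS magnitude and studies, on a synthetic cohort, how
normalizing the evoked magnitude by the individual's spontaneous
distribution changes inter-individual variability and cross-individual
prediction.

## Generative model of the synthetic cohort

Per individual *j* the simulator draws:

| parameter | default | meaning |
|---|---|---|
| scale *s_j* | log-normal, median 1, log-SD 0.4 | multiplicative factor on **all** of the individual's EEG (spontaneous SD and evoked amplitude); stands in for skull/impedance-type factors |
| max energy *E_j* | uniform on [3.75, 4.5] J | top of the energy ladder (1 J upward in 0.25 J steps → 12–15 levels, 10 pulses each) |
| sensitivity | 8 / *E_j* NRS per J | calibrated so the top energy elicits an expected rating of 8 |
| evoked base *b_j* | 15 µV × log-normal(CV 0.15) | evoked RMS at and below NRS 4 |
| evoked slope *m_j* | 10 µV × log-normal(CV 0.15) | evoked RMS per NRS unit above 4 |

Per trial at energy *E*: the rating is `round_half_up(sensitivity · E +
N(0, 1))` clipped to [0, 10]; both segments are Gaussian noise band-limited
to 1–30 Hz with ensemble SD `s_j · 10 µV` (white noise is passed through the
same zero-phase filter used in preprocessing, pre-scaled by the filter's
white-noise gain, so simulated and preprocessed spectra match); the post
segment adds a fixed biphasic template (unit RMS over the window, N2-like
lobe at 200 ms / σ 30 ms, P2-like at 350 ms / σ 50 ms) with amplitude

    A = max(0, s_j · (b_j + m_j · max(0, rating − 4)) + N(0, s_j · 2 µV)).

Because the template has unit RMS, `b_j` and `m_j` are in µV of post-segment
RMS, and with noise at zero the high-pain regression slope equals
`s_j · m_j` exactly — which is what the parameter-recovery tests check.

Magnitude choices reflect ordinary vertex EEG: ~10 µV RMS background in the
1–30 Hz band, evoked responses growing to several tens of µV at the highest
ratings. The scale log-SD of 0.4 (CV ≈ 0.42) produces the several-fold
spread of magnitudes across people that motivates normalization in the first
place. The baseline noise SD is common to all individuals, so that when
scale sharing is disabled (`scale_sigma = 0`) the expected cross-individual
correlation between spontaneous and evoked means is zero — the negative
control for the correlation analysis.

Defaults mirror the emulated design: 34 individuals, 1000 Hz sampling,
±0.5 s epochs. Analyses and tests simulate at 250 Hz (and some at 150–200
Hz): every downstream statistic operates on RMS magnitudes, which are
insensitive to the sampling rate of band-limited signals, and the package's
own determinism and recovery tests confirm this at those rates.

### What the generator does *not* emulate

No habituation or inter-stimulus-interval effects, no attention or vigilance
drift, no ocular or muscle artifacts, no sex differences, no multi-channel
structure, and ratings depend on energy only through a fixed linear
sensitivity. Consequently, green tests establish that the *pipeline* behaves
as designed under the assumed statistical structure (shared multiplicative
scale, flat-then-linear evoked growth); they do not establish that real
pain-EEG obeys that structure.

## Preprocessing and features

Continuous (or simulated epoched) signals are band-pass filtered 1–30 Hz
with a zero-phase forward–backward Butterworth filter (order 4 per pass),
applied before epoching so transients stay away from epoch edges. Epochs use
half-open windows [−0.5, 0) / [0, +0.5) s — the stimulus sample starts the
post segment — and the pre-segment mean is subtracted from both segments.
RMS is computed per segment; the filter contract is specified by response
bounds (unit passband gain within 5% mid-band, ≥ 20 dB one octave outside)
rather than by realization.

## Normalization

`nRMS_P = (RMS_P − μ(RMS_S)) / σ(RMS_S)` with μ, σ over all of the
individual's trials; σ uses the sample convention (divisor n−1) — baselines
are estimated from 120–150 trials, where the divisor choice is numerically
immaterial. The transform is exactly invariant to any common positive
rescaling of an individual's samples, which is the mechanism being tested
throughout. Baselines use only spontaneous data, never ratings, so held-out
individuals in cross-validation are normalized without label leakage.
`divide_mean` and `subtract_mean` are provided as comparison modes; neither
removes scale from the z-score's denominator side, and neither is used by
default.

The Kolmogorov–Smirnov check standardizes the sample first and tests against
N(0, 1); with parameters estimated from the same sample this inflates
p-values (the Lilliefors effect). It is recorded purely as a diagnostic —
no behavior is conditioned on it.

## Analyses

* **Binning**: unit bins (0,1] … (7,8] plus a combined (8,10] (top ratings
  are sparse), and aggregates (0,4], (4,10]. Rating-0 trials enter no
  descriptive bin but remain low-pain trials for classification.
* **Correlation**: per bin, Pearson r across individuals between
  per-individual means (and SDs) of RMS_S and RMS_P; bins with < 3
  individuals are skipped.
* **Model comparison**: per individual, RMS_P is averaged per rating level
  and fitted by one global OLS line and by two independent OLS segments
  split at NRS 4 (no continuity constraint — nothing in the flat-then-linear
  hypothesis requires the segments to meet). MSE uses divisor n, so the
  nested-model inequality (piecewise ≤ global) holds identically. Raw-trial
  fitting is available via `use_level_means=False`.
* **ANOVA**: one-way F with individual as factor, per unit bin, on trials of
  individuals contributing ≥ 2 trials there.
* **Thresholds**: exhaustive search over midpoints of consecutive distinct
  feature values plus one cut below the minimum and one above the maximum;
  rule `feature > threshold ⇒ high`; accuracy ties break toward the smallest
  threshold so the output is deterministic.
* **Variance comparison**: two-sample variance-ratio F (larger/smaller, df
  matched, two-sided p by doubling the tail, capped at 1). Raw and
  normalized parameters live on different scales (µV vs z-units); the
  comparison is reproduced as defined, and scale-free coefficient-of-
  variation diagnostics are reported alongside as a clearly labelled
  extension.

## Prediction

Stage 1 trains a one-feature Gaussian equal-variance LDA (closed form:
pooled within-class variance; with equal priors the boundary is the midpoint
of class means; priors default to empirical class frequencies, with an
equal-priors switch). Stage 2 trains `rating = α · feature + c` by OLS on
the training individuals' *true* high-pain trials — labels are available for
training data, making this the information-maximizing choice — and predicted
ratings are clipped to [0, 10]. Both the trials *predicted* high and the
trials *truly* high are scored by MAE, so the regression is evaluated
independently of stage-1 mistakes. Metrics are compared across features by
two-sided paired t-tests over individuals.

## Numerical and degenerate-input conventions

Ratings round half-up (ties at .5 go up) before clipping. Segments with
fewer than two distinct ratings fall back to their mean in the piecewise
fit. All-zero paired differences report t = 0, p = 1 with a degeneracy flag
rather than NaN. Zero variance in a variance comparison sets a flag and
omits the p-value. Individuals failing a statistic's preconditions (single
class, too few high-pain trials) are excluded from that statistic with a
logged notice, and the pipeline completes with whatever remains; hard errors
are reserved for structural problems (duplicate trials, mismatched
baselines, out-of-range energies). Seeded runs are bit-reproducible; the
pipeline writes a manifest (config, seed, versions) sufficient to replay a
run.

## Known limitations

Single-channel, single-feature by design — no time-frequency features,
multivariate classifiers, or automatic break-point estimation (NRS 4 is
fixed a priori as the pinprick threshold). The synthetic cohort's
favourable structure means effect sizes here (accuracies, MAEs, variance
ratios) should be read as demonstrations of the pipeline's behaviour under
its assumptions, not as forecasts of performance on recorded data.
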