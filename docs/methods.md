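# Methods

This note documents the models, numerical choices, and limitations of
`scgpipe`; the README gives the pipeline overview.

## Synthetic cohort generator

The generator (`scgpipe.synth`) produces ECG/SCG/GSR sessions with exactly
the statistical structure the downstream analysis exploits, and nothing
more.

**RR series.** RR_i = 60000/HR + A_LF·sin(2π·0.1·t_i) + A_HF·sin(2π·0.25·t_i)
+ ε_i (ms), ε_i white Gaussian with SD `rr_jitter_ms`, clipped at a 200 ms
physiological floor.  Defaults: HR 70 bpm, A_LF = A_HF = 30 ms, jitter
25 ms.  The two fixed modulation frequencies sit in the canonical LF and HF
HRV bands, so LFP/HFP/TP are directly controllable; white jitter controls
pNN50 through the closed-form normal-difference tail probability
P(|Δ| > 50 ms), Δ ~ N(0, √2·σ).  The first R-peak is placed 0.2 s into the
record so its pre-R segmentation window exists.

**ECG.** A Ricker (second-derivative-of-Gaussian, 12 ms width) wavelet at
each R time, peaked exactly at the R sample, plus low-level baseline noise.

**SCG.** Each beat is a blend of two damped-oscillation templates,
beat_k = (1−w_k)·A + w_k·B with w_k = depth·(1+sin φ_k)/2 and φ_k the
respiration phase at the R time.  A has a dominant early (AO-like) 22 Hz
packet, B a dominant late, polarity-inverted (AC-like) 26 Hz packet; the
templates differ in amplitude structure, not merely timing, because a
dissimilarity that time-warping could absorb would make DTW clustering
unrecoverable by construction.  Per-beat jitter is band-limited (10–40 Hz)
Gaussian noise scaled by `beat_jitter_sigma` relative to the template
peak-to-peak, the main driver of the WV features.

**GSR.** sin(2π·0.25·t) plus a slow linear drift (removed later by
detrending) and measurement noise.

**Groups and subjects.** Group effects are multiplicative: relative to
non-readmitted (×1), healthy-like subjects get 0.4× beat jitter, 1.5× HRV
amplitudes and 1.6× RR jitter; readmitted-like get 2×, 0.5× and 0.6×.
These effect sizes are free choices — the source data are not public and
the group contrasts are reported only as boxplots — picked so that the
orderings (waveform variability: healthy < non-readmitted < readmitted;
HRV indices reversed) are clear at n = 20 sessions/group without being
trivially separable at the default scale.  `effect_scale` exponentiates
the multipliers: 0 yields an exchangeable null cohort, values > 1 an
(arbitrarily) separable one; both regimes are used as controls.  Subject-
level log-normal (SD 0.15) random effects on the three multipliers make
repeated sessions of a subject correlated, which is what makes
leave-one-subject-out validation meaningful.

What the generator does **not** emulate: hemodynamic waveform detail,
arrhythmia, motion artifacts, sensor drift, inter-subject template
morphology differences.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes (respiration-driven morphology
clusters, jitter-driven variability, band-limited RR modulation), not that
it would perform at any particular level on recorded patient data.

## Preprocessing

The Chebyshev type-II band-pass is 4th order with 40 dB stopband
attenuation, applied forward–backward (zero phase).  The 0.5 and 100 Hz
cutoffs are treated as the band the filter must pass: since a type-II
design is parameterized by its stopband edges, those are placed one octave
outside the passband (0.25 and 200 Hz, the upper edge clamped to the
midpoint of [high, Nyquist] when 2·high exceeds Nyquist).  Placing the
stated cutoffs at the stopband edges directly would sag mid-band gain to
≈ 0.7 at 50 Hz, which contradicts the purpose of a 0.5–100 Hz passband.

Downsampling uses polyphase resampling with an anti-alias FIR and linear
edge padding.  The GSR channel is only linearly detrended (lung volume) and
low-passed at 2 Hz before the central-difference derivative (flow rate);
2 Hz is far above any respiration rate and suppresses the derivative's
noise amplification.  Manual exclusion is a first-class boolean mask:
masked samples are excised, the splice points are recorded, and beats that
straddle a splice are dropped downstream; sessions under 30 s of usable
data are flagged.

## Segmentation

Pan–Tompkins with the classic stages (5–15 Hz band-pass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds, 200 ms refractory period), followed by refinement
of each detection to the local band-passed-ECG maximum and rejection of
peaks implying a heart rate outside 20–220 bpm.  Beat windows are
half-open, 0-based sample intervals [R_i − 0.1 s, R_{i+1} − 0.1 s), so
consecutive beats tile the record exactly.  Respiration covariates are
sampled at the beat's start sample — a deterministic, phase-consistent
choice.  Beats are normalized by peak-to-peak amplitude; flat beats are
dropped.

## Clustering

DTW is the classic dynamic program with unit steps and local cost
|a_i − b_j|; ties prefer the diagonal step, then the vertical, which fixes
the reported warping-path length deterministically.  Beats of unequal
length are compared directly (no resampling); the path-length
normalization (÷ l_i) appears only in the feature formulas, not in
clustering decisions.  The per-session pairwise cost and path-length
matrices are computed once (numba kernel) and shared by initialization,
k-medoids, and the WV features — this matrix is the dominant cost of the
pipeline, quadratic in both beats per session and samples per beat.

The cross-correlation distance is 1 − max over lags of the normalized
cross-correlation coefficient, each lag normalized by the norms of the two
overlapping segments (so a zero-padded shift of a waveform scores ≈ 0) and
restricted to lags with at least half the shorter waveform overlapping
(unrestricted per-lag normalization lets a few-sample overlap reach
coefficient 1 spuriously).  Note that for oscillatory templates a sign
flip is largely absorbed by a half-period lag; only the zero-lag
coefficient of a negated waveform is −1.

k-medoids alternates nearest-medoid assignment (medoids pinned to their own
cluster, which resolves zero-distance ties) and in-cluster argmin-of-row-sum
medoid updates, stopping when the assignment is unchanged between
consecutive iterations (cap 50, logged if hit).  An emptied cluster is
re-seeded with the beat farthest from the other medoid.  All remaining ties
resolve to the lowest beat index.  "Best of the four initializations" is
defined as minimum WV_intra, consistent with the motivation that
clustering should minimize within-cluster variability; all four WV_intra
values are kept for audit.  Representative beats average the
max(1, round(0.15·n)) beats nearest the medoid after linear resampling to
the cluster's median beat length.

## Features

Sample entropy uses m = 2, r = 0.2·SD — the standard defaults for the
template-matching entropy family — with both counts over the common n − m
templates and self-matches excluded; zero matches raise a typed error and
the session's value becomes NaN (excluded from averages).  Higuchi uses
k_max = 10, appropriate for beats of a few hundred to a thousand samples;
out-of-range dimensions are reported unclipped with a warning.  HRV
spectra: the RR tachogram (sampled at each interval's closing R time) is
cubic-spline interpolated to 4 Hz, Welch-estimated (64 s segments, 50 %
overlap, constant detrend), and band powers are trapezoidal integrals; the
"0–0.4 Hz" total power integrates from 0.003 Hz to avoid the DC bin.
pNN50 is a proportion in [0, 1].  The per-beat features (F_ins RMS, TPR,
SmEn, D_H) are computed on the two cluster representatives and averaged.

## Polynomial chirplet transform

Base distribution: Gaussian-window (σ = M/6, window 0.25 s, hop M/8) STFT
power of the analytic signal, nfft the next power of two ≥ max(4·M, fs)
(≈ 1 Hz bins).  Each refinement iteration estimates the ridge (per-frame
argmax), fits a polynomial (default degree 5) to it, demodulates the
analytic signal by the fitted IF law (frequency-rotation operator), and
recomputes the STFT with a per-frame complex remodulation by the fitted IF
at the frame centre (frequency-shift operator) — an exact, unquantized
shift.  Iteration stops when the ridge moves < 0.5 Hz RMS (cap 3).  With
`max_iter=0` the transform is exactly the plain spectrogram, kept as a
regression anchor.  F_ins(t) is the first moment of the distribution over
0.5–50 Hz (trapezoidal), frames with negligible band energy (denominator
< 1e-12 of the maximum) are skipped, and the exported scalar is the RMS
over the beat.  Images are 224×224 nearest-neighbor resizes of the
colormapped matrix (Parula-like anchors), time horizontal, frequency
increasing upward.

## Modeling

Hyperparameters (all overridable): KNN k = 5 distance-weighted; MLP one
hidden layer of 16, L2 1e-3, Adam, 2000 iterations; XGBoost 200 trees,
depth 3, learning rate 0.1, exact split finding — histogram binning places
split thresholds at bin edges, which on cohorts of tens of sessions can
put the cut directly on the minimum of one class instead of mid-gap.
Features are z-scored inside the estimator with training-fold statistics
only.  The decision threshold defaults to 0.7 on the *non-readmitted*
class probability (positive if p(readmit) ≥ 0.3): with 41 positive and 101
negative sessions, a threshold tuned to maximize sensitivity must lower
the effective positive-class cutoff, and this reading realizes that;
applying 0.7 to the positive class directly is available via
`threshold_on="positive"`.  For the balanced separable-recovery control the
tests use the neutral 0.5 cutoff, since the shifted threshold exists only
to trade specificity for sensitivity under imbalance.

Feature selection (random forest, 500 trees, Gini importances, top-11) is
performed once on the full table by default, replicating the original
procedure; a nested variant is a matter of passing the selector inside the
fold loop, which the API permits but does not default to.

LOOCV leaves out all sessions of one subject per fold; a leakage assertion
(train ∩ test subject sets empty) runs on every fold.  Metrics are pooled
at the session level and are exactly recomputable from the per-session
prediction table.  Note that pooled LOOCV AUC under a true null is known
to sit slightly below 0.5 (each fold's model is repelled from the held-out
subject's class by one subject's worth of data) with substantial sampling
spread at a few hundred sessions; the zero-effect control asserts AUC
within ±0.05 of chance at 160 sessions.

## Problem sizes

Tests and the acceptance script run the generator at 30–40 s sessions and
500 Hz (250 Hz for the large null cohort) rather than the 120 s / 1 kHz
defaults, keeping the quadratic DTW matrices small while leaving 20–45
beats per session; the 10 kHz → 1 kHz decimation path is exercised by an
explicit high-rate fixture.  Cohort controls use 8 subjects per patient
group (2 sessions each) for the separable regime, 20 sessions per group
for effect-ordering checks, and 120–240 single-session subjects for the
null regime.

## Known limitations

- The 52 additional SCG features and 4 additional HRV features of the full
  71-feature set are not implemented (not specified individually); the
  feature table schema is extensible.
- CNN training on the exported time–frequency images is out of scope; the
  images are produced so a downstream user could train one.
- Automated signal-quality control is not implemented; exclusion is an
  input mask (the original protocol used a human observer).
- The cross-correlation distance's minimum-overlap fraction (0.5) is a
  robustness choice with no counterpart in the source description.
- Group effect sizes of the generator are not calibrated to any published
  effect magnitudes (none are printed); only orderings and qualitative
  contrasts are meaningful.
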