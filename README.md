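# scgpipe

Seismocardiogram (SCG) analysis for heart-failure readmission prediction:
beat segmentation, respiration-informed k-medoids clustering, waveform and
heart-rate-variability (HRV) feature extraction, and threshold-tuned
classification under leave-one-subject-out cross-validation (LOOCV).

## The problem

The SCG is the low-frequency chest-surface vibration produced by the
mechanical activity of the heart, recorded with an accelerometer at the
sternum.  In heart-failure patients, beat-to-beat SCG waveform variability
rises with disease severity while vagally mediated HRV indices fall, so a
short multi-channel recording (ECG + dorso-ventral SCG + a galvanic-skin-
response channel used as a lung-volume proxy) carries signal about the risk
of hospital readmission.  This package implements that analysis chain as a
tested library for researchers working with synchronized ECG/SCG/respiration
recordings.  Because no public recording archive exists for this protocol,
the package ships a first-class synthetic cohort generator whose ground
truth (R times, respiration phase, per-beat morphology blend) makes every
stage testable.

## Method

Per session, the pipeline computes:

1. **Preprocessing** — downsampling to 1 kHz, zero-phase 4th-order
   Chebyshev-II band-pass (0.5–100 Hz) of ECG and SCG, linear detrending of
   the GSR channel into a lung-volume signal and differentiation into a
   flow-rate signal.
2. **Segmentation** — Pan–Tompkins R-peak detection; SCG beat *i* spans
   [R_i − 0.1 s, R_{i+1} − 0.1 s) and is normalized by its peak-to-peak
   amplitude.
3. **Clustering** — two-cluster k-medoids on dynamic-time-warping (DTW)
   distance.  Initial medoids come from a median split of lung volume or
   flow rate with DTW or cross-correlation as the within-half metric; all
   four combinations are run and the one minimizing intra-cluster
   variability is kept.  Each cluster's *representative beat* is the
   average of the 15 % of beats nearest its medoid.
4. **Features** (one row of 11 per session):
   - WV_bc = (1/n) Σᵢ dtw(C, Xᵢ)/lᵢ — beat variability before clustering
     (C the pre-clustering medoid, lᵢ the DTW warping-path length);
   - WV_inter, WV_intra — the analogous cross- and within-cluster
     medoid-to-beat averages;
   - F_ins RMS — RMS of the first moment of the polynomial chirplet
     transform over 0.5–50 Hz on the representative beats;
   - turning point ratio, sample entropy (m = 2, r = 0.2·SD), Higuchi
     fractal dimension on the representative beats;
   - LFP (0.04–0.15 Hz), HFP (0.15–0.40 Hz), TP (0–0.40 Hz) Welch band
     powers of the RR tachogram, and pNN50.
5. **Modeling** — random-forest (Gini) feature selection; KNN, MLP, or
   XGBoost classifiers behind a common thresholded interface (the default
   applies a 0.7 cutoff to the non-readmitted class probability to favor
   sensitivity under class imbalance); subject-wise LOOCV with session-level
   pooling; sensitivity/specificity/precision/F1/accuracy and trapezoidal
   ROC AUC; pairwise two-sample t-tests for healthy / non-readmitted /
   readmitted group comparisons.

## Worked example

```python
import numpy as np
from scgpipe.synth import SyntheticConfig, generate_cohort
from scgpipe.pipeline import extract_cohort_features
from scgpipe.modeling import ReadmissionClassifier, loocv

cfg = SyntheticConfig(
    duration_s=30.0, fs_hz=500.0, effect_scale=0.5,
    n_subjects_per_group={"healthy": 0, "non_readmitted": 8, "readmitted": 8},
    sessions_per_subject=2, seed=4,
)
sessions, manifest = generate_cohort(cfg)
features = extract_cohort_features(sessions)
result = loocv(features, ReadmissionClassifier(kind="knn", seed=0))
print({k: round(v, 3) for k, v in result.metrics.items()})
```

Output:

```
{'sensitivity': 0.875, 'specificity': 0.688, 'precision': 0.737,
 'f1': 0.8, 'accuracy': 0.781, 'tp': 14, 'tn': 11, 'fp': 5, 'fn': 2,
 'auc': 0.867}
```

Sixteen synthetic subjects (two 30 s sessions each) yield 32 feature rows.
`effect_scale=0.5` halves the group separation (on the log scale) to make
the task non-trivial: the distance-weighted KNN then ranks sessions at AUC
0.87 and, with the sensitivity-favoring default threshold, catches 14 of 16
readmitted-like sessions at the cost of 5 false alarms.
`result.predictions` holds the per-session probabilities and fold
assignments; the aggregate metrics are exactly recomputable from it.

A YAML-driven end-to-end run (simulate → features → train/eval with files
written per stage) is available as `scg-readmit run --out rundir`, with
`simulate`, `preprocess`, `segment`, `cluster`, `features`, `tfd`,
`train-eval` and `report` subcommands for the individual stages.

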