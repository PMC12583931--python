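"""Per-session feature extraction: 7 SCG features + 4 HRV features.

SCG features
    wv_bc     mean path-normalized DTW distance of every beat to the
              pre-clustering medoid (beat-to-beat variability of a session)
    wv_inter  mean cross-cluster medoid-to-beat normalized DTW distance
    wv_intra  mean within-cluster medoid-to-beat normalized DTW distance
    f_ins_rms RMS of the instantaneous frequency (first moment of the
              polynomial chirplet TFD over 0.5-50 Hz), averaged over the two
              cluster representative beats
    tpr       turning point ratio (fraction of strict local extrema)
    smen      sample entropy (m=2, r=0.2*SD), -ln(A/B)
    d_h       Higuchi fractal dimension

HRV features (from the RR tachogram)
    lfp, hfp, tp  Welch band powers (ms^2) over 0.04-0.15, 0.15-0.40 and
                  0-0.40 Hz of the 4 Hz cubic-interpolated tachogram
    pnn50         proportion of successive RR differences > 50 ms

The per-beat waveform features (f_ins_rms, tpr, smen, d_h) are computed on
each of the two cluster representative waveforms and averaged.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import interpolate, signal as sps

from . import tfd
from .clustering import BeatDistanceCache, ClusterResult
from .errors import FeatureUnavailableError, InvalidConfigError
from .preprocess import PreprocessedSession
from .segmentation import BeatSet

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "subject_id", "session_id", "label",
    "wv_bc", "wv_inter", "wv_intra", "f_ins_rms", "tpr", "smen", "d_h",
    "lfp", "hfp", "tp", "pnn50",
]
FEATURE_NAMES = FEATURE_COLUMNS[3:]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TP_BAND = (0.003, 0.40)  # lower edge avoids DC leakage of the "0-0.4" band
TACHO_FS = 4.0
MIN_RR_INTERVALS = 30


# ---------------------------------------------------------------------------
# waveform-variability features (path-normalized DTW)
# ---------------------------------------------------------------------------

def global_medoid(cache: BeatDistanceCache) -> int:
    """Pre-clustering medoid: beat minimizing the summed DTW cost."""
    return int(np.argmin(cache.dtw_cost.sum(axis=1)))


def wv_before_clustering(cache: BeatDistanceCache, medoid: int | None = None) -> float:
    ND = cache.dtw_normalized
    c = global_medoid(cache) if medoid is None else medoid
    return float(np.mean(ND[c, :]))


def wv_inter(cache: BeatDistanceCache, result: ClusterResult) -> float:
    ND = cache.dtw_normalized
    other = np.where(result.labels == 1, result.medoid_2, result.medoid_1)
    return float(np.mean(ND[np.arange(len(result.labels)), other]))


def wv_intra(cache: BeatDistanceCache, result: ClusterResult) -> float:
    ND = cache.dtw_normalized
    own = np.where(result.labels == 1, result.medoid_1, result.medoid_2)
    return float(np.mean(ND[np.arange(len(result.labels)), own]))


# ---------------------------------------------------------------------------
# scalar waveform features
# ---------------------------------------------------------------------------

def turning_point_ratio(x: np.ndarray) -> float:
    """Fraction of samples that are strict local extrema."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InvalidConfigError("turning point ratio needs length >= 3")
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return float(np.count_nonzero(d1 * d2 > 0) / len(x))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B): template matching with Chebyshev tolerance r.

    A counts matched (m+1)-length template pairs, B matched m-length pairs,
    self-matches excluded.  Raises if no m-template pair matches (entropy
    undefined).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise InvalidConfigError("series too short for sample entropy")
    sd = x.std()
    if sd == 0:
        raise InvalidConfigError("sample entropy undefined for constant series")
    if r is None:
        r = 0.2 * sd

    def _count_pairs(templates: np.ndarray) -> int:
        total = 0
        for i in range(len(templates) - 1):
            d = np.abs(templates[i + 1 :] - templates[i]).max(axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    # both counts use the same n-m templates (standard Richman-Moorman form)
    b = _count_pairs(np.lib.stride_tricks.sliding_window_view(x, m)[: n - m])
    a = _count_pairs(np.lib.stride_tricks.sliding_window_view(x, m + 1))
    if b == 0:
        raise FeatureUnavailableError("no m-template matches: sample entropy undefined")
    if a == 0:
        raise FeatureUnavailableError("no (m+1)-template matches: sample entropy infinite")
    return float(-math.log(a / b))


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension from curve-length scaling over k=1..k_max."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * k_max:
        raise InvalidConfigError(f"need length >= {10 * k_max} for k_max={k_max}")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)  # reconstruction factor
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(ks), np.log(lk), 1)[0]
    d = -slope
    if not (1.0 <= d <= 2.0):
        log.warning("Higuchi dimension %.3f outside [1, 2]; reported unclipped", d)
    return float(d)


# ---------------------------------------------------------------------------
# HRV features
# ---------------------------------------------------------------------------

def hrv_features(r_peaks: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """(LFP, HFP, TP, pNN50) from R-peak sample indices.

    The RR tachogram (ms) is cubic-interpolated onto a uniform 4 Hz grid and
    a Welch periodogram (64 s segments, 50% overlap) integrated by the
    trapezoidal rule over each band.
    """
    r_peaks = np.asarray(r_peaks)
    rr_ms = np.diff(r_peaks) / fs * 1000.0
    if len(rr_ms) < MIN_RR_INTERVALS:
        raise FeatureUnavailableError(
            f"need >= {MIN_RR_INTERVALS} RR intervals, got {len(rr_ms)}"
        )
    pnn50 = float(np.count_nonzero(np.abs(np.diff(rr_ms)) > 50.0) / (len(rr_ms) - 1))

    # tachogram sample time = time of the interval's closing R-peak
    t_rr = (r_peaks[1:] - r_peaks[0]) / fs
    if np.ptp(rr_ms) == 0:
        return 0.0, 0.0, 0.0, pnn50
    cs = interpolate.CubicSpline(t_rr, rr_ms)
    t_uni = np.arange(t_rr[0], t_rr[-1], 1.0 / TACHO_FS)
    tach = cs(t_uni)
    nperseg = min(len(t_uni), int(64 * TACHO_FS))
    f, psd = sps.welch(tach, fs=TACHO_FS, nperseg=nperseg, noverlap=nperseg // 2,
                       detrend="constant")

    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], f[m]))

    lfp = band_power(*LF_BAND)
    hfp = band_power(*HF_BAND)
    tp = band_power(*TP_BAND)
    return lfp, hfp, tp, pnn50


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def session_features(
    pre: PreprocessedSession,
    beats: BeatSet,
    result: ClusterResult,
    cache: BeatDistanceCache,
    smen_m: int = 2,
    higuchi_k_max: int = 10,
) -> dict:
    """Assemble the 11-feature row for one session."""
    fs = pre.fs_hz
    row: dict = {
        "subject_id": beats.subject_id,
        "session_id": beats.session_id,
        "label": beats.label,
    }
    row["wv_bc"] = wv_before_clustering(cache)
    row["wv_inter"] = wv_inter(cache, result)
    row["wv_intra"] = wv_intra(cache, result)

    per_rep: dict[str, list[float]] = {"f_ins_rms": [], "tpr": [], "smen": [], "d_h": []}
    for rep in (result.representative_1, result.representative_2):
        tfd_mat = tfd.pct(rep, fs)
        per_rep["f_ins_rms"].append(tfd.instantaneous_frequency_rms(tfd_mat))
        per_rep["tpr"].append(turning_point_ratio(rep))
        try:
            per_rep["smen"].append(sample_entropy(rep, m=smen_m))
        except FeatureUnavailableError as exc:
            log.warning("session %s: %s", beats.session_id, exc)
            per_rep["smen"].append(np.nan)
        per_rep["d_h"].append(higuchi_fd(rep, k_max=higuchi_k_max))
    for k, vals in per_rep.items():
        row[k] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan

    lfp, hfp, tp, pnn50 = hrv_features(beats.r_peaks, fs)
    row.update({"lfp": lfp, "hfp": hfp, "tp": tp, "pnn50": pnn50})
    return row
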