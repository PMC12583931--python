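"""Filtering, resampling, and respiration-signal derivation.

The canonical chain for a recording session is:

1. drop manually excluded samples (``apply_exclusion``),
2. downsample all channels to 1 kHz (``downsample``),
3. zero-phase Chebyshev-II band-pass (0.5-100 Hz) of ECG and SCG
   (``bandpass_filter``),
4. detrend the GSR lung-volume proxy and differentiate it into a flow-rate
   signal (``derive_respiration``).

The GSR channel is deliberately not band-passed: its information lives below
0.5 Hz and only detrending + smoothing are applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, SessionRejectedError
from .synth import SessionRecording

log = logging.getLogger(__name__)

MIN_USABLE_S = 30.0


@dataclass
class PreprocessedSession:
    """Filtered channels plus derived respiration signals for one session."""

    subject_id: str
    session_id: str
    label: str
    fs_hz: float
    ecg_f: np.ndarray
    scg_f: np.ndarray
    lung_volume: np.ndarray
    flow_rate: np.ndarray
    cut_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased resampling from ``fs_in`` to ``fs_out`` (fs_out <= fs_in)."""
    if fs_out > fs_in:
        raise InvalidConfigError("fs_out must not exceed fs_in")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(
        np.asarray(x, dtype=float), frac.numerator, frac.denominator, padtype="line"
    )


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 100.0,
    order: int = 4,
    rs_db: float = 40.0,
) -> np.ndarray:
    """Zero-phase Chebyshev type-II band-pass (forward-backward).

    ``low`` and ``high`` are the band the filter must pass.  A Chebyshev-II
    design is specified by its stopband edges, so these are placed an octave
    outside the passband (clamped below Nyquist); with the stated cutoffs as
    stopband edges directly, the 40 dB transition would sag the passband to
    ~0.7 gain at 50 Hz.
    """
    if not (0 < low < high):
        raise InvalidConfigError("need 0 < low < high")
    if high >= fs / 2:
        raise InvalidConfigError("high cutoff must be below Nyquist")
    stop_lo = low / 2.0
    stop_hi = 2.0 * high
    if stop_hi >= fs / 2:
        stop_hi = (high + fs / 2) / 2.0
    sos = sps.cheby2(
        order, rs_db, [stop_lo, stop_hi], btype="bandpass", fs=fs, output="sos"
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def derive_respiration(
    gsr: np.ndarray, fs: float, smooth_hz: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Lung volume (linearly detrended GSR) and flow rate (its derivative).

    The derivative amplifies high-frequency noise, so the detrended signal is
    low-passed (default 2 Hz, well above any respiration rate) before the
    central-difference derivative.
    """
    gsr = np.asarray(gsr, dtype=float)
    if len(gsr) < 2 * fs:
        raise InvalidConfigError("need at least 2 s of GSR signal")
    if np.ptp(gsr) == 0:
        log.warning("constant GSR input: lung volume and flow rate are zero")
        return np.zeros_like(gsr), np.zeros_like(gsr)
    lung_volume = sps.detrend(gsr, type="linear")
    sos = sps.butter(4, smooth_hz, btype="lowpass", fs=fs, output="sos")
    smoothed = sps.sosfiltfilt(sos, lung_volume)
    flow_rate = np.gradient(smoothed) * fs
    return lung_volume, flow_rate


def apply_exclusion(session: SessionRecording) -> tuple[SessionRecording, float]:
    """Drop masked samples; return the compacted session and usable seconds.

    Sample removal splices the time axis; the indices (in the new arrays)
    where a splice happened are recorded in ``cut_points`` so that beat
    segmentation can refuse beats that straddle a discontinuity.
    """
    mask = np.asarray(session.exclusion_mask, dtype=bool)
    keep = ~mask
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise SessionRejectedError(
            f"session {session.session_id}: exclusion mask removes all samples"
        )
    usable_s = n_keep / session.fs_hz
    if usable_s < MIN_USABLE_S:
        warnings.warn(
            f"session {session.session_id}: only {usable_s:.1f} s usable "
            f"(< {MIN_USABLE_S:.0f} s)",
            stacklevel=2,
        )
    if not mask.any():
        return session, usable_s
    # new index of each kept sample; a cut lands where the gap between
    # consecutive kept original indices exceeds 1
    kept_idx = np.flatnonzero(keep)
    gap_after = np.flatnonzero(np.diff(kept_idx) > 1)
    cuts = gap_after + 1  # position in the compacted array
    old_to_new = np.cumsum(keep) - 1

    truth = dict(session.truth)
    if "r_samples" in truth:
        r_old = np.asarray(truth["r_samples"])
        ok = keep[r_old]
        truth = dict(truth)
        truth["r_samples"] = old_to_new[r_old[ok]]
        truth["r_times_s"] = truth["r_samples"] / session.fs_hz
        for k in ("rr_ms", "resp_phase", "blend_w"):
            if k in truth and len(np.asarray(truth[k])) == len(ok):
                truth[k] = np.asarray(truth[k])[ok]
    out = SessionRecording(
        subject_id=session.subject_id,
        session_id=session.session_id,
        label=session.label,
        fs_hz=session.fs_hz,
        ecg=session.ecg[keep],
        scg_z=session.scg_z[keep],
        gsr=session.gsr[keep],
        exclusion_mask=np.zeros(n_keep, dtype=bool),
        cut_points=cuts.astype(int),
        truth=truth,
    )
    return out, usable_s


def preprocess_session(
    session: SessionRecording,
    target_fs: float | None = None,
    low: float = 0.5,
    high: float = 100.0,
    order: int = 4,
) -> PreprocessedSession:
    """Run the full preprocessing chain on one session.

    ``target_fs=None`` keeps the native sampling rate; pass 1000.0 to
    exercise the canonical 10 kHz -> 1 kHz decimation path.
    """
    sess, usable_s = apply_exclusion(session)
    fs = sess.fs_hz
    if target_fs is None:
        target_fs = fs
    ecg, scg, gsr = sess.ecg, sess.scg_z, sess.gsr
    cuts = sess.cut_points.astype(float)
    truth = dict(sess.truth)
    if fs != target_fs:
        ecg = downsample(ecg, fs, target_fs)
        scg = downsample(scg, fs, target_fs)
        gsr = downsample(gsr, fs, target_fs)
        ratio = target_fs / fs
        cuts = cuts * ratio
        if "r_samples" in truth:
            truth["r_samples"] = np.round(np.asarray(truth["r_samples"]) * ratio).astype(int)
        fs = target_fs
    ecg_f = bandpass_filter(ecg, fs, low=low, high=high, order=order)
    scg_f = bandpass_filter(scg, fs, low=low, high=high, order=order)
    lung_volume, flow_rate = derive_respiration(gsr, fs)
    return PreprocessedSession(
        subject_id=sess.subject_id,
        session_id=sess.session_id,
        label=sess.label,
        fs_hz=fs,
        ecg_f=ecg_f,
        scg_f=scg_f,
        lung_volume=lung_volume,
        flow_rate=flow_rate,
        cut_points=np.round(cuts).astype(int),
        truth=truth,
        provenance={
            "filter": {"type": "cheby2", "order": order, "low_hz": low, "high_hz": high, "rs_db": 40.0},
            "target_fs": fs,
            "usable_s": usable_s,
        },
    )
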