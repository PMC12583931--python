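"""R-peak detection (Pan-Tompkins) and SCG beat extraction/normalization.

Beats are R-locked windows: beat *i* spans ``[R_i - 0.1 s, R_{i+1} - 0.1 s)``
(half-open, 0-based samples) so consecutive beats tile the record exactly.
Each beat is normalized by its peak-to-peak amplitude, making every
downstream waveform feature invariant to sensor gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateBeatError, SessionUnusableError
from .preprocess import PreprocessedSession

log = logging.getLogger(__name__)

PRE_R_OFFSET_S = 0.1
REFRACTORY_S = 0.2
HR_MIN_BPM = 20.0
HR_MAX_BPM = 220.0


@dataclass
class Beat:
    index: int
    start_sample: int
    end_sample: int
    samples: np.ndarray  # peak-to-peak normalized SCG waveform
    rr_ms: float
    lv_value: float
    fr_value: float


@dataclass
class BeatSet:
    subject_id: str
    session_id: str
    label: str
    fs_hz: float
    r_peaks: np.ndarray
    beats: list[Beat] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.beats)

    def waveforms(self) -> list[np.ndarray]:
        return [b.samples for b in self.beats]

    def covariate(self, basis: str) -> np.ndarray:
        if basis == "lung_volume":
            return np.array([b.lv_value for b in self.beats])
        if basis == "flow_rate":
            return np.array([b.fr_value for b in self.beats])
        raise ValueError(f"unknown basis {basis!r}")


def detect_r_peaks(ecg_f: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection.

    Stages: 5-15 Hz band-pass -> 5-point derivative -> squaring -> 150 ms
    moving-window integration -> adaptive signal/noise thresholding with a
    200 ms refractory period, followed by refinement of each detection to the
    local band-passed-ECG maximum.  Peaks implying an instantaneous heart
    rate outside [20, 220] bpm are dropped with a warning.
    """
    ecg_f = np.asarray(ecg_f, dtype=float)
    if fs < 200:
        raise SessionUnusableError("Pan-Tompkins requires fs >= 200 Hz")
    if len(ecg_f) < 2 * fs:
        raise SessionUnusableError("need at least 2 s of ECG")
    if np.ptp(ecg_f) == 0:
        raise SessionUnusableError("flat ECG signal")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg_f)
    # 5-point derivative (Pan-Tompkins kernel), then squaring
    h = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, h, mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        raise SessionUnusableError("no QRS candidates found")

    # adaptive thresholding over candidate peaks
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    peaks = []
    for c in cand:
        v = mwi[c]
        thr = npki + 0.25 * (spki - npki)
        if v > thr:
            peaks.append(c)
            spki = 0.125 * v + 0.875 * spki
        else:
            npki = 0.125 * v + 0.875 * npki
    if len(peaks) < 2:
        raise SessionUnusableError("fewer than 2 R-peaks detected")

    # refine to the local maximum of the band-passed ECG
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)

    # drop peaks implying an out-of-range instantaneous HR
    out = [int(refined[0])]
    for p in refined[1:]:
        rr_s = (p - out[-1]) / fs
        hr = 60.0 / rr_s
        if hr > HR_MAX_BPM:
            log.warning("dropping R-peak at %d: implied HR %.0f bpm > %.0f", p, hr, HR_MAX_BPM)
            continue
        if hr < HR_MIN_BPM:
            log.warning("R-peak gap at %d implies HR %.0f bpm < %.0f", p, hr, HR_MIN_BPM)
        out.append(int(p))
    if len(out) < 2:
        raise SessionUnusableError("fewer than 2 plausible R-peaks")
    return np.asarray(out, dtype=int)


def normalize_beat(samples: np.ndarray) -> np.ndarray:
    """Scale a beat by its peak-to-peak amplitude (output ptp == 1)."""
    samples = np.asarray(samples, dtype=float)
    ptp = np.ptp(samples)
    if ptp == 0:
        raise DegenerateBeatError("flat beat cannot be normalized")
    return samples / ptp


def segment_beats(
    scg_f: np.ndarray,
    r_peaks: np.ndarray,
    fs: float,
    lung_volume: np.ndarray,
    flow_rate: np.ndarray,
    cut_points: np.ndarray | None = None,
    subject_id: str = "",
    session_id: str = "",
    label: str = "",
    truth: dict | None = None,
) -> BeatSet:
    """Extract normalized R-locked SCG beats with respiration covariates.

    Beats whose window leaves the record, straddles an exclusion splice, or
    is flat are dropped (logged).  Respiration covariates are sampled at the
    beat's start sample.
    """
    scg_f = np.asarray(scg_f, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise SessionUnusableError("need at least 2 R-peaks to segment")
    cuts = np.asarray(cut_points, dtype=int) if cut_points is not None else np.array([], dtype=int)
    off = int(round(PRE_R_OFFSET_S * fs))
    beats: list[Beat] = []
    for i in range(len(r_peaks) - 1):
        start = r_peaks[i] - off
        end = r_peaks[i + 1] - off
        if start < 0 or end > len(scg_f):
            log.info("beat %d window [%d, %d) exits the record; dropped", i, start, end)
            continue
        if len(cuts) and np.any((cuts > start) & (cuts < end)):
            log.info("beat %d straddles an exclusion splice; dropped", i)
            continue
        try:
            samples = normalize_beat(scg_f[start:end])
        except DegenerateBeatError:
            log.info("beat %d is flat; dropped", i)
            continue
        rr_ms = (r_peaks[i + 1] - r_peaks[i]) / fs * 1000.0
        beats.append(
            Beat(
                index=i,
                start_sample=int(start),
                end_sample=int(end),
                samples=samples,
                rr_ms=rr_ms,
                lv_value=float(lung_volume[start]),
                fr_value=float(flow_rate[start]),
            )
        )
    return BeatSet(
        subject_id=subject_id,
        session_id=session_id,
        label=label,
        fs_hz=fs,
        r_peaks=r_peaks,
        beats=beats,
        truth=truth or {},
    )


def segment_session(pre: PreprocessedSession) -> BeatSet:
    """Detect R-peaks on the filtered ECG and segment SCG beats."""
    r_peaks = detect_r_peaks(pre.ecg_f, pre.fs_hz)
    return segment_beats(
        pre.scg_f,
        r_peaks,
        pre.fs_hz,
        pre.lung_volume,
        pre.flow_rate,
        cut_points=pre.cut_points,
        subject_id=pre.subject_id,
        session_id=pre.session_id,
        label=pre.label,
        truth=pre.truth,
    )
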