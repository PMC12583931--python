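"""Synthetic ECG / SCG / GSR cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* RR series with controllable LF (0.1 Hz) and HF (0.25 Hz) modulation and
  white beat-to-beat jitter, so spectral HRV indices and pNN50 are tunable.
* R-peak-locked SCG beats whose morphology blends between two damped-wavelet
  templates across the respiration phase (creating two beat clusters).
* Per-beat waveform jitter whose amplitude differs between subject groups:
  readmitted-like subjects get noisier beats and flatter RR series than
  non-readmitted-like subjects; healthy-like subjects sit at the other end.
* A GSR channel that acts as a lung-volume proxy (sinusoid at the
  respiration rate plus a slow drift removed later by detrending).

The generator makes no attempt at hemodynamic realism; it provides signals
whose ground truth (R times, respiration phase per beat, template blend
weight per beat) is known exactly, so every downstream stage can be tested
without recorded patient data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidConfigError

GROUP_LABELS = ("healthy", "non_readmitted", "readmitted")

# RR modulation frequencies (Hz): classic LF / HF (respiratory) bands.
LF_FREQ_HZ = 0.1
HF_FREQ_HZ = 0.25

# Group effect multipliers applied on top of the base config.  Beat-level
# waveform jitter grows with disease severity while HRV amplitudes shrink:
# healthy < non_readmitted < readmitted in waveform variability and the
# reverse ordering in LFP/HFP/TP/pNN50.
GROUP_EFFECTS = {
    "healthy": {"beat_jitter": 0.4, "hrv_amp": 1.5, "rr_jitter": 1.6},
    "non_readmitted": {"beat_jitter": 1.0, "hrv_amp": 1.0, "rr_jitter": 1.0},
    "readmitted": {"beat_jitter": 2.0, "hrv_amp": 0.5, "rr_jitter": 0.6},
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Amplitudes are in the units of the quantity they modulate (ms for RR
    terms, fraction of beat peak-to-peak for ``beat_jitter_sigma``).
    """

    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 5, "non_readmitted": 5, "readmitted": 5}
    )
    sessions_per_subject: int = 2
    duration_s: float = 120.0
    fs_hz: float = 1000.0
    mean_hr_bpm: float = 70.0
    rr_lf_amp_ms: float = 30.0
    rr_hf_amp_ms: float = 30.0
    rr_jitter_ms: float = 25.0
    resp_rate_hz: float = 0.25
    morph_mod_depth: float = 0.8
    beat_jitter_sigma: float = 0.05
    noise_sigma: float = 0.02
    # exponent on the group-effect multipliers: 0 removes all group
    # differences (null cohort), 1 is the default effect size, >1
    # exaggerates the separation between groups
    effect_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.mean_hr_bpm <= 0:
            raise InvalidConfigError("mean_hr_bpm must be > 0")
        if self.fs_hz <= 0 or self.resp_rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("rates and duration must be > 0")
        if not (0.0 <= self.morph_mod_depth <= 1.0):
            raise InvalidConfigError("morph_mod_depth must lie in [0, 1]")
        if self.sessions_per_subject < 1:
            raise InvalidConfigError("sessions_per_subject must be >= 1")
        for g in self.n_subjects_per_group:
            if g not in GROUP_LABELS:
                raise InvalidConfigError(f"unknown group label {g!r}")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SessionRecording:
    """Raw multi-channel signals plus metadata for one recording session."""

    subject_id: str
    session_id: str
    label: str
    fs_hz: float
    ecg: np.ndarray
    scg_z: np.ndarray
    gsr: np.ndarray
    exclusion_mask: np.ndarray
    # sample indices (in the current arrays) at which earlier excision made
    # the time axis discontinuous; empty for an untouched recording
    cut_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    # generator ground truth (synthetic sessions only)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.ecg)
        if not (len(self.scg_z) == len(self.gsr) == len(self.exclusion_mask) == n):
            raise InvalidConfigError("all channels must have equal length")
        if self.fs_hz <= 0:
            raise InvalidConfigError("fs_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)


def generate_rr_series(
    config: SyntheticConfig, n_beats: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate an RR series (ms) and the R times (s) it implies.

    RR_i = 60000/HR + A_LF sin(2π·0.1·t_i) + A_HF sin(2π·0.25·t_i) + ε_i,
    with ε_i white Gaussian of SD ``rr_jitter_ms`` and a 200 ms physiological
    floor.  Beat times accumulate: t_{i+1} = t_i + RR_i/1000.
    """
    config.validate()
    if n_beats < 2:
        raise InvalidConfigError("n_beats must be >= 2")
    base = 60000.0 / config.mean_hr_bpm
    rr = np.empty(n_beats)
    t = np.empty(n_beats)
    ti = 0.0
    eps = rng.normal(0.0, config.rr_jitter_ms, n_beats) if config.rr_jitter_ms > 0 else np.zeros(n_beats)
    for i in range(n_beats):
        t[i] = ti
        rr_i = (
            base
            + config.rr_lf_amp_ms * np.sin(2 * np.pi * LF_FREQ_HZ * ti)
            + config.rr_hf_amp_ms * np.sin(2 * np.pi * HF_FREQ_HZ * ti)
            + eps[i]
        )
        rr[i] = max(rr_i, 200.0)  # physiological floor, avoids beat overlap
        ti += rr[i] / 1000.0
    return rr, t


def _ricker_qrs(fs: float, width_s: float = 0.012) -> np.ndarray:
    """QRS template: Ricker wavelet peaked exactly at its centre sample."""
    half = int(round(4 * width_s * fs))
    tt = (np.arange(2 * half + 1) - half) / fs
    a = width_s
    return (1 - (tt / a) ** 2) * np.exp(-(tt**2) / (2 * a**2))


def _scg_templates(fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Two SCG beat templates: damped oscillatory packets (~AO and ~AC).

    Template B shifts the packet frequencies and timings so that blending
    between A and B across the respiration phase produces two morphology
    clusters with 10-40 Hz content.
    """

    def packet(t, t0, f, tau, amp):
        env = np.exp(-np.maximum(t - t0, 0.0) / tau) * (t >= t0)
        return amp * env * np.sin(2 * np.pi * f * (t - t0))

    dur = 0.45
    t = np.arange(int(round(dur * fs))) / fs
    # A: dominant early (AO-like) packet; B: dominant late (AC-like) packet
    # with inverted polarity.  The amplitude structure (not just timing)
    # differs, so the dissimilarity survives DTW warping.
    a = packet(t, 0.03, 22.0, 0.05, 1.0) + packet(t, 0.30, 32.0, 0.03, 0.35)
    b = packet(t, 0.03, 18.0, 0.05, 0.40) - packet(t, 0.28, 26.0, 0.05, 1.0)
    return a, b


_BEAT_NOISE_BAND = (10.0, 40.0)


_SOS_CACHE: dict[float, np.ndarray] = {}


def _band_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited (10-40 Hz) Gaussian noise."""
    w = rng.standard_normal(n)
    sos = _SOS_CACHE.get(fs)
    if sos is None:
        sos = sps.butter(2, _BEAT_NOISE_BAND, btype="bandpass", fs=fs, output="sos")
        _SOS_CACHE[fs] = sos
    x = sps.sosfiltfilt(sos, w)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_session(
    config: SyntheticConfig,
    group_label: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
    session_id: str = "S000-01",
    subject_effects: dict | None = None,
) -> SessionRecording:
    """Generate one SessionRecording for a subject of the given group.

    ``subject_effects`` holds per-subject multiplicative random effects (drawn
    once per subject by :func:`generate_cohort`) so that repeated sessions of
    one subject are correlated.
    """
    config.validate()
    if group_label not in GROUP_LABELS:
        raise InvalidConfigError(f"unknown group label {group_label!r}")
    eff = {k: v**config.effect_scale for k, v in GROUP_EFFECTS[group_label].items()}
    if subject_effects:
        for k in eff:
            eff[k] *= subject_effects.get(k, 1.0)

    cfg = config.replace(
        rr_lf_amp_ms=config.rr_lf_amp_ms * eff["hrv_amp"],
        rr_hf_amp_ms=config.rr_hf_amp_ms * eff["hrv_amp"],
        rr_jitter_ms=config.rr_jitter_ms * eff["rr_jitter"],
        beat_jitter_sigma=config.beat_jitter_sigma * eff["beat_jitter"],
    )

    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    # enough beats to overrun the record, then trim
    n_beats_max = max(2, int(np.ceil(cfg.duration_s * cfg.mean_hr_bpm / 60.0 * 1.6)) + 4)
    rr_ms, r_times = generate_rr_series(cfg, n_beats_max, rng)
    # first R sits 0.2 s into the record so its pre-R window exists
    r_times = r_times + 0.2
    keep = r_times < cfg.duration_s
    rr_ms, r_times = rr_ms[keep], r_times[keep]
    if len(r_times) < 2:
        raise InvalidConfigError("duration too short for 2 beats")

    t = np.arange(n) / fs

    # --- ECG: QRS template at each R time + baseline noise ----------------
    ecg = np.zeros(n)
    qrs = _ricker_qrs(fs)
    half = len(qrs) // 2
    r_samples = np.round(r_times * fs).astype(int)
    for rs in r_samples:
        lo, hi = rs - half, rs + half + 1
        slo, shi = max(lo, 0), min(hi, n)
        ecg[slo:shi] += qrs[slo - lo : len(qrs) - (hi - shi)]
    if cfg.noise_sigma > 0:
        ecg += rng.normal(0.0, 0.05 * cfg.noise_sigma / 0.02, n)

    # --- GSR: lung-volume proxy -------------------------------------------
    resp_phase_t = 2 * np.pi * cfg.resp_rate_hz * t
    gsr = np.sin(resp_phase_t) + 0.01 * t  # slow drift removed by detrending
    if cfg.noise_sigma > 0:
        gsr += rng.normal(0.0, 0.01, n)

    # --- SCG: respiration-blended templates + per-beat jitter --------------
    tmpl_a, tmpl_b = _scg_templates(fs)
    tl = len(tmpl_a)
    scg = np.zeros(n)
    phase_k = (2 * np.pi * cfg.resp_rate_hz * r_times) % (2 * np.pi)
    w_k = cfg.morph_mod_depth * (1.0 + np.sin(phase_k)) / 2.0
    ptp_ref = np.ptp(tmpl_a)
    for k, rs in enumerate(r_samples):
        beat = (1.0 - w_k[k]) * tmpl_a + w_k[k] * tmpl_b
        if cfg.beat_jitter_sigma > 0:
            beat = beat + cfg.beat_jitter_sigma * ptp_ref * _band_noise(tl, fs, rng)
        hi = min(rs + tl, n)
        if hi > rs >= 0:
            scg[rs:hi] += beat[: hi - rs]
    if cfg.noise_sigma > 0:
        scg += rng.normal(0.0, cfg.noise_sigma * ptp_ref, n)

    truth = {
        "r_times_s": r_times,
        "r_samples": r_samples,
        "rr_ms": rr_ms,
        "resp_phase": phase_k,
        "blend_w": w_k,
        "config": cfg.to_dict(),
        "group_effects": eff,
    }
    return SessionRecording(
        subject_id=subject_id,
        session_id=session_id,
        label=group_label,
        fs_hz=fs,
        ecg=ecg,
        scg_z=scg,
        gsr=gsr,
        exclusion_mask=np.zeros(n, dtype=bool),
        truth=truth,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Generate a full cohort and its manifest (subject_id, session_id, label).

    Subject-level random effects (log-normal multipliers on beat jitter and
    HRV amplitudes) are drawn once per subject, so the sessions of a subject
    are correlated and leave-one-subject-out validation is meaningful.
    """
    config.validate()
    for g, ns in config.n_subjects_per_group.items():
        if ns and ns < 2:
            raise InvalidConfigError(f"group {g!r} needs >= 2 subjects (got {ns})")
    rng = np.random.default_rng(config.seed)
    sessions: list[SessionRecording] = []
    rows = []
    sub_idx = 0
    for group in GROUP_LABELS:
        ns = config.n_subjects_per_group.get(group, 0)
        for _ in range(ns):
            sub_idx += 1
            subject_id = f"S{sub_idx:03d}"
            subject_effects = {
                "beat_jitter": float(np.exp(rng.normal(0.0, 0.15))),
                "hrv_amp": float(np.exp(rng.normal(0.0, 0.15))),
                "rr_jitter": float(np.exp(rng.normal(0.0, 0.15))),
            }
            for s in range(config.sessions_per_subject):
                session_id = f"{subject_id}-{s + 1:02d}"
                sess = generate_session(
                    config,
                    group,
                    rng,
                    subject_id=subject_id,
                    session_id=session_id,
                    subject_effects=subject_effects,
                )
                sessions.append(sess)
                rows.append(
                    {"subject_id": subject_id, "session_id": session_id, "label": group}
                )
    manifest = pd.DataFrame(rows, columns=["subject_id", "session_id", "label"])
    return sessions, manifest


# ---------------------------------------------------------------------------
# Session I/O: multi-channel CSV (t, ecg, scg_z, gsr, excluded)
# ---------------------------------------------------------------------------

def write_session_csv(session: SessionRecording, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(session.n_samples) / session.fs_hz
    df = pd.DataFrame(
        {
            "t": t,
            "ecg": session.ecg,
            "scg_z": session.scg_z,
            "gsr": session.gsr,
            "excluded": session.exclusion_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "subject_id": session.subject_id,
        "session_id": session.session_id,
        "label": session.label,
        "fs_hz": session.fs_hz,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session_csv(path: str | Path) -> SessionRecording:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        dt = np.median(np.diff(df["t"].to_numpy()))
        meta = {
            "subject_id": path.stem,
            "session_id": path.stem,
            "label": "non_readmitted",
            "fs_hz": 1.0 / dt,
        }
    return SessionRecording(
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        label=meta["label"],
        fs_hz=float(meta["fs_hz"]),
        ecg=df["ecg"].to_numpy(float),
        scg_z=df["scg_z"].to_numpy(float),
        gsr=df["gsr"].to_numpy(float),
        exclusion_mask=df["excluded"].to_numpy().astype(bool)
        if "excluded" in df
        else np.zeros(len(df), dtype=bool),
    )


def write_cohort(
    sessions: Iterable[SessionRecording], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sess in sessions:
        write_session_csv(sess, out_dir / f"{sess.session_id}.csv")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
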