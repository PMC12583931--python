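import numpy as np
import pytest

from scgpipe.pipeline import analyze_session, extract_cohort_features
from scgpipe.segmentation import Beat, BeatSet
from scgpipe.synth import SyntheticConfig, generate_cohort, generate_session

# Analysis problem sizes: short sessions at 500 Hz keep the DTW pairwise
# matrices small while leaving ~20+ beats per session.
FAST_FS = 500.0


@pytest.fixture(scope="session")
def default_session_art():
    """One default-parameter session plus its full analysis artifacts."""
    cfg = SyntheticConfig(duration_s=40.0, fs_hz=FAST_FS)
    sess = generate_session(cfg, "non_readmitted", np.random.default_rng(0))
    return sess, analyze_session(sess)


@pytest.fixture(scope="session")
def three_group_features():
    """Feature table for a 3-group cohort (10 subjects x 2 sessions/group)."""
    cfg = SyntheticConfig(
        duration_s=30.0,
        fs_hz=FAST_FS,
        n_subjects_per_group={"healthy": 10, "non_readmitted": 10, "readmitted": 10},
        sessions_per_subject=2,
        seed=7,
    )
    sessions, _ = generate_cohort(cfg)
    return extract_cohort_features(sessions)


@pytest.fixture
def make_beatset():
    """Factory for hand-built BeatSets from waveforms and covariates."""

    def _make(waveforms, lv=None, fr=None, fs=500.0):
        n = len(waveforms)
        lv = np.arange(n, dtype=float) if lv is None else np.asarray(lv, float)
        fr = np.zeros(n) if fr is None else np.asarray(fr, float)
        beats = [
            Beat(
                index=i,
                start_sample=i * 1000,
                end_sample=i * 1000 + len(w),
                samples=np.asarray(w, dtype=float),
                rr_ms=len(w) / fs * 1000.0,
                lv_value=float(lv[i]),
                fr_value=float(fr[i]),
            )
            for i, w in enumerate(waveforms)
        ]
        r_peaks = np.arange(n + 1) * 1000 + 100
        return BeatSet(
            subject_id="T", session_id="T-01", label="non_readmitted",
            fs_hz=fs, r_peaks=r_peaks, beats=beats,
        )

    return _make


def truth_partition_agreement(sess, beats, labels):
    """Fraction of beats whose cluster matches the respiration-phase truth."""
    w = sess.truth["blend_w"]
    rsamp = np.asarray(sess.truth["r_samples"])
    det = beats.r_peaks
    truth = []
    for b in beats.beats:
        r = det[b.index]
        truth.append(w[int(np.argmin(np.abs(rsamp - r)))] > 0.5)
    truth = np.asarray(truth)
    lab = np.asarray(labels) == 1
    return max(np.mean(lab == truth), np.mean(lab != truth))
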