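"""Polynomial chirplet transform (PCT) and instantaneous-frequency features.

The PCT is a spectrogram sharpened for frequency-modulated content: starting
from an ordinary Gaussian-window spectrogram of the analytic signal, the
instantaneous-frequency (IF) ridge is estimated, a polynomial is fitted to
it, and the signal is demodulated by the fitted IF law (frequency-rotation
operator) before the spectrogram is recomputed; each time frame's frequency
axis is then shifted back by the fitted IF at that frame (frequency-shift
operator).  The iteration stops when the ridge moves by less than 0.5 Hz
RMS.  With ``max_iter=0`` the transform reduces exactly to the plain
spectrogram, which serves as a regression anchor.

The instantaneous-frequency feature is the first moment of the distribution
over 0.5-50 Hz, and its RMS over the beat duration is the scalar exported
per waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import gaussian

from .errors import FeatureUnavailableError, InvalidConfigError

IF_BAND = (0.5, 50.0)
RIDGE_TOL_HZ = 0.5


@dataclass
class TFDMatrix:
    values: np.ndarray  # (n_freq, n_time) non-negative energy density
    time_axis: np.ndarray  # seconds
    freq_axis: np.ndarray  # Hz, non-negative, strictly increasing
    params: dict = field(default_factory=dict)


def _stft_power(
    z: np.ndarray,
    fs: float,
    window_s: float,
    nfft: int,
    shift_hz: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-window STFT power of a complex signal.

    ``shift_hz`` applies a per-frame frequency-shift operator: frame *k* is
    modulated by exp(+j 2π shift_hz[k] τ) before the FFT (τ measured from
    the frame centre), moving its content up by ``shift_hz[k]`` without any
    bin quantization.  Returns (freq axis ascending, frame times, power).
    """
    m = int(round(window_s * fs))
    if m > len(z):
        raise InvalidConfigError("window longer than signal")
    win = gaussian(m, std=m / 6.0, sym=True)
    hop = max(1, m // 8)
    half = m // 2
    zp = np.concatenate([np.zeros(half, complex), z, np.zeros(m, complex)])
    centers = np.arange(0, len(z) + 1, hop)
    tau = (np.arange(m) - half) / fs
    P = np.empty((nfft, len(centers)))
    for k, c0 in enumerate(centers):
        seg = zp[c0 : c0 + m] * win
        if shift_hz is not None:
            seg = seg * np.exp(2j * np.pi * shift_hz[k] * tau)
        P[:, k] = np.abs(np.fft.fft(seg, nfft)) ** 2
    f = np.fft.fftshift(np.fft.fftfreq(nfft, d=1.0 / fs))
    P = np.fft.fftshift(P, axes=0)
    t = centers / fs
    return f, t, P


def _nfft_for(fs: float, m: int) -> int:
    return int(2 ** np.ceil(np.log2(max(4 * m, fs, 64))))


def spectrogram(x: np.ndarray, fs: float, window_s: float = 0.25) -> TFDMatrix:
    """Plain Gaussian-window spectrogram of the analytic signal."""
    return pct(x, fs, poly_order=0, window_s=window_s, max_iter=0)


def pct(
    x: np.ndarray,
    fs: float,
    poly_order: int = 5,
    window_s: float = 0.25,
    max_iter: int = 3,
) -> TFDMatrix:
    """Iteratively refined polynomial chirplet transform of a real waveform."""
    x = np.asarray(x, dtype=float)
    m = int(round(window_s * fs))
    if m > len(x):
        raise InvalidConfigError("window longer than signal")
    nfft = _nfft_for(fs, m)
    params = {
        "window_s": window_s,
        "poly_order": poly_order,
        "max_iter": max_iter,
        "nfft": nfft,
    }

    if np.all(x == 0):
        f, t, P = _stft_power(x.astype(complex), fs, window_s, nfft)
        pos = f >= 0
        return TFDMatrix(values=P[pos], time_axis=t, freq_axis=f[pos],
                         params=params | {"n_iterations": 0})

    z = hilbert(x)
    f_full, t, P_full = _stft_power(z, fs, window_s, nfft)
    pos = f_full >= 0
    f_pos = f_full[pos]
    P = P_full[pos]

    def _ridge(Pmat: np.ndarray) -> np.ndarray:
        return f_pos[np.argmax(Pmat, axis=0)]

    ridge = _ridge(P)
    it_done = 0
    ts = np.arange(len(z)) / fs
    for _ in range(max_iter):
        deg = min(poly_order, max(len(t) - 1, 0))
        coeffs = np.polyfit(t, ridge, deg)
        # frequency-rotation operator: demodulate by the fitted IF law
        c_samples = np.polyval(coeffs, ts)
        phase = 2 * np.pi * np.cumsum(c_samples) / fs
        z_d = z * np.exp(-1j * phase)
        # frequency-shift operator: restore each frame by its fitted IF
        c_frames = np.polyval(coeffs, t)
        _, _, Pd = _stft_power(z_d, fs, window_s, nfft, shift_hz=c_frames)
        P_new = Pd[pos]
        new_ridge = _ridge(P_new)
        it_done += 1
        P = P_new
        moved = float(np.sqrt(np.mean((new_ridge - ridge) ** 2)))
        ridge = new_ridge
        if moved < RIDGE_TOL_HZ:
            break
    return TFDMatrix(values=P, time_axis=t, freq_axis=f_pos,
                     params=params | {"n_iterations": it_done})


def ridge_frequencies(tfd: TFDMatrix) -> np.ndarray:
    """Per-frame ridge frequency with parabolic (sub-bin) refinement."""
    P = tfd.values
    f = tfd.freq_axis
    idx = np.argmax(P, axis=0)
    ridge = f[idx].astype(float)
    df = f[1] - f[0]
    for col, i in enumerate(idx):
        if 0 < i < len(f) - 1:
            y0, y1, y2 = P[i - 1, col], P[i, col], P[i + 1, col]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                ridge[col] += 0.5 * (y0 - y2) / denom * df
    return ridge


def instantaneous_frequency(tfd: TFDMatrix, band: tuple[float, float] = IF_BAND) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame first moment of the TFD over ``band`` and a validity mask."""
    lo, hi = band
    if tfd.freq_axis[0] > lo or tfd.freq_axis[-1] < hi:
        raise InvalidConfigError(f"TFD must cover [{lo}, {hi}] Hz")
    sel = (tfd.freq_axis >= lo) & (tfd.freq_axis <= hi)
    f = tfd.freq_axis[sel]
    P = tfd.values[sel]
    num = np.trapezoid(f[:, None] * P, f, axis=0)
    den = np.trapezoid(P, f, axis=0)
    valid = den > 1e-12 * max(den.max(), 1e-300)
    f_ins = np.zeros_like(den)
    f_ins[valid] = num[valid] / den[valid]
    return f_ins, valid


def instantaneous_frequency_rms(
    tfd: TFDMatrix,
    beat_span: tuple[float, float] | None = None,
    band: tuple[float, float] = IF_BAND,
) -> float:
    """RMS of the instantaneous frequency over the beat duration (Hz)."""
    f_ins, valid = instantaneous_frequency(tfd, band)
    if beat_span is not None:
        t0, t1 = beat_span
        valid = valid & (tfd.time_axis >= t0) & (tfd.time_axis <= t1)
    if not np.any(valid):
        raise FeatureUnavailableError("TFD energy negligible everywhere in the band")
    return float(np.sqrt(np.mean(f_ins[valid] ** 2)))


# Parula-like colormap anchors (perceptually uniform blue->green->yellow).
_PARULA_ANCHORS = np.array(
    [
        [0.2422, 0.1504, 0.6603],
        [0.2810, 0.3228, 0.9579],
        [0.1786, 0.5289, 0.9682],
        [0.0689, 0.6948, 0.8394],
        [0.2161, 0.7843, 0.5923],
        [0.6720, 0.7793, 0.2227],
        [0.9970, 0.7659, 0.2199],
        [0.9769, 0.9839, 0.0805],
    ]
)


def _apply_colormap(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    vmax, vmin = v.max(), v.min()
    norm = (v - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(v)
    xp = np.linspace(0.0, 1.0, len(_PARULA_ANCHORS))
    rgb = np.stack(
        [np.interp(norm, xp, _PARULA_ANCHORS[:, c]) for c in range(3)], axis=-1
    )
    return (rgb * 255).round().astype(np.uint8)


def export_tfd_image(tfd: TFDMatrix, path, size: int = 224):
    """Save the TFD as a ``size`` x ``size`` PNG (nearest-neighbor resize).

    Time runs horizontally, frequency vertically (low frequencies at the
    bottom), colored with a Parula-like colormap.
    """
    from PIL import Image

    if tfd.values.size == 0:
        raise InvalidConfigError("empty TFD matrix")
    rgb = _apply_colormap(tfd.values)
    rgb = rgb[::-1]  # freq axis increases upward in the image
    img = Image.fromarray(rgb, mode="RGB")
    img = img.resize((size, size), Image.NEAREST)
    img.save(path, format="PNG")
    return path
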