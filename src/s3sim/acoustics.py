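"""Acoustic analysis of heart-sound signals.

Covers four jobs: superposing an S3 displacement waveform onto an
S1-S2 track, the phonocardiogram preprocessing recipe (resample to
1 kHz, zero-phase 25-400 Hz band-pass, despiking), the 15 Hz
band-energy spectrum with a 300 Hz low-pass, and EBU R 128 / ITU-R
BS.1770 integrated loudness.

Band energies are trapezoidal areas under the *magnitude* spectrum,
normalised by the total area over 0-300 Hz; the dominant frequency is
the argmax of the magnitude spectrum on the fine FFT grid within
0-300 Hz.

Loudness follows the BS.1770 mono pipeline: K-weighting (high-shelf +
high-pass biquads standardised at 48 kHz, hence the internal
48 kHz resample), mean square over 400 ms blocks with 75% overlap, a
-0.691 dB offset, a -70 LUFS absolute gate, then a relative gate 10 LU
below the intermediate loudness.  Digital silence returns ``-inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.ndimage import median_filter

from .s3 import S3Waveform

__all__ = [
    "AudioSignal", "SpectrumBands", "LoudnessValue",
    "superpose", "preprocess_pcg", "band_energy_spectrum",
    "integrated_loudness", "read_wav", "write_wav",
]

#: fixed physical-to-digital gain (digital units per metre of
#: displacement) applied identically across conditions so that LUFS
#: comparisons between conditions are scale-consistent
DISPLACEMENT_GAIN = 1e4


@dataclass
class AudioSignal:
    """Mono audio at a known sample rate with optional onset markers (ms)."""

    fs: float
    samples: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SpectrumBands:
    """Normalised 15 Hz band energies and the dominant frequency."""

    band_edges: np.ndarray   # Hz, len = n_bands + 1
    energies: np.ndarray     # sum to 1
    dominant_frequency: float  # Hz


@dataclass
class LoudnessValue:
    """EBU R 128 integrated loudness with gating metadata."""

    lufs: float
    blocks_total: int
    blocks_gated: int
    abs_gate: float = -70.0
    rel_gate: float | None = None

    @property
    def below_gate(self) -> bool:
        return not math.isfinite(self.lufs)


def superpose(track: AudioSignal, s3: S3Waveform, t_onset: float) -> AudioSignal:
    """Add an S3 waveform into an S1-S2 track at ``t_onset`` ms.

    The track may be an all-zero stub when only the S3 is studied.
    Occurrence times do not interact: it is plain sample-wise addition.
    """
    if not (0.0 <= t_onset < len(track.samples) / track.fs * 1000.0):
        raise ValueError("S3 onset lies outside the track")
    if abs(track.fs - s3.fs) > 1e-9:
        raise ValueError("track and S3 sample rates differ")
    out = track.samples.copy()
    i0 = int(round(t_onset / 1000.0 * track.fs))
    seg = s3.samples[: max(len(out) - i0, 0)]
    out[i0: i0 + len(seg)] += seg
    ann = dict(track.annotations)
    ann["S3"] = t_onset
    return AudioSignal(fs=track.fs, samples=out, annotations=ann)


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator)


def preprocess_pcg(raw: AudioSignal, despike_window_ms: float = 20.0,
                   despike_mads: float = 5.0) -> AudioSignal:
    """Phonocardiogram preprocessing: 1 kHz, 25-400 Hz, despiked.

    Resamples to 1000 Hz, applies a zero-phase 4th-order Butterworth
    band-pass between 25 and 400 Hz, then clips spikes: residuals
    against a moving median (20 ms window) larger than 5 robust
    standard deviations (MAD-based) are clamped.
    """
    if raw.fs < 1000.0:
        raise ValueError("need a sample rate of at least 1000 Hz")
    x = raw.samples
    if len(x) < int(raw.fs * 0.05):
        raise ValueError("signal too short for filter warm-up")
    if raw.fs != 1000.0:
        x = _resample(x, raw.fs, 1000.0)
    sos = sps.butter(4, [25.0, 400.0], btype="bandpass", fs=1000.0, output="sos")
    x = sps.sosfiltfilt(sos, x)
    w = max(int(despike_window_ms), 3) | 1  # odd window, samples at 1 kHz
    med = median_filter(x, size=w, mode="nearest")
    resid = x - med
    sigma = 1.4826 * np.median(np.abs(resid))
    if sigma > 0:
        lim = despike_mads * sigma
        x = med + np.clip(resid, -lim, lim)
    return AudioSignal(fs=1000.0, samples=x, annotations=dict(raw.annotations))


def band_energy_spectrum(signal: AudioSignal, band_width: float = 15.0,
                         lowpass_cutoff: float = 300.0,
                         resolution: float = 0.5) -> SpectrumBands:
    """15 Hz band energies of the 300 Hz low-passed magnitude spectrum.

    The signal is low-pass filtered (zero phase), Hann-windowed and
    zero-padded to at least ``resolution`` Hz FFT spacing; per-band
    trapezoidal areas under the magnitude spectrum are normalised by
    the total over 0-``lowpass_cutoff`` Hz.

    Raises
    ------
    ValueError
        for an all-zero signal (undefined spectrum).
    """
    x = signal.samples
    if not np.any(x):
        raise ValueError("all-zero signal: spectrum undefined")
    if signal.fs <= 2.0 * lowpass_cutoff:
        raise ValueError("sample rate too low for the requested low-pass")
    sos = sps.butter(6, lowpass_cutoff, btype="lowpass", fs=signal.fs, output="sos")
    if len(x) < 30:
        raise ValueError("signal too short for the low-pass filter")
    xf = sps.sosfiltfilt(sos, x)
    xw = xf * np.hanning(len(xf))
    nfft = int(2 ** math.ceil(math.log2(max(len(xw), signal.fs / resolution))))
    mag = np.abs(np.fft.rfft(xw, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / signal.fs)
    n_bands = int(math.ceil(lowpass_cutoff / band_width))
    edges = np.arange(n_bands + 1) * band_width
    areas = np.empty(n_bands)
    for i in range(n_bands):
        sel = (freqs >= edges[i]) & (freqs <= edges[i + 1])
        areas[i] = np.trapezoid(mag[sel], freqs[sel])
    total = areas.sum()
    if total <= 0:
        raise ValueError("no spectral energy below the low-pass cutoff")
    in_range = freqs <= lowpass_cutoff
    f_dom = float(freqs[in_range][np.argmax(mag[in_range])])
    return SpectrumBands(band_edges=edges, energies=areas / total,
                         dominant_frequency=f_dom)


# --- ITU-R BS.1770 K-weighting, standardised biquads at 48 kHz ----------
_FS_K = 48000.0
_PRE_B = (1.53512485958697, -2.69169618940638, 1.19839281085285)
_PRE_A = (1.0, -1.69065929318241, 0.73248077421585)
_RLB_B = (1.0, -2.0, 1.0)
_RLB_A = (1.0, -1.99004745483398, 0.99007225036621)
_BLOCK_S = 0.400
_HOP_S = 0.100
_OFFSET = -0.691
_ABS_GATE = -70.0
_REL_GATE_LU = 10.0


def _k_weight(x: np.ndarray) -> np.ndarray:
    y = sps.lfilter(_PRE_B, _PRE_A, x)
    return sps.lfilter(_RLB_B, _RLB_A, y)


def integrated_loudness(signal: AudioSignal) -> LoudnessValue:
    """EBU R 128 / BS.1770 integrated loudness of a mono signal (LUFS).

    Signals not at 48 kHz are resampled internally (the K-weighting
    biquads are standardised at that rate).  Returns ``-inf`` when no
    400 ms block passes the -70 LUFS absolute gate.
    """
    x = signal.samples
    if signal.fs != _FS_K:
        x = _resample(x, signal.fs, _FS_K)
    block = int(_BLOCK_S * _FS_K)
    hop = int(_HOP_S * _FS_K)
    if len(x) < block:
        x = np.pad(x, (0, block - len(x)))
    y = _k_weight(x)
    n_blocks = 1 + (len(y) - block) // hop
    starts = np.arange(n_blocks) * hop
    z = np.array([np.mean(y[s: s + block] ** 2) for s in starts])
    with np.errstate(divide="ignore"):
        l_blocks = _OFFSET + 10.0 * np.log10(z)
    above_abs = l_blocks > _ABS_GATE
    if not np.any(above_abs):
        return LoudnessValue(lufs=float("-inf"), blocks_total=n_blocks,
                             blocks_gated=0)
    rel_thresh = (_OFFSET + 10.0 * np.log10(np.mean(z[above_abs]))
                  - _REL_GATE_LU)
    keep = above_abs & (l_blocks > rel_thresh)
    if not np.any(keep):
        return LoudnessValue(lufs=float("-inf"), blocks_total=n_blocks,
                             blocks_gated=0, rel_gate=rel_thresh)
    lufs = _OFFSET + 10.0 * np.log10(np.mean(z[keep]))
    return LoudnessValue(lufs=float(lufs), blocks_total=n_blocks,
                         blocks_gated=int(keep.sum()), rel_gate=rel_thresh)


def read_wav(path) -> AudioSignal:
    """Read a mono (or mixed-down) WAV file as float samples in [-1, 1]."""
    fs, data = wavfile.read(path)
    x = np.asarray(data, dtype=float)
    if x.ndim > 1:
        x = x.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    return AudioSignal(fs=float(fs), samples=x)


def write_wav(path, signal: AudioSignal, dtype: str = "float32",
              normalize: bool = False) -> None:
    """Write a WAV file (PCM 16-bit or float32)."""
    x = signal.samples
    if normalize and np.max(np.abs(x)) > 0:
        x = x / np.max(np.abs(x))
    if dtype == "int16":
        wavfile.write(path, int(signal.fs),
                      np.clip(x * 32767.0, -32768, 32767).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, int(signal.fs), x.astype(np.float32))
    else:
        raise ValueError("dtype must be 'int16' or 'float32'")
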