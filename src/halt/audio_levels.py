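"""Core level, weighting, and loudness computations.

Conventions
-----------
Digital full scale is 1.0 linear; a full-scale sine has a true peak of
0 dBFS (dBTP).  All level quantities are energy (RMS) based except the
true peak, which is an inter-sample peak estimate obtained by
oversampling.  Loudness follows the gated, K-weighted broadcast
integrated measure (absolute gate at -70 LUFS, relative gate 10 LU below
the absolutely-gated mean).

A-weighting is available in two forms that must agree closely: the
analytic pole magnitude formula (for tones and spectrum analysis) and a
bilinear-transformed IIR filter (for time-domain equivalent levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import UnmeasurableError

__all__ = [
    "AudioSignal",
    "LevelReport",
    "a_weight_attenuation",
    "a_weighting_sos",
    "true_peak_dbfs",
    "sample_peak_dbfs",
    "integrated_loudness",
    "equivalent_level",
    "measure_levels",
    "read_wav",
    "write_wav",
]

SILENCE_DB = -np.inf

# A-weighting pole frequencies (Hz), IEC 61672-1 analytic form.
_F1, _F2, _F3, _F4 = 20.598997, 107.65265, 737.86223, 12194.217


@dataclass
class AudioSignal:
    """A sampled waveform in linear full-scale units.

    ``samples`` has shape (n,) for mono or (n, 2) for stereo.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")
        if self.samples.ndim == 2 and self.samples.shape[1] not in (1, 2):
            raise ValueError("only 1 or 2 channels are supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def as_2d(self) -> np.ndarray:
        """Samples with an explicit channel axis, shape (n, channels)."""
        return self.samples[:, None] if self.samples.ndim == 1 else self.samples

    def gain(self, gain_db: float) -> "AudioSignal":
        """Return a copy scaled by ``gain_db`` decibels."""
        return AudioSignal(self.samples * 10.0 ** (gain_db / 20.0), self.rate)


@dataclass
class LevelReport:
    """Summary levels of one signal (all dB re full scale)."""

    true_peak_dbfs: float
    integrated_lufs: float | None
    leq_a: float
    leq_z: float


def _a_weight_magnitude(freq: np.ndarray) -> np.ndarray:
    f2 = np.asarray(freq, dtype=np.float64) ** 2
    num = _F4**2 * f2**2
    den = (f2 + _F1**2) * np.sqrt((f2 + _F2**2) * (f2 + _F3**2)) * (f2 + _F4**2)
    return num / den


# Normalisation so that the response is exactly 0 dB at 1 kHz.
_A_OFFSET_DB = -20.0 * math.log10(float(_a_weight_magnitude(np.array(1000.0))))


def a_weight_attenuation(frequency, *, nominal: bool = False):
    """Standard A-weighting gain in dB, normalised to 0 dB at 1 kHz.

    Parameters
    ----------
    frequency
        Frequency in Hz (scalar or array); must be positive.
    nominal
        If true, frequencies that match a standard renard-series nominal
        band frequency (20, 25, 31.5, ... Hz) are evaluated at the exact
        preferred frequency ``10**(n/10)`` instead, which is how the
        published weighting tables are computed (e.g. nominal 20 Hz is
        evaluated at 19.953 Hz, giving the tabulated -50.5 dB).
    """
    freq = np.asarray(frequency, dtype=np.float64)
    if np.any(freq <= 0):
        raise ValueError("frequency must be positive")
    if nominal:
        # Snap to the exact preferred frequency when the input is within
        # rounding distance of a tenth-decade nominal value.
        n = np.round(10.0 * np.log10(freq))
        exact = 10.0 ** (n / 10.0)
        freq = np.where(np.abs(np.log10(freq) - n / 10.0) < 0.006, exact, freq)
    out = 20.0 * np.log10(_a_weight_magnitude(freq)) + _A_OFFSET_DB
    return float(out) if np.isscalar(frequency) else out


def a_weighting_sos(rate: int) -> np.ndarray:
    """Digital A-weighting filter (bilinear transform of the analog
    pole-zero prototype) as second-order sections for ``rate`` Hz."""
    z = [0.0, 0.0, 0.0, 0.0]
    p = (
        [-2 * np.pi * _F1] * 2
        + [-2 * np.pi * _F2, -2 * np.pi * _F3]
        + [-2 * np.pi * _F4] * 2
    )
    # Analog gain chosen for 0 dB at 1 kHz before warping.
    k = (2 * np.pi * _F4) ** 2 * 10 ** (_A_OFFSET_DB / 20.0)
    zd, pd, kd = sps.bilinear_zpk(z, p, k, rate)
    # Renormalise exactly at 1 kHz in the digital domain.
    w = 2 * np.pi * 1000.0 / rate
    _, h = sps.freqz_zpk(zd, pd, kd, worN=[w])
    kd /= np.abs(h[0])
    return sps.zpk2sos(zd, pd, kd)


_A_FILTER_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def a_weighting_filter(rate: int) -> tuple[np.ndarray, np.ndarray]:
    """Precision time-domain A-weighting: the bilinear IIR cascaded with a
    linear-phase FIR correction.

    The bilinear transform places the prototype's two excess zeros at
    Nyquist, which depresses the response near the band top (≈6 dB at
    16 kHz for 48 kHz audio).  The FIR is designed from the ratio of the
    analytic magnitude to the IIR response, restoring agreement with the
    closed form to within ~0.01 dB up to min(16 kHz, 0.9×Nyquist).
    Results are cached per rate.
    """
    if rate in _A_FILTER_CACHE:
        return _A_FILTER_CACHE[rate]
    sos = a_weighting_sos(rate)
    nyq = rate / 2.0
    grid = np.linspace(0.0, nyq, 2049)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * grid / rate)
    current = np.abs(h)
    desired = 10.0 ** (a_weight_attenuation(np.maximum(grid, 1e-3)) / 20.0)
    band = grid <= min(0.9 * nyq, 20000.0)
    ratio = np.ones_like(grid)
    ratio[band] = desired[band] / np.maximum(current[band], 1e-12)
    ratio[~band] = ratio[band][-1]
    ratio[0] = 1.0
    ratio = np.clip(ratio, 0.0, 10.0 ** (12 / 20))
    fir = sps.firwin2(513, grid / nyq, ratio, nfreqs=4097)
    _A_FILTER_CACHE[rate] = (sos, fir)
    return sos, fir


def sample_peak_dbfs(signal: AudioSignal) -> float:
    peak = float(np.max(np.abs(signal.samples))) if signal.n_samples else 0.0
    return SILENCE_DB if peak == 0.0 else 20.0 * math.log10(peak)


def true_peak_dbfs(signal: AudioSignal, oversample: int = 4) -> float:
    """Inter-sample (true) peak in dBTP.

    Estimated by polyphase oversampling (default 4x with an 81-tap
    low-pass interpolator, the common broadcast-metering arrangement).
    Returns ``-inf`` for digital silence.
    """
    if signal.n_samples == 0:
        raise ValueError("empty signal")
    x = signal.as_2d()
    if not np.any(x):
        return SILENCE_DB
    peak = 0.0
    for ch in range(x.shape[1]):
        up = sps.resample_poly(x[:, ch], oversample, 1)
        peak = max(peak, float(np.max(np.abs(up))), float(np.max(np.abs(x[:, ch]))))
    return 20.0 * math.log10(peak)


def _k_weighting_sos(rate: int) -> np.ndarray:
    """K-weighting pre-filter (high shelf + high pass) for ``rate`` Hz,
    designed parametrically so any sample rate reproduces the published
    48 kHz coefficients."""
    # Stage 1: +4 dB high shelf.
    f0, gain_db, q = 1681.9744509742, 3.99984385397, 0.7071752369
    k = math.tan(math.pi * f0 / rate)
    vh = 10.0 ** (gain_db / 20.0)
    vb = vh**0.499666774155
    a0 = 1.0 + k / q + k * k
    shelf_b = np.array([vh + vb * k / q + k * k, 2 * (k * k - vh), vh - vb * k / q + k * k]) / a0
    shelf_a = np.array([1.0, 2 * (k * k - 1) / a0, (1.0 - k / q + k * k) / a0])
    # Stage 2: high pass.
    f0, q = 38.13547087613982, 0.5003270373253953
    k = math.tan(math.pi * f0 / rate)
    a0 = 1.0 + k / q + k * k
    hp_b = np.array([1.0, -2.0, 1.0])
    hp_a = np.array([1.0, 2 * (k * k - 1) / a0, (1.0 - k / q + k * k) / a0])
    return np.vstack([np.concatenate([shelf_b, shelf_a]), np.concatenate([hp_b, hp_a])])


_BLOCK_S = 0.400  # gating block length
_OVERLAP = 0.75
_ABS_GATE_LUFS = -70.0
_REL_GATE_LU = -10.0


def integrated_loudness(signal: AudioSignal) -> float:
    """Gated integrated loudness in LUFS (K-weighting, absolute -70 LUFS
    gate, relative -10 LU gate).

    Raises
    ------
    UnmeasurableError
        If the signal is shorter than one gating block or every block is
        gated out (e.g. digital silence).
    """
    x = signal.as_2d()
    block = int(round(_BLOCK_S * signal.rate))
    step = int(round(block * (1 - _OVERLAP)))
    if signal.n_samples < block:
        raise UnmeasurableError("signal shorter than one gating block")
    sos = _k_weighting_sos(signal.rate)
    y = sps.sosfilt(sos, x, axis=0)
    n_blocks = (signal.n_samples - block) // step + 1
    # Per-block mean square per channel via cumulative sums.
    csum = np.concatenate([np.zeros((1, y.shape[1])), np.cumsum(y * y, axis=0)])
    starts = np.arange(n_blocks) * step
    z = (csum[starts + block] - csum[starts]) / block  # (n_blocks, ch)
    power = z.sum(axis=1)  # channel weights are 1 for mono/stereo
    with np.errstate(divide="ignore"):
        l_blocks = -0.691 + 10.0 * np.log10(power)
    keep = l_blocks > _ABS_GATE_LUFS
    if not np.any(keep):
        raise UnmeasurableError("all blocks below the absolute gate")
    rel_gate = -0.691 + 10.0 * math.log10(float(power[keep].mean())) + _REL_GATE_LU
    keep &= l_blocks > rel_gate
    if not np.any(keep):
        raise UnmeasurableError("all blocks below the relative gate")
    return -0.691 + 10.0 * math.log10(float(power[keep].mean()))


def equivalent_level(signal: AudioSignal, weighting: str = "Z") -> float:
    """Energy-equivalent level (Leq) over the full duration, dB re full
    scale.  ``weighting`` is ``"A"`` (perceptual) or ``"Z"`` (flat); the
    Z-weighted Leq equals the plain RMS level."""
    if signal.n_samples == 0:
        raise ValueError("empty signal")
    x = signal.as_2d()
    n = x.shape[0]
    if weighting.upper() == "A":
        sos, fir = a_weighting_filter(signal.rate)
        x = sps.sosfilt(sos, x, axis=0)
        x = sps.fftconvolve(x, fir[:, None], axes=0)
    elif weighting.upper() != "Z":
        raise ValueError(f"unknown weighting {weighting!r}")
    # Power-average across channels (mono-equivalent energy); the FIR
    # tail is included in the energy but the duration stays the original.
    mean_sq = float(np.mean(np.sum(x**2, axis=0) / n))
    if mean_sq == 0.0:
        return SILENCE_DB
    return 10.0 * math.log10(mean_sq)


def measure_levels(signal: AudioSignal) -> LevelReport:
    """All summary levels of a signal in one report; the loudness entry is
    None when the gated measure is undefined."""
    try:
        lufs = integrated_loudness(signal)
    except UnmeasurableError:
        lufs = None
    return LevelReport(
        true_peak_dbfs=true_peak_dbfs(signal),
        integrated_lufs=lufs,
        leq_a=equivalent_level(signal, "A"),
        leq_z=equivalent_level(signal, "Z"),
    )


def read_wav(path: str | Path) -> AudioSignal:
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    return AudioSignal(x, int(rate))


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a WAV file.  ``subtype`` is ``"float32"`` (default, lossless
    for rendering pipelines) or ``"int16"``."""
    if subtype == "float32":
        data = signal.samples.astype(np.float32)
    elif subtype == "int16":
        data = np.clip(np.round(signal.samples * 32767.0), -32768, 32767).astype(np.int16)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(str(path), signal.rate, data)
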