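"""Swept-sine measurement analysis for playback devices.

The measurement chain follows loudspeaker/headphone measurement
practice: an exponential sine sweep (ESS) is played through the device,
the recording is deconvolved with the sweep's amplitude-compensated
inverse filter, and the log-frequency sweep law places the impulse
responses of the k-th harmonic distortion products *ahead* of the linear
impulse response by ``L * ln(k)`` seconds, so each can be windowed out
separately.

On top of the recovered responses the module computes total harmonic
distortion, third-octave-smoothed magnitude responses, the
log-frequency median magnitude, median-relative frequency limits
(-3/-6/-20 dB), gain-linearity deviations, stimulus equivalent levels
via impulse-response convolution, and the low-frequency audibility
criterion (magnitude re median plus A-weighting, threshold -40 dB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .audio_levels import AudioSignal, a_weight_attenuation, equivalent_level
from .errors import UnmeasurableError

__all__ = [
    "ImpulseResponse",
    "MagnitudeSpectrum",
    "DeviceMeasurement",
    "InverseFilter",
    "DeconvolutionResult",
    "generate_ess",
    "deconvolve_ir",
    "thd_percent",
    "magnitude_spectrum",
    "smooth_third_octave",
    "median_magnitude",
    "frequency_limits",
    "linearity_deviation",
    "stimulus_leq_via_ir",
    "lowfreq_valuation",
    "log_frequency_grid",
    "LOWFREQ_CRITERION_DB",
]

BAND = (20.0, 20000.0)
POINTS_PER_OCTAVE = 48
LOWFREQ_CRITERION_DB = -40.0


@dataclass
class ImpulseResponse:
    samples: np.ndarray
    rate: int
    channel_label: str = "left_ear"  # {left_ear, right_ear}
    gain_db: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class MagnitudeSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing
    magnitude_db: np.ndarray
    smoothing: float | None = None  # fraction of octave, None = raw

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=np.float64)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def at(self, freq: float) -> float:
        """Magnitude at ``freq`` by log-frequency linear interpolation."""
        if not (self.freqs[0] <= freq <= self.freqs[-1]):
            raise ValueError(f"{freq} Hz outside spectrum coverage")
        return float(np.interp(np.log(freq), np.log(self.freqs), self.magnitude_db))


@dataclass
class DeviceMeasurement:
    """Impulse responses per (gain setting, ear channel)."""

    irs: dict  # {(gain_db, channel_label): ImpulseResponse}
    device: str = ""
    stereo: bool = True

    def __post_init__(self) -> None:
        if not self.irs:
            raise ValueError("at least one impulse response is required")

    @property
    def gains(self) -> list[float]:
        return sorted({g for g, _ in self.irs})


@dataclass
class InverseFilter:
    samples: np.ndarray
    rate: int
    sweep_samples: int
    sweep_rate_l: float  # L = T / ln(f2/f1), seconds
    f1: float
    f2: float


@dataclass
class DeconvolutionResult:
    linear_ir: ImpulseResponse
    harmonic_irs: dict  # {k: np.ndarray}, k >= 2
    raw: np.ndarray
    peak_index: int


# ---------------------------------------------------------------------------
# sweep generation and deconvolution


def generate_ess(f1: float, f2: float, duration: float, rate: int,
                 amplitude: float = 0.5, fade_in: float | None = None,
                 fade_out: float | None = None):
    """Exponential sine sweep and its amplitude-compensated inverse.

    The sweep's instantaneous frequency rises exponentially from ``f1``
    to ``f2`` over ``duration`` seconds.  The inverse filter is the
    time-reversed sweep with a -6 dB/octave amplitude envelope and is
    normalised so that sweep ⊛ inverse gives a unit-peak band-limited
    impulse at index ``len(sweep) - 1``.

    Returns ``(AudioSignal, InverseFilter)``.
    """
    if not (0 < f1 < f2 <= rate / 2):
        raise ValueError("need 0 < f1 < f2 <= rate/2")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    big_l = duration / math.log(f2 / f1)
    phase = 2 * np.pi * f1 * big_l * (np.exp(t / big_l) - 1.0)
    sweep = amplitude * np.sin(phase)
    # Edge fades suppress spectral ripple that would otherwise raise the
    # deconvolution side lobes; the fade-in covers a few periods of f1.
    fade_in = 4.0 / f1 if fade_in is None else fade_in
    fade_out = 0.01 * duration if fade_out is None else fade_out
    n_in = min(int(round(fade_in * rate)), n // 2)
    n_out = min(int(round(fade_out * rate)), n // 2)
    if n_in:
        sweep[:n_in] *= 0.5 * (1 - np.cos(np.pi * np.arange(n_in) / n_in))
    if n_out:
        sweep[-n_out:] *= 0.5 * (1 + np.cos(np.pi * np.arange(n_out) / n_out))
    # Inverse: time reversal with exponential amplitude compensation,
    # normalised so the deconvolved pulse has unit (0 dB) in-band
    # spectral magnitude rather than unit time-domain peak — the former
    # is what calibrates recovered transfer functions.
    inverse = sweep[::-1] * np.exp(-t / big_l)
    ref = sps.fftconvolve(sweep, inverse)
    spec = np.abs(np.fft.rfft(ref))
    freqs = np.fft.rfftfreq(ref.shape[0], 1.0 / rate)
    plateau = (freqs >= 2 * f1) & (freqs <= 0.5 * f2)
    inverse = inverse / float(np.median(spec[plateau]))
    sig = AudioSignal(sweep, rate)
    inv = InverseFilter(inverse, rate, n, big_l, f1, f2)
    return sig, inv


def deconvolve_ir(recording: AudioSignal, inverse: InverseFilter,
                  max_harmonic: int = 5, ir_length: float = 0.5,
                  channel_label: str = "left_ear",
                  gain_db: float = 0.0) -> DeconvolutionResult:
    """Deconvolve a sweep recording into linear and harmonic impulse
    responses.

    The linear impulse response sits at the reference index
    ``len(sweep) - 1``; the k-th harmonic response arrives
    ``L * ln(k)`` seconds earlier and is extracted with a Tukey window
    spanning half the gap to each neighbouring harmonic arrival.
    """
    if recording.rate != inverse.rate:
        raise ValueError("recording/inverse rate mismatch")
    if recording.channels != 1:
        raise ValueError("deconvolution expects a mono recording")
    if recording.n_samples < inverse.sweep_samples:
        raise ValueError("recording shorter than the sweep")
    raw = sps.fftconvolve(recording.samples, inverse.samples)
    idx0 = inverse.sweep_samples - 1
    rate = recording.rate
    n_ir = int(round(ir_length * rate))
    linear = raw[idx0: idx0 + n_ir].copy()
    pre = int(round(0.25 * inverse.sweep_rate_l * math.log(2) * rate))
    pre = min(pre, idx0)
    if pre:
        head = raw[idx0 - pre: idx0].copy()
        linear = np.concatenate([head, linear])
    harmonic_irs: dict[int, np.ndarray] = {}
    arrivals = {
        k: idx0 - int(round(inverse.sweep_rate_l * math.log(k) * rate))
        for k in range(2, max_harmonic + 1)
    }
    for k in range(2, max_harmonic + 1):
        center = arrivals[k]
        if center < 0:
            continue
        gap_prev = (arrivals.get(k - 1, idx0) - center) if k > 2 else idx0 - center
        gap_next = center - arrivals.get(k + 1, 0)
        half = max(int(0.5 * min(gap_prev, gap_next)), 8)
        lo, hi = max(center - half, 0), min(center + half, raw.shape[0])
        seg = raw[lo:hi] * sps.windows.tukey(hi - lo, alpha=0.5)
        harmonic_irs[k] = seg
    ir = ImpulseResponse(linear, rate, channel_label, gain_db)
    return DeconvolutionResult(ir, harmonic_irs, raw, idx0)


def thd_percent(harmonic_amplitudes) -> float:
    """Total harmonic distortion in percent, distortion-factor form:
    ``100 * sqrt(sum_{k>=2} A_k^2) / sqrt(sum_{k>=1} A_k^2)`` where the
    first entry is the fundamental amplitude."""
    amps = np.asarray(harmonic_amplitudes, dtype=float)
    if amps.size == 0 or amps[0] <= 0:
        raise UnmeasurableError("fundamental amplitude must be positive")
    harm = float(np.sum(amps[1:] ** 2))
    total = float(np.sum(amps**2))
    return 100.0 * math.sqrt(harm / total)


def harmonic_amplitudes_at(result: DeconvolutionResult, freq: float,
                           max_harmonic: int = 5) -> np.ndarray:
    """Amplitudes of the fundamental and harmonics for a stimulus
    frequency ``freq``: |H_1(f)| from the linear response and |H_k(k f)|
    from each harmonic response."""
    rate = result.linear_ir.rate
    amps = [_spectrum_amplitude(result.linear_ir.samples, rate, freq)]
    for k in range(2, max_harmonic + 1):
        h = result.harmonic_irs.get(k)
        amps.append(0.0 if h is None else _spectrum_amplitude(h, rate, k * freq))
    return np.asarray(amps)


def _spectrum_amplitude(x: np.ndarray, rate: int, freq: float) -> float:
    n = max(x.shape[0], 4096)
    spec = np.abs(np.fft.rfft(x, n))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    return float(np.interp(freq, freqs, spec))


# ---------------------------------------------------------------------------
# magnitude spectra


def log_frequency_grid(lo: float = BAND[0], hi: float = BAND[1],
                       points_per_octave: int = POINTS_PER_OCTAVE) -> np.ndarray:
    n = int(round(math.log2(hi / lo) * points_per_octave)) + 1
    return lo * 2.0 ** (np.arange(n) / points_per_octave)


def magnitude_spectrum(ir: ImpulseResponse, n_fft: int | None = None) -> MagnitudeSpectrum:
    """Raw magnitude response of an impulse response, restricted to the
    audio band up to Nyquist."""
    n = n_fft or max(1 << int(math.ceil(math.log2(max(ir.samples.shape[0], 2)))), 8192)
    spec = np.abs(np.fft.rfft(ir.samples, n))
    freqs = np.fft.rfftfreq(n, 1.0 / ir.rate)
    keep = (freqs >= BAND[0] * 0.5) & (freqs <= min(BAND[1] * 1.1, ir.rate / 2)) & (freqs > 0)
    with np.errstate(divide="ignore"):
        mag = 20.0 * np.log10(np.maximum(spec[keep], 1e-300))
    return MagnitudeSpectrum(freqs[keep], mag)


def smooth_third_octave(spectrum: MagnitudeSpectrum,
                        fraction: float = 3.0) -> MagnitudeSpectrum:
    """Fractional-octave smoothing (default 1/3 octave) in the power
    domain on a uniform log-frequency grid.

    The Gaussian kernel's half-power width equals one ``1/fraction``
    octave, so an isolated narrow peak is widened to ≈ 1/3 octave at its
    -3 dB points."""
    ppo = 192
    lo, hi = spectrum.freqs[0], spectrum.freqs[-1]
    n = int(round(math.log2(hi / lo) * ppo)) + 1
    grid = lo * 2.0 ** (np.arange(n) / ppo)
    mag = np.interp(np.log(grid), np.log(spectrum.freqs), spectrum.magnitude_db)
    power = 10.0 ** (mag / 10.0)
    fwhm_bins = ppo / fraction
    sigma = fwhm_bins / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sm = gaussian_filter1d(power, sigma, mode="nearest")
    sm_db = 10.0 * np.log10(np.maximum(sm, 1e-300))
    out = np.interp(np.log(spectrum.freqs), np.log(grid), sm_db)
    return MagnitudeSpectrum(spectrum.freqs.copy(), out, smoothing=1.0 / fraction)


def median_magnitude(spectrum: MagnitudeSpectrum,
                     band: tuple[float, float] = BAND) -> float:
    """Median magnitude over a log-spaced grid spanning the audio band
    (20 Hz – 20 kHz), i.e. equal weight per octave."""
    lo = max(band[0], spectrum.freqs[0])
    hi = min(band[1], spectrum.freqs[-1])
    if lo > band[0] * 1.05 or hi < band[1] * 0.95:
        raise ValueError("spectrum does not cover the 20 Hz – 20 kHz band")
    grid = log_frequency_grid(lo, hi)
    mag = np.interp(np.log(grid), np.log(spectrum.freqs), spectrum.magnitude_db)
    return float(np.median(mag))


def frequency_limits(spectrum: MagnitudeSpectrum, median: float | None = None,
                     drops: tuple = (3.0, 6.0, 20.0)) -> dict:
    """Frequencies at which the (smoothed) magnitude first falls below
    the median by each drop, scanning outward from the geometric
    mid-band frequency (≈632 Hz); ripple re-crossings further out are
    ignored.  Returns ``{drop: (lower_hz | None, upper_hz | None)}``."""
    if median is None:
        median = median_magnitude(spectrum)
    lo = max(BAND[0], spectrum.freqs[0])
    hi = min(BAND[1], spectrum.freqs[-1])
    grid = log_frequency_grid(lo, hi, points_per_octave=96)
    mag = np.interp(np.log(grid), np.log(spectrum.freqs), spectrum.magnitude_db)
    mid = int(np.argmin(np.abs(grid - math.sqrt(BAND[0] * BAND[1]))))
    out: dict[float, tuple] = {}
    for drop in drops:
        threshold = median - drop
        lower = upper = None
        for i in range(mid, 0, -1):
            if mag[i - 1] < threshold <= mag[i]:
                frac = (threshold - mag[i]) / (mag[i - 1] - mag[i])
                lower = float(np.exp(np.log(grid[i]) + frac * (np.log(grid[i - 1]) - np.log(grid[i]))))
                break
        for i in range(mid, len(grid) - 1):
            if mag[i + 1] < threshold <= mag[i]:
                frac = (threshold - mag[i]) / (mag[i + 1] - mag[i])
                upper = float(np.exp(np.log(grid[i]) + frac * (np.log(grid[i + 1]) - np.log(grid[i]))))
                break
        out[float(drop)] = (lower, upper)
    return out


def linearity_deviation(measurement: DeviceMeasurement, reference_gain: float,
                        flag_db: float = 1.0, smooth: bool = True,
                        channel: str | None = None) -> dict:
    """Gain-linearity analysis: for each measured gain g, the deviation
    spectrum ``[mag(g, f) - mag(ref, f)] - (g - ref)`` (dB), with flags
    where |deviation| exceeds ``flag_db``.  A perfectly linear device
    deviates by 0 everywhere.

    Returns ``{gain: (MagnitudeSpectrum, flags boolean array)}``.
    """
    def spectra_for(gain):
        items = [ir for (g, ch), ir in measurement.irs.items()
                 if g == gain and (channel is None or ch == channel)]
        if not items:
            return None
        specs = []
        for ir in items:
            s = magnitude_spectrum(ir)
            specs.append(smooth_third_octave(s) if smooth else s)
        freqs = specs[0].freqs
        power = np.mean([10 ** (np.interp(np.log(freqs), np.log(s.freqs),
                                          s.magnitude_db) / 10) for s in specs], axis=0)
        return MagnitudeSpectrum(freqs, 10 * np.log10(power),
                                 smoothing=specs[0].smoothing)

    ref = spectra_for(reference_gain)
    if ref is None:
        raise ValueError(f"no impulse response at reference gain {reference_gain}")
    out = {}
    for gain in measurement.gains:
        spec = spectra_for(gain)
        dev = (spec.magnitude_db - np.interp(np.log(spec.freqs), np.log(ref.freqs),
                                             ref.magnitude_db)) - (gain - reference_gain)
        dev_spec = MagnitudeSpectrum(spec.freqs, dev, smoothing=spec.smoothing)
        out[gain] = (dev_spec, np.abs(dev) > flag_db)
    return out


def stimulus_leq_via_ir(ir_pairs: dict, stimulus: AudioSignal,
                        weighting: str = "A") -> dict:
    """Per-ear equivalent level of a stimulus played through measured
    impulse responses, including crosstalk paths.

    ``ir_pairs`` maps ``(source_channel, ear)`` → ImpulseResponse, where
    ``source_channel`` is "left"/"right" (or "mono") and ``ear`` is
    "left_ear"/"right_ear".  Each ear's signal is the sum of all source
    channels convolved with their path to that ear.
    """
    x = stimulus.as_2d()
    chan_index = {"left": 0, "right": 1 if x.shape[1] > 1 else 0, "mono": 0}
    ears: dict[str, np.ndarray] = {}
    for (src, ear), ir in ir_pairs.items():
        if ir.rate != stimulus.rate:
            raise ValueError("impulse-response/stimulus rate mismatch")
        if src not in chan_index:
            raise ValueError(f"unknown source channel {src!r}")
        y = sps.fftconvolve(x[:, chan_index[src]], ir.samples)
        ears[ear] = ears.get(ear, 0) + y
    return {
        ear: equivalent_level(AudioSignal(y, stimulus.rate), weighting)
        for ear, y in ears.items()
    }


def lowfreq_valuation(spectrum: MagnitudeSpectrum, freq: float,
                      median: float | None = None,
                      criterion_db: float = LOWFREQ_CRITERION_DB):
    """Low-frequency audibility criterion for a probe tone.

    ``criterion = (magnitude(freq) - median) + A-weighting(freq)``; the
    tone is predicted audible when the criterion is at or above the
    -40 dB listening threshold relative to the spectral median.

    Returns ``(criterion_value_db, predicted_audible)``.
    """
    if median is None:
        median = median_magnitude(spectrum)
    value = (spectrum.at(freq) - median) + a_weight_attenuation(freq, nominal=True)
    return float(value), bool(value >= criterion_db)
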