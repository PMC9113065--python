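"""Swept-sine analysis: deconvolution round-trips against analytic
transfer functions, THD closed forms, smoothing/median/limit behaviour,
linearity flags and IR-based equivalent levels."""

import numpy as np
import pytest
from scipy import signal as sps

from halt.audio_levels import AudioSignal, equivalent_level
from halt.electroacoustics import (
    DeviceMeasurement,
    ImpulseResponse,
    MagnitudeSpectrum,
    deconvolve_ir,
    frequency_limits,
    generate_ess,
    harmonic_amplitudes_at,
    log_frequency_grid,
    lowfreq_valuation,
    magnitude_spectrum,
    median_magnitude,
    smooth_third_octave,
    stimulus_leq_via_ir,
    thd_percent,
)
from halt.errors import UnmeasurableError

from conftest import RATE, sine


def _with_tail(x, n=9600):
    return AudioSignal(np.concatenate([x, np.zeros(n)]), RATE)


# ---------------------------------------------------------------------------
# sweep generation


def test_ess_deterministic_and_band(ess_pair):
    sweep, inv = ess_pair
    sweep2, _ = generate_ess(10.0, 22000.0, 3.0, RATE)
    assert np.array_equal(sweep.samples, sweep2.samples)


def test_ess_instantaneous_frequency_endpoints():
    """Log-law sweep runs from f1 at t=0 to f2 at t=duration."""
    rate, f1, f2, dur = 48000, 100.0, 8000.0, 1.0
    sweep, _ = generate_ess(f1, f2, dur, rate, fade_in=0.0, fade_out=0.0)
    analytic = sps.hilbert(sweep.samples)
    inst = np.diff(np.unwrap(np.angle(analytic))) * rate / (2 * np.pi)
    n = len(inst)
    assert np.median(inst[: n // 100]) == pytest.approx(f1, rel=0.05)
    assert np.median(inst[-n // 100:]) == pytest.approx(f2, rel=0.05)


def test_ess_pulse_sidelobe_suppression():
    """sweep ⊛ inverse approximates a band-limited impulse: outside the
    pulse's own band-edge main lobe (±half an f1 period) everything is
    at least 60 dB down."""
    sweep, inv = generate_ess(20.0, 20000.0, 2.0, RATE)
    ref = sps.fftconvolve(sweep.samples, inv.samples)
    n = len(sweep.samples)
    peak = np.max(np.abs(ref))
    half = int(0.5 / 20.0 * RATE)
    mask = np.ones(len(ref), bool)
    mask[n - 1 - half: n - 1 + half] = False
    psr = 20 * np.log10(peak / np.max(np.abs(ref[mask])))
    assert psr >= 60.0


def test_ess_rejects_bad_band():
    with pytest.raises(ValueError):
        generate_ess(200.0, 100.0, 1.0, RATE)
    with pytest.raises(ValueError):
        generate_ess(20.0, 30000.0, 1.0, RATE)


# ---------------------------------------------------------------------------
# deconvolution


def test_identity_deconvolution_flat_and_clean(ess_pair):
    sweep, inv = ess_pair
    res = deconvolve_ir(_with_tail(sweep.samples), inv)
    spec = magnitude_spectrum(res.linear_ir)
    flat = [spec.at(f) for f in np.geomspace(30, 15000, 200)]
    assert np.max(np.abs(flat)) < 0.2
    lin_energy = np.sum(res.linear_ir.samples**2)
    for k, h in res.harmonic_irs.items():
        assert 10 * np.log10(np.sum(h**2) / lin_energy) < -80.0


def test_cubic_waveshaper_shows_third_harmonic_only(ess_pair):
    """An odd-symmetric (cubic) nonlinearity produces a 3rd-harmonic
    response but no 2nd."""
    sweep, inv = ess_pair
    y = sweep.samples + 0.1 * sweep.samples**3
    res = deconvolve_ir(_with_tail(y), inv)
    e2 = np.sum(res.harmonic_irs[2] ** 2)
    e3 = np.sum(res.harmonic_irs[3] ** 2)
    assert 10 * np.log10(e3 / e2) > 10.0


def test_known_fir_recovered(ess_pair):
    sweep, inv = ess_pair
    fir = sps.firwin(401, [200, 8000], fs=RATE, pass_zero=False)
    res = deconvolve_ir(_with_tail(sps.lfilter(fir, 1, sweep.samples)), inv)
    h = res.linear_ir.samples
    start = len(h) - int(0.5 * RATE)
    err = np.sum((h[start: start + 401] - fir) ** 2) / np.sum(fir**2)
    assert 10 * np.log10(err) < -50.0


def test_deconvolve_rejects_short_recording(ess_pair):
    _, inv = ess_pair
    with pytest.raises(ValueError):
        deconvolve_ir(AudioSignal(np.zeros(1000), RATE), inv)


def test_end_to_end_lti_device_recovery(ess_pair):
    """Synthetic LTI playback chain: sweep → device → deconvolution
    recovers the analytic transfer function within 0.5 dB, 30 Hz–15 kHz."""
    sweep, inv = ess_pair
    sos = sps.butter(2, 100.0, btype="highpass", fs=RATE, output="sos")
    res = deconvolve_ir(_with_tail(sps.sosfilt(sos, sweep.samples)), inv)
    spec = magnitude_spectrum(res.linear_ir)
    freqs = np.geomspace(30, 15000, 300)
    mag = np.array([spec.at(f) for f in freqs])
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / RATE)
    assert np.max(np.abs(mag - 20 * np.log10(np.abs(h)))) < 0.5


def test_harmonic_amplitudes_of_waveshaped_sweep(ess_pair):
    sweep, inv = ess_pair
    y = sweep.samples + 0.05 * sweep.samples**2
    res = deconvolve_ir(_with_tail(y), inv)
    amps = harmonic_amplitudes_at(res, 1000.0)
    assert amps[0] > 0
    assert amps[1] > amps[2]  # quadratic shaper: 2nd harmonic dominates


# ---------------------------------------------------------------------------
# THD closed forms


def test_thd_zero_for_pure_fundamental():
    assert thd_percent([1.0, 0.0, 0.0]) == 0.0


def test_thd_minus_40db_second_harmonic_is_one_percent():
    a2 = 10 ** (-40 / 20)
    expected = 100 * a2 / np.sqrt(1 + a2**2)
    assert thd_percent([1.0, a2]) == pytest.approx(expected, abs=1e-9)
    assert thd_percent([1.0, a2]) == pytest.approx(1.0, abs=0.01)


def test_thd_equal_second_harmonic_is_70_percent():
    assert thd_percent([1.0, 1.0]) == pytest.approx(100 / np.sqrt(2), abs=1e-9)


def test_thd_scale_invariance():
    amps = [0.5, 0.03, 0.01, 0.004]
    assert thd_percent(amps) == pytest.approx(
        thd_percent([a * 7.3 for a in amps]), abs=1e-12
    )


def test_thd_zero_fundamental_undefined():
    with pytest.raises(UnmeasurableError):
        thd_percent([0.0, 0.1])


# ---------------------------------------------------------------------------
# smoothing, median, limits


def _flat_spectrum(level=0.0):
    f = log_frequency_grid(20, 20000)
    return MagnitudeSpectrum(f, np.full(f.shape, level))


def test_smoothing_preserves_flat_spectrum():
    sm = smooth_third_octave(_flat_spectrum())
    assert np.max(np.abs(sm.magnitude_db)) < 0.01


def test_smoothing_widens_spike_to_third_octave():
    spec = _flat_spectrum(-60.0)
    mags = spec.magnitude_db.copy()
    center = len(mags) // 2
    mags[center] = 0.0
    spiked = MagnitudeSpectrum(spec.freqs, mags)
    sm = smooth_third_octave(spiked)
    peak = np.max(sm.magnitude_db)
    above = sm.freqs[sm.magnitude_db > peak - 3.0]
    width_oct = np.log2(above[-1] / above[0])
    assert width_oct == pytest.approx(1 / 3, abs=0.12)


def test_smoothing_nearly_idempotent():
    """A response with sub-octave ripple changes little on a second
    smoothing pass."""
    f = log_frequency_grid(20, 20000)
    lf = np.log2(f)
    ripple = 4.0 * np.sin(2 * np.pi * lf / 4.0) + 1.0 * np.sin(2 * np.pi * lf + 1.0)
    once = smooth_third_octave(MagnitudeSpectrum(f, ripple))
    twice = smooth_third_octave(once)
    assert np.max(np.abs(twice.magnitude_db - once.magnitude_db)) < 0.5


def test_median_of_flat_spectrum():
    assert median_magnitude(_flat_spectrum(0.0)) == pytest.approx(0.0, abs=1e-9)


def test_median_ignores_minority_low_shelf():
    """A -30 dB shelf below 200 Hz covers only ~1/3 of the log axis, so
    the median stays at the passband level."""
    f = log_frequency_grid(20, 20000)
    mag = np.where(f < 200.0, -30.0, 0.0)
    assert median_magnitude(MagnitudeSpectrum(f, mag)) == pytest.approx(0.0, abs=0.01)


def test_median_shift_equivariance():
    f = log_frequency_grid(20, 20000)
    rng = np.random.default_rng(5)
    mag = rng.normal(0, 2, f.shape)
    a = median_magnitude(MagnitudeSpectrum(f, mag))
    b = median_magnitude(MagnitudeSpectrum(f, mag + 6.0))
    assert b - a == pytest.approx(6.0, abs=1e-9)


def test_median_requires_band_coverage():
    f = np.geomspace(100, 10000, 200)
    with pytest.raises(ValueError):
        median_magnitude(MagnitudeSpectrum(f, np.zeros_like(f)))


def _butterworth_hp_spectrum(fc=100.0, order=2):
    f = log_frequency_grid(20, 20000, 96)
    mag = 10 * np.log10(f ** (2 * order) / (f ** (2 * order) + fc ** (2 * order)))
    return MagnitudeSpectrum(f, mag)


def test_flat_spectrum_has_no_limits():
    lim = frequency_limits(_flat_spectrum(), 0.0)
    assert all(v == (None, None) for v in lim.values())


def test_butterworth_highpass_limit_frequencies():
    """2nd-order high-pass at 100 Hz: -3 dB limit ≈ 100 Hz, -6 dB limit
    ≈ 76 Hz (closed-form crossings), each within 1/24 octave."""
    spec = _butterworth_hp_spectrum()
    med = median_magnitude(spec)
    lim = frequency_limits(spec, med)
    tol = 2 ** (1 / 24)
    lo3 = lim[3.0][0]
    lo6 = lim[6.0][0]
    f6 = 100.0 * (10 ** -0.6 / (1 - 10 ** -0.6)) ** 0.25
    assert lo3 is not None and 100.0 / tol <= lo3 <= 100.0 * tol
    assert lo6 is not None and f6 / tol <= lo6 <= f6 * tol
    assert lim[3.0][1] is None


def test_limit_ordering_property():
    spec = _butterworth_hp_spectrum(fc=300.0, order=4)
    lim = frequency_limits(spec)
    lows = [lim[d][0] for d in (3.0, 6.0, 20.0)]
    assert all(l is not None for l in lows)
    assert lows[0] >= lows[1] >= lows[2]


# ---------------------------------------------------------------------------
# linearity


def _ir_from_sos(sos, gain_db, label="left_ear", n=4096):
    x = np.zeros(n)
    x[0] = 10 ** (gain_db / 20)
    return ImpulseResponse(sps.sosfilt(sos, x), RATE, label, gain_db)


def test_linear_device_has_no_linearity_flags():
    sos = sps.butter(2, 150, btype="highpass", fs=RATE, output="sos")
    meas = DeviceMeasurement({
        (g, "left_ear"): _ir_from_sos(sos, g) for g in (-12.0, -6.0, 0.0)
    })
    from halt.electroacoustics import linearity_deviation
    out = linearity_deviation(meas, reference_gain=-6.0)
    for g, (dev, flags) in out.items():
        band = (dev.freqs > 40) & (dev.freqs < 18000)
        assert np.max(np.abs(dev.magnitude_db[band])) < 0.1
        assert not flags[band].any()


def test_reference_gain_deviation_is_zero():
    sos = sps.butter(2, 150, btype="highpass", fs=RATE, output="sos")
    meas = DeviceMeasurement({
        (g, "left_ear"): _ir_from_sos(sos, g) for g in (-6.0, 0.0)
    })
    from halt.electroacoustics import linearity_deviation
    dev, flags = linearity_deviation(meas, reference_gain=-6.0)[-6.0]
    assert np.max(np.abs(dev.magnitude_db)) < 1e-9


def test_limiter_flags_high_gain():
    """A device that stops getting louder above a ceiling deviates
    beyond ±1 dB at high gains and gets flagged."""
    def limited_ir(gain_db):
        lin = 10 ** (gain_db / 20)
        ceiling = 10 ** (-6.0 / 20)
        amp = min(lin, ceiling * (lin / ceiling) ** 0.25)
        x = np.zeros(4096)
        x[0] = amp
        return ImpulseResponse(x, RATE, "left_ear", gain_db)

    meas = DeviceMeasurement({
        (g, "left_ear"): limited_ir(g) for g in (-24.0, -12.0, 0.0)
    })
    from halt.electroacoustics import linearity_deviation
    out = linearity_deviation(meas, reference_gain=-24.0)
    _, flags0 = out[0.0]
    _, flags_ref = out[-24.0]
    assert flags0.all()
    assert not flags_ref.any()


def test_linearity_requires_reference():
    from halt.electroacoustics import linearity_deviation
    meas = DeviceMeasurement({(0.0, "left_ear"): ImpulseResponse(np.eye(1)[0], RATE)})
    with pytest.raises(ValueError):
        linearity_deviation(meas, reference_gain=-6.0)


# ---------------------------------------------------------------------------
# stimulus Leq through impulse responses


def _delta_ir(scale=1.0):
    x = np.zeros(64)
    x[0] = scale
    return ImpulseResponse(x, RATE)


def test_identity_ir_reproduces_equivalent_level():
    stim = sine(1000.0, 1.0, 0.25)
    out = stimulus_leq_via_ir({("mono", "left_ear"): _delta_ir()}, stim, "Z")
    assert out["left_ear"] == pytest.approx(equivalent_level(stim, "Z"), abs=0.01)


def test_scaled_ir_shifts_leq():
    stim = sine(1000.0, 1.0, 0.25)
    base = stimulus_leq_via_ir({("mono", "left_ear"): _delta_ir()}, stim, "Z")
    scaled = stimulus_leq_via_ir({("mono", "left_ear"): _delta_ir(0.5)}, stim, "Z")
    assert base["left_ear"] - scaled["left_ear"] == pytest.approx(6.02, abs=0.05)


def test_coherent_crosstalk_adds_6db():
    """Identical signals on both channels through equal unity paths sum
    coherently: +6 dB versus a single path."""
    mono = sine(500.0, 1.0, 0.2)
    stereo = AudioSignal(np.column_stack([mono.samples, mono.samples]), RATE)
    single = stimulus_leq_via_ir({("left", "left_ear"): _delta_ir()}, stereo, "Z")
    both = stimulus_leq_via_ir(
        {("left", "left_ear"): _delta_ir(), ("right", "left_ear"): _delta_ir()},
        stereo, "Z",
    )
    assert both["left_ear"] - single["left_ear"] == pytest.approx(6.02, abs=0.05)


def test_leq_via_ir_rejects_rate_mismatch():
    stim = sine(1000.0, 0.5)
    with pytest.raises(ValueError):
        stimulus_leq_via_ir(
            {("mono", "left_ear"): ImpulseResponse([1.0], 44100)}, stim
        )


# ---------------------------------------------------------------------------
# low-frequency valuation criterion


def test_flat_device_valuation():
    """On a perfectly flat device the criterion equals the A-weighting:
    20 Hz is predicted inaudible (-50.5 < -40), 140 Hz audible."""
    spec = _flat_spectrum()
    v20, audible20 = lowfreq_valuation(spec, 20.0)
    v140, audible140 = lowfreq_valuation(spec, 140.0)
    assert v20 == pytest.approx(-50.5, abs=0.1) and not audible20
    assert v140 == pytest.approx(-14.8, abs=0.1) and audible140


def test_dip_device_valuation():
    f = log_frequency_grid(20, 20000)
    mag = np.where(np.abs(np.log2(f / 60.0)) < 0.3, -20.0, 0.0)
    spec = MagnitudeSpectrum(f, mag)
    value, audible = lowfreq_valuation(spec, 60.0, median=0.0)
    assert value == pytest.approx(-47.1, abs=0.1)
    assert not audible


def test_valuation_monotone_for_highpass_devices():
    """For a monotone high-pass response, predicted audibility never
    decreases with frequency."""
    for fc in (60.0, 120.0, 240.0):
        spec = _butterworth_hp_spectrum(fc=fc, order=4)
        med = median_magnitude(spec)
        flags = [lowfreq_valuation(spec, f, med)[1] for f in (20.0, 60.0, 100.0, 140.0)]
        assert flags == sorted(flags)


def test_valuation_rejects_out_of_band():
    with pytest.raises(ValueError):
        lowfreq_valuation(_flat_spectrum(), 5.0)
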