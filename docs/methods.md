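# Methods

This note documents the models, conventions and numerical choices behind
the toolkit, in the spirit of a measurement-procedure appendix: what each
component assumes, which parameters matter, and what the simulation-based
tests do and do not demonstrate.

## Level conventions

Digital full scale is 1.0 linear; a full-scale sine peaks at 0 dBFS. All
stimuli are referenced by **true peak** (dBTP), the inter-sample peak
estimated by 4× polyphase oversampling with an 81-tap low-pass
interpolator (common broadcast-metering practice; the test suite checks it
against a 512× sinc-interpolated oracle). True peak is used rather than
sample peak because band-limited signals overshoot between samples; the
stimulus ceiling of −1 dBFS true peak leaves headroom against clipping
from reconstruction overshoot.

**Integrated loudness** follows the gated, K-weighted broadcast measure:
K pre-filter (high shelf + high pass, designed parametrically so any
sample rate reproduces the published 48 kHz coefficients), 400 ms blocks
with 75 % overlap, an absolute gate at −70 LUFS and a relative gate 10 LU
below the absolutely-gated mean. Signals shorter than one block, or gated
out entirely (digital silence), raise `UnmeasurableError` rather than
returning a number.

**Equivalent levels** LAeq/LZeq are energy averages over the full signal;
Z-weighting is flat (Leq,Z = RMS level in dBFS). A-weighting exists in two
mutually-checked forms:

* the analytic pole-magnitude closed form (poles at 20.599, 107.653,
  737.862 and 12194.217 Hz, normalised to 0 dB at 1 kHz), used for tones
  and spectrum analysis. `a_weight_attenuation(..., nominal=True)`
  evaluates standard nominal band frequencies at their exact preferred
  frequencies (nominal 20 Hz → 19.953 Hz), which is how the published
  weighting tables are produced (−50.5 dB at nominal 20 Hz);
* a time-domain filter for Leq: the bilinear-transformed IIR cascaded
  with a 513-tap linear-phase FIR correction. The bilinear transform
  parks the prototype's two excess zeros at Nyquist, depressing the raw
  IIR response by ≈6 dB at 16 kHz for 48 kHz audio; the FIR is designed
  from the analytic/IIR magnitude ratio and restores agreement with the
  closed form to ~0.01 dB up to min(16 kHz, 0.9×Nyquist). At rates below
  ≈32 kHz the Nyquist zeros limit accuracy near the band top; the
  virtual lab uses the plain IIR consistently for its *relative* event
  levels, where this does not matter.

## Stimulus construction

Event timing is slot-based. Regularly presented events (the loud
deterrents of the loop task, the maskers of the low-frequency task) sit on
an exactly periodic grid; irregular events (soft noise segments, probe
tones) are assigned randomly to the intervals between them and placed with
jittered gaps, with a minimum silent gap of 0.2 s enforced everywhere (to
avoid forward/backward masking between events). The period is sized for
the worst-case interval occupancy, so the anchor grid stays periodic
regardless of the random assignment.

Durations are configuration parameters (`StimulusConfig`): noise events
0.5 s, probe tones 1.0 s, maskers 1.5 s, 10 ms raised-cosine ramps, 0.8 s
of jitter slack per slot. These are choices, not measurements: long enough
that events are comfortably countable, short enough that a full stimulus
set stays in the single-digit-minutes range.

Pink noise is generated in the spectral domain (1/√f amplitude shaping of
seeded white noise, brick-walled to 20 Hz–20 kHz or to Nyquist if lower),
giving exact −3 dB/octave density slope control. Because ramps and
band-limiting shift inter-sample peaks, each event is calibrated
iteratively (measure true peak, correct gain, re-measure; tolerance
0.05 dB). Calibrating by true peak rather than RMS means different noise
realisations of the same nominal level differ by a few tenths of a dB in
energy — visible in the virtual lab as per-event level spread.

Every constructor is deterministic in (parameters, seed): per-event RNG
streams are spawned from the package seed, so rendering is reproducible
and independent of evaluation order. `StimulusPackage.validate()` enforces
the type invariants (key/tally agreement, gaps, ceiling) and is exercised
over randomized seeds in the tests.

The ±3 dB manipulation duplicates shift all event levels; when a +3 dB
shift would push an at-ceiling event above −1 dBFS the default is to
refuse (`ClippingError`), with an explicit `shift_low_only` mode that
shifts only sub-ceiling events (the loud deterrents are already at the
ceiling and cannot carry the manipulation). In duplicates the answer key
is deliberately kept identical to the original: the key records what the
participant should count, which the level shift does not change.

## Scoring rules

All rules are pure functions. The accuracy classification takes the
expected count as the events at −46 dBFS and louder, because the loop
method anchors audibility at −46 dBFS; −52 dBFS events are
intended-inaudible. The three categories are modelled as an ordinal scale
(too_soft < accurate < too_loud) so a manipulation check is simply a
signed category comparison; a two-step jump (too_soft → too_loud) counts
as an increase. Undetectable cases are exactly the floor/ceiling ones: a
decrease from too_soft, an increase from too_loud. Unclassifiable stereo
counts return a `miscount` verdict rather than an error, since a counting
slip is an expected participant behaviour, and a swapped verdict combined
with a failed visual left/right control is flagged as a possible
right-left discrimination confound rather than a wiring fault.

## Electroacoustic analysis

Device measurement follows the exponential-sine-sweep method: the sweep's
log-frequency law places the k-th harmonic distortion product's impulse
response `L·ln k` seconds *before* the linear response (L = T/ln(f2/f1)),
so each is extracted with a Tukey window spanning half the gap to its
neighbours. The inverse filter is the time-reversed sweep with −6
dB/octave amplitude compensation, normalised so the deconvolved pulse has
unit *in-band spectral* magnitude (normalising by the time-domain peak
instead biases recovered transfer functions by the band-limitation
factor — about +1.2 dB for a 10 Hz–22 kHz sweep at 48 kHz). Edge fades
(a few periods of f1 at the start, 1 % of the duration at the end)
suppress spectral ripple; the remaining energy near the pulse is the
band-limited impulse's own 20 Hz-edge ringing, which spans roughly
±half an f1 period.

THD uses the distortion-factor convention (harmonic RMS over total RMS),
which is bounded by 100 %. Noise in the harmonic windows is *reported*,
not corrected: at very low drive levels the apparent THD rises again
because the noise floor is misattributed to harmonics — an artifact of
the short-time-Fourier family of methods that users should expect.

Magnitude responses are smoothed in the power domain on a uniform
log-frequency grid (192 points/octave) with a Gaussian kernel whose
half-power width is 1/3 octave. The spectral **median** is taken over a
log-spaced 20 Hz–20 kHz grid (48 points/octave), i.e. equal weight per
octave. Frequency limits (−3/−6/−20 dB below the median) are found by
scanning outward from the geometric mid-band (√(20·20000) ≈ 632 Hz) and
taking the first crossing per direction, with log-linear interpolation;
ripple re-crossings further out are ignored.

The low-frequency audibility criterion for a probe tone is
`(magnitude(f) − median) + A(f) ≥ −40 dB`: the device's deficit at the
tone frequency relative to its overall level, plus the ear's own
low-frequency insensitivity, compared against a −40 dB detection
threshold. On a perfectly flat device the criterion reduces to the
A-weighting itself, predicting 20 Hz inaudible (−50.5) and 60/100/140 Hz
audible.

Gain-linearity analysis compares smoothed magnitude responses across gain
settings: `deviation(g, f) = [mag(g, f) − mag(ref, f)] − (g − ref)`, with
|deviation| > 1 dB flagged. A linear time-invariant chain deviates by
zero; devices with built-in dynamics processing flag at high gains.

## Virtual lab

The virtual device is a parametric playback chain: wiring (stereo,
mono-summed, swapped), an optional Butterworth high-pass for the
low-frequency roll-off, an optional static nonlinearity (memoryless soft
limiter or polynomial waveshaper), and a sensitivity (dBSPL at 0 dBFS).
The virtual listener is a hard threshold on the A-weighted event level at
the ear, plus an optional ±1 miscount probability per trial; hard
thresholding keeps sessions deterministic at `miscount_prob = 0`, which
the recovery tests rely on. A soft (logistic) detection model would be
more realistic psychophysically but would turn every recovery statement
into a stochastic one.

A session runs the procedure in order: the feedback loop from a start
gain of −60 dB in 1.5 dB steps (a typical OS volume-step size; the
procedure text only says "smallest possible value"), capped at 40
attempts (enough steps to traverse the gain range; sessions that exhaust
the cap are recorded as non-completers), then the accuracy, stereo and
low-frequency tasks at the anchored gain. For linear devices per-event
levels are rendered once at 0 dB and shifted arithmetically per gain,
which makes thousand-session recovery runs cheap; nonlinear devices are
re-rendered per gain.

The built-in `laptop_model()` uses a 4th-order high-pass at 190 Hz. The
cutoff was chosen by margin analysis so that the loop-anchored session
reproduces the characteristic laptop audibility row (20/60 Hz inaudible,
100/140 Hz audible) with ≥3.5 dB of margin on the 60 Hz side over the
worst-case loop overshoot of one volume step: the session's audibility
boundary sits near A(f) + HP(f) ≈ −63 dB, because the probe tones are
calibrated by true peak (RMS ≈ −4 dBFS) while the loop anchors on pink
noise whose crest factor puts its A-weighted RMS ≈ 16 dB below its true
peak. A gentler cutoff (e.g. 100 Hz) leaves the 60 Hz tone audible to a
hard-threshold listener anchored this way. Note that for a real laptop
the tasks can also succeed through distortion artifacts that reproduce
none of the physical fundamental — a behaviour the linear device model
deliberately does not emulate.

What the simulations show — and what they do not: recovery of wiring,
audibility patterns and loop convergence demonstrates that the *decision
rules* are consistent with the *stimulus design* under a transparent
listener model. They do not validate human detection thresholds, room
acoustics, binaural effects, or real transducer nonlinearity; those
require the laboratory measurements the procedure was designed around.

## Calibration and statistics

The gain→SPL mapping fits a linear polynomial first and promotes to
quadratic only if the linear fit's **adjusted** R² (1 − (1−R²)(n−1)/(n−p−1))
falls below .99, with ties broken toward the simpler model; quadratic
candidacy needs at least four points, and fewer than three is an error.
Left/right-ear averaging is available as preprocessing. Predictions
outside the fitted gain range are returned but flagged as extrapolation.
NIOSH permissible exposure is `480 / 2^((L−85)/3)` minutes (85 dBA
recommended exposure limit over 8 h, 3-dB exchange rate).

Reliability statistics: Spearman–Brown prophecy `n·r / (1 + (n−1)·r)`;
log variability ratio `ln(sd_e/sd_c) + 1/(2(n_e−1)) − 1/(2(n_c−1))`
(small-sample corrected); empirical coefficient of variation `sd/mean`.
Test–retest correlations (Pearson or Spearman) carry Fisher-z 95 %
intervals; the Spearman interval uses the 1.06/(n−3) variance convention.
Correlation inference is frequentist throughout; Bayes-factor analyses
are out of scope, as the reliability statements of interest concern the
correlation magnitude.

## Problem sizes and tolerances

The test suite and the acceptance script use deliberately modest sizes
chosen for tightness of the corresponding statistical checks: 1000
simulated sessions for wiring recovery (error-free at zero miscount
probability), 100 random seeds for the stimulus validator (run at
24 kHz — the package invariants are rate-agnostic), 500 replicates for
calibration model selection and for correlation recovery (ρ = 0.9,
n = 160, mean estimate within ±0.02), and a 17-point gain sweep
(−24…0 dB in 1.5 dB steps) for coefficient recovery, where the 3-SE
coverage criterion accounts for Student-t tails at 14 residual degrees
of freedom. Numerical tolerances follow the component accuracies
documented above (e.g. 0.5 dB for the swept-sine round trip over
30 Hz–15 kHz, 0.1 LU for loudness against the block-equation oracle,
1/24 octave for frequency limits).

## Known limitations

* No binaural/HRTF or room-reverberation modelling in the virtual lab.
* The listener model has a single broadband A-weighted threshold; no
  per-band audiogram, masking model, or distortion-artifact detection.
* WAV I/O supports float32 and 16/32-bit integer PCM; 24-bit packed PCM
  is not written (float32 is the lossless default for pipelines).
* The time-domain A-weighting correction degrades near Nyquist for rates
  below ≈32 kHz (see above).
* Absolute SPL requires user-supplied gain→SPL measurement pairs; the
  toolkit cannot know a device's sensitivity on its own.
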