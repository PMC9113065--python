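# halt

A Python toolkit for the **headphone and loudspeaker test (HALT, part I)**:
an objective, counting-task-based procedure for controlling playback
characteristics in remote (internet-based) listening experiments.

When auditory experiments move online, the playback chain becomes an
uncontrolled confound: participants' volume settings, mono/stereo wiring and
loudspeaker low-frequency limits all vary, and none of them are observable
through self-report. HALT addresses this with short counting tasks whose
answer keys are known to the experimenter, so every decision rule is
criteria-based:

* **Level adjustment (loop method).** Soft pink-noise segments at −46 dBFS
  true peak appear at irregular times between loud deterrent segments at
  −1 dBFS. Participants count *all* segments. Reporting too few means the
  volume is too low ("raise it by the smallest step and repeat"); too many
  means "listen more carefully"; the exact count lets them proceed. The loop
  anchors every participant's volume at the audibility of the −46 dBFS events.
* **Adjustment accuracy.** Noise events at −52/−46/−40 dBFS true peak in
  shuffled order; with counts (3, 4, 2), the expected report is 6 (the −52
  events should be inaudible at an accurate setting), and counts of 5–7 are
  classified *accurate*, below 5 *too soft*, above 7 *too loud*. Comparing two
  classifications over time detects volume manipulations.
* **Mono/stereo check.** Loud noise events alternate irregularly between
  channels (never simultaneous, counts differing per channel); counting the
  right-channel events distinguishes stereo (right count), mono playback
  (grand total) and swapped channels (left count).
* **Low-frequency limit.** Pure tones at 20/60/100/140 Hz (−1 dBFS true peak)
  between loud pink-noise maskers; a tone counted correctly implies the device
  reproduces that frequency. The companion electroacoustic criterion predicts
  audibility when `(magnitude(f) − spectral median) + A-weighting(f) ≥ −40 dB`.

The package implements all of this as a library plus a thin `halt` CLI:
stimulus synthesis with answer keys (`stimulus_factory`), level/loudness/
weighting primitives — true peak via oversampling, gated integrated loudness,
LAeq/LZeq (`audio_levels`), the scoring rules (`scoring`), swept-sine device
analysis — Farina-style exponential sweep deconvolution, harmonic impulse
responses, THD, third-octave smoothing, median-relative frequency limits,
linearity flags (`electroacoustics`), digital-gain→SPL regression and NIOSH
exposure durations (`calibration`), reliability/heterogeneity statistics —
Spearman–Brown, ln VR, coefficient of variation (`psychometrics`), and a
seeded **virtual lab** of parametric devices and listeners that runs the whole
procedure end to end without human subjects (`virtual_lab`).

## Worked example

```python
from halt import stimulus_factory as sf, virtual_lab as vl
from halt.audio_levels import measure_levels

# 1. Build the loop stimulus with its answer key.
pkg = sf.make_loop_stimulus(n_low=8, n_high=4, seed=1)
report = measure_levels(pkg.signal)

# 2. Simulate a participant using a laptop-class device.
listener = vl.VirtualListener(threshold_dbspl=20.0, miscount_prob=0.0)
session = vl.simulate_session(vl.laptop_model(), listener, seed=4)
```

This prints (via the accompanying format calls):

```
loop stimulus: 12 events (8 soft at -46 dBFS, 4 loud at -1 dBFS)
true peak -1.00 dBTP, integrated loudness -14.4 LUFS, LAeq -21.6 dBFS
final gain -16.5 dB after 30 loop attempts
accuracy: accurate, stereo verdict: stereo
audible probe tones: [100, 140], lowest audible 100 Hz
```

Reading the numbers: the rendered stimulus honours the −1 dBFS true-peak
ceiling; the simulated listener needed 30 passes through the feedback loop
(raising the gain 1.5 dB each time from −60 dB) before all twelve segments
were audible; at that anchored volume the accuracy task lands in the
*accurate* band; the stereo task confirms intact two-channel wiring; and the
laptop model's steep low-frequency roll-off makes the 20 and 60 Hz probe
tones inaudible while 100 and 140 Hz are counted correctly — the audibility
signature of small built-in loudspeakers.

The same things are available from the shell:

```bash
halt synth loop --seed 1 --out loop_stim     # loop_stim.wav + loop_stim.key.json
halt simulate --scenario scenario.yaml --seed 4
halt calibrate --points gain_spl.tsv         # linear vs quadratic gain→SPL fit
```

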