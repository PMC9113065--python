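"""Virtual playback devices and listeners: seeded end-to-end session
simulation so every scoring and analysis rule is testable without human
subjects or measurement hardware.

A :class:`VirtualDevice` is a parametric playback chain — channel wiring
(stereo / mono-summed / swapped), a Butterworth high-pass modelling the
transducer's low-frequency roll-off, an optional static nonlinearity,
and a sensitivity mapping 0 dBFS to a sound pressure level.  A
:class:`VirtualListener` is a hard A-weighted audibility threshold plus
an optional ±1 miscount probability per trial.

:func:`simulate_session` runs the full procedure: the feedback volume
loop (raising the gain by the smallest volume step until the soft
segments are counted correctly), then the adjustment-accuracy, stereo
and low-frequency counting tasks, emitting the same response records the
scoring module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio_levels import AudioSignal, a_weighting_sos
from . import scoring
from .scoring import (
    AccuracyCategory,
    SessionResponses,
    classify_accuracy,
    classify_stereo,
    infer_lowfreq_audibility,
    loop_feedback,
)
from .stimulus_factory import (
    StimulusConfig,
    StimulusPackage,
    make_accuracy_stimulus,
    make_loop_stimulus,
    make_lowfreq_stimulus,
    make_stereo_stimulus,
    SUPPORTED_TONE_FREQS,
)

__all__ = [
    "VirtualDevice",
    "VirtualListener",
    "ProcedureConfig",
    "TaskStimuli",
    "SessionResult",
    "EventLevel",
    "render_playback",
    "simulate_count",
    "simulate_session",
    "SessionSimulator",
    "build_default_stimuli",
    "laptop_model",
    "flat_device",
]

SILENT_DB = -400.0  # stand-in for log(0) segments


@dataclass
class VirtualDevice:
    """Parametric playback chain."""

    highpass_hz: float | None = None
    highpass_order: int = 4
    wiring: str = "stereo"  # {stereo, mono_sum, swapped}
    sensitivity_dbspl: float = 100.0  # SPL at 0 dBFS, 1 kHz
    nonlinearity: dict | None = None  # {"kind": "compressor", ...} | {"kind": "poly", ...}
    label: str = "device"

    def __post_init__(self) -> None:
        if self.highpass_hz is not None and not (0 < self.highpass_hz < 20000):
            raise ValueError("high-pass cutoff must lie in (0, 20000) Hz")
        if self.wiring not in ("stereo", "mono_sum", "swapped"):
            raise ValueError(f"unknown wiring {self.wiring!r}")
        nl = self.nonlinearity
        if nl is not None and nl.get("kind") == "compressor" and nl.get("ratio", 1) < 1:
            raise ValueError("compressor ratio must be >= 1")

    @property
    def is_linear(self) -> bool:
        return self.nonlinearity is None

    def apply(self, signal: AudioSignal, gain_db: float = 0.0) -> AudioSignal:
        """Play a digital signal through the chain (output still in
        full-scale units; add ``sensitivity_dbspl`` for SPL)."""
        x = signal.as_2d().copy()
        if x.shape[1] == 1:
            x = np.repeat(x, 2, axis=1)
        if self.wiring == "mono_sum":
            mono = 0.5 * (x[:, 0] + x[:, 1])
            x = np.stack([mono, mono], axis=1)
        elif self.wiring == "swapped":
            x = x[:, ::-1]
        x = x * 10.0 ** (gain_db / 20.0)
        if self.highpass_hz is not None:
            sos = sps.butter(self.highpass_order, self.highpass_hz,
                             btype="highpass", fs=signal.rate, output="sos")
            x = sps.sosfilt(sos, x, axis=0)
        if self.nonlinearity is not None:
            x = _apply_nonlinearity(x, self.nonlinearity)
        return AudioSignal(x, signal.rate)


def _apply_nonlinearity(x: np.ndarray, spec: dict) -> np.ndarray:
    kind = spec.get("kind")
    if kind == "compressor":
        # Memoryless soft limiter: above threshold the output level grows
        # at 1/ratio of the input level.
        threshold = 10.0 ** (spec.get("threshold_dbfs", -10.0) / 20.0)
        ratio = float(spec.get("ratio", 4.0))
        mag = np.abs(x)
        over = mag > threshold
        out = x.copy()
        out[over] = np.sign(x[over]) * threshold * (mag[over] / threshold) ** (1.0 / ratio)
        return out
    if kind == "poly":
        coeffs = np.asarray(spec["coefficients"], dtype=float)
        return np.polynomial.polynomial.polyval(x, coeffs)
    raise ValueError(f"unknown nonlinearity {kind!r}")


def laptop_model(**overrides) -> VirtualDevice:
    """Built-in laptop-loudspeaker model: steep low-frequency roll-off
    (4th-order Butterworth high-pass at 190 Hz).  The cutoff is chosen so
    that, for a listener anchored by the feedback volume loop, probe
    tones at 20 and 60 Hz fall below the audibility threshold while 100
    and 140 Hz remain above it with a few dB of margin on each side —
    the audibility signature a small-membrane laptop speaker shows in
    practice."""
    params = dict(highpass_hz=190.0, highpass_order=4, label="laptop")
    params.update(overrides)
    return VirtualDevice(**params)


def flat_device(**overrides) -> VirtualDevice:
    params = dict(highpass_hz=None, label="flat")
    params.update(overrides)
    return VirtualDevice(**params)


@dataclass
class VirtualListener:
    """Hard audibility threshold on the A-weighted event level, with an
    optional probability of a ±1 counting slip per trial."""

    threshold_dbspl: float = 20.0
    miscount_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miscount_prob < 1.0:
            raise ValueError("miscount_prob must lie in [0, 1)")


@dataclass
class EventLevel:
    """A-weighted level of one stimulus event at the virtual ear, per
    output channel (dBSPL)."""

    kind: str
    channel: str  # designed channel of the event
    left: float
    right: float

    @property
    def max(self) -> float:
        return max(self.left, self.right)


def render_playback(pkg: StimulusPackage, device: VirtualDevice,
                    gain_db: float = 0.0):
    """Play a stimulus package through a device at a gain setting.

    Returns ``(event_levels, rendered)`` where ``event_levels`` is a list
    of :class:`EventLevel` (one per package event, in event order) and
    ``rendered`` is the device output as an :class:`AudioSignal`.
    """
    rendered = device.apply(pkg.signal, gain_db)
    weighted = sps.sosfilt(a_weighting_sos(rendered.rate), rendered.as_2d(), axis=0)
    rate = rendered.rate
    levels = []
    for e in pkg.events:
        i0 = int(round(e.onset * rate))
        i1 = min(i0 + int(round(e.duration * rate)), weighted.shape[0])
        seg = weighted[i0:i1]
        ms = np.mean(seg**2, axis=0)
        db = np.where(ms > 0, 10.0 * np.log10(np.maximum(ms, 1e-40)), SILENT_DB)
        levels.append(EventLevel(e.kind, e.channel,
                                 float(db[0]) + device.sensitivity_dbspl,
                                 float(db[1]) + device.sensitivity_dbspl))
    return levels, rendered


def simulate_count(event_levels, listener: VirtualListener, seed: int,
                   channel: str = "max") -> int:
    """Count the events a listener hears: those whose A-weighted level
    (on ``channel``: "left", "right" or the louder of both) exceeds the
    threshold, perturbed by ±1 with ``miscount_prob``."""
    def level(ev):
        if isinstance(ev, EventLevel):
            return {"left": ev.left, "right": ev.right, "max": ev.max}[channel]
        return float(ev)

    count = sum(1 for ev in event_levels
                if np.isfinite(level(ev)) and level(ev) > listener.threshold_dbspl)
    rng = np.random.default_rng(seed)
    if listener.miscount_prob > 0 and rng.random() < listener.miscount_prob:
        count = max(0, count + int(rng.choice([-1, 1])))
    return count


@dataclass
class ProcedureConfig:
    """Procedure parameters for a simulated session."""

    start_gain_db: float = -60.0
    volume_step_db: float = 1.5  # the "smallest possible" volume step
    max_loop_attempts: int = 40
    tone_freqs: tuple = SUPPORTED_TONE_FREQS


@dataclass
class TaskStimuli:
    """The stimulus set shared by all sessions of a simulated study."""

    loop: StimulusPackage
    accuracy: StimulusPackage
    stereo: StimulusPackage
    lowfreq: dict  # {freq: StimulusPackage}


def build_default_stimuli(seed: int = 0, rate: int = 48000,
                          tone_freqs: tuple = SUPPORTED_TONE_FREQS) -> TaskStimuli:
    cfg = StimulusConfig(rate=rate)
    return TaskStimuli(
        loop=make_loop_stimulus(8, 4, seed=seed, cfg=cfg),
        accuracy=make_accuracy_stimulus(seed=seed + 1, cfg=cfg),
        stereo=make_stereo_stimulus(5, 7, seed=seed + 2, cfg=cfg),
        lowfreq={
            f: make_lowfreq_stimulus(f, 5, seed=seed + 3 + i, cfg=cfg)
            for i, f in enumerate(tone_freqs)
        },
    )


@dataclass
class SessionResult:
    completed: bool
    final_gain_db: float
    loop_attempts: int
    responses: list
    accuracy_category: AccuracyCategory | None
    stereo_verdict: str | None
    lowfreq_audible: dict | None
    lowest_audible_hz: float | None


class SessionSimulator:
    """Runs many sessions against one device and stimulus set cheaply.

    For linear devices the per-event A-weighted levels are rendered once
    at 0 dB gain and shifted arithmetically for any other gain; nonlinear
    devices are re-rendered per gain.
    """

    def __init__(self, device: VirtualDevice, stimuli: TaskStimuli | None = None,
                 config: ProcedureConfig | None = None, rate: int = 48000,
                 stimulus_seed: int = 0):
        self.device = device
        self.config = config or ProcedureConfig()
        self.stimuli = stimuli or build_default_stimuli(
            stimulus_seed, rate, self.config.tone_freqs)
        self._cache: dict = {}

    def event_levels(self, task: str, gain_db: float):
        pkg = (self.stimuli.lowfreq[task[1]] if isinstance(task, tuple)
               else getattr(self.stimuli, task))
        key = task
        if self.device.is_linear:
            if key not in self._cache:
                self._cache[key] = render_playback(pkg, self.device, 0.0)[0]
            base = self._cache[key]
            return [EventLevel(ev.kind, ev.channel, ev.left + gain_db,
                               ev.right + gain_db) for ev in base]
        return render_playback(pkg, self.device, gain_db)[0]

    def run(self, listener: VirtualListener, seed: int) -> SessionResult:
        cfg = self.config
        rng_seeds = np.random.SeedSequence(seed).generate_state(64) & 0x7FFFFFFF
        responses: list[SessionResponses] = []

        # --- feedback loop for basic level adjustment
        gain = cfg.start_gain_db
        truth = self.stimuli.loop.key["total"]
        completed = False
        attempts = 0
        while attempts < cfg.max_loop_attempts:
            attempts += 1
            levels = self.event_levels("loop", gain)
            reported = simulate_count(levels, listener, int(rng_seeds[attempts % 64]))
            responses.append(SessionResponses("loop", attempts, reported))
            fb = loop_feedback(reported, truth)
            if fb == scoring.PROCEED:
                completed = True
                break
            if fb == scoring.INCREASE_VOLUME:
                gain += cfg.volume_step_db
        if not completed:
            return SessionResult(False, gain, attempts, responses,
                                 None, None, None, None)

        # --- adjustment accuracy
        acc_levels = self.event_levels("accuracy", gain)
        acc_reported = simulate_count(acc_levels, listener, int(rng_seeds[41]))
        responses.append(SessionResponses("accuracy", 1, acc_reported))
        acc_cat = classify_accuracy(acc_reported,
                                    self.stimuli.accuracy.key["per_level"])

        # --- stereo check: count events heard on the right channel
        st_levels = self.event_levels("stereo", gain)
        st_reported = simulate_count(st_levels, listener, int(rng_seeds[42]),
                                     channel="right")
        responses.append(SessionResponses("stereo", 1, st_reported))
        verdict = classify_stereo(st_reported, self.stimuli.stereo.key)

        # --- lower-frequency limit
        per_freq = {}
        for i, f in enumerate(cfg.tone_freqs):
            levels = self.event_levels(("lowfreq", f), gain)
            tone_levels = [ev for ev in levels if ev.kind == "tone"]
            reported = simulate_count(tone_levels, listener, int(rng_seeds[43 + i]))
            responses.append(SessionResponses(f"lowfreq_{f:g}", 1, reported))
            per_freq[f] = (reported, self.stimuli.lowfreq[f].key["total"])
        audible, lowest = infer_lowfreq_audibility(per_freq)

        return SessionResult(True, gain, attempts, responses, acc_cat,
                             verdict, audible, lowest)


def simulate_session(device: VirtualDevice, listener: VirtualListener,
                     stimuli: TaskStimuli | None = None,
                     config: ProcedureConfig | None = None,
                     seed: int = 0, rate: int = 48000) -> SessionResult:
    """Run one full simulated session (see :class:`SessionSimulator`)."""
    sim = SessionSimulator(device, stimuli, config, rate=rate)
    return sim.run(listener, seed)
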