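"""Deterministic, seeded construction of every counting-task stimulus
with its answer key.

The stimuli implement the level-adjustment and screening tasks of the
remote listening-test procedure:

* ``make_loop_stimulus`` — irregular soft pink-noise segments (-46 dBFS
  true peak) interleaved with regularly spaced loud deterrent segments
  (-1 dBFS); counting all segments drives the feedback volume loop.
* ``make_accuracy_stimulus`` — noise events at -52/-46/-40 dBFS true
  peak in shuffled order; the reported count classifies the adjusted
  volume as too soft / accurate / too loud.
* ``make_stereo_stimulus`` — events alternating irregularly between the
  left and right channel, never simultaneous, with differing counts per
  channel so mono and channel-swapped playback are distinguishable.
* ``make_lowfreq_stimulus`` — pure tones (-1 dBFS true peak) between
  regular loud pink-noise maskers, probing the device's low-frequency
  reproduction limit.

All stimuli respect a minimum 0.2 s silent gap between events (masking
avoidance) and a -1 dBFS true-peak ceiling (headroom against inter-
sample clipping).  Event true peaks are calibrated iteratively because
ramps and band-limiting shift inter-sample peaks.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .audio_levels import (
    AudioSignal,
    integrated_loudness,
    read_wav,
    true_peak_dbfs,
    write_wav,
)
from .errors import ClippingError, LayoutError

__all__ = [
    "SegmentEvent",
    "StimulusPackage",
    "StimulusConfig",
    "make_pink_noise",
    "make_loop_stimulus",
    "make_accuracy_stimulus",
    "make_stereo_stimulus",
    "make_lowfreq_stimulus",
    "normalize_music",
    "duplicate_with_offset",
]

CEILING_DBTP = -1.0
MIN_GAP_S = 0.2
ACCURACY_LEVELS = (-52.0, -46.0, -40.0)


@dataclass(frozen=True)
class SegmentEvent:
    """One auditory event inside a stimulus."""

    onset: float  # seconds
    duration: float  # seconds
    level_dbfs_tp: float  # true-peak level, dB re full scale
    channel: str = "both"  # {left, right, both}
    kind: str = "noise"  # {noise, tone, masker}
    tone_freq: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.level_dbfs_tp > CEILING_DBTP + 1e-9:
            raise ValueError("event level exceeds the -1 dBFS ceiling")
        if self.channel not in ("left", "right", "both"):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class StimulusConfig:
    """Timing defaults for event construction (seconds / Hz)."""

    rate: int = 48000
    noise_dur: float = 0.5
    masker_dur: float = 1.5
    tone_dur: float = 1.0
    ramp: float = 0.010
    gap: float = MIN_GAP_S
    jitter: float = 0.8  # extra per-slot slack jittered over (s)
    lead_in: float = 0.5
    lead_out: float = 0.5
    max_duration: float | None = None  # cap on total length (s), None = unlimited


@dataclass
class StimulusPackage:
    """A rendered stimulus plus its answer key."""

    signal: AudioSignal
    events: list[SegmentEvent]
    key: dict
    seed: int
    task: str

    def validate(self, tol_db: float = 0.1) -> None:
        """Check type invariants: key/tally agreement, minimum gaps and
        the true-peak ceiling.  Raises ``AssertionError`` on violation."""
        tallies = _tally(self.events)
        if self.task == "lowfreq":
            # the counting task asks for tones only; maskers are context
            tallies["total"] = sum(1 for e in self.events if e.kind == "tone")
        assert self.key["total"] == tallies["total"], "key/tally mismatch"
        assert self.key["per_channel"] == tallies["per_channel"]
        assert self.key["per_level"] == tallies["per_level"]
        ordered = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(ordered, ordered[1:]):
            gap = b.onset - (a.onset + a.duration)
            assert gap >= MIN_GAP_S - 1e-9, f"gap {gap:.3f}s below minimum"
        tp = true_peak_dbfs(self.signal)
        assert tp <= CEILING_DBTP + tol_db, f"true peak {tp:.2f} dBTP above ceiling"

    def save(self, basename: str | Path) -> None:
        """Write ``<basename>.wav`` (float32 PCM) and ``<basename>.key.json``."""
        basename = Path(basename)
        write_wav(basename.with_suffix(".wav"), self.signal)
        payload = {
            "task": self.task,
            "seed": self.seed,
            "rate": self.signal.rate,
            "key": self.key,
            "events": [asdict(e) for e in self.events],
        }
        basename.with_suffix(".key.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, basename: str | Path) -> "StimulusPackage":
        basename = Path(basename)
        payload = json.loads(basename.with_suffix(".key.json").read_text())
        sig = read_wav(basename.with_suffix(".wav"))
        events = [SegmentEvent(**e) for e in payload["events"]]
        key = payload["key"]
        key["per_level"] = {float(k): v for k, v in key["per_level"].items()}
        return cls(sig, events, key, payload["seed"], payload["task"])


def _tally(events: list[SegmentEvent]) -> dict:
    per_channel = {"left": 0, "right": 0, "both": 0}
    per_level: dict[float, int] = {}
    for e in events:
        per_channel[e.channel] += 1
        per_level[e.level_dbfs_tp] = per_level.get(e.level_dbfs_tp, 0) + 1
    return {"total": len(events), "per_channel": per_channel, "per_level": per_level}


def _make_key(events: list[SegmentEvent]) -> dict:
    return _tally(events)


# ---------------------------------------------------------------------------
# waveform primitives


def _raised_cosine_ramps(x: np.ndarray, rate: int, ramp: float) -> np.ndarray:
    n = min(int(round(ramp * rate)), x.shape[0] // 2)
    if n > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))
        x = x.copy()
        x[:n] *= win
        x[-n:] *= win[::-1]
    return x


def _pink_burst(n: int, rate: int, rng: np.random.Generator,
                band: tuple[float, float] = (20.0, 20000.0)) -> np.ndarray:
    """Band-limited pink noise (1/f power spectrum), unit-normalised."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    lo, hi = band[0], min(band[1], 0.999 * rate / 2)
    in_band = (freqs >= lo) & (freqs <= hi)
    shape[in_band] = 1.0 / np.sqrt(freqs[in_band])
    x = np.fft.irfft(spec * shape, n)
    return x / np.max(np.abs(x))


def _calibrate_true_peak(x: np.ndarray, rate: int, target_db: float,
                         tol: float = 0.05, max_iter: int = 8) -> np.ndarray:
    """Iteratively scale ``x`` so its inter-sample peak hits ``target_db``."""
    for _ in range(max_iter):
        tp = true_peak_dbfs(AudioSignal(x, rate))
        err = target_db - tp
        if abs(err) <= tol:
            return x
        x = x * 10.0 ** (err / 20.0)
    return x


def _render_event_waveform(event: SegmentEvent, rate: int, ramp: float,
                           rng: np.random.Generator) -> np.ndarray:
    n = int(round(event.duration * rate))
    if event.tone_freq is not None:
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * event.tone_freq * t)
    else:
        x = _pink_burst(n, rate, rng)
    x = _raised_cosine_ramps(x, rate, ramp)
    return _calibrate_true_peak(x, rate, event.level_dbfs_tp)


def _render_events(events: list[SegmentEvent], seed: int, cfg: StimulusConfig,
                   channels: int = 1) -> AudioSignal:
    """Render an event list into a signal.  Each event gets its own child
    RNG stream (spawned from the package seed and the event index) so the
    result is bit-reproducible and independent of rendering order."""
    end = max(e.onset + e.duration for e in events) + cfg.lead_out
    if cfg.max_duration is not None and end > cfg.max_duration:
        raise LayoutError(
            f"events need {end:.2f}s but max_duration is {cfg.max_duration:.2f}s"
        )
    n = int(round(end * cfg.rate))
    buf = np.zeros(n if channels == 1 else (n, channels))
    streams = np.random.SeedSequence(seed).spawn(len(events))
    for idx, event in enumerate(sorted(events, key=lambda e: e.onset)):
        rng = np.random.default_rng(streams[idx])
        x = _render_event_waveform(event, cfg.rate, cfg.ramp, rng)
        i0 = int(round(event.onset * cfg.rate))
        seg = slice(i0, i0 + x.shape[0])
        if channels == 1:
            buf[seg] += x
        elif event.channel == "both":
            buf[seg, 0] += x
            buf[seg, 1] += x
        else:
            buf[seg, 0 if event.channel == "left" else 1] += x
    return AudioSignal(buf, cfg.rate)


# ---------------------------------------------------------------------------
# schedulers


def _sequential_onsets(durations: list[float], cfg: StimulusConfig,
                       rng: np.random.Generator) -> list[float]:
    """Events in order, separated by the minimum gap plus uniform jitter."""
    onsets = []
    t = cfg.lead_in + rng.uniform(0.0, cfg.jitter)
    for d in durations:
        onsets.append(t)
        t += d + cfg.gap + rng.uniform(0.0, cfg.jitter)
    return onsets


def _regular_grid_layout(n_irregular: int, n_regular: int, irr_dur: float,
                         reg_dur: float, cfg: StimulusConfig,
                         rng: np.random.Generator):
    """Regularly spaced anchor events with jittered extra events packed
    into the intervals between them.

    Returns (regular_onsets, irregular_onsets).  The anchor period is
    sized so each interval can hold its worst-case share of irregular
    events with minimum gaps plus jitter slack, keeping the anchor grid
    exactly periodic regardless of how the irregular events fall.
    """
    if n_irregular < 1 or n_regular < 1:
        raise ValueError("need at least one event of each kind")
    cap = math.ceil(n_irregular / n_regular)
    slack = cfg.jitter
    period = reg_dur + cfg.gap + cap * (irr_dur + cfg.gap) + slack
    reg_onsets = [cfg.lead_in + i * period for i in range(n_regular)]
    # Assign each irregular event to an anchor interval, at most `cap` per
    # interval, uniformly at random.
    slots = np.repeat(np.arange(n_regular), cap)
    chosen = rng.permutation(slots)[:n_irregular]
    irr_onsets: list[float] = []
    for i in range(n_regular):
        k = int(np.sum(chosen == i))
        if k == 0:
            continue
        # Split this interval's slack into k+1 jittered gaps.
        parts = rng.uniform(0.2, 1.0, size=k + 1)
        parts = parts / parts.sum() * slack
        t = reg_onsets[i] + reg_dur + cfg.gap + parts[0]
        for j in range(k):
            irr_onsets.append(t)
            t += irr_dur + cfg.gap + parts[j + 1]
    return reg_onsets, irr_onsets


# ---------------------------------------------------------------------------
# public constructors


def make_pink_noise(duration: float, level_dbfs_tp: float = CEILING_DBTP,
                    seed: int = 0, rate: int = 48000) -> AudioSignal:
    """Band-limited (20 Hz–20 kHz) pink noise calibrated to a true-peak
    level.  Same seed, same parameters → bit-identical output."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if level_dbfs_tp > 0:
        raise ValueError("level must not exceed full scale")
    rng = np.random.default_rng(seed)
    x = _pink_burst(int(round(duration * rate)), rate, rng)
    x = _calibrate_true_peak(x, rate, level_dbfs_tp)
    return AudioSignal(x, rate)


def make_loop_stimulus(n_low: int = 8, n_high: int = 4, seed: int = 0,
                       cfg: StimulusConfig | None = None) -> StimulusPackage:
    """Feedback-loop stimulus: ``n_low`` soft (-46 dBFS) noise segments at
    irregular times between ``n_high`` loud (-1 dBFS) deterrent segments
    on an exactly regular grid.  The answer key counts all segments."""
    if n_low < 1 or n_high < 1:
        raise ValueError("n_low and n_high must be at least 1")
    cfg = cfg or StimulusConfig()
    rng = np.random.default_rng(seed)
    reg, irr = _regular_grid_layout(n_low, n_high, cfg.noise_dur,
                                    cfg.masker_dur, cfg, rng)
    events = [
        SegmentEvent(t, cfg.masker_dur, CEILING_DBTP, "both", "noise")
        for t in reg
    ] + [
        SegmentEvent(t, cfg.noise_dur, -46.0, "both", "noise") for t in irr
    ]
    events.sort(key=lambda e: e.onset)
    sig = _render_events(events, seed, cfg)
    return StimulusPackage(sig, events, _make_key(events), seed, "loop")


def make_accuracy_stimulus(counts_by_level: dict[float, int] | None = None,
                           seed: int = 0,
                           cfg: StimulusConfig | None = None) -> StimulusPackage:
    """Adjustment-accuracy stimulus: noise events at -52/-46/-40 dBFS true
    peak in seeded shuffled order.  Defaults to the worked example of
    3 x -52, 4 x -46 and 2 x -40 (nine events)."""
    counts_by_level = counts_by_level or {-52.0: 3, -46.0: 4, -40.0: 2}
    counts = {float(k): int(v) for k, v in counts_by_level.items()}
    if set(counts) != set(ACCURACY_LEVELS):
        raise ValueError(f"levels must be exactly {ACCURACY_LEVELS}")
    if any(v < 1 for v in counts.values()):
        raise ValueError("need at least one event per level")
    cfg = cfg or StimulusConfig()
    rng = np.random.default_rng(seed)
    levels = [lvl for lvl, k in counts.items() for _ in range(k)]
    order = rng.permutation(len(levels))
    onsets = _sequential_onsets([cfg.noise_dur] * len(levels), cfg, rng)
    events = [
        SegmentEvent(onsets[i], cfg.noise_dur, levels[order[i]], "both", "noise")
        for i in range(len(levels))
    ]
    sig = _render_events(events, seed, cfg)
    return StimulusPackage(sig, events, _make_key(events), seed, "accuracy")


def make_stereo_stimulus(n_left: int = 5, n_right: int = 7, seed: int = 0,
                         cfg: StimulusConfig | None = None) -> StimulusPackage:
    """Stereo-check stimulus: loud noise events alternating irregularly
    between channels, never simultaneous.  The per-channel counts must
    differ so mono and swapped playback give distinct total counts."""
    if n_left < 1 or n_right < 1:
        raise ValueError("need at least one event per channel")
    if n_left == n_right:
        raise ValueError("the number of events per channel must differ")
    cfg = cfg or StimulusConfig()
    rng = np.random.default_rng(seed)
    channels = ["left"] * n_left + ["right"] * n_right
    channels = [channels[i] for i in rng.permutation(len(channels))]
    onsets = _sequential_onsets([cfg.noise_dur] * len(channels), cfg, rng)
    events = [
        SegmentEvent(t, cfg.noise_dur, CEILING_DBTP, ch, "noise")
        for t, ch in zip(onsets, channels)
    ]
    sig = _render_events(events, seed, cfg, channels=2)
    key = _make_key(events)
    key["left"] = key["per_channel"]["left"]
    key["right"] = key["per_channel"]["right"]
    return StimulusPackage(sig, events, key, seed, "stereo")


SUPPORTED_TONE_FREQS = (20.0, 60.0, 100.0, 140.0)


def make_lowfreq_stimulus(tone_freq: float, n_tones: int = 5, seed: int = 0,
                          cfg: StimulusConfig | None = None,
                          allowed_freqs: tuple = SUPPORTED_TONE_FREQS) -> StimulusPackage:
    """Low-frequency-limit stimulus: ``n_tones`` pure tones at -1 dBFS
    true peak jittered between regularly spaced loud pink-noise maskers."""
    if float(tone_freq) not in {float(f) for f in allowed_freqs}:
        raise ValueError(f"tone_freq must be one of {allowed_freqs}")
    if n_tones < 1:
        raise ValueError("n_tones must be at least 1")
    cfg = cfg or StimulusConfig()
    rng = np.random.default_rng(seed)
    n_maskers = max(2, math.ceil(n_tones / 2) + 1)
    reg, irr = _regular_grid_layout(n_tones, n_maskers, cfg.tone_dur,
                                    cfg.masker_dur, cfg, rng)
    events = [
        SegmentEvent(t, cfg.masker_dur, CEILING_DBTP, "both", "masker")
        for t in reg
    ] + [
        SegmentEvent(t, cfg.tone_dur, CEILING_DBTP, "both", "tone", float(tone_freq))
        for t in irr
    ]
    events.sort(key=lambda e: e.onset)
    sig = _render_events(events, seed, cfg)
    key = _make_key(events)
    key["total"] = n_tones  # the task counts tones only
    key["n_maskers"] = n_maskers
    return StimulusPackage(sig, events, key, seed, "lowfreq")


def normalize_music(signal: AudioSignal, target_lufs: float) -> AudioSignal:
    """Gain a music-like signal to an integrated-loudness target.

    Raises ``ClippingError`` when the required gain would push the true
    peak above 0 dBFS (the clipping limit) — the classical-music case
    where a low average level coexists with peaks near full scale."""
    measured = integrated_loudness(signal)
    gain = target_lufs - measured
    if true_peak_dbfs(signal) + gain > 0.0:
        raise ClippingError(
            f"gain of {gain:+.1f} dB to reach {target_lufs} LUFS would exceed 0 dBFS"
        )
    return signal.gain(gain)


def duplicate_with_offset(pkg: StimulusPackage, offset: float,
                          mode: str = "strict",
                          cfg: StimulusConfig | None = None) -> StimulusPackage:
    """Level-manipulation duplicate: shift all event levels by ``offset``
    dB (the ±3 dB manipulation-check conditions), keeping the key.

    ``mode="strict"`` raises ``ClippingError`` if any event would exceed
    the -1 dBFS ceiling; ``mode="shift_low_only"`` instead leaves
    at-ceiling events untouched and re-renders.
    """
    over = [e for e in pkg.events if e.level_dbfs_tp + offset > CEILING_DBTP + 1e-9]
    if mode == "strict":
        if over:
            raise ClippingError(
                f"{len(over)} event(s) would exceed the {CEILING_DBTP} dBFS ceiling"
            )
        sig = pkg.signal.gain(offset)
        events = [
            SegmentEvent(e.onset, e.duration, e.level_dbfs_tp + offset,
                         e.channel, e.kind, e.tone_freq)
            for e in pkg.events
        ]
    elif mode == "shift_low_only":
        cfg = cfg or StimulusConfig(rate=pkg.signal.rate)
        events = [
            e if e in over else SegmentEvent(
                e.onset, e.duration, min(e.level_dbfs_tp + offset, CEILING_DBTP),
                e.channel, e.kind, e.tone_freq)
            for e in pkg.events
        ]
        sig = _render_events(events, pkg.seed, cfg,
                             channels=pkg.signal.channels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StimulusPackage(sig, events, dict(pkg.key), pkg.seed, pkg.task)
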