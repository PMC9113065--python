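"""Objective decision rules applied to participants' reported counts.

Every rule is a pure function of the reported count and the stimulus
answer key, so all inclusion/exclusion decisions are criteria-based
rather than self-report based:

* the feedback loop for basic level adjustment,
* the three-category adjustment-accuracy classification,
* the manipulation (volume-change) check between two classifications,
* mono / stereo / swapped-channel detection,
* low-frequency audibility inference, and
* aggregation into summary rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import pandas as pd

__all__ = [
    "SessionResponses",
    "AccuracyCategory",
    "StereoVerdict",
    "LoopFeedback",
    "loop_feedback",
    "classify_accuracy",
    "detect_manipulation",
    "manipulation_detectable",
    "classify_stereo",
    "infer_lowfreq_audibility",
    "score_visual_lr",
    "summarize_sessions",
    "percent",
    "MAX_LOOP_ATTEMPTS",
]

#: Default cap on feedback-loop repetitions before a session is recorded
#: as a non-completer (the procedure itself does not prescribe one).
MAX_LOOP_ATTEMPTS = 5


class AccuracyCategory(IntEnum):
    """Ordered volume-setting categories; the ordering carries the
    direction information used by the manipulation check."""

    TOO_SOFT = 0
    ACCURATE = 1
    TOO_LOUD = 2


class StereoVerdict(str):
    pass


STEREO, MONO, SWAPPED, MISCOUNT = "stereo", "mono", "swapped", "miscount"


class LoopFeedback(str):
    pass


PROCEED = "proceed"
REPEAT_LISTEN = "repeat_listen_carefully"
INCREASE_VOLUME = "increase_volume_and_repeat"


@dataclass
class SessionResponses:
    """One participant response record."""

    task: str
    trial: int
    reported_count: int
    loudness_rating: str | None = None  # {too_soft, comfortable, too_loud}
    visual_lr_correct: bool | None = None

    def __post_init__(self) -> None:
        if self.reported_count < 0:
            raise ValueError("reported_count must be non-negative")


def loop_feedback(reported: int, truth: int) -> str:
    """Feedback-loop rule: the true count means progress; too many means
    listen again more carefully; too few means the volume is too low, so
    raise it by the smallest step and repeat."""
    if reported < 0 or truth < 0:
        raise ValueError("counts must be non-negative")
    if reported == truth:
        return PROCEED
    return REPEAT_LISTEN if reported > truth else INCREASE_VOLUME


def classify_accuracy(reported: int, counts_by_level: dict[float, int],
                      tolerance: int = 1) -> AccuracyCategory:
    """Classify a reported count as too soft / accurate / too loud.

    The expected count is the number of events at -46 dBFS and louder
    (-40 dBFS): the preceding feedback loop anchors audibility at
    -46 dBFS, while -52 dBFS events are intended to be inaudible at an
    accurately set volume.  A ±``tolerance`` band around the expected
    count counts as accurate."""
    counts = {float(k): int(v) for k, v in counts_by_level.items()}
    for lvl in (-52.0, -46.0, -40.0):
        if lvl not in counts:
            raise ValueError(f"missing level {lvl} in counts_by_level")
    expected = counts[-46.0] + counts[-40.0]
    if reported > expected + tolerance:
        return AccuracyCategory.TOO_LOUD
    if reported < expected - tolerance:
        return AccuracyCategory.TOO_SOFT
    return AccuracyCategory.ACCURATE


def detect_manipulation(baseline: AccuracyCategory,
                        later: AccuracyCategory) -> str:
    """Direction of an inferred volume change between two classifications
    on the ordinal too_soft < accurate < too_loud scale."""
    if later == baseline:
        return "none"
    return "increased" if later > baseline else "decreased"


def manipulation_detectable(baseline: AccuracyCategory, direction: str) -> bool:
    """Whether a manipulation in ``direction`` ("increase"/"decrease") is
    detectable from ``baseline``: at the bottom category no further
    decrease can register, at the top no further increase."""
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")
    if baseline == AccuracyCategory.TOO_SOFT and direction == "decrease":
        return False
    if baseline == AccuracyCategory.TOO_LOUD and direction == "increase":
        return False
    return True


def classify_stereo(reported: int, key: dict) -> str:
    """Stereo-task verdict from the count of events heard on the right
    channel: the right-channel count means stereo, the grand total means
    mono (both channels summed into one), the left-channel count means
    swapped channels, anything else is a miscount."""
    left, right, total = int(key["left"]), int(key["right"]), int(key["total"])
    if left == right or total in (left, right):
        raise ValueError("key counts must be pairwise distinguishable")
    if reported == right:
        return STEREO
    if reported == total:
        return MONO
    if reported == left:
        return SWAPPED
    return MISCOUNT


def infer_lowfreq_audibility(per_freq_responses: dict[float, tuple[int, int]]):
    """Per-frequency audibility from (reported, truth) count pairs.

    A frequency counts as audible only when the reported tone count
    equals the truth — the tones can only be counted if the device
    reproduces them.  Returns ``(audible_map, lowest_audible)`` where
    ``lowest_audible`` is None when no frequency was audible."""
    if not per_freq_responses:
        raise ValueError("empty response map")
    audible = {
        float(f): reported == truth
        for f, (reported, truth) in sorted(per_freq_responses.items())
    }
    lowest = min((f for f, ok in audible.items() if ok), default=None)
    return audible, lowest


def score_visual_lr(response: str, truth: str) -> bool:
    """Visual left/right control task (circle-vs-triangle position); used
    to separate swapped-channel verdicts from right-left-discrimination
    difficulties."""
    if response not in ("left", "right") or truth not in ("left", "right"):
        raise ValueError("labels must be 'left' or 'right'")
    return response == truth


def percent(k: int, n: int) -> float:
    """Percentage 100*k/n rounded to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * k / n, 1)


def summarize_sessions(records) -> pd.DataFrame:
    """Aggregate scored sessions into counts and percentages.

    ``records`` is an iterable of mappings (or a DataFrame) with at least
    ``task`` and ``verdict`` columns; a ``discrimination_confound``
    column is added for swapped verdicts whose visual control failed.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no session records")
    if {"verdict", "visual_lr_correct"} <= set(df.columns):
        df = df.copy()
        df["discrimination_confound"] = (
            (df["verdict"] == SWAPPED) & (df["visual_lr_correct"] == False)  # noqa: E712
        )
    rows = []
    for task, group in df.groupby("task"):
        n = len(group)
        for verdict, k in group["verdict"].value_counts().items():
            rows.append({
                "task": task,
                "verdict": verdict,
                "count": int(k),
                "n": n,
                "percent": percent(int(k), n),
            })
    return pd.DataFrame(rows).sort_values(["task", "verdict"]).reset_index(drop=True)
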