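"""Reliability and heterogeneity statistics for adjusted-level data.

The level-adjustment procedures produce, per participant and device, an
adjusted A-weighted sound pressure level.  Comparing adjustment methods
rests on variance-heterogeneity effect sizes — the log variability
ratio ln VR and the empirical coefficient of variation v — plus
test–retest correlations and the Spearman–Brown prophecy for test
lengthening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UnmeasurableError

__all__ = [
    "GroupStats",
    "ln_variability_ratio",
    "coefficient_of_variation",
    "spearman_brown",
    "test_retest",
    "describe_levels",
]


@dataclass
class GroupStats:
    """Descriptive statistics of one group of adjusted levels (dB)."""

    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    range: float
    p25: float
    p50: float
    p75: float


def ln_variability_ratio(sd_e: float, n_e: int, sd_c: float, n_c: int) -> float:
    """Log variability ratio with small-sample correction:

    ``ln(sd_e / sd_c) + 1/(2(n_e - 1)) - 1/(2(n_c - 1))``

    Negative values mean the experimental method (e) is less variable
    than the comparison method (c)."""
    if sd_e <= 0 or sd_c <= 0:
        raise UnmeasurableError("standard deviations must be positive")
    if n_e < 2 or n_c < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    return math.log(sd_e / sd_c) + 1.0 / (2 * (n_e - 1)) - 1.0 / (2 * (n_c - 1))


def coefficient_of_variation(sd: float, mean: float) -> float:
    """Empirical coefficient of variation v = sd / mean (mean > 0)."""
    if mean <= 0:
        raise UnmeasurableError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return sd / mean


def spearman_brown(r: float, n: float) -> float:
    """Spearman–Brown prophecy: reliability of a test lengthened by
    factor ``n``: ``r_k = n*r / (1 + (n-1)*r)``."""
    if not 0 < r <= 1:
        raise ValueError("r must be in (0, 1]")
    if n < 1:
        raise ValueError("length factor n must be >= 1")
    return n * r / (1.0 + (n - 1.0) * r)


def test_retest(pairs, method: str = "spearman", conf: float = 0.95):
    """Test–retest correlation with a Fisher-z confidence interval.

    ``pairs`` is an (n, 2) array of (test, retest) values.  ``method`` is
    "pearson" or "spearman" (rank-based; its Fisher-z standard error uses
    the 1.06/(n-3) variance convention).  Returns ``(r, (lo, hi))``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = arr.shape[0]
    if n < 4:
        raise InsufficientDataError("need at least 4 complete pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise UnmeasurableError("constant input has no defined correlation")
    if method == "pearson":
        r = float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)
        var = 1.0 / (n - 3)
    elif method == "spearman":
        r = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
        var = 1.06 / (n - 3)
    else:
        raise ValueError(f"unknown method {method!r}")
    if abs(r) >= 1.0:
        return r, (r, r)
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + conf / 2) * math.sqrt(var)
    return r, (math.tanh(z - half), math.tanh(z + half))


def describe_levels(levels) -> GroupStats:
    """Descriptive statistics (mean, SD, median, range, quartiles) of a
    list of adjusted levels in dB."""
    x = np.asarray(levels, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 levels")
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    return GroupStats(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        minimum=float(x.min()),
        maximum=float(x.max()),
        range=float(x.max() - x.min()),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
    )
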