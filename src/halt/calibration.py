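"""Digital gain → sound pressure level mapping and exposure safety.

A measured set of (gain in dB of digital amplification, level in dBSPL)
pairs is fitted with the simplest polynomial that reaches an adjusted
R² of at least .99: linear first, quadratic only if the linear fit falls
short.  Well-behaved amplifier/transducer chains are linear in this
coordinate system; devices with built-in dynamics processing (e.g.
laptop loudspeaker protection) need the quadratic term.

Exposure safety uses the NIOSH recommended exposure limit: 85 dBA over
8 hours with a 3-dB exchange rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

__all__ = [
    "GainLevelCurve",
    "fit_gain_to_spl",
    "predict_spl",
    "niosh_permissible_minutes",
    "average_ears",
    "ADJ_R2_THRESHOLD",
]

ADJ_R2_THRESHOLD = 0.99


@dataclass
class GainLevelCurve:
    """A fitted gain→SPL regression.

    ``coefficients`` are polynomial coefficients in ascending order
    (intercept first), as fitted on the raw gain values.
    """

    points: np.ndarray  # shape (n, 2): (gain_db, level_db)
    weighting: str  # {"A", "Z"}
    model: str  # {"linear", "quadratic"}
    coefficients: np.ndarray
    adjusted_r2: float
    r2: float
    coef_se: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def gain_range(self) -> tuple[float, float]:
        return float(self.points[:, 0].min()), float(self.points[:, 0].max())


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _polyfit(x: np.ndarray, y: np.ndarray, degree: int):
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    pred = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n, p = len(x), degree
    dof = n - p - 1
    if dof > 0:
        sigma2 = ss_res / dof
        design = np.vander(x, p + 1, increasing=True)
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(p + 1, np.nan)
    return coeffs, r2, se


def average_ears(left_points, right_points) -> np.ndarray:
    """Average left- and right-ear level measurements per gain value (the
    standard preprocessing before fitting a single curve per device)."""
    left = np.asarray(left_points, float)
    right = np.asarray(right_points, float)
    if left.shape != right.shape or not np.allclose(left[:, 0], right[:, 0]):
        raise ValueError("left/right measurements must share gain values")
    out = left.copy()
    out[:, 1] = 0.5 * (left[:, 1] + right[:, 1])
    return out


def fit_gain_to_spl(points, weighting: str = "A") -> GainLevelCurve:
    """Fit the simplest gain→SPL regression with adjusted R² ≥ .99.

    A linear model is fitted first and kept if its adjusted R² reaches
    the threshold (ties break toward the simpler model); otherwise a
    quadratic is fitted (requires ≥ 4 points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): (gain_db, level_db)")
    if pts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (gain, level) points")
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    if np.any(np.diff(pts[:, 0]) <= 0):
        raise ValueError("gain values must be strictly increasing")
    x, y = pts[:, 0], pts[:, 1]

    coeffs, r2, se = _polyfit(x, y, 1)
    adj = _adjusted_r2(r2, len(x), 1)
    if adj >= ADJ_R2_THRESHOLD or len(x) < 4:
        return GainLevelCurve(pts, weighting, "linear", coeffs, adj, r2, se)
    coeffs, r2, se = _polyfit(x, y, 2)
    adj = _adjusted_r2(r2, len(x), 2)
    return GainLevelCurve(pts, weighting, "quadratic", coeffs, adj, r2, se)


def predict_spl(curve: GainLevelCurve, gain: float,
                extrapolation_margin: float = 0.0):
    """Evaluate a fitted curve at ``gain`` dB.

    Returns ``(level_db, extrapolated)`` where ``extrapolated`` flags a
    gain outside the fitted range ± ``extrapolation_margin``.
    """
    lo, hi = curve.gain_range
    extrapolated = not (lo - extrapolation_margin <= gain <= hi + extrapolation_margin)
    level = float(np.polynomial.polynomial.polyval(gain, curve.coefficients))
    return level, extrapolated


def niosh_permissible_minutes(level_dba: float, rel_dba: float = 85.0,
                              base_minutes: float = 480.0,
                              exchange_db: float = 3.0) -> float:
    """Permissible exposure duration in minutes under the NIOSH criteria
    (REL 85 dBA over 8 h, 3-dB exchange rate):
    ``T = 480 / 2**((L - 85) / 3)``."""
    if level_dba < 0:
        raise ValueError("level must be non-negative")
    return base_minutes / 2.0 ** ((level_dba - rel_dba) / exchange_db)
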