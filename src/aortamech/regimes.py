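"""Two-regime tangent-stiffness analysis of J-shaped stress–stretch curves.

Arterial stress–stretch responses show a compliant elastin-dominated
low-stiffness regime followed by a steep collagen-recruited high-stiffness
regime.  Each regime's tangent slope is estimated from an R²-optimal linear
window: the low-stiffness window is anchored at the first point of the
curve, the high-stiffness window at the last point, and the free endpoint is
scanned exhaustively.  Curves are first truncated at fiber breakage (the
point where the response deviates from the high-stiffness trend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from aortamech.curves import StressStretchCurve, MIN_POINTS

__all__ = [
    "RegimeSlopes",
    "LinearRange",
    "truncate_at_fiber_breakage",
    "optimal_linear_range",
    "regime_slopes",
]

#: Shortest admissible OLS window (points); keeps noisy slopes stable.
MIN_WINDOW = 5

#: Floating-point tolerance treated as an R² tie (broken toward longer windows).
_R2_TIE = 1e-12


@dataclass(frozen=True)
class LinearRange:
    """An OLS fit on a contiguous index window [start, stop)."""

    start: int
    stop: int
    slope: float
    intercept: float
    r2: float

    @property
    def indices(self) -> tuple[int, int]:
        return (self.start, self.stop)


@dataclass(frozen=True)
class RegimeSlopes:
    """Low- and high-stiffness tangent slopes of one truncated curve.

    Slopes are in MPa per unit stretch.  ``degenerate`` flags curves whose
    optimal windows overlap and jointly cover the whole curve (a single
    linear regime with no identifiable transition).
    """

    low_slope: float
    high_slope: float
    low_range: tuple[int, int]
    high_range: tuple[int, int]
    low_r2: float
    high_r2: float
    transition_stretch: float
    degenerate: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of an ordinary least-squares line."""
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("degenerate window: constant x")
    slope = float(dx @ dy) / sxx
    intercept = ym - slope * xm
    ss_tot = float(dy @ dy)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def truncate_at_fiber_breakage(curve: StressStretchCurve,
                               slope_window: int = 7,
                               collapse_fraction: float = 0.5) -> StressStretchCurve:
    """Keep the curve prefix up to the fiber-breakage point.

    Breakage is detected as the earlier of (a) the global stress maximum and
    (b) the first window whose running least-squares tangent drops below
    ``collapse_fraction`` of the running maximum tangent.  Raises if fewer
    than 10 points remain (no identifiable high-stiffness regime).
    """
    stress = curve.stress
    stretch = curve.stretch
    n = len(curve)
    peak = int(np.argmax(stress))

    cut = peak
    w = max(3, min(slope_window, n))
    slopes = np.full(n - w + 1, np.nan)
    for i in range(n - w + 1):
        dx = stretch[i:i + w] - stretch[i:i + w].mean()
        dy = stress[i:i + w] - stress[i:i + w].mean()
        sxx = float(dx @ dx)
        slopes[i] = float(dx @ dy) / sxx if sxx > 0 else 0.0
    run_max = np.fmax.accumulate(slopes)
    collapsed = np.flatnonzero(
        (slopes < collapse_fraction * run_max) & (run_max > 0)
    )
    if collapsed.size:
        cut = min(cut, int(collapsed[0]) + w - 1)

    if cut + 1 < MIN_POINTS:
        raise ValueError(
            "curve too short after fiber-breakage truncation "
            f"({cut + 1} points); no identifiable high-stiffness regime"
        )
    return curve.prefix(cut + 1)


def optimal_linear_range(curve: StressStretchCurve, anchor: str,
                         min_window: int = MIN_WINDOW) -> LinearRange:
    """R²-optimal linear window anchored at one end of the curve.

    ``anchor="first_point"`` scans windows ``[0, k)`` (low-stiffness regime);
    ``anchor="last_point"`` scans windows ``[k, n)`` (high-stiffness regime).
    Among R² ties the longer window wins (lower-variance slope).
    """
    if anchor not in ("first_point", "last_point"):
        raise ValueError(f"anchor must be 'first_point' or 'last_point', got {anchor!r}")
    n = len(curve)
    if n < min_window:
        raise ValueError(f"all candidate windows shorter than {min_window}")
    x, y = curve.stretch, curve.stress

    candidates: list[LinearRange] = []
    for length in range(min_window, n + 1):
        if anchor == "first_point":
            start, stop = 0, length
        else:
            start, stop = n - length, n
        slope, intercept, r2 = _ols(x[start:stop], y[start:stop])
        candidates.append(LinearRange(start, stop, slope, intercept, r2))

    best_r2 = max(c.r2 for c in candidates)
    tied = [c for c in candidates if c.r2 >= best_r2 - _R2_TIE]
    return max(tied, key=lambda c: c.stop - c.start)


def regime_slopes(curve: StressStretchCurve,
                  derivative_fit: str = "linear",
                  min_window: int = MIN_WINDOW) -> RegimeSlopes:
    """Tangent slopes of the low- and high-stiffness regimes.

    The optimal windows are found from both anchors; a fitting equation
    (default: the window's own OLS line, option ``"quadratic"``: a local
    second-order polynomial) is evaluated at each window's midpoint to give
    the tangent slope.  The transition stretch is the midpoint between the
    low window's end and the high window's start.
    """
    low = optimal_linear_range(curve, "first_point", min_window)
    high = optimal_linear_range(curve, "last_point", min_window)

    def tangent(rng: LinearRange) -> float:
        if derivative_fit == "linear":
            return rng.slope
        if derivative_fit == "quadratic":
            x = curve.stretch[rng.start:rng.stop]
            y = curve.stress[rng.start:rng.stop]
            coeffs = np.polyfit(x, y, 2)
            mid = 0.5 * (x[0] + x[-1])
            return float(2.0 * coeffs[0] * mid + coeffs[1])
        raise ValueError(f"unknown derivative_fit {derivative_fit!r}")

    # A shared breakpoint gives a 1-point overlap; only a substantial overlap
    # (the two windows jointly re-reading the same >= min_window points)
    # indicates a single linear regime with no transition.
    degenerate = (low.stop - high.start) >= min_window
    if degenerate:
        warnings.warn(
            "optimal regime windows overlap and cover the whole curve; "
            "no identifiable transition (single-regime curve)",
            RuntimeWarning,
            stacklevel=2,
        )
    inner_low = curve.stretch[min(low.stop - 1, len(curve) - 1)]
    inner_high = curve.stretch[high.start]
    transition = 0.5 * (inner_low + inner_high)

    return RegimeSlopes(
        low_slope=tangent(low),
        high_slope=tangent(high),
        low_range=low.indices,
        high_range=high.indices,
        low_r2=low.r2,
        high_r2=high.r2,
        transition_stretch=float(transition),
        degenerate=bool(degenerate),
    )
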