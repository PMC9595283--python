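"""The per-specimen uniaxial record shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from aortamech.models import LoadingDirection

__all__ = ["StressStretchCurve", "REGIONS"]

#: Aortic test regions: proximal/distal x anterior/posterior.
REGIONS = ("PA", "PP", "DA", "DP")

#: Fewest points a curve may carry (OLS windows and regime detection need slack).
MIN_POINTS = 10


@dataclass(frozen=True)
class StressStretchCurve:
    """One specimen's uniaxial stress–stretch record.

    ``stretch`` is strictly increasing and starts near 1; ``stress`` is the
    Cauchy stress in MPa, non-negative after baseline correction.  ``region``
    is one of PA/PP/DA/DP and ``direction`` the loading axis.
    """

    stretch: np.ndarray
    stress: np.ndarray
    region: str
    direction: LoadingDirection
    specimen_id: str = ""

    def __post_init__(self):
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)
        if stretch.ndim != 1 or stress.ndim != 1:
            raise ValueError("stretch and stress must be 1-D")
        if len(stretch) != len(stress):
            raise ValueError("stretch and stress lengths differ")
        if len(stretch) < MIN_POINTS:
            raise ValueError(f"curve needs >= {MIN_POINTS} points, got {len(stretch)}")
        if np.any(np.diff(stretch) <= 0):
            raise ValueError("stretch must be strictly increasing")
        if np.any(stress < 0):
            raise ValueError("stress must be non-negative")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not isinstance(self.direction, LoadingDirection):
            object.__setattr__(
                self, "direction", LoadingDirection.from_code(str(self.direction))
            )

    def __len__(self) -> int:
        return len(self.stretch)

    def prefix(self, n: int) -> "StressStretchCurve":
        """First ``n`` points as a new curve."""
        return replace(self, stretch=self.stretch[:n], stress=self.stress[:n])
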