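"""Virtual biaxial datasets by one-to-many cross-mapping.

A true biaxial test is emulated by pairing each circumferential specimen of
a region with every longitudinal specimen of the same region (the exhaustive
Cartesian product).  With the study's per-region specimen counts this gives
1,015 + 625 + 728 + 784 = 3,152 virtual pairs, i.e. 9,456 fit cases over the
three constitutive models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aortamech.curves import StressStretchCurve
from aortamech.models import LoadingDirection

__all__ = [
    "SpecimenSet",
    "VirtualBiaxialPair",
    "cross_map_pairs",
    "count_cases",
    "subsample_pairs",
    "pair_manifest",
]


@dataclass(frozen=True)
class SpecimenSet:
    """All specimens of one region, split by loading direction."""

    region: str
    circumferential: tuple
    longitudinal: tuple

    def __post_init__(self):
        object.__setattr__(self, "circumferential", tuple(self.circumferential))
        object.__setattr__(self, "longitudinal", tuple(self.longitudinal))
        for c in self.circumferential:
            if c.region != self.region or c.direction is not LoadingDirection.CIRCUMFERENTIAL:
                raise ValueError("circumferential list holds a mismatched curve")
        for c in self.longitudinal:
            if c.region != self.region or c.direction is not LoadingDirection.LONGITUDINAL:
                raise ValueError("longitudinal list holds a mismatched curve")


@dataclass(frozen=True)
class VirtualBiaxialPair:
    """One circumferential curve cross-mapped to one longitudinal curve."""

    circ_curve: StressStretchCurve
    long_curve: StressStretchCurve
    pair_index: tuple[int, int]

    @property
    def region(self) -> str:
        return self.circ_curve.region


def cross_map_pairs(s: SpecimenSet) -> list[VirtualBiaxialPair]:
    """Exhaustive Cartesian product, circumferential-major order.

    Deterministic: ``|output| = |circ| * |long|`` and every (i, j) appears
    exactly once.
    """
    if not s.circumferential or not s.longitudinal:
        raise ValueError(f"region {s.region}: both direction lists must be non-empty")
    return [
        VirtualBiaxialPair(c, l, (i, j))
        for i, c in enumerate(s.circumferential)
        for j, l in enumerate(s.longitudinal)
    ]


def count_cases(sets: list[SpecimenSet], n_models: int) -> int:
    """Total fit cases: sum of per-region pair counts times model count."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return n_models * sum(
        len(s.circumferential) * len(s.longitudinal) for s in sets
    )


def subsample_pairs(pairs: list[VirtualBiaxialPair], n: int,
                    seed: int) -> list[VirtualBiaxialPair]:
    """Seeded subsample without replacement (runtime control; never a default)."""
    if n >= len(pairs):
        return list(pairs)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pairs), size=n, replace=False))
    return [pairs[i] for i in idx]


def pair_manifest(pairs: list[VirtualBiaxialPair]) -> pd.DataFrame:
    """Tabular manifest (region, i, j, circ_specimen_id, long_specimen_id)."""
    return pd.DataFrame(
        {
            "region": [p.region for p in pairs],
            "i": [p.pair_index[0] for p in pairs],
            "j": [p.pair_index[1] for p in pairs],
            "circ_specimen_id": [p.circ_curve.specimen_id for p in pairs],
            "long_specimen_id": [p.long_curve.specimen_id for p in pairs],
        }
    )
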