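"""Synthetic region-structured cohorts with known ground truth.

The generator emulates the study conditions of a porcine descending
thoracic aorta uniaxial campaign: eight specimen sets (four regions x two
loading directions) with the published per-region specimen counts
(PAC/PAL 35/29, PPC/PPL 25/25, DAC/DAL 26/28, DPC/DPL 28/28), J-shaped
stress–stretch curves with a compliant and a steep regime, circumferential
specimens stiffer than longitudinal ones, the distal-posterior region the
stiffest, per-specimen parameter heterogeneity (lognormal jitter on the
stress-like moduli) and multiplicative measurement noise.  Region-level
parameters are drawn from configured plausible ranges; every draw is
reproducible from the single cohort seed and is recorded in a
:class:`GroundTruth` sidecar for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from aortamech.curves import REGIONS, StressStretchCurve
from aortamech.models import (
    MODEL_PARAM_CLASSES,
    LoadingDirection,
    uniaxial_stress,
)
from aortamech.pairing import SpecimenSet

__all__ = [
    "DEFAULT_REGION_COUNTS",
    "SyntheticConfig",
    "GroundTruth",
    "sample_region_params",
    "generate_curve",
    "generate_cohort",
]

#: Published per-region (circumferential, longitudinal) specimen counts.
DEFAULT_REGION_COUNTS = {
    "PA": (35, 29),
    "PP": (25, 25),
    "DA": (26, 28),
    "DP": (28, 28),
}

# Region-level plausible parameter ranges (uniform draws).  Centred on the
# magnitudes reported for porcine thoracic aorta (c ~ 0.05 MPa, k1 ~ 0.1 MPa,
# k2 up to ~3.3 in the stiffest region); the distal-posterior (DP) ranges sit
# highest so DP is the stiffest region, and fiber angles stay below pi/4 so
# circumferential specimens are stiffer than longitudinal ones.
_HOLZAPFEL_RANGES = {
    "PA": {"c": (0.030, 0.055), "k1": (0.06, 0.14), "k2": (1.2, 2.0), "gamma": (0.45, 0.60)},
    "DA": {"c": (0.030, 0.060), "k1": (0.06, 0.14), "k2": (1.4, 2.2), "gamma": (0.45, 0.60)},
    "PP": {"c": (0.035, 0.065), "k1": (0.07, 0.16), "k2": (1.6, 2.4), "gamma": (0.45, 0.60)},
    "DP": {"c": (0.050, 0.090), "k1": (0.10, 0.22), "k2": (2.6, 3.6), "gamma": (0.52, 0.66)},
}

_FUNG_RANGES = {
    "PA": {"c1": (0.08, 0.20), "b1": (1.6, 2.4), "b2": (0.8, 1.2), "b3": (1.0, 1.4),
           "b4": (0.05, 0.25), "b5": (0.7, 1.1), "b6": (0.05, 0.25)},
    "DA": {"c1": (0.10, 0.30), "b1": (1.7, 2.5), "b2": (0.8, 1.3), "b3": (1.0, 1.4),
           "b4": (0.05, 0.25), "b5": (0.7, 1.1), "b6": (0.05, 0.25)},
    "PP": {"c1": (0.08, 0.22), "b1": (1.8, 2.6), "b2": (0.9, 1.3), "b3": (1.0, 1.4),
           "b4": (0.05, 0.25), "b5": (0.7, 1.1), "b6": (0.02, 0.15)},
    "DP": {"c1": (0.08, 0.22), "b1": (2.2, 3.0), "b2": (1.0, 1.5), "b3": (1.1, 1.5),
           "b4": (0.02, 0.15), "b5": (0.8, 1.2), "b6": (0.05, 0.25)},
}

# CMM ranges are set so the collagen exponential stays physiological over the
# generated stretch window (peak stresses of a few MPa): with a deposition
# pre-stretch Gh ~ 1.1-1.25 the fibers are already taut at reference, so the
# shape exponents c3 must stay below ~1.5 over lam <= 1.5.
_CMM_RANGES = {
    "PA": {"c1": (1e-4, 3e-4), "c2_1": (0.06, 0.20), "c2_2": (0.04, 0.12),
           "c3_1": (0.4, 1.0), "c3_2": (0.3, 0.8), "G1": (1.00, 1.12),
           "G2": (1.00, 1.12), "Gh": (1.10, 1.20), "alpha": (0.55, 0.65)},
    "DA": {"c1": (1e-4, 3e-4), "c2_1": (0.06, 0.20), "c2_2": (0.04, 0.12),
           "c3_1": (0.5, 1.1), "c3_2": (0.3, 0.8), "G1": (1.00, 1.12),
           "G2": (1.00, 1.12), "Gh": (1.10, 1.20), "alpha": (0.56, 0.66)},
    "PP": {"c1": (1e-4, 3e-4), "c2_1": (0.05, 0.18), "c2_2": (0.05, 0.14),
           "c3_1": (0.5, 1.1), "c3_2": (0.35, 0.9), "G1": (1.00, 1.12),
           "G2": (1.00, 1.12), "Gh": (1.14, 1.24), "alpha": (0.56, 0.66)},
    "DP": {"c1": (1e-4, 3e-4), "c2_1": (0.08, 0.24), "c2_2": (0.06, 0.16),
           "c3_1": (0.8, 1.5), "c3_2": (0.5, 1.1), "G1": (1.00, 1.12),
           "G2": (1.00, 1.12), "Gh": (1.12, 1.22), "alpha": (0.60, 0.70)},
}

DEFAULT_PARAM_RANGES = {
    "holzapfel": _HOLZAPFEL_RANGES,
    "fung": _FUNG_RANGES,
    "cmm": _CMM_RANGES,
}

#: Stress-like parameters receiving per-specimen lognormal jitter.
_JITTERED = {
    "fung": ("c1",),
    "holzapfel": ("c", "k1"),
    "cmm": ("c1", "c2_1", "c2_2"),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    ``noise_sd_fraction`` is the relative SD of multiplicative Gaussian
    measurement noise; ``jitter_sd`` the lognormal sigma of per-specimen
    heterogeneity on stress-like moduli; ``stretch_max`` the grid endpoint
    per loading direction (circumferential specimens transition earlier, so
    their grid is shorter).
    """

    seed: int = 0
    region_counts: dict = field(default_factory=lambda: dict(DEFAULT_REGION_COUNTS))
    model: str = "holzapfel"
    noise_sd_fraction: float = 0.02
    points_per_curve: int = 80
    stretch_max: dict = field(default_factory=lambda: {
        "circumferential": 1.5, "longitudinal": 1.65})
    jitter_sd: float = 0.08
    param_ranges: dict | None = None

    def __post_init__(self):
        if self.model not in MODEL_PARAM_CLASSES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_sd_fraction < 0 or self.jitter_sd < 0:
            raise ValueError("noise and jitter must be >= 0")
        if self.points_per_curve < 10:
            raise ValueError("need at least 10 points per curve")
        for region, (nc, nl) in self.region_counts.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if nc < 1 or nl < 1:
                raise ValueError(f"region {region}: counts must be >= 1")

    def ranges_for(self, region: str) -> dict:
        ranges = (self.param_ranges or DEFAULT_PARAM_RANGES[self.model])
        r = ranges[region]
        for name, (lo, hi) in r.items():
            if hi < lo:
                raise ValueError(f"empty range for {name} in region {region}")
        return r


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters stored alongside a cohort for recovery tests.

    ``region_params`` maps region -> the region-level parameter object;
    ``specimen_params`` maps (region, direction code, index) -> the jittered
    per-specimen parameters actually evaluated.
    """

    model: str
    region_params: dict
    specimen_params: dict


def sample_region_params(cfg: SyntheticConfig, region: str, rng=None):
    """Draw the region-level parameter vector from the configured ranges.

    Deterministic in (cfg.seed, region); a zero-width range yields its
    midpoint exactly.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, REGIONS.index(region), 7919])
    cls = MODEL_PARAM_CLASSES[cfg.model]
    ranges = cfg.ranges_for(region)
    vals = {}
    for name in cls.param_names():
        lo, hi = ranges[name]
        vals[name] = float(lo + (hi - lo) * rng.random())
    return cls(**vals)


def _jitter(params, model: str, sd: float, rng) -> object:
    """Lognormal multiplicative jitter on the stress-like parameters.

    Draws are made even at sd=0 so the random stream is configuration-
    independent.
    """
    out = {}
    for name in _JITTERED[model]:
        z = rng.standard_normal()
        out[name] = getattr(params, name) * float(np.exp(sd * z))
    return dc_replace(params, **out)


def generate_curve(params, model: str, direction: LoadingDirection,
                   cfg: SyntheticConfig, rng=None, region: str = "PA",
                   specimen_id: str = "", return_params: bool = False):
    """One synthetic specimen curve from a parameter vector.

    Stretch grid from 1 to the direction's maximum; stress is the model
    closed form under per-specimen jittered parameters plus multiplicative
    Gaussian noise (SD = ``noise_sd_fraction`` x pointwise stress), clipped
    at zero.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam = np.linspace(1.0, cfg.stretch_max[direction.value], cfg.points_per_curve)
    p = _jitter(params, model, cfg.jitter_sd, rng)
    stress = np.asarray(uniaxial_stress(model, p, lam, direction), dtype=float)
    noise = rng.standard_normal(len(lam))
    stress = np.clip(stress * (1.0 + cfg.noise_sd_fraction * noise), 0.0, None)
    curve = StressStretchCurve(lam, stress, region, direction, specimen_id)
    if return_params:
        return curve, p
    return curve


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[SpecimenSet], GroundTruth]:
    """Full eight-set cohort honoring the configured per-region counts.

    With the default counts the per-region cross-mapped pair counts are
    1,015 / 625 / 728 / 784 (3,152 pairs per constitutive model; 9,456 fit
    cases over three models).  Fixed seed implies a byte-identical cohort.
    """
    rng = np.random.default_rng([cfg.seed, 104729])
    sets = []
    region_params = {}
    specimen_params = {}
    for region in REGIONS:
        if region not in cfg.region_counts:
            continue
        base = sample_region_params(cfg, region)
        region_params[region] = base
        n_circ, n_long = cfg.region_counts[region]
        curves = {LoadingDirection.CIRCUMFERENTIAL: [],
                  LoadingDirection.LONGITUDINAL: []}
        for direction, n in ((LoadingDirection.CIRCUMFERENTIAL, n_circ),
                             (LoadingDirection.LONGITUDINAL, n_long)):
            for i in range(n):
                sid = f"{region}{direction.code}{i + 1:02d}"
                curve, p = generate_curve(
                    base, cfg.model, direction, cfg, rng=rng,
                    region=region, specimen_id=sid, return_params=True)
                curves[direction].append(curve)
                specimen_params[(region, direction.code, i)] = p
        sets.append(SpecimenSet(
            region=region,
            circumferential=curves[LoadingDirection.CIRCUMFERENTIAL],
            longitudinal=curves[LoadingDirection.LONGITUDINAL],
        ))
    gt = GroundTruth(model=cfg.model, region_params=region_params,
                     specimen_params=specimen_params)
    return sets, gt
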