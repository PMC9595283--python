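"""Shared fixtures: session-scoped expensive fits reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from aortamech import (
    CMMParams,
    FungParams,
    HolzapfelParams,
    LoadingDirection,
    SyntheticConfig,
    VirtualBiaxialPair,
    fit_virtual_pair,
    generate_curve,
)
from aortamech.models import uniaxial_stress


def rmse_over_max(params, curve, model: str) -> float:
    pred = np.asarray(uniaxial_stress(model, params, curve.stretch, curve.direction))
    return float(np.sqrt(np.mean((pred - curve.stress) ** 2)) / curve.stress.max())


def noiseless_pair(truth, model: str, seed: int = 0) -> VirtualBiaxialPair:
    """Circumferential + longitudinal curves from one shared parameter set."""
    cfg = SyntheticConfig(seed=seed, model=model, noise_sd_fraction=0.0,
                          jitter_sd=0.0, points_per_curve=60)
    cc = generate_curve(truth, model, LoadingDirection.CIRCUMFERENTIAL, cfg,
                        region="PA", specimen_id="c")
    cl = generate_curve(truth, model, LoadingDirection.LONGITUDINAL, cfg,
                        region="PA", specimen_id="l")
    return VirtualBiaxialPair(cc, cl, (0, 0))


HOLZ_TRUTH = HolzapfelParams(c=0.05, k1=0.1, k2=2.0, gamma=0.5)
FUNG_TRUTH = FungParams(c1=0.15, b1=2.2, b2=1.0, b3=1.2, b4=0.1, b5=0.9, b6=0.1)
CMM_TRUTH = CMMParams(c1=2e-4, c2_1=0.12, c2_2=0.08, c3_1=0.8, c3_2=0.5,
                      G1=1.06, G2=1.03, Gh=1.15, alpha=0.62)


@pytest.fixture(scope="session")
def holz_pair_fit():
    pair = noiseless_pair(HOLZ_TRUTH, "holzapfel")
    return pair, fit_virtual_pair(pair, "holzapfel", seed=11)


@pytest.fixture(scope="session")
def fung_pair_fit():
    pair = noiseless_pair(FUNG_TRUTH, "fung")
    return pair, fit_virtual_pair(pair, "fung", seed=12)


@pytest.fixture(scope="session")
def cmm_pair_fit():
    pair = noiseless_pair(CMM_TRUTH, "cmm")
    return pair, fit_virtual_pair(pair, "cmm", seed=13)
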