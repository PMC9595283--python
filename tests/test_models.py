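"""Constitutive closed forms against independent numeric stress oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortamech.models import (
    CMMParams,
    FungParams,
    HolzapfelParams,
    LoadingDirection,
    NonFiniteStressError,
    cmm_uniaxial_stress,
    fung_uniaxial_stress,
    holzapfel_uniaxial_stress,
    lagrange_elimination_oracle,
    numeric_stress_oracle,
    strain_energy,
    uniaxial_stress,
)

CIRC = LoadingDirection.CIRCUMFERENTIAL
LONG = LoadingDirection.LONGITUDINAL
LAMBDAS = np.arange(1.05, 1.601, 0.05)


def rel_err(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))


def random_fung(rng):
    return FungParams(c1=10 ** rng.uniform(-2, 0),
                      **{f"b{i}": rng.uniform(0.0, 3.0) for i in range(1, 7)})


def random_holzapfel(rng):
    return HolzapfelParams(c=10 ** rng.uniform(-2, 0),
                           k1=rng.uniform(0.01, 0.5),
                           k2=rng.uniform(0.1, 5.0),
                           gamma=rng.uniform(0.0, np.pi / 2))


def random_cmm(rng):
    return CMMParams(c1=rng.uniform(1e-4, 0.05),
                     c2_1=rng.uniform(0.0, 0.3), c2_2=rng.uniform(0.0, 0.3),
                     c3_1=rng.uniform(0.1, 1.5), c3_2=rng.uniform(0.1, 1.5),
                     G1=rng.uniform(0.9, 1.3), G2=rng.uniform(0.9, 1.3),
                     Gh=rng.uniform(1.0, 1.3), alpha=rng.uniform(0.0, np.pi / 2))


class TestFrozenValues:
    """Example stresses frozen from the numeric oracles before the build."""

    def test_fung_circumferential_example(self):
        p = FungParams(c1=0.1, b1=2, b2=1, b3=0.5, b4=0.5, b5=0.5, b6=0.5)
        frozen = 0.11231025607478935  # radial-face elimination oracle value
        assert fung_uniaxial_stress(p, 1.3, CIRC) == pytest.approx(frozen, rel=1e-12)
        assert lagrange_elimination_oracle("fung", p, 1.3, CIRC) == pytest.approx(
            frozen, rel=1e-6)

    def test_holzapfel_aligned_fiber_example(self):
        p = HolzapfelParams(c=0.05, k1=0.1, k2=1.0, gamma=0.0)
        frozen = 0.3379108396737432  # path oracle value (exact at gamma=0)
        assert holzapfel_uniaxial_stress(p, 1.2, CIRC) == pytest.approx(frozen, rel=1e-12)
        assert numeric_stress_oracle("holzapfel", p, 1.2, CIRC) == pytest.approx(
            frozen, rel=1e-6)

    def test_cmm_energy_consistent_example(self):
        p = CMMParams(c1=0.02, c2_1=0.05, c2_2=0.0, c3_1=2.0, c3_2=1.0,
                      G1=1.2, G2=1.2, Gh=1.1, alpha=np.pi / 4)
        frozen = 0.03220969135360979  # path oracle on the stored energies
        assert cmm_uniaxial_stress(p, 1.15, LONG) == pytest.approx(frozen, rel=1e-10)
        assert numeric_stress_oracle("cmm", p, 1.15, LONG) == pytest.approx(
            frozen, rel=1e-6)


class TestZeroAtIdentity:
    def test_fung_and_holzapfel_vanish_at_unit_stretch(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pf, ph = random_fung(rng), random_holzapfel(rng)
            for d in (CIRC, LONG):
                assert fung_uniaxial_stress(pf, 1.0, d) == 0.0
                assert holzapfel_uniaxial_stress(ph, 1.0, d) == 0.0

    def test_cmm_vanishes_with_unit_prestretches(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = random_cmm(rng)
            p = CMMParams(p.c1, p.c2_1, p.c2_2, p.c3_1, p.c3_2,
                          G1=1.0, G2=1.0, Gh=1.0, alpha=p.alpha)
            for d in (CIRC, LONG):
                assert cmm_uniaxial_stress(p, 1.0, d) == pytest.approx(0.0, abs=1e-15)

    def test_cmm_prestretch_residual_stress_at_identity(self):
        p = CMMParams(0.02, 0.05, 0.0, 1.0, 1.0, G1=1.2, G2=1.1, Gh=1.1, alpha=0.5)
        assert cmm_uniaxial_stress(p, 1.0, CIRC) != pytest.approx(0.0, abs=1e-6)


class TestClosedFormLimits:
    def test_holzapfel_neo_hookean_limit(self):
        p = HolzapfelParams(c=0.05, k1=0.0, k2=1.0, gamma=0.3)
        lam = np.linspace(1.01, 1.6, 30)
        np.testing.assert_allclose(
            holzapfel_uniaxial_stress(p, lam, CIRC),
            0.05 * (lam**2 - 1.0 / lam), rtol=1e-15)
        np.testing.assert_allclose(
            holzapfel_uniaxial_stress(p, lam, LONG),
            0.05 * (lam**2 - 1.0 / lam), rtol=1e-15)

    def test_cmm_elastin_neo_hookean_limit(self):
        p = CMMParams(0.03, 0.0, 0.0, 1.0, 1.0, G1=1.0, G2=1.0, Gh=1.0, alpha=0.2)
        assert cmm_uniaxial_stress(p, 1.2, CIRC) == pytest.approx(
            0.03 * (1.2**2 - 1.2**-1), rel=1e-12)

    @given(st.floats(1.05, 1.6), st.booleans())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_fung_direction_swap_symmetry(self, lam, circ_first):
        """Swapping (b1, b2) and (b5, b6) exchanges the T1 and T2 forms."""
        p = FungParams(c1=0.1, b1=2.0, b2=0.8, b3=1.1, b4=0.3, b5=0.9, b6=0.2)
        q = FungParams(c1=0.1, b1=0.8, b2=2.0, b3=1.1, b4=0.3, b5=0.2, b6=0.9)
        d1, d2 = (CIRC, LONG) if circ_first else (LONG, CIRC)
        assert fung_uniaxial_stress(p, lam, d1) == pytest.approx(
            fung_uniaxial_stress(q, lam, d2), rel=1e-12)


class TestOracleEquivalence:
    """The closed forms against two independent numeric differentiations."""

    def test_closed_forms_match_tensor_elimination_oracle(self):
        # 100 random parameter sets x both directions x the stretch grid
        rng = np.random.default_rng(2024)
        for _ in range(50):
            pf, ph = random_fung(rng), random_holzapfel(rng)
            for d in (CIRC, LONG):
                assert rel_err(
                    fung_uniaxial_stress(pf, LAMBDAS, d),
                    lagrange_elimination_oracle("fung", pf, LAMBDAS, d)) < 1e-6
                assert rel_err(
                    holzapfel_uniaxial_stress(ph, LAMBDAS, d),
                    lagrange_elimination_oracle("holzapfel", ph, LAMBDAS, d)) < 1e-6

    def test_path_oracle_matches_on_lateral_symmetric_subspace(self):
        # the scalar lam*dW/dlam derivative is the traction-free stress when
        # the two lateral responses coincide: b2=b3 & b4=b5 (circ loading),
        # b1=b3 & b4=b6 (longitudinal), or on-axis fibers for Holzapfel
        rng = np.random.default_rng(5)
        for _ in range(50):
            b1, b2, b45, b6 = rng.uniform(0.0, 3.0, 4)
            pc = FungParams(0.1, b1, b2, b2, b45, b45, b6)
            assert rel_err(fung_uniaxial_stress(pc, LAMBDAS, CIRC),
                           numeric_stress_oracle("fung", pc, LAMBDAS, CIRC)) < 1e-6
            pl = FungParams(0.1, b2, b1, b2, b45, b6, b45)
            assert rel_err(fung_uniaxial_stress(pl, LAMBDAS, LONG),
                           numeric_stress_oracle("fung", pl, LAMBDAS, LONG)) < 1e-6
        ph = HolzapfelParams(c=0.05, k1=0.2, k2=1.5, gamma=0.0)
        assert rel_err(holzapfel_uniaxial_stress(ph, LAMBDAS, CIRC),
                       numeric_stress_oracle("holzapfel", ph, LAMBDAS, CIRC)) < 1e-6

    def test_lateral_asymmetry_separates_the_two_conventions(self):
        # off the symmetric subspace the radial-face elimination and the
        # symmetric path derivative are genuinely different stresses
        p = FungParams(c1=0.1, b1=2, b2=1, b3=0.5, b4=0.5, b5=0.5, b6=0.5)
        assert rel_err(fung_uniaxial_stress(p, 1.3, CIRC),
                       numeric_stress_oracle("fung", p, 1.3, CIRC)) > 1e-3
        ph = HolzapfelParams(c=0.05, k1=0.2, k2=1.5, gamma=0.6)
        assert rel_err(holzapfel_uniaxial_stress(ph, 1.3, CIRC),
                       numeric_stress_oracle("holzapfel", ph, 1.3, CIRC)) > 1e-3

    def test_cmm_energy_consistent_form_matches_path_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = random_cmm(rng)
            for d in (CIRC, LONG):
                assert rel_err(cmm_uniaxial_stress(p, LAMBDAS, d),
                               numeric_stress_oracle("cmm", p, LAMBDAS, d)) < 1e-6

    def test_cmm_literal_transcription_differs_measurably(self):
        p = CMMParams(0.02, 0.05, 0.03, 2.0, 1.0, G1=1.2, G2=1.1, Gh=1.1,
                      alpha=np.pi / 4)
        lit = cmm_uniaxial_stress(p, LAMBDAS, CIRC, form="literal")
        energy = cmm_uniaxial_stress(p, LAMBDAS, CIRC)
        assert rel_err(lit, energy) > 1e-2

    def test_path_oracle_second_order_convergence(self):
        p = HolzapfelParams(c=0.05, k1=0.1, k2=1.0, gamma=0.0)
        exact = holzapfel_uniaxial_stress(p, 1.3, CIRC)
        errs = [abs(numeric_stress_oracle("holzapfel", p, 1.3, CIRC, h=h) - exact)
                for h in (1e-2, 5e-3, 2.5e-3)]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(1.8 < o < 2.2 for o in orders)

    def test_path_oracle_rejects_too_large_step(self):
        p = HolzapfelParams(c=0.05, k1=0.3, k2=4.0, gamma=0.1)
        with pytest.raises(ValueError, match="too large"):
            numeric_stress_oracle("holzapfel", p, 1.5, CIRC, h=0.25,
                                  check_truncation=True)


class TestStrainEnergy:
    @pytest.mark.parametrize("model,params", [
        ("fung", FungParams(0.1, 2, 1, 0.5, 0.5, 0.5, 0.5)),
        ("holzapfel", HolzapfelParams(0.05, 0.1, 1.0, 0.4)),
        ("cmm", CMMParams(0.02, 0.05, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.4)),
    ])
    def test_vanishes_at_identity(self, model, params):
        assert strain_energy(model, params, 1.0, CIRC) == pytest.approx(0.0, abs=1e-15)

    def test_cmm_stores_prestretch_energy_at_identity(self):
        p = CMMParams(0.02, 0.05, 0.0, 1.0, 1.0, G1=1.2, G2=1.1, Gh=1.15, alpha=0.5)
        assert strain_energy("cmm", p, 1.0, CIRC) > 1e-5

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            strain_energy("ogden", None, 1.2, CIRC)
        with pytest.raises(ValueError, match="unknown model"):
            uniaxial_stress("ogden", None, 1.2, CIRC)


class TestGuards:
    def test_exponential_overflow_raises(self):
        p = HolzapfelParams(c=0.05, k1=0.1, k2=50.0, gamma=0.0)
        with pytest.raises(NonFiniteStressError):
            holzapfel_uniaxial_stress(p, 6.0, CIRC)

    def test_nonpositive_stretch_rejected(self):
        p = HolzapfelParams(c=0.05, k1=0.1, k2=1.0, gamma=0.0)
        with pytest.raises(ValueError):
            holzapfel_uniaxial_stress(p, 0.0, CIRC)

    @pytest.mark.parametrize("kwargs", [
        {"c": -0.1, "k1": 0.1, "k2": 1.0, "gamma": 0.1},
        {"c": 0.1, "k1": 0.1, "k2": -1.0, "gamma": 0.1},
        {"c": 0.1, "k1": 0.1, "k2": 1.0, "gamma": 2.0},
    ])
    def test_invalid_holzapfel_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HolzapfelParams(**kwargs)

    def test_invalid_cmm_prestretch_rejected(self):
        with pytest.raises(ValueError):
            CMMParams(0.02, 0.05, 0.0, 1.0, 1.0, G1=-1.0, G2=1.0, Gh=1.0, alpha=0.4)


def test_holzapfel_anisotropy_monotone_in_fiber_alignment():
    """With fibers in tension, the anisotropic contribution grows as the
    fiber family rotates toward the loaded (circumferential) axis."""
    lam = 1.3
    gammas = np.linspace(0.0, np.pi / 2, 91)
    base = HolzapfelParams(c=0.05, k1=0.0001, k2=1.0, gamma=0.0)
    iso = holzapfel_uniaxial_stress(
        HolzapfelParams(c=0.05, k1=0.0001, k2=1.0, gamma=0.0), lam, CIRC) * 0
    aniso = []
    for g in gammas:
        p = HolzapfelParams(c=0.05, k1=0.2, k2=1.0, gamma=float(g))
        p0 = HolzapfelParams(c=0.05, k1=1e-9, k2=1.0, gamma=float(g))
        aniso.append(holzapfel_uniaxial_stress(p, lam, CIRC)
                     - holzapfel_uniaxial_stress(p0, lam, CIRC))
    aniso = np.array(aniso)
    i4 = lam**2 * np.cos(gammas) ** 2 + np.sin(gammas) ** 2 / lam
    tension = i4 >= 1.0
    assert np.all(np.diff(aniso[tension]) <= 1e-12)
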