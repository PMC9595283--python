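"""Anisotropic hyperelastic constitutive models for arterial tissue.

Three strain-energy functions are implemented together with their uniaxial
Cauchy-stress closed forms for both in-plane loading directions:

* **Fung** — orthotropic exponential ``W = c1/2 (exp Q - 1)`` with a
  quadratic form ``Q`` in the Green–Lagrange strains (seven parameters
  ``c1, b1..b6``).
* **Holzapfel** — neo-Hookean matrix plus two symmetric exponential
  collagen-fiber families (``c, k1, k2`` and fiber angle ``gamma``).
* **Constrained mixture (CMM)** — incompressible elastin network with
  in-plane pre-stretches ``G1, G2`` plus collagen fiber-family groups with
  deposition pre-stretch ``Gh`` and angle ``alpha`` (nine parameters).

Kinematics: incompressible uniaxial extension with symmetric lateral
contraction, ``F = diag(lam, lam**-0.5, lam**-0.5)`` in the material frame
(circumferential, longitudinal, radial).  The loaded axis is selected by
:class:`LoadingDirection`.

Two independent numeric oracles cross-validate the closed forms:

* :func:`numeric_stress_oracle` — central difference of the strain energy
  along the uniaxial path, ``T = lam * dW/dlam``.  This is the exact
  traction-free uniaxial Cauchy stress whenever the two lateral extra
  stresses are equal (always true for the CMM energy-consistent form; true
  for Fung/Holzapfel on a lateral-symmetric parameter subspace).
* :func:`lagrange_elimination_oracle` — numeric ``dW/dC`` pushed through
  ``T = -p I + 2 F (dW/dC) F^T`` with the multiplier ``p`` fixed by the
  traction-free radial face.  This reproduces the hand-derived closed forms
  for *all* parameter values and validates the multiplier elimination.

Stress unit is MPa throughout (a documented convention); stretches and all
exponents are dimensionless; angles are radians internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "LoadingDirection",
    "FungParams",
    "HolzapfelParams",
    "CMMParams",
    "NonFiniteStressError",
    "MODEL_PARAM_CLASSES",
    "fung_uniaxial_stress",
    "holzapfel_uniaxial_stress",
    "cmm_uniaxial_stress",
    "uniaxial_stress",
    "strain_energy",
    "numeric_stress_oracle",
    "lagrange_elimination_oracle",
]

#: Largest exponent argument accepted before the stress is declared non-finite.
_EXP_CLIP = 700.0


class NonFiniteStressError(FloatingPointError):
    """Raised when a model's exponential term overflows at a given stretch."""


class LoadingDirection(str, enum.Enum):
    """Uniaxial loading axis of a flat arterial specimen."""

    CIRCUMFERENTIAL = "circumferential"
    LONGITUDINAL = "longitudinal"

    @classmethod
    def from_code(cls, code: str) -> "LoadingDirection":
        """Map the single-letter file code (``C``/``L``) to a direction."""
        code = code.strip().upper()
        if code in ("C", "CIRCUMFERENTIAL"):
            return cls.CIRCUMFERENTIAL
        if code in ("L", "LONGITUDINAL"):
            return cls.LONGITUDINAL
        raise ValueError(f"unknown loading-direction code {code!r}")

    @property
    def code(self) -> str:
        return "C" if self is LoadingDirection.CIRCUMFERENTIAL else "L"


def _check_exponent(q, lam) -> np.ndarray:
    """Guard exponent arguments; overflow is an error, never silent saturation."""
    q = np.asarray(q, dtype=float)
    bad = ~np.isfinite(q) | (q > _EXP_CLIP)
    if np.any(bad):
        lam_bad = np.broadcast_to(np.asarray(lam, dtype=float), q.shape)[bad]
        raise NonFiniteStressError(
            f"exponent overflow (>{_EXP_CLIP:g}) at stretch lam={np.ravel(lam_bad)[0]:g}"
        )
    return q


@dataclass(frozen=True)
class FungParams:
    """Fung orthotropic exponential model parameters.

    ``c1`` is stress-like (MPa); ``b1..b6`` weight the squared and cross
    products of the principal Green–Lagrange strains in the exponent Q
    (index 1 = circumferential, 2 = longitudinal, 3 = radial).
    """

    c1: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float

    def __post_init__(self):
        if not self.c1 > 0:
            raise ValueError(f"c1 must be > 0, got {self.c1}")
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([self.c1, self.b1, self.b2, self.b3, self.b4, self.b5, self.b6])

    @classmethod
    def from_array(cls, x) -> "FungParams":
        return cls(*(float(v) for v in x))

    @classmethod
    def param_names(cls):
        return ["c1", "b1", "b2", "b3", "b4", "b5", "b6"]


@dataclass(frozen=True)
class HolzapfelParams:
    """Holzapfel two-fiber-family model parameters.

    ``c`` (MPa) is the neo-Hookean matrix stiffness, ``k1`` (MPa) and ``k2``
    (dimensionless) govern the exponential fiber response, and ``gamma``
    (radians, in [0, pi/2]) is the fiber angle.  In the uniaxial closed
    forms the cos^2(gamma) term pairs with the circumferential stretch, so
    algebraically gamma is measured from the circumferential axis.
    """

    c: float
    k1: float
    k2: float
    gamma: float

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.gamma <= np.pi / 2 + 1e-12:
            raise ValueError(f"gamma must lie in [0, pi/2], got {self.gamma}")

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.k1, self.k2, self.gamma])

    @classmethod
    def from_array(cls, x) -> "HolzapfelParams":
        return cls(*(float(v) for v in x))

    @classmethod
    def param_names(cls):
        return ["c", "k1", "k2", "gamma"]

    @property
    def gamma_degrees(self) -> float:
        return float(np.degrees(self.gamma))


@dataclass(frozen=True)
class CMMParams:
    """Constrained-mixture model parameters.

    ``c1`` (MPa) scales the incompressible elastin network whose in-plane
    pre-stretches are ``G1`` (circumferential) and ``G2`` (longitudinal);
    the radial elastin pre-stretch follows from constituent
    incompressibility as 1/(G1*G2).  Two collagen fiber-family groups
    ``(c2_1, c3_1)`` and ``(c2_2, c3_2)`` share the deposition pre-stretch
    ``Gh`` and the symmetric fiber angle ``alpha`` (radians; the cos^2(alpha)
    term pairs with the circumferential stretch in the closed forms).
    Constituent mass densities are absorbed into the stress-like moduli.
    """

    c1: float
    c2_1: float
    c2_2: float
    c3_1: float
    c3_2: float
    G1: float
    G2: float
    Gh: float
    alpha: float

    def __post_init__(self):
        for name in ("c1", "c2_1", "c2_2", "c3_1", "c3_2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("G1", "G2", "Gh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.alpha <= np.pi / 2 + 1e-12:
            raise ValueError(f"alpha must lie in [0, pi/2], got {self.alpha}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.c1, self.c2_1, self.c2_2, self.c3_1, self.c3_2,
             self.G1, self.G2, self.Gh, self.alpha]
        )

    @classmethod
    def from_array(cls, x) -> "CMMParams":
        return cls(*(float(v) for v in x))

    @classmethod
    def param_names(cls):
        return ["c1", "c2_1", "c2_2", "c3_1", "c3_2", "G1", "G2", "Gh", "alpha"]

    @property
    def alpha_degrees(self) -> float:
        return float(np.degrees(self.alpha))


MODEL_PARAM_CLASSES = {
    "fung": FungParams,
    "holzapfel": HolzapfelParams,
    "cmm": CMMParams,
}


def _validate_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be > 0")
    return lam


# ---------------------------------------------------------------------------
# Fung model
# ---------------------------------------------------------------------------

def _fung_Q_uniaxial(p: FungParams, lam, direction: LoadingDirection):
    """Exponent Q along the uniaxial path, with the loaded-axis strain a
    = (lam^2-1)/2 and both lateral strains el = (1/lam-1)/2."""
    a = (lam**2 - 1.0) / 2.0
    el = (1.0 / lam - 1.0) / 2.0
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        e1, e2, e3 = a, el, el
    else:
        e1, e2, e3 = el, a, el
    return (
        p.b1 * e1**2 + p.b2 * e2**2 + p.b3 * e3**2
        + 2.0 * p.b4 * e1 * e2 + 2.0 * p.b5 * e1 * e3 + 2.0 * p.b6 * e2 * e3
    )


def fung_uniaxial_stress(p: FungParams, lam, direction: LoadingDirection):
    """Uniaxial Cauchy stress (MPa) of the Fung model.

    The lateral boundary condition is eliminated through the radial
    traction-free face, giving the T1 form for circumferential loading and
    the T2 form for longitudinal loading.
    """
    lam = _validate_stretch(lam)
    A = lam**2 - 1.0          # loaded-axis (lam^2 - 1)
    B = 1.0 / lam - 1.0       # lateral (lam^-1 - 1)
    Q = _check_exponent(_fung_Q_uniaxial(p, lam, direction), lam)
    eQ = np.exp(Q)
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        axial = p.b1 * A + p.b4 * B + p.b5 * B
        radial = p.b3 * B + p.b5 * A + p.b6 * B
    else:
        axial = p.b2 * A + p.b4 * B + p.b6 * B
        radial = p.b3 * B + p.b5 * B + p.b6 * A
    T = 0.5 * p.c1 * eQ * (lam**2 * axial - radial / lam)
    return T if T.shape else float(T)


# ---------------------------------------------------------------------------
# Holzapfel model
# ---------------------------------------------------------------------------

def _holzapfel_I4_minus_1(p: HolzapfelParams, lam, direction: LoadingDirection):
    """I4 - 1 in cancellation-free difference form (exactly 0 at lam=1)."""
    cos2, sin2 = np.cos(p.gamma) ** 2, np.sin(p.gamma) ** 2
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        return (lam**2 - 1.0) * cos2 + (1.0 / lam - 1.0) * sin2
    return (1.0 / lam - 1.0) * cos2 + (lam**2 - 1.0) * sin2


def holzapfel_uniaxial_stress(p: HolzapfelParams, lam, direction: LoadingDirection):
    """Uniaxial Cauchy stress (MPa) of the Holzapfel two-fiber-family model.

    Neo-Hookean matrix term ``c (lam^2 - 1/lam)`` plus the two (identical)
    fiber families; no tension-only switch is applied — the printed
    equations are implemented literally.
    """
    lam = _validate_stretch(lam)
    I4m1 = _holzapfel_I4_minus_1(p, lam, direction)
    q = _check_exponent(p.k2 * I4m1**2, lam)
    fiber_common = 2.0 * p.k1 * I4m1 * np.exp(q)
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        trig2 = np.cos(p.gamma) ** 2
    else:
        trig2 = np.sin(p.gamma) ** 2
    # sum over the two families i = 4, 6 with I4 = I6
    T = p.c * (lam**2 - 1.0 / lam) + 2.0 * fiber_common * lam**2 * trig2
    return T if T.shape else float(T)


# ---------------------------------------------------------------------------
# Constrained mixture model
# ---------------------------------------------------------------------------

def _cmm_fiber_stretch_sq_minus_1(p: CMMParams, lam, direction: LoadingDirection):
    """lam_k^2 - 1 in cancellation-free difference form (exactly 0 at lam=1)."""
    cos2, sin2 = np.cos(p.alpha) ** 2, np.sin(p.alpha) ** 2
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        return (lam**2 - 1.0) * cos2 + (1.0 / lam - 1.0) * sin2
    return (lam**2 - 1.0) * sin2 + (1.0 / lam - 1.0) * cos2


def cmm_uniaxial_stress(p: CMMParams, lam, direction: LoadingDirection,
                        form: str = "energy_consistent"):
    """Uniaxial Cauchy stress (MPa) of the constrained mixture model.

    ``form="energy_consistent"`` (default) differentiates the stored
    energies along the incompressible uniaxial path (closed form, equal to
    ``lam * dW/dlam``).  ``form="literal"`` transcribes the printed stress
    equations verbatim, including their ambiguous ``(Gh lam_n)^2 lam^2``
    grouping; the two forms are both exposed so their discrepancy is
    measurable.
    """
    lam = _validate_stretch(lam)
    cos2, sin2 = np.cos(p.alpha) ** 2, np.sin(p.alpha) ** 2
    lk2m1 = _cmm_fiber_stretch_sq_minus_1(p, lam, direction)
    # ln2 - 1 = Gh^2 (lam_k^2 - 1) + (Gh^2 - 1): exact 0 at lam=1, Gh=1
    ln2m1 = p.Gh**2 * lk2m1 + (p.Gh**2 - 1.0)
    ln2 = 1.0 + ln2m1
    q1 = _check_exponent(p.c3_1 * ln2m1**2, lam)
    q2 = _check_exponent(p.c3_2 * ln2m1**2, lam)

    if direction is LoadingDirection.CIRCUMFERENTIAL:
        G_load, G_tran = p.G1, p.G2
        trig2_load, trig2_tran = cos2, sin2
    else:
        G_load, G_tran = p.G2, p.G1
        trig2_load, trig2_tran = sin2, cos2
    G_rad_sq = 1.0 / (p.G1**2 * p.G2**2)  # elastin radial pre-stretch squared

    if form == "energy_consistent":
        elastin = (
            p.c1 * G_load**2 * lam**2
            - 0.5 * p.c1 * (G_tran**2 + G_rad_sq) / lam
        )
        fiber_kin = 2.0 * lam**2 * trig2_load - trig2_tran / lam
        collagen = (
            0.5 * (p.c2_1 * ln2m1 * np.exp(q1) + p.c2_2 * ln2m1 * np.exp(q2))
            * p.Gh**2 * fiber_kin
        )
        T = elastin + collagen
    elif form == "literal":
        # Verbatim transcription of the printed T1/T2, duplicated lam^2 and
        # (Gh * lam_n)^2 grouping included.
        ln = np.sqrt(ln2)
        elastin = -p.c1 / (G_load * lam) + p.c1 * G_load**2 * lam**2
        coll_sum = p.c2_1 * ln2m1 * np.exp(q1) + p.c2_2 * ln2m1 * np.exp(q2)
        T = elastin + lam**2 * coll_sum * (p.Gh * ln) ** 2 * lam**2 * trig2_load
    else:
        raise ValueError(f"unknown CMM stress form {form!r}")
    return T if T.shape else float(T)


# ---------------------------------------------------------------------------
# Strain energies along the uniaxial path, generic dispatch, oracles
# ---------------------------------------------------------------------------

def _principal_C_uniaxial(lam, direction: LoadingDirection):
    """Diagonal of C = F^T F in the material frame (circ, long, radial)."""
    lam = np.asarray(lam, dtype=float)
    lat = 1.0 / lam
    if direction is LoadingDirection.CIRCUMFERENTIAL:
        return lam**2, lat, lat
    return lat, lam**2, lat


def _fung_energy_C(p: FungParams, Cc, Cl, Cr):
    e1, e2, e3 = (Cc - 1.0) / 2.0, (Cl - 1.0) / 2.0, (Cr - 1.0) / 2.0
    Q = (
        p.b1 * e1**2 + p.b2 * e2**2 + p.b3 * e3**2
        + 2.0 * p.b4 * e1 * e2 + 2.0 * p.b5 * e1 * e3 + 2.0 * p.b6 * e2 * e3
    )
    return 0.5 * p.c1 * (np.exp(_check_exponent(Q, np.nan)) - 1.0)


def _holzapfel_energy_C(p: HolzapfelParams, Cc, Cl, Cr):
    I1 = Cc + Cl + Cr
    cos2, sin2 = np.cos(p.gamma) ** 2, np.sin(p.gamma) ** 2
    I4 = Cc * cos2 + Cl * sin2  # fibers in the circ-long plane
    aniso_q = _check_exponent(p.k2 * (I4 - 1.0) ** 2, np.nan)
    # two identical families i = 4, 6
    return 0.5 * p.c * (I1 - 3.0) + (p.k1 / p.k2) * (np.exp(aniso_q) - 1.0)


def _cmm_energy_C(p: CMMParams, Cc, Cl, Cr):
    # Elastin: in-plane C composed with pre-stretches; radial component by
    # constituent incompressibility.  Normalized to vanish in the elastin
    # natural configuration (constant offset; stress-invariant).
    l1sq = p.G1**2 * Cc
    l2sq = p.G2**2 * Cl
    We = 0.5 * p.c1 * (l1sq + l2sq + 1.0 / (l1sq * l2sq) - 3.0)
    cos2, sin2 = np.cos(p.alpha) ** 2, np.sin(p.alpha) ** 2
    lk2 = Cc * cos2 + Cl * sin2
    ln2 = p.Gh**2 * lk2
    q1 = _check_exponent(p.c3_1 * (ln2 - 1.0) ** 2, np.nan)
    q2 = _check_exponent(p.c3_2 * (ln2 - 1.0) ** 2, np.nan)
    Wc = 0.0
    if p.c2_1 > 0:
        Wc = Wc + p.c2_1 / (4.0 * p.c3_1) * (np.exp(q1) - 1.0)
    if p.c2_2 > 0:
        Wc = Wc + p.c2_2 / (4.0 * p.c3_2) * (np.exp(q2) - 1.0)
    return We + Wc


_ENERGY_C = {
    "fung": _fung_energy_C,
    "holzapfel": _holzapfel_energy_C,
    "cmm": _cmm_energy_C,
}

_CLOSED_FORMS = {
    "fung": fung_uniaxial_stress,
    "holzapfel": holzapfel_uniaxial_stress,
    "cmm": cmm_uniaxial_stress,
}


def uniaxial_stress(model: str, params, lam, direction: LoadingDirection, **kw):
    """Dispatch to the closed-form uniaxial Cauchy stress of ``model``."""
    try:
        f = _CLOSED_FORMS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return f(params, lam, direction, **kw)


def strain_energy(model: str, params, lam, direction: LoadingDirection):
    """Strain-energy density (MPa) at the uniaxial state ``lam``.

    Vanishes at lam=1 for Fung and Holzapfel; for the CMM the value at
    lam=1 is the stored pre-stretch energy (zero only for unit
    pre-stretches).
    """
    if model not in _ENERGY_C:
        raise ValueError(f"unknown model {model!r}")
    lam = _validate_stretch(lam)
    Cc, Cl, Cr = _principal_C_uniaxial(lam, direction)
    W = _ENERGY_C[model](params, Cc, Cl, Cr)
    return W if np.ndim(W) else float(W)


def numeric_stress_oracle(model: str, params, lam, direction: LoadingDirection,
                          h: float = 1e-5, check_truncation: bool = False,
                          truncation_rtol: float = 1e-4):
    """Path-derivative stress oracle: ``lam * (W(lam+h) - W(lam-h)) / (2h)``.

    ``W`` is the strain energy along the incompressible uniaxial path.  This
    equals the traction-free uniaxial Cauchy stress whenever the two lateral
    extra stresses coincide (see the module docstring); it is second-order
    accurate in ``h``.  With ``check_truncation`` the estimate at ``h`` is
    compared against ``h/2`` and a too-large step is rejected.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam - h <= 0):
        raise ValueError("require lam - h > 0")

    def deriv(step):
        wp = strain_energy(model, params, lam + step, direction)
        wm = strain_energy(model, params, lam - step, direction)
        return lam * (np.asarray(wp) - np.asarray(wm)) / (2.0 * step)

    T = deriv(h)
    if check_truncation:
        T2 = deriv(h / 2.0)
        scale = np.maximum(np.abs(T2), 1e-12)
        if np.any(np.abs(T - T2) / scale > truncation_rtol):
            raise ValueError(
                f"finite-difference step h={h:g} too large "
                f"(relative truncation error exceeds {truncation_rtol:g})"
            )
        T = T2
    return T if T.shape else float(T)


def lagrange_elimination_oracle(model: str, params, lam,
                                direction: LoadingDirection,
                                h: float = 1e-4):
    """Tensor-form stress oracle validating the multiplier elimination.

    Computes ``T = -p I + 2 F (dW/dC) F^T`` on the uniaxial state with
    ``dW/dC`` obtained by central differences on the principal components of
    ``C`` and the Lagrange multiplier fixed by the traction-free radial
    face, ``p = 2 lam^{-1} dW/dC_rr``.  This reproduces the hand-derived
    closed forms of the Fung and Holzapfel models for arbitrary parameters.
    """
    if model not in _ENERGY_C:
        raise ValueError(f"unknown model {model!r}")
    lam = _validate_stretch(np.asarray(lam, dtype=float))
    energy = _ENERGY_C[model]
    Cc, Cl, Cr = (np.asarray(x) for x in _principal_C_uniaxial(lam, direction))

    def central(i, step):
        dC = [np.zeros_like(Cc + 0.0) for _ in range(3)]
        dC[i] = np.full_like(dC[i], step)
        wp = energy(params, Cc + dC[0], Cl + dC[1], Cr + dC[2])
        wm = energy(params, Cc - dC[0], Cl - dC[1], Cr - dC[2])
        return (np.asarray(wp) - np.asarray(wm)) / (2.0 * step)

    def dW(i):
        # Richardson extrapolation of the central difference (4th order)
        return (4.0 * central(i, h / 2.0) - central(i, h)) / 3.0

    if direction is LoadingDirection.CIRCUMFERENTIAL:
        dW_load = dW(0)
    else:
        dW_load = dW(1)
    p_mult = 2.0 * dW(2) / lam
    T = 2.0 * lam**2 * dW_load - p_mult
    return T if T.shape else float(T)
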