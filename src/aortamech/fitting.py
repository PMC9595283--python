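"""Constitutive-parameter estimation on virtual biaxial pairs.

Each loading direction is fitted separately by bounded nonlinear least
squares with seeded Latin-hypercube multistart; a per-parameter *plausible
interval* is profiled around each direction's optimum (the contiguous range
of the parameter, others held at the best fit, keeping the residual norm
within a configurable factor of its minimum).  The two directions are then
integrated: the per-parameter intervals are intersected to a *common range*
and a single parameter vector is refitted on the concatenated two-direction
residual constrained to that range.  When the common range is empty or too
narrow, the residual factor is relaxed along a fixed non-decreasing schedule
and, past the cap, the fit falls back to an unconstrained joint fit with a
warning.

Uniaxial data cannot identify all Fung/CMM parameters uniquely (their
strong inter-correlations are themselves an analysis output), so the
estimation contract is reproduction of the stress–stretch curves; parameter
recovery is only expected for the four-parameter Holzapfel model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from aortamech.curves import StressStretchCurve
from aortamech.models import (
    MODEL_PARAM_CLASSES,
    LoadingDirection,
    NonFiniteStressError,
    uniaxial_stress,
)
from aortamech.pairing import VirtualBiaxialPair

__all__ = [
    "FitResult",
    "ParameterDistribution",
    "default_bounds",
    "fit_direction",
    "fit_virtual_pair",
    "summarize_distribution",
]

#: Non-decreasing residual-factor schedule for common-range relaxation.
TOLERANCE_SCHEDULE = (1.05, 1.1, 1.25, 1.5)

_STRESS_LIKE = {
    "fung": ["c1"],
    "holzapfel": ["c", "k1"],
    "cmm": ["c1", "c2_1", "c2_2"],
}


def default_bounds(model: str) -> dict[str, tuple[float, float]]:
    """Default fitting bounds per parameter (MPa for stress-like entries).

    Stress-like moduli span [1e-6, 10] MPa, exponential shape parameters
    [1e-4, 50], fiber angles [0, pi/2] rad and pre-stretches [0.8, 2.0] —
    generous headroom around values reported for thoracic aorta.
    """
    stress = (1e-6, 10.0)
    expo = (1e-4, 50.0)
    angle = (0.0, np.pi / 2)
    prestretch = (0.8, 2.0)
    if model == "fung":
        b = {f"b{i}": (0.0, 50.0) for i in range(1, 7)}
        return {"c1": stress, **b}
    if model == "holzapfel":
        return {"c": stress, "k1": stress, "k2": expo, "gamma": angle}
    if model == "cmm":
        return {
            "c1": stress, "c2_1": stress, "c2_2": stress,
            "c3_1": expo, "c3_2": expo,
            "G1": prestretch, "G2": prestretch, "Gh": prestretch,
            "alpha": angle,
        }
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameter vector and goodness of fit for one curve or pair."""

    model: str
    params: object
    per_direction_R2: tuple[float, float]  # (circumferential, longitudinal)
    residual_norm: float
    converged: bool
    tolerance_used: float
    fallback: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class ParameterDistribution:
    """Five-number summary of one parameter over converged fits."""

    model: str
    region: str
    parameter: str
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int
    n_excluded: int = 0

    def __post_init__(self):
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError(f"quartile ordering violated: {vals}")

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class _Profile:
    """Residual-norm scans used to extract plausible intervals at any factor.

    ``norm_floor`` keeps the threshold meaningful on (near-)noiseless data,
    where the minimum residual is at machine zero; ``pool`` holds all
    near-optimal multistart solutions, which sample the correlated parameter
    ridges that a one-at-a-time profile under-covers.
    """

    names: list[str]
    grids: list[np.ndarray]
    norms: list[np.ndarray]
    best: np.ndarray
    best_norm: float
    norm_floor: float = 0.0
    pool: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def intervals(self, factor: float) -> dict[str, tuple[float, float]]:
        """Per-parameter range keeping the residual norm <= factor * minimum."""
        out = {}
        thresh = factor * max(self.best_norm, self.norm_floor, 1e-12)
        pool_ok = [x for x, norm in self.pool if norm <= thresh]
        for k, (name, grid, norm, b) in enumerate(
                zip(self.names, self.grids, self.norms, self.best)):
            ok = norm <= thresh
            i0 = int(np.argmin(np.abs(grid - b)))
            lo = i0
            while lo > 0 and ok[lo - 1]:
                lo -= 1
            hi = i0
            while hi < len(grid) - 1 and ok[hi + 1]:
                hi += 1
            # interpolate the threshold crossing into the first failing
            # neighbour (the true boundary lies between grid points)
            b_lo, b_hi = grid[lo], grid[hi]
            if lo > 0 and np.isfinite(norm[lo - 1]) and norm[lo - 1] > thresh:
                f = (thresh - norm[lo]) / (norm[lo - 1] - norm[lo])
                b_lo = grid[lo] + f * (grid[lo - 1] - grid[lo])
            if (hi < len(grid) - 1 and np.isfinite(norm[hi + 1])
                    and norm[hi + 1] > thresh):
                f = (thresh - norm[hi]) / (norm[hi + 1] - norm[hi])
                b_hi = grid[hi] + f * (grid[hi + 1] - grid[hi])
            vals = [b_lo, b_hi, b] + [x[k] for x in pool_ok]
            out[name] = (float(min(vals)), float(max(vals)))
        return out


def _is_log_scaled(lo: float, hi: float) -> bool:
    return lo > 0 and hi / lo > 1e3


def _starts(model: str, bounds: dict, n_starts: int, seed: int,
            init) -> list[np.ndarray]:
    """Informed starts (clipped to bounds) followed by seeded Latin-hypercube
    points over the bounds; ``n_starts`` is the total budget."""
    names = MODEL_PARAM_CLASSES[model].param_names()
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    if init is None:
        inits = []
    elif isinstance(init, (list, tuple)):
        inits = [np.asarray(x, dtype=float) for x in init]
    else:
        inits = [np.asarray(init, dtype=float)]
    pts = [np.clip(x, lo, hi) for x in inits]
    n_lhs = max(n_starts - len(pts), 0)
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        u = sampler.random(n_lhs)
        for row in u:
            x = np.empty_like(row)
            for k, n in enumerate(names):
                if _is_log_scaled(*bounds[n]):
                    x[k] = 10 ** (np.log10(lo[k]) + row[k] * (np.log10(hi[k]) - np.log10(lo[k])))
                else:
                    x[k] = lo[k] + row[k] * (hi[k] - lo[k])
            pts.append(x)
    return pts


def _residual_fn(model: str, curves_dirs: list[tuple[np.ndarray, np.ndarray, LoadingDirection]]):
    cls = MODEL_PARAM_CLASSES[model]

    def resid(x: np.ndarray) -> np.ndarray:
        try:
            p = cls.from_array(x)
            parts = [
                np.asarray(uniaxial_stress(model, p, lam, d)) - obs
                for lam, obs, d in curves_dirs
            ]
            r = np.concatenate(parts)
            if not np.all(np.isfinite(r)):
                raise NonFiniteStressError
            return r
        except (NonFiniteStressError, ValueError, FloatingPointError):
            return np.full(sum(len(o) for _, o, _ in curves_dirs), 1e6)

    return resid


def _solve(model: str, curves_dirs, bounds: dict, n_starts: int, seed: int,
           init=None):
    """Multistart bounded least squares.

    Returns ``(x_best, cost, success, pool)`` where ``pool`` is every
    start's ``(x, residual_norm)``.  Multistart stops early once a fit is
    essentially exact relative to the data scale (further starts cannot
    improve it meaningfully).
    """
    names = MODEL_PARAM_CLASSES[model].param_names()
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    resid = _residual_fn(model, curves_dirs)
    data_norm = float(np.linalg.norm(np.concatenate([o for _, o, _ in curves_dirs])))
    exact_cost = 0.5 * (1e-7 * max(data_norm, 1e-12)) ** 2
    best = None
    pool = []
    for x0 in _starts(model, bounds, n_starts, seed, init):
        try:
            with np.errstate(all="ignore"):  # penalty plateaus overflow inside trf
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                    xtol=1e-10, ftol=1e-10, gtol=1e-10, x_scale='jac',
                                    max_nfev=100 * len(names))
        except Exception:  # optimizer failure at one start is not fatal
            continue
        pool.append((sol.x.copy(), float(np.sqrt(2.0 * sol.cost))))
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= exact_cost:
            break
    if best is None:
        raise RuntimeError("all multistart attempts failed")
    return best.x, float(best.cost), bool(best.success), pool


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - pred) ** 2))
    if ss_tot <= 1e-300:
        return 1.0 if ss_res <= 1e-300 else 0.0
    return 1.0 - ss_res / ss_tot


def _fixed_param_resid(model: str, curves_dirs, k: int, value: float):
    """Residual over the remaining parameters with parameter ``k`` fixed."""
    full = _residual_fn(model, curves_dirs)

    def resid(x_red: np.ndarray) -> np.ndarray:
        x = np.insert(x_red, k, value)
        return full(x)

    return resid


def _profile_scan(model: str, curves_dirs, x_best: np.ndarray,
                  bounds: dict, n_grid: int = 15,
                  pool: list | None = None,
                  max_factor: float = TOLERANCE_SCHEDULE[-1]) -> _Profile:
    """Re-optimizing residual profile per parameter.

    For each grid value of one parameter the *remaining* parameters are
    refitted (warm-started marching outward from the optimum), so the
    profile follows the correlated parameter ridges instead of slicing
    across them.  Marching stops once the profiled norm exceeds the largest
    factor the relaxation schedule can ever request.
    """
    names = MODEL_PARAM_CLASSES[model].param_names()
    resid_full = _residual_fn(model, curves_dirs)
    best_norm = float(np.linalg.norm(resid_full(x_best)))
    data_norm = float(np.linalg.norm(np.concatenate([o for _, o, _ in curves_dirs])))
    norm_floor = 1e-4 * data_norm
    stop_norm = max_factor * max(best_norm, norm_floor, 1e-12) * 1.001

    grids, norms = [], []
    for k, name in enumerate(names):
        lo, hi = bounds[name]
        if _is_log_scaled(lo, hi):
            grid = np.geomspace(lo, hi, n_grid)
        else:
            grid = np.linspace(lo, hi, n_grid)
        grid = np.unique(np.append(grid, x_best[k]))
        ns = np.full(len(grid), np.inf)
        i0 = int(np.argmin(np.abs(grid - x_best[k])))
        ns[i0] = best_norm
        lo_red = np.delete([bounds[n][0] for n in names], k)
        hi_red = np.delete([bounds[n][1] for n in names], k)
        def refit(value, x0_red):
            r = _fixed_param_resid(model, curves_dirs, k, value)
            try:
                with np.errstate(all="ignore"):
                    sol = least_squares(
                        r, np.clip(x0_red, lo_red, hi_red),
                        bounds=(lo_red, hi_red), method="trf",
                        xtol=1e-9, ftol=1e-9, gtol=1e-9, x_scale='jac',
                        max_nfev=60 * len(names))
                return float(np.sqrt(2.0 * sol.cost)), sol.x
            except Exception:
                return np.inf, x0_red

        for direction in (1, -1):
            x_red = np.delete(x_best, k)
            i = i0 + direction
            while 0 <= i < len(grid):
                ns[i], x_red = refit(grid[i], x_red)
                if ns[i] > stop_norm:
                    # marching may have left the optimal ridge: one retry
                    # warm-started from the global optimum's companions
                    n2, x2 = refit(grid[i], np.delete(x_best, k))
                    if n2 < ns[i]:
                        ns[i], x_red = n2, x2
                if ns[i] > stop_norm:
                    break
                i += direction
        grids.append(grid)
        norms.append(ns)
    return _Profile(names, grids, norms, x_best.copy(), best_norm,
                    norm_floor=norm_floor, pool=pool or [])


def fit_direction(curve: StressStretchCurve, model: str,
                  init: np.ndarray | None = None,
                  bounds: dict | None = None,
                  n_starts: int = 8, seed: int = 0,
                  profile_factor: float = 1.05,
                  r2_floor: float = 0.9):
    """Fit one model to one uniaxial curve.

    Returns ``(FitResult, intervals)`` where ``intervals`` maps each
    parameter to its plausible range at ``profile_factor``.  The full
    profile scan is attached to the result for cheap re-extraction at
    relaxed factors (used by :func:`fit_virtual_pair`).
    """
    bounds = bounds or default_bounds(model)
    curves_dirs = [(curve.stretch, curve.stress, curve.direction)]
    x, cost, success, pool = _solve(model, curves_dirs, bounds, n_starts, seed, init)
    cls = MODEL_PARAM_CLASSES[model]
    p = cls.from_array(x)
    pred = np.asarray(uniaxial_stress(model, p, curve.stretch, curve.direction))
    r2 = _r2(curve.stress, pred)
    degenerate = float(np.max(np.abs(curve.stress))) == 0.0
    if curve.direction is LoadingDirection.CIRCUMFERENTIAL:
        per_dir = (r2, np.nan)
    else:
        per_dir = (np.nan, r2)
    res = FitResult(
        model=model, params=p, per_direction_R2=per_dir,
        residual_norm=float(np.sqrt(2.0 * cost)),
        converged=bool(degenerate or r2 >= r2_floor),
        tolerance_used=profile_factor, degenerate=degenerate,
    )
    n_grid = 15 if len(cls.param_names()) <= 4 else 11
    profile = _profile_scan(model, curves_dirs, x, bounds, n_grid=n_grid,
                            pool=pool)
    intervals = profile.intervals(profile_factor)
    return res, intervals, profile


def _intersect(a: dict, b: dict, bounds: dict,
               min_rel_width: float = 1e-3) -> tuple[dict | None, bool]:
    """Per-parameter interval intersection.

    Returns ``(common, narrow)``: ``common`` is None when any intersection
    is empty; ``narrow`` marks intersections thinner than
    ``min_rel_width`` of the parameter span (e.g. a pair caught in
    transition), which triggers tolerance relaxation before acceptance.
    """
    out = {}
    narrow = False
    for name in a:
        lo = max(a[name][0], b[name][0])
        hi = min(a[name][1], b[name][1])
        span = bounds[name][1] - bounds[name][0]
        if hi < lo - 1e-9 * span:  # span-relative slack: point intervals touch
            return None, False
        hi = max(hi, lo)
        if (hi - lo) < min_rel_width * span:
            narrow = True
        out[name] = (lo, hi)
    return out, narrow


def _pad_ranges(common: dict, bounds: dict,
                min_rel_width: float = 1e-3) -> dict:
    """Widen degenerate common ranges so the bounded refit is well posed."""
    out = {}
    for name, (lo, hi) in common.items():
        blo, bhi = bounds[name]
        w = min_rel_width * (bhi - blo)
        if hi - lo < w:
            mid = 0.5 * (lo + hi)
            lo, hi = mid - 0.5 * w, mid + 0.5 * w
            lo, hi = max(lo, blo), min(hi, bhi)
        out[name] = (lo, hi)
    return out


def fit_virtual_pair(pair: VirtualBiaxialPair, model: str,
                     bounds: dict | None = None,
                     n_starts: int = 8, joint_starts: int = 4,
                     seed: int = 0,
                     schedule: tuple = TOLERANCE_SCHEDULE,
                     r2_floor: float = 0.9) -> FitResult:
    """Joint two-direction fit with common-range integration.

    Per-direction fits give plausible intervals; their intersection bounds a
    joint refit on the concatenated residual.  The residual factor relaxes
    along ``schedule`` (never tightens) and, past the cap, the joint fit
    runs unconstrained with a warning.
    """
    if list(schedule) != sorted(schedule):
        raise ValueError("tolerance schedule must be non-decreasing")
    bounds = bounds or default_bounds(model)
    circ, long_ = pair.circ_curve, pair.long_curve

    try:
        fit_c, _, prof_c = fit_direction(circ, model, bounds=bounds,
                                         n_starts=n_starts, seed=seed,
                                         r2_floor=r2_floor)
        fit_l, _, prof_l = fit_direction(long_, model, bounds=bounds,
                                         n_starts=n_starts, seed=seed + 1,
                                         r2_floor=r2_floor)
    except RuntimeError:
        nan_p = None
        return FitResult(model, nan_p, (np.nan, np.nan), np.inf,
                         converged=False, tolerance_used=np.nan, fallback=True)

    joint_dirs = [
        (circ.stretch, circ.stress, circ.direction),
        (long_.stretch, long_.stress, long_.direction),
    ]
    cls = MODEL_PARAM_CLASSES[model]
    xc, xl = fit_c.params.to_array(), fit_l.params.to_array()
    inits = [0.5 * (xc + xl), xc, xl]

    common = None
    tol = np.nan
    for factor in schedule:
        cand, narrow = _intersect(prof_c.intervals(factor),
                                  prof_l.intervals(factor), bounds)
        if cand is not None:
            common, tol = cand, factor
            if not narrow:
                break
    if common is not None:
        # a still-narrow but non-empty range at the cap is usable once padded
        common = _pad_ranges(common, bounds)

    fallback = common is None
    if fallback:
        warnings.warn(
            f"pair {pair.pair_index} ({model}): empty/too-narrow common "
            "parameter range after full tolerance relaxation; falling back "
            "to unconstrained joint fitting",
            RuntimeWarning,
            stacklevel=2,
        )
        joint_bounds = bounds
        tol = schedule[-1]
    else:
        joint_bounds = common

    x, cost, success, _ = _solve(model, joint_dirs, joint_bounds,
                                 max(joint_starts, len(inits) + 1),
                                 seed + 2, init=inits)

    # Quality guard: the common range is built from profiled boundaries and
    # can narrowly exclude the jointly optimal vector.  If the constrained
    # fit is materially worse than the two direction fits imply is possible,
    # refit without the common-range constraint and keep the better result.
    target_norm = float(np.hypot(fit_c.residual_norm, fit_l.residual_norm))
    data_norm = float(np.hypot(np.linalg.norm(circ.stress),
                               np.linalg.norm(long_.stress)))
    attainable = max(target_norm, 1e-4 * data_norm)
    if not fallback and np.sqrt(2.0 * cost) > schedule[-1] * attainable:
        x2, cost2, success2, _ = _solve(model, joint_dirs, bounds,
                                        max(joint_starts, len(inits) + 1),
                                        seed + 3, init=inits)
        if cost2 < cost:
            warnings.warn(
                f"pair {pair.pair_index} ({model}): common-range joint fit "
                "under-performs the per-direction fits; using the "
                "unconstrained joint fit instead",
                RuntimeWarning,
                stacklevel=2,
            )
            x, cost, success = x2, cost2, success2
            fallback = True
    p = cls.from_array(x)
    r2c = _r2(circ.stress, np.asarray(uniaxial_stress(model, p, circ.stretch, circ.direction)))
    r2l = _r2(long_.stress, np.asarray(uniaxial_stress(model, p, long_.stretch, long_.direction)))
    converged = bool(r2c >= r2_floor and r2l >= r2_floor)
    return FitResult(
        model=model, params=p, per_direction_R2=(r2c, r2l),
        residual_norm=float(np.sqrt(2.0 * cost)),
        converged=converged, tolerance_used=float(tol), fallback=fallback,
    )


def summarize_distribution(fits: list[FitResult], region: str,
                           model: str) -> list[ParameterDistribution]:
    """Five-number summaries (linear-interpolation quartiles) per parameter.

    Non-converged fits are excluded and counted; raises when no fit
    converged.
    """
    converged = [f for f in fits if f.converged and f.model == model]
    n_excluded = sum(1 for f in fits if f.model == model) - len(converged)
    if not converged:
        raise ValueError(f"no converged {model} fits for region {region}")
    names = MODEL_PARAM_CLASSES[model].param_names()
    arr = np.array([f.params.to_array() for f in converged])
    out = []
    for k, name in enumerate(names):
        v = arr[:, k]
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        out.append(ParameterDistribution(
            model=model, region=region, parameter=name,
            min=float(v.min()), q1=float(q1), median=float(med),
            q3=float(q3), max=float(v.max()), n=len(v), n_excluded=n_excluded,
        ))
    return out
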