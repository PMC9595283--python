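"""Distributional and correlation statistics over regions.

Implements the study's statistical flow: every sample is gated through a
Shapiro–Wilk normality test; samples failing the gate are Box–Cox
transformed (maximum-likelihood lambda) before any mean comparison;
regional differences are then examined by two-sample t-tests over the six
region pairs and by one-way ANOVA with Bonferroni-corrected post-hoc
pairwise tests.  Correlations (Pearson or Spearman) are computed per region
and a variable pair is *reported* only when it is significantly correlated
in all four regions; the per-region coefficients are averaged into a single
trend statistic and checked for sign uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from aortamech.curves import REGIONS

__all__ = [
    "RegionComparison",
    "ComparisonReport",
    "CorrelationResult",
    "REGION_PAIRS",
    "normality_gate",
    "boxcox_optimal",
    "compare_regions",
    "correlation_matrix",
]

#: The six region contrasts, in the study's order:
#: proximal-distal, anterior-posterior, and their interactions.
REGION_PAIRS = (
    ("PA", "DA"), ("PP", "DP"), ("PA", "PP"),
    ("DA", "DP"), ("PA", "DP"), ("PP", "DA"),
)

ALPHA = 0.05


@dataclass(frozen=True)
class RegionComparison:
    """One difference test between two regions for one variable."""

    variable: str
    region_a: str
    region_b: str
    test: str  # "t" | "anova" | "anova_bonferroni"
    statistic: float
    p_value: float
    transformed: bool
    significant: bool

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class ComparisonReport:
    """All difference tests for one variable, plus the normality audit log.

    ``audit`` records, for every test actually run, which groups passed the
    normality gate and whether a Box–Cox transform was applied first — so
    the no-untransformed-t-test-on-non-normal-data rule is checkable.
    """

    variable: str
    comparisons: list[RegionComparison] = field(default_factory=list)
    audit: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    """Per-region correlation of one variable pair with region-averaged r."""

    var_x: str
    var_y: str
    method: str
    r_by_region: dict
    p_by_region: dict
    mean_r: float
    uniform_sign: bool
    reported: bool


def normality_gate(values) -> tuple[bool, float]:
    """Shapiro–Wilk normality gate; normal iff p >= 0.05."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality undefined")
    stat, p = sps.shapiro(v)
    return bool(p >= ALPHA), float(p)


def boxcox_optimal(values) -> tuple[np.ndarray, float]:
    """Box–Cox transform with maximum-likelihood lambda.

    ``y = (x**lam - 1)/lam`` (``log x`` at lam = 0); requires strictly
    positive input and raises on (near-)constant samples, for which the
    likelihood in lambda is flat.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: Box-Cox lambda undefined")
    transformed, lam = sps.boxcox(v)
    return transformed, float(lam)


def _gated_transform(groups: dict[str, np.ndarray], audit: list, context: str):
    """Apply the normality gate to every group; Box–Cox (shared pooled
    lambda) when any group fails.  Returns (groups, transformed_flag)."""
    gates = {k: normality_gate(v) for k, v in groups.items()}
    all_normal = all(ok for ok, _ in gates.values())
    entry = {
        "context": context,
        "gate_p": {k: p for k, (_, p) in gates.items()},
        "all_normal": all_normal,
        "transformed": False,
    }
    if all_normal:
        audit.append(entry)
        return groups, False
    pooled = np.concatenate(list(groups.values()))
    shift = 0.0
    if pooled.min() <= 0:
        shift = 1.0 - pooled.min()
    _, lam = boxcox_optimal(pooled + shift)
    out = {k: sps.boxcox(v + shift, lmbda=lam) for k, v in groups.items()}
    entry["transformed"] = True
    entry["boxcox_lambda"] = lam
    audit.append(entry)
    return out, True


def compare_regions(values_by_region: dict, variable: str,
                    alpha: float = ALPHA,
                    equal_var: bool = False) -> ComparisonReport:
    """Regional difference tests for one variable.

    Runs the six pairwise t-tests (Welch by default) and a one-way ANOVA
    with Bonferroni-corrected post-hoc pairwise tests, each preceded by the
    normality gate and, on failure, a shared Box–Cox transform.  Requires
    at least two regions with n >= 3 non-constant values each.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_region.items()}
    if len(groups) < 2:
        raise ValueError("need at least two regions")
    for k, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"region {k}: need n >= 3")
        if np.ptp(v) == 0:
            raise ValueError(f"region {k}: constant sample")
    report = ComparisonReport(variable=variable)

    # -- pairwise t-tests over the six contrasts present in the data
    for a, b in REGION_PAIRS:
        if a not in groups or b not in groups:
            continue
        pair_groups, transformed = _gated_transform(
            {a: groups[a], b: groups[b]}, report.audit, f"t:{a}-{b}")
        stat, p = sps.ttest_ind(pair_groups[a], pair_groups[b],
                                equal_var=equal_var)
        report.comparisons.append(RegionComparison(
            variable, a, b, "t", float(stat), float(p),
            transformed, bool(p < alpha)))

    # -- one-way ANOVA + Bonferroni post-hoc
    if len(groups) >= 2:
        anova_groups, transformed = _gated_transform(
            groups, report.audit, "anova")
        fstat, fp = sps.f_oneway(*anova_groups.values())
        report.comparisons.append(RegionComparison(
            variable, "all", "all", "anova", float(fstat), float(fp),
            transformed, bool(fp < alpha)))
        pairs = [pr for pr in REGION_PAIRS if pr[0] in groups and pr[1] in groups]
        raw = []
        stats_ = []
        for a, b in pairs:
            s, p = sps.ttest_ind(anova_groups[a], anova_groups[b],
                                 equal_var=equal_var)
            raw.append(p)
            stats_.append(s)
        if raw:
            _, corrected, _, _ = multipletests(raw, method="bonferroni")
            for (a, b), s, p in zip(pairs, stats_, corrected):
                report.comparisons.append(RegionComparison(
                    variable, a, b, "anova_bonferroni", float(s), float(p),
                    transformed, bool(p < alpha)))
    return report


def correlation_matrix(tables: dict[str, pd.DataFrame],
                       method: str = "spearman",
                       alpha: float = ALPHA,
                       pairs: list[tuple[str, str]] | None = None
                       ) -> list[CorrelationResult]:
    """Region-wise correlations with four-region averaging.

    ``tables`` maps each of the four regions to a DataFrame of paired
    observations (rows: specimens/fits; columns: variables).  For every
    variable pair the per-region r and p are computed; ``mean_r`` averages r
    over PA, PP, DA, DP; ``reported`` is true only when the pair is
    significantly correlated (p < alpha, r != 0) in all four regions.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    missing = [r for r in REGIONS if r not in tables]
    if missing:
        raise ValueError(f"missing region(s): {missing}")
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr

    common_cols = set(tables[REGIONS[0]].columns)
    for r in REGIONS[1:]:
        common_cols &= set(tables[r].columns)
    if pairs is None:
        pairs = list(combinations(sorted(common_cols), 2))

    results = []
    for vx, vy in pairs:
        r_by, p_by = {}, {}
        for region in REGIONS:
            t = tables[region][[vx, vy]].dropna()
            if len(t) < 3:
                raise ValueError(f"region {region}: need >= 3 paired observations")
            r, p = corr(t[vx].to_numpy(), t[vy].to_numpy())
            r_by[region] = float(r)
            p_by[region] = float(p)
        rs = np.array([r_by[r] for r in REGIONS])
        finite = np.all(np.isfinite(rs))
        mean_r = float(rs.mean()) if finite else np.nan
        uniform = bool(finite and (np.all(rs > 0) or np.all(rs < 0)))
        reported = bool(
            finite
            and all(p_by[r] < alpha for r in REGIONS)
            and np.all(rs != 0)
        )
        results.append(CorrelationResult(
            var_x=vx, var_y=vy, method=method,
            r_by_region=r_by, p_by_region=p_by,
            mean_r=mean_r, uniform_sign=uniform, reported=reported,
        ))
    return results
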