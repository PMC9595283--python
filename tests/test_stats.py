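"""Statistical pipeline: gate calibration, Box-Cox, comparisons, correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aortamech.curves import REGIONS
from aortamech.stats import (
    REGION_PAIRS,
    boxcox_optimal,
    compare_regions,
    correlation_matrix,
    normality_gate,
)


class TestNormalityGate:
    def test_level_under_the_null(self):
        """Gaussian samples pass the gate in >= 90% of seeded repetitions."""
        passed = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            ok, _ = normality_gate(rng.standard_normal(500))
            passed += ok
        assert passed >= 90

    def test_power_against_lognormal(self):
        rejected = 0
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            ok, _ = normality_gate(rng.lognormal(0.0, 1.0, 500))
            rejected += not ok
        assert rejected >= 99

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_gate(np.ones(20))
        with pytest.raises(ValueError, match="n >= 3"):
            normality_gate([1.0, 2.0])


class TestBoxCox:
    def test_lambda_near_zero_for_lognormal(self):
        rng = np.random.default_rng(3)
        _, lam = boxcox_optimal(rng.lognormal(0.0, 1.0, 1000))
        assert abs(lam) < 0.15

    def test_transformed_lognormal_passes_gate(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0.0, 1.0, 400)
        assert not normality_gate(x)[0]
        y, _ = boxcox_optimal(x)
        assert normality_gate(y)[0]

    def test_nonpositive_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_optimal([1.0, -2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            boxcox_optimal([1.0, 1.0, 1.0])


class TestCompareRegions:
    def groups(self, rng, shift=0.0, n=50):
        g = {r: rng.standard_normal(n) for r in REGIONS}
        g["DP"] = g["DP"] + shift
        return g

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        rep = compare_regions({"PA": x, "DA": x.copy()}, "v")
        t = [c for c in rep.comparisons if c.test == "t"][0]
        assert t.p_value == pytest.approx(1.0)
        assert not t.significant

    def test_power_for_one_sd_shift(self):
        hits = 0
        for rep_i in range(200):
            rng = np.random.default_rng(4000 + rep_i)
            a, b = rng.standard_normal(50), rng.standard_normal(50) + 1.0
            rep = compare_regions({"PA": a, "DA": b}, "v")
            t = [c for c in rep.comparisons if c.test == "t"][0]
            hits += t.significant
        assert hits >= 180

    def test_six_region_pairs_and_anova_emitted(self):
        rng = np.random.default_rng(6)
        rep = compare_regions(self.groups(rng), "v")
        t_pairs = [(c.region_a, c.region_b) for c in rep.comparisons if c.test == "t"]
        assert t_pairs == list(REGION_PAIRS)
        assert sum(c.test == "anova" for c in rep.comparisons) == 1
        assert sum(c.test == "anova_bonferroni" for c in rep.comparisons) == 6

    def test_gate_always_precedes_untransformed_t_test(self):
        """Audit rule: a t-test on non-normal data must follow a Box-Cox pass."""
        rng = np.random.default_rng(7)
        groups = {r: rng.lognormal(0.0, 1.0, 60) for r in REGIONS}
        rep = compare_regions(groups, "v")
        for entry in rep.audit:
            if not entry["all_normal"]:
                assert entry["transformed"]
        transformed_flags = {(c.region_a, c.region_b): c.transformed
                             for c in rep.comparisons if c.test == "t"}
        assert all(transformed_flags.values())

    def test_bonferroni_never_reduces_p(self):
        rng = np.random.default_rng(8)
        groups = self.groups(rng, shift=0.6)
        rep = compare_regions(groups, "v")
        raw = {(c.region_a, c.region_b): c.p_value
               for c in rep.comparisons if c.test == "t"}
        # same transform state for pairwise t and post-hoc here (all normal)
        for c in rep.comparisons:
            if c.test == "anova_bonferroni":
                assert c.p_value >= raw[(c.region_a, c.region_b)] - 1e-12

    def test_small_or_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_regions({"PA": [1.0, 2.0], "DA": [1.0, 2.0, 3.0]}, "v")
        with pytest.raises(ValueError, match="constant"):
            compare_regions({"PA": [1.0, 1.0, 1.0], "DA": [1.0, 2.0, 3.0]}, "v")


class TestCorrelations:
    def tables(self, rng, n=20, monotone=True):
        out = {}
        for r in REGIONS:
            x = rng.uniform(0.5, 2.0, n)
            y = x**3 if monotone else rng.standard_normal(n)
            out[r] = pd.DataFrame({"x": x, "y": y})
        return out

    def test_spearman_one_on_monotone_pair(self):
        res = correlation_matrix(self.tables(np.random.default_rng(9)),
                                 method="spearman")[0]
        assert all(v == pytest.approx(1.0) for v in res.r_by_region.values())
        assert res.mean_r == pytest.approx(1.0)
        assert res.reported and res.uniform_sign

    def test_spearman_minus_one_on_antimonotone_pair(self):
        rng = np.random.default_rng(10)
        tables = {}
        for r in REGIONS:
            x = rng.uniform(0.5, 2.0, 15)
            tables[r] = pd.DataFrame({"x": x, "y": -np.exp(x)})
        res = correlation_matrix(tables, method="spearman")[0]
        assert res.mean_r == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        tables = {r: pd.DataFrame({"x": rng.standard_normal(25),
                                   "y": rng.standard_normal(25)})
                  for r in REGIONS}
        base = correlation_matrix(tables, method="spearman")[0]
        warped = {r: pd.DataFrame({"x": np.exp(t["x"]), "y": t["y"] ** 3})
                  for r, t in tables.items()}
        res = correlation_matrix(warped, method="spearman")[0]
        assert res.r_by_region == base.r_by_region

    def test_independent_pairs_rarely_reported_in_all_regions(self):
        """Requiring p < 0.05 in all four regions is a ~0.05^4-order event."""
        reported = 0
        for rep in range(1000):
            rng = np.random.default_rng(5000 + rep)
            res = correlation_matrix(self.tables(rng, monotone=False),
                                     method="spearman")[0]
            reported += res.reported
        assert reported <= 10  # <= 1%

    def test_mixed_signs_break_uniformity(self):
        rng = np.random.default_rng(12)
        tables = {}
        for i, r in enumerate(REGIONS):
            x = rng.uniform(0.5, 2.0, 15)
            sign = -1.0 if r == "PP" else 1.0
            tables[r] = pd.DataFrame({"x": x, "y": sign * x})
        res = correlation_matrix(tables, method="spearman")[0]
        assert not res.uniform_sign

    def test_missing_region_rejected(self):
        rng = np.random.default_rng(13)
        tables = self.tables(rng)
        del tables["DP"]
        with pytest.raises(ValueError, match="missing region"):
            correlation_matrix(tables)

    def test_pearson_method_supported(self):
        res = correlation_matrix(self.tables(np.random.default_rng(14)),
                                 method="pearson")[0]
        assert all(0.9 < v <= 1.0 for v in res.r_by_region.values())
        with pytest.raises(ValueError, match="method"):
            correlation_matrix(self.tables(np.random.default_rng(15)),
                               method="kendall")
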