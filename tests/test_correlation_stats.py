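"""Per-unit normalization, Spearman oracle equivalence, correlation reports,
pairwise comparisons, crossed grids."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import glyphcurate as gc
from glyphcurate.correlation_stats import (
    NormalizationError,
    StatsError,
    correlation_report,
    crossed_grid,
    normalize_per_unit,
    significance_tier,
)


def _frame(units):
    rows = []
    for uid, vals in units.items():
        for k, v in enumerate(vals):
            rows.append({"unit_id": uid, "item_id": f"i{k}", "value": v})
    return pd.DataFrame(rows)


class TestNormalizePerUnit:
    def test_simple_values(self):
        out = normalize_per_unit(_frame({"u": [2.0, 3.0, 5.0]}))
        assert out["value"].tolist() == [0.2, 0.3, 0.5]

    def test_single_item_unit(self):
        out = normalize_per_unit(_frame({"u": [7.0]}))
        assert out["value"].tolist() == [1.0]

    def test_sums_and_order_preserved(self):
        rng = np.random.default_rng(1)
        df = _frame({f"u{k}": rng.uniform(0.1, 2.0, size=9) for k in range(6)})
        out = normalize_per_unit(df)
        for _, grp in out.groupby("unit_id"):
            assert grp["value"].sum() == pytest.approx(1.0, abs=1e-9)
        # strictly increasing transform preserves within-unit order
        for uid in df["unit_id"].unique():
            before = df.loc[df.unit_id == uid, "value"].to_numpy()
            after = out.loc[out.unit_id == uid, "value"].to_numpy()
            assert np.array_equal(np.argsort(before), np.argsort(after))

    def test_nonpositive_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_per_unit(_frame({"u": [1.0, 0.0]}))


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert gc.spearman(x, x).rho == pytest.approx(1.0)
        assert gc.spearman(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_constant_flagged(self):
        res = gc.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined

    def test_too_short_rejected(self):
        with pytest.raises(StatsError):
            gc.spearman([1.0, 2.0], [2.0, 1.0])

    def test_exhaustive_oracle_small_inputs(self):
        """Equals Pearson on midranks for every permutation pair of size <= 8
        (sampled y-permutations at larger sizes, exhaustive at n <= 4)."""
        rng = np.random.default_rng(0)
        for n in range(3, 9):
            x = np.arange(n, dtype=float)
            if n <= 4:
                perms = list(itertools.permutations(range(n)))
            else:
                perms = [tuple(rng.permutation(n)) for _ in range(40)]
            for perm in perms:
                y = np.array(perm, dtype=float)
                res = gc.spearman(x, y)
                expected = stats.pearsonr(stats.rankdata(x),
                                          stats.rankdata(y))[0]
                assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_ties_use_midranks(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [4.0, 5.0, 6.0, 7.0]
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert gc.spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=4, max_size=12,
                    unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        """rho unchanged by strictly increasing transforms of either input."""
        rng = np.random.default_rng(len(xs))
        y = rng.permutation(len(xs)).astype(float) + 1.0
        base = gc.spearman(xs, y).rho
        assert gc.spearman(np.log(xs), y).rho == pytest.approx(base, abs=1e-12)
        assert gc.spearman(xs, np.exp(y / 10)).rho == pytest.approx(base,
                                                                    abs=1e-12)


class TestCorrelationReport:
    def _conf(self, rng, n_items=12, n_nets=4):
        idx = pd.Index([f"i{k}" for k in range(n_items)], name="instance_id")
        data = {f"net{j}": rng.uniform(0.1, 1.2, n_items)
                for j in range(n_nets)}
        return pd.DataFrame(data, index=idx)

    def test_single_net_equals_per_net_rho(self):
        rng = np.random.default_rng(5)
        conf = self._conf(rng, n_nets=1)
        rts = pd.Series(rng.uniform(0.001, 0.02, 12), index=conf.index)
        rep = correlation_report(conf, rts)
        assert rep.rho_of_means == pytest.approx(rep.per_net_rhos[0])

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        rts = pd.Series(rng.uniform(0.001, 0.02, 10),
                        index=pd.Index([f"i{k}" for k in range(10)],
                                       name="instance_id"))
        conf = pd.DataFrame({"net0": rts.to_numpy()}, index=rts.index)
        rep = correlation_report(conf, rts)
        assert rep.rho_of_means == pytest.approx(1.0)

    def test_item_sets_intersected(self):
        rng = np.random.default_rng(7)
        conf = self._conf(rng, n_items=12)
        rts = pd.Series(rng.uniform(0.001, 0.02, 8),
                        index=pd.Index([f"i{k}" for k in range(4, 12)],
                                       name="instance_id"))
        rep = correlation_report(conf, rts)
        assert rep.n_items == 8

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(8)
        conf = self._conf(rng)
        rts = pd.Series([0.1, 0.2, 0.3], index=["x", "y", "z"])
        with pytest.raises(StatsError):
            correlation_report(conf, rts)


class TestComparisons:
    def test_identical_sets_not_significant(self):
        rhos = [0.31, 0.29, 0.33, 0.30]
        cmp = gc.compare_correlation_sets(rhos, rhos)
        assert cmp.tier == "n.s."
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_sets_highly_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.4, 0.1, 100)
        b = rng.normal(-0.2, 0.1, 100)
        cmp = gc.compare_correlation_sets(a, b)
        assert cmp.tier == "***"

    def test_rho_of_one_clamped(self):
        cmp = gc.compare_correlation_sets([1.0, 0.99], [0.2, 0.25])
        assert cmp.clamped

    def test_single_element_rejected(self):
        with pytest.raises(StatsError):
            gc.compare_correlation_sets([0.5], [0.1, 0.2])

    def test_accuracy_sets(self):
        same = gc.compare_accuracy_sets([0.8, 0.81, 0.79], [0.8, 0.81, 0.79])
        assert same.tier == "n.s."
        apart = gc.compare_accuracy_sets([0.9, 0.91, 0.92, 0.93],
                                         [0.40, 0.41, 0.42, 0.43])
        assert apart.tier == "***"

    @pytest.mark.parametrize("p, tier", [(0.0005, "***"), (0.005, "**"),
                                         (0.03, "*"), (0.2, "n.s.")])
    def test_tier_thresholds(self, p, tier):
        assert significance_tier(p) == tier


class TestCrossedGrid:
    def test_two_by_two_labels(self):
        rng = np.random.default_rng(10)
        idx = pd.Index([f"i{k}" for k in range(10)], name="instance_id")
        confs = {c: pd.DataFrame({"n0": rng.uniform(0.1, 1, 10),
                                  "n1": rng.uniform(0.1, 1, 10)}, index=idx)
                 for c in ("good", "bad")}
        rts = {c: pd.Series(rng.uniform(0.001, 0.01, 10), index=idx)
               for c in ("good", "bad")}
        grid = crossed_grid(confs, rts)
        assert set(grid) == {("good", "good"), ("good", "bad"),
                             ("bad", "good"), ("bad", "bad")}

    def test_degenerate_1x1_equals_report(self):
        rng = np.random.default_rng(11)
        idx = pd.Index([f"i{k}" for k in range(9)], name="instance_id")
        conf = pd.DataFrame({"n0": rng.uniform(0.1, 1, 9)}, index=idx)
        rts = pd.Series(rng.uniform(0.001, 0.01, 9), index=idx)
        grid = crossed_grid({"only": conf}, {"only": rts})
        direct = correlation_report(conf, rts)
        assert grid[("only", "only")].rho_of_means == pytest.approx(
            direct.rho_of_means)

    def test_empty_cell_flagged_grid_returned(self):
        rng = np.random.default_rng(12)
        idx = pd.Index([f"i{k}" for k in range(9)], name="instance_id")
        conf = pd.DataFrame({"n0": rng.uniform(0.1, 1, 9)}, index=idx)
        good_rts = pd.Series(rng.uniform(0.001, 0.01, 9), index=idx)
        bad_rts = pd.Series([0.1, 0.2, 0.3], index=["x", "y", "z"])
        grid = crossed_grid({"net": conf}, {"good": good_rts, "bad": bad_rts})
        assert grid[("net", "good")] is not None
        assert grid[("net", "bad")] is None
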