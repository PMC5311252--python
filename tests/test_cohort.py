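"""Cohort signature and survival: BH step-up, percentile grouping,
Spearman/complete-linkage clustering, Wilcoxon, KM/log-rank and Cox — each
checked against brute-force or hand-computed oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncomotif import (
    bh_adjust,
    cox_regression,
    derive_signature,
    genotype_association,
    hierarchical_cluster,
    km_logrank,
    percentile_groups,
    sum_family_expression,
)


class TestFamilySum:
    def test_single_member(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 100, (5, 3)),
            index=[f"s{i}" for i in range(5)],
            columns=["mA", "mB", "mC"],
        )
        s = sum_family_expression(expr, ["mB"])
        assert np.allclose(s, expr["mB"])

    def test_manual_addition(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 100, (10, 5)),
            index=[f"s{i}" for i in range(10)],
            columns=list("abcde"),
        )
        s = sum_family_expression(expr, list("abcde"))
        manual = [expr.loc[i].sum() for i in expr.index]
        assert np.allclose(s.values, manual)

    def test_missing_members_warn_then_skip(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 1, (3, 2)), columns=["a", "b"])
        with pytest.warns(UserWarning, match="absent"):
            s = sum_family_expression(expr, ["a", "zz"])
        assert np.allclose(s, expr["a"])

    def test_empty_family_error(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 1, (3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            sum_family_expression(expr, ["zz"])


class TestPercentileGroups:
    def test_exact_division(self):
        sums = pd.Series(np.arange(100.0), index=[f"s{i:03d}" for i in range(100)])
        high, low = percentile_groups(sums, pct=5)
        assert len(high) == len(low) == 5

    def test_ceiling_rule(self):
        sums = pd.Series(np.arange(40.0), index=[f"s{i:02d}" for i in range(40)])
        high, low = percentile_groups(sums, pct=5)
        assert len(high) == len(low) == 2

    def test_order_statistic_property(self, rng):
        sums = pd.Series(rng.normal(0, 1, 83), index=[f"s{i}" for i in range(83)])
        high, low = percentile_groups(sums)
        assert sums[low].max() <= sums[high].min()
        assert not set(high) & set(low)

    def test_too_small_group(self):
        with pytest.raises(ValueError):
            percentile_groups(pd.Series([1.0, 2.0, 3.0]), pct=5)


def bh_oracle(p):
    """Direct step-up formula: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 57)
        assert np.allclose(bh_adjust(p), bh_oracle(p), rtol=1e-10)

    def test_outputs_dominate_inputs(self, rng):
        p = rng.uniform(0, 1, 30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeriveSignature:
    def _matrix(self, rng, n=40, genes=30):
        return pd.DataFrame(
            rng.normal(8, 0.5, (n, genes)),
            index=[f"s{i:02d}" for i in range(n)],
            columns=[f"g{i:02d}" for i in range(genes)],
        )

    def test_null_no_selection(self, rng):
        expr = self._matrix(rng)
        high = list(expr.index[:10])
        low = list(expr.index[10:20])
        sig = derive_signature(expr, high, low)
        assert sig["selected"].sum() == 0

    def test_planted_gene_selected_up(self, rng):
        expr = self._matrix(rng)
        high = list(expr.index[:20])
        low = list(expr.index[20:40])
        expr.loc[high, "g00"] += 3.0
        sig = derive_signature(expr, high, low)
        assert sig.loc["g00", "selected"]
        assert sig.loc["g00", "direction"] == "up"

    def test_antisymmetry_under_group_swap(self, rng):
        expr = self._matrix(rng)
        high = list(expr.index[:10])
        low = list(expr.index[10:20])
        a = derive_signature(expr, high, low)
        b = derive_signature(expr, low, high)
        assert np.allclose(a["log2fc"], -b["log2fc"])

    def test_overlapping_groups_rejected(self, rng):
        expr = self._matrix(rng)
        with pytest.raises(ValueError):
            derive_signature(expr, list(expr.index[:5]), list(expr.index[4:9]))


def complete_linkage_oracle(d):
    """Brute-force agglomeration on a dense distance matrix: returns the
    sorted merge heights."""
    clusters = [{i} for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


class TestHierarchicalCluster:
    def test_separable_blocks(self):
        # two blocks with identical within-block rankings, anti-correlated
        # across blocks
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rows = {
            "a1": base, "a2": base * 2 + 1, "a3": base + 0.5,
            "b1": base[::-1], "b2": base[::-1] * 3,
        }
        expr = pd.DataFrame.from_dict(rows, orient="index")
        labels, _ = hierarchical_cluster(expr)
        assert len(set(labels[["a1", "a2", "a3"]])) == 1
        assert len(set(labels[["b1", "b2"]])) == 1
        assert labels["a1"] != labels["b1"]

    def test_merge_heights_match_hand_agglomeration(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (4, 12)), index=list("wxyz")
        )
        from oncomotif.cohort import spearman_distance_matrix

        d = spearman_distance_matrix(expr)
        _, link = hierarchical_cluster(expr)
        assert np.allclose(sorted(link[:, 2]), complete_linkage_oracle(d),
                           rtol=1e-10)

    def test_invariance_under_monotone_transform(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (8, 20)), index=[f"s{i}" for i in range(8)]
        )
        labels_raw, _ = hierarchical_cluster(expr)
        labels_exp, _ = hierarchical_cluster(np.exp(expr))
        # rank-based distance: the partition is identical
        agree = (labels_raw == labels_exp).mean()
        assert agree in (0.0, 1.0)  # identical up to label naming
        assert (labels_raw.groupby(labels_exp).nunique() == 1).all()

    def test_constant_profile_error(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(expr)


def wilcoxon_exact_oracle(a, b):
    """Two-sided exact rank-sum p by enumeration of all labelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    stats_all = [
        sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n1)
    ]
    dev = abs(obs - mu)
    return np.mean([abs(s - mu) >= dev - 1e-12 for s in stats_all])


class TestGenotypeAssociation:
    def test_identical_groups_p_one(self):
        sums = pd.Series([5.0, 5.0, 5.0, 5.0], index=list("abcd"))
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        _, p = genotype_association(sums, labels)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_example(self):
        sums = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        _, p = genotype_association(sums, labels)
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(
            wilcoxon_exact_oracle(sums[:3].values, sums[3:].values)
        )

    def test_exact_matches_brute_force_random(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 6)
        sums = pd.Series(np.concatenate([a, b]))
        labels = pd.Series([0] * 5 + [1] * 6)
        _, p = genotype_association(sums, labels)
        assert p == pytest.approx(wilcoxon_exact_oracle(a, b), rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(0, 1, 30)
        sums = pd.Series(vals)
        labels = pd.Series(rng.integers(0, 2, 30))
        if labels.nunique() < 2:
            labels.iloc[0] = 1 - labels.iloc[0]
        _, p1 = genotype_association(sums, labels)
        _, p2 = genotype_association(np.exp(sums), labels)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_one_class_error(self):
        sums = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            genotype_association(sums, pd.Series([1, 1]))


class TestSurvival:
    def test_km_product_limit_by_hand(self):
        curve = __import__("oncomotif").cohort.km_curve([1, 2, 3], [1, 1, 1])
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1] == pytest.approx(2 / 3)
        assert surv[2] == pytest.approx(1 / 3)
        assert surv[3] == pytest.approx(0.0)

    def test_no_events_flat_curves_undefined_p(self):
        times = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        events = pd.Series([0, 0, 0, 0], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        res = km_logrank(times, events, groups)
        assert np.isnan(res["p"])
        for curve in res["curves"].values():
            assert (curve["survival"] == 1.0).all()

    def test_km_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        curve = __import__("oncomotif").cohort.km_curve(t, np.ones(50, int))
        for time, s in zip(curve["time"][1:], curve["survival"][1:]):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_identical_groups_logrank_null(self):
        times = pd.Series(np.tile([1.0, 2, 3, 4, 5], 2))
        events = pd.Series(np.ones(10, int))
        groups = pd.Series(["x"] * 5 + ["y"] * 5)
        res = km_logrank(times, events, groups)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_logrank_matches_hand_score_statistic(self, rng):
        # tie-free data: the log-rank chi2 equals the Cox score test at
        # beta=0, computable by hand from the risk sets
        n = 30
        x = np.array([0] * 15 + [1] * 15)
        t = rng.exponential(1 / np.exp(0.8 * x))
        t += rng.uniform(0, 1e-6, n)  # enforce uniqueness
        e = np.ones(n, int)
        idx = [f"s{i}" for i in range(n)]
        res = km_logrank(pd.Series(t, idx), pd.Series(e, idx),
                         pd.Series(x, idx))
        order = np.argsort(t)
        U = V = 0.0
        at_risk = list(order)
        for i in order:
            xs = x[at_risk]
            pbar = xs.mean()
            U += x[i] - pbar
            V += pbar * (1 - pbar)
            at_risk = [j for j in at_risk if t[j] > t[i]]
        assert res["chi2"] == pytest.approx(U**2 / V, rel=1e-6)

    def test_cox_null_hr_near_one(self, rng):
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n)
        res = cox_regression(pd.Series(t), pd.Series(np.ones(n, int)),
                             pd.DataFrame({"x": x}))
        assert abs(res["coef"].iloc[0]) < 0.15

    def test_cox_recovers_true_hr(self, rng):
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * x)))
        res = cox_regression(pd.Series(t), pd.Series(np.ones(n, int)),
                             pd.DataFrame({"x": x}))
        se = (np.log(res["ci_upper"].iloc[0]) - res["coef"].iloc[0]) / 1.96
        assert abs(res["coef"].iloc[0] - np.log(2)) < 3 * se

    def test_cox_constant_covariate_error(self, rng):
        t = rng.exponential(1, 20)
        with pytest.raises(ValueError):
            cox_regression(pd.Series(t), pd.Series(np.ones(20, int)),
                           pd.DataFrame({"x": np.ones(20)}))
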