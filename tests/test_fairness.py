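"""Fairness metrics vs independent brute-force counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from embaudit import (build_table, demographic_parity_gap,
                      equal_opportunity_gaps, fairness_report,
                      stratified_performance)

# ---------------------------------------------------------------------------
# Brute-force oracles: plain loops over records, no shared code with the
# implementation (which uses vectorized counting and sklearn).
# ---------------------------------------------------------------------------


def oracle_dp_gap(y_pred, groups, classes, min_support=1):
    per_class = {}
    gs = sorted({g for g in groups})
    for c in classes:
        rates = []
        for g in gs:
            members = [i for i, gg in enumerate(groups) if gg == g]
            if len(members) < min_support:
                continue
            rates.append(sum(1 for i in members if y_pred[i] == c) / len(members))
        per_class[c] = max(rates) - min(rates) if len(rates) >= 2 else 0.0
    return per_class, sum(per_class.values()) / len(per_class)


def oracle_eo_gaps(y_true, y_pred, groups, classes, min_support=1):
    gs = sorted({g for g in groups})
    tpr_gaps, fpr_gaps = {}, {}
    for c in classes:
        tprs, fprs = [], []
        for g in gs:
            pos = [i for i, _ in enumerate(groups)
                   if groups[i] == g and y_true[i] == c]
            neg = [i for i, _ in enumerate(groups)
                   if groups[i] == g and y_true[i] != c]
            if len(pos) >= min_support:
                tprs.append(sum(1 for i in pos if y_pred[i] == c) / len(pos))
            if len(neg) >= min_support:
                fprs.append(sum(1 for i in neg if y_pred[i] == c) / len(neg))
        tpr_gaps[c] = max(tprs) - min(tprs) if len(tprs) >= 2 else 0.0
        fpr_gaps[c] = max(fprs) - min(fprs) if len(fprs) >= 2 else 0.0
    return tpr_gaps, fpr_gaps


def oracle_group_macro(y_true, y_pred, groups, g):
    yt = [t for t, gg in zip(y_true, groups) if gg == g]
    yp = [p for p, gg in zip(y_pred, groups) if gg == g]
    labels = sorted(set(yt) | set(yp))
    precs, recs, f1s = [], [], []
    for c in labels:
        tp = sum(1 for t, p in zip(yt, yp) if t == c and p == c)
        fp = sum(1 for t, p in zip(yt, yp) if t != c and p == c)
        fn = sum(1 for t, p in zip(yt, yp) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec); recs.append(rec); f1s.append(f1)
    acc = sum(1 for t, p in zip(yt, yp) if t == p) / len(yt)
    return (sum(precs) / len(precs), sum(recs) / len(recs),
            sum(f1s) / len(f1s), acc)


def random_instance(rng, n_max=100, n_classes_max=5, n_groups_max=4):
    n = rng.integers(5, n_max + 1)
    classes = [f"c{i}" for i in range(rng.integers(2, n_classes_max + 1))]
    groups = [f"g{i}" for i in range(rng.integers(1, n_groups_max + 1))]
    y_true = rng.choice(classes, size=n)
    y_pred = rng.choice(classes, size=n)
    grp = rng.choice(groups, size=n)
    return list(y_true), list(y_pred), list(grp)


# ---------------------------------------------------------------------------


class TestBuildTable:
    def test_trivial_all_correct_single_group(self):
        t = build_table(["A"] * 4, ["A"] * 4, ["g"] * 4)
        assert t.pred_cg[("A", "g")] == 4
        assert t.tp_cg[("A", "g")] == 4
        assert t.fp_cg[("A", "g")] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_table([], [], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_table(["a"], ["a", "b"], ["g", "g"])

    def test_pred_counts_partition_each_group(self):
        rng = np.random.default_rng(0)
        y_true, y_pred, grp = random_instance(rng)
        t = build_table(y_true, y_pred, grp)
        for g in t.groups:
            assert sum(t.pred_cg[(c, g)] for c in t.classes) == t.n_g[g]
            for c in t.classes:
                assert t.tp_cg[(c, g)] <= min(t.n_cg[(c, g)], t.pred_cg[(c, g)])

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(1)
        y_true, y_pred, grp = random_instance(rng)
        t = build_table(y_true, y_pred, grp)
        for c in t.classes:
            for g in t.groups:
                tp = sum(1 for yt, yp, gg in zip(y_true, y_pred, grp)
                         if gg == g and yt == c and yp == c)
                assert t.tp_cg[(c, g)] == tp


class TestDemographicParity:
    def test_worked_example(self):
        # group A: 4 of 10 predicted class "1"; group B: 9 of 10
        y_pred = ["1"] * 4 + ["0"] * 6 + ["1"] * 9 + ["0"] * 1
        groups = ["A"] * 10 + ["B"] * 10
        y_true = ["1", "0"] * 10
        t = build_table(y_true, y_pred, groups)
        per_class, _ = demographic_parity_gap(t)
        assert per_class["1"] == pytest.approx(0.5)

    def test_identical_distributions_give_zero(self):
        y_pred = ["a", "b"] * 10
        t = build_table(["a", "b"] * 10, y_pred, ["g1"] * 10 + ["g2"] * 10)
        per_class, macro = demographic_parity_gap(t)
        assert macro == 0.0

    def test_single_group_zero(self):
        t = build_table(["a", "b"] * 5, ["b", "a"] * 5, ["only"] * 10)
        _, macro = demographic_parity_gap(t)
        assert macro == 0.0

    def test_constant_classifier_zero_gap(self):
        rng = np.random.default_rng(2)
        y_true, _, grp = random_instance(rng)
        t = build_table(y_true, ["c0"] * len(y_true), grp)
        per_class, macro = demographic_parity_gap(t)
        assert macro == 0.0

    def test_min_support_excludes_small_groups(self):
        y_pred = ["a"] * 10 + ["b"]
        groups = ["big"] * 10 + ["tiny"]
        t = build_table(y_pred, y_pred, groups)
        _, macro = demographic_parity_gap(t, min_support=5)
        assert macro == 0.0  # only "big" qualifies -> single group
        with pytest.raises(ValueError):
            demographic_parity_gap(t, min_support=100)

    def test_perfect_classifier_gap_equals_prevalence_gap(self):
        rng = np.random.default_rng(3)
        y_true, _, grp = random_instance(rng, n_max=80)
        t = build_table(y_true, y_true, grp)
        per_class, _ = demographic_parity_gap(t)
        for c in t.classes:
            prev = [t.n_cg[(c, g)] / t.n_g[g] for g in t.groups]
            expect = max(prev) - min(prev) if len(prev) >= 2 else 0.0
            assert per_class[c] == pytest.approx(expect)


class TestEqualOpportunity:
    def test_perfect_classifier_zero_gaps(self):
        y = ["a", "b"] * 6
        grp = ["g1", "g1", "g2", "g2"] * 3
        t = build_table(y, y, grp)
        tpr, fpr, macro_tpr, macro_fpr, excl = equal_opportunity_gaps(t)
        assert macro_tpr == 0.0 and macro_fpr == 0.0

    def test_class_in_one_group_excluded(self):
        y_true = ["a"] * 5 + ["b"] * 5
        groups = ["g1"] * 5 + ["g2"] * 5  # class a only in g1
        t = build_table(y_true, y_true, groups)
        tpr, fpr, _, _, excl = equal_opportunity_gaps(t)
        assert tpr["a"] == 0.0
        assert ("a", "tpr") in excl

    def test_matches_oracle_on_random_table(self):
        rng = np.random.default_rng(4)
        y_true, y_pred, grp = random_instance(rng)
        t = build_table(y_true, y_pred, grp)
        tpr, fpr, _, _, _ = equal_opportunity_gaps(t)
        otpr, ofpr = oracle_eo_gaps(y_true, y_pred, grp, t.classes)
        for c in t.classes:
            assert tpr[c] == pytest.approx(otpr[c])
            assert fpr[c] == pytest.approx(ofpr[c])


class TestStratifiedPerformance:
    def test_perfect_single_group(self):
        df = stratified_performance(["a", "b"] * 5, ["a", "b"] * 5, ["g"] * 10)
        assert df.loc["g", "macro_f1"] == pytest.approx(1.0)

    def test_single_record_group(self):
        df = stratified_performance(["a"] * 5 + ["b"], ["a"] * 5 + ["b"],
                                    ["g1"] * 5 + ["solo"])
        assert df.loc["solo", "accuracy"] == 1.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        y_true, y_pred, grp = random_instance(rng)
        df = stratified_performance(y_true, y_pred, grp)
        for g in sorted(set(grp)):
            prec, rec, f1, acc = oracle_group_macro(y_true, y_pred, grp, g)
            assert df.loc[g, "macro_precision"] == pytest.approx(prec)
            assert df.loc[g, "macro_recall"] == pytest.approx(rec)
            assert df.loc[g, "macro_f1"] == pytest.approx(f1)
            assert df.loc[g, "accuracy"] == pytest.approx(acc)


class TestRelabelInvariance:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_gaps_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        y_true, y_pred, grp = random_instance(rng, n_max=60)
        rep = fairness_report(y_true, y_pred, grp)
        relabel_c = {c: f"Z{c}" for c in set(y_true) | set(y_pred)}
        relabel_g = {g: f"Q{g}" for g in set(grp)}
        rep2 = fairness_report([relabel_c[c] for c in y_true],
                               [relabel_c[c] for c in y_pred],
                               [relabel_g[g] for g in grp])
        assert rep2.dp_gap == pytest.approx(rep.dp_gap)
        assert rep2.eo_tpr_gap == pytest.approx(rep.eo_tpr_gap)
        assert rep2.eo_fpr_gap == pytest.approx(rep.eo_fpr_gap)

    def test_gaps_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y_true, y_pred, grp = random_instance(rng)
            rep = fairness_report(y_true, y_pred, grp)
            for v in (rep.dp_gap, rep.eo_tpr_gap, rep.eo_fpr_gap):
                assert 0.0 <= v <= 1.0


def test_mean_pairwise_aggregation_option():
    y_pred = ["1"] * 4 + ["0"] * 6 + ["1"] * 9 + ["0"] + ["1", "0"] * 5
    groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
    t = build_table(y_pred, y_pred, groups)
    per_max, _ = demographic_parity_gap(t, aggregation="max_min")
    per_mp, _ = demographic_parity_gap(t, aggregation="mean_pairwise")
    # rates for class "1": 0.4, 0.9, 0.5 -> max-min 0.5; mean pairwise
    # (|0.4-0.9|+|0.4-0.5|+|0.9-0.5|)/3
    assert per_max["1"] == pytest.approx(0.5)
    assert per_mp["1"] == pytest.approx((0.5 + 0.1 + 0.4) / 3)
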