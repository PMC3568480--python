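"""CR-tree interaction miner: worked example, brute-force oracles, caching."""

from __future__ import annotations

import io
import itertools
import random
from collections import Counter

import pytest

import adrmine as am
from adrmine.acm_ms import FrequentPattern, TransactionSet

from conftest import random_warehouse

D = "Drug"


def brute_patterns(ts: TransactionSet, min_count: int) -> set[FrequentPattern]:
    """Exhaustive per-transaction subset enumeration."""
    counter: Counter = Counter()
    for t in ts:
        for r in range(1, len(t.items) + 1):
            for sub in itertools.combinations(t.items, r):
                for s in t.labels:
                    counter[(frozenset(sub), s)] += 1
    return {
        FrequentPattern(i, s, n) for (i, s), n in counter.items() if n >= min_count
    }


@pytest.fixture
def toy_ts(toy):
    return am.build_transactions(toy, 3)


@pytest.fixture
def age_query():
    return am.QuerySpec(
        mode="drug-interaction", attributes=("Age",), measure="PRR", min_count=3
    )


class TestDataTransformation:
    def test_toy_frequent_supports(self, toy_ts):
        assert dict(toy_ts.order.support) == {
            ("Age", "a2"): 4, ("Weight", "w2"): 4, (D, "d2"): 4, (D, "d3"): 4,
            ("Year", "y1"): 3, ("Gender", "g1"): 3, ("Gender", "g2"): 3,
            (D, "d1"): 3,
        }
        assert dict(toy_ts.symptom_support) == {"s1": 4}

    def test_toy_global_item_order(self, toy_ts):
        assert toy_ts.order.items == (
            ("Age", "a2"), ("Weight", "w2"), (D, "d2"), (D, "d3"),
            ("Year", "y1"), ("Gender", "g1"), ("Gender", "g2"), (D, "d1"),
        )

    def test_toy_reduced_transactions(self, toy_ts):
        got = [(t.tid, t.items, set(t.labels)) for t in toy_ts]
        assert got == [
            ("1", (("Age", "a2"), ("Weight", "w2"), (D, "d2"), (D, "d3"),
                   ("Gender", "g1"), (D, "d1")), {"s1"}),
            ("3", (("Age", "a2"), ("Weight", "w2"), (D, "d3"),
                   ("Gender", "g2"), (D, "d1")), {"s1"}),
            ("4", (("Age", "a2"), (D, "d3"), ("Year", "y1"),
                   ("Gender", "g1"), (D, "d1")), {"s1"}),
            ("5", ((D, "d2"), ("Year", "y1"), ("Gender", "g2")), {"s1"}),
        ]

    def test_min_count_one_keeps_every_report_and_item(self, toy):
        ts = am.build_transactions(toy, 1)
        assert len(ts) == 6
        by_tid = {t.tid: t for t in ts}
        assert len(by_tid["1"].items) == 5 + 3  # 5 demographics + 3 drugs

    @pytest.mark.parametrize("seed", range(6))
    def test_supports_match_brute_force_counter(self, seed):
        rs = random_warehouse(random.Random(300 + seed), n_reports=70)
        ts = am.build_transactions(rs, 3)
        support: Counter = Counter()
        for r in rs:
            for a, v in r.demographics.items():
                support[(a, v)] += 1
            for d in r.drugs:
                support[(D, d)] += 1
        assert dict(ts.order.support) == {
            it: n for it, n in support.items() if n >= 3
        }

    def test_items_strictly_follow_global_order(self, toy_ts):
        for t in toy_ts:
            idx = [toy_ts.order.index(it) for it in t.items]
            assert idx == sorted(idx) and len(set(idx)) == len(idx)


class TestPruning:
    def test_toy_pruned_transactions(self, toy_ts, age_query):
        pruned = am.prune_transactions(toy_ts, age_query)
        got = [(t.tid, t.items) for t in pruned]
        assert got == [
            ("1", (("Age", "a2"), (D, "d2"), (D, "d3"), (D, "d1"))),
            ("3", (("Age", "a2"), (D, "d3"), (D, "d1"))),
            ("4", (("Age", "a2"), (D, "d3"), (D, "d1"))),
        ]

    def test_no_attributes_keeps_all_with_drug_items_only(self, toy_ts):
        q = am.QuerySpec(mode="drug-interaction", attributes=())
        pruned = am.prune_transactions(toy_ts, q)
        assert [t.tid for t in pruned] == ["1", "3", "4", "5"]
        assert all(all(a == D for a, _ in t.items) for t in pruned)

    def test_pruning_does_not_mutate_the_cache(self, toy_ts, age_query):
        before = [(t.tid, t.items, t.labels) for t in toy_ts]
        am.prune_transactions(toy_ts, age_query)
        am.prune_transactions(
            toy_ts, am.QuerySpec(mode="drug-interaction", attributes=("Gender",))
        )
        assert [(t.tid, t.items, t.labels) for t in toy_ts] == before

    @pytest.mark.parametrize("seed", range(5))
    def test_pruned_set_matches_rederivation_from_reports(self, seed):
        rs = random_warehouse(random.Random(400 + seed), n_reports=60)
        ts = am.build_transactions(rs, 3)
        q = am.QuerySpec(mode="drug-interaction", attributes=("A1",), min_count=3)
        pruned = am.prune_transactions(ts, q)
        # oracle: rebuild from raw reports
        expect = []
        for t in ts:
            items = tuple(it for it in t.items if it[0] in (D, "A1"))
            if not any(a == "A1" for a, _ in items):
                continue
            expect.append((t.tid, items, t.labels))
        assert [(t.tid, t.items, t.labels) for t in pruned] == expect


class TestCRTree:
    def test_toy_tree_structure(self, toy_ts, age_query):
        tree = am.build_cr_tree(am.prune_transactions(toy_ts, age_query))
        a2 = tree.root.children[("Age", "a2")]
        assert a2.count == 3
        d2 = a2.children[(D, "d2")]
        d3 = a2.children[(D, "d3")]
        assert d2.count == 1 and d3.count == 2
        leaf1 = d2.children[(D, "d3")].children[(D, "d1")]
        assert dict(leaf1.symptoms) == {"s1": 1}
        leaf2 = d3.children[(D, "d1")]
        assert dict(leaf2.symptoms) == {"s1": 2}

    def test_single_transaction_is_a_unit_chain(self, toy_ts):
        one = TransactionSet(
            [toy_ts.transactions[1]], toy_ts.order,
            dict(toy_ts.symptom_support), 3,
        )
        tree = am.build_cr_tree(one)
        node = tree.root
        seen = 0
        while node.children:
            (node,) = node.children.values()
            assert node.count == 1
            seen += 1
        assert seen == 5

    def test_root_children_counts_conserve_transactions(self, toy_ts, age_query):
        pruned = am.prune_transactions(toy_ts, age_query)
        tree = am.build_cr_tree(pruned)
        assert sum(c.count for c in tree.root.children.values()) == len(pruned)

    def test_out_of_order_transaction_rejected(self, toy_ts):
        bad = am.Transaction("x", ((D, "d1"), ("Age", "a2")), frozenset({"s1"}))
        ts = TransactionSet([bad], toy_ts.order, {}, 3)
        with pytest.raises(am.IntegrityError):
            am.build_cr_tree(ts)


class TestPatternMining:
    def test_toy_seven_patterns_all_count_three(self, toy_ts, age_query):
        tree = am.build_cr_tree(am.prune_transactions(toy_ts, age_query))
        pats = am.mine_patterns(tree, 3)
        expected = {
            frozenset({(D, "d1")}),
            frozenset({(D, "d1"), (D, "d3")}),
            frozenset({("Age", "a2"), (D, "d1")}),
            frozenset({("Age", "a2"), (D, "d1"), (D, "d3")}),
            frozenset({(D, "d3")}),
            frozenset({("Age", "a2"), (D, "d3")}),
            frozenset({("Age", "a2")}),
        }
        assert {p.itemset for p in pats} == expected
        assert all(p.symptom == "s1" and p.count == 3 for p in pats)
        assert len(pats) == 7

    def test_age_filter_retains_four_patterns(self, toy_ts, age_query):
        tree = am.build_cr_tree(am.prune_transactions(toy_ts, age_query))
        pats = am.mine_patterns(tree, 3)
        with_age = {p.itemset for p in pats if "Age" in p.demographics}
        assert len(with_age) == 4

    def test_min_count_above_transactions_gives_nothing(self, toy_ts, age_query):
        tree = am.build_cr_tree(am.prune_transactions(toy_ts, age_query))
        assert am.mine_patterns(tree, 4) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_enumeration(self, seed):
        rs = random_warehouse(
            random.Random(500 + seed), n_reports=50, n_attrs=2, n_drugs=4
        )
        ts = am.build_transactions(rs, 3)
        q = am.QuerySpec(
            mode="drug-interaction",
            attributes=(("A0",), (), ("A0", "A1"))[seed % 3],
            min_count=3,
        )
        pruned = am.prune_transactions(ts, q)
        tree = am.build_cr_tree(pruned)
        assert am.mine_patterns(tree, 3) == brute_patterns(pruned, 3)

    def test_insertion_order_independence(self, toy_ts, age_query):
        pruned = am.prune_transactions(toy_ts, age_query)
        rev = TransactionSet(
            list(reversed(pruned.transactions)), pruned.order,
            dict(pruned.symptom_support), pruned.min_count,
        )
        assert am.mine_patterns(am.build_cr_tree(pruned), 3) == am.mine_patterns(
            am.build_cr_tree(rev), 3
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_anti_monotone_support(self, seed):
        rs = random_warehouse(random.Random(600 + seed), n_reports=60)
        ts = am.build_transactions(rs, 2)
        tree = am.build_cr_tree(
            am.prune_transactions(
                ts, am.QuerySpec(mode="drug-interaction", attributes=("A0",), min_count=2)
            )
        )
        pats = am.mine_patterns(tree, 2)
        by_key = {(p.itemset, p.symptom): p.count for p in pats}
        for (items, s), n in by_key.items():
            for (items2, s2), n2 in by_key.items():
                if s == s2 and items < items2:
                    assert n2 <= n

    def test_multi_label_transaction_counts_once_per_label(self, toy_ts):
        order = toy_ts.order
        t1 = am.Transaction("x", (("Age", "a2"), (D, "d3")), frozenset({"s1", "s2"}))
        t2 = am.Transaction("y", (("Age", "a2"), (D, "d3")), frozenset({"s1"}))
        ts = TransactionSet([t1, t2], order, {"s1": 2, "s2": 1}, 1)
        tree = am.build_cr_tree(ts)
        pats = am.mine_patterns(tree, 1)
        counts = {(tuple(sorted(p.itemset)), p.symptom): p.count for p in pats}
        key = ((("Age", "a2"), (D, "d3")), "s1")
        assert counts[key] == 2
        assert counts[((("Age", "a2"), (D, "d3")), "s2")] == 1


class TestRunAcmMs:
    def test_toy_drug_interaction_output(self, toy, age_query):
        rules = am.run_acm_ms(toy, age_query)
        assert len(rules) == 1
        (r,) = rules
        assert r.antecedent == (("Age", "a2"),)
        assert r.drugs == {"d1", "d3"}
        assert r.symptom == "s1"
        assert r.contingency.cells == (3, 0, 0, 1)
        assert r.measure_result.value == pytest.approx(3.0)
        assert r.measure_result.is_signal

    def test_no_surviving_transactions_gives_empty_output(self, toy):
        q = am.QuerySpec(
            mode="drug-interaction", attributes=("Age",), min_count=3,
            fixed_symptom="s3",
        )
        assert am.run_acm_ms(toy, q) == []

    def test_cached_transactions_give_identical_output(self, toy, toy_ts, age_query):
        direct = am.run_acm_ms(toy, age_query)
        cached = am.run_acm_ms(toy, age_query, transactions=toy_ts)
        assert [(r.antecedent, r.drugs, r.symptom) for r in direct] == [
            (r.antecedent, r.drugs, r.symptom) for r in cached
        ]

    def test_cache_with_wrong_min_count_rejected(self, toy, toy_ts):
        q = am.QuerySpec(mode="drug-interaction", attributes=("Age",), min_count=2)
        with pytest.raises(am.QueryError):
            am.run_acm_ms(toy, q, transactions=toy_ts)

    @pytest.mark.parametrize("seed", range(6))
    def test_singleton_drug_rules_coincide_with_cube_miner(self, seed):
        rs = random_warehouse(random.Random(700 + seed), n_reports=80)
        q_acm = am.QuerySpec(
            mode="drug-interaction", attributes=("A0",), min_count=3,
            min_drugs=1, measure="PRR",
        )
        q_cbm = am.QuerySpec(
            mode="single-drug", attributes=("A0",), min_count=3, measure="PRR"
        )
        acm = {
            (r.antecedent, tuple(sorted(r.drugs)), r.symptom): (
                r.contingency.cells, round(r.measure_result.value, 9))
            for r in am.run_acm_ms(rs, q_acm)
            if len(r.drugs) == 1
        }
        cbm = {
            (r.antecedent, tuple(sorted(r.drugs)), r.symptom): (
                r.contingency.cells, round(r.measure_result.value, 9))
            for r in am.run_cbm_ss(rs, q_cbm)
        }
        assert acm == cbm

    def test_single_drug_pattern_contingency_matches_cube(self, toy, age_query):
        # cross-module consistency on the toy example
        q = am.QuerySpec(
            mode="drug-interaction", attributes=("Age",), min_count=3, min_drugs=1
        )
        cube = am.build_cube(toy, ("Age", "Drug", "PT"))
        for r in am.run_acm_ms(toy, q):
            if len(r.drugs) == 1:
                t = cube.contingency(dict(r.antecedent), set(r.drugs), r.symptom)
                assert t.cells == r.contingency.cells


class TestCacheSerialization:
    def test_round_trip_preserves_everything(self, toy_ts):
        buf = io.StringIO()
        am.write_transactions(toy_ts, buf)
        buf.seek(0)
        back = am.read_transactions(buf)
        assert back.min_count == toy_ts.min_count
        assert back.order.items == toy_ts.order.items
        assert dict(back.order.support) == dict(toy_ts.order.support)
        assert dict(back.symptom_support) == dict(toy_ts.symptom_support)
        assert [(t.tid, t.items, t.labels) for t in back] == [
            (t.tid, t.items, t.labels) for t in toy_ts
        ]
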