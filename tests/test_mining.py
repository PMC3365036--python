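import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histonecode import (
    Item,
    MiningConfig,
    PtmType,
    Transaction,
    UNMODIFIED,
    apriori,
    build_transactions,
    derive_rules,
    filter_peptides,
    parse_peptide,
    rule_matrix,
    support_of,
)
from histonecode.mining import derive_vocabulary


def brute_force_itemsets(transactions, min_support):
    """Independent oracle: tally every subset of every transaction."""
    total = sum(t.weight for t in transactions)
    tally = {}
    for t in transactions:
        items = sorted(t.items)
        for r in range(1, len(items) + 1):
            for combo in itertools.combinations(items, r):
                key = frozenset(combo)
                tally[key] = tally.get(key, 0) + t.weight
    return {k: v / total for k, v in tally.items() if v / total > min_support}


def random_transactions(rng, n_positions=4, n_transactions=20, max_states=2):
    positions = list(range(n_positions))
    states = ["ac", "me2", UNMODIFIED][:max_states + 1]
    out = []
    for _ in range(n_transactions):
        items = frozenset(
            Item(pos, states[rng.integers(len(states))]) for pos in positions
        )
        out.append(Transaction(items, weight=int(rng.integers(1, 4))))
    return out


class TestFilterPeptides:
    def test_length_boundary_21(self, h4):
        short = parse_peptide(h4.sequence[:20], h4)   # 20 aa
        long = parse_peptide(h4.sequence[:21], h4)    # 21 aa
        config = MiningConfig(region=(1, 20))
        kept = filter_peptides([short, long], config)
        assert kept == [long]

    def test_partial_region_coverage_removed(self, h4):
        config = MiningConfig(region=(1, 24), min_peptide_length=5)
        inside = parse_peptide(h4.sequence[:24], h4)
        half = parse_peptide(h4.sequence[:12], h4)
        assert filter_peptides([inside, half], config) == [inside]

    def test_empty_input(self):
        assert filter_peptides([], MiningConfig(region=(1, 24))) == []


class TestBuildTransactions:
    def test_stated_vocabulary_yields_one_item_per_position(self, h4):
        p = parse_peptide("SGRGKGGKGLGKGGAKacRHRKVLRD", h4)
        config = MiningConfig(region=(1, 24), vocabulary=(0, 1, 3, 5, 8, 12, 16, 20))
        (t,) = build_transactions([p], config)
        expected = {
            Item(0, UNMODIFIED),
            Item(1, UNMODIFIED),
            Item(3, UNMODIFIED),
            Item(5, UNMODIFIED),
            Item(8, UNMODIFIED),
            Item(12, UNMODIFIED),
            Item(16, "ac"),
            Item(20, UNMODIFIED),
        }
        assert t.items == expected

    def test_ambiguous_annotation_becomes_unmodified(self, h4):
        p = parse_peptide("SGRGKGGKGLGK(ac)GGAKRHRKVLRD", h4)
        config = MiningConfig(region=(1, 24), vocabulary=(12,))
        (t,) = build_transactions([p], config)
        assert t.items == {Item(12, UNMODIFIED)}

    def test_fully_unmodified_transaction(self, h4):
        p = parse_peptide("SGRGKGGKGLGKGGAKRHRKVLRD", h4)
        config = MiningConfig(region=(1, 24), vocabulary=(5, 16))
        (t,) = build_transactions([p], config)
        assert t.items == {Item(5, UNMODIFIED), Item(16, UNMODIFIED)}

    def test_vocabulary_outside_region_rejected(self, h4):
        p = parse_peptide("SGRGKGGKGLGKGGAKRHRKVLRD", h4)
        with pytest.raises(ValueError):
            build_transactions([p], MiningConfig(region=(1, 24), vocabulary=(30,)))

    def test_derived_vocabulary_is_modified_positions_plus_nterm(self, h4):
        peps = [
            parse_peptide("ac-SGRGKGGKGLGKGGAKacRHRKVLRD", h4),
            parse_peptide("SGRGKGGKGLGK(ac)GGAKRHRKVLRD", h4),  # ambiguous: excluded
        ]
        config = MiningConfig(region=(1, 24))
        assert derive_vocabulary(peps, config) == (0, 16)


class TestApriori:
    def test_worked_example(self):
        a, b = Item(1, "ac"), Item(2, "ac")
        na, nb = Item(1, UNMODIFIED), Item(2, UNMODIFIED)
        tx = [
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, nb})),
            Transaction(frozenset({na, b})),
        ]
        got = {frozenset(fs.items): fs.support for fs in apriori(tx, 0.4)}
        assert got == {
            frozenset({a}): 0.75,
            frozenset({b}): 0.75,
            frozenset({a, b}): 0.5,
        }

    def test_single_transaction_all_subsets_support_one(self):
        items = frozenset({Item(1, "ac"), Item(2, UNMODIFIED), Item(3, "me1")})
        result = apriori([Transaction(items)], 0.5)
        assert len(result) == 2 ** 3 - 1
        assert all(fs.support == 1.0 for fs in result)

    def test_support_exactly_at_threshold_is_excluded(self):
        a = Item(1, "ac")
        tx = [Transaction(frozenset({a}))] + [
            Transaction(frozenset({Item(1, UNMODIFIED)}))
        ] * 4
        # support(a) = 0.20 exactly: strict > drops it
        assert all(a not in fs.items for fs in apriori(tx, 0.20))
        assert any(a in fs.items for fs in apriori(tx, 0.19))

    def test_empty_transactions(self):
        assert apriori([], 0.2) == []

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(20120531)
        for _ in range(25):
            tx = random_transactions(
                rng,
                n_positions=int(rng.integers(2, 6)),
                n_transactions=int(rng.integers(1, 30)),
            )
            min_support = float(rng.uniform(0.05, 0.6))
            mined = {fs.items: fs.support for fs in apriori(tx, min_support)}
            oracle = brute_force_itemsets(tx, min_support)
            assert mined.keys() == oracle.keys()
            for k in mined:
                assert mined[k] == pytest.approx(oracle[k])

    def test_anti_monotonicity_across_output(self):
        rng = np.random.default_rng(7)
        tx = random_transactions(rng, n_positions=5, n_transactions=40)
        result = {fs.items: fs.support for fs in apriori(tx, 0.1)}
        for items, supp in result.items():
            for sub in map(frozenset, itertools.combinations(items, len(items) - 1)):
                if sub:
                    assert result[sub] >= supp

    def test_support_invariant_under_row_splitting(self):
        rng = np.random.default_rng(11)
        weighted = random_transactions(rng, n_positions=4, n_transactions=15)
        split = [
            Transaction(t.items, weight=1)
            for t in weighted
            for _ in range(t.weight)
        ]
        r1 = {fs.items: fs.support for fs in apriori(weighted, 0.15)}
        r2 = {fs.items: fs.support for fs in apriori(split, 0.15)}
        assert r1 == r2

    def test_output_sorted_by_size_then_items(self):
        rng = np.random.default_rng(3)
        tx = random_transactions(rng, n_positions=4, n_transactions=20)
        result = apriori(tx, 0.1)
        keys = [(len(fs.items), tuple(sorted(fs.items))) for fs in result]
        assert keys == sorted(keys)


class TestDeriveRules:
    def test_confidence_is_joint_over_antecedent(self):
        a, b = Item(1, "ac"), Item(2, "ac")
        na, nb = Item(1, UNMODIFIED), Item(2, UNMODIFIED)
        tx = [
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, nb})),
            Transaction(frozenset({na, b})),
        ]
        rules = derive_rules(apriori(tx, 0.4))
        lookup = {(r.antecedent, r.consequent): r.confidence for r in rules}
        assert lookup[(frozenset({a}), frozenset({b}))] == pytest.approx(0.5 / 0.75)

    def test_confidence_one_iff_containment(self):
        rng = np.random.default_rng(42)
        tx = random_transactions(rng, n_positions=4, n_transactions=30)
        rules = derive_rules(apriori(tx, 0.1))
        for r in rules:
            contained = all(
                r.consequent <= t.items for t in tx if r.antecedent <= t.items
            )
            assert (r.confidence == 1.0) == contained

    def test_confidence_recomputed_independently(self):
        rng = np.random.default_rng(99)
        tx = random_transactions(rng, n_positions=5, n_transactions=25)
        rules = derive_rules(apriori(tx, 0.15))
        assert rules
        for r in rules:
            supp_x = support_of(r.antecedent, tx)
            supp_xy = support_of(r.antecedent | r.consequent, tx)
            assert r.confidence == pytest.approx(supp_xy / supp_x)
            assert r.support == pytest.approx(supp_xy)

    def test_min_confidence_filters(self):
        rng = np.random.default_rng(5)
        tx = random_transactions(rng, n_positions=4, n_transactions=30)
        rules = derive_rules(apriori(tx, 0.1), min_confidence=0.8)
        assert all(r.confidence >= 0.8 for r in rules)


class TestRuleMatrix:
    def test_matches_brute_force_confidences(self):
        a, b = Item(1, "ac"), Item(2, "ac")
        na, nb = Item(1, UNMODIFIED), Item(2, UNMODIFIED)
        tx = [
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, b})),
            Transaction(frozenset({a, nb})),
            Transaction(frozenset({na, b})),
        ]
        rules = derive_rules(apriori(tx, 0.1))
        m = rule_matrix(rules, [a, b], [a, b])
        assert m.loc[str(a), str(b)] == pytest.approx(2 / 3)
        assert m.loc[str(b), str(a)] == pytest.approx(2 / 3)

    def test_diagonal_is_one(self):
        a = Item(1, "ac")
        m = rule_matrix([], [a], [a])
        assert m.loc[str(a), str(a)] == 1.0

    def test_underivable_cells_are_missing_not_zero(self):
        a, b = Item(1, "ac"), Item(2, "ac")
        m = rule_matrix([], [a], [b])
        assert math.isnan(m.loc[str(a), str(b)])

    def test_group_antecedent(self):
        a, b, c = Item(1, "ac"), Item(2, "ac"), Item(3, "ac")
        tx = [Transaction(frozenset({a, b, c}))] * 3 + [
            Transaction(frozenset({a, Item(2, UNMODIFIED), Item(3, UNMODIFIED)}))
        ]
        rules = derive_rules(apriori(tx, 0.1))
        m = rule_matrix(rules, [[b, c]], [a])
        assert m.iloc[0, 0] == pytest.approx(1.0)
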