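"""Indiscernibility partitions, approximations, and reduct enumeration.

The partition oracle here is deliberately different machinery from the
implementation: it unions all-pairs indiscernibility edges (a discernibility-
matrix sweep) instead of grouping by value signature.  The reduct oracle
re-derives acceptance per subset from Partition objects.
"""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from roughnet import (
    approximations,
    find_reducts,
    ind_partition,
    partition_similarity,
    positive_region,
    subset_counts,
)
from roughnet.core import AttributeSchema, DECISION, build_information_system
from roughnet.roughset import Partition

from .strategies import small_tables


def pairwise_partition_oracle(table, attrs, universe=None):
    """Union-find over all indiscernible pairs — independent of the impl."""
    ids = list(universe) if universe is not None else list(table.object_ids)
    parent = {o: o for o in ids}

    def find(o):
        while parent[o] != o:
            parent[o] = parent[parent[o]]
            o = parent[o]
        return o

    for a, b in itertools.combinations(ids, 2):
        if all(table.values.loc[a, c] == table.values.loc[b, c] for c in attrs):
            parent[find(a)] = find(b)
    blocks = {}
    for o in ids:
        blocks.setdefault(find(o), set()).add(o)
    return {frozenset(b) for b in blocks.values()}


class TestIndPartition:
    def test_printed_single_attribute_partition(self, heart_sample):
        p = ind_partition(heart_sample, ["Chp"])
        assert p.as_sets() == {
            frozenset({"P1", "P4"}),
            frozenset({"P2"}),
            frozenset({"P3", "P5", "P6"}),
        }

    def test_full_attribute_partition(self, heart_sample):
        p = ind_partition(heart_sample, heart_sample.condition_names)
        assert p.as_sets() == {
            frozenset({"P1"}), frozenset({"P2"}), frozenset({"P3"}),
            frozenset({"P4"}), frozenset({"P5", "P6"}),
        }

    def test_empty_attribute_set_gives_one_block(self, heart_sample):
        p = ind_partition(heart_sample, [])
        assert p.as_sets() == {frozenset(heart_sample.object_ids)}

    def test_unknown_attribute_rejected(self, heart_sample):
        with pytest.raises(ValueError, match="not in the condition set"):
            ind_partition(heart_sample, ["Nope"])

    @given(small_tables())
    def test_agrees_with_pairwise_oracle(self, table):
        names = table.condition_names
        for k in range(len(names) + 1):
            for attrs in itertools.combinations(names, k):
                got = ind_partition(table, attrs).as_sets()
                assert got == pairwise_partition_oracle(table, attrs)

    @given(small_tables(max_attrs=4))
    def test_adding_attributes_refines(self, table):
        names = table.condition_names
        for k in range(len(names)):
            for attrs in itertools.combinations(names, k):
                coarse = ind_partition(table, attrs)
                fine = ind_partition(table, names)
                for block in fine.blocks:
                    assert any(block <= b for b in coarse.blocks)


class TestApproximations:
    def test_worked_example_both_classes(self, heart_sample):
        yes = approximations(heart_sample, heart_sample.condition_names, "Yes")
        assert yes.lower == {"P1", "P3"}
        assert yes.upper == {"P1", "P3", "P5", "P6"}
        assert yes.boundary == {"P5", "P6"}
        no = approximations(heart_sample, heart_sample.condition_names, "No")
        assert no.lower == {"P2", "P4"}
        assert no.upper == {"P2", "P4", "P5", "P6"}

    def test_unknown_class_rejected(self, heart_sample):
        with pytest.raises(ValueError, match="unknown class"):
            approximations(heart_sample, ["Chp"], "Maybe")

    def test_positive_region_of_worked_example(self, heart_sample):
        pos = positive_region(heart_sample, heart_sample.condition_names)
        assert pos.ids == {"P1", "P2", "P3", "P4"}

    def test_constant_attribute_gives_empty_positive_region(self):
        attrs = [AttributeSchema("a")]
        decision = AttributeSchema("class", role=DECISION)
        table = build_information_system(
            [["x"], ["x"], ["x"]], attrs, decision, ["A", "B", "A"]
        )
        assert positive_region(table, ["a"]).ids == frozenset()

    @given(small_tables())
    def test_sandwich_and_positive_region_identity(self, table):
        names = table.condition_names
        pos_union = set()
        for label in table.decision_classes():
            members = {
                o for o, d in zip(table.object_ids, table.decision_values) if d == label
            }
            ap = approximations(table, names, label)
            assert ap.lower <= members <= ap.upper
            assert ap.boundary == ap.upper - ap.lower
            pos_union |= ap.lower
        assert positive_region(table, names).ids == pos_union


class TestSubsetCounts:
    @pytest.mark.parametrize(
        "n, total", [(18, 262142), (9, 510), (13, 8190), (2, 2), (1, 0)]
    )
    def test_totals(self, n, total):
        assert subset_counts(n).total == total

    def test_per_size_is_binomial_and_sums_to_total(self):
        sc = subset_counts(18)
        assert sc.per_size[9] == 48620
        assert all(sc.per_size[k] == math.comb(18, k) for k in range(1, 18))
        assert sum(sc.per_size.values()) == sc.total

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            subset_counts(0)


class TestPartitionSimilarity:
    def test_worked_example_pair_agreement(self, heart_sample):
        p = ind_partition(heart_sample, ["Chp"])
        q = ind_partition(heart_sample, heart_sample.condition_names)
        assert partition_similarity(p, q) == pytest.approx(12 / 15)

    def test_identical_partitions_score_one(self, heart_sample):
        p = ind_partition(heart_sample, ["Chp"])
        assert partition_similarity(p, p) == 1.0

    def test_opposite_extremes_score_zero(self):
        u = frozenset({"a", "b"})
        singles = Partition(u, (frozenset({"a"}), frozenset({"b"})))
        one = Partition(u, (u,))
        assert partition_similarity(singles, one) == 0.0

    def test_universe_mismatch_rejected(self):
        p = Partition(frozenset({"a"}), (frozenset({"a"}),))
        q = Partition(frozenset({"b"}), (frozenset({"b"}),))
        with pytest.raises(ValueError, match="universe"):
            partition_similarity(p, q)

    @given(small_tables(max_attrs=4))
    def test_symmetric_bounded_and_discriminating(self, table):
        names = table.condition_names
        p = ind_partition(table, names[:1])
        q = ind_partition(table, names)
        s = partition_similarity(p, q)
        assert 0.0 <= s <= 1.0
        assert s == partition_similarity(q, p)
        assert (s == 1.0) == (p.as_sets() == q.as_sets())


def reduct_oracle(table, semantics="restricted"):
    """Accepted subsets re-derived from Partition objects, one at a time."""
    names = table.condition_names
    ref = positive_region(table, names).ids
    full_ref = {b & ref for b in ind_partition(table, names).blocks} - {frozenset()}
    accepted = []
    for k in range(1, len(names)):
        for attrs in itertools.combinations(names, k):
            if semantics == "restricted":
                sub = {
                    b & ref for b in ind_partition(table, attrs).blocks
                } - {frozenset()}
                ok = sub == full_ref
            else:
                ok = positive_region(table, attrs).ids == ref
            if ok:
                accepted.append(frozenset(attrs))
    return accepted


class TestFindReducts:
    def test_worked_example_reducts_and_core(self, heart_sample):
        report = find_reducts(heart_sample, mode="exact")
        assert report.reduct_sets() == [
            frozenset({"Chp", "Vessel"}),
            frozenset({"ECG", "Vessel"}),
        ]
        assert report.core == {"Vessel"}
        assert report.counts.total == 2**3 - 2
        assert all(r.score == 1.0 for r in report.reducts)

    def test_worked_example_under_pos_preserving_flag(self, heart_sample):
        # {ECG, Vessel} merges P4 into a mixed block over U, so the classical
        # positive-region criterion keeps only {Chp, Vessel}
        report = find_reducts(heart_sample, semantics="pos_preserving")
        assert report.reduct_sets() == [frozenset({"Chp", "Vessel"})]

    def test_single_attribute_table_has_no_candidates(self):
        attrs = [AttributeSchema("a")]
        decision = AttributeSchema("class", role=DECISION)
        table = build_information_system([["x"], ["y"]], attrs, decision, ["A", "B"])
        report = find_reducts(table)
        assert report.reducts == ()
        assert report.core == frozenset()
        assert report.counts.total == 0

    def test_attribute_cap_enforced_without_size_range(self, heart_sample):
        with pytest.raises(ValueError, match="exceed"):
            find_reducts(heart_sample, max_attributes=2)
        report = find_reducts(heart_sample, max_attributes=2, size_range=(1, 2))
        assert report.reduct_sets() == [
            frozenset({"Chp", "Vessel"}),
            frozenset({"ECG", "Vessel"}),
        ]

    def test_approx_mode_converges_to_exact_as_threshold_rises(self, heart_sample):
        exact = set(find_reducts(heart_sample, mode="exact").reduct_sets())
        loose = set(find_reducts(heart_sample, mode="approx", threshold=0.5).reduct_sets())
        tight = set(
            find_reducts(heart_sample, mode="approx", threshold=0.999).reduct_sets()
        )
        assert exact <= loose
        assert tight == exact

    @given(small_tables(min_objects=4, max_objects=10, min_attrs=2, max_attrs=5))
    def test_matches_oracle_both_semantics(self, table):
        for semantics in ("restricted", "pos_preserving"):
            got = find_reducts(table, semantics=semantics).reduct_sets()
            assert sorted(got, key=sorted) == sorted(
                reduct_oracle(table, semantics), key=sorted
            )

    @given(small_tables(min_objects=4, max_objects=10, min_attrs=3, max_attrs=5))
    def test_exact_acceptance_is_superset_closed(self, table):
        names = set(table.condition_names)
        accepted = set(find_reducts(table).reduct_sets())
        for r in accepted:
            for extra in names - r:
                grown = r | {extra}
                if grown != names:
                    assert grown in accepted

    @given(small_tables(min_objects=4, max_objects=10, min_attrs=2, max_attrs=5))
    def test_candidate_accounting(self, table):
        report = find_reducts(table)
        n = len(table.condition_names)
        assert report.counts.total == 2**n - 2 == sum(report.counts.per_size.values())

    def test_report_serialization_carries_bitmasks(self, heart_sample):
        report = find_reducts(heart_sample)
        payload = report.to_dict(sequence=heart_sample.condition_names)
        assert payload["n_reducts"] == 2
        assert payload["core"] == ["Vessel"]
        masks = {tuple(e["bitmask"]) for e in payload["reducts"]}
        assert masks == {(1, 0, 1), (0, 1, 1)}
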