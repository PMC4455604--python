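import random

import pytest

from vennkit import (
    ParseError,
    UnionGrouping,
    ValidationError,
    build_family,
    compute_region_table,
    grouping_at_level,
    max_level,
    parse_union_code,
    parse_union_list,
    parse_union_tree,
    quotient_signature_code,
    quotient_table,
)
from conftest import random_family


@pytest.fixture
def fam4():
    return build_family([(n, "") for n in ("w", "x", "y", "z")])


@pytest.fixture
def fam6():
    return build_family([(n, "") for n in ("s", "t", "u", "v", "w", "x")])


class TestParseUnionTree:
    def test_leaf_depths_of_caterpillar(self, fam4):
        tree = parse_union_tree("(A,(B,(C,D)))", fam4)
        depths = {}

        def walk(node, d):
            if node.is_leaf:
                depths[node.label] = d
            else:
                for c in node.children:
                    walk(c, d + 1)

        walk(tree.root, 0)
        assert depths == {"A": 1, "B": 2, "C": 3, "D": 3}

    def test_trailing_semicolon_and_whitespace(self, fam4):
        tree = parse_union_tree(" ((A, B), (C, D)) ; ", fam4)
        assert max_level(tree) == 2

    def test_set_names_resolve_to_labels(self, fam4):
        tree = parse_union_tree("(w,(x,(y,z)))", fam4)
        assert sorted(tree.root.leaves()) == list("ABCD")

    @pytest.mark.parametrize(
        "text, reason",
        [
            ("(A,(B,C))", "missing leaf"),
            ("(A,B,(C,D))", "non-binary"),
            ("(A,(B,(C,D))", "unbalanced"),
            ("(A,(B,(C,D))))", "trailing"),
            ("(A,(A,(C,D)))", "duplicated leaf"),
            ("(A,(B,(C,E)))", "unknown leaf"),
            ("(A:1,(B,(C,D)))", "branch length"),
            ("('A',(B,(C,D)))", "quoted label"),
            ("(A,(B,(C,[x]D)))", "comment"),
        ],
    )
    def test_rejected_inputs(self, fam4, text, reason):
        with pytest.raises(ParseError):
            parse_union_tree(text, fam4)

    def test_error_carries_position(self, fam4):
        with pytest.raises(ParseError, match="position"):
            parse_union_tree("(A,(B,(C,D))", fam4)


class TestLevels:
    @pytest.mark.parametrize(
        "newick, expected",
        [("(A,(B,(C,D)))", 3), ("((A,B),(C,D))", 2)],
    )
    def test_max_level(self, fam4, newick, expected):
        assert max_level(parse_union_tree(newick, fam4)) == expected

    def test_max_level_unbalanced_six(self, fam6):
        tree = parse_union_tree("(A,((B,(C,D)),(E,F)))", fam6)
        assert max_level(tree) == 4

    @pytest.mark.parametrize(
        "k, groups",
        [
            (3, ("A", "B", "C", "D")),
            (2, ("A", "B", "CD")),
            (1, ("A", "BCD")),
            (0, ("ABCD",)),
        ],
    )
    def test_caterpillar_navigation(self, fam4, k, groups):
        tree = parse_union_tree("(A,(B,(C,D)))", fam4)
        assert grouping_at_level(tree, k).groups == groups

    def test_level_out_of_range(self, fam4):
        tree = parse_union_tree("(A,(B,(C,D)))", fam4)
        for k in (-1, 4):
            with pytest.raises(ValidationError):
                grouping_at_level(tree, k)

    def test_six_leaf_unbalanced_levels(self, fam6):
        # leaf depths: A:1, B:3, C:4, D:4, E:3, F:3
        tree = parse_union_tree("(A,((B,(C,D)),(E,F)))", fam6)
        assert grouping_at_level(tree, 4).groups == tuple("ABCDEF")
        assert grouping_at_level(tree, 3).groups == ("A", "B", "CD", "E", "F")
        assert grouping_at_level(tree, 2).groups == ("A", "BCD", "EF")
        assert grouping_at_level(tree, 1).groups == ("A", "BCDEF")
        assert grouping_at_level(tree, 0).groups == ("ABCDEF",)

    @pytest.mark.parametrize("newick", ["(A,(B,(C,D)))", "((A,B),(C,D))"])
    def test_each_level_refines_the_previous(self, fam4, newick):
        tree = parse_union_tree(newick, fam4)
        for k in range(1, max_level(tree) + 1):
            fine = grouping_at_level(tree, k)
            coarse = grouping_at_level(tree, k - 1)
            for group in fine.groups:
                assert any(set(group) <= set(cg) for cg in coarse.groups)


class TestUnionCodes:
    def test_single_group_rest_singletons(self):
        fam5 = build_family([(n, "") for n in "vwxyz"])
        assert parse_union_code("BC", fam5).groups == ("A", "BC", "D", "E")
        assert parse_union_code("ABCDE", fam5).groups == ("ABCDE",)

    def test_repeated_label_rejected(self, fam4):
        with pytest.raises(ValidationError, match="'B'"):
            parse_union_code("AB,BC", fam4)

    def test_unknown_label_rejected(self, fam4):
        with pytest.raises(ValidationError):
            parse_union_code("AZ", fam4)

    def test_lowercase_and_order_canonicalized(self, fam4):
        assert parse_union_code("dc", fam4).groups == ("A", "B", "CD")


class TestUnionLists:
    def test_worked_example(self, fam4):
        prog = parse_union_list(";CD;CB;AB,CD", fam4)
        assert [s.groups for s in prog.steps] == [
            ("A", "B", "C", "D"),
            ("A", "B", "CD"),
            ("A", "BC", "D"),
            ("AB", "CD"),
        ]

    def test_empty_program_is_identity(self, fam4):
        prog = parse_union_list("", fam4)
        assert len(prog.steps) == 1
        assert prog.steps[0].is_identity

    def test_matches_tree_levels(self, fam4):
        prog = parse_union_list(";CD;CDB;CDBA", fam4)
        tree = parse_union_tree("(A,(B,(C,D)))", fam4)
        expected = [grouping_at_level(tree, k) for k in (3, 2, 1, 0)]
        assert list(prog.steps) == expected

    def test_error_identifies_step(self, fam4):
        with pytest.raises(ParseError, match="step 2"):
            parse_union_list(";CD;AB,BC", fam4)


def _recompute_united(fam, grouping):
    """Oracle: literally unite each group's element sets, then recompute."""
    entries = []
    for group in grouping.groups:
        text = "\n".join(el for lab in group for el in fam[lab].elements)
        entries.append(("+".join(fam[lab].name for lab in group), text))
    united = build_family(entries)
    # map recomputed codes (over new labels) onto quotient codes
    relabel = dict(zip(united.labels, grouping.groups))
    table = compute_region_table(united)
    return {
        frozenset(relabel[lab] for lab in code): set(els)
        for code, els in table.regions.items()
    }


class TestQuotient:
    def test_identity_equals_original(self, two_set_family):
        table = compute_region_table(two_set_family)
        q = quotient_table(table, UnionGrouping.identity("AB"))
        assert q.counts() == table.counts()
        assert q.codes() == table.codes()

    def test_forced_example(self):
        fam = build_family([("p", "x"), ("q", "y"), ("r", "z"), ("s", "z")])
        table = compute_region_table(fam)
        q = quotient_table(table, parse_union_code("CD", fam))
        counts = q.counts()
        assert counts["A"] == 1 and counts["B"] == 1 and counts["CD"] == 1
        assert sum(counts.values()) == 3  # every mixed region empty

    def test_mismatched_family_rejected(self, two_set_family):
        table = compute_region_table(two_set_family)
        with pytest.raises(ValidationError):
            quotient_table(table, UnionGrouping.identity("ABC"))

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_recomputation_on_united_sets(self, seed):
        rng = random.Random(1000 + seed)
        fam = random_family(rng, n=rng.randint(2, 6), max_elements=120)
        table = compute_region_table(fam)
        grouping = _random_grouping(rng, fam.labels)
        q = quotient_table(table, grouping)
        oracle = _recompute_united(fam, grouping)
        assert {sig: set(els) for sig, els in q.regions.items()} == oracle

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation(self, seed):
        rng = random.Random(2000 + seed)
        fam = random_family(rng, n=rng.randint(2, 6))
        table = compute_region_table(fam)
        grouping = _random_grouping(rng, fam.labels)
        assert quotient_table(table, grouping).total() == table.total()

    def test_composition(self):
        fam = random_family(random.Random(5), n=4, max_elements=80)
        table = compute_region_table(fam)
        g1 = UnionGrouping.from_groups("ABCD", ["AB", "C", "D"])
        # apply a further merge of g1's groups: {AB}+{C} -> ABC
        g2 = UnionGrouping.from_groups("ABCD", ["ABC", "D"])
        twice = quotient_table(quotient_table(table, g1), _lift(g1, [["AB", "C"], ["D"]]))
        once = quotient_table(table, g2)
        assert twice.counts() == once.counts()


def _lift(grouping, merges):
    """Build a grouping over original labels by merging groups of `grouping`."""
    labels = grouping.labels
    groups = ["".join(sorted("".join(m))) for m in merges]
    return UnionGrouping.from_groups(labels, groups)


def _random_grouping(rng, labels):
    groups: dict[int, list[str]] = {}
    k = rng.randint(1, len(labels))
    for lab in labels:
        groups.setdefault(rng.randint(0, k - 1), []).append(lab)
    return UnionGrouping.from_groups(labels, ["".join(g) for g in groups.values()])


class TestQuotientCodes:
    def test_singleton_signatures_concatenate(self):
        assert quotient_signature_code({"A", "B"}) == "AB"

    def test_united_signatures_join_with_underscore(self):
        assert quotient_signature_code({"CD", "B"}) == "B_CD"
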