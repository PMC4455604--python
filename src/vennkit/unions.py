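"""Set unions that preserve the diagram shape.

Three equivalent front-ends describe which sets are united:

* a **union code** like ``"BC"`` (unite B and C; commas separate
  several disjoint groups, e.g. ``"AB,CD"``),
* a **union list** like ``";CD;CB;AB,CD"`` — a ``;``-separated sequence
  of union codes, each an independent diagram state (the empty step is
  the all-singletons identity),
* a **union tree** — a strictly binary Newick-style topology such as
  ``(A,(B,(C,D)))`` whose depth levels induce progressively coarser
  groupings: level ``max`` is all singletons, level 0 one group.

Every front-end produces a :class:`UnionGrouping` — a partition of the
family's labels — and :func:`quotient_table` folds a full region table
under such a partition without recomputing memberships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from .errors import ParseError, ValidationError
from .setcore import RegionTable, SetFamily, canonical_code

__all__ = [
    "TreeNode",
    "UnionTree",
    "UnionGrouping",
    "UnionListProgram",
    "QuotientRegionTable",
    "parse_union_tree",
    "max_level",
    "grouping_at_level",
    "parse_union_code",
    "parse_union_list",
    "quotient_table",
    "quotient_signature_code",
]


@dataclass(frozen=True)
class TreeNode:
    """A node of a union tree: a leaf with a label, or two children."""

    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> Iterator[str]:
        if self.is_leaf:
            yield self.label  # type: ignore[misc]
        else:
            for child in self.children:  # type: ignore[union-attr]
                yield from child.leaves()


@dataclass(frozen=True)
class UnionTree:
    """Strictly binary tree whose leaves are exactly the family labels."""

    root: TreeNode
    labels: str  # the family's label string, e.g. "ABCD"


@dataclass(frozen=True)
class UnionGrouping:
    """A partition of the family's labels into union groups.

    ``groups`` is a tuple of canonical group codes (member labels sorted
    alphabetically), itself sorted alphabetically.
    """

    labels: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        covered = "".join(sorted("".join(self.groups)))
        if covered != self.labels:
            raise ValidationError(
                f"groups {self.groups!r} do not partition labels {self.labels!r}"
            )
        if tuple(sorted(self.groups)) != self.groups:
            raise ValidationError("group codes must be sorted alphabetically")

    @property
    def is_identity(self) -> bool:
        return all(len(g) == 1 for g in self.groups)

    def group_of(self, label: str) -> str:
        for g in self.groups:
            if label in g:
                return g
        raise ValidationError(f"label {label!r} not covered by grouping")

    @staticmethod
    def identity(labels: str) -> "UnionGrouping":
        return UnionGrouping(labels=labels, groups=tuple(labels))

    @staticmethod
    def from_groups(labels: str, groups: list[str]) -> "UnionGrouping":
        canon = tuple(sorted("".join(sorted(set(g))) for g in groups))
        return UnionGrouping(labels=labels, groups=canon)


@dataclass(frozen=True)
class UnionListProgram:
    """An ordered sequence of diagram states, one grouping per step."""

    steps: tuple[UnionGrouping, ...]


# ---------------------------------------------------------------------------
# Newick-subset union trees
# ---------------------------------------------------------------------------


class _NewickParser:
    """Recursive-descent parser for the bare-topology Newick dialect.

    Accepts labels or exact set names at leaves and binary bifurcations
    only.  Branch lengths, comments and quoted labels are rejected — the
    union-tree language is topology-only, and silently dropping
    annotations could mask a user error.
    """

    def __init__(self, text: str, family: SetFamily):
        self.text = text
        self.pos = 0
        self.family = family
        # exact set names resolve to labels; a single-letter name takes
        # precedence over the bare label it collides with
        self.by_name = {s.name: s.label for s in family.sets}

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, position=self.pos)

    def peek(self) -> str:
        # end of input reads as a sentinel that matches no delimiter class
        return self.text[self.pos] if self.pos < len(self.text) else "\0"

    def skip_ws(self) -> None:
        while self.peek() in " \t\r\n":
            self.pos += 1

    def parse(self) -> TreeNode:
        self.skip_ws()
        node = self.parse_node()
        self.skip_ws()
        if self.peek() == ";":
            self.pos += 1
            self.skip_ws()
        if self.pos != len(self.text):
            raise self.error(f"unexpected trailing text {self.text[self.pos:]!r}")
        return node

    def parse_node(self) -> TreeNode:
        self.skip_ws()
        if self.peek() == "(":
            self.pos += 1
            left = self.parse_node()
            self.skip_ws()
            if self.peek() != ",":
                raise self.error("expected ',' — every internal node must bifurcate")
            self.pos += 1
            right = self.parse_node()
            self.skip_ws()
            if self.peek() == ",":
                raise self.error("non-binary node: more than two children")
            if self.peek() != ")":
                raise self.error("unbalanced parentheses: expected ')'")
            self.pos += 1
            self.skip_ws()
            if self.peek() == ":":
                raise self.error("branch lengths are not allowed")
            return TreeNode(children=(left, right))
        return self.parse_leaf()

    def parse_leaf(self) -> TreeNode:
        self.skip_ws()
        if self.peek() in "'\"":
            raise self.error("quoted labels are not allowed")
        if self.peek() == "[":
            raise self.error("comments are not allowed")
        start = self.pos
        while self.peek() not in "(),;:\0":
            self.pos += 1
        token = self.text[start : self.pos].strip()
        if self.peek() == ":":
            raise self.error("branch lengths are not allowed")
        if not token:
            raise self.error("expected a leaf label or set name")
        if token in self.by_name:
            return TreeNode(label=self.by_name[token])
        if len(token) == 1 and token in self.family.labels:
            return TreeNode(label=token)
        self.pos = start
        raise self.error(f"unknown leaf {token!r}")


def parse_union_tree(text: str, family: SetFamily) -> UnionTree:
    """Parse a topology-only Newick expression into a union tree.

    Leaves may be bare labels (``A``..) or exact set names; each of the
    family's labels must appear exactly once.
    """
    root = _NewickParser(text, family).parse()
    leaves = list(root.leaves())
    if len(set(leaves)) != len(leaves):
        dup = sorted(l for l in set(leaves) if leaves.count(l) > 1)
        raise ParseError(f"duplicated leaf {dup[0]!r}")
    missing = sorted(set(family.labels) - set(leaves))
    if missing:
        raise ParseError(f"leaf {missing[0]!r} missing from tree")
    if family.n > 1 and root.is_leaf:
        raise ParseError("tree must cover all sets")
    return UnionTree(root=root, labels=family.labels)


def max_level(tree: UnionTree) -> int:
    """Maximum leaf depth (root has depth 0)."""

    def depth(node: TreeNode) -> int:
        if node.is_leaf:
            return 0
        return 1 + max(depth(c) for c in node.children)  # type: ignore[union-attr]

    return depth(tree.root)


def grouping_at_level(tree: UnionTree, k: int) -> UnionGrouping:
    """The union grouping induced by cutting the tree at depth ``k``.

    Groups are the leaf sets of the maximal frontier at level ``k``: one
    group per node at depth ``k``, plus one singleton per leaf shallower
    than ``k``.  ``k = max_level`` gives all singletons; ``k = 0`` the
    single total group.
    """
    if not 0 <= k <= max_level(tree):
        raise ValidationError(
            f"level {k} out of range 0..{max_level(tree)} for this tree"
        )
    groups: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        if depth == k or node.is_leaf:
            groups.append("".join(sorted(node.leaves())))
            return
        for child in node.children:  # type: ignore[union-attr]
            walk(child, depth + 1)

    walk(tree.root, 0)
    return UnionGrouping.from_groups(tree.labels, groups)


# ---------------------------------------------------------------------------
# Union codes and union lists
# ---------------------------------------------------------------------------


def parse_union_code(code: str, family: SetFamily) -> UnionGrouping:
    """Parse a union code like ``"BC"`` or ``"AB,CD"`` into a grouping.

    Each comma-separated token unites the named sets; labels not
    mentioned stay as singleton groups.  A label used in two groups is
    an error — groups must be disjoint.
    """
    mentioned: set[str] = set()
    groups: list[str] = []
    for token in code.split(","):
        token = token.strip()
        if not token:
            continue
        canon = canonical_code(token, family.labels)
        overlap = mentioned & set(canon)
        if overlap:
            raise ValidationError(
                f"label {sorted(overlap)[0]!r} repeated across union groups in {code!r}"
            )
        mentioned.update(canon)
        groups.append(canon)
    for label in family.labels:
        if label not in mentioned:
            groups.append(label)
    return UnionGrouping.from_groups(family.labels, groups)


def parse_union_list(text: str, family: SetFamily) -> UnionListProgram:
    """Parse a ``;``-separated union-list program.

    Each step is an independent union code; an empty step denotes the
    all-singletons identity grouping, so a leading ``;`` starts the
    program from the un-united diagram.
    """
    steps: list[UnionGrouping] = []
    for i, step_text in enumerate(text.split(";")):
        try:
            steps.append(parse_union_code(step_text, family))
        except ValidationError as exc:
            raise ParseError(f"step {i}: {exc}") from exc
    return UnionListProgram(steps=tuple(steps))


# ---------------------------------------------------------------------------
# Quotient region tables
# ---------------------------------------------------------------------------


def quotient_signature_code(groups: frozenset[str] | set[str] | tuple[str, ...]) -> str:
    """Canonical printable code for a quotient signature.

    Singleton-only signatures concatenate as plain region codes ("AB"),
    so the identity grouping reproduces the original table's codes;
    signatures touching a united group join group codes with ``_``
    ("B_CD") to keep multi-letter group codes unambiguous.
    """
    parts = sorted(groups)
    if all(len(g) == 1 for g in parts):
        return "".join(parts)
    return "_".join(parts)


@dataclass(frozen=True)
class QuotientRegionTable:
    """A region table folded under a union grouping.

    Keys are frozensets of group codes; each region's elements are the
    concatenation of the original regions that map onto it.  Exactly
    ``2**m - 1`` signatures are present for ``m`` groups.
    """

    family: SetFamily
    grouping: UnionGrouping
    regions: Mapping[frozenset[str], tuple[str, ...]]

    def codes(self) -> list[str]:
        sigs = sorted(self.regions, key=lambda s: (len(s), quotient_signature_code(s)))
        return [quotient_signature_code(s) for s in sigs]

    def signatures(self) -> list[frozenset[str]]:
        return sorted(self.regions, key=lambda s: (len(s), quotient_signature_code(s)))

    def counts(self) -> dict[str, int]:
        return {
            quotient_signature_code(s): len(self.regions[s]) for s in self.signatures()
        }

    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())


def quotient_table(
    table: RegionTable | QuotientRegionTable, grouping: UnionGrouping
) -> QuotientRegionTable:
    """Fold a region table under a grouping.

    Each original signature S maps to the set of groups it touches; the
    quotient region's contents are the union (concatenation, original
    order preserved per source region) of all original regions mapping
    to it.  Equivalent to recomputing the table on literally-united
    sets.

    An already-folded :class:`QuotientRegionTable` may be folded again
    by any grouping coarser than its own (quotients compose), which is
    how successive union steps are applied without returning to the
    full table.
    """
    if grouping.labels != table.family.labels:
        raise ValidationError(
            f"grouping over {grouping.labels!r} does not match family {table.family.labels!r}"
        )
    if isinstance(table, QuotientRegionTable):
        for g in table.grouping.groups:
            if not set(g) <= set(grouping.group_of(g[0])):
                raise ValidationError(
                    f"grouping must be coarser than the table's: group {g!r} is split"
                )
        source = [(sig, els) for sig, els in table.regions.items()]
        mapped = [
            (frozenset(grouping.group_of(g[0]) for g in sig), els)
            for sig, els in source
        ]
    else:
        mapped = [
            (frozenset(grouping.group_of(label) for label in code), table.regions[code])
            for code in table.codes()
        ]
    m = len(grouping.groups)
    regions: dict[frozenset[str], list[str]] = {}
    for mask in range(1, 1 << m):
        sig = frozenset(grouping.groups[i] for i in range(m) if mask >> i & 1)
        regions[sig] = []
    for sig, els in mapped:
        regions[sig].extend(els)
    return QuotientRegionTable(
        family=table.family,
        grouping=grouping,
        regions={s: tuple(v) for s, v in regions.items()},
    )
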