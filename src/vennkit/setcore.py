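"""Set families and disjoint Venn regions.

A Venn diagram over *n* named sets partitions the union of all elements
into ``2**n - 1`` disjoint *regions*, one per non-empty subset of the
sets.  An element lies in the region whose *signature* is exactly the
collection of sets containing it: the "AB" region of a three-set family
holds the elements in A and in B but **not** in C (the exclusive
intersection, not the full one).

Labels ``A``..``F`` are assigned to sets in input order; at most six
sets are supported, which is the practical ceiling for a readable Venn
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import CapacityError, ValidationError

#: The full alphabet of set labels, in assignment order.
LABELS = "ABCDEF"

#: Hard upper bound on the number of sets in one diagram.
MAX_SETS = 6


def normalize_elements(raw_text: str) -> list[str]:
    """Turn a block of text into a clean element list.

    One element per line; leading/trailing whitespace is stripped, empty
    lines are dropped, and duplicates are removed keeping the first
    occurrence.  Comparison is exact and case-sensitive.  Idempotent:
    normalizing the joined output is a fixed point.
    """
    seen: set[str] = set()
    out: list[str] = []
    for line in raw_text.splitlines():
        item = line.strip()
        if item and item not in seen:
            seen.add(item)
            out.append(item)
    return out


@dataclass(frozen=True)
class NamedSet:
    """A labeled, named, deduplicated collection of element strings."""

    label: str
    name: str
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.label) != 1 or self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS!r}, got {self.label!r}")
        if not self.name:
            raise ValidationError("set name must be non-empty")
        seen: set[str] = set()
        for el in self.elements:
            if not el or el != el.strip():
                raise ValidationError(
                    f"element {el!r} in set {self.label} is empty or has surrounding whitespace"
                )
            if el in seen:
                raise ValidationError(f"duplicate element {el!r} in set {self.label}")
            seen.add(el)

    def __contains__(self, element: object) -> bool:
        return element in set(self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class SetFamily:
    """An ordered family of 1..6 named sets labeled ``A``.. in input order."""

    sets: tuple[NamedSet, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.sets) <= MAX_SETS:
            raise CapacityError(
                f"a family must contain 1..{MAX_SETS} sets, got {len(self.sets)}"
            )
        expected = LABELS[: len(self.sets)]
        got = "".join(s.label for s in self.sets)
        if got != expected:
            raise ValidationError(f"labels must be {expected!r} in order, got {got!r}")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError("set names must be pairwise distinct")

    @property
    def n(self) -> int:
        return len(self.sets)

    @property
    def labels(self) -> str:
        return LABELS[: self.n]

    def __getitem__(self, label: str) -> NamedSet:
        i = self.labels.find(label)
        if i < 0:
            raise ValidationError(f"unknown set label {label!r}")
        return self.sets[i]

    def union(self) -> set[str]:
        """Union of all element collections."""
        out: set[str] = set()
        for s in self.sets:
            out.update(s.elements)
        return out


def build_family(entries: Sequence[tuple[str, str]]) -> SetFamily:
    """Build a :class:`SetFamily` from ordered ``(name, raw_text)`` pairs.

    Each raw text block is passed through :func:`normalize_elements`;
    labels A.. are assigned by position.

    Raises
    ------
    CapacityError
        if more than six entries are given.
    ValidationError
        on empty or duplicate names.
    """
    if len(entries) > MAX_SETS:
        raise CapacityError(f"at most {MAX_SETS} sets are supported, got {len(entries)}")
    if not entries:
        raise CapacityError("at least one set is required")
    sets = []
    for label, (name, raw) in zip(LABELS, entries):
        name = name.strip()
        if not name:
            raise ValidationError("set names must be non-empty")
        sets.append(NamedSet(label=label, name=name, elements=tuple(normalize_elements(raw))))
    return SetFamily(sets=tuple(sets))


def all_signatures(labels: str) -> list[str]:
    """All ``2**n - 1`` canonical region codes for a label string.

    Ordered by subset size then alphabetically: A, B, AB, ... so that
    tabular output reads naturally.
    """
    n = len(labels)
    codes = []
    for mask in range(1, 1 << n):
        codes.append("".join(labels[i] for i in range(n) if mask >> i & 1))
    codes.sort(key=lambda c: (len(c), c))
    return codes


def canonical_code(code: str, labels: str) -> str:
    """Canonicalize a region/group code: uppercase, sorted, deduplicated.

    Raises :class:`ValidationError` naming the offending character when a
    label is unknown, or when the code is empty.
    """
    if not code:
        raise ValidationError("region code must not be empty")
    members = sorted(set(code.upper()))
    for ch in members:
        if ch not in labels:
            raise ValidationError(f"unknown set label {ch!r} (family has labels {labels!r})")
    return "".join(members)


@dataclass(frozen=True)
class RegionTable:
    """The disjoint-region partition of a family's union.

    ``regions`` maps every canonical signature code (all ``2**n - 1`` of
    them, empty regions included) to the tuple of elements whose
    membership pattern is exactly that signature.  Element order within
    a region follows first occurrence across the family's sets.
    """

    family: SetFamily
    regions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def codes(self) -> list[str]:
        return all_signatures(self.family.labels)

    def counts(self) -> dict[str, int]:
        return {code: len(self.regions[code]) for code in self.codes()}

    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())


def compute_region_table(family: SetFamily) -> RegionTable:
    """Assign every element of the family's union to its unique region."""
    membership: dict[str, list[str]] = {}  # element -> labels containing it
    order: list[str] = []  # first-occurrence order across sets
    for s in family.sets:
        for el in s.elements:
            if el not in membership:
                membership[el] = []
                order.append(el)
            membership[el].append(s.label)
    regions: dict[str, list[str]] = {code: [] for code in all_signatures(family.labels)}
    for el in order:
        regions["".join(membership[el])].append(el)
    return RegionTable(family=family, regions={c: tuple(v) for c, v in regions.items()})


def region_elements(table: RegionTable, code: str) -> tuple[str, ...]:
    """Elements of one exclusive region, looked up by (lax) code.

    The code is canonicalized first, so ``"ba"`` and ``"AB"`` name the
    same region.
    """
    return table.regions[canonical_code(code, table.family.labels)]


def region_counts(table: RegionTable) -> tuple[dict[str, int], int]:
    """Per-region sizes plus the union total (== sum of all counts)."""
    counts = table.counts()
    return counts, sum(counts.values())


def signature_of(element: str, family: SetFamily) -> str | None:
    """Direct membership signature of one element, or None if absent.

    Evaluates raw membership against every set; exists as the simple
    reference definition that :func:`compute_region_table` must agree
    with.
    """
    code = "".join(s.label for s in family.sets if element in s)
    return code or None
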