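"""Seeded synthetic set families with known ground truth.

Two generators cover the shapes of data this tool is typically fed:

* :func:`generate_family` builds a family by *construction from the
  regions*: you say how many elements each region signature should
  hold, and get back both the family and the region table that is true
  by construction — the independent yardstick for the engine's own
  region computation.

* :func:`generate_ranked_lists` emulates comparing the top-*n* ranked
  outputs of several selection methods (e.g. candidate-biomarker lists
  from different feature-selection models): every list has exactly
  ``n_top`` entries, exactly ``shared_core`` of which are common to all
  methods, with the remainder scattered deterministically over proper
  subsets of the methods.

Element strings are synthetic alphanumeric tokens, not real gene or
protein symbols; both generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .setcore import (
    LABELS,
    NamedSet,
    RegionTable,
    SetFamily,
    all_signatures,
    canonical_code,
)

__all__ = ["OverlapSpec", "generate_family", "generate_ranked_lists"]


@dataclass(frozen=True)
class OverlapSpec:
    """Intended per-region element counts for a synthetic family.

    ``target_counts`` maps region codes (any letter order) to the exact
    number of elements that region must contain; unmentioned regions
    stay empty.
    """

    n: int
    target_counts: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n <= len(LABELS):
            raise ValidationError(f"set count must be 1..{len(LABELS)}, got {self.n}")
        labels = LABELS[: self.n]
        canon: dict[str, int] = {}
        for code, count in self.target_counts.items():
            c = canonical_code(code, labels)
            if count < 0:
                raise ValidationError(f"negative count for region {c!r}")
            if c in canon:
                raise ValidationError(f"region {c!r} specified twice")
            canon[c] = count
        object.__setattr__(self, "target_counts", canon)


def _token(rng: np.random.Generator, used: set[str]) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    while True:
        tok = "T" + "".join(rng.choice(list(alphabet), size=8))
        if tok not in used:
            used.add(tok)
            return tok


def generate_family(spec: OverlapSpec) -> tuple[SetFamily, RegionTable]:
    """Synthesize a family realizing the spec's region counts exactly.

    Returns the family and its ground-truth region table; the table the
    engine computes from the family must agree with it element for
    element.
    """
    rng = np.random.default_rng(spec.seed)
    labels = LABELS[: spec.n]
    used: set[str] = set()
    per_set: dict[str, list[str]] = {lab: [] for lab in labels}
    regions: dict[str, tuple[str, ...]] = {}
    for code in all_signatures(labels):
        members = [_token(rng, used) for _ in range(spec.target_counts.get(code, 0))]
        regions[code] = tuple(members)
        for lab in code:
            per_set[lab].extend(members)
    sets = tuple(
        NamedSet(label=lab, name=f"set-{lab}", elements=tuple(per_set[lab]))
        for lab in labels
    )
    family = SetFamily(sets=sets)
    return family, RegionTable(family=family, regions=regions)


def generate_ranked_lists(
    n_methods: int, n_top: int, shared_core: int, seed: int = 0
) -> list[tuple[str, list[str]]]:
    """Emulate top-``n_top`` ranked lists from ``n_methods`` methods.

    Exactly ``shared_core`` elements appear in every list; the rest of
    each list is filled with elements shared by proper subsets of the
    methods (including singletons), drawn deterministically from the
    seed.  Returns ``(method name, element list)`` pairs; every list
    has exactly ``n_top`` entries.
    """
    if not 2 <= n_methods <= len(LABELS):
        raise ValidationError(f"n_methods must be 2..{len(LABELS)}, got {n_methods}")
    if n_top < 0 or shared_core < 0 or shared_core > n_top:
        raise ValidationError(
            f"need 0 <= shared_core <= n_top, got shared_core={shared_core}, n_top={n_top}"
        )
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    lists: list[list[str]] = [[] for _ in range(n_methods)]
    core = [_token(rng, used) for _ in range(shared_core)]
    for lst in lists:
        lst.extend(core)
    deficits = [n_top - shared_core] * n_methods
    while any(deficits):
        open_methods = [i for i, d in enumerate(deficits) if d > 0]
        # never complete the all-methods signature: the fully-shared core
        # must stay exactly shared_core
        max_size = min(len(open_methods), n_methods - 1)
        size = int(rng.integers(1, max_size + 1)) if max_size >= 1 else 1
        chosen = sorted(rng.choice(open_methods, size=size, replace=False).tolist())
        tok = _token(rng, used)
        for i in chosen:
            lists[i].append(tok)
            deficits[i] -= 1
    return [(f"method-{i + 1}", lst) for i, lst in enumerate(lists)]
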