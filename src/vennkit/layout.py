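"""Fixed diagram geometry for 1–6 sets.

The geometry is shipped as static vertex/anchor tables (JSON under
``vennkit/data/``, regenerated by ``scripts/generate_geometry.py``) and
is the same for every dataset: the number of sets alone determines the
diagram shape.  Circles serve up to three sets, tilted congruent
ellipses four and five; six sets use an Edwards-style construction (two
half-plane rectangles, a circle, and three cogwheel curves with
doubling tooth counts), which exposes all 63 regions — a regime where
circles and ellipses provably cannot.

Every region signature owns an *anchor*: a point strictly inside every
curve of the signature and strictly outside all others, where the
region's count is drawn.  Union groupings reuse the same curves and the
same anchors, so uniting sets never changes the diagram shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import CapacityError, ValidationError
from .setcore import MAX_SETS, all_signatures
from .unions import UnionGrouping

__all__ = ["DiagramLayout", "layout_for", "locate_point", "quotient_anchor"]


@dataclass(frozen=True)
class DiagramLayout:
    """Static geometry for an ``n``-set diagram.

    Coordinates live in a fixed canvas (origin top-left, x right,
    y down, SVG user units).  ``curves`` maps each label to its closed
    polygonal outline; ``anchors`` maps each of the ``2**n - 1`` region
    codes to its count placement point; ``name_positions`` holds one
    caption point per label.
    """

    n: int
    canvas: tuple[float, float]
    curves: Mapping[str, tuple[tuple[float, float], ...]]
    anchors: Mapping[str, tuple[float, float]]
    name_positions: Mapping[str, tuple[float, float]]

    @property
    def labels(self) -> str:
        return "ABCDEF"[: self.n]

    def polygon(self, label: str) -> Polygon:
        return _polygon(self.n, label)


@lru_cache(maxsize=None)
def layout_for(n: int) -> DiagramLayout:
    """Load the shipped layout for an ``n``-set diagram (1 <= n <= 6)."""
    if not isinstance(n, int) or not 1 <= n <= MAX_SETS:
        raise CapacityError(f"layouts exist for 1..{MAX_SETS} sets, got {n!r}")
    raw = json.loads(
        resources.files("vennkit.data").joinpath(f"layout{n}.json").read_text()
    )
    return DiagramLayout(
        n=raw["n"],
        canvas=tuple(raw["canvas"]),
        curves={k: tuple(map(tuple, v)) for k, v in raw["curves"].items()},
        anchors={k: tuple(v) for k, v in raw["anchors"].items()},
        name_positions={k: tuple(v) for k, v in raw["name_positions"].items()},
    )


@lru_cache(maxsize=None)
def _polygon(n: int, label: str) -> Polygon:
    return Polygon(layout_for(n).curves[label])


@lru_cache(maxsize=None)
def _prepared(n: int, label: str):
    return prep(_polygon(n, label))


def locate_point(layout: DiagramLayout, point: Sequence[float]) -> str:
    """Classify a canvas point: region code, or ``"outside"``.

    A point belongs to the region whose signature is the set of curves
    strictly containing it (boundary points count as outside their
    curve).
    """
    pt = Point(point[0], point[1])
    code = "".join(
        lab for lab in layout.labels if _prepared(layout.n, lab).contains(pt)
    )
    return code or "outside"


def quotient_anchor(
    layout: DiagramLayout, grouping: UnionGrouping, signature: frozenset[str] | set[str]
) -> tuple[float, float]:
    """Anchor for a quotient region: its canonical representative.

    The representative of a quotient signature is the original region
    containing *all* member labels of every included group and no label
    of any excluded group; it always exists in the full layout, so the
    count of a united region lands at a stable, shape-preserving spot.
    """
    if grouping.labels != layout.labels:
        raise ValidationError(
            f"grouping over {grouping.labels!r} does not match {layout.n}-set layout"
        )
    sig = frozenset(signature)
    if not sig or not sig <= set(grouping.groups):
        unknown = sorted(sig - set(grouping.groups))
        raise ValidationError(
            f"invalid quotient signature: {unknown or 'empty'} not among groups {grouping.groups!r}"
        )
    code = "".join(sorted("".join(sig)))
    return layout.anchors[code]
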