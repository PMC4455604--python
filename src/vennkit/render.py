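"""SVG diagram rendering (PNG rasterization optional).

The SVG is the canonical output: one filled path per set curve, one
caption per set name, and one count text per region, placed at the
region's anchor.  Under a union grouping the curve path data is
byte-identical to the un-united diagram — only fill colors (united sets
share the color of the group's alphabetically first member) and count
placement change, so successive unions can be compared visually without
the shapes moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from .errors import CapabilityUnavailableError, ValidationError
from .layout import DiagramLayout, quotient_anchor
from .setcore import RegionTable
from .unions import QuotientRegionTable, UnionGrouping, quotient_table

__all__ = ["DiagramStyle", "render_svg", "rasterize_png", "PALETTE"]

#: Default fill palette, one color per label A..F.
PALETTE = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b")


@dataclass(frozen=True)
class DiagramStyle:
    """Visual knobs: font size (pt), fill opacity in [0,1], per-label colors."""

    font_size: float = 14.0
    fill_opacity: float = 0.5
    colors: tuple[str, ...] = PALETTE
    stroke: str = "#333333"

    def __post_init__(self) -> None:
        if not self.font_size > 0:
            raise ValidationError(f"font size must be positive, got {self.font_size}")
        if not 0.0 <= self.fill_opacity <= 1.0:
            raise ValidationError(
                f"fill opacity must be within [0, 1], got {self.fill_opacity}"
            )


def _fmt(v: float) -> str:
    return f"{v:g}"


def _path_d(points) -> str:
    head = f"M {_fmt(points[0][0])},{_fmt(points[0][1])}"
    body = " ".join(f"L {_fmt(x)},{_fmt(y)}" for x, y in points[1:])
    return f"{head} {body} Z"


def render_svg(
    table: RegionTable | QuotientRegionTable,
    layout: DiagramLayout,
    style: DiagramStyle | None = None,
) -> str:
    """Render a (possibly union-folded) region table to SVG text.

    Accepts a plain :class:`RegionTable` (treated as the identity
    grouping — the output is byte-identical either way) or a
    :class:`QuotientRegionTable`.
    """
    style = style or DiagramStyle()
    if isinstance(table, RegionTable):
        grouping = UnionGrouping.identity(table.family.labels)
        table = quotient_table(table, grouping)
    grouping = table.grouping
    if len(grouping.labels) != layout.n:
        raise ValidationError(
            f"table has {len(grouping.labels)} sets but layout is for {layout.n}"
        )

    w, h = layout.canvas
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
    ]
    for i, label in enumerate(layout.labels):
        group = grouping.group_of(label)
        color = style.colors[layout.labels.index(group[0])]
        lines.append(
            f'<path class="curve curve-{label}" d="{_path_d(layout.curves[label])}" '
            f'fill="{color}" fill-opacity="{_fmt(style.fill_opacity)}" '
            f'stroke="{style.stroke}" stroke-width="1"/>'
        )
    names = {s.label: s.name for s in table.family.sets}
    for label in layout.labels:
        x, y = layout.name_positions[label]
        text = _escape(names.get(label, label))
        lines.append(
            f'<text class="set-name" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'font-size="{_fmt(style.font_size)}" text-anchor="middle" '
            f'font-family="sans-serif">{text}</text>'
        )
    counts = table.counts()
    for sig, code in zip(table.signatures(), table.codes()):
        x, y = quotient_anchor(layout, grouping, sig)
        lines.append(
            f'<text class="count count-{code}" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'font-size="{_fmt(style.font_size)}" text-anchor="middle" '
            f'font-family="sans-serif">{counts[code]}</text>'
        )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def rasterize_png(svg_text: str, dpi: float = 96.0) -> bytes:
    """Rasterize SVG text to PNG bytes (optional capability).

    Requires the ``cairosvg`` backend; without it a
    :class:`CapabilityUnavailableError` is raised — the SVG output is
    canonical and always available.
    """
    if not dpi > 0:
        raise ValidationError(f"dpi must be positive, got {dpi}")
    try:
        etree.fromstring(svg_text.encode())
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed SVG: {exc}") from exc
    try:
        import cairosvg  # type: ignore[import-not-found]
    except ImportError as exc:
        raise CapabilityUnavailableError(
            "PNG rasterization needs the optional 'cairosvg' backend; "
            "install it or use the canonical SVG output"
        ) from exc
    return cairosvg.svg2png(bytestring=svg_text.encode(), dpi=dpi)
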