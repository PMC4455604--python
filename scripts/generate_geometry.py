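"""Regenerate the static diagram geometry shipped in src/vennkit/data/.

The package ships fixed, validated curve geometry per set count:

* n=1..3 — circles;
* n=4   — two mirrored pairs of tilted congruent ellipses;
* n=5   — five congruent ellipses under 5-fold rotational symmetry;
* n=6   — an Edwards-style construction: two half-plane rectangles, a
  circle, and three "cogwheel" star curves whose tooth counts double
  (8, 16, 32 teeth) so that every new curve bisects every existing
  region, exposing all 63 regions.

For every region signature the anchor (count placement point) is a
point strictly interior to the region, obtained from the region's
boolean geometry.  The script re-validates every anchor after
coordinate rounding and refuses to emit an unsound layout.

Run from the repository root:  python scripts/generate_geometry.py
"""

import json
import math
import pathlib

import numpy as np
from shapely.geometry import Point, Polygon

CANVAS = 700.0
C = CANVAS / 2
LABELS = "ABCDEF"
OUT = pathlib.Path(__file__).resolve().parent.parent / "src" / "vennkit" / "data"


def circle(cx, cy, r, k=128):
    t = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in t]


def ellipse(cx, cy, a, b, deg, k=128):
    th = math.radians(deg)
    cs, sn = math.cos(th), math.sin(th)
    pts = []
    for t in np.linspace(0, 2 * np.pi, k, endpoint=False):
        x, y = a * math.cos(t), b * math.sin(t)
        pts.append((cx + x * cs - y * sn, cy + x * sn + y * cs))
    return pts


def rectangle(x0, y0, x1, y1, per_edge=16):
    pts = []
    corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    for (ax, ay), (bx, by) in zip(corners, corners[1:] + corners[:1]):
        for i in range(per_edge):
            f = i / per_edge
            pts.append((ax + f * (bx - ax), ay + f * (by - ay)))
    return pts


def cogwheel(r0, amp, teeth_deg, k_per_seg=8):
    """Star polygon r(theta) = r0 + amp * s(theta), s alternating per tooth."""
    pts = []
    nseg = int(round(360 / teeth_deg))
    for seg in range(nseg):
        r = r0 + amp * (1 if seg % 2 == 0 else -1)
        for i in range(k_per_seg):
            th = math.radians(seg * teeth_deg + i * teeth_deg / k_per_seg)
            pts.append((C + r * math.cos(th), C + r * math.sin(th)))
    return pts


def curves_for(n):
    if n == 1:
        return [circle(C, C, 220)]
    if n == 2:
        return [circle(C - 90, C, 170), circle(C + 90, C, 170)]
    if n == 3:
        return [
            circle(C + 95 * math.cos(math.radians(ang)), C + 95 * math.sin(math.radians(ang)), 170)
            for ang in (270, 30, 150)
        ]
    if n == 4:
        a, b, ang = 210, 140, 40
        return [
            ellipse(C - 80, C + 25, a, b, -ang),
            ellipse(C - 20, C - 25, a, b, -ang),
            ellipse(C + 20, C - 25, a, b, ang),
            ellipse(C + 80, C + 25, a, b, ang),
        ]
    if n == 5:
        out = []
        for i in range(5):
            ang = 90 + i * 72
            th = math.radians(ang)
            out.append(ellipse(C + 70 * math.cos(th), C + 70 * math.sin(th), 210, 105, ang + 20))
        return out
    if n == 6:
        return [
            rectangle(5, 5, C, CANVAS - 5),       # left half-plane
            rectangle(5, 5, CANVAS - 5, C),       # top half-plane
            circle(C, C, 160, 256),
            cogwheel(160, 60, 45),
            cogwheel(160, 35, 22.5),
            cogwheel(160, 15, 11.25, 6),
        ]
    raise ValueError(n)


def signatures(n):
    codes = []
    for mask in range(1, 1 << n):
        codes.append("".join(LABELS[i] for i in range(n) if mask >> i & 1))
    return sorted(codes, key=lambda c: (len(c), c))


def region_polygon(polys, code, labels):
    region = None
    for i, lab in enumerate(labels):
        if lab in code:
            region = polys[i] if region is None else region.intersection(polys[i])
    for i, lab in enumerate(labels):
        if lab not in code:
            region = region.difference(polys[i])
    return region


def build_layout(n):
    raw = curves_for(n)
    labels = LABELS[:n]
    curves = {lab: [[round(x, 2), round(y, 2)] for x, y in pts] for lab, pts in zip(labels, raw)}
    polys = [Polygon(curves[lab]) for lab in labels]
    anchors = {}
    for code in signatures(n):
        region = region_polygon(polys, code, labels)
        assert region.area > 0.5, f"n={n}: region {code} is degenerate ({region.area:.3f})"
        p = (region if region.geom_type == "Polygon" else max(region.geoms, key=lambda g: g.area)).representative_point()
        anchors[code] = [round(p.x, 2), round(p.y, 2)]
    # captions near each set's exclusive region, nudged off the count text
    name_positions = {
        lab: [anchors[lab][0], round(anchors[lab][1] - 18, 2)] for lab in labels
    }
    # validate after rounding: every anchor strictly inside exactly its own curves
    for code, (x, y) in anchors.items():
        pt = Point(x, y)
        for i, lab in enumerate(labels):
            inside = polys[i].contains(pt)
            assert inside == (lab in code), f"n={n}: anchor {code} fails containment for {lab}"
    assert len(set(map(tuple, anchors.values()))) == len(anchors)
    return {
        "n": n,
        "canvas": [CANVAS, CANVAS],
        "curves": curves,
        "anchors": anchors,
        "name_positions": name_positions,
    }


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for n in range(1, 7):
        layout = build_layout(n)
        path = OUT / f"layout{n}.json"
        path.write_text(json.dumps(layout, separators=(",", ":")) + "\n")
        print(f"wrote {path} ({path.stat().st_size} bytes, {2**n - 1} anchors)")


if __name__ == "__main__":
    main()
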