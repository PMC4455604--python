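# Methods

## Region model

A family holds 1–6 named sets of element strings, labeled `A`..`F` in input
order. Elements are compared exactly and case-sensitively; the only
normalization applied on ingestion is per-line: surrounding whitespace is
stripped, empty lines dropped, and within-set duplicates removed keeping the
first occurrence (sets are sets; *cross*-set duplicates are the object of
study and are kept). No identifier mapping or fuzzy matching is attempted —
if two gene symbols differ by case they are different elements.

The region table assigns every element of the union to the unique signature
given by direct membership evaluation against all sets. All `2^n − 1`
signatures are always present as keys, empty regions included, because an
empty region is information (a method that shares nothing exclusively with
another is a finding). The implementation is a single pass over the sets
accumulating per-element label lists; `signature_of` retains the literal
per-element membership definition and serves as the brute-force oracle in
tests and in the acceptance sweep.

Empty sets are legal: a set with no elements still owns a label and a curve,
so partially filled inputs still render.

## Union semantics

A union grouping is a partition of the labels; its groups are kept as
canonical codes (member labels sorted, group list sorted). Three parsers
produce groupings:

* **Union codes** (`BC`, `AB,CD`): each comma token becomes a group after
  canonicalization (case-insensitive, order-free); unmentioned labels stay
  singletons. A label appearing in two groups is an error, not a merge —
  the union-list grammar's worked examples force this reading, and silent
  merging would hide typos.
* **Union lists** (`;CD;CB;AB,CD`): `;` separates steps, each step is an
  independent union code; an empty step is the identity grouping. Errors
  report the 0-based step index.
* **Union trees**: a topology-only Newick dialect — labels or exact set
  names at leaves (names win when a single-letter name collides with a
  label), strictly binary, optional whitespace and trailing semicolon.
  Branch lengths, comments and quoted labels are *rejected* with a position
  rather than ignored: accepting and discarding annotations could mask a
  malformed tree. Level `k` induces the grouping of the *maximal frontier*:
  one group per node at depth `k`, plus one singleton per leaf shallower
  than `k`. This rule handles unbalanced trees (a 6-leaf caterpillar has
  levels 0..4) and makes level `max` all singletons and level 0 the total
  union; each level refines the one above it, which is asserted as a
  property test.

Folding (the *quotient* table) maps original signature `S` to
`{g : g ∩ S ≠ ∅}` and unions region contents. The central correctness
property — folded table equals a from-scratch region table over literally
united element sets — is tested on seeded random families and groupings,
with the recomputation path written independently of the fold. Quotients
compose: an already-folded table may be folded again by any coarser
partition, and the result equals folding once by the composite.

Quotient region codes concatenate plainly when every touched group is a
singleton (so the identity grouping reproduces the original codes exactly)
and otherwise join group codes with `_` in alphabetical order (`B_CD`),
which keeps multi-letter codes unambiguous in filenames.

## Geometry

Geometry is static data, not computed per dataset: the set count alone
determines the shape, which is what makes union navigation visually stable.
Shipped layouts (JSON vertex/anchor tables under `vennkit/data/`,
regenerated by `scripts/generate_geometry.py`) use a 700×700 canvas, origin
top-left, y down:

* n=1–3: circles (radius 170–220, the 3-set layout on a 120°-symmetric
  triangle of centers);
* n=4: two mirrored pairs of congruent ellipses (semi-axes 210×140, ±40°);
* n=5: five congruent ellipses (210×105) under 5-fold rotational symmetry;
* n=6: an Edwards-style construction — left and top half-plane rectangles,
  a circle of radius 160, and three cogwheel star curves around the circle
  with 8, 16 and 32 teeth and radial amplitudes 60, 35 and 15. Each
  successive curve alternates inside/outside the circle at twice the
  angular frequency, so it bisects every existing region; all 63 regions
  are realized with a minimum region area of ≈340 canvas units².

Ellipse parameters for n=4/5 were chosen by a coarse grid search maximizing
the smallest region area (155 and 297 units² respectively), then frozen.
Every curve is a closed polygon with ≥64 vertices; coordinates are rounded
to 0.01 units. Each region's **anchor** is an interior point of the
region's boolean geometry (shapely `representative_point`), revalidated
after rounding: the generator refuses to emit a layout in which any anchor
fails the strict point-in-polygon test against its own signature.
Containment is strict — boundary points classify as outside a curve — and
`locate_point` evaluates it per curve with prepared shapely polygons.

A quotient region's count is placed at the anchor of its **canonical
representative**: the original region containing every member label of
every included group and none of the excluded groups' labels. That region
always exists in the full layout, giving a deterministic placement rule;
the other constituent sub-regions are left unlabeled.

## Rendering

SVG is assembled as deterministic text (no timestamps, fixed number
formatting), one filled path per curve in label order, one set-name caption
per label, one count text per (quotient) region. United sets take the fill
color of the group's alphabetically first member from a fixed six-color
palette; default opacity 0.5, default font 14 pt; opacity outside [0, 1]
and non-positive font sizes are rejected. Identical inputs produce
byte-identical SVG, and the path data is invariant under groupings of the
same family — only fills and count placements change. PNG export is an
optional capability behind a `cairosvg` backend probe; without the backend
it raises a capability error rather than degrading silently, since the SVG
is canonical.

## File formats

The sets file is a FASTA-like text format: a version line
(`#vennkit sets v1`), then one `>`-headed block per set with one element
per line. Only a line-initial `>` is structural; an element that itself
begins with `>` is written with one leading space, which read-side
normalization strips again, so write→read→write is byte-identical for any
constructible family (set names are whitespace-stripped on construction for
the same reason). Region exports write one sorted element list per
non-empty region plus a `manifest.tsv`; the counts table is a TSV with a
trailing `TOTAL` row equal to the union size. All writers go through an
atomic temp-file-and-rename path, so a failed run leaves no partial output.

## Synthetic data

`generate_family` builds a family *from* intended region counts, returning
the ground-truth table alongside — by construction the engine must
reproduce it exactly, making it the fixture generator for every module.
`generate_ranked_lists` emulates the comparison of top-*n* ranked outputs
from several selection methods: each of the `n_methods` lists has exactly
`n_top` entries, exactly `shared_core` of them common to all methods, and
the remainder assigned to uniformly drawn proper subsets of the methods.
Defaults (5 methods, top-50, core 38) reflect a typical biomarker-method
comparison. Elements are synthetic alphanumeric tokens, deliberately not
real gene symbols; both generators are pure functions of their integer
seed (NumPy PCG64).

What these fixtures do not emulate: real ranked lists have rank-dependent
overlap structure (agreement concentrates near the top), identifier noise,
and non-uniform subset sharing; passing tests therefore demonstrate the
correctness of the set algebra and plumbing, not any statistical property
of real method comparisons.

## Validation problem sizes

The test suite and acceptance script sweep 1000 seeded random families
(n = 1..6, ≤200 elements each, drawn from a shared pool so that overlaps of
every order occur) for the brute-force signature check, 50 random
family/grouping pairs for the quotient-vs-recompute check, 10 000 random
canvas points for the hit-testing oracle, and all 120 shipped anchors
across the six layouts. These sizes keep the full validation in the order
of seconds while covering every set count and grouping shape.

## Known limitations

* Layouts are fixed, not area-proportional: region area carries no
  information about cardinality (Euler-style proportional diagrams are a
  non-goal).
* The six-set limit is a hard ceiling — beyond six, Venn layouts stop
  being readable and the geometry table simply does not exist.
* The sets-file dialect is this package's own; saved files from other Venn
  tools are not importable.
* Newick inputs are topology-only; trees with branch lengths must be
  stripped upstream.
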