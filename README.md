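# vennkit

Scriptable Venn-diagram set analysis for up to six named sets.

Comparing lists of genes, proteins, gene families or any other string-keyed
entities is a routine step in omics workflows: which candidates did every
method retrieve, which are exclusive to one method, what do two related
species share that a third lacks. `vennkit` computes the complete
disjoint-region decomposition behind such comparisons, lets you *unite* sets
in place — guided by a union code, a union-list program, or a binary tree
(e.g. a phylogeny over species whose gene sets you compare) — without the
diagram shape changing, and exports region element lists, count tables and
SVG diagrams.

## The model

For sets S_A, …, S_F labeled `A`..`F`, every element of U = S_A ∪ … has a
**membership signature**: the subset of labels whose sets contain it. The
2ⁿ − 1 signatures partition U into the disjoint **regions** of the Venn
diagram; the region coded `AB` in a three-set family is
(S_A ∩ S_B) ∖ S_C — the *exclusive* intersection, not the full one.

A **union grouping** is a partition G of the labels. Folding the region
table under G maps each signature S to the set of groups it touches,
{g ∈ G : g ∩ S ≠ ∅}, and unions the corresponding
regions — provably the same table you would get by literally uniting each
group's element sets and recomputing. Groupings come from:

* **union codes** — `BC` unites B and C; `AB,CD` makes two groups;
* **union lists** — `;CD;CB;AB,CD` is a sequence of diagram states,
  starting from the all-singletons identity (the leading empty step);
* **union trees** — a strictly binary Newick-style topology such as
  `(A,(B,(C,D)))`; cutting it at depth k gives one group per node at
  that depth (plus shallower leaves as singletons), so navigating from the
  deepest level to level 0 walks from all-singletons to the total union.

Diagram geometry is fixed per set count (circles up to three sets, tilted
ellipses for 4–5, an Edwards-style construction with all 63 regions for 6),
so successive unions are visually comparable: only colors and counts change.

## Worked example

Emulate comparing the top-50 ranked candidate lists of five selection
methods that share a 38-item core, then unite methods B and C:

```sh
vennkit fixtures ranked --methods 5 --top 50 --shared-core 38 --seed 1 -o methods.sets
vennkit load methods.sets
```

```
A       method-1        50
B       method-2        50
C       method-3        50
D       method-4        50
E       method-5        50
TOTAL           63
```

Each list has 50 entries; together they cover 63 distinct elements (the
38-item core plus method-specific and partially-shared tails). Now fold:

```sh
vennkit union methods.sets --code BC -o union_bc
grep -E '^(BC|TOTAL)\b' union_bc/counts.tsv
```

```
BC      2
TOTAL   63
```

`BC` here is the *exclusive* region of the united pair: 2 elements were
retrieved by B or C and by no other method. The total is conserved — folding
never creates or loses elements. `union_bc/regions/` holds one sorted
element list per non-empty region (`A.txt`, `BC.txt`, `A_BC.txt`, ...), and

```sh
vennkit render methods.sets --svg diagram.svg
```

writes the five-ellipse diagram with one count per region. Tree-guided
navigation works the same way:

```sh
vennkit tree methods.sets --newick "(A,((B,C),(D,E)))" --all-levels -o levels
```

emits one counts/elements bundle per tree level, from every-set-distinct
down to the single total union.

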