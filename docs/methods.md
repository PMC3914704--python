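# Methods

This note records the conventions, models and numerical choices behind
`karyoclust`, and what its tests do and do not establish.

## The data model

A composite karyotype `[cpN]` summarizes N metaphases of one cell line. Each
comma-separated token is parsed into an `AberrationEvent`:

- **numerical** events (`+7`, `-18x4[3]`): a gain or loss of one chromosome,
  with a multiplicity (`xN` = that many copies gained/lost in the same cell)
  and a cell count (`[N]` metaphases carry exactly this state);
- **structural** events (`der`, `del`, `dup`, `add`, `dic`, `ins`, `i`, `t`):
  an ordered chain of constituent operations, each with a chromosome list and
  an optional, positionally aligned band list. `?` marks an unknown
  breakpoint and is preserved; no band ontology is imposed, bands are opaque
  strings. Segment order/orientation inside compound derivatives is not
  modeled — the notation does not encode it.

The modal header (`76~88<4n>`) supplies the chromosome-count range and the
ploidy baseline p ∈ {2,3,4}; 23·p is the reference count used by nullisomy
logic. Leading ploidy-relative sex tokens (`X`, `XXX`) are recorded but do
not generate copy-number calls: only explicit `+`/`-` events count as
aberrations, matching how per-line tallies are conventionally computed.

### Lenient parsing

Printed karyotype tables are noisy. Lenient mode (the default) loads the
bundled fixture verbatim by applying, and reporting, five repairs: commas for
semicolons inside parentheses (`t(8,12)`), `(5)` where `[5]` was meant,
missing separators between tokens (`-1[22]-1x2[2]`), stray whitespace, and a
bare multiplier with a missing `x`. Strict mode rejects all of these; the
serializer always emits canonical text, so lenient-parse → serialize →
strict-parse is the normalization path (a tested round trip for every fixture
token plus fuzzed random events).

The MCF7 string prints `der(7)t(7;7)(p15;?)[19]` and `...[2]` as two entries;
they are kept as printed (plausibly one x1/x2 pair, but that is a guess) and
merged only at identity level.

## Identities and the two granularities

Within a line the analysis unit is the **entry** — the multiplicity-resolved
token. `-18` and `-18x2` are different per-metaphase states, and their cell
counts are mutually exclusive: the MCF7 `-18` variants sum exactly to the
composite count (4+14+5+3 = 26), which is what motivates the exclusivity rule.

Across lines the unit is the **identity** — multiplicity collapsed:
numerical events to *(direction, chromosome)*, structural events to their
canonical text. This convention reproduces the published distinct-numerical
totals for MCF7 (31), BT474 (35) and SKBR3 (29). Two published numbers do
*not* reproduce and are left discrepant rather than patched:

- T47D is quoted as 27 numerical; the karyotype string contains 17 distinct
  chromosome losses and 8 gains = 25, under every collapsing convention we
  tried. The computed 25 is pinned in tests; 27 is not asserted.
- MCF7 is quoted as 27 structural; 28 distinct structural entries are
  printed (the `dup(7)` pair and the duplicated `der(7)t(7;7)` are candidate
  merges). Not targeted.

Structural identity matching across lines is exact on the canonical string.
This is deliberately conservative: `der(14;14)(q10;q10)` and
`der(14;14)(q11.2;q11.2)` stay distinct even though a reader might regard
them as the same whole-arm rearrangement.

## Frequencies, nullisomy, shared aberrations

The frequency of an identity in a line is the summed cell count of its
variants divided by the composite count; sums above the composite count are
capped (warning in lenient mode, error in strict). An identity at frequency
1 is *clonal*.

Nullisomy: a loss with multiplicity equal to the ploidy baseline (e.g.
`-20x4` under `<4n>`) is a cell with no copy at all; its frequency is the
summed cell count of such events over the composite count. Percentages are
reported to one decimal with round-half-even; 8/26 is therefore 30.8%, where
the published figure truncates to 30.7% — agreement is within the 0.1-point
reporting granularity.

The shared-aberration report lists identities at frequency ≥ t in *every*
selected line (default t = 0.5). On the fixture this yields `-4, -15, -18,
-X`, plus `der(12)t(5;12)(q23;q23)` for the two HER2+ lines. The published
shared list also names `-2`, but BT474 prints `-2[7]` = 30.4% of metaphases,
which no per-line threshold can admit without also admitting `-9` (per-line
minimum 34.6%); the corresponding acceptance test is left failing with this
explanation rather than weakened.

## The chromosome profile rule

Which chromosomes count as "structurally affected" is not well defined by the
notation when breakpoints are unknown. The default rule weighs evidence over
the distinct structural identities: a chromosome is affected if it appears in
some operation with an at least partially localized breakpoint (any band
other than a bare `?`), **or** if it appears in two or more operations; a
single appearance with a wholly unknown breakpoint is unconfirmed. This rule
reproduces the published structurally-unaffected sets of all three lines for
which they are quoted: MCF7 {4,5,13,14,18}, T47D {2,4,18,19,21,22}, SKBR3
{3,9,10,16} (SKBR3 chromosome 3 appears once, as `?`, inside a five-way
derivative). Two simpler rules are kept selectable: `any` (every listed
chromosome counts — differs from the quoted sets only by that SKBR3
chromosome 3) and `derived` (first-listed chromosome only).

## Composite expansion

Figures built from per-metaphase presence/absence cannot be reproduced
cell-for-cell from a composite: the notation records *how many* metaphases
carry each entry, not *which*. `expand_composite` therefore draws a binary
matrix uniformly at random subject to the recorded counts — each entry in
exactly its cell count of rows, multiplicity variants of one identity on
disjoint rows, different identities independent — reproducibly from a seed,
and all outputs derived from it are labeled "reconstruction". Independence
is a modeled simplification, not an inference: the composite carries no
co-occurrence information, and none is invented. Re-aggregating any
expansion reproduces the input frequencies exactly (tested across seeds).

## Clustering

Distances are Euclidean (binary presence vectors within a line; frequency
vectors across lines). Ward linkage is implemented via the Lance–Williams
recurrence:

d²(i∪j,k) = [(nᵢ+nₖ)d²(i,k) + (nⱼ+nₖ)d²(j,k) − nₖd²(i,j)] / (nᵢ+nⱼ+nₖ)

- `variant="ward"` (default): the recurrence runs on squared distances and
  heights are reported on the distance scale (minimum-variance Ward; equals
  scipy's `ward` and R `hclust` `ward.D2`).
- `variant="ward.D"`: the recurrence runs on the input distances as given
  (the legacy behavior of old R `hclust(method="ward")`), kept because
  historical analyses often used it without saying so. The fixture's
  cross-line conclusions hold under both variants (tested).

Ties are broken by the lexicographically smallest pair of member labels, so
runs are fully deterministic; heights are clamped to be non-decreasing
against ulp-level noise. Correctness is established by three routes: a naive
O(n³) oracle that recomputes every candidate merge's variance increase from
coordinates, scipy's ward, and R's `hclust` (both variants).

Trees are cut into k flat clusters by undoing the k−1 highest merges (ids
assigned in leaf order, so refinements nest); cophenetic matrices are
ultrametric by construction; Newick export places each internal node at half
its merge height, so path lengths reproduce cophenetic distances (round trip
verified via dendropy). The aberration dendrogram's default cut is k = 5,
the number of interpretable groups on the bundled panel (one pan-line
numerical cluster plus four line-specific ones); it is a CLI parameter, not
a model constant. Partition agreement uses the permutation-model adjusted
Rand index (scikit-learn's implementation, verified against exhaustive pair
counting).

## Synthetic lines

`CellLineSpec` describes a simulated line: n metaphases; ploidy baseline; a
clonal core present in every cell; subclones as (name, private events,
fraction) triples — membership one binomial draw per subclone, or a single
categorical draw per metaphase when marked disjoint; Poisson(noise_rate)
sporadic events per metaphase drawn without replacement from a catalog of
simple valid events not colliding with the planted ones; optional per-identity
multiplicity distributions. One seeded generator drives everything; the CLI
logs the seed.

Defaults follow the study conditions the package models: ~20–26 metaphases
per line, a clonal core plus sporadic noise and *no* discrete subclones (the
characterized lines showed homogeneous metaphases, not clones), noise well
under one event per metaphase. The planted-recovery benchmark uses 40
metaphases, two disjoint subclones at fractions 0.6/0.4 with five private
events each and noise rate 0.2, scored over 100 seeds; Ward at k = 2 recovers
the partition at ARI ≥ 0.9 in ≥ 95% of them.

What the generator does **not** emulate — so what passing tests do not show
about real data: breakpoint realism (noise bands come from a generic list
and may name bands a chromosome lacks), co-segregation of aberrations,
polyploid doubling, culture-passage drift, and observation error in
G-banding/M-FISH calls themselves. Recovery results bound what clustering
can do under the stated independence assumptions, not under real cytogenetic
noise.

## Numerical choices and degenerate inputs

- Percentages: one decimal, round-half-even; comparisons against published
  values use ±0.1 points (published rounding is inconsistent).
- Writers: floats at 4 decimals, JSON keys sorted; reruns with equal config
  and seed are byte-identical.
- Degenerate inputs rejected with named errors: cell count above composite
  count, variant sums above composite count (named identity), empty
  metaphase lists, mixed ploidy baselines, specs with nothing to generate,
  fewer than two items to cluster, k outside 1..n.
- Single-metaphase records serialize without `[N]`/`[cpN]`; a zero-event
  record serializes to its header and sex tokens (`46,XX`).

## Problem sizes

All analyses of the bundled panel run in seconds on one CPU (≤ 26 metaphases,
≤ 156 identities, 4 lines). Test-suite simulations use 40 metaphases × 100
seeds for recovery and n ≤ 8 × dozens of instances for oracle equivalence —
sizes at which the naive O(n³) oracle is exact and fast.

## Known limitations

- The ISCN subset covers what occurs in composite tumor karyotypes of this
  kind; stemline notation (`idem`/`sl`/`sdl`), `fis`, `hsr`, `dmin`, `mar`
  and mosaicism slashes are out of scope.
- Within-line heatmap/dendrogram reconstructions are frequency-faithful but
  not cell-faithful (see Composite expansion above).
- Exact structural matching can under-merge across lines when the same
  rearrangement is written at different band resolution.
- Breakpoints are cytogenetic bands only; no genomic coordinates, no
  gene-level consequences.
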