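# Methods

## Variant model

A variant representation is a finite collection of atomic operations on a
reference string `R` over a finite alphabet (inferred from the input,
uppercased; symbols are compared literally, with no IUPAC ambiguity
semantics): deletions of single symbols at 1-based positions and
insertions of single symbols anchored after a position, anchor 0 denoting
the start.  All operations are indexed on *original* reference
coordinates, so deletions commute and only the relative order of
insertions sharing an anchor is significant.  `patch` emits non-deleted
reference symbols in order, with each anchor's insertions immediately
after it; it validates ranges, duplicate deletions and optional deletion
symbol annotations (the `T` in `7delT`), which are otherwise ignored and
excluded from operation identity.

Higher-order descriptions are expansion conventions, not primitives: an
SNV `NX>Y` becomes `[NdelX; N_N+1insY]`, and `N_MdelinsSEQ` becomes
deletions `N..M` with every inserted symbol anchored at `M`.  The anchor
choice is immaterial for all downstream results because relations are
functions of the patched observed sequence only — a non-minimal input is
re-minimized by the alignment step.  The textual formatter collapses a
maximal run of consecutive deletions together with the insertions anchored
at its end into del/delins/SNV shorthand and emits remaining insertions as
`p_p+1insSEQ`; since no canonical multi-operation form is standardized,
this collapsing is our convention and is validated only up to
patch-equivalence on round trips.

## Distance and the LCS-graph

The simple edit distance (indels only, unit weight) is computed by A\*
over the implicit DP matrix with the admissible, consistent heuristic
`h(i,j) = |(|R|−i) − (|O|−j)|`.  Expansion proceeds in waves of constant
`f = D + h`: the first wave runs at `f = ||R|−|O||` and successive waves
step by 2 (orthogonal steps change `D` by +1 and `h` by ±1; diagonal match
steps are free), so the distance is the f-value of the wave reaching the
bottom-right cell.

Rows are indexed by the reference, columns by the observed sequence.  Per
anti-diagonal `k = i − j` only the furthest covered row is stored: along a
diagonal `D` is non-decreasing (in steps of 2, with parity `k mod 2`), so
the covered cells always form a prefix, and a cell first covered at wave
`f` on diagonal `k` has `D = f − |Δ − k|` exactly, with `Δ = |R|−|O|`.
Each wave processes diagonals from both ends towards `Δ` so that same-wave
propagation (deletions feeding `k−1 → k` below `Δ`, insertions `k+1 → k`
above) sees updated neighbours, while the opposite neighbour is correctly
one wave old; match runs ("snakes") are followed greedily at no cost.  The
frontier is mirrored into the two linear `rows`/`cols` arrays (right-most
expanded column per row, bottom-most expanded row per column), recorded
per wave for inspection.  Temporary space is O(|R|+|O|) beyond the stored
match list; no quadratic table is ever allocated, which is what makes
20 kb-scale references with few differences effectively linear.

Match cells become LCS-graph nodes at level `⌊(i+j−D(i,j))/2⌋`, between a
virtual source `(0,0)` at level 0 and sink `(|R|+1,|O|+1)` above the top
level, so leading/trailing gaps are ordinary edges.  Edges connect
consecutive levels whenever both coordinates strictly increase, labelled
with the skipped reference run (deletions) and skipped observed run
(insertions).  Because every source→sink path holds exactly one match per
level, each path carries exactly `|R|+|O|−2·|LCS|` operations — i.e. every
path is minimal by construction — and a forward-plus-backward reachability
sweep removes the matches on no optimal path (we sweep after building
rather than constructing backwards from the sink; the output is the same).

Enumeration of Φ(R,O) walks all paths and, per gap with `m` deletions and
`n` insertions, emits all `C(m+n, n)` monotone interleavings (an inserted
symbol may be anchored after any prefix of the gap's deletions, anchors
non-decreasing).  The count is computed with `math.comb` before
materialization so the default cap of 10 000 representations aborts
cleanly.  The element set Ψ(R,O) is read directly off the edges — gap
deletions `a..b` contribute those positions, and each inserted symbol
contributes one element per anchor in `[a−1, b]` — without enumeration;
repeated insertions of one symbol at one anchor collapse, which is safe
because only emptiness of Ψ-intersections is consumed.  The per-gap
anchor-range rule is validated against the enumeration oracle
exhaustively rather than assumed.  Edge-overlap element reduction and
bit-string set encodings are deliberately not implemented
(correctness-first; both are pure optimizations).

## Relations

`compare` resolves both inputs to observed sequences, then applies, in
order: string equality (equivalent); the distance characterizations
`dO − dP = dOP` (contains), `dP − dO = dOP` (is contained),
`dO + dP = dOP` (disjoint); and finally Ψ-intersection to separate
disjoint from overlap.  `d(O,P)` is computed directly between the observed
sequences, not inferred from alignments against `R`.  Empty variants
(observed equals reference) are rejected rather than given a silent
convention — the relations are undefined for them and a default would
corrupt database semantics.

The definition-based oracle treats a representation as a deletion-position
set plus per-anchor inserted strings.  Sub-representation means deletion
sets by inclusion and each anchor's inserted string by *subsequence*
inclusion: insertion order at a shared anchor is part of the
representation, and plain multiset inclusion would declare containment in
cases (e.g. `R=A`, `O=AAC`, `P=ACAA`) where removing operations cannot
actually produce the smaller variant.  Under these semantics the distance
tests and the definitions agree on every `{A,C}` triple with `|R| ≤ 4`,
`|O|,|P| ≤ 5` (115 320 triples, checked in the acceptance suite).

## Influence intervals and the prefilter

The maximal influence interval is the hull of per-operation spans over all
surviving graph edges: a deletion at `i` spans `[i, i+1)`, an insertion
anchored at `p` the degenerate `[p, p)`.  Intersection is strict half-open
for two non-degenerate intervals, inclusive at both boundaries when a
degenerate point meets an interval, and equality for two points — the
asymmetry exists because an insertion changes a flanking *gap* rather than
a position.

One configuration needs extra care: a non-degenerate hull whose endpoint
*is* an insertion anchor (possible only for variants with several
insertion anchors and no deletion beyond them, a case with no printed
example).  Two such hulls can merely touch yet share an insertion element,
so computed intervals carry endpoint provenance flags
(`start_is_anchor`/`end_is_anchor`, excluded from equality) and touching
hulls count as intersecting exactly when both touching endpoints are
anchors.  This keeps the prefilter conservative — a rejected pair is
guaranteed disjoint — which the suite verifies on 500 seeded repeat-rich
cases; false positives are allowed and resolved by the full comparison.
The batch driver computes each variant's interval once, emits rejected
pairs as disjoint without alignment work, caches Ψ per variant, and is
bitwise-identical with the prefilter disabled.

## Supremal representations

For influence interval `[s, e)` the supremal variant deletes reference
positions `max(s,1)..e−1` and inserts the observed span between the
matched prefix (length `s−1`) and matched suffix (length `|R|−e+1`);
a degenerate interval yields the pure combined insertion at its anchor.
Two boundary choices are ours, as the source material does not discuss
variants touching the sequence ends or anchor-valued endpoints: when
`s = 0` the deletion start is clamped to 1 with the inserted string
extended, and when the hull end is an insertion anchor the deletion span
extends one further position so the matched suffix is genuinely intact.
Patch-equivalence (`patch(R, supremal(R,v)) = patch(R,v)`) is the binding
invariant and is property-tested; the deletion span equals the influence
interval except for that trailing-anchor extension.  We deliberately do
not use SPDI-style rolling extension, which does not in general cover all
minimal alignments; our construction comes from the LCS-graph directly.

## Random-case generator

`random_case(seed, ...)` drives the property suites.  References are
repeat-rich by construction — ~40 % homopolymer runs (2–6 symbols), ~30 %
short tandem repeats (unit 2–3, 2–4 copies), the rest random — because
repeats are what inflate the number of co-optimal alignments and hence
stress every code path; defaults (length ~20–60, 2–3 edit events per
variant, ACGT) keep cases within oracle range while exercising multi-gap
graphs.  Output is fully determined by the seed.  The generator emulates
small, dense, locally clustered variation; it does not emulate structural
variants, long reads, base-quality noise or inter-reference mapping, so
passing tests say nothing about those regimes.

## Problem sizes and numerical choices

The suites run the oracle comparison exhaustively at the sizes above,
500 random pairs up to length 12 for Φ/Ψ agreement, and a 20 000-symbol
near-identical pair as the scaling check; these sizes were chosen to keep
the full suite in tens of seconds while the exhaustive spaces are already
complete for their alphabets.  All arithmetic is integer; there are no
tolerances.  Ties (choice among co-optimal alignments) are never broken —
keeping all of them is the point.  Degenerate inputs are handled
explicitly: empty strings are valid sequences for distance/graph purposes
(`d("", S) = |S|`), empty variants are rejected where relations or
intervals are requested, and brute-force oracles guard their input sizes
(strings ≤ 64, ≤ 100 000 paths) with clean errors.

## Known limitations

The makeup or maximal size of an overlap is not computed (that requires
enumerating exponentially many alignments); relations across different
reference sequences, unions/subtractions of variants, and variant
remapping are out of scope; inversions compare as plain delins, which may
not reflect their biological nature; the HGVS subset is genomic-coordinate
only.
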