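# varrel — Boolean relations between genetic variants

`varrel` classifies every pair of genetic variants described against a
shared reference sequence as exactly one of five Boolean relations:

| relation | meaning |
|---|---|
| `equivalent` | both variants yield the same observed sequence |
| `contains` | every change of the second variant occurs within the first |
| `is_contained` | the converse of `contains` |
| `overlap` | the variants share at least one change, neither contains the other |
| `disjoint` | no minimal alignment of one shares anything with the other |

The point of the package is that these questions **cannot** be answered
from any single normalized representation.  A variant like `3C>T` on
`CACAT` admits several co-optimal alignments, and an insertion such as
`2_3insT` is contained in it even though their normalized positions do not
touch.  `varrel` therefore reasons over *all* minimal alignments
simultaneously.

## Who this is for

Maintainers of locus-specific variant databases, VCF annotation pipelines,
and anyone matching observed alleles against recorded variants (suballele
identification, star-allele calling, strain typing) who needs containment
and overlap queries, not just equivalence.

## The model

A variant is a set of atomic operations — single-symbol deletions at
1-based reference positions and single-symbol insertions anchored after a
position (anchor 0 = before the first symbol) — applied deterministically
by a `patch` procedure, cf. Unix `diff`/`patch`.  Alignment quality is the
*simple edit distance* `d(R, O)`: the Levenshtein distance without
substitutions, with unit-cost deletions and insertions,

```
D(i, j) = D(i-1, j-1)                      if R_i = O_j,
          min(D(i-1, j), D(i, j-1)) + 1    otherwise,
```

which relates to the longest common subsequence by
`D(i, j) = i + j − 2·|LCS(R_1..i, O_1..j)|`.  Let Φ(R, O) be the set of all
*minimal* representations (monotone paths through the matrix) and Ψ(R, O)
the set of atomic operations occurring in any of them; Φ can be exponential
in size, Ψ is at most quadratic.

The relation of a pair is decided in stages:

1. `O = P` — equivalent;
2. `d(R,O) − d(R,P) = d(O,P)` — contains (a minimal path from R to O
   passes through P); the mirror-image test gives is-contained;
3. `d(R,O) + d(R,P) = d(O,P)` — disjoint;
4. otherwise, Ψ(R,O) ∩ Ψ(R,P) decides disjoint vs. overlap.  (Distances
   alone cannot: `R=CT`, `O=TG`, `P=GC` are pairwise at distance 2 yet
   disjoint.)

Ψ is read off an **LCS-graph** — a DAG of single-symbol matches whose
source→sink paths spell exactly the minimal alignments — built by a
wave-based A\* expansion of the DP matrix with the admissible heuristic
`h(i,j) = |(|R|−i) − (|O|−j)|`.  Waves run at constant
`f = D(i,j) + h(i,j)`, starting at `||R|−|O||` and stepping by 2, with the
frontier stored in two linear arrays; temporary space is O(|R|+|O|) and
expected run time is linear for similar sequences.

Two supporting constructions make batch work practical:

* **maximal influence interval** — the hull of reference positions a
  variant can touch in any minimal alignment (half-open; a pure insertion
  gets the degenerate `[p,p)`).  Pairs whose intervals do not intersect are
  disjoint without any alignment work.
* **supremal representation** — a single deletion-insertion spanning the
  whole influence interval (the insertion may repeat reference symbols,
  e.g. `2_3delinsAT` for `3C>T` on `CACAT`); a convenient database key
  that captures every minimal alignment at once.

## Worked example

The reference is `TCCCTTTA`; four variants from a text list (ids default
to line numbers):

```sh
$ cat vars.txt
3C>A
6T>G
[4del;5_6insC]
2_3insT

$ varrel all-pairs --reference ref.fa vars.txt --out pairs.tsv
equivalent      0
contains        0
is_contained    0
overlap 2
disjoint        4

$ cat pairs.tsv
lhs_id  rhs_id  relation  lhs_interval_start  lhs_interval_end  rhs_interval_start  rhs_interval_end
1       2       disjoint  2  5  5  8
1       3       overlap   2  5  2  8
1       4       disjoint  2  5  2  2
2       3       overlap   5  8  2  8
2       4       disjoint  5  8  2  2
3       4       disjoint  2  8  2  2
```

`3C>A` (interval `[2,5)`) and `6T>G` (`[5,8)`) are disjoint straight from
the prefilter; `[4del;5_6insC]` spreads across `[2,8)` and genuinely
overlaps both substitutions; the insertion `2_3insT` touches `[2,2)` inside
the other intervals but the full comparison still proves it disjoint.
Other commands:

```sh
$ varrel distance CATATATCG CTTATAGCAT
7
$ varrel compare --reference ref.fa "3C>A" "[4del;5_6insC]"
overlap
$ varrel supremal --reference cacat.fa "3C>T"    # reference CACAT
2_3delinsAT
$ varrel influence --reference ref.fa "3C>A"
[2,5)
$ varrel graph --reference ref.fa "3C>A" --dot graph.dot
```

The same surface is available as a library:

```python
>>> from varrel import compare, parse_variant
>>> compare("CACAT", parse_variant("3C>T", 5), parse_variant("2_3insT", 5))
<Relation.CONTAINS: 'contains'>
```

## Supported variant syntax

A genomic (g.) HGVS subset: `NdelS?`, `N_MdelS?`, `N_MinsSEQ`,
`N_MdelinsSEQ`, `NdelinsSEQ`, SNVs `NX>Y`, and bracketed alleles
`[op1;op2;...]`.  Anything else (dup, inv, repeats, uncertain positions,
c./p. coordinates) raises an explicit unsupported-variant error.  A minimal
experimental VCF adapter (`read_vcf_variants`) maps POS/REF/ALT records to
delins representations.

## Deliberate limitations

Overlap is detected but its makeup is not quantified; variants on
different reference sequences are not compared; no variant ordering is
defined beyond sorting supremal deletion intervals; inversions are treated
as plain delins.  See `docs/methods.md` for the full methods note.
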