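# Methods

This note documents the models and procedures implemented in `selexmotif`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Gapped patterns and the Huddinge distance

A pattern is a string over `{A,C,G,T,n}` whose ends are defined bases; `n`
marks internal unconstrained positions.  The canonical pattern space used in
counting has a single contiguous gap run (configurable bounds; defaults
4–10 defined bases, gap 0–10).  Multi-run patterns are representable but are
outside the default counting space.

The distance between patterns `p, q` is `d − a` with
`d = max(defined(p), defined(q))` and `a` the maximum, over all rigid
relative offsets, of the number of positions at which both patterns have
equal defined bases.  No offset is excluded: "no new gaps" means the
patterns are held rigid, not that gap columns must coincide.  With strand
merging (the default — SELEX ligands are double stranded) the distance is
the minimum over `q` and its reverse complement, which keeps the metric
consistent with strand-merged counting; the strand-canonical representative
of a pattern is the lexicographically smaller of pattern and reverse
complement under the symbol order `A < C < G < T < n`.

Key consequences, all verified against an independently coded brute-force
oracle in the test suite:

- substitutions, one-base truncations/extensions, and one-position shifts of
  *ungapped* patterns are at distance 1;
- a one-position shift of a *gapped* pattern is at distance exactly 2,
  because the shift both desynchronizes the gap (losing the base the gap
  slides onto) and exposes a new unmatched base.

Neighbor enumeration (`huddinge_neighbors`) generates candidates by the
complete edit family — delete one defined base; add one defined base at the
ends, beyond the ends, or in the gap; delete-one-plus-add-one — and then
verifies each candidate against the distance function, so the returned set
is exactly the distance-1 sphere restricted to the configured bounds.
Completeness is property-tested against exhaustive enumeration.

## Pattern counting

Counting enumerates, for every read window and every in-bounds gap shape,
the induced pattern, encoded as a base-5 integer (digits A,C,G,T,n).  In
`per_read` mode (default) a read contributes at most once per canonical
pattern, which damps PCR jackpots; `per_occurrence` mode counts every
window and is containment-monotone (used as an internal consistency oracle).
Strand merging accumulates forward and reverse-complement occurrences to the
canonical pattern; deduplication pools all gap shapes of equal span because
forward and reverse hits of one canonical pattern arrive via mirrored
shapes.  The implementation is vectorized (one BLAS code computation per
window span; codes stay below 2^53 so float64 matmuls are exact) and counts
a 50k-read cycle at default desk-scale bounds in a few seconds.

## Autoseed

A pattern `P` with count `c(P)` is a local maximum iff

1. `c(P) > c(Q)` for every equal-length Huddinge-1 neighbor `Q` (ties break
   dominance — "higher than any neighbor" is strict);
2. `c(P) > θ·c(S)` for every Huddinge-1 neighbor `S` with one defined base
   fewer;
3. no Huddinge-1 neighbor `L` with one defined base more has
   `c(L) > θ·c(P)`;
4. `c(P) ≥ min_count`.

θ compensates for shorter patterns being unavoidably at least as frequent as
any extension.  Under a null of no enrichment the expected long/short count
ratio is ≈ 1/4 per added defined base; under perfect enrichment it
approaches 1.  The default θ = 0.5 is the log-scale midpoint between those
regimes and is configurable; `min_count` defaults to 10 to suppress
sampling noise at desk-scale depths.  The scan visits patterns in
descending count order with a cheap direct-construction pre-check of rule 3,
then the exact neighbor predicate; output is deterministic (count
descending, lexicographic ties).

The rank-1 maximum is the primary model.  Secondary maxima are classified
against it with precedence spacing_orientation > flank > dinucleotide:
same half-site multiset (up to strand) around the gap → spacing/orientation
variant; all of the shorter pattern's defined bases covered inside the
longer at some offset → flank variant; equal defined-base counts with the
best alignment differing at exactly two adjacent positions → dinucleotide
variant; anything else → unrelated.  Expert manual refinement of seeds is
replaced by an explicit seed override (`--seed`).

## Multinomial PWM with background correction

Window selection: each read's best window maximizes matching defined bases
over positions and strands, ties to the leftmost position then the forward
strand (deterministic).  "Multinomial order n" is formalized as: column `i`
counts windows that mismatch the seed's defined bases at positions *other*
than `i` in at most `n − 1` places (order 1 = exact elsewhere).  Flank
positions add unconstrained columns; windows protruding past the read edge
skip those cells, which reproduces the known edge artifact of flanks only at
high flank widths.

Background correction (`cycle0`, the default) computes the same matrix on
unselected cycle-0 reads, scales it column-wise to the observed totals, and
forms `(obs + 1) / (expected + 1)` before renormalizing columns; the +1 on
both sides guarantees an identical observed/background pair yields exactly
uniform columns and no division by zero.  A subtractive variant
(`subtract=True`, floored at 0) and `uniform` / `none` modes are provided.
Division was chosen as the default because a ratio-to-expectation is the
least-assuming reading of "background corrected" and is exact in the
self-correction limit.

Site-structure classification slides the PWM's highest-information window
(default length 5) along the PWM on both strands, collects placements with
mean per-column Pearson correlation ≥ 0.85, keeps non-overlapping ones
greedily best-first, and maps 1/2/3/≥4 copies to monomer / dimer / trimer /
dimer-of-dimers.  This is a deliberate heuristic: it reproduces clean
constructed repeats and is not intended as a substitute for curation of
borderline cases.

## Dependency score

For site windows selected as above (with a mismatch allowance, default 1),
every position pair's joint 4×4 distribution is compared with the product of
its marginals.  The mispredicted fraction is formalized as total variation
distance `½·Σ|joint − marg⊗marg|`, and the score is `200 ×` that fraction:
0 for exact independence, 100 for the equal two-dinucleotide case (AA/TT
half-and-half), the stated maximal anchor.  The score is invariant under
base relabeling and pair transposition and shrinks monotonically under
mixing toward independence.  It is *not* clipped by default: a joint
supported on a 4-state diagonal reaches 150, and whether such cases should
clip, renormalize, or stand is genuinely open — a `clip` flag caps at 100
for presentation.  Finite samples never score exactly 0; with `n` sites the
independence noise floor scales as `O(√(1/n))` (~6% at n = 4000), so small
scores should be read against the site count stored in the table.

## Similarity, clustering, networks, k-mer tables

Gapped 6-mer fingerprints score every `3 + gap(0..G) + 3` pattern (default
G = 10) by its best placement inside the PWM over both strands, summing
`log(freq + 0.01)` at defined positions; the 0.01 pseudocount avoids −∞ on
zero cells, and placements that do not fit score the flat background
`6·log(0.26)`.  Motif similarity is the Pearson correlation of two
fingerprints (Spearman available); reverse-complement invariance is exact
by construction (strand-max), and zero-variance fingerprints (uniform PWMs)
are rejected as degenerate rather than silently correlated.

Protein similarity multiplies the local-alignment score (BLOSUM62, affine
gaps open 11 / extend 1 — blastp-like defaults, implemented with Biopython's
PairwiseAligner and cross-checked against an independent Smith–Waterman/
Gotoh oracle) by the alignment length and divides by the shorter sequence
length.  Multi-domain proteins combine either by the best-scoring domain
pair or by concatenation.

Dendrograms use euclidean distances between similarity-matrix rows with
average linkage (scipy), serialized as Newick via scikit-bio; networks draw
an undirected edge wherever similarity ≥ threshold, keep isolated nodes,
and export as TSV edge list and GraphML.  An externally computed similarity
matrix (e.g. from a dedicated PWM-comparison tool) can be loaded from TSV
and fed to the same clustering/network/heatmap outputs.

k-mer enrichment tables compute, per ungapped k-mer (default k = 10),
`log2[(c_late+1)/(N_late+4^k)] − log2[(c_early+1)/(N_early+4^k)]` for two
experiments side by side, with optional best-match PWM scores for 2D
coloring of scatter plots.

## Visualization

All renderers emit SVG 1.1 as pure functions — byte-identical output for
identical input — with the geometry embedded in `data-*` attributes so
tests recover it exactly.  Barcode logos take "proportional" literally:
height and intensity fractions equal the column's maximum base frequency on
its native [0.25, 1] range (a uniform column renders at quarter height, not
zero).  Base colors are A green, C blue, G orange, T red.  Sequence logos
use standard information content (bits, column max 2).  The dependency
heatmap draws one tile per upper-triangle position pair with a 4×4 dot grid
(over = yellow, under = blue); the 2D similarity heatmap maps motif
similarity and scaled protein similarity to the red and green channels, so
both-high renders yellow.

## Synthetic SELEX generator

`simulate_experiment` emulates: a uniform random initial library of the
ligand design's randomized-region length (default design: 6 bp 5' barcode,
20 bp region, 2 bp 3' barcode); selection rounds in which each read's
affinity is the maximum over placements, strands, and mixture components of
the site probability ratio versus uniform background (winner-take-all —
single-site binding dominates short ligands; a sum-occupancy mode exists),
with optional dinucleotide couplings multiplying in their joint/product
ratio; Bernoulli retention with probability `(1 + s·A)` normalized by the
round maximum; and resampling with replacement to constant depth (PCR;
duplicate reads are intentional and exercise per-read counting).  Defaults —
50,000 reads/cycle, 3 cycles, selection strength 5, planted site with 0.8
per-base match probability — are desk-scale choices within the regime the
selection protocol operates in (selection repeated several times, strong
enrichment per round).

It does **not** emulate sequencing error, bead/washing kinetics, barcode
cross-talk, PCR bias beyond resampling, or carrier-dependent background.
Consequently passing recovery tests show the inference machinery is correct
under the stated generative model, not that it is robust to every artifact
of bench data.  Two behaviors of the generator matter when reading results:
(1) planted sites arise *by chance* in the random library, so a planted
consensus should keep its expected occurrence count in mind — a motif of 8+
defined bases has only a handful of perfect founder reads at 20k × 20 bp
and its descendants can fix by drift; the bundled fixtures use 6-defined-
base sites, the typical core length, for that reason; (2) multi-cycle
selection sharpens the site distribution beyond the generator PWM
(occurrence ∝ p·(p/0.25)^cycles), so per-cell agreement with the planted
matrix is asserted on directly sampled site reads, while cycle-3 recovery is
asserted as per-column correlation (≥ 0.95).

## Problem sizes and numerical choices

- Distance oracle checks: exhaustive over all pattern pairs at ≤4 defined
  bases / gap ≤1 (~1,250 patterns), plus 1,500–2,000 seeded random pairs
  from the ≤6 defined / gap ≤2 space (~57k patterns), both strand policies.
- Autoseed oracle checks: full-space predicate equivalence on dense random
  tables at 2–3 defined / gap ≤1, and on sparse random tables at 3–5
  defined / gap ≤1.
- Seed-recovery replication: 20 simulations of 50,000 reads × 3 cycles,
  counting bounds 4–7 defined / gap ≤2 (the planted seed has 6 defined
  bases, so cross-length dominance is exercised from both sides).
- Tolerances: frequency-column normalization 1e-9; over/under sign epsilon
  1e-6; SVG geometry written at 6 decimals; degenerate-fingerprint variance
  threshold 1e-12.
- Tie-breaks are all deterministic and documented at the definition site:
  window selection leftmost-then-forward; strand-canonical lexicographic
  with `n` ranked last; seed ranking count-descending then lexicographic.

## Known limitations

- The seeder's θ rule is a formalization of a qualitative description; the
  default 0.5 is principled but not fitted to any reference implementation.
- Relation classification covers the three named structural classes;
  composite changes (e.g. flank + spacing) fall through to `unrelated`
  rather than guessing.
- The site-structure heuristic assumes tandem-ish half-site geometry and a
  dominant core; heavily overlapping or palindromic half-sites may
  undercount copies.
- Dependency scores above 100 are possible by construction (see above).
- The amino-acid score uses one aligner parameterization; scores are
  comparable within a run, not across substitution matrices.
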