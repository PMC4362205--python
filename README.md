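# selexmotif

Motif analysis for HT-SELEX experiments: seed discovery over gapped
subsequences, background-corrected multinomial position weight matrices
(PWMs), dinucleotide-dependency scoring, motif and DNA-binding-domain
similarity with clustering and network export, and compact barcode-logo
rendering — plus a ground-truth SELEX simulator so every stage can be
exercised and validated without any external data.

## Who this is for

HT-SELEX enriches protein-bound DNA ligands from a randomized library over
successive selection/amplification cycles and sequences the pool after each
cycle.  Turning those read pools into binding models raises a chain of
computational problems — where in k-mer space are the enriched sites, how to
summarize them as a PWM without library bias, whether base positions inside a
site are independent, and how to compare hundreds of resulting models.  This
package implements that chain as an importable library (`import selexmotif`)
with a thin `selexmotif` command-line wrapper for pipeline use.

## The methods at the core

**Huddinge distance.**  Binding sites are represented as *gapped patterns*
over `{A,C,G,T,n}` (e.g. `ACnGT`: four defined bases, one unconstrained
position).  The distance between two patterns is `d − a`, where `d` is the
larger defined-base count and `a` is the maximum number of defined bases that
align as perfect matches when the patterns are slid rigidly against each
other (no new gaps).  Substitutions, truncations, extensions, and shifts of
ungapped patterns are all at distance 1; a shifted *gapped* pattern is at
distance ≥ 2, which lets the seeder distinguish gapped sites from their own
shifts, and monomers from dimers of the same half-site.

**Autoseed.**  Every in-bounds pattern is counted in a cycle's reads
(strand-merged, one count per read by default).  A pattern is a *seed* when
it is a local maximum of the count landscape: strictly more frequent than
every equal-length neighbor at Huddinge distance 1, and dominant across
lengths under a threshold rule — a longer neighbor `L` beats a shorter
pattern `S` when `count(L) > θ·count(S)` (default θ = 0.5), compensating for
shorter patterns being unavoidably more frequent.  The strongest maximum is
the primary binding mode; other maxima are secondary modes, classified
against the primary as spacing/orientation variants, flank variants, or
dinucleotide variants.

**Multinomial PWM.**  For a chosen seed, each read contributes its best
matching window (either strand).  Column `i` counts bases at `i` over windows
that match the seed at all *other* defined positions with at most
`order − 1` mismatches (order 1 = exact elsewhere).  Counts are divided by
the same tally on the unselected cycle-0 library, cancelling library
composition bias, and renormalized per column.

**Dinucleotide dependency score.**  For every pair of site positions, the
observed joint 4×4 base distribution is compared with the product of its
marginals.  The score is the mispredicted-count fraction (total variation
distance), scaled so 0% = independent and 100% = the case where only two
dinucleotides (e.g. AA/TT) occur at equal frequency and a mononucleotide
model mispredicts half of all counts.

**Similarity.**  Motif–motif similarity is the Pearson correlation of
*gapped 6-mer score vectors* (each `3 + gap + 3` pattern scored by its best
log-probability placement in the PWM, both strands) — exactly invariant to
reverse complementation.  Protein (DBD) similarity is local-alignment score
× aligned length / length of the shorter sequence (BLOSUM62, gap open 11 /
extend 1).  Matrices feed average-linkage dendrograms (Newick), thresholded
similarity networks (edge list / GraphML), and a 2D motif×protein heatmap.

**Barcode logo.**  A PWM column is drawn as four bars whose widths are the
base frequencies; bar height and color intensity equal the column's maximum
base frequency (range 0.25–1).  Motifs render as color stripes that can be
aligned visually across hundreds of models.

## Worked example

`examples/01_simulate_and_autoseed.py` plants a GGCGTG site (85% per-base
match probability) in a 20 bp randomized library, runs 3 selection cycles of
20,000 reads, counts gapped patterns and finds the local maxima:

```
simulated 3 cycles of 20000 reads
counted 37760 gapped patterns in cycle 3
rank 1: CACGCC  count=19944  role=primary  relation=none
rank 2: AACT  count=2662  role=secondary  relation=unrelated
rank 3: CCCAGnA  count=739  role=secondary  relation=unrelated
```

The rank-1 seed `CACGCC` is the strand-canonical form (reverse complement)
of the planted `GGCGTG`; its count says ~19,944 of 20,000 cycle-3 reads
carry the site on one strand or the other.  The lower-ranked maxima are
noise-level background patterns, an order of magnitude less frequent.

`examples/03_dinucleotide_dependency.py` plants an AA/TT coupling at the two
unconstrained middle positions of a GGCnnGCC site and recovers it:

```
top position pairs by dependency score (1-based):
  (4,5): 80.8%
  (4,7): 0.0%
  (5,7): 0.0%
signs at the planted pair: AA over / TT over / AT under / TA under
```

The other examples build and render PWMs (`02`), compare and cluster motifs
(`04`), and walk through the distance itself (`05`).  Each prints what its
numbers mean.

## Command line

```bash
selexmotif simulate --model model.yaml --seed 1 --out-prefix sim
selexmotif count --max-defined 7 --max-gap 2 --out counts.tsv sim_cycle3.fasta
selexmotif autoseed --out seeds.tsv counts.tsv
selexmotif pwm --seed GGCGTG --flank 2 --background sim_cycle0.fasta \
    --out pwm.tsv sim_cycle3.fasta
selexmotif logo --style barcode --out logo.svg pwm.tsv
selexmotif run --config pipeline.yaml    # demux→count→seed→pwm→dinuc→viz
```

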