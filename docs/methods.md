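# Methods

This note documents the models and conventions behind `sine-scout`: what each
stage computes, the defaults and why, what the synthetic-data generator does
and does not emulate, and the numerical choices that make results
deterministic.

## Coordinates, sequences, scoring

All internal coordinates are 0-based half-open; GFF3 is converted on the way
in/out (1-based inclusive), BED6 is written 0-based half-open. Sequences are
uppercased on ingest and symbols outside `ACGTN` become `N`; `N` never counts
as a match in any identity or distance computation. Alignment scoring is
match +1, mismatch −2, and a gap of length L costs −5 − 2L, used identically
in the search DP and in the Biopython-backed global alignments. Identity is
matches/columns with internal gap columns counted as mismatches and terminal
gap columns excluded. Minus-strand hits are stored with plus-strand genomic
coordinates and a strand flag; their stored alignment rows are oriented to
the query so copies from both strands feed one consensus frame.

## Homology search

The genome scan is k-mer seeding (word size 11; two seeds on the same
diagonal band within 25) followed by full affine-gap Smith–Waterman inside a
padded candidate window, iterated with masking so tandem copies sharing a
window are all recovered. The window DP is an own vectorized Gotoh
implementation; the within-row gap state is resolved in closed form with a
prefix maximum, which is exact because re-opening a gap out of a gap state is
always dominated by extending it. Three regimes reuse this machinery:
discovery (identity ≥0.70, ≥50 aligned columns), copy counting (≥0.80 over
≥100 columns, with hits falling entirely inside a caller-supplied ambiguous
head region excluded, and >50%-overlapping same-strand hits merged keeping
the higher identity), and the divergence set (identity ≥0.80 and query
coverage ≥0.80). Word size 11 keeps seeding sensitive down to ~15% copy
divergence for queries of a few hundred bp; short tail queries use word
size 7.

## Consensus and boundaries

Family consensi come from a center-star multiple alignment: the copy
maximizing summed pairwise identity is the center (ties: lexicographically
smallest id, making the result input-order independent); all others are
aligned to it semiglobally and gap patterns are merged. Majority collapse
drops columns with >50% gaps and breaks base ties A<C<G<T. The
reconstruction set is copies with query coverage ≥0.9, capped at 60 — the
consensus is saturated well below that for the family sizes involved.

Boundary refinement aligns a filled locus (element ± 500-bp flanks) to its
empty site twice (second pass with the first alignment masked); element
boundaries are the innermost flank-alignment endpoints, and the overlap of
the two alignments on the empty site, if ≥5 bp, is the TSD. Both flank
alignments must be ≥50 bp at ≥70% identity or the result is "no orthologous
site". Alignment ends are trimmed back to a run of 4 exact matches: a chance
extension past the true junction ends ragged (a mismatch propped up by a few
matches) and is cut to the last solid anchor, while genuine junction-flush
alignments end in exact TSD sequence and are untouched. Direct TSD detection
on flanks takes the longest suffix/prefix match of length 5–20 with at most
one mismatch.

## Structural annotation

Promoter scanning matches degenerate box consensi (IUPAC) in the first
120 bp: type 2 is A box `TRGCNNARYNNG` then B box `GWTCRANNC` starting
25–60 bp after the A box; type 1 is A box, intermediate element `GATGGR` and
C box `RGGTCGGGC` in order with 2–30-bp gaps. Positions failing their IUPAC
class count as mismatches; up to 2 are tolerated per box but only 1 across
the whole architecture by default. That total budget was calibrated by Monte
Carlo against i.i.d. random sequence: with a total budget of 2 a random
300-bp sequence yields an architecture in ~7% of trials, with 1 in ~0.6%.
Both budgets are user-settable for permissive scanning. Head origin is
decided by semiglobal alignment of each reference head against the 5'
150 bp — the reference must align in full so short perfect sub-matches
cannot fake a call — with a 0.55 identity floor chosen below the 63–66%
head identities typical of genuine tRNA/5S derivation; a matching promoter
architecture also suffices.

Tail detection searches the 3' 60 bp for tandem runs of 1–6-bp units
reaching within 5 bp of the 3' end at ≥80% purity with ≥3 units. Two guards
were added after measuring that the purity rule alone fires on about half of
random windows: the defining unit must repeat exactly once (a tandem repeat
must repeat) and the run must span ≥10 bp. Candidates are ranked by
full-unit run length, then purity, then primitive-unit length; the unit is
reported as the lexicographically smallest rotation of its primitive form,
so (GT)n and (TG)n are one family tail.

## Divergence and age profiles

Distances use the Kimura-2-parameter model on gap-free compared sites
(pairwise deletion): d = −½·ln((1−2P−Q)·√(1−2Q)). Pairs with 1−2P−Q ≤ 0 or
1−2Q ≤ 0 raise a saturation error and are excluded from family means (and
counted) rather than clamped, keeping the mean unbiased and the accounting
explicit. Copy identity to the consensus reuses the search alignment
(no realignment), is multiplied by 100 and rounded half-up; age profiles are
histograms over integer bins 80–100 with zero bins retained. Because the
search alignment is local, a strongly diverged copy loses a few terminal
columns, which biases identity up and mean divergence down by well under one
percentage point at the divergences involved; raw-sequence inputs use strict
global alignment, where a terminal mismatch is not silently converted into an
unpenalized overhang.

## Insertion context

Classification is by copy midpoint against interval trees of gene features
with precedence CDS > UTR5/UTR3 > non-coding exon > intron > downstream-5k >
upstream-5k > intergenic; UTR5 and UTR3 share one level and same-level
conflicts between overlapping genes resolve to the smaller gene id. Flank
windows are measured from the gene span respecting strand. Intergenic copies
report the nearest gene and its distance. Per-gene reports count genic
copies per family and list genes at or above a threshold (default 10).

## Comparative screens

Consensus p-distances are base differences per site under pairwise deletion.
Trees are neighbor joining on K2P distances from a center-star alignment of
the consensi, with site-resampling bootstrap supports; a bootstrap replicate
whose pair saturates falls back to a capped distance (5.0) so every
replicate yields a tree. This NJ/K2P+bootstrap combination is a deliberate,
simpler substitution for likelihood tree building: topology is reproduced
(verified against an independent NJ implementation), support values are not
claimed to match any particular published analysis. Partner-LINE candidates
are hits of the family's 3'-tail 50-mer (≥80% identity over ≥30 bp) with
≥2 kb of same-contig sequence upstream in element orientation; candidate
spans (3 kb) are annotated with their longest ATG-to-stop ORF on either
strand (flag at ≥200 codons — a heuristic stand-in for explicit
endonuclease/reverse-transcriptase domain detection) and any flank TSD. HTT
screening scores all cross-species consensus pairs: a pair is flagged at
identity ≥0.90 with hosts at least a family apart (ranks from a user-supplied
lineage table; no taxonomy download), and stays provisional until an
orthologous-empty-site check on related genomes — both flanks aligning at
≥70% identity, in order, within 50 bp of each other — attaches its evidence.
Mechanism (e.g. end-joining inferred from missing TSDs) is reported as raw
evidence only, never as a verdict.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions.
Masters are head + body + tail: the head is a diverged copy (default K2P
0.25) of a synthetic tRNA (72 bp) or 5S (118 bp) reference with the exact
promoter boxes re-planted at fixed offsets; the default family is 263 bp
with a (GT)×9 tail; later families share a 44-bp body segment with the
first. Copies are mutated under the K2P process — `kappa` is the expected
transition/transversion *count* ratio (default 2), per-site substitution
probabilities are solved from the K2P expectation so re-estimated distances
recover the target — with optional 5' truncation; mutation is
substitution-only by default (an indel knob exists, default 0) so identity
arithmetic in oracles stays exact. Burst age models place every copy at one
divergence; mixtures draw per copy. `divergence_for_identity` inverts the
expected mismatch proportion P(d)+Q(d) numerically for identity-centered
designs.

Gene models (≥2 exons, CDS, both UTRs) are spaced ≥12 kb so 5-kb flank
windows never overlap a neighbor. Insertion points are drawn per configured
context weights (defaults: intron 0.45, downstream-5k 0.25, intergenic 0.22,
upstream-5k 0.05, UTR3 0.02, CDS 0.01 — an intron- and downstream-biased
landscape); each insertion duplicates the target site (5–15 bp) and all
downstream coordinates, including gene features, shift accordingly, so
features containing an insertion stretch around it and genic truth labels
are exact by construction. Two placement guards hold: flank-category points
are sampled ≤2.8 kb from the gene edge because insertions stacking between
the gene and a later implant push its realized distance outward (residual
drift to intergenic is a few per mil at n=1000), and an implant is re-drawn
if its terminal base equals the adjacent host base — otherwise the TSD is
genuinely one longer than drawn and exact recovery is ill-posed. The partner
LINE is a 3-kb element (700-codon ORF) whose final 43 bp are ~84% identical
to the first family's tail. The HTT event inserts a near-identical copy
(K2P 0.01) of a family master into a 15-kb virus record behind an 800-bp
host-derived flank, with no TSD and no upstream host sequence, and emits two
related virus records carrying the joined empty site plus a lineage table
placing the virus kingdom-distant from the host.

What the generator does **not** emulate: background sequence is i.i.d. at a
set GC (no Markov structure, no other repeat families), insertions never
interrupt each other, and real assemblies add gaps, segmental duplications
and repeat-masking artifacts. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure, not
performance on raw field data; the promoter-scan false-positive calibration
in particular is against the i.i.d. null.

## Problem sizes and determinism

The test suite and acceptance script run at the sizes the properties are
stated for: parameter recovery on a 3-Mb genome with 200 copies at d=0.05
(recall ≥95%, consensus ≥99%, |mean d − 0.05| ≤ 0.01); search-vs-oracle
equivalence on twenty 50-kb genomes; age-profile bimodality with 400 copies
at identity centers 98 and 85; context classification on 1,000 copies over a
50-gene annotation (exact oracle agreement, χ² at α=0.01); TSD/boundary
recovery on 200 spaced implants (≥95% exact); and fifty all-vertical
replicates with zero HTT flags. Consensus recovery uses 10 seeded replicates
and the estimator round-trip 4,000 copies, sizes at which the binomial noise
is far inside the asserted tolerances. Every stochastic step takes an
explicit seed or `numpy.random.Generator`; identical configurations produce
byte-identical FASTA/GFF/truth outputs.

## Known limitations

Discovery-threshold search (70%/50 bp) near the two-hit seeding limit can
miss copies beyond ~25% divergence; the stated guarantees hold for the
copy-counting regime. The ORF heuristic cannot distinguish a LINE from any
long ORF next to a shared tail. The HTT screen compares consensi, not
genome-wide copies, and its relatedness ranks are only as good as the
supplied lineage table. Absolute dating (substitutions → years) and CpG- or
composition-aware substitution models are out of scope.
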