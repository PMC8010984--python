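# sine-scout

Discovery and characterization of **SINE retrotransposon families** in genome
assemblies: thresholded homology search, consensus reconstruction, structural
annotation, divergence and relative-age profiling, insertion-context analysis,
partner-LINE discovery and horizontal-transfer screening — with a synthetic
genome generator that provides exact ground truth for every stage.

## Who this is for

Short interspersed nuclear elements (SINEs) are non-autonomous non-LTR
retrotransposons: a 5' head derived from a Pol III transcript (tRNA or 5S
rRNA, still carrying the internal promoter boxes), a central body, and a
simple-repeat 3' tail recognized by the reverse transcriptase of a partner
LINE. Their minimal sequence signal makes them chronically under-annotated.
`sine-scout` packages the classic copy-and-characterize workflow used in
insect SINE surveys as a tested, reusable library and CLI for anyone
annotating repeats in a new assembly.

## The method in brief

* **Search** — k-mer seeded (two-hit), affine-gap local alignment, applied
  under three threshold regimes: *discovery* (≥70% identity over ≥50 bp),
  *copy counting* (≥80% over ≥100 bp, head-only copies shared between
  families excluded), and the *divergence set* (≥80% identity over ≥80% of
  the consensus length).
* **Consensus** — center-star multiple alignment of near-full-length copies,
  majority-rule collapse (columns >50% gap dropped, ties A<C<G<T).
* **Boundaries & TSDs** — a filled locus is aligned against its empty
  insertion site; the innermost flank-alignment endpoints define the element
  and the overlap of the two flank alignments on the empty site is the
  target-site duplication.
* **Divergence & age** — Kimura-2-parameter distance with pairwise deletion,
  `d = -1/2 ln((1-2P-Q)sqrt(1-2Q))`, and per-family histograms of integer
  copy-to-consensus identities over 80–100% (a mode near 100% = recent
  burst).
* **Genic context** — midpoint classification against gene models with the
  precedence CDS > UTR > non-coding exon > intron > 5-kb-downstream >
  5-kb-upstream > intergenic.
* **Comparative screens** — p-distance matrices and neighbor-joining trees
  (K2P, site-resampling bootstrap); partner-LINE candidates found by querying
  the family's 3'-tail 50-mer and demanding ≥2 kb of element upstream plus a
  long ORF; horizontal-transfer candidates flagged when cross-species
  consensus identity ≥90% despite host separation at or beyond family rank,
  corroborated by orthologous *empty* sites in related genomes.

## Worked example

Generate a 500-kb genome carrying one 263-bp tRNA-derived family (80 copies
implanted at true K2P distance 0.05), then characterize it from scratch:

```python
import sine_scout as ss
from sine_scout.synthetic_data import (
    FamilySpec, SimulationConfig, generate_genome_with_families,
)
from sine_scout.consensus_builder import build_msa_center_star, majority_consensus
from sine_scout.divergence_age import age_distribution, family_divergence_summary
from sine_scout.structure_annotator import detect_tail_repeat, scan_pol3_boxes

cfg = SimulationConfig(
    genome_bp=500_000, n_genes=20,
    families=[FamilySpec(name="SE1", n_copies=80, age_model=("burst", 0.05))],
    seed=42,
)
ds = generate_genome_with_families(cfg)
master = ds.truth.masters["SE1"]

copies, n = ss.count_copies(master, ds.genome)
divset = ss.select_divergence_set(master, copies)
cons = majority_consensus(build_msa_center_star([c.seq for c in divset[:60]]))
mean_d, n_used, _ = family_divergence_summary(divset, cons.seq)
```

Printed results (seed 42):

```
copies detected: 80
consensus: 263 bp from 60 copies
mean K2P divergence to consensus: 0.047 (n=80)
promoter: pol3_type2 {'A': (8, 20), 'B': (52, 61)}
head origin: tRNA (85% to synthetic_tRNA_Arg)
3' tail: (GT)n x9
age-profile mode: 95% identity (22 of 80 copies)
```

Reading this: all 80 implanted copies are recovered at copy-counting
thresholds; the majority consensus reconstructs the 263-bp master exactly;
the mean copy divergence (0.047) recovers the simulated 0.05; the head
carries an A-box/B-box type-2 Pol III promoter and classifies as
tRNA-derived; the tail is the expected (GT)n; and the age profile peaks at
the identity implied by d = 0.05 — the signature of a single recent burst.

The same steps are available from the shell:

```bash
sine-scout simulate --genome-bp 500000 --n-copies 80 --seed 42 --out sim/
sine-scout search --query sim/masters.fa --genome sim/genome.fa --mode count -o hits.tsv
sine-scout context --copies hits.bed --gff sim/genes.gff3 -o context.tsv
```

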