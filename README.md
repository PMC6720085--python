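# tecoex

Quantification and co-expression analysis of transposable-element (TE)
derived transcripts in bulk RNA-seq, for researchers who need locus-level
repeat expression that is not an artifact of multi-mapping or of pre-mRNA
read-through.

Repeat-derived reads are hard to count: young TE copies are nearly
identical, so their reads map to many loci, and TEs embedded in introns
pick up reads from unspliced or retained host transcripts.  `tecoex`
addresses both:

* **EM assignment of multi-mapped reads.**  Fragments carry candidate-locus
  sets `A_r`; a multinomial mixture over locus abundances π is fit by EM
  (`w_{r,l} = π_l / Σ_{l'∈A_r} π_{l'}`, counts = summed weights), conserving
  total read mass exactly.  A unique-only mode and a mappability-bias
  diagnostic quantify what single-best-alignment counting would distort.
* **Read-through correction.**  For a TE inside an intron, with read depths
  `R = count/(len − read_len)` over the element and its flanking intron
  segments, the corrected count is
  `count_TE · (1 − (R_IL + R_IR)/(2 R_TE))`, floored at zero.  Exonic TEs
  are zeroed; intergenic TEs pass through.
* **Downstream analyses.**  Two-step median-ratio (DEGES) size factors from
  gene counts applied to TE matrices; top-variance UPGMA tissue clustering
  scored by normalized mutual information with permutation baselines;
  consensus weighted co-expression networks (signed adjacency
  `((1+r)/2)^14`, topological overlap, element-wise-minimum consensus,
  static tree-cut modules, eigengenes, kME); and association screens
  (KZFP × TE family correlations with locus follow-up and binding-overlap
  Fisher tests; L1HS 5′ × gene linear models with all-subsets AICc
  covariate selection).
* **A synthetic-data generator** producing genomes, annotations, expression
  with planted factor structure, and exact-match multi-mapped SAM
  alignments with read-through — the ground truth every stage is validated
  against.

## Worked example

Three identical copies of a TE family make every interior read ambiguous;
EM splits the mass while unique-only counting discards it
(`examples/01_simulate_and_quantify.py`):

```
TE-overlapping fragments ingested: 648
           true     em  unique_only
FAM1_dup1   223  216.0          0.0
FAM1_dup2   166  216.0          0.0
FAM1_dup3   259  216.0          0.0
```

The 648 ambiguous fragments are allocated evenly (identical copies are
statistically indistinguishable, so EM returns the symmetric optimum
≈ 216 each, close to the planted 223/166/259), whereas unique-only
counting reports zero expression for all three loci.

Read-through correction (`examples/02_read_through_correction.py`) on
intronic TEs with both autonomous transcription and intron retention:

```
totals: raw 4222, corrected 2967, true autonomous 3042
```

The raw EM total is inflated ~40% by read-through; the corrected total
recovers the planted autonomous expression within ~2.5%.

The other examples cover normalization + clustering (NMI = 1.0 on three
planted tissues from top-150 variance TE loci, chance ≈ 0.05), consensus
modules with anti-correlated eigengenes, and the association screens.
Each prints what its numbers mean.

A thin CLI mirrors the stages for shell use:

```bash
tecoex simulate --out toy --seed 1          # toy dataset + full pipeline
tecoex quantify --sam s.sam --te te_context.tsv --genes genes.gtf \
    --mode em --out counts
tecoex cluster --matrix log2.tsv --meta meta.tsv --top 150 --k 16
```

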