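"""DEGES normalization and NMI-scored tissue clustering.

Size factors estimated from gene counts (two-step median-ratio with
elimination of DE-like genes) are applied to TE counts; samples are then
clustered by UPGMA on the top-variance TE loci and scored against the true
tissue grouping with normalized mutual information.
"""

import pandas as pd

from tecoex.cluster import (
    cluster_samples, permutation_baseline, select_top_variance,
)
from tecoex.normalize import (
    deges_size_factors, log_transform, normalize_counts,
)
from tecoex.simulate import SimConfig, simulate_annotation, simulate_expression

cfg = SimConfig(
    n_chromosomes=2, chrom_length=90_000, n_genes=8, exons_per_gene=2,
    n_te_families=6, loci_per_family=32, family_divergence=0.15,
    family_contexts={f"FAM{i}": "intergenic" for i in range(1, 7)},
    te_base_mean=30.0, tissue_specificity=1.5,
    n_samples_per_tissue=12, n_tissues=3, frag_reads_per_sample=12_000,
    seed=8,
)
ann = simulate_annotation(cfg)
truth = simulate_expression(cfg, ann)

genes = pd.DataFrame(truth.gene_fragment_counts, index=truth.gene_ids,
                     columns=truth.sample_ids)
loci = pd.DataFrame(truth.locus_fragment_counts, index=truth.locus_ids,
                    columns=truth.sample_ids)
tissue = pd.Series(truth.sample_tissue)

sf = deges_size_factors(genes, tissue)
log2 = log_transform(normalize_counts(loci, sf))
chroms = pd.Series({t.locus_id: t.chrom for t in ann.te_loci})
top = select_top_variance(log2, n=150, feature_chroms=chroms, raw_counts=loci)

res = cluster_samples(log2.loc[top], tissue, k=3)
base = permutation_baseline(tissue, reps=100, seed=0)

print(f"clustering NMI at k=3: {res.nmi:.3f}")
print(f"cluster -> majority tissue: {res.cluster_label}")
print(f"chance-level mean NMI (100 shuffles): {base['shuffle']:.3f}")
print("\nNMI of 1.0 means the top-150 variance TE loci alone carry enough "
      "tissue-specific signal to reconstruct the tissue grouping; the "
      "permutation baseline shows what label noise would score.")
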