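"""End-to-end orchestration on synthetic data plus input validation.

The pipeline runs simulate -> annotate -> quantify (EM + unique) -> correct
-> normalize -> cluster -> network -> screens on a toy dataset, writing TSV
artifacts and a manifest with SHA-256 hashes so identical configs and seeds
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import annotations as ann_mod
from . import cluster as cluster_mod
from . import correction, network, normalize, quantify, screens
from .simulate import (
    KmerIndex, SimConfig, kmer_mappability, simulate_alignments,
    simulate_annotation, simulate_expression,
)

STAGES = ("simulate", "annotate", "quantify", "correct", "normalize",
          "cluster", "network", "screen")


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: SimConfig, out_dir, seed: int | None = None,
                 k_clusters: int | None = None, top_n: int = 150,
                 beta: float = 14.0, min_module_size: int = 30) -> dict:
    """Run every stage on a simulated dataset; return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    manifest: dict = {"stages": {}, "seed": config.seed}

    # -- simulate ----------------------------------------------------------
    ann = simulate_annotation(config)
    truth = simulate_expression(config, ann)
    index = KmerIndex(ann.genome, config.read_len)
    sam_dir = out / "alignments"
    sam_dir.mkdir(exist_ok=True)
    frags = simulate_alignments(truth, ann, config, out_dir=sam_dir,
                                kmer_index=index)
    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(ann.genome):
            fh.write(f">{chrom}\n{ann.genome[chrom]}\n")
    ann_mod.write_gene_gtf(ann.genes, out / "genes.gtf")
    ann_mod.write_te_gtf(ann.te_loci, out / "te.gtf")
    ann_mod.write_te_bed(ann.te_loci, out / "te.bed")
    save_config(config, out / "config.yaml")
    truth_df = pd.DataFrame(truth.true_locus_abundance, index=truth.locus_ids,
                            columns=truth.sample_ids)
    _write_tsv(truth_df, out / "truth_locus_abundance.tsv")
    meta = pd.DataFrame({
        "sample": truth.sample_ids,
        "tissue": [truth.sample_tissue[s] for s in truth.sample_ids],
    }).set_index("sample")
    _write_tsv(meta, out / "metadata.tsv")
    manifest["stages"]["simulate"] = _stage_entry(
        out, ["genome.fa", "genes.gtf", "te.gtf", "te.bed", "config.yaml"])

    # -- annotate ----------------------------------------------------------
    mappable = kmer_mappability(ann.genome, ann.te_loci, k=config.read_len)
    loci = [dataclasses.replace(t, mappable_len=mappable[t.locus_id])
            for t in ann.te_loci]
    ann_mod.write_context_table(loci, out / "te_context.tsv")
    manifest["stages"]["annotate"] = _stage_entry(out, ["te_context.tsv"])

    # -- quantify ----------------------------------------------------------
    locus_ids = [t.locus_id for t in loci]
    em_cols, uniq_cols = {}, {}
    intron_tables = {}
    qc = {}
    for sample in truth.sample_ids:
        sam = sam_dir / f"{sample}.sam"
        asets, st = quantify.ingest_alignments(sam, loci, ann.genes,
                                               multimap_cap=config.multimap_cap)
        if asets:
            res = quantify.em_assign(asets, locus_ids=locus_ids,
                                     return_stats=True)
            em_cols[sample] = res.counts
            uniq_cols[sample] = quantify.unique_only_counts(asets, locus_ids)
            qc[sample] = {"ingested": st.fragments_ingested,
                          "dropped_multimap": st.dropped_multimap,
                          "em_iterations": res.n_iter}
        else:
            em_cols[sample] = pd.Series(0.0, index=locus_ids)
            uniq_cols[sample] = pd.Series(0.0, index=locus_ids)
            qc[sample] = {"ingested": 0, "dropped_multimap": 0,
                          "em_iterations": 0}
        intron_tables[sample] = correction.intron_counts(sam, loci)
    em = pd.DataFrame(em_cols)
    uniq = pd.DataFrame(uniq_cols)
    _write_tsv(em, out / "locus_counts_em.tsv")
    _write_tsv(uniq, out / "locus_counts_unique.tsv")
    (out / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
    manifest["stages"]["quantify"] = _stage_entry(
        out, ["locus_counts_em.tsv", "locus_counts_unique.tsv", "qc.json"])

    # -- correct -----------------------------------------------------------
    corrected, report = correction.apply_counting_policy(
        em, loci, intron_tables, read_len=config.read_len)
    fam = quantify.aggregate_family(corrected, loci)
    _write_tsv(corrected, out / "locus_counts_corrected.tsv")
    _write_tsv(fam, out / "family_counts.tsv")
    _write_tsv(report, out / "correction_report.tsv")
    manifest["stages"]["correct"] = _stage_entry(
        out, ["locus_counts_corrected.tsv", "family_counts.tsv",
              "correction_report.tsv"])

    # -- normalize ---------------------------------------------------------
    genes_df = pd.DataFrame(truth.gene_fragment_counts, index=truth.gene_ids,
                            columns=truth.sample_ids)
    sf = normalize.deges_size_factors(genes_df, meta["tissue"])
    te_norm = normalize.normalize_counts(corrected, sf)
    te_log2 = normalize.log_transform(te_norm)
    gene_log2 = normalize.log_transform(normalize.normalize_counts(genes_df, sf))
    _write_tsv(pd.DataFrame({"size_factor": sf.factors}), out / "size_factors.tsv")
    _write_tsv(te_log2, out / "locus_log2.tsv")
    _write_tsv(gene_log2, out / "gene_log2.tsv")
    manifest["stages"]["normalize"] = _stage_entry(
        out, ["size_factors.tsv", "locus_log2.tsv", "gene_log2.tsv"])

    # -- cluster -----------------------------------------------------------
    k = k_clusters or config.n_tissues
    chroms = pd.Series({t.locus_id: t.chrom for t in loci})
    try:
        top = cluster_mod.select_top_variance(
            te_log2, n=min(top_n, max(2, len(te_log2) - 1)),
            feature_chroms=chroms, raw_counts=em)
        cres = cluster_mod.cluster_samples(te_log2.loc[top], meta["tissue"], k)
        base = cluster_mod.permutation_baseline(meta["tissue"], reps=100,
                                                seed=config.seed)
        _write_tsv(cres.sample_cluster.to_frame(), out / "clusters.tsv")
        (out / "nmi.json").write_text(json.dumps(
            {"nmi": cres.nmi, "baseline": base}, indent=1))
        manifest["stages"]["cluster"] = _stage_entry(
            out, ["clusters.tsv", "nmi.json"])
    except ValueError as exc:  # too few eligible features on tiny configs
        manifest["stages"]["cluster"] = {"skipped": str(exc)}

    # -- network -----------------------------------------------------------
    fam_norm = normalize.normalize_counts(
        quantify.aggregate_family(corrected, loci), sf)
    fam_log2 = normalize.log_transform(fam_norm)
    by_tissue = {}
    for tissue in sorted(meta["tissue"].unique()):
        cols = meta.index[meta["tissue"] == tissue]
        block = pd.concat([gene_log2[cols], fam_log2[cols]])
        block = block[block.std(axis=1) > 0]
        by_tissue[tissue] = block
    shared = None
    for b in by_tissue.values():
        shared = b.index if shared is None else shared.intersection(b.index)
    by_tissue = {t: b.loc[shared] for t, b in by_tissue.items()}
    if len(shared) >= 3 and all(b.shape[1] >= 3 for b in by_tissue.values()):
        mods = network.fit_modules(by_tissue, beta=beta,
                                   min_module_size=min(min_module_size,
                                                       max(2, len(shared) // 3)))
        _write_tsv(mods.assignments.to_frame(), out / "modules.tsv")
        manifest["stages"]["network"] = _stage_entry(out, ["modules.tsv"])
    else:
        manifest["stages"]["network"] = {"skipped": "too few shared features"}

    # -- screen ------------------------------------------------------------
    expressed = screens.expressed_loci(em)
    (out / "expressed_loci.json").write_text(
        json.dumps(sorted(expressed), indent=0))
    screen_files = ["expressed_loci.json"]
    if config.n_samples_per_tissue >= 8 and len(fam_log2) >= 1:
        gene_by, fam_by = {}, {}
        for tissue in sorted(meta["tissue"].unique()):
            cols = meta.index[meta["tissue"] == tissue]
            gene_by[tissue] = gene_log2[cols]
            fam_by[tissue] = fam_log2[cols]
        results, replication = screens.pairwise_family_screen(gene_by, fam_by)
        screens.screen_results_frame(results).to_csv(
            out / "family_screen.tsv", sep="\t", index=False)
        screen_files.append("family_screen.tsv")
    manifest["stages"]["screen"] = _stage_entry(out, screen_files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_entry(out: Path, files: list[str]) -> dict:
    return {"outputs": {f: _sha256(out / f) for f in files}}


def validate_inputs(sam_path=None, te_gtf=None, gene_gtf=None,
                    bed=None, metadata=None) -> list[str]:
    """Consistency report across inputs; empty list means clean."""
    import pysam

    report: list[str] = []
    sam_chroms: set[str] = set()
    if sam_path is not None:
        try:
            with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
                sam_chroms = set(fh.references or ())
        except (ValueError, OSError) as exc:
            report.append(f"unreadable SAM: {exc}")
    annot_chroms: set[str] = set()
    for label, path, reader in (("te", te_gtf, ann_mod.read_te_gtf),
                                ("gene", gene_gtf, ann_mod.read_gene_gtf)):
        if path is None:
            continue
        try:
            records = reader(path)
        except (ValueError, KeyError, IndexError) as exc:
            report.append(f"unparseable {label} GTF: {exc}")
            continue
        if not records:
            report.append(f"empty {label} GTF")
        annot_chroms |= {r.chrom for r in records}
        for r in records:
            s, e = (r.start, r.end) if label == "te" else r.span
            if s < 0 or e <= s:
                report.append(f"bad coordinates in {label} GTF: {s}-{e}")
    if bed is not None:
        rows = ann_mod.read_bed(bed)
        if not rows:
            report.append("empty BED")
        annot_chroms |= {r[0] for r in rows}
    if sam_chroms and annot_chroms and not (sam_chroms & annot_chroms):
        report.append(
            f"no shared chromosomes between SAM ({sorted(sam_chroms)[:3]}) "
            f"and annotations ({sorted(annot_chroms)[:3]})")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t")
        if "tissue" not in meta.columns:
            report.append("metadata missing 'tissue' column")
        if meta.isna().any().any():
            report.append("metadata contains missing values")
    return report
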