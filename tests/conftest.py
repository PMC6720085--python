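import dataclasses

import pytest

from tecoex.simulate import (
    KmerIndex, SimConfig, simulate_alignments, simulate_annotation,
    simulate_expression,
)


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2, chrom_length=60_000, n_genes=8, exons_per_gene=3,
        n_te_families=4, loci_per_family=6, family_divergence=0.1,
        n_samples_per_tissue=2, n_tissues=2, frag_reads_per_sample=5_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def base_annotation(base_config):
    return simulate_annotation(base_config)


@pytest.fixture(scope="session")
def base_truth(base_config, base_annotation):
    return simulate_expression(base_config, base_annotation)


@pytest.fixture(scope="session")
def base_fragments(base_config, base_annotation, base_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("sam")
    frags = simulate_alignments(base_truth, base_annotation, base_config,
                                out_dir=out)
    return frags, out


@pytest.fixture(scope="session")
def multimap_setup(tmp_path_factory):
    """Zero-divergence family: every interior fragment maps to all copies."""
    cfg = SimConfig(
        family_divergence=0.0, n_te_families=1, loci_per_family=3,
        family_contexts={"FAM1": "intergenic"}, n_genes=4,
        n_samples_per_tissue=1, n_tissues=1, frag_reads_per_sample=3_000,
        te_base_mean=60.0, seed=5,
    )
    ann = simulate_annotation(cfg)
    truth = simulate_expression(cfg, ann)
    out = tmp_path_factory.mktemp("mm_sam")
    frags = simulate_alignments(truth, ann, cfg, out_dir=out)
    return cfg, ann, truth, frags, out


@pytest.fixture(scope="session")
def retention_setup(tmp_path_factory):
    """Intronic TEs with both autonomous expression and read-through."""
    cfg = SimConfig(
        n_te_families=2, loci_per_family=3, family_divergence=0.2,
        family_contexts={"FAM1": "intronic", "FAM2": "intronic"},
        te_base_mean=50.0, gene_base_mean=150.0, retention_fraction=0.4,
        n_samples_per_tissue=1, n_tissues=1, frag_reads_per_sample=20_000,
        seed=2,
    )
    ann = simulate_annotation(cfg)
    truth = simulate_expression(cfg, ann)
    out = tmp_path_factory.mktemp("ret_sam")
    frags = simulate_alignments(truth, ann, cfg, out_dir=out)
    return cfg, ann, truth, frags, out


def replace_config(cfg: SimConfig, **kw) -> SimConfig:
    return dataclasses.replace(cfg, **kw)
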