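"""Ground-truth validation experiments for the whole pipeline.

Each experiment builds a synthetic dataset with planted structure, runs the
corresponding pipeline stage, and measures recovery.  They are the package's
quantitative self-checks: the acceptance script reports their numbers and
the test suite asserts them.  Problem sizes are chosen to be informative at
desk scale (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cluster_mod
from . import network as network_mod
from . import screens as screens_mod
from .correction import apply_counting_policy, correct_count, intron_counts
from .normalize import (
    deges_size_factors, log_transform, median_ratio_size_factors,
    normalize_counts,
)
from .quantify import (
    AlignmentSet, CandidateAlignment, em_assign, ingest_alignments,
    mappability_bias_test, unique_only_counts,
)
from .simulate import (
    KmerIndex, SimConfig, kmer_mappability, simulate_alignments,
    simulate_annotation, simulate_depth_counts, simulate_expression,
)


def _seed(base: int, offset: int) -> int:
    return (base * 1009 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# 1. KZFP x TE family pair universe
# ---------------------------------------------------------------------------

def pair_universe(n_kzfp: int = 221, n_families: int = 909) -> dict:
    """Tested-combination count for the binding-overlap universe."""
    kzfps = {f"KZFP{i}" for i in range(n_kzfp)}
    families = {f"FAM{i}" for i in range(n_families)}
    enrichment = pd.DataFrame(
        [{"kzfp": "KZFP0", "family": "FAM0", "score": 2.0}])
    table = screens_mod.binding_overlap_family(
        {("KZFP0", "FAM1")}, enrichment, kzfps, families)
    return {"n_combinations": table.total}


# ---------------------------------------------------------------------------
# 2. Correction formula unit suite
# ---------------------------------------------------------------------------

def correction_units(seed: int = 0, n_random: int = 10_000) -> dict:
    cases = {
        "no_discount": correct_count(100.0, 0.1, 0.0, 0.0),
        "half_discount": correct_count(100.0, 0.1, 0.05, 0.05),
        "zero_out": correct_count(100.0, 0.1, 0.15, 0.15),
    }
    rng = np.random.default_rng(_seed(seed, 2))
    violations = 0
    for _ in range(n_random):
        count = rng.uniform(0, 1e5)
        r_te = rng.uniform(1e-6, 10.0)
        out = correct_count(count, r_te, rng.uniform(0, 10.0),
                            rng.uniform(0, 10.0))
        if not (0.0 <= out <= count):
            violations += 1
    cases["bound_violations"] = violations
    cases["n_random"] = n_random
    return cases


# ---------------------------------------------------------------------------
# 3. EM vs brute-force ML
# ---------------------------------------------------------------------------

def _grid_ml_counts(composition: dict[tuple[int, ...], int], n_loci: int,
                    step: float = 2e-5) -> np.ndarray:
    """Brute-force grid maximization of the multinomial-mixture likelihood
    (max-entropy tie-break on flat directions)."""
    sets = [(np.array(k), n) for k, n in composition.items() if n > 0]

    def loglik(pis):
        ll = np.zeros(pis.shape[0])
        for members, n in sets:
            ll += n * np.log(np.maximum(pis[:, members].sum(axis=1), 1e-300))
        return ll

    def pick(pis):
        ll = loglik(pis)
        ties = pis[ll >= ll.max() - 1e-9]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(ties > 0, ties * np.log(ties), 0.0),
                             axis=1)
        return ties[np.argmax(ent)]

    if n_loci == 2:
        p = np.arange(0.0, 1.0 + step, step)
        best = pick(np.column_stack([p, 1.0 - p]))
    else:
        coarse = np.arange(0.0, 1.0 + 1e-3, 1e-3)
        a, b = np.meshgrid(coarse, coarse, indexing="ij")
        mask = a + b <= 1.0
        c0 = pick(np.column_stack([a[mask], b[mask], 1 - a[mask] - b[mask]]))
        fine = np.arange(-2e-3, 2e-3 + step, step)
        a, b = np.meshgrid(np.clip(c0[0] + fine, 0, 1),
                           np.clip(c0[1] + fine, 0, 1), indexing="ij")
        mask = a + b <= 1.0
        best = pick(np.column_stack([a[mask], b[mask], 1 - a[mask] - b[mask]]))
    counts = np.zeros(n_loci)
    for members, n in sets:
        tot = best[members].sum()
        if tot <= 0:
            counts[members] += n / len(members)
        else:
            counts[members] += n * best[members] / tot
    return counts


def _em_counts_for(composition: dict[tuple[int, ...], int],
                   n_loci: int) -> np.ndarray:
    locus_ids = [chr(ord("A") + i) for i in range(n_loci)]
    sets = []
    i = 0
    for loci, n in composition.items():
        for _ in range(n):
            i += 1
            cands = tuple(CandidateAlignment(locus_ids[l], "chr1", 0, 48)
                          for l in loci)
            sets.append(AlignmentSet(f"f{i}", cands, len(loci)))
    return em_assign(sets, locus_ids=locus_ids).to_numpy()


def em_oracle_equivalence(seed: int = 0, max_fragments: int = 20,
                          n_three_locus: int = 40) -> dict:
    """Max |EM - grid ML| count over 2-locus (exhaustive) and 3-locus
    (sampled) configurations with <= ``max_fragments`` fragments."""
    max_dev = 0.0
    n_checked = 0
    for n_a in range(max_fragments + 1):
        for n_b in range(max_fragments + 1 - n_a):
            n_ab = max_fragments - n_a - n_b
            comp = {(0,): n_a, (1,): n_b, (0, 1): n_ab}
            if sum(comp.values()) == 0:
                continue
            dev = np.abs(_em_counts_for(comp, 2)
                         - _grid_ml_counts(comp, 2)).max()
            max_dev = max(max_dev, float(dev))
            n_checked += 1
    rng = np.random.default_rng(_seed(seed, 3))
    subsets = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]
    for _ in range(n_three_locus):
        n = int(rng.integers(3, max_fragments + 1))
        alloc = rng.multinomial(n, np.ones(7) / 7)
        comp = {s: int(c) for s, c in zip(subsets, alloc) if c}
        dev = np.abs(_em_counts_for(comp, 3) - _grid_ml_counts(comp, 3)).max()
        max_dev = max(max_dev, float(dev))
        n_checked += 1
    return {"max_abs_count_deviation": max_dev, "n_configurations": n_checked}


# ---------------------------------------------------------------------------
# 4. Mappability bias (unique-only vs EM)
# ---------------------------------------------------------------------------

def mappability_bias_experiment(seed: int = 0, n_loci: int = 200,
                                n_samples: int = 2) -> dict:
    """Equal true abundance, divergence-graded family: unique-only counts
    track mappable length; EM counts do not."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_length=70_000, n_genes=8, exons_per_gene=2,
        n_te_families=1, loci_per_family=n_loci, family_divergence=0.12,
        divergence_gradient=True, family_contexts={"FAM1": "intergenic"},
        te_base_mean=50.0, gene_base_mean=20.0, retention_fraction=0.0,
        n_samples_per_tissue=n_samples, n_tissues=1,
        frag_reads_per_sample=11_000, seed=_seed(seed, 4),
    )
    ann = simulate_annotation(cfg)
    truth = simulate_expression(cfg, ann)
    index = KmerIndex(ann.genome, cfg.read_len)
    mappable = kmer_mappability(ann.genome, ann.te_loci, k=cfg.read_len)
    locus_ids = [t.locus_id for t in ann.te_loci]
    with tempfile.TemporaryDirectory() as d:
        simulate_alignments(truth, ann, cfg, out_dir=d, kmer_index=index)
        em_cols, uq_cols = {}, {}
        for s in truth.sample_ids:
            asets, _ = ingest_alignments(Path(d) / f"{s}.sam", ann.te_loci,
                                         ann.genes)
            em_cols[s] = em_assign(asets, locus_ids=locus_ids)
            uq_cols[s] = unique_only_counts(asets, locus_ids)
    em = pd.DataFrame(em_cols)
    uq = pd.DataFrame(uq_cols)
    res_uq = mappability_bias_test(uq, mappable)
    res_em = mappability_bias_test(em, mappable)
    return {
        "unique_correlation": res_uq.correlation,
        "unique_p_value": res_uq.p_value,
        "em_correlation": res_em.correlation,
        "em_p_value": res_em.p_value,
        "n_loci": len(locus_ids),
    }


# ---------------------------------------------------------------------------
# 5. Retention correction recovery
# ---------------------------------------------------------------------------

def _retention_config(seed: int, te_base_mean: float,
                      retention_fraction: float) -> SimConfig:
    return SimConfig(
        n_chromosomes=2, chrom_length=70_000, n_genes=10, exons_per_gene=3,
        n_te_families=4, loci_per_family=5, family_divergence=0.2,
        family_contexts={f"FAM{i}": "intronic" for i in range(1, 5)},
        te_base_mean=te_base_mean, gene_base_mean=200.0,
        retention_fraction=retention_fraction, n_samples_per_tissue=3,
        n_tissues=1, frag_reads_per_sample=40_000, seed=seed,
    )


def _corrected_counts(cfg: SimConfig, ann, truth,
                      index: KmerIndex) -> tuple[pd.DataFrame, pd.DataFrame]:
    locus_ids = [t.locus_id for t in ann.te_loci]
    with tempfile.TemporaryDirectory() as d:
        simulate_alignments(truth, ann, cfg, out_dir=d, kmer_index=index)
        em_cols, tables = {}, {}
        for s in truth.sample_ids:
            sam = Path(d) / f"{s}.sam"
            asets, _ = ingest_alignments(sam, ann.te_loci, ann.genes)
            em_cols[s] = em_assign(asets, locus_ids=locus_ids)
            tables[s] = intron_counts(sam, ann.te_loci)
    em = pd.DataFrame(em_cols)
    corrected, _ = apply_counting_policy(em, ann.te_loci, tables,
                                         read_len=cfg.read_len)
    return em, corrected


def retention_only_experiment(seed: int = 0) -> dict:
    """Read-through only (no autonomous TE transcription): corrected counts
    should collapse to ~0."""
    cfg = _retention_config(_seed(seed, 5), te_base_mean=1e-3,
                            retention_fraction=0.5)
    cfg = dataclasses.replace(cfg, frag_reads_per_sample=100_000,
                              n_samples_per_tissue=4)
    ann = simulate_annotation(cfg)
    index = KmerIndex(ann.genome, cfg.read_len)
    truth = simulate_expression(cfg, ann)
    em, corrected = _corrected_counts(cfg, ann, truth, index)
    raw = em.to_numpy().ravel()
    cor = corrected.to_numpy().ravel()
    mask = raw > 0
    frac_small = float((cor[mask] < 0.05 * raw[mask]).mean())
    return {
        "fraction_below_5pct_of_raw": frac_small,
        "median_raw_count": float(np.median(raw[mask])),
        "n_cells": int(mask.sum()),
    }


def retention_recovery_experiment(seed: int = 0, n_seeds: int = 50) -> dict:
    """Autonomous expression x plus read-through: mean corrected count should
    recover x."""
    cfg0 = _retention_config(0, te_base_mean=50.0, retention_fraction=0.4)
    ann = simulate_annotation(cfg0)
    index = KmerIndex(ann.genome, cfg0.read_len)
    corrected_totals, true_totals = [], []
    for i in range(n_seeds):
        cfg = dataclasses.replace(cfg0, seed=_seed(seed, 100 + i),
                                  n_samples_per_tissue=1)
        truth = simulate_expression(cfg, ann)
        _, corrected = _corrected_counts(cfg, ann, truth, index)
        corrected_totals.append(corrected.to_numpy().sum())
        true_totals.append(truth.locus_fragment_counts.sum())
    mean_cor = float(np.mean(corrected_totals))
    mean_true = float(np.mean(true_totals))
    return {
        "mean_corrected": mean_cor,
        "mean_autonomous": mean_true,
        "relative_error": (mean_cor - mean_true) / mean_true,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 6. DEGES recovery
# ---------------------------------------------------------------------------

def deges_experiment(seed: int = 0, n_genes: int = 5000,
                     n_samples: int = 12) -> dict:
    rng = np.random.default_rng(_seed(seed, 6))
    depths = np.exp(rng.uniform(-0.7, 0.7, size=n_samples))
    groups = np.repeat([0, 1], n_samples // 2)
    counts, _ = simulate_depth_counts(
        n_genes, depths, groups, de_fraction=0.3, de_fold=4.0,
        nb_dispersion=20.0, seed=_seed(seed, 7))
    df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(n_samples)])
    meta = pd.Series(groups, index=df.columns)

    def rescale(x):
        return x / np.exp(np.log(x).mean())

    truth = rescale(pd.Series(depths, index=df.columns))
    one = rescale(median_ratio_size_factors(df).factors)
    two = rescale(deges_size_factors(df, meta).factors)
    return {
        "one_step_max_rel_error": float(np.abs(one / truth - 1).max()),
        "two_step_max_rel_error": float(np.abs(two / truth - 1).max()),
        "two_step_closer": bool(
            np.abs(np.log(two / truth)).max()
            < np.abs(np.log(one / truth)).max()),
    }


# ---------------------------------------------------------------------------
# 7. Tissue clustering
# ---------------------------------------------------------------------------

def clustering_experiment(seed: int = 0) -> dict:
    """Three tissues with tissue-specific intergenic TE loci: UPGMA on the
    top-150 variance loci should reproduce the tissue grouping exactly."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_length=90_000, n_genes=8, exons_per_gene=2,
        n_te_families=6, loci_per_family=32, family_divergence=0.15,
        family_contexts={f"FAM{i}": "intergenic" for i in range(1, 7)},
        te_base_mean=30.0, gene_base_mean=100.0, retention_fraction=0.0,
        tissue_specificity=1.5, n_samples_per_tissue=12, n_tissues=3,
        frag_reads_per_sample=12_000, seed=_seed(seed, 8),
    )
    ann = simulate_annotation(cfg)
    truth = simulate_expression(cfg, ann)
    locus_counts = pd.DataFrame(truth.locus_fragment_counts,
                                index=truth.locus_ids,
                                columns=truth.sample_ids)
    gene_counts = pd.DataFrame(truth.gene_fragment_counts,
                               index=truth.gene_ids,
                               columns=truth.sample_ids)
    tissue = pd.Series(truth.sample_tissue)
    sf = median_ratio_size_factors(gene_counts)
    log2 = log_transform(normalize_counts(locus_counts, sf))
    chroms = pd.Series({t.locus_id: t.chrom for t in ann.te_loci})
    top = cluster_mod.select_top_variance(log2, n=150, feature_chroms=chroms,
                                          raw_counts=locus_counts)
    res = cluster_mod.cluster_samples(log2.loc[top], tissue, k=3)
    baseline = cluster_mod.permutation_baseline(tissue, reps=100,
                                                seed=_seed(seed, 9))
    return {
        "nmi": res.nmi,
        "baseline_shuffle_mean_nmi": baseline["shuffle"],
        "baseline_resample_mean_nmi": baseline["resample"],
        "n_loci_used": len(top),
    }


# ---------------------------------------------------------------------------
# 8. Consensus network recovery
# ---------------------------------------------------------------------------

def network_experiment(seed: int = 0, n_samples: int = 50,
                       block_size: int = 150, within_cor: float = 0.8) -> dict:
    from sklearn.metrics import rand_score

    rng = np.random.default_rng(_seed(seed, 10))
    load, noise = math.sqrt(within_cor), math.sqrt(1 - within_cor)
    matrices = {}
    factors = {}
    ids = [f"b{b}_f{i}" for b in (1, 2) for i in range(block_size)]
    truth = pd.Series([1] * block_size + [2] * block_size, index=ids)
    for tissue in ("t1", "t2"):
        f1 = rng.standard_normal(n_samples)
        f2 = rng.standard_normal(n_samples)
        rows = [load * f1 + noise * rng.standard_normal(n_samples)
                for _ in range(block_size)]
        rows += [load * f2 + noise * rng.standard_normal(n_samples)
                 for _ in range(block_size)]
        matrices[tissue] = pd.DataFrame(
            rows, index=ids, columns=[f"s{i}" for i in range(n_samples)])
        factors[tissue] = (f1, f2)
    mods = network_mod.fit_modules(matrices, beta=14, min_module_size=30)
    ri = float(rand_score(truth, mods.assignments))
    cors = []
    for tissue, (f1, f2) in factors.items():
        eig = mods.eigengenes[tissue]
        for mod in eig.columns:
            members = mods.assignments.index[mods.assignments == mod]
            block = truth.loc[members].mode()[0]
            f = f1 if block == 1 else f2
            cors.append(abs(np.corrcoef(eig[mod], f)[0, 1]))
    return {
        "rand_index": ri,
        "min_eigengene_factor_abs_cor": float(min(cors)) if cors else 0.0,
        "n_modules": int(mods.assignments.max()),
    }


# ---------------------------------------------------------------------------
# 9. Screen calibration
# ---------------------------------------------------------------------------

def family_screen_calibration(seed: int = 0, n_null: int = 1000,
                              n_planted: int = 50, n_samples: int = 50,
                              planted_r: float = 0.6, reps: int = 10) -> dict:
    """Empirical FDR and power of the family screen at q < 0.05."""
    fdrs, powers = [], []
    for rep in range(reps):
        rng = np.random.default_rng(_seed(seed, 11 + rep))
        samples = [f"s{i}" for i in range(n_samples)]
        kz_rows, te_rows = {}, {}
        planted = set()
        for i in range(n_planted):
            x, f = rng.standard_normal((2, n_samples))
            shared = math.sqrt(planted_r) * f
            noise = math.sqrt(1 - planted_r)
            kz_rows[f"KZp{i}"] = shared + noise * rng.standard_normal(n_samples)
            te_rows[f"TEp{i}"] = shared + noise * rng.standard_normal(n_samples)
            planted.add((f"KZp{i}", f"TEp{i}"))
        n_side = int(math.isqrt(n_null))
        for i in range(n_side):
            kz_rows[f"KZn{i}"] = rng.standard_normal(n_samples)
        for i in range(math.ceil(n_null / n_side)):
            te_rows[f"TEn{i}"] = rng.standard_normal(n_samples)
        kz = pd.DataFrame(kz_rows, index=samples).T
        te = pd.DataFrame(te_rows, index=samples).T
        results, _ = screens_mod.pairwise_family_screen({"t": kz}, {"t": te})
        hits = {(r.predictor, r.response) for r in results if r.q_value < 0.05}
        # only planted pairs and pure-null pairs enter the tally (the
        # cross pairs KZp x TEn etc. are neither planted nor pure null)
        null_hits = [h for h in hits
                     if h[0].startswith("KZn") and h[1].startswith("TEn")]
        planted_hits = hits & planted
        relevant = len(null_hits) + len(planted_hits)
        fdrs.append(len(null_hits) / max(relevant, 1))
        powers.append(len(planted_hits) / n_planted)
    return {
        "empirical_fdr": float(np.mean(fdrs)),
        "power": float(np.mean(powers)),
        "nominal_q": 0.05,
        "reps": reps,
    }


def aicc_selection_experiment(seed: int = 0, n: int = 100,
                              runs: int = 30) -> dict:
    """All-subsets AICc recovery of the full active covariate set when every
    optional covariate carries signal (residual SD = half the signal SD)."""
    rng = np.random.default_rng(_seed(seed, 30))
    exact = 0
    for _ in range(runs):
        gene = rng.standard_normal(n)
        batch = rng.integers(0, 3, n)
        cov = pd.DataFrame({
            "batch=1": (batch == 1).astype(float),
            "batch=2": (batch == 2).astype(float),
            "libsize": rng.standard_normal(n),
            "n1": rng.standard_normal(n),
            "radiation": rng.integers(0, 2, n).astype(float),
        }, index=range(n))
        signal = (0.8 * gene + 0.9 * cov["libsize"].to_numpy()
                  + 1.2 * (batch == 1) - 1.0 * (batch == 2)
                  + 0.7 * cov["n1"].to_numpy()
                  + 1.0 * cov["radiation"].to_numpy())
        y = signal + rng.standard_normal(n) * (signal.std() / 2)
        _, _, _, sel = screens_mod.fit_l1hs_gene_model(y, gene, cov)
        exact += set(sel) == {"batch", "libsize", "n1", "radiation"}
    return {"recovery_rate": exact / runs, "runs": runs, "n": n}


# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "pair_universe": lambda seed: pair_universe(),
    "correction_units": correction_units,
    "em_oracle": em_oracle_equivalence,
    "mappability_bias": mappability_bias_experiment,
    "retention_only": retention_only_experiment,
    "retention_recovery": retention_recovery_experiment,
    "deges": deges_experiment,
    "clustering": clustering_experiment,
    "network": network_experiment,
    "family_screen": family_screen_calibration,
    "aicc": aicc_selection_experiment,
}


def run_all(seed: int = 0) -> dict:
    return {name: fn(seed) for name, fn in EXPERIMENTS.items()}
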