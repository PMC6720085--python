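"""Synthetic genomes, annotations, expression and multi-mapped alignments.

The generator builds a toy genome in which every downstream stage of the
pipeline can be validated against known ground truth:

* TE families are random consensus sequences; loci are copies mutated at a
  configurable per-base divergence, so low divergence yields controlled
  multi-mappability and high divergence yields effectively unique loci.
* Loci are placed in all three genomic contexts (intronic, exonic,
  intergenic); intronic loci sit centrally inside an intron, with flanking
  segments half the element length (see docs/methods.md for why that keeps
  the three boundary-overlap depth estimators commensurate).
* Expression follows a log-linear latent-factor model: planted factors with
  group loadings create the co-expression structure (TE core module with
  positively loading KZFP-like genes and negatively loading immune-like
  genes; intronic-TE factor anti-correlated with mitochondrial-like genes),
  and a per-(feature, tissue) effect creates tissue specificity.
* Counts are Negative-Binomial (mean mu, variance mu + mu^2/dispersion).
* Pre-mRNA / retained-intron read-through is emulated by fragments tiling
  the full intron uniformly, covering any embedded TE.
* Fragments are single-end reads of ``read_len`` bases, reported at every
  genomic position matching their sequence exactly (forward or reverse
  complement), with the alignment multiplicity written as an NH tag,
  capped at 200.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotations import GeneModel, TELocus, classify_te_context

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PlacementError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    ``family_divergence`` is the per-base substitution probability applied to
    each locus copy of the family consensus. ``retention_fraction`` (rho) is
    the expected read-through fragment mass per gene relative to its mature
    mRNA expression; the source study gives no quantitative value, so the
    default is a documented assumption, not a biological claim.
    """

    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_genes: int = 8
    exons_per_gene: int = 3
    exon_len: int = 400
    intron_len: int = 600
    n_te_families: int = 4
    loci_per_family: int = 6
    te_len: int = 300
    family_names: list[str] | None = None
    family_lengths: dict[str, int] = field(default_factory=dict)
    family_classes: dict[str, str] = field(default_factory=dict)
    family_divergence: float = 0.10
    divergence_gradient: bool = False
    context_mix: dict[str, float] = field(default_factory=lambda: {
        "intergenic": 0.5, "intronic": 0.35, "exonic": 0.15})
    family_contexts: dict[str, str] = field(default_factory=dict)
    read_len: int = 48
    frag_reads_per_sample: int = 30_000
    retention_fraction: float = 0.3
    n_samples_per_tissue: int = 10
    n_tissues: int = 3
    tissue_specificity: float = 0.0
    gene_base_mean: float = 100.0
    te_base_mean: float = 20.0
    gene_groups: dict[str, int] = field(default_factory=dict)
    factor_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    nb_dispersion: float = 10.0
    multimap_cap: int = 200
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "n_chromosomes", "chrom_length", "n_genes", "exons_per_gene",
            "exon_len", "intron_len", "n_te_families", "loci_per_family",
            "te_len", "read_len", "frag_reads_per_sample",
            "n_samples_per_tissue", "n_tissues",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.retention_fraction <= 1.0):
            raise ValueError("retention_fraction must be in [0, 1]")
        if not (0.0 <= self.family_divergence <= 1.0):
            raise ValueError("family_divergence must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for group, loads in self.factor_loadings.items():
            for f, v in loads.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite loading {group}/{f}")

    @property
    def families(self) -> list[str]:
        if self.family_names is not None:
            return list(self.family_names)
        return [f"FAM{i + 1}" for i in range(self.n_te_families)]

    def family_len(self, fam: str) -> int:
        return int(self.family_lengths.get(fam, self.te_len))


@dataclass
class Annotation:
    """Toy genome with its gene models and contexted TE loci."""

    genome: dict[str, str]
    genes: list[GeneModel]
    te_loci: list[TELocus]
    family_consensus: dict[str, str]

    def locus_sequences(self) -> dict[str, str]:
        return {
            t.locus_id: self.genome[t.chrom][t.start:t.end] for t in self.te_loci
        }


@dataclass
class GroundTruth:
    """Planted expression state with the NB-drawn fragment counts."""

    sample_ids: list[str]
    sample_tissue: dict[str, str]
    true_locus_abundance: "np.ndarray"  # loci x samples expected fragments
    true_gene_abundance: "np.ndarray"   # genes x samples expected fragments
    locus_fragment_counts: "np.ndarray"  # NB-drawn, loci x samples
    gene_fragment_counts: "np.ndarray"   # NB-drawn, genes x samples
    retention_reads: "np.ndarray"        # genes x samples (summed over introns)
    retention_by_intron: "np.ndarray"    # genes x introns x samples
    factor_values: "np.ndarray"          # samples x factors
    factor_names: list[str]
    locus_ids: list[str]
    gene_ids: list[str]
    module_membership: dict[str, str]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < divergence
    # substitute with one of the three other bases
    subs = rng.integers(1, 4, size=int(hit.sum()))
    idx = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(idx + subs) % 4]
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> Annotation:
    """Lay out genes, intergenic gaps and TE loci on random chromosomes.

    Raises :class:`PlacementError` when the requested features do not fit
    (too little chromosome, or more contexted loci than available slots).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    families = config.families
    # per-locus plan: (family, copy index, context, divergence)
    plan: list[tuple[str, int, str, float]] = []
    mix_items = [(c, f) for c, f in config.context_mix.items() if f > 0]
    total_frac = sum(f for _, f in mix_items)
    cum = np.cumsum([f / total_frac for _, f in mix_items])
    for fam in families:
        for i in range(config.loci_per_family):
            fixed = config.family_contexts.get(fam)
            if fixed is not None:
                ctx = fixed
            else:
                u = (i + 0.5) / config.loci_per_family
                ctx = mix_items[int(np.searchsorted(cum, u))][0]
            if config.divergence_gradient and config.loci_per_family > 1:
                div = config.family_divergence * i / (config.loci_per_family - 1)
            else:
                div = config.family_divergence
            plan.append((fam, i, ctx, div))

    n_ctx = {c: sum(1 for p in plan if p[2] == c) for c in
             ("intronic", "exonic", "intergenic")}

    n_introns_per_gene = config.exons_per_gene - 1
    intron_slots = config.n_genes * n_introns_per_gene
    exon_slots = config.n_genes * config.exons_per_gene
    if n_ctx["intronic"] > intron_slots:
        raise PlacementError(
            f"{n_ctx['intronic']} intronic loci requested, {intron_slots} intron slots")
    if n_ctx["exonic"] > exon_slots:
        raise PlacementError(
            f"{n_ctx['exonic']} exonic loci requested, {exon_slots} exon slots")

    max_te = max([config.family_len(f) for f in families])
    if n_ctx["intronic"] and config.intron_len <= max(
            config.family_len(p[0]) for p in plan if p[2] == "intronic"):
        raise PlacementError("intron shorter than an intronic TE")
    if n_ctx["exonic"] and config.exon_len < 2 + max(
            config.family_len(p[0]) for p in plan if p[2] == "exonic"):
        raise PlacementError("exon too short to contain an exonic TE")

    per_gap = max(1, math.ceil(n_ctx["intergenic"] / config.n_genes))
    gap_len = 1100 + per_gap * (max_te + 100) + 1100
    gene_len = (config.exons_per_gene * config.exon_len
                + n_introns_per_gene * config.intron_len)
    margin = 300

    # lay out gene+gap blocks across chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    gene_coords: list[tuple[str, int]] = []  # (chrom, gene start)
    gap_coords: list[tuple[str, int, int]] = []
    ci, cursor = 0, margin
    for _ in range(config.n_genes):
        while cursor + gene_len + gap_len + margin > config.chrom_length:
            ci += 1
            cursor = margin
            if ci >= config.n_chromosomes:
                raise PlacementError(
                    f"cannot fit {config.n_genes} genes of {gene_len} bases plus "
                    f"{gap_len}-base gaps on {config.n_chromosomes} chromosomes "
                    f"of {config.chrom_length} bases")
        gene_coords.append((chrom_names[ci], cursor))
        gap_coords.append((chrom_names[ci], cursor + gene_len,
                           cursor + gene_len + gap_len))
        cursor += gene_len + gap_len

    genes: list[GeneModel] = []
    intron_ivs: list[tuple[str, int, int]] = []
    exon_ivs: list[tuple[str, int, int]] = []
    for gi, (chrom, gs) in enumerate(gene_coords):
        exons = []
        pos = gs
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_len))
            pos += config.exon_len + config.intron_len
        gene = GeneModel(gene_id=f"G{gi + 1}", chrom=chrom,
                         strand="+" if gi % 2 == 0 else "-",
                         exons=tuple(exons))
        genes.append(gene)
        intron_ivs.extend((chrom, s, e) for (s, e) in gene.introns)
        exon_ivs.extend((chrom, s, e) for (s, e) in gene.exons)

    # intergenic slots within gaps, >= 1000 bases from both gene boundaries
    inter_slots: list[tuple[str, int]] = []
    for chrom, g0, g1 in gap_coords:
        p = g0 + 1100
        for _ in range(per_gap):
            inter_slots.append((chrom, p))
            p += max_te + 100

    consensus = {f: _random_seq(rng, config.family_len(f)) for f in families}

    genome = {c: np.frombuffer(_random_seq(rng, config.chrom_length).encode(),
                               dtype="S1").copy()
              for c in chrom_names}

    te_loci: list[TELocus] = []
    slot_i = {"intronic": 0, "exonic": 0, "intergenic": 0}
    for fam, i, ctx, div in plan:
        L = config.family_len(fam)
        if ctx == "intronic":
            chrom, s, e = intron_ivs[slot_i[ctx]]
            start = s + (e - s - L) // 2
        elif ctx == "exonic":
            chrom, s, e = exon_ivs[slot_i[ctx]]
            start = s + (e - s - L) // 2
        else:
            chrom, start = inter_slots[slot_i[ctx]]
        slot_i[ctx] += 1
        seq = _mutate(rng, consensus[fam], div)
        genome[chrom][start:start + L] = np.frombuffer(seq.encode(), dtype="S1")
        te_loci.append(TELocus(
            locus_id=f"{fam}_dup{i + 1}", chrom=chrom, start=start,
            end=start + L, strand=str(rng.choice(["+", "-"])), family=fam,
            te_class=config.family_classes.get(fam, "LINE"),
        ))

    genome_str = {c: a.tobytes().decode() for c, a in genome.items()}
    te_loci = classify_te_context(te_loci, genes)
    return Annotation(genome=genome_str, genes=genes, te_loci=te_loci,
                      family_consensus=consensus)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB with mean mu and variance mu + mu^2/dispersion (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    lam = np.where(mean > 0,
                   rng.gamma(dispersion, np.maximum(mean, 1e-300) / dispersion),
                   0.0)
    return rng.poisson(lam)


def simulate_expression(config: SimConfig, ann: Annotation) -> GroundTruth:
    """Plant factor structure and draw per-sample fragment counts.

    Expected abundance is ``exp(log base + sum_f loading * factor +
    tissue effect)``, rescaled per sample so expected library size (gene
    mRNA + read-through + autonomous TE fragments) equals
    ``frag_reads_per_sample``; counts are then Negative-Binomial.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)

    sample_ids, tissues = [], {}
    for t in range(config.n_tissues):
        for i in range(config.n_samples_per_tissue):
            sid = f"T{t + 1}S{i + 1}"
            sample_ids.append(sid)
            tissues[sid] = f"T{t + 1}"
    n_s = len(sample_ids)
    tissue_idx = np.array([int(tissues[s][1:]) - 1 for s in sample_ids])

    gene_ids = [g.gene_id for g in ann.genes]
    locus_ids = [t.locus_id for t in ann.te_loci]

    # feature -> group
    gene_group: dict[str, str] = {}
    gi = 0
    for grp, n in config.gene_groups.items():
        for _ in range(n):
            if gi >= len(gene_ids):
                raise ValueError("gene_groups exceeds n_genes")
            gene_group[gene_ids[gi]] = grp
            gi += 1
    for g in gene_ids[gi:]:
        gene_group[g] = "background"
    locus_group = {t.locus_id: t.family for t in ann.te_loci}

    factor_names = sorted({
        f for loads in config.factor_loadings.values() for f in loads
    })
    factors = rng.standard_normal((n_s, len(factor_names)))

    def log_mean(feature_ids, groups, base):
        lm = np.full((len(feature_ids), n_s), math.log(base))
        for i, fid in enumerate(feature_ids):
            loads = config.factor_loadings.get(groups[fid], {})
            for fname, v in loads.items():
                lm[i] += v * factors[:, factor_names.index(fname)]
        if config.tissue_specificity > 0:
            eff = rng.normal(0.0, config.tissue_specificity,
                             (len(feature_ids), config.n_tissues))
            lm += eff[:, tissue_idx]
        return lm

    gene_mu = np.exp(log_mean(gene_ids, gene_group, config.gene_base_mean))
    locus_mu = np.exp(log_mean(locus_ids, locus_group, config.te_base_mean))

    rho = config.retention_fraction
    totals = (gene_mu.sum(axis=0) * (1.0 + rho) + locus_mu.sum(axis=0))
    # one global scale (not per sample) so the mean expected library size hits
    # the target while planted between-feature correlations stay intact
    scale = config.frag_reads_per_sample / totals.mean()
    gene_mu *= scale
    locus_mu *= scale

    n_introns = config.exons_per_gene - 1
    ret_mu = np.zeros((len(gene_ids), max(n_introns, 1), n_s))
    if n_introns > 0 and rho > 0:
        per_intron = rho * gene_mu / n_introns
        for j in range(n_introns):
            ret_mu[:, j, :] = per_intron

    gene_counts = _nb_draw(rng, gene_mu, config.nb_dispersion)
    locus_counts = _nb_draw(rng, locus_mu, config.nb_dispersion)
    ret_counts = _nb_draw(rng, ret_mu, config.nb_dispersion)

    module = {}
    for fid, grp in {**gene_group, **locus_group}.items():
        loads = config.factor_loadings.get(grp, {})
        if loads:
            module[fid] = max(loads, key=lambda f: abs(loads[f]))
    return GroundTruth(
        sample_ids=sample_ids, sample_tissue=tissues,
        true_locus_abundance=locus_mu, true_gene_abundance=gene_mu,
        locus_fragment_counts=locus_counts, gene_fragment_counts=gene_counts,
        retention_reads=ret_counts.sum(axis=1), retention_by_intron=ret_counts,
        factor_values=factors, factor_names=factor_names,
        locus_ids=locus_ids, gene_ids=gene_ids, module_membership=module,
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedFragment:
    fragment_id: str
    origin: str          # locus_id, gene_id, or "retention:<gene>"
    chrom: str
    start: int           # true sampling position
    alignments: tuple[tuple[str, int, bool], ...]  # (chrom, pos, is_revcomp)
    multiplicity: int


class KmerIndex:
    """Exact-match index of all read-length windows of the genome."""

    def __init__(self, genome: dict[str, str], k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for p in range(len(seq) - k + 1):
                self.index.setdefault(seq[p:p + k], []).append((chrom, p))

    def hits(self, seq: str) -> list[tuple[str, int, bool]]:
        fwd = [(c, p, False) for c, p in self.index.get(seq, ())]
        rc = revcomp(seq)
        if rc != seq:
            fwd += [(c, p, True) for c, p in self.index.get(rc, ())]
        return sorted(fwd)


def simulate_alignments(
    truth: GroundTruth,
    ann: Annotation,
    config: SimConfig,
    out_dir=None,
    kmer_index: KmerIndex | None = None,
) -> dict[str, list[SimulatedFragment]]:
    """Place the NB-drawn fragments and discover all exact-match alignments.

    Autonomous TE fragments are sampled uniformly from the element's own
    transcript, so they lie fully inside the locus; read-through fragments
    start uniformly within their intron and never leave it; gene mRNA
    fragments lie fully within single exons.  Every fragment is reported at
    each genomic position matching its sequence with 0 mismatches, on either
    strand, with the multiplicity capped at ``multimap_cap``.  Written SAM is
    byte-identical for a fixed seed.
    """
    rl = config.read_len
    index = kmer_index or KmerIndex(ann.genome, rl)
    genome = ann.genome
    loci = {t.locus_id: t for t in ann.te_loci}

    chrom_len = {c: len(s) for c, s in genome.items()}
    out: dict[str, list[SimulatedFragment]] = {}
    for si, sample in enumerate(truth.sample_ids):
        rng = np.random.default_rng((config.seed + 100_003 * (si + 1)) % 2**31)
        frags: list[SimulatedFragment] = []
        serial = 0

        def emit(origin, chrom, start):
            nonlocal serial
            seq = genome[chrom][start:start + rl]
            hits = index.hits(seq)
            mult = len(hits)
            if mult > config.multimap_cap:
                hits = hits[:config.multimap_cap]
                mult = config.multimap_cap
            serial += 1
            frags.append(SimulatedFragment(
                fragment_id=f"{sample}.f{serial}", origin=origin, chrom=chrom,
                start=start, alignments=tuple(hits), multiplicity=mult))

        for li, lid in enumerate(truth.locus_ids):
            n = int(truth.locus_fragment_counts[li, si])
            if n == 0:
                continue
            t = loci[lid]
            hi = min(t.end - rl + 1, chrom_len[t.chrom] - rl + 1)
            if hi <= t.start:
                hi = t.start + 1  # locus shorter than a read: anchor at start
            starts = rng.integers(t.start, hi, size=n)
            for st in starts:
                emit(lid, t.chrom, int(st))

        for gi, gid in enumerate(truth.gene_ids):
            gene = ann.genes[gi]
            n = int(truth.gene_fragment_counts[gi, si])
            if n > 0:
                # positions fully inside single exons
                spans = [(s, e - rl) for (s, e) in gene.exons if e - s >= rl]
                weights = np.array([e - s + 1 for s, e in spans], dtype=float)
                choice = rng.choice(len(spans), size=n, p=weights / weights.sum())
                for c in choice:
                    s, e = spans[c]
                    emit(gid, gene.chrom, int(rng.integers(s, e + 1)))
            introns = gene.introns
            for j, (is_, ie) in enumerate(introns):
                nr = int(truth.retention_by_intron[gi, j, si])
                if nr == 0 or ie - is_ < rl:
                    continue
                starts = rng.integers(is_, ie - rl + 1, size=nr)
                for st in starts:
                    emit(f"retention:{gid}", gene.chrom, int(st))
        out[sample] = frags
        if out_dir is not None:
            write_sam(frags, genome, rl, f"{out_dir}/{sample}.sam", rng=rng)
    return out


def write_sam(fragments, genome: dict[str, str], read_len: int, path,
              rng: np.random.Generator | None = None) -> None:
    """Write one SAM record per alignment; NH holds the multiplicity.

    FLAG is 0/16 chosen uniformly per fragment for the primary record (the
    library is unstranded); secondary records add 0x100.  SEQ is the genome
    substring at the record's own position, so every record is consistent
    with its coordinates.
    """
    rng = rng or np.random.default_rng(0)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(genome):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}\n")
        for fr in fragments:
            rev = bool(rng.integers(0, 2))
            for ai, (chrom, pos, is_rc) in enumerate(fr.alignments):
                flag = (16 if rev != is_rc else 0) | (256 if ai > 0 else 0)
                seq = genome[chrom][pos:pos + read_len]
                fh.write("\t".join([
                    fr.fragment_id, str(flag), chrom, str(pos + 1), "255",
                    f"{read_len}M", "*", "0", "0", seq, "*",
                    f"NH:i:{fr.multiplicity}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Mappability
# ---------------------------------------------------------------------------

def kmer_mappability(genome: dict[str, str], te_loci: list[TELocus],
                     k: int = 48) -> dict[str, int]:
    """Per-locus count of uniquely mappable start positions.

    A position is uniquely mappable iff its k-mer, counting forward and
    reverse-complement occurrences genome-wide together, occurs exactly once.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    for chrom, seq in genome.items():
        if k > len(seq):
            raise ValueError(f"k exceeds length of {chrom}")
    counts: dict[str, int] = {}
    for seq in genome.values():
        for p in range(len(seq) - k + 1):
            kmer = seq[p:p + k]
            rc = revcomp(kmer)
            canon = min(kmer, rc)
            counts[canon] = counts.get(canon, 0) + 1
    out = {}
    for t in te_loci:
        seq = genome[t.chrom]
        hi = min(t.end, len(seq) - k + 1)
        n = 0
        for p in range(t.start, hi):
            kmer = seq[p:p + k]
            canon = min(kmer, revcomp(kmer))
            if counts[canon] == 1:
                n += 1
        out[t.locus_id] = n
    return out


# ---------------------------------------------------------------------------
# Depth-only count matrices (normalization validation)
# ---------------------------------------------------------------------------

def simulate_depth_counts(
    n_genes: int,
    depths: np.ndarray,
    group_of_sample: np.ndarray,
    de_fraction: float = 0.3,
    de_fold: float = 4.0,
    de_group: int = 0,
    base_mean_log_sd: float = 1.0,
    nb_dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts whose between-sample variation is sequencing depth plus a
    planted fraction of differentially expressed genes.

    Returns ``(counts, is_de)`` with counts shaped genes x samples. The known
    ``depths`` are the ground truth that size-factor estimation must recover.
    """
    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=float)
    group_of_sample = np.asarray(group_of_sample)
    base = np.exp(rng.normal(math.log(100.0), base_mean_log_sd, n_genes))
    is_de = rng.random(n_genes) < de_fraction
    mu = np.outer(base, depths)
    mu[np.ix_(is_de, group_of_sample == de_group)] *= de_fold
    return _nb_draw(rng, mu, nb_dispersion), is_de
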