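"""Multi-mapped fragment assignment to TE loci by expectation-maximization.

The model is a multinomial mixture over loci: fragment *r* carries a
candidate set ``A_r`` of loci its alignments overlap; with locus abundances
``pi`` the E-step weights are ``w_{r,l} = pi_l / sum_{l' in A_r} pi_{l'}``
and the M-step sets ``pi_l`` proportional to ``sum_r w_{r,l}``.  Reported
counts are the summed weights, so total EM mass equals the ingested
fragment count exactly.  Unique-only mode reproduces single-best-alignment
counting: fragments with more than one reported alignment are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

from .annotations import GeneModel, L1HS5pRegion, TELocus


@dataclass(frozen=True)
class CandidateAlignment:
    locus_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class AlignmentSet:
    """Per-fragment candidate TE alignments with alignment multiplicity."""

    fragment_id: str
    candidates: tuple[CandidateAlignment, ...]
    multiplicity: int

    @property
    def candidate_loci(self) -> frozenset[str]:
        return frozenset(c.locus_id for c in self.candidates)


@dataclass
class IngestStats:
    fragments_seen: int = 0
    fragments_ingested: int = 0
    dropped_multimap: int = 0
    dropped_exonic_only: int = 0
    dropped_no_te: int = 0
    malformed: int = 0


def _trees(te_loci: list[TELocus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in te_loci:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.locus_id)
    return trees


def _exon_trees(gene_models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        for (s, e) in g.exons:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e)
    return trees


def ingest_alignments(
    sam_path,
    te_loci: list[TELocus],
    gene_models: list[GeneModel],
    multimap_cap: int = 200,
) -> tuple[list[AlignmentSet], IngestStats]:
    """Group SAM records by fragment and intersect with the TE annotation.

    An alignment is a candidate iff it overlaps a TE locus by >= 1 base;
    alignments overlapping a non-TE exon are discarded. Fragments whose every
    alignment is exonic-non-TE (or TE-free) are excluded, and fragments with
    multiplicity above ``multimap_cap`` are dropped and tallied.  A missing
    NH tag means a single reported alignment.
    """
    te_trees = _trees(te_loci)
    ex_trees = _exon_trees(gene_models)
    stats_ = IngestStats()

    by_frag: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                stats_.malformed += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            by_frag.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start, rec.reference_end, nh))

    out: list[AlignmentSet] = []
    for frag_id in by_frag:
        alns = by_frag[frag_id]
        stats_.fragments_seen += 1
        mult = max(max(nh for *_, nh in alns), len(alns))
        if mult > multimap_cap:
            stats_.dropped_multimap += 1
            continue
        cands: dict[str, CandidateAlignment] = {}
        any_exonic = False
        for chrom, start, end, _ in alns:
            hits = te_trees.get(chrom, IntervalTree()).overlap(start, end) \
                if chrom in te_trees else set()
            if hits:
                for h in hits:
                    cands.setdefault(h.data, CandidateAlignment(
                        locus_id=h.data, chrom=chrom, start=start, end=end))
            elif chrom in ex_trees and ex_trees[chrom].overlap(start, end):
                any_exonic = True
        if cands:
            stats_.fragments_ingested += 1
            out.append(AlignmentSet(
                fragment_id=frag_id,
                candidates=tuple(cands[k] for k in sorted(cands)),
                multiplicity=mult))
        elif any_exonic:
            stats_.dropped_exonic_only += 1
        else:
            stats_.dropped_no_te += 1
    return out, stats_


@dataclass
class EMResult:
    counts: pd.Series
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


def em_assign(
    alignment_sets: list[AlignmentSet],
    locus_ids: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    return_stats: bool = False,
) -> pd.Series | EMResult:
    """EM counts per locus; total mass equals the number of fragments.

    ``tol`` is the maximum absolute per-locus count change at which iteration
    stops.  Identical candidate sets are collapsed for speed; the returned
    Series covers ``locus_ids`` (defaults to the union of candidates).
    """
    if not alignment_sets:
        raise ValueError("no alignment sets")
    if locus_ids is None:
        locus_ids = sorted({l for a in alignment_sets for l in a.candidate_loci})
    idx = {l: i for i, l in enumerate(locus_ids)}
    n_loci = len(locus_ids)

    groups: dict[frozenset, int] = {}
    for a in alignment_sets:
        key = a.candidate_loci
        groups[key] = groups.get(key, 0) + 1
    sets = [np.fromiter((idx[l] for l in sorted(k)), dtype=int) for k in groups]
    mult = np.fromiter(groups.values(), dtype=float)
    n_frag = float(mult.sum())

    pi = np.full(n_loci, 1.0 / n_loci)
    counts = n_frag * pi
    trace: list[float] = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        new_counts = np.zeros(n_loci)
        ll = 0.0
        for members, m in zip(sets, mult):
            p = pi[members]
            tot = p.sum()
            if tot <= 0:
                w = np.full(len(members), 1.0 / len(members))
                ll += m * math.log(1.0 / len(members))
            else:
                w = p / tot
                ll += m * math.log(tot)
            new_counts[members] += m * w
        trace.append(ll)
        delta = np.abs(new_counts - counts).max()
        counts = new_counts
        pi = counts / n_frag
        if delta < tol:
            converged = True
            break
    series = pd.Series(counts, index=locus_ids, name="em_count")
    if return_stats:
        return EMResult(counts=series, n_iter=n_iter, loglik_trace=trace,
                        converged=converged)
    return series


def em_weights(alignment_sets: list[AlignmentSet],
               em_counts: pd.Series) -> dict[str, dict[str, float]]:
    """Per-fragment E-step weights at the fitted abundances."""
    pi = em_counts / em_counts.sum() if em_counts.sum() > 0 else em_counts
    out = {}
    for a in alignment_sets:
        loci = sorted(a.candidate_loci)
        p = np.array([pi.get(l, 0.0) for l in loci])
        tot = p.sum()
        w = p / tot if tot > 0 else np.full(len(loci), 1.0 / len(loci))
        out[a.fragment_id] = dict(zip(loci, w))
    return out


def unique_only_counts(
    alignment_sets: list[AlignmentSet],
    locus_ids: list[str] | None = None,
) -> pd.Series:
    """Counts from fragments with a single reported alignment only."""
    if locus_ids is None:
        locus_ids = sorted({l for a in alignment_sets for l in a.candidate_loci})
    counts = pd.Series(0.0, index=locus_ids, name="unique_count")
    for a in alignment_sets:
        if a.multiplicity == 1 and len(a.candidates) == 1:
            lid = a.candidates[0].locus_id
            if lid in counts.index:
                counts[lid] += 1.0
    return counts


def aggregate_family(locus_counts: pd.DataFrame | pd.Series,
                     te_loci: list[TELocus]) -> pd.DataFrame | pd.Series:
    """Family counts as the sum over non-exonic member loci.

    Exonic loci contribute zero (their reads are parts of mature transcripts,
    per the exonic counting policy), so the family total conserves the
    non-exonic locus mass exactly.
    """
    fam = {}
    for t in te_loci:
        if t.family is None:
            raise ValueError(f"{t.locus_id} has no family")
        fam[t.locus_id] = (t.family, t.context == "exonic")
    is_series = isinstance(locus_counts, pd.Series)
    df = locus_counts.to_frame() if is_series else locus_counts
    keep = [lid for lid in df.index if lid in fam and not fam[lid][1]]
    grouped = df.loc[keep].groupby([fam[l][0] for l in keep]).sum()
    families = sorted({f for f, _ in fam.values()})
    grouped = grouped.reindex(families, fill_value=0.0)
    grouped.index.name = "family"
    return grouped.iloc[:, 0] if is_series else grouped


def count_l1hs_5prime(
    alignment_sets: list[AlignmentSet],
    regions: list[L1HS5pRegion],
    te_loci: list[TELocus],
    em_counts: pd.Series,
) -> float:
    """EM-weighted fragment mass over the L1HS 5' regions of a sample.

    Each fragment contributes the fraction of its EM weight carried by
    candidate alignments overlapping a 5' region (region coordinates are
    locus-relative and mapped to the genome through the locus interval).
    """
    import warnings

    if not regions:
        warnings.warn("empty L1HS 5' region set; count is 0")
        return 0.0
    locus_by_id = {t.locus_id: t for t in te_loci}
    genomic = {}
    for r in regions:
        t = locus_by_id[r.locus_id]
        genomic[r.locus_id] = (t.start + r.start, t.start + r.end)
    pi = em_counts / em_counts.sum() if em_counts.sum() > 0 else em_counts

    total = 0.0
    for a in alignment_sets:
        loci = sorted(a.candidate_loci)
        p = np.array([pi.get(l, 0.0) for l in loci])
        tot = p.sum()
        w = p / tot if tot > 0 else np.full(len(loci), 1.0 / len(loci))
        by_locus = dict(zip(loci, w))
        for c in a.candidates:
            span = genomic.get(c.locus_id)
            if span and c.start < span[1] and c.end > span[0]:
                total += by_locus[c.locus_id]
    return total


@dataclass
class MappabilityBias:
    slope: float | None
    correlation: float | None
    p_value: float | None
    n: int
    degenerate: bool = False


def mappability_bias_test(
    locus_counts: pd.DataFrame | pd.Series,
    mappable_lengths: dict[str, int] | pd.Series,
    stat: str = "sum",
) -> MappabilityBias:
    """Correlate log2 locus counts with uniquely-mappable length.

    A significant positive correlation indicates the quantification measures
    mappability rather than transcription (the unique-only failure mode);
    EM-based counts should show no such bias.
    """
    ml = pd.Series(mappable_lengths)
    df = locus_counts.to_frame() if isinstance(locus_counts, pd.Series) else locus_counts
    agg = df.sum(axis=1) if stat == "sum" else df.max(axis=1)
    common = agg.index.intersection(ml.index)
    if len(common) < 10:
        raise ValueError("need >= 10 loci")
    y = np.log2(agg.loc[common].to_numpy(dtype=float) + 1.0)
    x = ml.loc[common].to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0) or np.allclose(x.var(), 0.0):
        return MappabilityBias(None, None, None, len(common), degenerate=True)
    res = stats.linregress(x, y)
    return MappabilityBias(slope=float(res.slope), correlation=float(res.rvalue),
                           p_value=float(res.pvalue), n=len(common))
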