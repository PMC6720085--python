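"""Gene and transposable-element annotation handling.

Coordinates are 0-based half-open internally. GTF is read and written
1-based inclusive; BED in its native 0-based half-open convention.

A TE locus is classified by its genomic context:

* ``exonic``     -- overlaps any exon by >= 1 base (including non-coding genes);
* ``intronic``   -- otherwise, fully inside a gene span (hence inside one intron);
* ``intergenic`` -- outside all genes and >= ``intergenic_distance`` bases away
  from every gene start/end;
* ``proximal``   -- outside all genes but closer than the threshold; excluded
  from intergenic analysis sets.

For an intronic TE the flanking-intron intervals are the portions of the
containing intron to the left and right of the element.  They feed the
read-through correction, which discounts TE counts by flanking read depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

CONTEXTS = ("exonic", "intronic", "intergenic", "proximal")


@dataclass(frozen=True)
class GeneModel:
    """A gene with an ordered, non-overlapping exon structure."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon {s}-{e}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class TELocus:
    """An annotated repeat interval, optionally with genomic context."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    context: str | None = None
    left_intron: tuple[int, int] | None = None
    right_intron: tuple[int, int] | None = None
    dist_to_nearest_gene: int | None = None
    mappable_len: int | None = None
    single_flank: bool = False
    ambiguous_gene: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class L1HS5pRegion:
    """The portion of an L1HS locus aligning to the consensus 5' 300 bases."""

    locus_id: str
    start: int  # locus-relative, 0-based half-open
    end: int
    consensus_offset: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid 5' region interval")
        if self.end - self.start > 300:
            raise ValueError("5' region longer than 300 bases")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_te_context(
    te_loci: list[TELocus],
    gene_models: list[GeneModel],
    intergenic_distance: int = 1000,
) -> list[TELocus]:
    """Assign each TE locus one context label and its flanking introns.

    Loci on chromosomes absent from the gene annotation's namespace are
    dropped with a warning (context is undefined without gene coordinates).
    A TE contained in two overlapping genes is attached to the gene with the
    smaller span and flagged ``ambiguous_gene``.
    """
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    boundaries: dict[str, list[int]] = {}
    for g in gene_models:
        et = exon_trees.setdefault(g.chrom, IntervalTree())
        for (s, e) in g.exons:
            et.addi(s, e, g.gene_id)
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(*g.span, g)
        s, e = g.span
        boundaries.setdefault(g.chrom, []).extend((s, e))

    known_chroms = set(boundaries)
    out: list[TELocus] = []
    dropped = 0
    for te in te_loci:
        if te.chrom not in known_chroms:
            dropped += 1
            continue
        iv = (te.start, te.end)
        if te.chrom in exon_trees and exon_trees[te.chrom].overlap(*iv):
            out.append(replace(te, context="exonic", left_intron=None,
                               right_intron=None, dist_to_nearest_gene=0))
            continue
        containing = [
            g.data for g in gene_trees.get(te.chrom, IntervalTree()).overlap(*iv)
            if g.data.span[0] <= te.start and te.end <= g.data.span[1]
        ]
        if containing:
            gene = min(containing, key=lambda g: (g.span[1] - g.span[0], g.gene_id))
            intron = next(
                (i for i in gene.introns if i[0] <= te.start and te.end <= i[1]), None
            )
            if intron is None:
                # partial gene overlap without exon overlap can only happen for a
                # TE spanning the gene boundary; treat as proximal
                out.append(replace(te, context="proximal", dist_to_nearest_gene=0))
                continue
            left = (intron[0], te.start) if te.start > intron[0] else None
            right = (te.end, intron[1]) if intron[1] > te.end else None
            out.append(replace(
                te, context="intronic", left_intron=left, right_intron=right,
                dist_to_nearest_gene=0, ambiguous_gene=len(containing) > 1,
                single_flank=(left is None) != (right is None),
            ))
            continue
        if gene_trees.get(te.chrom) and gene_trees[te.chrom].overlap(*iv):
            out.append(replace(te, context="proximal", dist_to_nearest_gene=0))
            continue
        dist = min(
            min(abs(te.start - b), abs(te.end - b))
            for b in boundaries[te.chrom]
        )
        ctx = "intergenic" if dist >= intergenic_distance else "proximal"
        out.append(replace(te, context=ctx, dist_to_nearest_gene=dist))
    if dropped:
        warnings.warn(f"dropped {dropped} TE loci on unknown chromosomes")
    return out


def distance_filtered_sets(
    te_loci: list[TELocus],
    thresholds: tuple[int, ...] = (1_000, 10_000, 100_000),
) -> dict[int, list[TELocus]]:
    """Nested intergenic subsets at increasing distance from gene boundaries.

    ``subset(d)`` contains the intergenic loci with distance >= d; for
    d1 <= d2, subset(d2) is a subset of subset(d1).
    """
    for te in te_loci:
        if te.context is None:
            raise ValueError("contexts must be assigned first")
    inter = [t for t in te_loci if t.context == "intergenic"]
    return {
        int(d): [t for t in inter if t.dist_to_nearest_gene >= d]
        for d in thresholds
    }


def l1hs_five_prime_regions(
    locus_sequences: dict[str, str],
    consensus_sequence: str,
    min_identity: float = 0.6,
    min_aligned: int = 50,
) -> list[L1HS5pRegion]:
    """Locate, per locus, the region aligning to the consensus 5' 300 bases.

    Local (Smith-Waterman) alignment with match +1 / mismatch -1 / gap -2 of
    each locus sequence against bases 1-300 of the consensus.  A region is
    emitted iff the best local alignment spans >= ``min_aligned`` aligned bases
    at >= ``min_identity`` identity.  Full-length elements yield their first
    ~300 bases; 5'-truncated copies yield nothing.
    """
    from Bio import Align

    if len(consensus_sequence) < 300:
        raise ValueError("consensus shorter than 300 bases")
    head = consensus_sequence[:300].upper()

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2

    regions: list[L1HS5pRegion] = []
    for locus_id, seq in locus_sequences.items():
        if not seq:
            raise ValueError(f"{locus_id}: empty sequence")
        seq = seq.upper()
        alns = aligner.align(seq, head)
        if len(alns) == 0:
            continue
        aln = alns[0]
        t_blocks, q_blocks = aln.aligned
        matches = 0
        aligned = 0
        for (ts, te_), (qs, qe) in zip(t_blocks, q_blocks):
            aligned += te_ - ts
            matches += sum(a == b for a, b in zip(seq[ts:te_], head[qs:qe]))
        if aligned < min_aligned or matches / aligned < min_identity:
            continue
        t_start = int(t_blocks[0][0])
        t_end = int(t_blocks[-1][1])
        if t_end - t_start > 300:
            t_end = t_start + 300
        regions.append(L1HS5pRegion(
            locus_id=locus_id, start=t_start, end=t_end,
            consensus_offset=int(q_blocks[0][0]),
        ))
    return regions


# ---------------------------------------------------------------------------
# Serialization: RepeatMasker-dialect GTF, 6-column BED, contexted TSV
# ---------------------------------------------------------------------------

def write_te_gtf(te_loci: list[TELocus], path) -> None:
    with open(path, "w") as fh:
        for t in te_loci:
            attrs = (
                f'gene_id "{t.family}"; transcript_id "{t.locus_id}"; '
                f'family_id "{t.family}"; class_id "{t.te_class}";'
            )
            fh.write("\t".join([
                t.chrom, "tecoex", "exon", str(t.start + 1), str(t.end),
                ".", t.strand, ".", attrs,
            ]) + "\n")


def read_te_gtf(path) -> list[TELocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = _parse_gtf_attrs(f[8])
            loci.append(TELocus(
                locus_id=attrs["transcript_id"], chrom=f[0],
                start=int(f[3]) - 1, end=int(f[4]), strand=f[6],
                family=attrs.get("family_id", attrs["gene_id"]),
                te_class=attrs.get("class_id", "Unknown"),
            ))
    return loci


def write_te_bed(te_loci: list[TELocus], path) -> None:
    with open(path, "w") as fh:
        for t in te_loci:
            fh.write("\t".join([
                t.chrom, str(t.start), str(t.end), t.locus_id, "0", t.strand,
            ]) + "\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a BED file into (chrom, start, end, name) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            rows.append((f[0], int(f[1]), int(f[2]), name))
    return rows


def write_gene_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for (s, e) in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write("\t".join([
                    g.chrom, "tecoex", "exon", str(s + 1), str(e),
                    ".", g.strand, ".", attrs,
                ]) + "\n")


def read_gene_gtf(path) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = _parse_gtf_attrs(f[8])
            gid = attrs["gene_id"]
            d = exons.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
            d["exons"].append((int(f[3]) - 1, int(f[4])))
    return [
        GeneModel(gene_id=gid, chrom=d["chrom"], strand=d["strand"],
                  exons=tuple(sorted(d["exons"])))
        for gid, d in exons.items()
    ]


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


_TSV_COLS = [
    "locus_id", "chrom", "start", "end", "strand", "family", "class", "context",
    "left_intron_start", "left_intron_end", "right_intron_start",
    "right_intron_end", "dist_to_nearest_gene", "mappable_len", "single_flank",
]


def write_context_table(te_loci: list[TELocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLS) + "\n")
        for t in te_loci:
            li = t.left_intron or ("", "")
            ri = t.right_intron or ("", "")
            fh.write("\t".join(str(x) for x in [
                t.locus_id, t.chrom, t.start, t.end, t.strand, t.family,
                t.te_class, t.context or "", li[0], li[1], ri[0], ri[1],
                "" if t.dist_to_nearest_gene is None else t.dist_to_nearest_gene,
                "" if t.mappable_len is None else t.mappable_len,
                int(t.single_flank),
            ]) + "\n")


def read_context_table(path) -> list[TELocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")

            def get(col):
                return f[idx[col]]

            def pair(a, b):
                return (int(get(a)), int(get(b))) if get(a) != "" else None

            loci.append(TELocus(
                locus_id=get("locus_id"), chrom=get("chrom"),
                start=int(get("start")), end=int(get("end")),
                strand=get("strand"), family=get("family"),
                te_class=get("class"), context=get("context") or None,
                left_intron=pair("left_intron_start", "left_intron_end"),
                right_intron=pair("right_intron_start", "right_intron_end"),
                dist_to_nearest_gene=(
                    int(get("dist_to_nearest_gene"))
                    if get("dist_to_nearest_gene") != "" else None),
                mappable_len=(
                    int(get("mappable_len")) if get("mappable_len") != "" else None),
                single_flank=bool(int(get("single_flank") or 0)),
            ))
    return loci
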