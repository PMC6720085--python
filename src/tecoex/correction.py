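"""Discounting TE counts for pre-mRNA / retained-intron read-through.

Reads covering a TE embedded in an intron may come from the unspliced or
retained intron rather than autonomous TE transcription.  Read depth in the
intron segments flanking the element estimates that background:

    R = count / (len - read_len)

    count'_TE = count_TE * (1 - (R_IL + R_IR) / (2 * R_TE))   if ratio < 1
              = 0                                             otherwise

where IL/IR are the intron segments left/right of the TE.  The counting
policy then keeps intergenic counts unchanged, corrects intronic counts, and
zeroes exonic counts altogether (reads over exonic TEs are parts of mature
transcripts, e.g. an Alu embedded in a lncRNA exon).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotations import TELocus


@dataclass(frozen=True)
class DepthTriple:
    """Counts and lengths for a focal TE and its flanking intron segments."""

    count_TE: float
    count_IL: float | None
    count_IR: float | None
    len_TE: int
    len_IL: int | None
    len_IR: int | None
    read_len: int

    @property
    def R_TE(self) -> float:
        return _depth_with_fallback(self.count_TE, self.len_TE, self.read_len)

    @property
    def R_IL(self) -> float | None:
        if self.count_IL is None or self.len_IL is None:
            return None
        return _depth_with_fallback(self.count_IL, self.len_IL, self.read_len)

    @property
    def R_IR(self) -> float | None:
        if self.count_IR is None or self.len_IR is None:
            return None
        return _depth_with_fallback(self.count_IR, self.len_IR, self.read_len)


def read_depth(count: float, length: int, read_len: int) -> float:
    """Reads per effective base: count / (length - read_len).

    The effective length is the number of start positions of a read fully
    inside the interval; callers must handle length <= read_len themselves
    (see :func:`_depth_with_fallback`).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if length <= read_len:
        raise ValueError("depth undefined for length <= read_len")
    return count / (length - read_len)


def _depth_with_fallback(count: float, length: int, read_len: int) -> float:
    """Depth with count/length fallback for intervals shorter than a read."""
    if length > read_len:
        return count / (length - read_len)
    return count / length


def correct_count(count_te: float, r_te: float, r_il: float | None,
                  r_ir: float | None) -> float:
    """Apply the flanking-depth discount to one TE count.

    With a single available flank its depth stands in for both.  The output
    is always within [0, count_te].
    """
    if count_te < 0:
        raise ValueError("count_te must be >= 0")
    if count_te == 0:
        return 0.0
    if r_te <= 0:
        # no fragments per effective base yet count>0 cannot arise from the
        # same counting; treat as no information
        return float(count_te)
    if r_il is None and r_ir is None:
        return float(count_te)
    if r_il is None:
        r_il = r_ir
    if r_ir is None:
        r_ir = r_il
    ratio = (r_il + r_ir) / (2.0 * r_te)
    if ratio < 1.0:
        return float(count_te * (1.0 - ratio))
    return 0.0


def correct_te_count(d: DepthTriple) -> float:
    """Corrected count for one :class:`DepthTriple`."""
    return correct_count(d.count_TE, d.R_TE, d.R_IL, d.R_IR)


def intron_counts(
    sam_path,
    te_loci: list[TELocus],
    by_fragment: dict[str, list[tuple[str, int, int]]] | None = None,
) -> pd.DataFrame:
    """Flanking-segment fragment tallies for every intronic TE.

    A fragment contributes 1 to a flank when at least one of its alignments
    overlaps that flank by >= 1 base, regardless of multiplicity (multi-mapped
    fragments are counted at face value, matching raw intron counting).
    Fragments overlapping only the embedded TE do not touch the flanks and
    are excluded by construction; a fragment straddling the TE boundary does
    overlap the flank and counts.
    """
    intronic = [t for t in te_loci if t.context == "intronic"]
    tree: dict[str, IntervalTree] = {}
    for t in intronic:
        for side, iv in (("IL", t.left_intron), ("IR", t.right_intron)):
            if iv is not None:
                tree.setdefault(t.chrom, IntervalTree()).addi(
                    iv[0], iv[1], (t.locus_id, side))

    counts = pd.DataFrame(0, index=[t.locus_id for t in intronic],
                          columns=["count_IL", "count_IR"])
    if by_fragment is None:
        by_fragment = {}
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                by_fragment.setdefault(rec.query_name, []).append(
                    (rec.reference_name, rec.reference_start, rec.reference_end))
    for alns in by_fragment.values():
        hits = set()
        for chrom, start, end in alns:
            if chrom in tree:
                for h in tree[chrom].overlap(start, end):
                    hits.add(h.data)
        for lid, side in hits:
            counts.loc[lid, f"count_{side}"] += 1
    return counts


def apply_counting_policy(
    locus_counts: pd.DataFrame,
    te_loci: list[TELocus],
    intron_count_tables: dict[str, pd.DataFrame],
    read_len: int = 48,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Context-dependent corrected locus counts plus a correction report.

    intronic  -> flanking-depth discount per sample;
    intergenic/proximal -> unchanged;
    exonic    -> zero.

    ``intron_count_tables`` maps sample id to the output of
    :func:`intron_counts`.  The report mirrors a per-locus correction table:
    raw and corrected totals, depths, and the maximum per-sample correction.
    """
    by_id = {t.locus_id: t for t in te_loci}
    missing = [lid for lid in locus_counts.index if lid not in by_id
               or by_id[lid].context is None]
    if missing:
        raise ValueError(f"missing context for loci: {missing[:5]}")

    corrected = locus_counts.astype(float).copy()
    rows = []
    for lid in locus_counts.index:
        t = by_id[lid]
        if t.context == "exonic":
            corrected.loc[lid] = 0.0
            rows.append((lid, t.context, float(locus_counts.loc[lid].sum()), 0.0,
                         float(locus_counts.loc[lid].max()), "", "", "", False))
            continue
        if t.context != "intronic":
            continue
        max_corr = 0.0
        r_te_last = r_il_last = r_ir_last = None
        for sample in locus_counts.columns:
            raw = float(locus_counts.loc[lid, sample])
            ic = intron_count_tables.get(sample)
            cil = float(ic.loc[lid, "count_IL"]) if ic is not None and lid in ic.index else 0.0
            cir = float(ic.loc[lid, "count_IR"]) if ic is not None and lid in ic.index else 0.0
            d = DepthTriple(
                count_TE=raw,
                count_IL=cil if t.left_intron else None,
                count_IR=cir if t.right_intron else None,
                len_TE=t.length,
                len_IL=(t.left_intron[1] - t.left_intron[0]) if t.left_intron else None,
                len_IR=(t.right_intron[1] - t.right_intron[0]) if t.right_intron else None,
                read_len=read_len,
            )
            val = correct_te_count(d)
            corrected.loc[lid, sample] = val
            max_corr = max(max_corr, raw - val)
            r_te_last, r_il_last, r_ir_last = d.R_TE, d.R_IL, d.R_IR
        rows.append((lid, t.context, float(locus_counts.loc[lid].sum()),
                     float(corrected.loc[lid].sum()), max_corr,
                     r_te_last, r_il_last, r_ir_last, t.single_flank))
    report = pd.DataFrame(
        rows, columns=["locus_id", "context", "raw_total", "corrected_total",
                       "max_correction", "R_TE", "R_IL", "R_IR", "single_flank"],
    ).set_index("locus_id")
    return corrected, report
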