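"""Median-ratio size factors, DEGES two-step normalization, log transform.

Size factors are estimated from gene counts (median over genes of the ratio
of each sample's count to the gene's geometric mean across samples) and then
applied unchanged to the TE matrices of the same samples.  The two-step
variant (differentially-expressed-genes elimination strategy, DEGES) ranks
genes by a between-group F statistic after a preliminary normalization,
drops the most DE-like fraction, and recomputes the median ratio on the
remaining reference set — robust when many genes differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SizeFactors:
    factors: pd.Series
    reference_gene_set: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


def median_ratio_size_factors(
    gene_counts: pd.DataFrame,
    gene_subset: list[str] | None = None,
) -> SizeFactors:
    """One-step median-ratio factors (genes x samples input).

    Only genes positive in every sample enter the reference (the geometric
    mean is otherwise zero).  Factors are equivariant: scaling one sample's
    counts by c scales its factor by c exactly.
    """
    if gene_counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    df = gene_counts if gene_subset is None else gene_counts.loc[gene_subset]
    eligible = df.index[(df > 0).all(axis=1)]
    if len(eligible) == 0:
        raise ValueError("no genes positive in all samples")
    sub = df.loc[eligible].astype(float)
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    return SizeFactors(factors=factors, reference_gene_set=list(eligible))


def _f_statistic(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Row-wise one-way ANOVA F statistic (vectorized over genes)."""
    uniq = np.unique(groups)
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    ss_between = np.zeros(values.shape[0])
    ss_within = np.zeros(values.shape[0])
    for g in uniq:
        cols = values[:, groups == g]
        m = cols.mean(axis=1, keepdims=True)
        ss_between += cols.shape[1] * ((m - grand) ** 2).ravel()
        ss_within += ((cols - m) ** 2).sum(axis=1)
    df_b = len(uniq) - 1
    df_w = n - len(uniq)
    if df_b == 0 or df_w == 0:
        return np.zeros(values.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def deges_size_factors(
    gene_counts: pd.DataFrame,
    sample_groups: pd.Series,
    drop_fraction: float = 0.3,
) -> SizeFactors:
    """Two-step DEGES factors: normalize, rank DE-like genes, re-normalize.

    Step 1 is plain median-ratio; candidate DE genes are the top
    ``drop_fraction`` by between-group F statistic on log2 step-1-normalized
    counts; step 2 recomputes the median ratio over the remainder, recorded
    as ``reference_gene_set``.  ``drop_fraction=0`` reduces to one step.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    step1 = median_ratio_size_factors(gene_counts)
    if drop_fraction == 0.0:
        return step1
    groups = sample_groups.loc[gene_counts.columns].to_numpy()
    norm = gene_counts.div(step1.factors, axis=1)
    logn = np.log2(norm.to_numpy(dtype=float) + 1.0)
    # residual error in the preliminary factors shifts every gene of a group
    # by nearly the same constant (the DE contamination biases the medians),
    # which would inflate the between-group statistic genome-wide; remove the
    # per-group gene-median offset, which a majority of non-DE genes pins to
    # the systematic error, before ranking
    uniq = np.unique(groups)
    gmeans = np.column_stack([logn[:, groups == g].mean(axis=1) for g in uniq])
    centered = gmeans - gmeans.mean(axis=1, keepdims=True)
    offset = {g: np.median(centered[:, i]) for i, g in enumerate(uniq)}
    logn = logn - np.array([offset[g] for g in groups])[None, :]
    f = _f_statistic(logn, groups)
    order = np.argsort(-f, kind="stable")
    n_drop = int(round(drop_fraction * len(order)))
    keep_idx = np.sort(order[n_drop:]) if n_drop else np.arange(len(order))
    keep = list(gene_counts.index[keep_idx])
    # the remaining genes still need positivity in all samples
    return median_ratio_size_factors(gene_counts, gene_subset=keep)


def normalize_counts(counts: pd.DataFrame, factors: SizeFactors) -> pd.DataFrame:
    """Divide each sample column by its (gene-derived) size factor."""
    missing = [s for s in counts.columns if s not in factors.factors.index]
    if missing:
        raise KeyError(f"missing size factors for samples: {missing[:5]}")
    return counts.div(factors.factors[counts.columns], axis=1)


def effective_library_size(normalized: pd.DataFrame) -> pd.Series:
    """Sum of normalized counts per sample (the library-size covariate)."""
    return normalized.sum(axis=0)


def log_transform(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); zeros map to zero at the default pseudocount."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log2(normalized + pseudocount)
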