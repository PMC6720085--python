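"""Association screens: KZFP x TE family correlations with locus-level
follow-up and binding overlap, L1HS 5' x gene linear models with all-subsets
AICc selection, and interval-mark category overlaps.

All correlation tests are Pearson on log2-normalized values with the
t-distributed null; q-values are Benjamini-Hochberg within a tissue batch.
A pair replicates when significant with a consistent sign in multiple
tissues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .annotations import TELocus


@dataclass(frozen=True)
class ScreenResult:
    predictor: str
    response: str
    tissue: str
    coefficient: float
    p_value: float
    q_value: float
    n_samples: int
    effect_size: float | None = None      # partial eta-squared
    selected_covariates: tuple[str, ...] = ()


@dataclass
class OverlapTable:
    """2x2 co-expressed x bound table with Fisher's exact association test."""

    both: int
    coexpressed_only: int
    bound_only: int
    neither: int
    p_value: float = math.nan
    odds_ratio: float = math.nan

    @property
    def total(self) -> int:
        return self.both + self.coexpressed_only + self.bound_only + self.neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.both, self.coexpressed_only],
                         [self.bound_only, self.neither]])


def _pearson_tests(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        raise FloatingPointError("constant profile")
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def pairwise_family_screen(
    kzfp_log2: dict[str, pd.DataFrame],
    te_family_log2: dict[str, pd.DataFrame],
    q_threshold: float = 0.05,
    min_samples: int = 8,
) -> tuple[list[ScreenResult], pd.DataFrame]:
    """Correlate every (KZFP, TE family) pair in every tissue.

    Inputs map tissue -> features x samples log2 matrices.  Returns all pair
    results plus a replication table (pair x [n_tissues_significant, sign])
    where a pair is co-expressed in a tissue iff BH q < ``q_threshold``.
    Constant profiles are skipped and tallied via NaN coefficients.
    """
    results: list[ScreenResult] = []
    for tissue in kzfp_log2:
        km = kzfp_log2[tissue]
        tm = te_family_log2[tissue]
        common = km.columns.intersection(tm.columns)
        if len(common) < min_samples:
            raise ValueError(f"{tissue}: fewer than {min_samples} samples")
        kx = km[common].to_numpy(dtype=float)
        tx = tm[common].to_numpy(dtype=float)
        rows = []
        for i, kz in enumerate(km.index):
            if kx[i].std() == 0:
                continue
            for j, fam in enumerate(tm.index):
                if tx[j].std() == 0:
                    continue
                r, p = _pearson_tests(kx[i], tx[j])
                rows.append((kz, fam, r, p))
        if not rows:
            continue
        ps = np.array([r[3] for r in rows])
        qs = multipletests(ps, method="fdr_bh")[1]
        for (kz, fam, r, p), q in zip(rows, qs):
            results.append(ScreenResult(
                predictor=kz, response=fam, tissue=tissue, coefficient=r,
                p_value=p, q_value=float(q), n_samples=len(common)))
    rep_rows = {}
    for res in results:
        key = (res.predictor, res.response)
        d = rep_rows.setdefault(key, {"n_tissues_significant": 0, "signs": []})
        if res.q_value < q_threshold:
            d["n_tissues_significant"] += 1
            d["signs"].append(np.sign(res.coefficient))
    replication = pd.DataFrame(
        [(k[0], k[1], v["n_tissues_significant"],
          int(v["signs"][0]) if v["signs"] and len(set(v["signs"])) == 1 else 0)
         for k, v in rep_rows.items()],
        columns=["kzfp", "family", "n_tissues_significant", "sign"],
    ).set_index(["kzfp", "family"])
    return results, replication


def locus_followup(
    significant_pairs: list[tuple[str, str, str]],
    kzfp_log2: dict[str, pd.DataFrame],
    te_locus_log2: dict[str, pd.DataFrame],
    locus_family: dict[str, str],
    q_threshold: float = 0.05,
) -> list[ScreenResult]:
    """Locus-level re-test of significant family pairs in their tissues.

    ``significant_pairs`` are (kzfp, family, tissue) triples; each is expanded
    to the family's loci in that tissue and BH-corrected within the whole
    follow-up batch (q = p for a batch of one).
    """
    rows = []
    for kz, fam, tissue in significant_pairs:
        loci = [l for l, f in locus_family.items() if f == fam
                and l in te_locus_log2[tissue].index]
        if not loci:
            continue
        km = kzfp_log2[tissue]
        lm = te_locus_log2[tissue]
        common = km.columns.intersection(lm.columns)
        x = km.loc[kz, common].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        for lid in loci:
            y = lm.loc[lid, common].to_numpy(dtype=float)
            if y.std() == 0:
                continue
            r, p = _pearson_tests(x, y)
            rows.append((kz, lid, tissue, r, p, len(common)))
    if not rows:
        return []
    qs = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    return [
        ScreenResult(predictor=kz, response=lid, tissue=tissue, coefficient=r,
                     p_value=p, q_value=float(q), n_samples=n)
        for (kz, lid, tissue, r, p, n), q in zip(rows, qs)
        if q < q_threshold
    ]


def binding_overlap_family(
    coexpressed_pairs: set[tuple[str, str]],
    enrichment: pd.DataFrame,
    assayed_kzfps: set[str],
    shared_families: set[str],
    threshold: float = 1.0,
) -> OverlapTable:
    """Fisher's exact association between co-expression and binding.

    The universe is the full cross of assayed KZFPs x shared TE families;
    a pair is "bound" iff its binding enrichment score exceeds ``threshold``.
    ``coexpressed_pairs`` should already reflect the replication mode in use
    (significant in >= 1 or >= 2 tissues).
    """
    if not assayed_kzfps or not shared_families:
        raise ValueError("empty universe")
    bound = {
        (str(r.kzfp), str(r.family))
        for r in enrichment.itertuples()
        if r.score > threshold and r.kzfp in assayed_kzfps
        and r.family in shared_families
    }
    coexp = {(k, f) for (k, f) in coexpressed_pairs
             if k in assayed_kzfps and f in shared_families}
    universe = len(assayed_kzfps) * len(shared_families)
    both = len(bound & coexp)
    co_only = len(coexp) - both
    bd_only = len(bound) - both
    neither = universe - both - co_only - bd_only
    table = OverlapTable(both=both, coexpressed_only=co_only,
                         bound_only=bd_only, neither=neither)
    odds, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    table.p_value = float(p)
    table.odds_ratio = float(odds)
    return table


def peak_te_overlap(
    peaks: list[tuple[str, int, int]],
    te_loci: list[TELocus],
    buffer: int = 250,
) -> set[str]:
    """Loci overlapped by any peak widened by +-``buffer`` bases.

    Peak coordinates are 0-based half-open; widened starts clamp at 0.  A
    single base of overlap binds the locus.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in peaks:
        if e <= s:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(max(0, s - buffer), e + buffer)
    bound = set()
    for t in te_loci:
        if t.chrom in trees and trees[t.chrom].overlap(t.start, t.end):
            bound.add(t.locus_id)
    return bound


def expressed_loci(raw_counts: pd.DataFrame, threshold: float = 5) -> set[str]:
    """Loci with more than ``threshold`` reads in at least one sample
    (strictly greater)."""
    mx = raw_counts.max(axis=1)
    return set(mx.index[mx > threshold])


def category_mark_overlap(
    te_loci: list[TELocus],
    expressed: set[str],
    bound: set[str],
    mark_sets: dict[str, list[tuple[str, int, int]]],
    split_by_region: bool = False,
) -> pd.DataFrame:
    """Proportion of each expressed x bound category overlapping each mark.

    Categories are ``expressed+bound``, ``expressed``, ``bound``, ``neither``;
    with ``split_by_region`` the proportions are additionally split into
    gene-region vs intergenic loci (by the assigned context).
    """
    mark_trees = {
        name: _peak_trees(ivs) for name, ivs in mark_sets.items()
    }

    def category(t: TELocus) -> str:
        e = t.locus_id in expressed
        b = t.locus_id in bound
        return {(True, True): "expressed+bound", (True, False): "expressed",
                (False, True): "bound", (False, False): "neither"}[(e, b)]

    def region(t: TELocus) -> str:
        return "intergenic" if t.context == "intergenic" else "gene_region"

    rows = []
    groups: dict[tuple, list[TELocus]] = {}
    for t in te_loci:
        key = (category(t), region(t)) if split_by_region else (category(t),)
        groups.setdefault(key, []).append(t)
    for key, members in sorted(groups.items()):
        row = {"category": key[0]}
        if split_by_region:
            row["region"] = key[1]
        row["n_loci"] = len(members)
        for name, trees in mark_trees.items():
            hit = sum(
                1 for t in members
                if t.chrom in trees and trees[t.chrom].overlap(t.start, t.end))
            row[name] = hit / len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def _peak_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in intervals:
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


# ---------------------------------------------------------------------------
# L1HS 5' x gene linear models
# ---------------------------------------------------------------------------

def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Second-order AIC: AIC + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    k = n_params
    if n_obs - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def gene_filters(
    gene_log2: pd.DataFrame,
    gene_raw: pd.DataFrame,
    rpm: pd.DataFrame,
    min_patients: int = 8,
    min_rpm: float = 2.0,
    rpm_fraction: float = 0.75,
    excluded_genes: set[str] = frozenset(),
) -> list[str]:
    """Eligibility for the L1HS screen: detected in >= ``min_patients``
    samples, RPM >= ``min_rpm`` in >= ``rpm_fraction`` of samples, and not
    positionally overlapping a counted L1HS locus (``excluded_genes``)."""
    detected = (gene_raw > 0).sum(axis=1) >= min_patients
    robust = (rpm >= min_rpm).mean(axis=1) >= rpm_fraction
    keep = detected & robust
    return [g for g in gene_log2.index
            if keep.get(g, False) and g not in excluded_genes]


def fit_l1hs_gene_model(
    y: np.ndarray,
    gene: np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[float, float, float, tuple[str, ...]]:
    """All-subsets AICc selection with the gene term always included.

    ``covariates`` columns are optional terms (already numeric; categorical
    terms one-hot encoded with a common prefix so a covariate enters or
    leaves as a block).  Returns (coefficient, p, partial eta-squared,
    selected covariate names) from the AICc-best model.
    """
    n = y.size
    blocks: dict[str, list[str]] = {}
    for col in covariates.columns:
        blocks.setdefault(str(col).split("=")[0], []).append(col)
    names = sorted(blocks)
    best = None
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            cols = [c for b in subset for c in blocks[b]]
            X = np.column_stack(
                [np.ones(n), gene]
                + [covariates[c].to_numpy(dtype=float) for c in cols])
            k = X.shape[1] + 1  # + residual variance
            if n - k - 1 <= 0:
                continue
            fit = OLS(y, X).fit()
            score = aicc(fit.llf, k, n)
            if best is None or score < best[0]:
                best = (score, fit, subset)
    if best is None:
        raise ValueError("no estimable model (n too small)")
    _, fit, subset = best
    coef = float(fit.params[1])
    p = float(fit.pvalues[1])
    t = float(fit.tvalues[1])
    pes = t * t / (t * t + fit.df_resid)
    return coef, p, float(pes), tuple(subset)


def l1hs_gene_screen(
    l1hs_log2: dict[str, pd.Series],
    gene_log2: dict[str, pd.DataFrame],
    covariates: dict[str, pd.DataFrame],
    genes: list[str] | None = None,
    q_threshold: float = 1e-4,
    min_replicated: int = 2,
) -> tuple[list[ScreenResult], list[str]]:
    """Per-tissue L1HS 5' ~ gene models; replicated correlated genes.

    For each eligible gene and tissue the AICc-best model over the optional
    covariates is fit with the gene term always present; q-values are BH
    within tissue; a gene replicates when q < ``q_threshold`` with a
    consistent coefficient sign in >= ``min_replicated`` tissues.
    """
    results: list[ScreenResult] = []
    for tissue, y in l1hs_log2.items():
        gm = gene_log2[tissue]
        cov = covariates.get(tissue, pd.DataFrame(index=y.index))
        use_genes = genes if genes is not None else list(gm.index)
        samples = y.index.intersection(gm.columns)
        yv = y.loc[samples].to_numpy(dtype=float)
        rows = []
        for g in use_genes:
            if g not in gm.index:
                continue
            gv = gm.loc[g, samples].to_numpy(dtype=float)
            if gv.std() == 0:
                continue
            coef, p, pes, sel = fit_l1hs_gene_model(
                yv, gv, cov.loc[samples] if len(cov.columns) else
                pd.DataFrame(index=samples))
            rows.append((g, coef, p, pes, sel))
        if not rows:
            continue
        qs = multipletests([r[2] for r in rows], method="fdr_bh")[1]
        for (g, coef, p, pes, sel), q in zip(rows, qs):
            results.append(ScreenResult(
                predictor=g, response="L1HS_5p", tissue=tissue,
                coefficient=coef, p_value=p, q_value=float(q),
                n_samples=len(samples), effect_size=pes,
                selected_covariates=sel))
    by_gene: dict[str, list[ScreenResult]] = {}
    for r in results:
        if r.q_value < q_threshold:
            by_gene.setdefault(r.predictor, []).append(r)
    replicated = sorted(
        g for g, hits in by_gene.items()
        if len(hits) >= min_replicated
        and len({np.sign(h.coefficient) for h in hits}) == 1)
    return results, replicated


def screen_results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results into the report table layout."""
    return pd.DataFrame([{
        "predictor": r.predictor, "response": r.response, "tissue": r.tissue,
        "coefficient": r.coefficient, "p_value": r.p_value,
        "q_value": r.q_value, "n_samples": r.n_samples,
        "partial_eta_squared": r.effect_size,
        "selected_covariates": ",".join(r.selected_covariates),
    } for r in results])
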