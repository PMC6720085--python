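"""Consensus weighted co-expression networks: adjacency, TOM, modules.

The signed adjacency is ``a_ij = ((1 + cor_ij)/2)^beta`` with the soft power
beta defaulting to 14 (selectable by the scale-free topology criterion).
The topological overlap matrix (TOM) augments direct adjacency with shared
neighbours; 1 - TOM is the clustering dissimilarity.  A consensus network
across tissue groups takes the element-wise minimum of the per-tissue TOMs,
so only edges supported in every tissue survive.  Modules are static-height
cuts of the average-linkage tree; each module is summarized by its
eigengene (first principal component of the standardized member profiles)
and features by their module membership kME (correlation with the
eigengene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def signed_adjacency(log2_matrix: pd.DataFrame, beta: float = 14) -> pd.DataFrame:
    """((1 + cor)/2)^beta over features (rows); requires non-zero variance."""
    if log2_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = log2_matrix.to_numpy(dtype=float)
    if (x.std(axis=1) == 0).any():
        bad = log2_matrix.index[x.std(axis=1) == 0]
        raise ValueError(f"zero-variance features: {list(bad[:5])}")
    cor = np.corrcoef(x)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=log2_matrix.index, columns=log2_matrix.index)


def soft_power_selection(
    log2_matrix: pd.DataFrame,
    candidate_powers: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    n_bins: int = 10,
    fallback: float = 14.0,
) -> float:
    """Smallest power with scale-free fit R^2 >= target, else the best one.

    The scale-free fit is the R^2 of log10 p(k) against log10 k over binned
    connectivities k_i = sum_j a_ij.  Degenerate inputs (all correlations
    ~ 0) fall back to ``fallback`` with a warning.
    """
    if not candidate_powers:
        raise ValueError("no candidate powers")
    best, best_r2 = None, -np.inf
    for beta in sorted(candidate_powers):
        adj = signed_adjacency(log2_matrix, beta=beta).to_numpy()
        k = adj.sum(axis=1) - 1.0
        if np.allclose(k.max(), k.min()):
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = (hist > 0) & (centers > 0)
        if mask.sum() < 3:
            continue
        lx = np.log10(centers[mask])
        ly = np.log10(hist[mask] / hist.sum())
        r = np.corrcoef(lx, ly)[0, 1]
        r2 = r * r if np.isfinite(r) else 0.0
        if r2 >= r2_target:
            return float(beta)
        if r2 > best_r2:
            best, best_r2 = beta, r2
    if best is None:
        warnings.warn("scale-free fit undefined; falling back to default power")
        return float(fallback)
    return float(best)


def tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j)+1-a_ij).

    The sum excludes u in {i, j}; k_i excludes the diagonal.  Off-diagonal
    values live in [0, 1]; the diagonal is 1 by convention.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum over all u of a_iu a_uj; u=i and u=j terms are 0
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


def consensus_tom(tom_by_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Element-wise minimum across tissues (identical feature sets required)."""
    if not tom_by_tissue:
        raise ValueError("no TOM matrices")
    mats = list(tom_by_tissue.values())
    idx = mats[0].index
    for m in mats[1:]:
        if not m.index.equals(idx) or not m.columns.equals(idx):
            raise ValueError("feature sets differ between tissues")
    out = mats[0].to_numpy().copy()
    for m in mats[1:]:
        np.minimum(out, m.to_numpy(), out=out)
    return pd.DataFrame(out, index=idx, columns=idx)


def detect_modules(
    consensus: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> pd.Series:
    """Static cut of the average-linkage tree on 1 - TOM.

    Clusters smaller than ``min_module_size`` become module 0 (unassigned);
    surviving modules are renumbered 1, 2, ... by decreasing size.
    """
    d = 1.0 - consensus.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = [remap.get(c, 0) for c in raw]
    return pd.Series(labels, index=consensus.index, name="module")


def eigengene(log2_matrix: pd.DataFrame, module_features: list[str]) -> pd.Series:
    """First principal component of the standardized member submatrix.

    Returned as a unit-norm sample profile, sign-oriented so that its mean
    correlation with the member features is non-negative.
    """
    if len(module_features) < 2:
        raise ValueError("need >= 2 module members")
    if log2_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sub = log2_matrix.loc[module_features].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance feature in module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # right singular vector of features x samples = sample scores
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    pc = pc / np.linalg.norm(pc)
    cors = np.array([np.corrcoef(pc, row)[0, 1] for row in z])
    if cors.mean() < 0:
        pc = -pc
    return pd.Series(pc, index=log2_matrix.columns, name="eigengene")


@dataclass
class ModuleSet:
    """Assignments, per-tissue eigengenes, and membership correlations."""

    assignments: pd.Series                         # feature -> module (0 = none)
    eigengenes: dict[str, pd.DataFrame]            # tissue -> samples x modules
    kme: dict[str, pd.DataFrame]                   # tissue -> features x modules
    module_correlations: dict[str, pd.DataFrame] = field(default_factory=dict)


def fit_modules(
    log2_by_tissue: dict[str, pd.DataFrame],
    beta: float = 14,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> ModuleSet:
    """Full consensus pipeline: adjacency -> TOM per tissue -> consensus ->
    modules -> per-tissue eigengenes, kME and module correlations."""
    toms = {t: tom(signed_adjacency(m, beta=beta))
            for t, m in log2_by_tissue.items()}
    cons = consensus_tom(toms)
    assignments = detect_modules(cons, min_module_size=min_module_size,
                                 cut_height=cut_height)
    modules = sorted(m for m in assignments.unique() if m != 0)
    eigs, kmes, mcors = {}, {}, {}
    for tissue, m in log2_by_tissue.items():
        cols = {}
        for mod in modules:
            feats = list(assignments.index[assignments == mod])
            cols[mod] = eigengene(m, feats)
        eig = pd.DataFrame(cols)
        eigs[tissue] = eig
        x = m.to_numpy(dtype=float)
        xc = (x - x.mean(axis=1, keepdims=True))
        xn = xc / np.where(xc.std(axis=1, keepdims=True) == 0, 1,
                           xc.std(axis=1, keepdims=True))
        kme = pd.DataFrame(index=m.index, columns=modules, dtype=float)
        for mod in modules:
            e = eig[mod].to_numpy()
            ez = (e - e.mean()) / e.std()
            kme[mod] = (xn * ez) .mean(axis=1)
        kmes[tissue] = kme
        mcors[tissue] = eig.corr()
    return ModuleSet(assignments=assignments, eigengenes=eigs, kme=kmes,
                     module_correlations=mcors)


@dataclass
class ModuleScreens:
    strict_members: dict[int, list[str]]
    anti_correlated_pairs: list[tuple[int, int]]
    te_modules: list[int]
    core_te_modules: list[int]


def module_screens(
    modules: ModuleSet,
    te_features: set[str],
    kme_threshold: float = 0.6,
    anti_threshold: float = -0.7,
    min_te_members: int = 10,
) -> ModuleScreens:
    """Cross-tissue module summaries.

    * strict members: features with kME > threshold in *every* tissue;
    * anti-correlated pairs: eigengene correlation < ``anti_threshold`` in
      every tissue;
    * TE modules: > ``min_te_members`` TE features; core TE modules:
      TE features form the member majority.
    """
    mods = sorted(m for m in modules.assignments.unique() if m != 0)
    strict: dict[int, list[str]] = {m: [] for m in mods}
    for feat in modules.assignments.index:
        m = modules.assignments[feat]
        if m == 0:
            continue
        if all(kme.loc[feat, m] > kme_threshold for kme in modules.kme.values()):
            strict[m].append(feat)
    anti = []
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if all(mc.loc[a, b] < anti_threshold
                   for mc in modules.module_correlations.values()):
                anti.append((a, b))
    te_mods, core = [], []
    for m in mods:
        members = list(modules.assignments.index[modules.assignments == m])
        n_te = sum(1 for f in members if f in te_features)
        if n_te > min_te_members:
            te_mods.append(m)
        if members and n_te > len(members) / 2:
            core.append(m)
    return ModuleScreens(strict_members=strict, anti_correlated_pairs=anti,
                         te_modules=te_mods, core_te_modules=core)
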