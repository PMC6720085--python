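"""Tissue clustering of samples and NMI-based evaluation.

Samples are clustered by UPGMA (average-linkage hierarchical clustering on
Euclidean distances) over the top-variance features, the tree is cut at k
clusters, each cluster takes the majority tissue label, and the induced
labeling is scored against the true tissue grouping with normalized mutual
information (arithmetic-mean normalization).  Permutation baselines shuffle
or resample the tissue labels to calibrate chance-level NMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import normalized_mutual_info_score


@dataclass
class ClusteringResult:
    sample_cluster: pd.Series          # sample -> cluster id (1..k)
    cluster_label: dict[int, str]      # cluster -> majority tissue label
    sample_label: pd.Series            # sample -> majority label of its cluster
    nmi: float
    feature_set_descriptor: str = ""


def select_top_variance(
    log2_matrix: pd.DataFrame,
    n: int = 150,
    feature_chroms: pd.Series | None = None,
    exclude_chroms: set[str] = frozenset({"chrX", "chrY", "X", "Y"}),
    raw_counts: pd.DataFrame | None = None,
    min_count_filter: float = 5,
) -> list[str]:
    """Top-n features by variance of log2 values across all samples.

    Features on excluded (sex) chromosomes are removed, as are locus-level
    features with fewer than ``min_count_filter`` raw counts in every sample.
    Ties at the cutoff break lexicographically by feature id, so selection is
    deterministic.
    """
    df = log2_matrix
    if feature_chroms is not None:
        keep = [f for f in df.index
                if feature_chroms.get(f) not in exclude_chroms]
        df = df.loc[keep]
    if raw_counts is not None:
        expressed = raw_counts.max(axis=1) >= min_count_filter
        df = df.loc[[f for f in df.index if expressed.get(f, True)]]
    if len(df) < n:
        raise ValueError(f"only {len(df)} eligible features for top-{n}")
    var = df.var(axis=1, ddof=1)
    order = sorted(df.index, key=lambda f: (-var[f], f))
    return order[:n]


def upgma_cluster(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage tree over samples (columns) into k clusters."""
    if k < 1 or k > matrix.shape[1]:
        raise ValueError("k must be in [1, n_samples]")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise ValueError(f"could not cut tree into exactly {k} clusters")
    return pd.Series(labels, index=matrix.columns, name="cluster")


def majority_labels(clusters: pd.Series, truth: pd.Series) -> tuple[dict[int, str], pd.Series]:
    """Assign each cluster the majority true label of its members."""
    label = {}
    for c in sorted(clusters.unique()):
        members = truth.loc[clusters.index[clusters == c]]
        label[int(c)] = members.value_counts().sort_index().idxmax()
    return label, clusters.map(label).rename("label")


def nmi(labels, truth_labels) -> float:
    """NMI normalized by the arithmetic mean of the two entropies.

    Zero when either partition is a single cluster (zero entropy).
    """
    labels = pd.Series(labels)
    truth_labels = pd.Series(truth_labels)
    if len(labels) == 0:
        raise ValueError("empty labels")
    if len(labels) != len(truth_labels):
        raise ValueError("label vectors differ in length")
    if labels.nunique() == 1 or truth_labels.nunique() == 1:
        return 0.0
    return float(normalized_mutual_info_score(
        truth_labels.to_numpy(), labels.to_numpy(), average_method="arithmetic"))


def cluster_samples(
    log2_matrix: pd.DataFrame,
    tissue_of_sample: pd.Series,
    k: int,
    descriptor: str = "",
) -> ClusteringResult:
    """UPGMA clustering + majority labeling + NMI against the true tissues."""
    clusters = upgma_cluster(log2_matrix, k)
    truth = tissue_of_sample.loc[clusters.index]
    label_map, labels = majority_labels(clusters, truth)
    return ClusteringResult(
        sample_cluster=clusters, cluster_label=label_map, sample_label=labels,
        nmi=nmi(labels, truth), feature_set_descriptor=descriptor)


def permutation_baseline(
    truth_labels: pd.Series,
    reps: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Mean NMI of label permutations against the truth, per mode.

    ``shuffle`` permutes the tissue labels without replacement; ``resample``
    draws them with replacement.  Both estimate the chance-level NMI.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    rng = np.random.default_rng(seed)
    arr = pd.Series(truth_labels).to_numpy()
    out = {}
    for mode in ("shuffle", "resample"):
        vals = []
        for _ in range(reps):
            perm = rng.permutation(arr) if mode == "shuffle" \
                else rng.choice(arr, size=arr.size, replace=True)
            vals.append(nmi(perm, arr))
        out[mode] = float(np.mean(vals))
    return out
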