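"""Consensus clustering of samples and G1/G2 subgroup assignment.

Subsampled k-means is re-run many times; the fraction of co-samplings in
which two samples land in the same cluster (the consensus matrix) measures
cluster stability.  The number of clusters k is chosen from the change in
area under the consensus CDF together with a floor on within-cluster
consensus.  The two final subgroups are oriented by mean immune score:
G1 is the immune-high cluster, matching the convention that the
high-infiltration subgroup is called G1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = ["ConsensusResult", "consensus_cluster", "select_k", "assign_subgroups"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and diagnostics.

    ``consensus[k]`` is the sample x sample co-clustering frequency matrix;
    ``cdf_area[k]`` the area under the empirical CDF of its off-diagonal
    entries; ``delta_area[k]`` the relative gain in that area over k-1
    (the raw area at the smallest k); ``cluster_consensus[k]`` the mean
    within-cluster consensus per cluster at k.
    """

    sample_ids: List[str]
    consensus: Dict[int, np.ndarray]
    assignments: Dict[int, np.ndarray]
    cdf_area: Dict[int, float]
    delta_area: Dict[int, float]
    cluster_consensus: Dict[int, np.ndarray]
    never_cosampled: Dict[int, int]
    cosample_counts: Optional[np.ndarray] = None
    resample_indices: Optional[List[np.ndarray]] = None

    def k_values(self) -> List[int]:
        return sorted(self.consensus)


def _cdf_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = M.shape[0]
    vals = np.sort(M[np.triu_indices(n, k=1)])
    if vals.size == 0:
        return 0.0
    # area = integral over [0,1] of ECDF; ECDF steps at each value
    xs = np.concatenate([[0.0], vals, [1.0]])
    ys = np.concatenate([[0.0], np.arange(1, vals.size + 1) / vals.size, [1.0]])
    widths = np.diff(xs)
    return float(np.sum(ys[:-1] * widths))


def consensus_cluster(expr_submatrix: pd.DataFrame,
                      k_range: Sequence[int] = range(2, 11),
                      n_resamples: int = 1000,
                      p_item: float = 0.8,
                      seed: int = 0,
                      keep_indices: bool = False) -> ConsensusResult:
    """Resampled k-means consensus clustering.

    ``expr_submatrix`` is genes x samples; genes are standardized before
    clustering (samples are the points).  For each resample, floor(p_item*n)
    samples are drawn without replacement and k-means (10 restarts) is run
    at each k; the consensus entry for a pair is its co-clustering count
    divided by its co-sampling count.  Pairs never co-sampled get 0 and are
    counted in ``never_cosampled``.  Deterministic given ``seed``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n = expr_submatrix.shape[1]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    X = expr_submatrix.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    points = Xs.T  # samples x genes

    rng = np.random.default_rng(seed)
    m = int(np.floor(p_item * n))
    idx_sets = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]

    cosample = np.zeros((n, n))
    for idx in idx_sets:
        cosample[np.ix_(idx, idx)] += 1

    consensus, assignments, cdf_area, cluster_consensus, never = {}, {}, {}, {}, {}
    for k in k_range:
        cocluster = np.zeros((n, n))
        for r, idx in enumerate(idx_sets):
            km = KMeans(n_clusters=k, n_init=10,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(points[idx])
            for c in range(k):
                members = idx[lab == c]
                cocluster[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        never_k = int(np.sum((cosample == 0)[np.triu_indices(n, k=1)]))
        if never_k:
            warnings.warn(f"k={k}: {never_k} sample pairs never co-sampled; "
                          "their consensus is 0")
        # final assignment at k: average-linkage tree on 1 - M
        lab_k = _cut_consensus(M, k)
        consensus[k] = M
        assignments[k] = lab_k
        cdf_area[k] = _cdf_area(M)
        cluster_consensus[k] = _cluster_consensus(M, lab_k)
        never[k] = never_k

    delta = {}
    ks = sorted(consensus)
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0

    return ConsensusResult(
        sample_ids=list(expr_submatrix.columns),
        consensus=consensus,
        assignments=assignments,
        cdf_area=cdf_area,
        delta_area=delta,
        cluster_consensus=cluster_consensus,
        never_cosampled=never,
        cosample_counts=cosample,
        resample_indices=idx_sets if keep_indices else None,
    )


def _cut_consensus(M: np.ndarray, k: int) -> np.ndarray:
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _cluster_consensus(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = []
    for c in sorted(set(labels)):
        members = np.where(labels == c)[0]
        if len(members) < 2:
            out.append(1.0)
            continue
        sub = M[np.ix_(members, members)]
        out.append(float(sub[np.triu_indices(len(members), k=1)].mean()))
    return np.array(out)


def select_k(result: ConsensusResult, delta_min: float = 0.1,
             consensus_floor: float = 0.9) -> int:
    """Choose k: the largest k whose relative delta-area is at least
    ``delta_min`` and whose minimum cluster consensus is at least
    ``consensus_floor``; if no k qualifies, the smallest k with a warning."""
    ks = result.k_values()
    if len(ks) < 2:
        raise ValueError("need at least 2 k values to select from")
    passing = [k for k in ks
               if result.delta_area[k] >= delta_min
               and result.cluster_consensus[k].min() >= consensus_floor]
    if not passing:
        warnings.warn("no k passed the delta-area/cluster-consensus rule; "
                      f"returning smallest k={ks[0]}")
        return ks[0]
    return max(passing)


def assign_subgroups(result: ConsensusResult, k: int = 2,
                     immune_scores: Optional[pd.Series] = None) -> pd.Series:
    """Cut the consensus tree at ``k`` and name the clusters.

    For k=2 the cluster with the higher mean immune score is G1 (the
    immune-high subgroup), the other G2; ties fall back to 'larger cluster
    is G1' with a warning.  Without immune scores clusters keep size order.
    """
    if k not in result.consensus:
        raise ValueError(f"no consensus matrix for k={k}")
    labels = result.assignments[k]
    uniq = sorted(set(labels))
    if len(uniq) < k:
        raise ValueError(f"consensus tree yields only {len(uniq)} distinct "
                         f"clusters at k={k} (degenerate input)")
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    if immune_scores is not None:
        s = immune_scores.reindex(result.sample_ids)
        means = {c: float(s.to_numpy()[labels == c].mean()) for c in uniq}
        if len(set(means.values())) < len(uniq):
            warnings.warn("tie in mean immune score; ordering clusters by size")
            order = sorted(uniq, key=lambda c: -sizes[c])
        else:
            order = sorted(uniq, key=lambda c: -means[c])
    else:
        order = sorted(uniq, key=lambda c: -sizes[c])
    name = {c: f"G{i + 1}" for i, c in enumerate(order)}
    return pd.Series([name[c] for c in labels], index=result.sample_ids,
                     name="subgroup")
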