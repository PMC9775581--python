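"""k-means and consensus clustering of the fused sample embedding.

The fused factor U is clustered by subsampled k-means consensus: for each
candidate k, samples are repeatedly subsampled and clustered, the fraction
of co-sampled runs in which each sample pair lands in the same cluster
forms the consensus matrix, final per-k labels come from complete-linkage
agglomeration of 1 - consensus, and k is selected by the delta-area
criterion on the consensus CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "PartitionLabels",
    "ConsensusResult",
    "kmeans_cluster",
    "consensus_cluster",
    "cluster_fused",
    "read_labels",
    "write_labels",
]


@dataclass
class PartitionLabels:
    """Cluster assignment of samples; semantics invariant to label permutation.

    Labels are integers 1..k with every cluster non-empty.
    """

    sample_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length must match sample_ids")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        if len(present) != self.k:
            raise ValueError("every cluster 1..k must be non-empty")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def cluster_members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and CDFs plus the selected k."""

    sample_ids: list[str]
    k_values: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, PartitionLabels]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]
    areas: dict[int, float]
    deltas: dict[int, float]
    selected_k: int
    reps: int
    subsample_fraction: float
    seed: int = 0


def _relabel_consecutive(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary integer labels onto 1..k keeping first-seen order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out[i] = mapping[r]
    return out, len(mapping)


def kmeans_cluster(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    sample_ids: Sequence[str] | None = None,
) -> PartitionLabels:
    """Best-of-n_init k-means with k-means++ seeding, deterministic given seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    labels, k_eff = _relabel_consecutive(raw)
    return PartitionLabels(list(sample_ids), labels, k_eff)


def read_labels(path) -> PartitionLabels:
    """Read a sample/cluster TSV into PartitionLabels (clusters renumbered 1..k)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"sample", "cluster"}.issubset(df.columns):
        raise ValueError(f"labels file must have columns sample, cluster; got {list(df.columns)}")
    raw = df["cluster"].to_numpy()
    codes = pd.factorize(raw, sort=True)[0] + 1
    return PartitionLabels(list(df["sample"].astype(str)), codes, int(codes.max()))


def write_labels(part: PartitionLabels, path) -> None:
    import pandas as pd

    pd.DataFrame({"sample": part.sample_ids, "cluster": part.labels}).to_csv(
        path, sep="\t", index=False
    )


def _consensus_for_k(X, k, reps, sub_n, rng):
    import warnings

    n = X.shape[0]
    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=sub_n, replace=False)
        seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            # subsamples of tight clusters can hold fewer than k distinct
            # points; k-means then returns fewer clusters, which is fine here
            warnings.filterwarnings("ignore", message="Number of distinct clusters")
            raw = KMeans(n_clusters=k, n_init=1, random_state=seed).fit_predict(X[idx])
        ind = np.zeros((n,), dtype=int) - 1
        ind[idx] = raw
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        co = mask[:, None] & mask[None, :]
        cosampled += co
        same = (ind[:, None] == ind[None, :]) & co
        together += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    return 0.5 * (consensus + consensus.T)


def _cdf_and_area(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    vals = consensus[np.triu_indices_from(consensus, k=1)]
    xs = np.sort(vals)
    ys = np.arange(1, xs.size + 1) / xs.size
    # area under the empirical CDF over [0, 1]
    grid = np.concatenate([[0.0], xs, [1.0]])
    cdf_at = np.concatenate([[0.0], ys, [1.0]])
    area = float(np.sum(np.diff(grid) * cdf_at[:-1]))
    return xs, ys, area


def consensus_cluster(
    X: np.ndarray,
    k_range: Sequence[int],
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Subsampled k-means consensus clustering with delta-area k selection.

    For each k in ``k_range``: ``reps`` subsamples of ``ceil(subsample*n)``
    samples (without replacement) are clustered by k-means; consensus(i,j) is
    the co-clustered fraction of co-sampled runs; final labels per k are
    complete-linkage agglomeration of 1 - consensus cut at k.  ``selected_k``
    is the largest k whose relative change in the area under the consensus
    CDF still exceeds ``delta_threshold`` (the delta plot plateaus beyond
    the true cluster count; the first k's delta is its own area, by
    convention).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValueError("empty k_range")
    if k_values[0] < 2 or k_values[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if reps < 10:
        raise ValueError("reps < 10 gives unstable consensus estimates")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    sub_n = int(np.ceil(subsample * n))
    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, PartitionLabels] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    for k in k_values:
        M = _consensus_for_k(X, k, reps, sub_n, rng)
        consensus[k] = M
        dist = 1.0 - M
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="complete")
        raw = fcluster(Z, t=k, criterion="maxclust")
        lab, k_eff = _relabel_consecutive(raw)
        labels[k] = PartitionLabels(list(sample_ids), lab, k_eff)
        xs, ys, area = _cdf_and_area(M)
        cdf[k] = (xs, ys)
        areas[k] = area
    deltas: dict[int, float] = {}
    for i, k in enumerate(k_values):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[k_values[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else areas[k]
    # the delta-area plot plateaus once k exceeds the true cluster count:
    # select the largest k still showing a substantial relative area gain
    substantial = [k for k in k_values if deltas[k] > delta_threshold]
    selected_k = max(substantial) if substantial else k_values[0]
    return ConsensusResult(
        sample_ids=list(sample_ids),
        k_values=k_values,
        consensus=consensus,
        labels=labels,
        cdf=cdf,
        areas=areas,
        deltas=deltas,
        selected_k=selected_k,
        reps=reps,
        subsample_fraction=subsample,
        seed=seed,
    )


def cluster_fused(
    fact,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    k_override: int | None = None,
) -> PartitionLabels:
    """Consensus-cluster the rows of a fitted joint factorization's U.

    ``k_override`` skips the delta-area selection and returns the labels at
    that k (the melanoma profile fixes k rather than auto-selecting).
    """
    res = consensus_cluster(
        fact.U, k_range, reps=reps, subsample=subsample, seed=seed, sample_ids=fact.sample_ids
    )
    k = k_override if k_override is not None else res.selected_k
    if k not in res.labels:
        raise ValueError(f"k_override={k} not in evaluated k_range {res.k_values}")
    return res.labels[k]
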