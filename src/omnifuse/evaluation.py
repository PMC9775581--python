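"""Evaluation indices for fused clusterings.

Rand index and Hubert-Arabie adjusted Rand index by pair counting /
contingency table, silhouette scores (per sample and per cluster), the
single-domain assessment table (ARI of a fused clustering against each
domain's own clustering), and Kaplan-Meier + log-rank survival comparison
of the clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.spatial.distance import pdist, squareform

from omnifuse.clustering import PartitionLabels
from omnifuse.io_formats import SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairCounts",
    "pair_counts",
    "rand_index",
    "adjusted_rand_index",
    "silhouette",
    "single_domain_assessment",
    "km_logrank",
    "KmLogrankResult",
]


@dataclass
class PairCounts:
    """Counts of sample pairs: a = together in both partitions, b = apart in
    both, c/d = together in exactly one."""

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_aligned(p1: PartitionLabels, p2: PartitionLabels) -> None:
    if p1.sample_ids != p2.sample_ids:
        raise ValueError("partitions must be on identical aligned samples")


def _contingency(p1: PartitionLabels, p2: PartitionLabels) -> np.ndarray:
    table = np.zeros((p1.k, p2.k), dtype=np.int64)
    np.add.at(table, (p1.labels - 1, p2.labels - 1), 1)
    return table


def pair_counts(p1: PartitionLabels, p2: PartitionLabels) -> PairCounts:
    """Pair-comembership counts via the contingency table."""
    _check_aligned(p1, p2)
    n = len(p1)
    table = _contingency(p1, p2)

    def comb2(x):
        return x * (x - 1) // 2

    a = int(comb2(table).sum())
    row_pairs = int(comb2(table.sum(axis=1)).sum())
    col_pairs = int(comb2(table.sum(axis=0)).sum())
    total = comb2(n)
    c = row_pairs - a  # together in p1 only
    d = col_pairs - a  # together in p2 only
    b = total - a - c - d
    return PairCounts(a=a, b=b, c=c, d=d)


def rand_index(p1: PartitionLabels, p2: PartitionLabels) -> float:
    """RI = (a + b) / C(n, 2): the fraction of sample pairs on which the two
    partitions agree (both together or both apart)."""
    pc = pair_counts(p1, p2)
    if pc.total == 0:
        raise ValueError("Rand index undefined for fewer than 2 samples")
    return (pc.a + pc.b) / pc.total


def adjusted_rand_index(p1: PartitionLabels, p2: PartitionLabels) -> float:
    """Hubert-Arabie ARI: (index - expected) / (max - expected).

    Zero in expectation under random labeling (permutation model), 1 for
    identical partitions.  Computed from the contingency table:
    (sum_ij C(n_ij,2) - E) / (M - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    """
    _check_aligned(p1, p2)
    n = len(p1)
    table = _contingency(p1, p2)

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(table.astype(float)).sum()
    row_pairs = comb2(table.sum(axis=1).astype(float)).sum()
    col_pairs = comb2(table.sum(axis=0).astype(float)).sum()
    total = comb2(float(n))
    expected = row_pairs * col_pairs / total if total > 0 else 0.0
    max_index = 0.5 * (row_pairs + col_pairs)
    if max_index == expected:
        # both partitions trivial (all-singletons or single cluster)
        return 1.0 if index == expected and row_pairs == col_pairs else 0.0
    return float((index - expected) / (max_index - expected))


def silhouette(
    X: np.ndarray,
    labels: PartitionLabels,
    precomputed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Silhouette SI(i) = (b(i) - a(i)) / max(a(i), b(i)) per sample, and the
    mean silhouette per cluster.

    ``a(i)`` is the mean distance to the other members of i's cluster,
    ``b(i)`` the smallest mean distance to any other cluster.  Distances are
    Euclidean on the rows of ``X`` unless ``precomputed``.  A singleton
    cluster's samples score 0 by convention.
    """
    if labels.k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    X = np.asarray(X, dtype=float)
    D = X if precomputed else squareform(pdist(X, metric="euclidean"))
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match number of samples")
    lab = labels.labels
    per_sample = np.zeros(n)
    sizes = {c: int(np.sum(lab == c)) for c in range(1, labels.k + 1)}
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            per_sample[i] = 0.0
            continue
        a_i = D[i, lab == own].sum() / (sizes[own] - 1)
        b_i = min(
            D[i, lab == c].mean() for c in range(1, labels.k + 1) if c != own
        )
        denom = max(a_i, b_i)
        per_sample[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    per_cluster = np.array([per_sample[lab == c].mean() for c in range(1, labels.k + 1)])
    return per_sample, per_cluster


@dataclass
class AssessmentTable:
    """Table-style assessment: rows = methods, columns = reference label
    sets, cells = ARI; plus per-cluster silhouettes per method."""

    table: pd.DataFrame
    silhouettes: dict[str, np.ndarray] = field(default_factory=dict)


def single_domain_assessment(
    fused: Mapping[str, PartitionLabels] | PartitionLabels,
    references: Mapping[str, PartitionLabels],
    silhouettes: Mapping[str, np.ndarray] | None = None,
) -> AssessmentTable:
    """ARI of each fused/method clustering against each single-domain
    reference clustering.

    A good fusion shares information with every domain's own clustering
    rather than mirroring only one, so a row with one ARI near 1 and the
    rest near 0 indicates the method relied on a single domain.
    """
    if isinstance(fused, PartitionLabels):
        fused = {"fused": fused}
    rows = {}
    for method, part in fused.items():
        rows[method] = {
            ref_name: adjusted_rand_index(part, ref) for ref_name, ref in references.items()
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AssessmentTable(table=table, silhouettes=dict(silhouettes or {}))


@dataclass
class KmLogrankResult:
    """Kaplan-Meier curves per cluster with overall and pairwise log-rank tests."""

    curves: dict[int, pd.DataFrame]
    chi2: float
    p_value: float
    pairwise_p: dict[tuple[int, int], float]
    n_used: dict[int, int]
    n_labeled: dict[int, int]


def km_logrank(labels: PartitionLabels, surv: SurvivalTable) -> KmLogrankResult:
    """Kaplan-Meier estimates per cluster and log-rank tests across clusters.

    Labeled samples lacking survival records are dropped with a logged
    per-cluster count.  The overall test is the k-group log-rank chi-square
    (k-1 df); pairwise tests compare two clusters with all others excluded.
    Clusters with zero survival records are excluded with a warning.
    """
    surv_idx = {s: i for i, s in enumerate(surv.sample_ids)}
    used_samples, used_time, used_event, used_label = [], [], [], []
    n_labeled: dict[int, int] = {c: 0 for c in range(1, labels.k + 1)}
    n_used: dict[int, int] = {c: 0 for c in range(1, labels.k + 1)}
    for s, l in zip(labels.sample_ids, labels.labels):
        n_labeled[l] += 1
        i = surv_idx.get(s)
        if i is None:
            continue
        n_used[l] += 1
        used_samples.append(s)
        used_time.append(surv.time[i])
        used_event.append(surv.event[i])
        used_label.append(l)
    for c in range(1, labels.k + 1):
        logger.info("cluster %d: %d of %d labeled samples have survival data", c, n_used[c], n_labeled[c])
    time = np.asarray(used_time, dtype=float)
    event = np.asarray(used_event, dtype=int)
    group = np.asarray(used_label, dtype=int)
    present = [c for c in range(1, labels.k + 1) if n_used[c] > 0]
    dropped = [c for c in range(1, labels.k + 1) if n_used[c] == 0]
    if dropped:
        logger.warning("clusters with no survival records excluded: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least two clusters with survival records")
    keep = np.isin(group, present)
    time, event, group = time[keep], event[keep], group[keep]
    curves: dict[int, pd.DataFrame] = {}
    for c in present:
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == c], event_observed=event[group == c], label=f"cluster{c}")
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        curves[c] = df
    overall = multivariate_logrank_test(time, group, event)
    pairwise: dict[tuple[int, int], float] = {}
    for ia, ca in enumerate(present):
        for cb in present[ia + 1 :]:
            m = np.isin(group, [ca, cb])
            res = logrank_test(
                time[m][group[m] == ca],
                time[m][group[m] == cb],
                event_observed_A=event[m][group[m] == ca],
                event_observed_B=event[m][group[m] == cb],
            )
            pairwise[(ca, cb)] = float(res.p_value)
    return KmLogrankResult(
        curves=curves,
        chi2=float(overall.test_statistic),
        p_value=float(overall.p_value),
        pairwise_p=pairwise,
        n_used=n_used,
        n_labeled=n_labeled,
    )
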