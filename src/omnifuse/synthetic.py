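"""Coupled two-domain synthetic generator with planted shared clusters.

Emulates the structure of a paired RNA-seq + DNA methylation cohort: a
shared partition of samples into k clusters drives cluster-specific log2
shifts on a subset of informative genes (negative-binomial counts over
log-normal baselines) and cluster-specific mean shifts on informative
methylation probes (Beta-distributed values).  Informative genes are paired
with informative probes; with probability ``coupling`` a gene's up-cluster
is the cluster in which its paired probe is hypo-methylated, planting the
overexpressed-and-demethylated pattern that the cross-domain feature view
measures.  Optional exponential survival times with cluster-specific
hazards feed the log-rank evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from omnifuse.clustering import PartitionLabels
from omnifuse.io_formats import OmicsMatrix, SurvivalTable

__all__ = ["SimConfig", "SyntheticTruth", "simulate_multiomics", "simulate_survival"]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    RNA counts: negative binomial with variance mu + dispersion * mu^2 over
    log-normal baseline means; informative genes gain ``log2_effect`` in
    their up-cluster.  Methylation: Beta with the given concentration;
    informative probes shift their mean by ``effect_delta`` downwards in the
    affected cluster.  ``coupling`` is the probability that a paired
    gene/probe share the same affected cluster.
    """

    n_samples: int = 120
    k_clusters: int = 3
    cluster_proportions: tuple = ()
    rna_n_genes: int = 2000
    rna_n_informative: int = 200
    nb_dispersion: float = 0.1
    log2_effect: float = 2.0
    meth_n_probes: int = 3000
    meth_n_informative: int = 300
    beta_concentration: float = 30.0
    effect_delta: float = 0.3
    coupling: float = 0.8
    hazard_ratios: tuple = (1.0, 0.35, 1.0)
    base_hazard: float = 1.0 / 500.0
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cluster_proportions:
            self.cluster_proportions = tuple([1.0 / self.k_clusters] * self.k_clusters)
        if len(self.cluster_proportions) != self.k_clusters:
            raise ValueError("cluster_proportions length must equal k_clusters")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-8:
            raise ValueError("cluster_proportions must sum to 1")
        if self.log2_effect < 0 or self.effect_delta < 0:
            raise ValueError("effect sizes must be non-negative")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if self.rna_n_informative > self.rna_n_genes:
            raise ValueError("rna_n_informative exceeds rna_n_genes")
        if self.meth_n_informative > self.meth_n_probes:
            raise ValueError("meth_n_informative exceeds meth_n_probes")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    labels: PartitionLabels
    informative_genes: list[str]
    informative_probes: list[str]
    gene_up_cluster: dict[str, int]
    probe_down_cluster: dict[str, int]
    probe_map: dict[str, str]
    log2_effect: float
    effect_delta: float
    coupling: float
    seed: int


def _planted_labels(cfg: SimConfig) -> np.ndarray:
    """Deterministic label counts: proportions are honored exactly (largest
    remainders get the leftover samples), then positions are contiguous."""
    counts = np.floor(np.asarray(cfg.cluster_proportions) * cfg.n_samples).astype(int)
    rem = cfg.n_samples - counts.sum()
    frac = np.asarray(cfg.cluster_proportions) * cfg.n_samples - counts
    for c in np.argsort(-frac, kind="stable")[:rem]:
        counts[c] += 1
    return np.repeat(np.arange(1, cfg.k_clusters + 1), counts)


def simulate_multiomics(cfg: SimConfig) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Draw a coupled (RNA counts, methylation betas, truth) triple.

    Fully determined by ``cfg.seed``: same config gives bit-identical
    matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_samples, cfg.k_clusters
    labels = _planted_labels(cfg)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"gene{j:05d}" for j in range(cfg.rna_n_genes)]
    probe_ids = [f"cg{j:05d}" for j in range(cfg.meth_n_probes)]

    # --- RNA counts ---
    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=cfg.rna_n_genes)
    info_genes = list(rng.choice(cfg.rna_n_genes, size=cfg.rna_n_informative, replace=False))
    gene_up = {j: int(rng.integers(1, k + 1)) for j in info_genes}
    mu = np.tile(base_mean, (n, 1))
    for j in info_genes:
        mu[labels == gene_up[j], j] *= 2.0 ** cfg.log2_effect
    if cfg.nb_dispersion > 0:
        # NB as gamma-mixed Poisson: shape r = 1/dispersion, mean mu
        r = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)

    # --- methylation betas ---
    base_beta = rng.uniform(0.15, 0.85, size=cfg.meth_n_probes)
    info_probes = list(rng.choice(cfg.meth_n_probes, size=cfg.meth_n_informative, replace=False))
    # pair informative probes with informative genes (recycled if needed)
    pairing = {
        p: info_genes[i % len(info_genes)] for i, p in enumerate(info_probes)
    }
    probe_down: dict[int, int] = {}
    for p in info_probes:
        paired_up = gene_up[pairing[p]]
        if rng.random() < cfg.coupling:
            probe_down[p] = paired_up
        else:
            others = [c for c in range(1, k + 1) if c != paired_up]
            probe_down[p] = int(rng.choice(others)) if others else paired_up
    mean_beta = np.tile(base_beta, (n, 1))
    for p in info_probes:
        mask = labels == probe_down[p]
        mean_beta[mask, p] = np.clip(mean_beta[mask, p] - cfg.effect_delta, 0.02, 0.98)
    c0 = cfg.beta_concentration
    a = mean_beta * c0
    b = (1.0 - mean_beta) * c0
    betas = rng.beta(a, b)
    betas = np.clip(betas, 1e-6, 1.0 - 1e-6)

    # probe -> gene map: paired informative probes map to their genes; the
    # remaining probes are assigned round-robin to non-informative genes so
    # aggregation has multi-probe genes to exercise
    probe_map: dict[str, str] = {probe_ids[p]: gene_ids[pairing[p]] for p in info_probes}
    non_info_genes = [j for j in range(cfg.rna_n_genes) if j not in set(info_genes)]
    for i, p in enumerate(j for j in range(cfg.meth_n_probes) if j not in set(info_probes)):
        if not non_info_genes:
            break
        probe_map[probe_ids[p]] = gene_ids[non_info_genes[i % len(non_info_genes)]]

    truth = SyntheticTruth(
        labels=PartitionLabels(sample_ids, labels, k),
        informative_genes=[gene_ids[j] for j in info_genes],
        informative_probes=[probe_ids[p] for p in info_probes],
        gene_up_cluster={gene_ids[j]: gene_up[j] for j in info_genes},
        probe_down_cluster={probe_ids[p]: probe_down[p] for p in info_probes},
        probe_map=probe_map,
        log2_effect=cfg.log2_effect,
        effect_delta=cfg.effect_delta,
        coupling=cfg.coupling,
        seed=cfg.seed,
    )
    rna = OmicsMatrix(sample_ids, gene_ids, counts, domain="rnaseq")
    meth = OmicsMatrix(sample_ids, probe_ids, betas, domain="methylation")
    return rna, meth, truth


def simulate_survival(truth: SyntheticTruth, cfg: SimConfig, seed: int | None = None) -> SurvivalTable:
    """Exponential event times with cluster-specific hazards.

    Hazard of cluster c is ``base_hazard * hazard_ratios[c-1]``.  Censoring:
    with probability ``censoring_rate`` a sample is censored at a uniform
    fraction of its event time (rate 0 observes every event).
    """
    hr = np.asarray(cfg.hazard_ratios, dtype=float)
    if hr.size != truth.labels.k:
        raise ValueError("hazard_ratios length must equal number of clusters")
    if np.any(hr <= 0) or cfg.base_hazard <= 0:
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    lab = truth.labels.labels
    lam = cfg.base_hazard * hr[lab - 1]
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(lab.size) < cfg.censoring_rate
    frac = rng.random(lab.size)
    time = np.where(censored, t_event * frac, t_event)
    event = (~censored).astype(int)
    return SurvivalTable(list(truth.labels.sample_ids), time, event)
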