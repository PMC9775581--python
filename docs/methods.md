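# Methods

## The joint factorization model

Given domain matrices `A_i ∈ R^{I×N_i}` on the same `I` aligned samples,
jSVD seeks one orthonormal sample factor `U ∈ St(I,k)` shared by all
domains and per-domain orthonormal feature factors `V_i ∈ St(N_i,k)` with
diagonal `Σ_i`, such that `A_i ≈ U Σ_i V_iᵀ`. The model assumes the
domains share a low-dimensional sample structure (the cluster geometry)
while their feature loadings and scales differ; it does not model
missing entries or domain-specific sample factors.

**Σ elimination.** The approximation form leaves the loss open. For fixed
`U, V_i` the Frobenius-optimal diagonal is `Σ_i = diag(UᵀA_iV_i)`;
substituting it reduces the problem to maximizing
`Σ_i ‖diag(UᵀA_iV_i)‖²` over the Stiefel product, i.e. minimizing the
residual `f = Σ_i ‖A_i‖² − Σ_i Σ_j (u_jᵀ A_i v_{ij})²`. This is the single
most consequential modeling choice in the package: alternatives (e.g.
penalizing off-diagonal energy of `UᵀA_iV_i`) coincide with it at optima
but produce different iterates.

**Optimization.** Riemannian trust region on the embedded Stiefel product:
Frobenius metric, tangent projection `ξ ↦ ξ − X sym(Xᵀξ)`, QR retraction
with positive-diagonal convention, exact Euclidean Hessian-vector products
converted with the standard correction
`Hess f[ξ] = Proj(∇²f[ξ] − ξ sym(Xᵀ∇f))`, truncated-CG inner solver
(κ = 0.1, θ = 1, Steihaug–Toint boundary handling), acceptance at ρ > 0.05
with the usual radius update. Accepted iterates therefore have a
non-increasing objective, and orthonormality holds to ~1e-14 at every
iterate by construction of the retraction.

**Stopping.** The run stops when the projected-gradient norm drops below
`mingradnorm` (default 1e-12, the melanoma profile value), when
`max_iterations` (default 1000) accepted-or-rejected steps are exhausted,
or when the trust radius collapses below `1e-12·Δ̄` — the floating-point
floor on problems whose objective is O(10⁶), where differences of f can no
longer resolve. On noisy data the gradient norm typically floors around
1e-4–1e-6 of the data scale; `converged=False` then simply reports that
1e-12 was not reachable, not a failure (the embedding is at its numerical
optimum).

**Initialization.** `init="svd"` (default, deterministic): `U` from the
top-k left singular vectors of the column-concatenated `[A₁ | A₂ | …]`,
each `V_i` as the polar factor of `A_iᵀU` (the closest orthonormal matrix).
`init="random"`: QR of a seeded Gaussian per factor, for multi-start.

**Canonical output.** The factorization is invariant to column permutation
and paired sign flips, so outputs are canonicalized: each `Σ_i` entry is
made non-negative by flipping the domain's `V` column, columns are ordered
by decreasing total energy `Σ_i Σ_i[j]²`, and each `U` column's
largest-magnitude entry is made positive (flipping the paired `V` columns
with it).

## Preprocessing

Count filters follow the RNA-seq protocol: genes with total count < 100 or
> 10⁶ are outliers; genes with zeros in ≥ 20% of samples are dropped
(zeros treated as missing). Normalization is a variance-stabilizing
surrogate — DESeq-style median-of-ratios size factors followed by
`log2(x/sf + 1)` — not a reimplementation of DESeq2's blind VST
(dispersion-trend fitting); the fusion only needs approximately
variance-stabilized input, and `normalize_counts(..., external=...)`
accepts an externally produced VST matrix for exact reproduction of an R
pipeline. Feature selection ranks by the raw median absolute deviation
(the 1.4826 consistency constant cancels in ranking); the methylation
"top 1% most variable" criterion also uses MAD, for consistency with the
RNA criterion, and betas are used untransformed. Filter order:
total-count, zero-fraction, normalization, MAD selection.

Matrix input is TSV with strict label handling; any feature containing a
non-finite value after parsing is dropped with a logged count, because the
downstream factorizations require complete matrices and no imputation step
is modeled. Sample alignment restricts all domains to their common samples
in lexicographic order, making results independent of file order.

## SNF baseline

Per-domain affinities use Euclidean sample distances with a locally
adaptive bandwidth: `W(i,j) = exp(−d²(i,j)/(μ·ε_ij))`,
`ε_ij = (mean d(i,KNN_i) + mean d(j,KNN_j) + d(i,j))/3`. Fusion is the
cross-diffusion scheme: full-kernel normalization `P` (off-diagonal rows
summing to 1/2, diagonal 1/2), sparse row-normalized K-NN kernel `S`, and
`P_v ← S_v · mean(P_other) · S_vᵀ` per iteration with re-symmetrization and
re-normalization; the output is the symmetrized average of the final `P`s.
Defaults K = 20, μ = 0.5, 20 iterations follow published SNF conventions
(the source protocol names the package without parameters); the melanoma
profile clusters the fused network into 3 groups. K-NN sets exclude self
and break distance ties by sample index for determinism. Spectral
clustering is Ng–Jordan–Weiss: bottom eigenvectors of the normalized
Laplacian, row-renormalized, then seeded k-means.

## Consensus clustering and the choice of k

For each candidate k, `reps` subsamples of `⌈0.8·I⌉` samples (without
replacement) are clustered by a single k-means run; `consensus(i,j)` is
the fraction of co-sampled runs in which i and j co-cluster. Final per-k
labels are complete-linkage agglomeration of `1 − consensus` cut at k —
the configuration matching "k-means method (complete agglomeration,
Euclidean distance)" with k-means as the inner resampled clusterer and
agglomeration on the consensus for the final labels.

**k selection.** The delta-area statistic is the relative change of the
area under the consensus CDF, `Δ(k) = (A(k) − A(k−1))/A(k−1)` with
`Δ(k_min) = A(k_min)`. A literal argmax of `Δ` always favors small k: on
clean data the consensus is near-binary at every k up to the true k*, so
`Δ` shrinks monotonically while remaining substantial, then plateaus for
k > k*. The selector therefore returns the **largest k with
`Δ(k) > 0.1`** (threshold configurable) — the plateau-onset reading of the
delta plot. On k* well-separated point masses this selects k* whether or
not k_min = k*; on the default synthetic cohort it selects 3 on both
fusion paths. A known limitation: on structureless data the areas grow
smoothly and the threshold rule can return k_min; inspect the per-k CDFs
in `ConsensusResult` when in doubt. Defaults: reps = 1000, subsample
fraction 0.8 (package conventions; the protocol is silent); tests and the
acceptance script run reps = 100, which the reps-stability test shows
selects the same k on clean data.

## Evaluation indices

`RI = (a+b)/C(n,2)` by pair counting via the contingency table. The
adjusted Rand index uses the Hubert–Arabie form
`(Σ C(n_ij,2) − E)/(½(Σ C(a_i,2)+Σ C(b_j,2)) − E)`; when both partitions
are trivial (max = expected) the value is defined as 1 for identical
partitions and 0 otherwise. Silhouette: `SI(i) = (b−a)/max(a,b)` with
Euclidean distances (or a precomputed matrix); singleton clusters score 0;
the per-cluster means are the reported quantity, computed on the
representation that produced the labels (U for jSVD, the fused network's
spectral embedding for SNF). The single-domain assessment tabulates the
ARI of each method's fused clustering against every single-domain
reference clustering: a good fusion shares information with all domains
rather than mirroring one.

Survival: Kaplan–Meier per cluster (lifelines), overall k-group log-rank
chi-square with k−1 df, pairwise tests between two clusters with all
others excluded, no multiple-testing correction on the pairwise p-values
(raw values are reported, matching the reporting convention of the
melanoma analysis). Labeled samples without survival records are dropped
with per-cluster accounting; clusters with zero records are excluded with
a warning.

## SAM differential features

Two-class contrasts (one-vs-one or the default one-vs-rest) use
`d = (mean_A − mean_B)/(s + s0)` with the pooled standard error `s`. The
fudge factor `s0` is chosen among the percentiles {0, 5, …, 100} of {s_i}
to minimize the coefficient of variation of the d-statistic's spread
(window-wise MAD/0.64) across windows of s. The null is label
permutation; `d̄` is the mean of the sorted permuted statistics, and for a
threshold δ the calling cut-points walk inwards from each end of the
sorted observed d while `|d_(i) − d̄_(i)| ≥ δ` (contiguous tails).
Candidate δ are the attained |excess| values — call sets change only
there — subsampled to ≤ 512. π0 is estimated from the fraction of
observed d inside the permutation quartiles.

The per-δ FDR estimate is `π0 · (median_false + 1)/n_called`. The `+1` is
a finite-sample correction: without it, the median permutation false-call
count at a single-extreme cut is 0 with probability ≈ 1/2 under the global
null (the observed and permuted maxima are exchangeable), so the raw
median estimate would declare FDR 0 for a one-feature call set and the
procedure would not be calibrated. With the correction the global-null
median call count is 0 across seeds, while a 3σ effect planted in 50 of
1000 features is recovered completely with ≤ 5 false calls at target FDR
0.05. The chosen δ is the smallest with estimated FDR ≤ the target; if
none qualifies nothing is called. A consequence of the `+1`: fewer than
`1/q` discoveries can never be declared at FDR target `q`.

Gene-level methylation is the unweighted mean of a gene's mapped probes.
Over-representation is the one-sided hypergeometric tail against a
user-supplied GMT with Benjamini–Hochberg correction across sets (no live
GO queries; term databases are version-dependent). The cross-domain view
reports, for each gene called up in the contrast class, the mean
methylation difference between the contrast classes, and the fraction of
up-genes with a negative difference — near 1 under expression/methylation
coupling, near 0.5 for independent domains.

## Synthetic generator

The generator emulates a paired RNA-seq + methylation cohort with a shared
planted partition. Defaults: 120 samples, 3 equal clusters; 2000 genes
with log-normal baseline means (median ≈ 100 counts) and NB sampling
(variance μ + 0.1μ²), 200 informative genes gaining log2 effect 2 in one
cluster; 3000 probes with Beta-distributed values (concentration 30), 300
informative probes whose mean drops by 0.3 in the affected cluster.
Informative probes are paired with informative genes; with probability
0.8 (the coupling) the probe's hypo-methylated cluster equals the paired
gene's up-cluster, planting the overexpressed-and-demethylated pattern.
Survival times are exponential with cluster hazard ratios (1.0, 0.35,
1.0) over a base hazard of 1/500 days; with probability 0.2 a sample is
censored at a uniform fraction of its event time. Effect sizes were
chosen once as a moderately strong, realistic bulk-omics signal: they make
the default recovery task solvable but not trivial (nulling the effects
sends recovery ARI to 0, as the tests check).

What the generator does **not** emulate: library-size variation between
samples, batch effects, probe-level spatial correlation, copy-number or
mutation domains, non-exponential hazards, and domain-specific sample
structure. Passing the recovery tests therefore shows the pipeline's
machinery is correct under the planted model, not that real cohorts will
yield clean three-cluster solutions — on TCGA-scale data the indices in
the evaluation module are the arbiter.

## Problem sizes and runtime choices

The test suite and acceptance script run at the generator's default scale
(120 × 1500 RNA after selection, 120 × 30 methylation), consensus with
reps = 100 over k ∈ 2..6, SAM with 100–200 permutations over 1000
features, and 200 replicates for the log-rank null calibration. These
sizes keep the full suite around two minutes on one core while leaving
every statistical check well-powered; all of them are parameters, not
constants.

## Known limitations

- The residual objective is non-convex; the trust-region method finds a
  stationary point. The deterministic SVD initialization lands in the
  dominant basin in all tested conditions, but `init="random"` multi-start
  is the guard for adversarial geometry.
- `mingradnorm = 1e-12` is below the floating-point floor for noisy
  data at O(10⁶) objective scale; `converged` then reports `False` by
  design.
- The delta-area threshold (0.1) is a heuristic; for marginal structure
  inspect the consensus CDFs rather than trusting `selected_k`.
- SAM's permutation null assumes exchangeable samples under H0 within the
  contrast; strong covariate structure (e.g. batch) violates this.
- No missing-data handling beyond dropping incomplete features.
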