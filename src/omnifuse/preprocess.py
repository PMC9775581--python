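"""Count filtering, normalization and MAD feature selection for fusion input.

The RNA-seq branch removes outlier genes by total read count (below 100 or
above 10^6 by default) and genes with zeros in 20% or more of the samples,
then applies a variance-stabilizing surrogate (median-of-ratios size factors
followed by log2(x/sf + 1)).  Unsupervised feature selection keeps the
features with the highest median absolute deviation — 1500 genes for RNA-seq
and the top 1% most variable probes for methylation in the melanoma profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from omnifuse.io_formats import OmicsMatrix

__all__ = ["PreprocessReport", "filter_counts", "normalize_counts", "mad_select"]


@dataclass
class PreprocessReport:
    """Audit of what each preprocessing step removed or kept."""

    n_features_in: int = 0
    n_removed_low_total: int = 0
    n_removed_high_total: int = 0
    n_removed_zero_frac: int = 0
    n_selected_mad: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return (
            self.n_features_in
            - self.n_removed_low_total
            - self.n_removed_high_total
            - self.n_removed_zero_frac
        )

    def to_dict(self) -> dict:
        return {
            "n_features_in": self.n_features_in,
            "n_removed_low_total": self.n_removed_low_total,
            "n_removed_high_total": self.n_removed_high_total,
            "n_removed_zero_frac": self.n_removed_zero_frac,
            "n_surviving": self.n_surviving,
            "n_selected_mad": self.n_selected_mad,
            "thresholds": self.thresholds,
        }


def filter_counts(
    counts: OmicsMatrix,
    min_total: float = 100,
    max_total: float = 1e6,
    max_zero_frac: float = 0.2,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Remove count outlier features and features with too many zeros.

    A feature is removed when its total count over all samples is below
    ``min_total`` or above ``max_total``, or when the fraction of samples
    with a zero count is >= ``max_zero_frac`` (zeros treated as missing).
    Filters are applied in that order and itemized in the report.
    """
    X = counts.values
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=0)
    zero_frac = (X == 0).mean(axis=0)
    low = totals < min_total
    high = totals > max_total
    zf = (~low & ~high) & (zero_frac >= max_zero_frac)
    keep = ~(low | high | zf)
    report = PreprocessReport(
        n_features_in=counts.n_features,
        n_removed_low_total=int(low.sum()),
        n_removed_high_total=int(high.sum()),
        n_removed_zero_frac=int(zf.sum()),
        thresholds={"min_total": min_total, "max_total": max_total, "max_zero_frac": max_zero_frac},
    )
    kept_ids = [f for f, k in zip(counts.feature_ids, keep) if k]
    return counts.subset_features(kept_ids), report


def size_factors(X: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample, samples on rows).

    The pseudo-reference is the per-feature geometric mean over samples,
    computed on features expressed in every sample; each sample's factor is
    the median of its ratios to the reference.
    """
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("a sample has all-zero counts; cannot compute size factors")
    positive = np.all(X > 0, axis=0)
    if not positive.any():
        raise ValueError("no feature is positive in all samples; cannot form reference")
    logX = np.log(X[:, positive])
    log_ref = logX.mean(axis=0)
    sf = np.exp(np.median(logX - log_ref, axis=1))
    return sf


def normalize_counts(counts: OmicsMatrix, external: OmicsMatrix | None = None) -> OmicsMatrix:
    """Variance-stabilizing surrogate: log2(count / size_factor + 1).

    Size factors are DESeq-style median-of-ratios, so library-depth
    differences between samples are divided out before the log transform.
    ``external`` is a hook accepting an externally produced normalized matrix
    (e.g. a blind VST from DESeq2) which is passed through unchanged after a
    label check, for exact reproduction of an external pipeline.
    """
    if external is not None:
        if external.sample_ids != counts.sample_ids:
            raise ValueError("external normalized matrix has mismatched samples")
        return external
    X = counts.values
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    sf = size_factors(X)
    norm = np.log2(X / sf[:, None] + 1.0)
    return OmicsMatrix(list(counts.sample_ids), list(counts.feature_ids), norm, counts.domain)


def mad_scores(X: np.ndarray) -> np.ndarray:
    """Per-feature raw median absolute deviation (no consistency constant)."""
    med = np.median(X, axis=0)
    return np.median(np.abs(X - med), axis=0)


def mad_select(
    matrix: OmicsMatrix,
    n_features: int | None = None,
    top_fraction: float | None = None,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Keep the features with the highest median absolute deviation.

    Exactly one of ``n_features`` (absolute count) or ``top_fraction``
    (fraction of available features, rounded up) must be given.  Ties in MAD
    are broken by feature id so the selection is deterministic.
    """
    if (n_features is None) == (top_fraction is None):
        raise ValueError("give exactly one of n_features or top_fraction")
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        n = math.ceil(top_fraction * matrix.n_features)
    else:
        n = int(n_features)  # type: ignore[arg-type]
    if n > matrix.n_features:
        raise ValueError(f"requested {n} features but only {matrix.n_features} available")
    if n < 1:
        raise ValueError("must select at least one feature")
    scores = mad_scores(matrix.values)
    # sort by (-MAD, feature id); stable and fully deterministic
    order = sorted(range(matrix.n_features), key=lambda j: (-scores[j], matrix.feature_ids[j]))
    chosen = sorted(order[:n])  # preserve original column order
    kept_ids = [matrix.feature_ids[j] for j in chosen]
    report = PreprocessReport(
        n_features_in=matrix.n_features,
        n_selected_mad=n,
        thresholds={"n_features": n_features, "top_fraction": top_fraction},
    )
    return matrix.subset_features(kept_ids), report
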