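"""Within-study normalization baselines.

Two families are provided:

* quantile normalization — forces every sample's value distribution onto a
  common quantile profile while preserving within-sample ranks; both the
  joint variant (reference = mean of the column-sorted matrix) and the
  to-reference variant (reference quantiles supplied, used when a single
  profile is calibrated against a fixed auxiliary dataset);
* median-of-ratios size factors — the count normalization popularized by
  differential-expression tools for sequencing data: each sample is scaled
  by the median, over genes with positive geometric mean, of its counts
  divided by the gene's across-sample geometric mean.

These serve both as comparison baselines for the harmonizer and as its
internal calibration step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "ReferenceQuantiles",
    "SizeFactors",
    "quantile_normalize",
    "quantile_normalize_to_reference",
    "estimate_size_factors",
    "normalize_by_size_factors",
    "floor_to_counts",
]


@dataclass(frozen=True)
class ReferenceQuantiles:
    """A fixed, non-decreasing target distribution for quantile mapping."""

    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sorted_values, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("reference quantiles must be finite")
        if np.any(np.diff(arr) < 0):
            raise ValueError("reference quantiles must be non-decreasing")
        object.__setattr__(self, "sorted_values", arr)

    def __len__(self) -> int:
        return len(self.sorted_values)


@dataclass(frozen=True)
class SizeFactors:
    """One positive scaling constant per sample."""

    factors: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.factors, dtype=float)
        if not np.isfinite(s.to_numpy()).all() or (s.to_numpy() <= 0).any():
            raise ValueError("size factors must be positive and finite")
        object.__setattr__(self, "factors", s)


def _map_column_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace ``col`` by ``ref`` quantiles, averaging over ties.

    A stable argsort aligns order statistics with the sorted reference;
    tied input values then receive the mean of the reference values their
    rank span covers, which makes the mapping independent of the original
    row order.
    """
    order = np.argsort(col, kind="mergesort")
    mapped = np.empty_like(ref)
    mapped[order] = ref
    _, inverse = np.unique(col, return_inverse=True)
    sums = np.bincount(inverse, weights=mapped)
    counts = np.bincount(inverse)
    return (sums / counts)[inverse]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Joint quantile normalization across all samples.

    The common target distribution is the row-wise mean of the
    column-sorted matrix; every column is then mapped onto it by rank,
    with ties averaged.
    """
    if matrix.n_samples < 2:
        raise ValueError(
            "joint quantile normalization needs >= 2 samples; use "
            "quantile_normalize_to_reference for a single profile"
        )
    arr = matrix.values.to_numpy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.column_stack(
        [_map_column_to_reference(arr[:, j], ref) for j in range(arr.shape[1])]
    )
    return matrix.with_values(out)


def quantile_normalize_to_reference(
    matrix: ExpressionMatrix, ref: ReferenceQuantiles
) -> ExpressionMatrix:
    """Map each column onto fixed reference quantiles (ties averaged)."""
    if len(ref) != matrix.n_genes:
        raise ValueError(
            f"reference length {len(ref)} != gene count {matrix.n_genes}"
        )
    arr = matrix.values.to_numpy()
    out = np.column_stack(
        [
            _map_column_to_reference(arr[:, j], ref.sorted_values)
            for j in range(arr.shape[1])
        ]
    )
    return matrix.with_values(out)


def estimate_size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    factor_j = median over genes g of counts[g, j] / geomean_g, taken over
    the genes whose counts are strictly positive in every sample (so the
    geometric mean is positive).
    """
    arr = counts.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("size factors require non-negative counts")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios size factors are undefined"
        )
    pos = arr[positive]
    geomean = np.exp(np.log(pos).mean(axis=1))
    factors = np.median(pos / geomean[:, None], axis=0)
    return SizeFactors(pd.Series(factors, index=counts.sample_ids))


def normalize_by_size_factors(
    counts: ExpressionMatrix, factors: SizeFactors
) -> ExpressionMatrix:
    """Divide each sample column by its size factor."""
    f = factors.factors
    if list(f.index) != list(counts.sample_ids):
        if len(f) != counts.n_samples or not set(counts.sample_ids) <= set(f.index):
            raise ValueError("size factors do not match the matrix samples")
        f = f.reindex(counts.sample_ids)
    return counts.with_values(counts.values.to_numpy() / f.to_numpy()[None, :])


def floor_to_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Integer part of non-negative intensities (pseudo-counts).

    Makes continuous microarray intensities formally acceptable to count
    models by truncating every value toward zero.
    """
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("floor_to_counts expects non-negative intensities")
    return matrix.with_values(np.floor(arr))
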