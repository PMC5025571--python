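"""Shared containers and numeric primitives for count normalization.

The central object is a genes × samples matrix of read counts
``X[g, s]`` with a condition label per sample.  All three scaling
normalization methods implemented in this package (TMM, RLE, MRN) are
built from a small set of primitives defined here: library sizes,
pre-normalization (counts per unit library), geometric means, medians,
trimmed means, and per-gene M/A values against a reference sample.

Notation used throughout the package
------------------------------------
``X_gkr``  raw count of gene *g* in condition *k*, replicate *r*
``N_kr``   library size (column sum of ``X``)
``Y_gkr``  pre-normalized count ``X_gkr / N_kr`` (columns sum to 1)
``M``      log2 ratio of two pre-normalized values (fold change)
``A``      half the log2 product of two pre-normalized values (abundance)
``tau``    relative scaling factor (relative transcriptome size)
``e``      effective library size
``f``      final size / normalization factor
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("countnorm")

__all__ = [
    "CountMatrix",
    "PreNormalizedMatrix",
    "MAPair",
    "NormalizationResult",
    "library_sizes",
    "pre_normalize",
    "geometric_mean",
    "median_of",
    "trimmed_mean",
    "ma_values",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes × samples matrix of non-negative read counts.

    Parameters
    ----------
    counts
        ``(G, S)`` array of non-negative counts.  Integral values are
        expected; real values (e.g. expected counts from an upstream
        estimator) are accepted with a logged warning.
    gene_ids
        ``G`` unique gene identifiers.
    sample_ids
        ``S`` unique sample identifiers.
    conditions
        ``S`` condition labels mapping each sample to its condition.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes × samples array")
        G, S = self.counts.shape
        if self.gene_ids.shape != (G,):
            raise ValueError(f"expected {G} gene ids, got {self.gene_ids.shape}")
        if self.sample_ids.shape != (S,):
            raise ValueError(f"expected {S} sample ids, got {self.sample_ids.shape}")
        if self.conditions.shape != (S,):
            raise ValueError(f"expected {S} condition labels, got {self.conditions.shape}")
        if len(set(self.gene_ids)) != G:
            raise ValueError("gene ids must be unique")
        if len(set(self.sample_ids)) != S:
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r} in sample "
                f"{self.sample_ids[s]!r}"
            )
        if np.any(self.counts != np.round(self.counts)):
            logger.warning(
                "count matrix contains non-integral values; proceeding "
                "(treating them as expected counts)"
            )
        colsums = self.counts.sum(axis=0)
        if np.any(colsums <= 0):
            bad = self.sample_ids[int(np.argmin(colsums))]
            raise ValueError(f"sample {bad!r} has zero library size")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def condition_labels(self) -> list:
        """Unique condition labels in order of first appearance."""
        seen: dict = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition) -> np.ndarray:
        """Column indices of the samples belonging to *condition*."""
        idx = np.flatnonzero(self.conditions == condition)
        if idx.size == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return idx

    @property
    def replicates_per_condition(self) -> dict:
        return {c: int(np.sum(self.conditions == c)) for c in self.condition_labels}


@dataclass
class PreNormalizedMatrix:
    """Counts divided columnwise by library size: ``Y[g, s] = X[g, s] / N_s``.

    Every column sums to 1 (to floating tolerance), so columns are
    directly comparable regardless of sequencing depth.
    """

    values: np.ndarray
    source: CountMatrix

    def __post_init__(self) -> None:
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0, rtol=0, atol=1e-12):
            raise ValueError("pre-normalized columns must sum to 1")

    @property
    def conditions(self) -> np.ndarray:
        return self.source.conditions


@dataclass
class MAPair:
    """Per-gene M (log2 fold change) and A (log2 mean abundance) values.

    ``valid[g]`` is True exactly where both pre-normalized values
    entering the ratio are strictly positive; ``m`` and ``a`` are finite
    exactly there and NaN elsewhere.
    """

    m: np.ndarray
    a: np.ndarray
    valid: np.ndarray


@dataclass
class NormalizationResult:
    """Factors produced by one normalization method.

    ``size_factors`` is the final per-sample output (Table-style Step VI):
    for TMM it equals the adjusted relative factors (library size is NOT
    folded in); for RLE and MRN it is the per-sample divisor applied to
    raw counts.
    """

    method: str
    sample_ids: np.ndarray
    conditions: np.ndarray
    relative_factors: np.ndarray
    size_factors: np.ndarray
    adjusted_factors: np.ndarray | None = None
    effective_library_sizes: np.ndarray | None = None
    usable_genes: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("relative_factors", "size_factors"):
            v = getattr(self, name)
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")

    def to_frame(self):
        """Tabular view with one row per sample (pandas DataFrame)."""
        import pandas as pd

        def col(v):
            return v if v is not None else np.full(len(self.sample_ids), np.nan)

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": self.conditions,
                "method": self.method,
                "relative_factor": self.relative_factors,
                "adjusted_factor": col(self.adjusted_factors),
                "effective_library_size": col(self.effective_library_sizes),
                "size_factor": self.size_factors,
            }
        )


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def library_sizes(cm: CountMatrix) -> np.ndarray:
    """Per-sample library sizes ``N_s`` (column sums of the count matrix)."""
    N = cm.counts.sum(axis=0)
    if np.any(N <= 0):
        bad = cm.sample_ids[int(np.argmin(N))]
        raise ValueError(f"sample {bad!r} has zero library size")
    return N


def pre_normalize(cm: CountMatrix) -> PreNormalizedMatrix:
    """Divide each column by its library size so columns sum to 1."""
    N = library_sizes(cm)
    return PreNormalizedMatrix(values=cm.counts / N, source=cm)


def geometric_mean(x: Sequence[float] | np.ndarray) -> float:
    """Geometric mean of strictly positive values, computed in log domain."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty vector is undefined")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(x))))


def median_of(x: Sequence[float] | np.ndarray) -> float:
    """Midpoint-interpolated median.

    For odd length this is the central order statistic; for even length
    the mean of the two central order statistics (the default convention
    of mainstream statistical software).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("no usable genes")
    return float(np.median(x))


def trimmed_mean(x: Sequence[float] | np.ndarray, trim_frac: float) -> float:
    """Mean after dropping ``floor(trim_frac * n)`` values from each tail.

    ``trim_frac`` must lie in [0, 0.5].  A trim proportion of exactly
    50% per tail is the median, and is special-cased to
    :func:`median_of` so the identity holds to machine precision.
    """
    if not 0.0 <= trim_frac <= 0.5:
        raise ValueError(f"trim_frac must be in [0, 0.5], got {trim_frac}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("no usable genes")
    if trim_frac == 0.5:
        return median_of(x)
    k = math.floor(trim_frac * x.size)
    xs = np.sort(x, kind="stable")
    kept = xs[k: x.size - k] if k else xs
    if kept.size == 0:
        raise ValueError("no usable genes after trimming")
    return float(np.mean(kept))


def ma_values(y_sample: np.ndarray, y_ref: np.ndarray) -> MAPair:
    """Per-gene M and A values of one pre-normalized column vs a reference.

    ``M = log2(y_sample / y_ref)`` and ``A = 0.5 * log2(y_sample * y_ref)``;
    a gene is valid only where both columns are strictly positive.
    """
    y_sample = np.asarray(y_sample, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    if y_sample.shape != y_ref.shape:
        raise ValueError(
            f"length mismatch: {y_sample.shape} vs {y_ref.shape}"
        )
    valid = (y_sample > 0) & (y_ref > 0)
    m = np.full(y_sample.shape, np.nan)
    a = np.full(y_sample.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        m[valid] = np.log2(y_sample[valid] / y_ref[valid])
        a[valid] = 0.5 * np.log2(y_sample[valid] * y_ref[valid])
    return MAPair(m=m, a=a, valid=valid)
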