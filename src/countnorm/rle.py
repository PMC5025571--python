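"""Relative log expression (RLE) normalization: median of ratios to a
geometric-mean pseudo-reference.

The pseudo-reference sample is the per-gene geometric mean of raw
counts across all samples; each sample's size factor is the median,
over genes expressed in every sample, of the ratio of its raw count to
the pseudo-reference.  No rescaling step follows: the size factors ARE
the medians, and they absorb both sequencing depth and transcriptome
composition, which is why they correlate strongly with library size.

:func:`rle_edger_style_factors` reproduces the variant computed when
the same procedure is fed pre-normalized counts (counts divided by
library size) and the result is rescaled to unit product — the form in
which the RLE recipe circulates inside TMM-style toolchains.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CountMatrix,
    NormalizationResult,
    geometric_mean,
    library_sizes,
    median_of,
    pre_normalize,
)

__all__ = [
    "rle_pseudo_reference",
    "rle_size_factors",
    "rle_normalize",
    "rle_edger_style_factors",
    "rle_factors",
]


def _pseudo_reference(values: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean; rows containing any zero get 0."""
    all_pos = np.all(values > 0, axis=1)
    ref = np.zeros(values.shape[0])
    if np.any(all_pos):
        ref[all_pos] = np.exp(np.mean(np.log(values[all_pos]), axis=1))
    return ref


def _median_ratio_factors(values: np.ndarray):
    """Median over usable genes of ``values[g, s] / pseudo_ref[g]``.

    Usable genes are those with a strictly positive pseudo-reference,
    i.e. expressed in every sample.  Returns ``(factors, n_usable)``.
    """
    ref = _pseudo_reference(values)
    usable = ref > 0
    if not np.any(usable):
        raise ValueError("no gene expressed in all samples")
    ratios = values[usable] / ref[usable, None]
    f = np.array([median_of(ratios[:, s]) for s in range(values.shape[1])])
    return f, int(np.sum(usable))


def rle_pseudo_reference(cm: CountMatrix) -> np.ndarray:
    """Per-gene geometric mean of raw counts across all samples.

    A gene with a zero count in any sample gets reference value 0 and
    is excluded from the downstream medians.
    """
    return _pseudo_reference(cm.counts)


def rle_size_factors(cm: CountMatrix) -> np.ndarray:
    """Per-sample size factors: median of count ratios to the
    pseudo-reference over genes expressed in all samples."""
    f, _ = _median_ratio_factors(cm.counts)
    return f


def rle_normalize(cm: CountMatrix, f: np.ndarray) -> np.ndarray:
    """Normalized counts ``Z[g, s] = X[g, s] / f_s``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("size factors must be positive")
    return cm.counts / f


def rle_edger_style_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios on PRE-NORMALIZED counts, rescaled to unit product.

    Equals ``rle_size_factors(X) / N`` rescaled to geometric mean 1,
    because pre-normalization divides gene-wise ratios and their
    pseudo-reference by per-sample and geometric-mean library sizes
    respectively.
    """
    Y = pre_normalize(cm)
    f, _ = _median_ratio_factors(Y.values)
    return f / geometric_mean(f)


def rle_factors(cm: CountMatrix, edger_style: bool = False) -> NormalizationResult:
    """RLE as a :class:`~countnorm.core.NormalizationResult`."""
    if edger_style:
        Y = pre_normalize(cm)
        raw, usable = _median_ratio_factors(Y.values)
        f = raw / geometric_mean(raw)
    else:
        f, usable = _median_ratio_factors(cm.counts)
    S = cm.n_samples
    return NormalizationResult(
        method="RLE",
        sample_ids=cm.sample_ids,
        conditions=cm.conditions,
        relative_factors=f,
        size_factors=f,
        usable_genes=np.full(S, usable, dtype=int),
        settings={"edger_style": edger_style},
    )
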