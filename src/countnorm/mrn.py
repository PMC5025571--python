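"""Median ratio normalization (MRN).

MRN estimates one relative transcriptome size per *condition* (not per
sample): pre-normalized counts are averaged over the replicates of
each condition, and the relative factor of condition *k* is the median
over genes of the ratio of its mean profile to the reference
condition's mean profile.  Effective library sizes multiply the
condition factor back onto each sample's raw library size, and the
final size factors are those effective sizes rescaled to geometric
mean 1.  Replicates of one condition therefore share a relative
factor but not a size factor.

Genes enter the median only when both the numerator and the
denominator condition means are strictly positive; in the two-sample
no-replicate design this usable set coincides with the set of genes
expressed in all samples, which is what makes MRN agree exactly with
the RLE median-of-ratios there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CountMatrix,
    NormalizationResult,
    PreNormalizedMatrix,
    geometric_mean,
    library_sizes,
    median_of,
    pre_normalize,
)

__all__ = [
    "MRNOptions",
    "condition_means",
    "mrn_relative_factors",
    "mrn_size_factors",
    "mrn_normalize",
]


@dataclass
class MRNOptions:
    """``reference_condition``: condition label used as denominator;
    ``None`` (default) picks the first condition in order of appearance."""

    reference_condition: object | None = None

    def resolve(self, cm: CountMatrix):
        labels = cm.condition_labels
        if self.reference_condition is None:
            return labels[0]
        if self.reference_condition not in labels:
            raise KeyError(
                f"reference condition {self.reference_condition!r} not among {labels}"
            )
        return self.reference_condition


def condition_means(Y: PreNormalizedMatrix, conditions=None) -> np.ndarray:
    """G × K matrix of pre-normalized values averaged over the
    replicates of each condition (columns ordered by first appearance)."""
    cm = Y.source
    if conditions is None:
        conditions = cm.conditions
    conditions = np.asarray(conditions, dtype=object)
    labels = cm.condition_labels
    out = np.empty((Y.values.shape[0], len(labels)))
    for j, lab in enumerate(labels):
        out[:, j] = Y.values[:, conditions == lab].mean(axis=1)
    return out


def mrn_relative_factors(cm: CountMatrix, opts: MRNOptions | None = None):
    """Per-condition relative factors ``tau_k`` (reference gets exactly 1).

    ``tau_k = median over genes with both means positive of
    mean_Y[g, k] / mean_Y[g, ref]``.

    Returns ``(tau, labels, usable)`` with ``tau`` aligned to
    ``labels`` (condition order of appearance) and ``usable`` the count
    of genes entering each median.
    """
    opts = opts or MRNOptions()
    ref_label = opts.resolve(cm)
    Y = pre_normalize(cm)
    means = condition_means(Y)
    labels = cm.condition_labels
    ref_j = labels.index(ref_label)
    K = len(labels)
    tau = np.ones(K)
    usable = np.zeros(K, dtype=int)
    ref_col = means[:, ref_j]
    usable[ref_j] = int(np.sum(ref_col > 0))
    for j in range(K):
        if j == ref_j:
            continue
        ok = (means[:, j] > 0) & (ref_col > 0)
        if not np.any(ok):
            raise ValueError(
                f"no usable genes for condition {labels[j]!r} vs "
                f"reference {ref_label!r}"
            )
        tau[j] = median_of(means[ok, j] / ref_col[ok])
        usable[j] = int(np.sum(ok))
    return tau, labels, usable


def mrn_size_factors(cm: CountMatrix, opts: MRNOptions | None = None) -> NormalizationResult:
    """Effective library sizes ``e_kr = tau_k * N_kr`` and size factors
    ``f_kr = e_kr / geometric_mean(e)`` (geometric mean of f is 1 by
    construction)."""
    opts = opts or MRNOptions()
    tau, labels, usable = mrn_relative_factors(cm, opts)
    tau_by_label = dict(zip(labels, tau))
    usable_by_label = dict(zip(labels, usable))
    tau_per_sample = np.array([tau_by_label[c] for c in cm.conditions])
    e = tau_per_sample * library_sizes(cm)
    f = e / geometric_mean(e)
    return NormalizationResult(
        method="MRN",
        sample_ids=cm.sample_ids,
        conditions=cm.conditions,
        relative_factors=tau_per_sample,
        effective_library_sizes=e,
        size_factors=f,
        usable_genes=np.array([usable_by_label[c] for c in cm.conditions]),
        settings={"reference_condition": opts.resolve(cm)},
    )


def mrn_normalize(cm: CountMatrix, f: np.ndarray) -> np.ndarray:
    """Normalized counts ``Z[g, s] = X[g, s] / f_s``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("size factors must be positive")
    return cm.counts / f
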