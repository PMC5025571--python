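"""Trimmed mean of M-values (TMM) normalization.

The method estimates the relative size of each sample's transcriptome
against a reference sample by a doubly trimmed mean over gene-wise
ratios of pre-normalized counts: genes with extreme M-values (log2
fold changes) and extreme A-values (log2 abundances) are discarded,
and the mean of the survivors is taken.  The resulting relative
scaling factors are rescaled to multiply to 1; multiplied by the raw
library sizes they yield effective library sizes, from which
counts-per-million are computed.

Two mean scales are offered.  ``"ratio"`` averages the surviving
ratios ``Y[g, s] / Y[g, ref]`` directly; ``"log2"`` averages the
surviving M-values and returns ``2**mean(M)``, which is how the method
is usually stated in the differential-expression literature.  At a
50% M-trim both reduce to the median of ratios (the median commutes
with monotone transforms), which is the hinge of the TMM/MRN
equivalence in the two-sample, no-replicate design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CountMatrix,
    NormalizationResult,
    PreNormalizedMatrix,
    geometric_mean,
    library_sizes,
    ma_values,
    median_of,
    pre_normalize,
)

__all__ = [
    "AUTO_UPPER_QUARTILE",
    "TMMOptions",
    "select_reference",
    "tmm_relative_factors",
    "adjust_to_unit_product",
    "tmm_effective_library_sizes",
    "tmm_cpm",
    "tmm_factors",
]

#: Sentinel: pick the sample whose upper quartile of pre-normalized
#: values is closest to the mean upper quartile over all samples.
AUTO_UPPER_QUARTILE = "auto-upper-quartile"

_MEAN_SCALES = ("ratio", "log2")


@dataclass
class TMMOptions:
    """Settings for TMM.

    reference
        Explicit sample index, or :data:`AUTO_UPPER_QUARTILE` (default)
        for the upper-quartile rule.
    m_trim, a_trim
        Per-tail trim proportions for M- and A-values, each in
        [0, 0.5].  Defaults 0.30 and 0.05, the customary values.
        ``m_trim = 0.5`` is the exact median of ratios.
    mean_scale
        ``"ratio"`` (default): trimmed arithmetic mean of ratios.
        ``"log2"``: 2 to the trimmed mean of M-values.
    """

    reference: int | str = AUTO_UPPER_QUARTILE
    m_trim: float = 0.30
    a_trim: float = 0.05
    mean_scale: str = "ratio"

    def __post_init__(self) -> None:
        for name in ("m_trim", "a_trim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.mean_scale not in _MEAN_SCALES:
            raise ValueError(
                f"mean_scale must be one of {_MEAN_SCALES}, got {self.mean_scale!r}"
            )


def select_reference(Y: PreNormalizedMatrix, opts: TMMOptions) -> int:
    """Resolve the reference sample index.

    Explicit indices pass through (after a range check).  Otherwise the
    sample minimizing ``|uq_s - mean(uq)|`` is chosen, where ``uq_s`` is
    the 75th percentile of the sample's pre-normalized values (linear
    interpolation between order statistics); ties break to the lowest
    index.
    """
    S = Y.values.shape[1]
    if opts.reference != AUTO_UPPER_QUARTILE:
        ref = int(opts.reference)
        if not 0 <= ref < S:
            raise IndexError(f"reference sample index {ref} out of range [0, {S})")
        return ref
    uq = np.quantile(Y.values, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _double_trim(m: np.ndarray, a: np.ndarray, m_trim: float, a_trim: float) -> np.ndarray:
    """Indices surviving rank-based trimming of each M and A tail.

    ``floor(trim * n)`` genes are dropped from each tail of the M order
    and of the A order independently; the survivors are the
    intersection.  Ties are broken by original gene order (stable sort),
    so the result is deterministic.
    """
    n = m.size
    keep = np.ones(n, dtype=bool)
    for vals, frac in ((m, m_trim), (a, a_trim)):
        k = math.floor(frac * n)
        if k:
            order = np.argsort(vals, kind="stable")
            keep[order[:k]] = False
            keep[order[n - k:]] = False
    return np.flatnonzero(keep)


def tmm_relative_factors(cm: CountMatrix, opts: TMMOptions | None = None):
    """Per-sample relative scaling factors ``tau`` (reference gets exactly 1).

    For each non-reference sample: compute M/A values of its
    pre-normalized column against the reference column, restrict to
    valid genes (both strictly positive), trim each tail of the M and A
    orders, and average the survivors on the configured scale.

    ``m_trim = 0.5`` takes the exact median over the A-trim survivors
    (both mean scales coincide there).

    Returns ``(tau, usable)``: the factors and the per-sample count of
    genes entering each mean.
    """
    opts = opts or TMMOptions()
    Y = pre_normalize(cm)
    ref = select_reference(Y, opts)
    S = cm.n_samples
    tau = np.ones(S)
    usable = np.zeros(S, dtype=int)
    y_ref = Y.values[:, ref]
    usable[ref] = int(np.sum(y_ref > 0))
    for s in range(S):
        if s == ref:
            continue
        ma = ma_values(Y.values[:, s], y_ref)
        idx = np.flatnonzero(ma.valid)
        if idx.size == 0:
            raise ValueError(
                f"no usable genes for sample {cm.sample_ids[s]!r} vs reference"
            )
        m, a = ma.m[idx], ma.a[idx]
        ratio = Y.values[idx, s] / y_ref[idx]
        if opts.m_trim == 0.5:
            # exact-median limit of the trimmed mean
            n = idx.size
            k = math.floor(opts.a_trim * n)
            if k:
                order = np.argsort(a, kind="stable")
                kept = np.sort(order[k: n - k])
            else:
                kept = np.arange(n)
            if kept.size == 0:
                raise ValueError("no usable genes after trimming")
            if opts.mean_scale == "ratio":
                tau[s] = median_of(ratio[kept])
            else:
                tau[s] = 2.0 ** median_of(m[kept])
        else:
            kept = _double_trim(m, a, opts.m_trim, opts.a_trim)
            if kept.size == 0:
                raise ValueError("no usable genes after trimming")
            if opts.mean_scale == "ratio":
                tau[s] = float(np.mean(ratio[kept]))
            else:
                tau[s] = 2.0 ** float(np.mean(m[kept]))
        usable[s] = kept.size
    return tau, usable


def adjust_to_unit_product(tau: np.ndarray) -> np.ndarray:
    """Rescale factors by their geometric mean so they multiply to 1."""
    tau = np.asarray(tau, dtype=float)
    if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
        raise ValueError("factors must be strictly positive and finite")
    return tau / geometric_mean(tau)


def tmm_effective_library_sizes(tau_adj: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Effective library sizes ``e_s = tau_adj_s * N_s``."""
    tau_adj = np.asarray(tau_adj, dtype=float)
    N = np.asarray(N, dtype=float)
    if tau_adj.shape != N.shape:
        raise ValueError(f"length mismatch: {tau_adj.shape} vs {N.shape}")
    return tau_adj * N


def tmm_cpm(cm: CountMatrix, e: np.ndarray) -> np.ndarray:
    """Counts per million: ``Z[g, s] = X[g, s] / e_s * 1e6``."""
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("effective library sizes must be positive")
    return cm.counts / e * 1e6


def tmm_factors(cm: CountMatrix, opts: TMMOptions | None = None) -> NormalizationResult:
    """Full TMM pipeline: relative factors, unit-product adjustment,
    effective library sizes.  The final size factors are the adjusted
    relative factors — library size is deliberately not folded in,
    which is why TMM size factors do not track sequencing depth.
    """
    opts = opts or TMMOptions()
    tau, usable = tmm_relative_factors(cm, opts)
    tau_adj = adjust_to_unit_product(tau)
    e = tmm_effective_library_sizes(tau_adj, library_sizes(cm))
    return NormalizationResult(
        method="TMM",
        sample_ids=cm.sample_ids,
        conditions=cm.conditions,
        relative_factors=tau,
        adjusted_factors=tau_adj,
        effective_library_sizes=e,
        size_factors=tau_adj,
        usable_genes=usable,
        settings={
            "reference": opts.reference,
            "m_trim": opts.m_trim,
            "a_trim": opts.a_trim,
            "mean_scale": opts.mean_scale,
        },
    )
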