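"""Executable checks of the three equivalence properties linking TMM,
RLE and MRN.

Each check computes the relevant factor vectors (or normalized count
matrices) with this package's own implementations and reports the
maximum relative discrepancy, alongside flags stating whether the
design meets the property's preconditions.  Factors are computed even
when preconditions fail, so the reports double as a diagnostic of how
far the methods drift apart on general designs — at default settings
on composition-biased data they genuinely disagree.

The three properties:

1. With one replicate per condition, TMM run unweighted at a 50%
   M-trim and 0% A-trim against the first sample gives the same
   relative scaling factors as MRN (the trimmed mean degenerates to
   the median of ratios).
2. With two conditions and no replicates, RLE and MRN size factors
   are equal: both reduce to ``sqrt`` of the median count ratio
   between the two samples (exactly when the usable-gene count is
   odd; to interpolation error otherwise).
3. Under the preconditions of 1 and 2 jointly, the normalized counts
   of RLE and MRN and the counts-per-million of TMM agree up to the
   constant ``sqrt(N1*N2) / 1e6`` — TMM's effective library sizes
   equal the common RLE/MRN divisor times ``sqrt(N1*N2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CountMatrix, library_sizes
from .mrn import MRNOptions, mrn_normalize, mrn_relative_factors, mrn_size_factors
from .rle import rle_normalize, rle_size_factors
from .tmm import TMMOptions, tmm_cpm, tmm_factors, tmm_relative_factors

__all__ = [
    "PropositionReport",
    "check_proposition1",
    "check_proposition2",
    "check_proposition3",
    "check_all",
]

#: TMM settings under which the trimmed mean degenerates to the median
#: of ratios (reference pinned to the first sample, unweighted).
PROP1_TMM_OPTIONS = TMMOptions(reference=0, m_trim=0.5, a_trim=0.0, mean_scale="ratio")


@dataclass
class PropositionReport:
    """Outcome of one equivalence check.

    ``max_abs_rel_discrepancy`` is ``max |a - b| / max(|a|, |b|)`` over
    entries (0 where both are 0); ``per_sample_values`` holds the
    compared factor vectors side by side, keyed by method.
    """

    proposition: int
    preconditions_met: dict = field(default_factory=dict)
    max_abs_rel_discrepancy: float = float("nan")
    per_sample_values: dict = field(default_factory=dict)

    @property
    def applicable(self) -> bool:
        return all(self.preconditions_met.values())


def _rel_discrepancy(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.maximum(np.abs(a), np.abs(b))
    diff = np.abs(a - b)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(denom > 0, diff / denom, 0.0)
    return float(np.max(rel)) if rel.size else 0.0


def _design(cm: CountMatrix):
    reps = cm.replicates_per_condition
    K = len(reps)
    return K, reps


def check_proposition1(cm: CountMatrix) -> PropositionReport:
    """TMM (50% M-trim, 0% A-trim, unweighted, reference = first
    sample) vs MRN relative scaling factors; requires one replicate
    per condition."""
    K, reps = _design(cm)
    pre = {"R=1": all(r == 1 for r in reps.values())}
    tau_tmm, _ = tmm_relative_factors(cm, PROP1_TMM_OPTIONS)
    tau_k, labels, _ = mrn_relative_factors(cm, MRNOptions())
    by_label = dict(zip(labels, tau_k))
    tau_mrn = np.array([by_label[c] for c in cm.conditions])
    return PropositionReport(
        proposition=1,
        preconditions_met=pre,
        max_abs_rel_discrepancy=_rel_discrepancy(tau_tmm, tau_mrn),
        per_sample_values={"TMM": tau_tmm, "MRN": tau_mrn},
    )


def check_proposition2(cm: CountMatrix) -> PropositionReport:
    """RLE vs MRN size factors; requires two conditions, one replicate each."""
    K, reps = _design(cm)
    pre = {"K=2": K == 2, "R=1": all(r == 1 for r in reps.values())}
    f_rle = rle_size_factors(cm)
    f_mrn = mrn_size_factors(cm).size_factors
    return PropositionReport(
        proposition=2,
        preconditions_met=pre,
        max_abs_rel_discrepancy=_rel_discrepancy(f_rle, f_mrn),
        per_sample_values={"RLE": f_rle, "MRN": f_mrn},
    )


def check_proposition3(cm: CountMatrix) -> PropositionReport:
    """RLE- and MRN-normalized counts vs TMM counts-per-million rescaled
    by ``sqrt(N1*N2) / 1e6``; requires the preconditions of checks 1 and 2."""
    K, reps = _design(cm)
    pre = {"K=2": K == 2, "R=1": all(r == 1 for r in reps.values())}
    f_rle = rle_size_factors(cm)
    res_mrn = mrn_size_factors(cm)
    z_rle = rle_normalize(cm, f_rle)
    z_mrn = mrn_normalize(cm, res_mrn.size_factors)
    res_tmm = tmm_factors(cm, PROP1_TMM_OPTIONS)
    z_tmm = tmm_cpm(cm, res_tmm.effective_library_sizes)
    N = library_sizes(cm)
    # sqrt(N1*N2) for two samples == geometric mean of library sizes
    constant = float(np.exp(np.mean(np.log(N))))
    z_tmm_rescaled = z_tmm * constant / 1e6
    disc = max(
        _rel_discrepancy(z_tmm_rescaled, z_rle),
        _rel_discrepancy(z_rle, z_mrn),
        _rel_discrepancy(z_tmm_rescaled, z_mrn),
    )
    return PropositionReport(
        proposition=3,
        preconditions_met=pre,
        max_abs_rel_discrepancy=disc,
        per_sample_values={
            "TMM_effective_library_size": res_tmm.effective_library_sizes,
            "RLE": f_rle,
            "MRN": res_mrn.size_factors,
        },
    )


def check_all(cm: CountMatrix) -> list[PropositionReport]:
    return [check_proposition1(cm), check_proposition2(cm), check_proposition3(cm)]
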