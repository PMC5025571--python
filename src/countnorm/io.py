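"""Readers and writers for count matrices, condition files and factor tables.

Count matrices are plain TSV/CSV: first column gene IDs, header row
sample IDs, remaining cells counts.  Condition assignments are
two-column TSV (sample_id, condition), with or without a header line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, NormalizationResult

logger = logging.getLogger("countnorm")

__all__ = [
    "read_counts",
    "read_conditions",
    "write_counts",
    "write_matrix",
    "write_factors",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt:
        return "," if fmt.lower() == "csv" else "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path,
    fmt: str | None = None,
    conditions=None,
    strict_integers: bool = True,
) -> CountMatrix:
    """Read a genes × samples count table.

    Parameters
    ----------
    path
        TSV (default) or CSV file; the separator is inferred from the
        extension unless ``fmt`` is given.
    conditions
        Optional mapping ``{sample_id: condition}`` or per-sample
        sequence.  Default: every sample is its own condition (the
        no-replicate design).
    strict_integers
        Reject non-integral cells, naming the offending gene and
        sample.  With ``False``, real-valued matrices (e.g. expected
        counts) are accepted with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-numeric cell for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if strict_integers and np.any(values != np.round(values)):
        g, s = np.argwhere(values != np.round(values))[0]
        raise ValueError(
            f"{path}: non-integer count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    sample_ids = np.array(df.columns, dtype=object)
    if conditions is None:
        cond = sample_ids.copy()
    elif isinstance(conditions, dict):
        missing = [s for s in sample_ids if s not in conditions]
        if missing:
            raise ValueError(f"no condition assigned to sample(s) {missing}")
        cond = np.array([conditions[s] for s in sample_ids], dtype=object)
    else:
        cond = np.asarray(list(conditions), dtype=object)
        if cond.shape != sample_ids.shape:
            raise ValueError(
                f"expected {sample_ids.size} condition labels, got {cond.size}"
            )
    return CountMatrix(
        counts=values,
        gene_ids=np.array(df.index, dtype=object),
        sample_ids=sample_ids,
        conditions=cond,
    )


def read_conditions(path) -> dict:
    """Read a two-column (sample_id, condition) TSV into a dict.

    A leading header line like ``sample_id<TAB>condition`` is tolerated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if first[0] in ("sample", "sample_id") or first[1] in ("condition", "group"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise ValueError(f"{path}: duplicate sample IDs in condition file")
    return mapping


def write_counts(cm: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix as TSV/CSV with gene IDs as the first column."""
    path = Path(path)
    df = pd.DataFrame(
        cm.counts.astype(np.int64) if np.all(cm.counts == np.round(cm.counts))
        else cm.counts,
        index=pd.Index(cm.gene_ids, name="gene_id"),
        columns=cm.sample_ids,
    )
    df.to_csv(path, sep=_sep_for(path, fmt))


def write_matrix(values: np.ndarray, cm: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a derived genes × samples matrix (normalized counts, CPM)."""
    path = Path(path)
    df = pd.DataFrame(
        values,
        index=pd.Index(cm.gene_ids, name="gene_id"),
        columns=cm.sample_ids,
    )
    df.to_csv(path, sep=_sep_for(path, fmt), float_format="%.7g")


def write_factors(result: NormalizationResult, path) -> None:
    """Write a factor table (one row per sample, 7 decimal places)."""
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.7f",
                             na_rep="NA")
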