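"""Reading and writing the tab-delimited tables the pipeline exchanges.

Conventions
-----------
Count and expression matrices are :class:`pandas.DataFrame` objects with
gene identifiers on the row index and sample identifiers on the columns
(genes x samples, the usual orientation of an RNA-seq count table).
Sample metadata is a DataFrame indexed by sample id with columns
``category``, ``dataset``, ``batch`` and ``is_control``.

Files are tab-delimited UTF-8 with a header row of sample ids and a first
column of gene ids; the delimiter is overridable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["category", "dataset", "batch", "is_control"]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


def validate_count_matrix(counts: pd.DataFrame,
                          min_samples: int = 2) -> pd.DataFrame:
    """Check the count-matrix invariants, returning the validated frame.

    Counts must be finite, non-negative numbers; gene and sample ids must
    be unique; a reference matrix needs at least two samples
    (``min_samples=1`` admits single-column query files).
    """
    _check_unique(counts.index, "gene")
    _check_unique(counts.columns, "sample")
    if counts.shape[1] < min_samples:
        raise ValueError(
            f"count matrix needs >= {min_samples} samples, got {counts.shape[1]}"
        )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_bad_cell(counts, lambda v: not _is_number(v))
        raise ValueError(f"non-numeric count at gene {bad[0]!r}, sample {bad[1]!r}")
    if not np.isfinite(values).all():
        bad = _first_bad_cell(counts, lambda v: not np.isfinite(v))
        raise ValueError(f"non-finite count at gene {bad[0]!r}, sample {bad[1]!r}")
    if (values < 0).any():
        bad = _first_bad_cell(counts, lambda v: v < 0)
        raise ValueError(f"negative count at gene {bad[0]!r}, sample {bad[1]!r}")
    return counts


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(df: pd.DataFrame, pred):
    for gene, row in df.iterrows():
        for sample, v in row.items():
            if pred(v):
                return gene, sample
    raise AssertionError("no offending cell found")  # pragma: no cover


def read_count_matrix(path, delimiter: str = "\t",
                      min_samples: int = 2) -> pd.DataFrame:
    """Read a gene x sample count matrix from a delimited text file.

    The first row is the header of sample ids and the first column holds
    gene ids. Duplicate ids, ragged rows and non-numeric or negative cells
    are hard errors naming the offending coordinate.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed count matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        gene = mask.index[mask.any(axis=1)][0]
        sample = mask.columns[mask.loc[gene]][0]
        raise ValueError(
            f"non-numeric count {df.loc[gene, sample]!r} at gene {gene!r}, "
            f"sample {sample!r} in {path}"
        )
    if (numeric.to_numpy() == numeric.to_numpy().astype(np.int64)).all():
        numeric = numeric.astype(np.int64)
    return validate_count_matrix(numeric, min_samples=min_samples)


def write_count_matrix(counts: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a gene x sample matrix as delimited text (round-trips exactly
    for integer counts)."""
    counts.to_csv(path, sep=delimiter, index_label="gene")


def read_expression_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene x sample real-valued expression matrix."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return df.astype(float)


write_expression_matrix = write_count_matrix


def read_metadata(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read per-sample metadata: columns ``sample`` and ``category`` are
    required; ``dataset`` defaults to the sample id, ``batch`` to
    ``"batch0"`` and ``is_control`` to False.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if "sample" not in df.columns or "category" not in df.columns:
        raise ValueError(
            f"metadata {path} must contain 'sample' and 'category' columns, "
            f"got {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"sample {dup!r} listed twice in metadata")
    if (df["category"].str.len() == 0).any():
        bad = df.loc[df["category"].str.len() == 0, "sample"].iloc[0]
        raise ValueError(f"empty category for sample {bad!r}")
    meta = pd.DataFrame(index=pd.Index(df["sample"], name="sample"))
    meta["category"] = df["category"].to_numpy()
    meta["dataset"] = df["dataset"].to_numpy() if "dataset" in df else meta.index
    meta["batch"] = df["batch"].to_numpy() if "batch" in df else "batch0"
    if "is_control" in df:
        meta["is_control"] = (
            df["is_control"].str.lower().isin(["true", "1", "yes"]).to_numpy()
        )
    else:
        meta["is_control"] = False
    if (meta["dataset"].str.len() == 0).any():
        raise ValueError("empty dataset id in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path, delimiter: str = "\t") -> None:
    meta.to_csv(path, sep=delimiter, index_label="sample")


def align_samples(counts: pd.DataFrame, meta: pd.DataFrame):
    """Restrict matrix and metadata to their common samples, in matrix order.

    Dropped samples are logged as a warning. Raises if fewer than two
    samples or fewer than two categories remain.
    """
    common = [s for s in counts.columns if s in meta.index]
    dropped = sorted(
        set(counts.columns).symmetric_difference(meta.index) & set(counts.columns)
        | (set(meta.index) - set(counts.columns))
    )
    if not common:
        raise ValueError("matrix and metadata share no samples")
    if dropped:
        logger.warning("align_samples dropped %d sample(s): %s", len(dropped), dropped)
    aligned_counts = counts.loc[:, common]
    aligned_meta = meta.loc[common]
    if aligned_counts.shape[1] < 2:
        raise ValueError("fewer than 2 samples after alignment")
    if aligned_meta["category"].nunique() < 2:
        raise ValueError("fewer than 2 categories after alignment")
    return aligned_counts, aligned_meta


def write_run_summary(path, summary: dict) -> None:
    """Write the JSON run summary (parameters, seed, file paths)."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
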