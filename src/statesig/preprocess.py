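"""Count filtering, normalization, transformation and batch correction.

The downstream statistics (F-ratios, distances, rank correlations) all
consume log-scale, size-factor-normalized expression. The transform chain
is: prefilter -> size factors (median-of-ratios) -> shifted-log2 transform
-> optional linear-model batch correction -> optional replicate collapse.

The shifted-log2 transform is used as the variance-stabilizing step: the
classification statistics downstream are rank-based or variance-ratio-based
and depend only weakly on the exact stabilizer, and the shifted log is
monotone in counts, which Spearman classification is invariant to.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConfoundedDesignError(ValueError):
    """Batch is aliased with the biological category; correction would
    remove the signal of interest."""


def prefilter_genes(counts: pd.DataFrame, min_count: int = 1,
                    min_fraction: float = 0.8) -> pd.DataFrame:
    """Keep genes detected (count >= ``min_count``) in at least
    ``min_fraction`` of samples; the boundary is inclusive.

    Raises if no gene survives.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n = counts.shape[1]
    n_ok = (counts.to_numpy() >= min_count).sum(axis=1)
    # integer comparison with a small tolerance so that e.g. 4/5 >= 0.8 holds
    keep = n_ok + 1e-9 >= min_fraction * n
    if not keep.any():
        raise ValueError(
            "prefilter removed every gene; relax min_count/min_fraction "
            f"(min_count={min_count}, min_fraction={min_fraction})"
        )
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over reference genes
    (genes with nonzero counts in every sample) of count_ij divided by the
    gene's geometric mean across samples. Factors are not rescaled further.
    """
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; prefilter the "
            "matrix before computing size factors"
        )
    ref = values[reference]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its upper quartile over nonzero-count genes
    matches the across-sample mean upper quartile."""
    values = counts.to_numpy(dtype=float)
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        nonzero = values[values[:, j] > 0, j]
        if nonzero.size == 0:
            raise ValueError(
                f"sample {counts.columns[j]!r} has no nonzero counts; "
                "cannot upper-quartile normalize"
            )
        uq[j] = np.percentile(nonzero, 75)
    if (uq <= 0).any():
        bad = counts.columns[np.argmax(uq <= 0)]
        raise ValueError(f"non-positive upper quartile for sample {bad!r}")
    scale = uq.mean() / uq
    return counts * scale


def vst_transform(counts: pd.DataFrame, factors: pd.Series | None = None,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Variance-stabilizing-style transform: log2(count / factor + pseudocount).

    Strictly increasing in counts for a fixed factor; doubling a sample's
    counts and its factor leaves the column unchanged.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if factors is None:
        factors = size_factors(counts)
    missing = [s for s in counts.columns if s not in factors.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing}")
    factors = factors.loc[counts.columns]
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("size factors must be positive and finite")
    normalized = counts.to_numpy(dtype=float) / factors.to_numpy()
    return pd.DataFrame(np.log2(normalized + pseudocount),
                        index=counts.index, columns=counts.columns)


def _dummies(labels: pd.Series) -> np.ndarray:
    """Treatment-coded indicator columns (first level dropped)."""
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).to_numpy(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def remove_batch_effect(expr: pd.DataFrame, meta: pd.DataFrame,
                        retain_category: bool = True) -> pd.DataFrame:
    """Subtract the least-squares batch component from each gene.

    Each gene is regressed on batch indicators plus (by default) category
    indicators; only the fitted batch component is removed, so
    between-category differences are retained. Single-batch input is
    returned unchanged. Raises :class:`ConfoundedDesignError` when batch
    is aliased with category.
    """
    meta = meta.loc[expr.columns]
    batches = meta["batch"]
    if batches.nunique() < 2:
        return expr.copy()
    batch_x = _dummies(batches)
    covar_x = _dummies(meta["category"]) if retain_category else \
        np.empty((len(meta), 0))
    intercept = np.ones((len(meta), 1))
    design = np.hstack([intercept, covar_x, batch_x])
    rank_full = np.linalg.matrix_rank(design)
    rank_covar = np.linalg.matrix_rank(np.hstack([intercept, covar_x]))
    if rank_full < rank_covar + batch_x.shape[1]:
        raise ConfoundedDesignError(
            "batch is confounded with category "
            f"(batches {sorted(batches.unique())} aliased with categories "
            f"{sorted(meta['category'].unique())}); cannot separate the effects"
        )
    y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_cols = slice(1 + covar_x.shape[1], None)
    fitted_batch = batch_x @ beta[batch_cols]
    corrected = y - fitted_batch
    return pd.DataFrame(corrected.T, index=expr.index, columns=expr.columns)


def collapse_to_datasets(expr: pd.DataFrame, meta: pd.DataFrame):
    """Average replicate columns into one column per dataset id.

    The category must be uniform within a dataset. Returns the collapsed
    expression matrix and a collapsed metadata table (one row per dataset,
    indexed by dataset id, in order of first appearance).
    """
    meta = meta.loc[expr.columns]
    collapsed_cols = {}
    rows = []
    for dataset in pd.unique(meta["dataset"]):
        samples = meta.index[meta["dataset"] == dataset]
        cats = meta.loc[samples, "category"].unique()
        if len(cats) > 1:
            raise ValueError(
                f"dataset {dataset!r} mixes categories {sorted(cats)}; "
                "cannot collapse replicates"
            )
        collapsed_cols[dataset] = expr[samples].mean(axis=1)
        rows.append({
            "category": cats[0],
            "dataset": dataset,
            "batch": ";".join(sorted(meta.loc[samples, "batch"].unique())),
            "is_control": bool(meta.loc[samples, "is_control"].all()),
        })
    collapsed = pd.DataFrame(collapsed_cols)
    collapsed.index = expr.index
    meta_out = pd.DataFrame(rows, index=pd.Index(collapsed.columns, name="sample"))
    return collapsed, meta_out


def preprocess_counts(counts: pd.DataFrame, meta: pd.DataFrame, *,
                      min_count: int = 1, min_fraction: float = 0.8,
                      pseudocount: float = 1.0, batch_correct: bool = True,
                      upper_quartile_samples=None) -> pd.DataFrame:
    """Full default chain: prefilter -> (optional per-sample UQ rescale) ->
    size factors -> shifted-log2 -> batch correction.

    ``upper_quartile_samples`` optionally names samples whose counts are
    first adjusted by upper-quartile normalization (dataset-specific rescue
    for library-construction artifacts); which samples need it is a caller
    decision.
    """
    filtered = prefilter_genes(counts, min_count=min_count,
                               min_fraction=min_fraction)
    working = filtered.astype(float)
    if upper_quartile_samples:
        uq = upper_quartile_normalize(filtered)
        working = working.copy()
        working[list(upper_quartile_samples)] = uq[list(upper_quartile_samples)]
    factors = size_factors(working)
    expr = vst_transform(working, factors, pseudocount=pseudocount)
    if batch_correct:
        expr = remove_batch_effect(expr, meta.loc[expr.columns])
    return expr
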