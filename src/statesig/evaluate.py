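"""Leave-one-out cross-validation and reference-subsampling robustness.

Each fold removes one unit (a dataset, or a sample in sample-level mode),
reruns gene selection on the remaining reference only (no leakage), and
classifies the held-out unit by Spearman correlation over the selected
genes. Robustness is probed by repeating LOOCV on stratified random
subsamples of the reference at decreasing proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import classify_query
from .preprocess import collapse_to_datasets
from .selection import SelectionResult, select_genes

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """LOOCV outcome, optionally with a subsampling-robustness table.

    Attributes
    ----------
    mode : {"dataset", "sample"} unit of cross-validation
    folds : per-fold records (unit, true, assigned, correct)
    accuracy : correct folds / evaluated folds
    per_category_recall : recall per true category
    robustness : rows (proportion, repeat, accuracy), or None
    selector : selection method descriptor
    seed : RNG seed used for subsampling (None for plain LOOCV)
    n_skipped : folds skipped because a category would have vanished
    """

    mode: str
    folds: pd.DataFrame
    accuracy: float
    per_category_recall: pd.Series
    selector: dict = field(default_factory=dict)
    robustness: pd.DataFrame | None = None
    seed: int | None = None
    n_skipped: int = 0


def _select_for_fold(expr, meta, selector, selector_params) -> SelectionResult:
    params = dict(selector_params or {})
    params.setdefault("level", "sample")  # units are already collapsed
    result = select_genes(expr, meta, method=selector, **params)
    # a rank correlation needs >= 3 genes; on degenerate folds (elbow right
    # after a dominant gene) pad the set with the next-ranked genes
    if len(result.selected_genes) < 3 and result.ranking is not None:
        logger.debug(
            "fold selected %d gene(s); padding to the top 3 ranked genes",
            len(result.selected_genes),
        )
        result.selected_genes = result.ranking["gene"].head(3).tolist()
    return result


def loocv(expr: pd.DataFrame, meta: pd.DataFrame, *,
          selector: str = "f_elbow", selector_params: dict | None = None,
          mode: str = "dataset", min_overlap: float = 0.5) -> EvaluationReport:
    """Leave-one-out cross-validation of the selection + classification chain.

    ``expr`` is a preprocessed genes x samples expression matrix. In
    dataset mode replicate columns are first averaged per dataset and each
    dataset is one unit. Gene selection is rerun inside every fold on the
    remaining units only. Folds whose removal would leave a category empty
    are skipped with a warning and excluded from the denominator.
    """
    if mode not in ("dataset", "sample"):
        raise ValueError(f"mode must be 'dataset' or 'sample', got {mode!r}")
    if mode == "dataset":
        units, unit_meta = collapse_to_datasets(expr, meta)
    else:
        units, unit_meta = expr, meta.loc[expr.columns]
    if units.shape[1] < 3:
        raise ValueError(f"need >= 3 units for LOOCV, got {units.shape[1]}")
    category_counts = unit_meta["category"].value_counts()
    records = []
    n_skipped = 0
    for unit in units.columns:
        true_cat = unit_meta.loc[unit, "category"]
        if category_counts[true_cat] < 2:
            logger.warning(
                "skipping fold %r: category %r would vanish from the reference",
                unit, true_cat,
            )
            n_skipped += 1
            continue
        rest = units.drop(columns=[unit])
        rest_meta = unit_meta.drop(index=[unit])
        selection = _select_for_fold(rest, rest_meta, selector, selector_params)
        result = classify_query(
            units[unit], rest, rest_meta, genes=selection.selected_genes,
            min_overlap=min_overlap,
        )
        records.append({
            "unit": unit,
            "true": true_cat,
            "assigned": result.assigned_category,
            "correct": result.assigned_category == true_cat,
            "n_genes": len(selection.selected_genes),
        })
    folds = pd.DataFrame(records)
    if folds.empty:
        raise ValueError("every fold was skipped; categories are too small")
    accuracy = float(folds["correct"].mean())
    recall = folds.groupby("true")["correct"].mean()
    return EvaluationReport(
        mode=mode,
        folds=folds,
        accuracy=accuracy,
        per_category_recall=recall,
        selector={"method": selector, **(selector_params or {})},
        n_skipped=n_skipped,
    )


def _stratified_subsample(unit_meta: pd.DataFrame, proportion: float,
                          rng: np.random.Generator) -> list:
    """Round-half-up per category, minimum one unit, without replacement."""
    chosen = []
    for cat in pd.unique(unit_meta["category"]):
        members = list(unit_meta.index[unit_meta["category"] == cat])
        n = max(1, int(np.floor(proportion * len(members) + 0.5)))
        picked = rng.choice(len(members), size=n, replace=False)
        chosen.extend(members[i] for i in sorted(picked))
    return chosen


def subsample_robustness(expr: pd.DataFrame, meta: pd.DataFrame, *,
                         selector: str = "f_elbow",
                         selector_params: dict | None = None,
                         mode: str = "dataset",
                         proportions=(1.0, 0.8, 0.6, 0.4, 0.2),
                         repeats: int = 10,
                         seed: int | None = None) -> EvaluationReport:
    """LOOCV accuracy under stratified reference subsampling.

    For each proportion and repeat, a stratified random subsample of the
    reference units is drawn (round-half-up per category, at least one
    unit each) and full LOOCV is run on the subsample. Proportion 1.0
    reproduces plain LOOCV exactly for every repeat.
    """
    for p in proportions:
        if not 0 < p <= 1:
            raise ValueError(f"proportions must be in (0, 1], got {p}")
    if mode == "dataset":
        units, unit_meta = collapse_to_datasets(expr, meta)
    else:
        units, unit_meta = expr, meta.loc[expr.columns]
    rng = np.random.default_rng(seed)
    rows = []
    full_report = None
    for p in sorted(proportions, reverse=True):
        for rep in range(repeats):
            if p == 1.0:
                if full_report is None:
                    full_report = loocv(
                        units, unit_meta, selector=selector,
                        selector_params=selector_params, mode="sample",
                    )
                acc = full_report.accuracy
            else:
                keep = _stratified_subsample(unit_meta, p, rng)
                sub_report = loocv(
                    units[keep], unit_meta.loc[keep], selector=selector,
                    selector_params=selector_params, mode="sample",
                )
                acc = sub_report.accuracy
            rows.append({"proportion": p, "repeat": rep, "accuracy": acc})
    robustness = pd.DataFrame(rows)
    if full_report is None:
        full_report = loocv(
            units, unit_meta, selector=selector,
            selector_params=selector_params, mode="sample",
        )
    return EvaluationReport(
        mode=mode,
        folds=full_report.folds,
        accuracy=full_report.accuracy,
        per_category_recall=full_report.per_category_recall,
        selector={"method": selector, **(selector_params or {})},
        robustness=robustness,
        seed=seed,
        n_skipped=full_report.n_skipped,
    )
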