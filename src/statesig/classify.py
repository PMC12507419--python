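"""Rank-correlation classification of query transcriptomes.

A query column is compared to every reference column by Spearman
correlation over the selected gene set, using pairwise-complete
observations (positions missing in either vector are dropped). Per
category, the mean correlation and its standard error are reported; the
query is assigned to the category with the highest mean correlation.
Because Spearman correlation depends only on ranks, the assignment is
invariant to any strictly monotone per-sample transform of expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .projection import Embedding, classical_mds, euclidean_distance_matrix

logger = logging.getLogger(__name__)

#: mean-correlation margin under which the top categories are flagged as tied
AMBIGUITY_MARGIN = 0.01


@dataclass
class ClassificationResult:
    """Per-category Spearman summary for one query.

    Attributes
    ----------
    summary : DataFrame indexed by category with columns mean_rho, sem,
        n_ref, assigned (the assigned row flagged True)
    assigned_category : category with maximal mean correlation
    tied_categories : categories within the ambiguity margin of the top
    ambiguous : True when more than one category is effectively tied
    rho : per-reference-sample correlations
    n_genes_used : size of the gene intersection the correlations used
    """

    summary: pd.DataFrame
    assigned_category: str
    tied_categories: list = field(default_factory=list)
    ambiguous: bool = False
    rho: pd.Series | None = None
    n_genes_used: int = 0


def spearman_pairwise_complete(x, y) -> float:
    """Spearman correlation over pairwise-complete observations.

    Positions where either vector is missing (NaN) are dropped; at least
    three complete pairs are required. Mid-ranks are used for ties. If
    either vector has zero rank variance the coefficient is undefined and
    NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    n = int(complete.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xc, yc = x[complete], y[complete]
    if np.unique(xc).size < 2 or np.unique(yc).size < 2:
        warnings.warn("zero rank variance; Spearman correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(xc, yc)
    return float(rho)


class SpearmanReferenceClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-category classifier by mean Spearman correlation.

    ``fit(X, y)`` stores the reference profiles (samples x genes) and their
    category labels; ``predict`` assigns each query row to the category
    whose reference samples it correlates with most strongly on average.

    Parameters
    ----------
    min_overlap : float, default 0.5
        Minimum fraction of the fitted gene set a query must share
        (non-missing) with the reference.
    ambiguity_margin : float, default 0.01
        Mean-correlation margin under which competing categories are
        reported as tied.
    """

    def __init__(self, min_overlap: float = 0.5,
                 ambiguity_margin: float = AMBIGUITY_MARGIN):
        self.min_overlap = min_overlap
        self.ambiguity_margin = ambiguity_margin

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.reference_ = X.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            self.reference_ = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != self.reference_.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 categories in the reference")
        self.labels_ = pd.Series(y, index=self.reference_.index)
        self.n_features_in_ = self.reference_.shape[1]
        return self

    def classify_one(self, query: pd.Series | np.ndarray) -> ClassificationResult:
        """Full per-category summary for a single query profile."""
        check_is_fitted(self, "reference_")
        if isinstance(query, pd.Series):
            query = query.reindex(self.reference_.columns)
        query = np.asarray(query, dtype=float)
        if query.shape[0] != self.n_features_in_:
            raise ValueError(
                f"query has {query.shape[0]} genes, reference {self.n_features_in_}"
            )
        usable = np.isfinite(query)
        overlap = usable.mean()
        if overlap < self.min_overlap:
            raise ValueError(
                f"query shares only {overlap:.1%} of the selected genes with "
                f"the reference (minimum {self.min_overlap:.0%})"
            )
        rho = pd.Series(
            {
                sample: spearman_pairwise_complete(
                    query, self.reference_.loc[sample].to_numpy()
                )
                for sample in self.reference_.index
            },
            name="rho",
        )
        rows = []
        for cat in self.classes_:
            vals = rho[self.labels_ == cat].dropna()
            n_ref = len(vals)
            mean_rho = float(vals.mean()) if n_ref else float("nan")
            sem = float(vals.std(ddof=1) / np.sqrt(n_ref)) if n_ref > 1 \
                else float("nan")
            rows.append({"category": cat, "mean_rho": mean_rho, "sem": sem,
                         "n_ref": n_ref})
        summary = pd.DataFrame(rows).set_index("category")
        ranked = summary["mean_rho"].sort_values(ascending=False)
        assigned = ranked.index[0]
        tied = ranked.index[
            ranked >= ranked.iloc[0] - self.ambiguity_margin
        ].tolist()
        summary["assigned"] = summary.index == assigned
        if len(tied) > 1:
            logger.debug(
                "ambiguous classification: categories %s within %.3g of the top",
                tied, self.ambiguity_margin,
            )
        return ClassificationResult(
            summary=summary,
            assigned_category=str(assigned),
            tied_categories=[str(t) for t in tied],
            ambiguous=len(tied) > 1,
            rho=rho,
            n_genes_used=int(usable.sum()),
        )

    def predict(self, X):
        check_is_fitted(self, "reference_")
        if isinstance(X, pd.DataFrame):
            rows = [X.loc[i] for i in X.index]
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            rows = list(X)
        return np.asarray([self.classify_one(r).assigned_category for r in rows])


def classify_query(query: pd.Series | pd.DataFrame, reference: pd.DataFrame,
                   meta: pd.DataFrame, genes=None, *,
                   min_overlap: float = 0.5,
                   ambiguity_margin: float = AMBIGUITY_MARGIN) -> ClassificationResult:
    """Classify one query column against a genes x samples reference.

    ``genes`` restricts the comparison to the selected gene set (the
    default workflow); pass None to correlate over all shared genes.
    """
    if isinstance(query, pd.DataFrame):
        if query.shape[1] != 1:
            raise ValueError("query must be a single column")
        query = query.iloc[:, 0]
    if genes is not None:
        genes = list(genes)
        if not genes:
            raise ValueError("empty gene subset")
        reference = reference.loc[[g for g in genes if g in reference.index]]
    meta = meta.loc[reference.columns]
    clf = SpearmanReferenceClassifier(
        min_overlap=min_overlap, ambiguity_margin=ambiguity_margin,
    ).fit(reference.T, meta["category"].to_numpy())
    return clf.classify_one(query.reindex(reference.index))


def project_query(query: pd.Series | pd.DataFrame, reference: pd.DataFrame,
                  meta: pd.DataFrame, genes=None, *,
                  query_id: str = "query", dims: int = 2) -> Embedding:
    """Place the query on the reference map by joint classical MDS.

    The distance matrix is recomputed over reference columns plus the
    query column, so the reference-only geometry may shift slightly;
    placement is joint, not out-of-sample interpolation.
    """
    if isinstance(query, pd.DataFrame):
        if query.shape[1] != 1:
            raise ValueError("query must be a single column")
        query = query.iloc[:, 0]
    combined = reference.copy()
    combined[query_id] = query.reindex(reference.index)
    if genes is not None:
        genes = [g for g in genes if g in combined.index]
        if not genes:
            raise ValueError("no selected genes present in the matrices")
        combined = combined.loc[genes]
    combined = combined.dropna(axis=0)
    return classical_mds(euclidean_distance_matrix(combined), dims=dims)
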