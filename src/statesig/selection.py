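"""Gene ranking and optimal-set selection.

The core selector ranks genes by the one-way ANOVA F-ratio of their
expression across category labels and cuts the ranked curve at its elbow:
the point of maximum perpendicular distance from the chord joining the
first and last points of the (min-max scaled) ranked F curve. Genes with
F-values strictly above the elbow gene's form the optimal set.

Two baseline selectors are provided: top-k across-sample variance (the
conventional default of MDS packages) and a shadow-feature ("Boruta"-style)
wrapper around a randomized-tree ensemble.

Estimators follow scikit-learn conventions: ``fit(X, y)`` with X of shape
(n_samples, n_features); module-level functions wrap them for the
genes x samples DataFrames used elsewhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

from .preprocess import collapse_to_datasets

logger = logging.getLogger(__name__)

#: relative clamp applied to infinite F sentinels before the elbow geometry
_INF_CLAMP = 1e-6


class NoGenesSelectedError(ValueError):
    """The selector confirmed no genes; advice is in the message."""


@dataclass
class SelectionResult:
    """Outcome of a gene-selection run.

    Attributes
    ----------
    method : {"f_elbow", "variance_topk", "shadow_feature"}
    selected_genes : list of gene ids, in selection order
    elbow_index : 1-based rank of the elbow gene (f_elbow only, else None)
    curve : ranked statistic sequence (descending), for plotting
    params : method parameters, including any seed
    ranking : per-gene table (gene, f_value/statistic, rank, selected)
    """

    method: str
    selected_genes: list
    elbow_index: int | None
    curve: np.ndarray
    params: dict = field(default_factory=dict)
    ranking: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.ranking is not None:
            out = self.ranking.copy()
            out["method"] = self.method
            return out
        return pd.DataFrame({
            "gene": self.selected_genes,
            "rank": np.arange(1, len(self.selected_genes) + 1),
            "selected": True,
            "method": self.method,
        })


def one_way_f(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F per column of X (samples x features).

    F = between-group mean square / within-group mean square. Columns with
    zero within-group variance but nonzero between-group variance get
    +inf; columns constant everywhere get 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = pd.unique(y)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 categories, got {len(groups)}")
    n_total = X.shape[0]
    grand_mean = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g in groups:
        block = X[y == g]
        if block.shape[0] == 0:
            raise ValueError(f"category {g!r} has no samples")
        gm = block.mean(axis=0)
        ss_between += block.shape[0] * (gm - grand_mean) ** 2
        ss_within += ((block - gm) ** 2).sum(axis=0)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within < 1:
        raise ValueError(
            "no residual degrees of freedom: need more samples than categories"
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    # scale-aware tolerance for "exactly constant within groups"
    scale = (X ** 2).mean(axis=0) + 1.0
    zero_within = ss_within <= 1e-12 * scale
    zero_between = ss_between <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f[zero_within & ~zero_between] = np.inf
    f[zero_within & zero_between] = 0.0
    return f


def rank_genes(f: np.ndarray, gene_ids) -> pd.DataFrame:
    """Descending-F ranking table; ties broken by gene id."""
    order = np.lexsort((np.asarray(gene_ids, dtype=object), -f))
    ranking = pd.DataFrame({
        "gene": np.asarray(gene_ids, dtype=object)[order],
        "f_value": f[order],
        "rank": np.arange(1, len(f) + 1),
    })
    return ranking


def perpendicular_distances(curve: np.ndarray) -> np.ndarray:
    """Distances of each ranked point to the chord through the first and
    last points, after min-max scaling both axes to [0, 1].

    Infinite values must be clamped by the caller. A flat (degenerate)
    curve yields all-zero distances.
    """
    n = len(curve)
    x = np.linspace(0.0, 1.0, n)
    lo, hi = curve.min(), curve.max()
    if hi - lo <= 0:
        return np.zeros(n)
    y = (curve - lo) / (hi - lo)
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    return np.abs((y1 - y0) * (x - x0) - (x1 - x0) * (y - y0)) / chord


def _clamp_infinite(curve: np.ndarray) -> np.ndarray:
    finite = np.isfinite(curve)
    if finite.all():
        return curve
    if not finite.any():
        raise ValueError("need >= 3 genes with finite F-values for the elbow")
    clamped = curve.copy()
    top = curve[finite].max()
    clamped[~finite] = top * (1 + _INF_CLAMP) if top > 0 else _INF_CLAMP
    return clamped


def elbow_select(ranking: pd.DataFrame) -> SelectionResult:
    """Cut a descending F ranking at its elbow.

    The elbow is the ranked point at maximum perpendicular distance from
    the chord joining the first and last points of the min-max scaled
    curve (ties -> smallest rank). Selected genes are those with F
    strictly greater than the elbow gene's F; if that set is empty the
    elbow gene (and any genes tied with it) is included instead.
    """
    curve = ranking["f_value"].to_numpy(dtype=float)
    if np.isfinite(curve).sum() < 3:
        raise ValueError(
            f"need >= 3 genes with finite F-values, got {np.isfinite(curve).sum()}"
        )
    geom = _clamp_infinite(curve)
    distances = perpendicular_distances(geom)
    if distances.max() <= 1e-12:
        logger.warning(
            "degenerate (linear) ranked-F curve: all chord distances ~0; "
            "elbow defaults to rank 1"
        )
    elbow_pos = int(np.argmax(distances))  # first occurrence = smallest rank
    elbow_f = geom[elbow_pos]
    selected_mask = geom > elbow_f
    if not selected_mask.any():
        selected_mask = geom >= elbow_f
    selected = ranking.loc[selected_mask, "gene"].tolist()
    out = ranking.copy()
    out["selected"] = selected_mask
    return SelectionResult(
        method="f_elbow",
        selected_genes=selected,
        elbow_index=elbow_pos + 1,
        curve=curve,
        params={},
        ranking=out,
    )


class FRatioSelector(SelectorMixin, BaseEstimator):
    """Select features by one-way ANOVA F-ratio with an elbow cutoff.

    Parameters
    ----------
    None (the procedure is parameter-free by design: the cutoff adapts to
    the ranked curve rather than to a user threshold).

    Attributes
    ----------
    f_values_ : ndarray of shape (n_features,)
        Per-feature F ratios in input order (+inf for zero within-group
        variance with signal, 0 for all-constant features).
    ranking_ : DataFrame with columns gene, f_value, rank, selected.
    elbow_index_ : int, 1-based rank of the elbow feature.
    selected_genes_ : list of selected feature names, best first.
    support_ : boolean mask over input features.
    """

    def fit(self, X, y):
        X_arr, feature_names = self._coerce(X)
        y = np.asarray(y)
        if len(y) != X_arr.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.f_values_ = one_way_f(X_arr, y)
        ranking = rank_genes(self.f_values_, feature_names)
        result = elbow_select(ranking)
        self.ranking_ = result.ranking
        self.elbow_index_ = result.elbow_index
        self.selected_genes_ = result.selected_genes
        self.result_ = result
        selected = set(result.selected_genes)
        self.support_ = np.array([g in selected for g in feature_names])
        self.n_features_in_ = X_arr.shape[1]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        return self

    @staticmethod
    def _coerce(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, list(range(X.shape[1]))

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class VarianceTopKSelector(SelectorMixin, BaseEstimator):
    """Select the k features with largest across-sample variance.

    The conventional default of MDS packages (k = 500). Ties at the cutoff
    are resolved by lexicographic feature name, so selection is
    deterministic.
    """

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        X_arr, feature_names = FRatioSelector._coerce(X)
        variances = X_arr.var(axis=0, ddof=1)
        order = np.lexsort((np.asarray(feature_names, dtype=object), -variances))
        k = min(self.k, X_arr.shape[1])
        chosen = order[:k]
        self.variances_ = variances
        self.selected_genes_ = [feature_names[i] for i in chosen]
        self.support_ = np.zeros(X_arr.shape[1], dtype=bool)
        self.support_[chosen] = True
        self.n_features_in_ = X_arr.shape[1]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.result_ = SelectionResult(
            method="variance_topk",
            selected_genes=list(self.selected_genes_),
            elbow_index=None,
            curve=variances[order],
            params={"k": self.k},
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class ShadowFeatureSelector(SelectorMixin, BaseEstimator):
    """Shadow-feature (Boruta-style) selection with a tree ensemble.

    Each iteration appends a column-permuted shadow copy of every feature,
    fits a randomized-tree classifier of the category labels, and records
    a "hit" for every real feature whose importance exceeds the maximum
    shadow importance. Features whose hit counts beat a Binomial(n_iter,
    0.5) upper tail at level ``alpha`` are Confirmed, returned in
    descending hit order. A fixed ``random_state`` makes runs identical.
    """

    def __init__(self, n_iter: int = 100, alpha: float = 0.05,
                 n_estimators: int = 100, random_state: int | None = None):
        self.n_iter = n_iter
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_iter < 10:
            raise ValueError(f"n_iter must be >= 10, got {self.n_iter}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        X_arr, feature_names = FRatioSelector._coerce(X)
        y = np.asarray(y)
        if len(pd.unique(y)) < 2:
            raise ValueError("need >= 2 categories")
        rng = check_random_state(self.random_state)
        n_features = X_arr.shape[1]
        hits = np.zeros(n_features, dtype=int)
        for _ in range(self.n_iter):
            shadow = X_arr.copy()
            for j in range(n_features):
                rng.shuffle(shadow[:, j])
            augmented = np.hstack([X_arr, shadow])
            forest = ExtraTreesClassifier(
                n_estimators=self.n_estimators,
                random_state=rng.randint(np.iinfo(np.int32).max),
            )
            forest.fit(augmented, y)
            importances = forest.feature_importances_
            hits += importances[:n_features] > importances[n_features:].max()
        # smallest hit count h with P(Bin(n_iter, 1/2) >= h) <= alpha
        threshold = int(stats.binom.isf(self.alpha, self.n_iter, 0.5)) + 1
        confirmed = hits >= threshold
        self.hits_ = hits
        self.hit_threshold_ = threshold
        if not confirmed.any():
            raise NoGenesSelectedError(
                "no gene confirmed by shadow-feature selection; increase "
                "n_iter, relax alpha, or check that categories differ"
            )
        order = np.lexsort(
            (np.asarray(feature_names, dtype=object), -hits)
        )
        chosen = [i for i in order if confirmed[i]]
        self.selected_genes_ = [feature_names[i] for i in chosen]
        self.support_ = confirmed
        self.n_features_in_ = n_features
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.result_ = SelectionResult(
            method="shadow_feature",
            selected_genes=list(self.selected_genes_),
            elbow_index=None,
            curve=np.sort(hits)[::-1].astype(float),
            params={
                "n_iter": self.n_iter,
                "alpha": self.alpha,
                "n_estimators": self.n_estimators,
                "seed": self.random_state,
                "hit_threshold": threshold,
                "backend": "ExtraTreesClassifier",
            },
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# DataFrame-level wrappers (genes x samples orientation)

def f_values(expr: pd.DataFrame, meta: pd.DataFrame,
             level: str = "dataset") -> pd.DataFrame:
    """Rank genes by one-way ANOVA F across categories.

    ``level="dataset"`` first averages replicate columns per dataset (the
    default analysis mode); ``level="sample"`` uses individual replicates.
    Returns a ranking table with columns gene, f_value, rank.
    """
    if level not in ("dataset", "sample"):
        raise ValueError(f"level must be 'dataset' or 'sample', got {level!r}")
    if level == "dataset":
        expr, meta = collapse_to_datasets(expr, meta)
    else:
        meta = meta.loc[expr.columns]
    f = one_way_f(expr.to_numpy(dtype=float).T, meta["category"].to_numpy())
    return rank_genes(f, expr.index)


def select_genes(expr: pd.DataFrame, meta: pd.DataFrame, *,
                 method: str = "f_elbow", level: str = "dataset",
                 k: int = 500, n_iter: int = 100, alpha: float = 0.05,
                 n_estimators: int = 100,
                 seed: int | None = None) -> SelectionResult:
    """Dispatch to one of the selectors on a genes x samples matrix."""
    if method == "f_elbow":
        ranking = f_values(expr, meta, level=level)
        result = elbow_select(ranking)
        result.params["level"] = level
        return result
    if level == "dataset":
        expr, meta = collapse_to_datasets(expr, meta)
    else:
        meta = meta.loc[expr.columns]
    X = expr.T  # samples x genes DataFrame keeps gene names
    if method == "variance_topk":
        sel = VarianceTopKSelector(k=k).fit(X)
    elif method == "shadow_feature":
        sel = ShadowFeatureSelector(
            n_iter=n_iter, alpha=alpha, n_estimators=n_estimators,
            random_state=seed,
        ).fit(X, meta["category"].to_numpy())
    else:
        raise ValueError(f"unknown selection method {method!r}")
    sel.result_.params["level"] = level
    return sel.result_
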