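"""Distances, classical (Torgerson) MDS and the silhouette clustering score.

Classical MDS double-centers the squared distance matrix, B = -1/2 J D^2 J,
and embeds samples with the top eigenvectors of B scaled by the square
roots of their eigenvalues. It is deterministic; axes are oriented so the
largest-magnitude loading on each axis is positive. Negative eigenvalues
(non-Euclidean residual) are truncated to zero with a warning and their
mass is reported as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """2D (or n-D) coordinates per sample plus the spectrum behind them.

    Attributes
    ----------
    coords : DataFrame, samples x dims (columns dim1, dim2, ...)
    eigenvalues : full eigenvalue spectrum, non-increasing
    stress : relative residual mismatch between input and embedded distances
    negative_eigenvalue_mass : |sum of negative eigenvalues| / sum |eigenvalues|
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    stress: float
    negative_eigenvalue_mass: float = 0.0

    @property
    def sample_ids(self):
        return list(self.coords.index)


def euclidean_distance_matrix(expr: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample columns over a gene subset."""
    if genes is not None:
        genes = list(genes)
        if len(genes) == 0:
            raise ValueError("empty gene subset")
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ValueError(f"genes not in expression matrix: {missing[:5]}")
        expr = expr.loc[genes]
    d = squareform(pdist(expr.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


class ClassicalMDS(BaseEstimator):
    """Classical (metric, eigendecomposition) multidimensional scaling.

    Parameters
    ----------
    n_components : int, default 2
        Output dimensionality; must be smaller than the number of samples.
    dissimilarity : {"euclidean", "precomputed"}, default "euclidean"
        With "euclidean", ``fit(X)`` takes a samples x features matrix;
        with "precomputed", a symmetric distance matrix.

    Attributes
    ----------
    embedding_ : ndarray (n_samples, n_components)
    eigenvalues_ : full spectrum, non-increasing
    stress_ : relative residual between input and embedded distances
    negative_eigenvalue_mass_ : diagnostic for non-Euclidean input
    """

    def __init__(self, n_components: int = 2, dissimilarity: str = "euclidean"):
        self.n_components = n_components
        self.dissimilarity = dissimilarity

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        if self.n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {self.n_components}")
        if self.dissimilarity == "precomputed":
            d = np.asarray(X, dtype=float)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("precomputed distance matrix must be square")
            if not np.allclose(d, d.T, atol=1e-8):
                raise ValueError("distance matrix is not symmetric")
            d = (d + d.T) / 2.0
        elif self.dissimilarity == "euclidean":
            arr = np.asarray(X, dtype=float)
            d = squareform(pdist(arr, metric="euclidean"))
        else:
            raise ValueError(
                f"dissimilarity must be 'euclidean' or 'precomputed', "
                f"got {self.dissimilarity!r}"
            )
        n = d.shape[0]
        if self.n_components >= n:
            raise ValueError(
                f"n_components={self.n_components} must be < n_samples={n}"
            )
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        total_mass = np.abs(eigvals).sum()
        neg_mass = np.abs(eigvals[eigvals < 0]).sum() / total_mass \
            if total_mass > 0 else 0.0
        top = eigvals[: self.n_components]
        if (top < -1e-10 * max(total_mass, 1.0)).any():
            logger.warning(
                "negative eigenvalues among the top %d (%.3g mass fraction); "
                "truncated to zero", self.n_components, neg_mass,
            )
        scaled = eigvecs[:, : self.n_components] * np.sqrt(np.clip(top, 0, None))
        # deterministic sign: largest-magnitude loading on each axis positive
        for k in range(scaled.shape[1]):
            col = scaled[:, k]
            if col.any() and col[np.argmax(np.abs(col))] < 0:
                scaled[:, k] = -col
        self.embedding_ = scaled
        self.eigenvalues_ = eigvals
        self.negative_eigenvalue_mass_ = float(neg_mass)
        d_hat = squareform(pdist(scaled, metric="euclidean"))
        denom = (d ** 2).sum()
        self.stress_ = float(np.sqrt(((d - d_hat) ** 2).sum() / denom)) \
            if denom > 0 else 0.0
        return self.embedding_


def classical_mds(d: pd.DataFrame, dims: int = 2) -> Embedding:
    """Embed a symmetric distance matrix with classical MDS."""
    model = ClassicalMDS(n_components=dims, dissimilarity="precomputed")
    coords = model.fit_transform(d.to_numpy(dtype=float))
    frame = pd.DataFrame(
        coords, index=d.index, columns=[f"dim{i + 1}" for i in range(dims)],
    )
    return Embedding(
        coords=frame,
        eigenvalues=model.eigenvalues_,
        stress=model.stress_,
        negative_eigenvalue_mass=model.negative_eigenvalue_mass_,
    )


def embed_expression(expr: pd.DataFrame, genes=None, dims: int = 2) -> Embedding:
    """Distances over a gene subset, then classical MDS."""
    return classical_mds(euclidean_distance_matrix(expr, genes), dims=dims)


def clustering_score(emb: Embedding, meta: pd.DataFrame,
                     labels: pd.Series | None = None) -> float:
    """Mean silhouette coefficient of the embedded samples under their
    category labels (Euclidean distance on the embedding coordinates).

    Samples in singleton categories contribute a silhouette of 0.
    """
    if labels is None:
        labels = meta.loc[emb.coords.index, "category"]
    else:
        labels = labels.loc[emb.coords.index]
    if labels.nunique() < 2:
        raise ValueError("clustering score needs >= 2 categories")
    values = silhouette_samples(emb.coords.to_numpy(), labels.to_numpy())
    return float(values.mean())


def distance_from_control(expr: pd.DataFrame, meta: pd.DataFrame,
                          genes=None) -> pd.Series:
    """Euclidean distance of each non-control sample to the mean control
    column, over a gene subset.

    Used to relate transcriptomic displacement to phenotype strength
    (e.g., extent of lifespan extension across alleles of one regimen).
    """
    meta = meta.loc[expr.columns]
    controls = meta.index[meta["is_control"]]
    if len(controls) == 0:
        raise ValueError("no control samples flagged (is_control)")
    if genes is not None:
        if len(list(genes)) == 0:
            raise ValueError("empty gene subset")
        expr = expr.loc[list(genes)]
    control_mean = expr[controls].mean(axis=1).to_numpy()
    others = [s for s in expr.columns if s not in set(controls)]
    dist = {
        s: float(np.linalg.norm(expr[s].to_numpy() - control_mean))
        for s in others
    }
    return pd.Series(dist, name="distance_from_control")
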