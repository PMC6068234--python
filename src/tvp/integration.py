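"""Integrative profile: discretized metrics, variant distances, non-metric MDS,
hierarchical clustering and genomics-predictor comparison.

The per-variant metric table combines conformation-specific stability,
channel electrostatics, hydropathy change and dynamics-derived flags into a
discretized altered/unaltered profile.  Variant similarity is Euclidean over
standardized columns (categoricals one-hot), embedded for visualization with
Kruskal's non-metric MDS and grouped by average-linkage clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from .errors import DataError, ParameterError

__all__ = [
    "discretize_metrics",
    "variant_distance_matrix",
    "KruskalMDS",
    "nonmetric_mds",
    "hierarchical_clusters",
    "merge_predictors",
    "classical_scaling",
]


def discretize_metrics(table: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Binarize continuous metric columns: 1 (altered) iff value > threshold.

    The inequality is strict, so a metric exactly at its cutoff is unaltered.
    Boolean columns pass through as 0/1; non-numeric (categorical) columns are
    kept as-is.  Every continuous column must have a threshold.
    """
    out = pd.DataFrame(index=table.index)
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_bool_dtype(s):
            out[col] = s.astype("Int64")
        elif pd.api.types.is_numeric_dtype(s):
            if col not in thresholds:
                raise ParameterError(f"no threshold for continuous column {col!r}")
            out[col] = (s > thresholds[col]).astype("Int64")
            out.loc[s.isna(), col] = pd.NA
        else:
            out[col] = s
    return out


def variant_distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distances over standardized columns.

    Categorical columns are one-hot encoded; every numeric column is scaled to
    unit sample standard deviation (ddof=1; constant columns contribute 0).
    Scattered missing values are mean-imputed after the all-missing-row check.
    """
    if table.shape[0] < 2:
        raise ParameterError("need at least 2 variants")
    all_missing = table.isna().all(axis=1)
    if all_missing.any():
        raise DataError(
            f"variant {table.index[all_missing][0]!r} has no observed metrics"
        )
    num = table.select_dtypes(include=["number", "bool", "boolean"]).astype(float)
    cat = table.drop(columns=num.columns)
    if not cat.empty:
        num = pd.concat([num, pd.get_dummies(cat, dtype=float)], axis=1)
    num = num.fillna(num.mean())
    std = num.std(ddof=1)
    scaled = num.loc[:, std > 0] / std[std > 0]
    dist = squareform(pdist(scaled.to_numpy(), metric="euclidean"))
    return pd.DataFrame(dist, index=table.index, columns=table.index)


def _check_distance_matrix(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise DataError("distance matrix must have a zero diagonal")
    return d


def classical_scaling(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling; deterministic start for the SMACOF iteration."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    coords = V[:, order] * np.sqrt(lam)
    # fix reflection signs for determinism
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


class KruskalMDS(BaseEstimator):
    """Kruskal non-metric MDS (stress-1 by SMACOF majorization).

    The iteration starts from deterministic classical scaling, so results are
    reproducible for a given input.  Fitted attributes: ``embedding_`` and
    ``stress_`` (Kruskal stress-1).
    """

    def __init__(self, n_components: int = 2, random_state: int | None = 0,
                 max_iter: int = 500):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, dist, y=None) -> "KruskalMDS":
        d = _check_distance_matrix(dist)
        if d.shape[0] < 3:
            raise ParameterError("need at least 3 points")
        init = classical_scaling(d, self.n_components)
        mds = MDS(
            n_components=self.n_components,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=self.max_iter,
            random_state=self.random_state,
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.embedding_ = mds.fit_transform(d, init=init)
        self.stress_ = float(mds.stress_)
        return self

    def fit_transform(self, dist, y=None) -> np.ndarray:
        return self.fit(dist).embedding_


def nonmetric_mds(
    dist: pd.DataFrame | np.ndarray, k: int = 2, seed: int | None = 0
) -> tuple[np.ndarray, float]:
    """Coordinates and Kruskal stress-1 for a distance matrix."""
    model = KruskalMDS(n_components=k, random_state=seed).fit(dist)
    return model.embedding_, model.stress_


def hierarchical_clusters(dist: pd.DataFrame | np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomerative labels (1..k), deterministic merges."""
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must lie in [1, {n}], got {k}")
    Z = linkage(squareform(d, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def merge_predictors(metrics: pd.DataFrame, predictors: pd.DataFrame) -> pd.DataFrame:
    """Left-join genomics predictor scores onto the metric table by variant.

    Unmatched predictor rows are dropped with a warning; metric rows without
    predictor entries keep missing cells.  Duplicate predictor keys are a data
    error, as is an empty overlap.
    """
    if predictors.index.duplicated().any():
        dup = predictors.index[predictors.index.duplicated()][0]
        raise DataError(f"duplicate predictor key {dup!r}")
    overlap = metrics.index.intersection(predictors.index)
    if overlap.empty:
        raise DataError("no overlapping variants between metrics and predictors")
    extra = predictors.index.difference(metrics.index)
    if not extra.empty:
        warnings.warn(
            f"{len(extra)} predictor rows without metric rows dropped "
            f"(e.g. {extra[0]!r})",
            stacklevel=2,
        )
    return metrics.join(predictors, how="left")
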