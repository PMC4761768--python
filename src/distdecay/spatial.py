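"""Explanatory distance matrices.

Builds the four pairwise predictor matrices used to explain species
turnover:

* geographic distance — WGS84 geodesic between site centroids, km;
* environmental distance — Euclidean distance in the space of the
  principal components retained from the (standardized) environmental
  variables, collapsing a collinear multivariate environment into a
  single pairwise variable;
* mean-elevation difference — |elev_i − elev_j|, a proxy for geographic
  isolation along the elevational gradient;
* elevation-range difference — |range_i − range_j|, a proxy for
  within-site environmental heterogeneity

plus the area-difference matrix for incremental-R² checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .containers import PairwiseMatrix, SiteTable
from .geodesic import geodesic_km

logger = logging.getLogger(__name__)

SCALAR_FIELDS = ("mean_elev", "elev_range", "area")


def geo_distance_matrix(sites: SiteTable) -> PairwiseMatrix:
    """Pairwise geodesic distance (km) between site centroids on WGS84.

    Coincident centroids are allowed (distance 0) but logged, because the
    logarithmic decay model cannot use zero distances.
    """
    lat = sites.column("lat")
    lon = sites.column("lon")
    d = geodesic_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    n_zero = int((squareform(d, checks=False) == 0).sum())
    if n_zero:
        logger.warning(
            "%d site pairs have coincident centroids (distance 0 km); "
            "they cannot enter a logarithmic decay fit",
            n_zero,
        )
    return PairwiseMatrix(sites.site_ids, d, "distance")


@dataclass
class PCAResult:
    """PCA of the environmental block on its correlation matrix.

    ``scores`` are the site coordinates on the retained components;
    ``explained_fraction`` the per-component variance fractions (all
    components, non-increasing); ``loadings`` the variable x component
    weight matrix for the retained components.
    """

    loadings: np.ndarray
    explained_fraction: np.ndarray
    n_retained: int
    scores: np.ndarray
    variables: list[str]

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_fraction[: self.n_retained].sum())


def env_pca(
    sites: SiteTable,
    variance_target: float = 0.95,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the environmental variables on their correlation matrix.

    Variables are standardized to zero mean and unit variance (so the
    covariance of the standardized data is the correlation matrix) before
    a standard PCA. Retains the smallest k whose cumulative explained
    variance reaches ``variance_target``; ``n_components`` overrides the
    threshold with a fixed count.

    Constant variables carry no correlation information and are dropped
    with a warning.
    """
    if sites.n_sites < 2:
        raise ValueError("PCA needs at least 2 sites")
    if not sites.env_columns:
        raise ValueError("site table has no environmental variables")
    X = sites.env_matrix()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(sites.env_columns, keep) if not k]
        logger.warning("dropping constant environmental variables: %s", dropped)
    variables = [c for c, k in zip(sites.env_columns, keep) if k]
    if not variables:
        raise ValueError("all environmental variables are constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA()
    scores_full = pca.fit_transform(Z)
    frac = pca.explained_variance_ratio_
    if n_components is not None:
        k = int(n_components)
        if not 1 <= k <= len(frac):
            raise ValueError(f"n_components must be in [1, {len(frac)}]")
    else:
        k = int(np.searchsorted(np.cumsum(frac), variance_target) + 1)
        k = min(k, len(frac))
    return PCAResult(
        loadings=pca.components_[:k].T.copy(),
        explained_fraction=frac.copy(),
        n_retained=k,
        scores=scores_full[:, :k].copy(),
        variables=variables,
    )


def env_distance_matrix(pca: PCAResult, site_ids: list[str] | None = None) -> PairwiseMatrix:
    """Euclidean distance over the retained component scores.

    The axes are unweighted: distance is taken in the raw score space of
    the retained components, treating the reduced environment as a single
    multivariate variable.
    """
    d = squareform(pdist(pca.scores, metric="euclidean"))
    ids = site_ids if site_ids is not None else [str(i) for i in range(len(pca.scores))]
    return PairwiseMatrix(list(ids), d, "distance")


def scalar_diff_matrix(sites: SiteTable, field: str) -> PairwiseMatrix:
    """Pairwise absolute difference |x_i − x_j| of a per-site scalar.

    ``field`` is typically one of ``mean_elev`` (isolation proxy),
    ``elev_range`` (heterogeneity proxy) or ``area``; any numeric column
    of the site table is accepted.
    """
    x = sites.column(field)
    d = np.abs(x[:, None] - x[None, :])
    return PairwiseMatrix(sites.site_ids, d, "distance")
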