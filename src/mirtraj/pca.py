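"""Principal component analysis of normalized expression time points.

Each time point is a vector of log-ratio expression values (one entry per
retained miR).  The PCA is an eigendecomposition of the covariance of the
mean-centered vectors: no unit-variance scaling is applied, since log-ratio
values already share a common scale.  Component signs are fixed by making
the largest-magnitude loading of each component positive; downstream angular
statistics compare directions within a single projection and are therefore
sign-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DegenerateDataError, ValidationError

__all__ = ["PCModel", "PCProjection", "fit_pca", "cumulative_variance", "project"]

_VARIANCE_EPS = 1e-12


@dataclass(frozen=True)
class PCModel:
    """Fitted orthonormal basis ordered by decreasing explained variance."""

    component_directions: np.ndarray  # (n_components, n_features)
    variance_fractions: np.ndarray  # (n_components,), sums to 1
    center: np.ndarray  # (n_features,)
    fitted_sample_ids: tuple = ()

    @property
    def n_components(self) -> int:
        return self.component_directions.shape[0]

    @property
    def n_features(self) -> int:
        return self.component_directions.shape[1]


@dataclass(frozen=True)
class PCProjection:
    """Coordinates of one time series in the first k principal components."""

    label: str
    days: tuple
    coordinates: np.ndarray  # (n_days, k)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def fit_pca(vectors, labels: Sequence | None = None) -> PCModel:
    """Fit a full PCA to a stack of time-point vectors (rows).

    Raises :class:`DegenerateDataError` when the vectors carry no variance
    (all identical), in which case no principal direction exists.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 vectors")
    total_var = float(np.var(X - X.mean(axis=0), ddof=0))
    if not np.isfinite(total_var) or total_var * X.shape[1] < _VARIANCE_EPS:
        raise DegenerateDataError("zero total variance: PCA is undefined on constant data")
    model = PCA(n_components=None, svd_solver="full")
    model.fit(X)
    components = model.components_.copy()
    # sign convention: largest-magnitude loading of each component positive
    for i, comp in enumerate(components):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            components[i] = -comp
    return PCModel(
        component_directions=components,
        variance_fractions=model.explained_variance_ratio_.copy(),
        center=model.mean_.copy(),
        fitted_sample_ids=tuple(labels) if labels is not None else (),
    )


def cumulative_variance(model: PCModel, k: int) -> float:
    """Fraction of total variance explained by the first ``k`` components."""
    if not 1 <= k <= model.n_components:
        raise ValidationError(
            f"k must be in [1, {model.n_components}], got {k}"
        )
    return float(model.variance_fractions[:k].sum())


def project(model: PCModel, series, k: int = 3) -> PCProjection:
    """Project a normalized series onto the first ``k`` principal components.

    ``series`` is either a :class:`~mirtraj.preprocess.NormalizedSeries` or a
    plain ``(days, vectors, label)``-like object exposing those attributes.
    """
    days = tuple(series.days)
    vectors = np.atleast_2d(np.asarray(series.vectors, dtype=float))
    if vectors.shape[1] != model.n_features:
        raise ValidationError(
            f"series dimension {vectors.shape[1]} does not match model "
            f"dimension {model.n_features}"
        )
    k = min(k, model.n_components) if k is None else k
    if not 1 <= k <= model.n_components:
        raise ValidationError(f"k must be in [1, {model.n_components}], got {k}")
    coords = (vectors - model.center) @ model.component_directions[:k].T
    label = getattr(series, "label", None) or f"{getattr(series, 'strain', '?')}/{getattr(series, 'treatment', '?')}"
    return PCProjection(label=label, days=days, coordinates=coords)
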