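"""Principal-component reduction used to regularise high-dimensional fits.

A centred data matrix decomposes as ``X = 1 mu' + T P' + E`` where ``P``
(p x q) holds the leading orthonormal eigenvectors of the sample covariance,
``T = (X - 1 mu') P`` the scores, and ``E`` the residual.  Fitting the
discriminant on the scores of the first few components removes the
high-dimensional noise directions along which a hyperplane on raw variables
would overfit when p >> n.

Computed via SVD of the centred matrix for numerical stability; equivalence
with the covariance eigen-decomposition is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["PCAModel", "fit_pca", "project_scores"]

#: default cumulative explained-variance fraction used to choose q
DEFAULT_VAR_THRESHOLD = 0.9

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class PCAModel:
    """Column means, loadings and explained-variance fractions of a PCA fit.

    ``explained`` covers the ``q`` retained components; ``explained_full``
    covers every component with positive variance and sums to one.
    """

    mu: np.ndarray
    loadings: np.ndarray          # p x q, orthonormal columns
    explained: np.ndarray         # length q, descending, in (0, 1]
    explained_full: np.ndarray
    q: int
    scale: np.ndarray = None      # per-column sd when unit-variance scaling is on

    @property
    def p(self) -> int:
        return self.mu.size


def fit_pca(X, q: int | None = None, var_threshold: float | None = None,
            scale: bool = False) -> PCAModel:
    """Fit the decomposition on training rows and choose the rank ``q``.

    Exactly one of ``q`` (component count) and ``var_threshold`` (smallest
    count whose cumulative explained fraction reaches the threshold) must be
    given.  Columns are always centred; ``scale=True`` additionally divides
    by the per-column standard deviation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError(f"X must be 2-d with n >= 2 rows, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite entries")
    if (q is None) == (var_threshold is None):
        raise ValidationError("give exactly one of q and var_threshold")
    if var_threshold is not None and not 0.0 < var_threshold <= 1.0:
        raise ValidationError(f"var_threshold must lie in (0, 1], got {var_threshold}")

    n, p = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValidationError("cannot unit-variance scale a zero-variance column")
        Xc = Xc / sd

    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise ValidationError("data have zero variance; PCA is undefined")
    rank = int(np.sum(s > s[0] * _RANK_RTOL))
    var = s[:rank] ** 2
    explained_full = var / var.sum()

    if q is None:
        q = int(np.searchsorted(np.cumsum(explained_full), var_threshold - 1e-12) + 1)
        q = min(q, rank)
    else:
        q = int(q)
        if not 1 <= q <= min(n - 1, p):
            raise ValidationError(
                f"q must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {q}"
            )
        if q > rank:
            raise ValidationError(f"q={q} exceeds the numerical rank {rank} of the centred data")

    loadings = Vt[:q].T.copy()
    # deterministic sign: the largest-|.| entry of each column is positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(q)] < 0
    loadings[:, flip] *= -1.0
    return PCAModel(mu=mu, loadings=loadings, explained=explained_full[:q].copy(),
                    explained_full=explained_full, q=q, scale=sd)


def project_scores(model: PCAModel, points) -> np.ndarray:
    """Scores ``T = (points - 1 mu') P`` of new points in the fitted basis."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != model.p:
        raise ValidationError(f"points must be n x {model.p}, got shape {np.shape(points)}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite entries")
    centred = pts - model.mu
    if model.scale is not None:
        centred = centred / model.scale
    return centred @ model.loadings
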