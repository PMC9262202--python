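"""Model/Results interface for two-group discriminant fits.

``LPDA`` holds the data and fit options; ``LPDA(...).fit()`` returns an
``LPDAResults`` carrying the hyperplane, the LP optimum and its slacks, the
optional PCA reduction, prediction methods and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core, pca as pca_mod
from .core import Hyperplane, LPSolution, TwoGroupData
from .exceptions import ValidationError
from .pca import PCAModel

__all__ = ["LPDA", "LPDAResults", "fit_lpda", "split_groups"]


def split_groups(features, groups, weights=None, group_order=None):
    """Split a labelled feature matrix into per-group matrices.

    Returns ``(ordered_labels, [matrix per label], [weight vector per label])``.
    ``group_order`` fixes which label is listed first (the positive / a'x > b
    side for two groups); by default labels are sorted.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 1:
        feats = feats[:, None]
    if feats.ndim != 2:
        raise ValidationError(f"features must be 2-d, got shape {feats.shape}")
    groups = np.asarray(groups)
    if groups.shape != (feats.shape[0],):
        raise ValidationError(
            f"groups must have one label per row ({feats.shape[0]}), got shape {groups.shape}"
        )
    present = sorted(pd.unique(groups).tolist(), key=str)
    if group_order is not None:
        group_order = list(group_order)
        if sorted(group_order, key=str) != present:
            raise ValidationError(
                f"group_order {group_order!r} does not match the labels present {present!r}"
            )
        present = group_order
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != (feats.shape[0],):
            raise ValidationError("weights must have one entry per sample")
    mats, wts = [], []
    for lab in present:
        mask = groups == lab
        mats.append(feats[mask])
        wts.append(None if weights is None else weights[mask])
    return present, mats, wts


class LPDA:
    """Two-group linear-programming discriminant model.

    Parameters
    ----------
    features : array-like, n x p
        Numeric sample-by-variable matrix.
    groups : array-like, length n
        Exactly two distinct group labels.  The first label (sorted, or as
        fixed by ``group_order``) is placed on the a'x > b side of the
        hyperplane; set ``group_order=(positive, negative)`` to choose it.
    weights : array-like, length n, optional
        Positive per-sample weights, renormalised to sum to one within each
        group.  Defaults to equal weights 1/n_g per group, which makes the
        fit insensitive to class imbalance.
    """

    def __init__(self, features, groups, weights=None, group_order=None):
        labels, mats, wts = split_groups(features, groups, weights, group_order)
        if len(labels) != 2:
            raise ValidationError(
                f"LPDA expects exactly 2 groups, found {len(labels)}: {labels!r} "
                "(use PairwiseLPDA for more)"
            )
        self.data = TwoGroupData(mats[0], mats[1], wts[0], wts[1], tuple(labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "group",
                       weight_col: str | None = None, group_order=None) -> "LPDA":
        """Build the model from a tidy frame with a label column."""
        if label_col not in df.columns:
            raise ValidationError(f"label column {label_col!r} not found")
        drop = [label_col] + ([weight_col] if weight_col else [])
        feats = df.drop(columns=drop)
        weights = df[weight_col].to_numpy(float) if weight_col else None
        return cls(feats.to_numpy(float), df[label_col].to_numpy(), weights, group_order)

    def fit(self, use_pca: bool = False, q: int | None = None,
            var_threshold: float | None = None, scale: bool = False,
            tol: float = core.DEFAULT_TOL) -> "LPDAResults":
        """Fit the discriminant hyperplane, optionally in PCA score space.

        With ``use_pca`` the decomposition is fitted on the pooled training
        rows of both groups (never on prediction-time points), both groups
        are projected, and the hyperplane is found in score space.  ``q``
        fixes the component count; ``var_threshold`` picks the smallest count
        reaching that cumulative explained-variance fraction (default 0.9
        when neither is given).
        """
        data = self.data
        model_pca = None
        if use_pca:
            if q is None and var_threshold is None:
                var_threshold = pca_mod.DEFAULT_VAR_THRESHOLD
            pooled = np.vstack([data.X, data.Y])
            model_pca = pca_mod.fit_pca(pooled, q=q, var_threshold=var_threshold, scale=scale)
            data = TwoGroupData(
                pca_mod.project_scores(model_pca, self.data.X),
                pca_mod.project_scores(model_pca, self.data.Y),
                self.data.m, self.data.w, self.data.labels,
            )
        hyperplane, solution = core.fit_hyperplane(data, tol=tol)
        return LPDAResults(model=self, hyperplane=hyperplane, solution=solution,
                           pca=model_pca, labels=self.data.labels, tol=tol)


@dataclass
class LPDAResults:
    """Fitted discriminant: hyperplane, LP diagnostics and prediction."""

    hyperplane: Hyperplane
    labels: tuple
    model: LPDA | None = None
    solution: LPSolution | None = None
    pca: PCAModel | None = None
    tol: float = core.DEFAULT_TOL
    objective: float = None

    def __post_init__(self):
        if self.objective is None:
            self.objective = self.solution.objective if self.solution is not None else float("nan")

    @property
    def separable(self) -> bool:
        """Separability certificate: v(P) = 0 within tolerance."""
        return self.objective <= self.tol

    @property
    def p(self) -> int:
        """Feature dimension expected at prediction time."""
        return self.pca.p if self.pca is not None else self.hyperplane.p

    def _scores(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
        if self.pca is not None:
            return pca_mod.project_scores(self.pca, pts)
        return pts

    def predict(self, points) -> np.ndarray:
        """Group labels for new points (ties a'x = b go to the first label)."""
        return core.predict_binary(self.hyperplane, self._scores(points), self.labels)

    def decision_function(self, points) -> np.ndarray:
        """Signed Euclidean distance to the hyperplane; positive on the first
        label's side."""
        return self.hyperplane.signed_distance(self._scores(points))

    def summary(self) -> str:
        h = self.hyperplane
        lines = [
            "Linear programming discriminant analysis",
            "=" * 48,
            f"groups:          {self.labels[0]!r} (a'x > b side) vs {self.labels[1]!r}",
        ]
        if self.model is not None:
            d = self.model.data
            lines.append(f"n per group:     {d.n1} / {d.n2}   features: {d.p}")
        lines.append(f"separation error v(P): {self.objective:.6g}")
        lines.append(f"strictly separable:    {self.separable}")
        if self.pca is not None:
            lines.append(
                f"PCA reduction:   q = {self.pca.q} components, "
                f"{100 * self.pca.explained.sum():.1f}% variance explained"
            )
        coef = ", ".join(f"{c:.4g}" for c in h.a[:8])
        if h.p > 8:
            coef += f", ... ({h.p} coefficients)"
        lines.append(f"hyperplane a:    [{coef}]")
        lines.append(f"hyperplane b:    {h.b:.6g}")
        return "\n".join(lines)


def fit_lpda(data: TwoGroupData, use_pca: bool = False, q: int | None = None,
             var_threshold: float | None = None, scale: bool = False,
             tol: float = core.DEFAULT_TOL) -> LPDAResults:
    """Functional entry point taking an already-assembled :class:`TwoGroupData`."""
    features = np.vstack([data.X, data.Y])
    groups = np.array([data.labels[0]] * data.n1 + [data.labels[1]] * data.n2)
    weights = np.concatenate([data.m, data.w])
    model = LPDA(features, groups, weights, group_order=list(data.labels))
    return model.fit(use_pca=use_pca, q=q, var_threshold=var_threshold, scale=scale, tol=tol)
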