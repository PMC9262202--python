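"""One-vs-one extension: k(k-1)/2 pairwise hyperplanes combined by voting.

Each unordered label pair gets its own two-group fit (with its own PCA
subspace when reduction is on, fitted on that pair's pooled rows).  A point
is assigned the label with most pairwise votes; ties are broken by the larger
summed signed margin over the tied labels' winning comparisons, then by label
order — deterministic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import LpdaError, ValidationError
from .model import LPDA, LPDAResults, split_groups

__all__ = ["PairwiseLPDA", "PairwiseLPDAResults", "fit_pairwise", "predict_vote"]


class PairwiseLPDA:
    """Multi-group discriminant model over all unordered label pairs."""

    def __init__(self, features, groups, weights=None, group_order=None):
        labels, mats, wts = split_groups(features, groups, weights, group_order)
        if len(labels) < 2:
            raise ValidationError(f"need at least 2 groups, found {len(labels)}")
        for lab, mat in zip(labels, mats):
            if mat.shape[0] == 0:
                raise ValidationError(f"group {lab!r} is empty")
        self.group_labels = list(labels)
        self._matrices = dict(zip(labels, mats))
        self._weights = dict(zip(labels, wts))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "group",
                       weight_col: str | None = None, group_order=None) -> "PairwiseLPDA":
        if label_col not in df.columns:
            raise ValidationError(f"label column {label_col!r} not found")
        drop = [label_col] + ([weight_col] if weight_col else [])
        feats = df.drop(columns=drop).to_numpy(float)
        weights = df[weight_col].to_numpy(float) if weight_col else None
        return cls(feats, df[label_col].to_numpy(), weights, group_order)

    def fit(self, **fit_kwargs) -> "PairwiseLPDAResults":
        """Fit one two-group discriminant per unordered pair of labels."""
        models: dict[tuple, LPDAResults] = {}
        for la, lb in combinations(self.group_labels, 2):
            Xa, Xb = self._matrices[la], self._matrices[lb]
            feats = np.vstack([Xa, Xb])
            grp = np.array([la] * Xa.shape[0] + [lb] * Xb.shape[0], dtype=object)
            wa, wb = self._weights[la], self._weights[lb]
            weights = None
            if wa is not None or wb is not None:
                weights = np.concatenate([
                    wa if wa is not None else np.full(Xa.shape[0], 1.0 / Xa.shape[0]),
                    wb if wb is not None else np.full(Xb.shape[0], 1.0 / Xb.shape[0]),
                ])
            try:
                models[(la, lb)] = LPDA(feats, grp, weights, group_order=[la, lb]).fit(**fit_kwargs)
            except LpdaError as err:
                raise type(err)(f"pair ({la!r}, {lb!r}): {err}") from err
        return PairwiseLPDAResults(group_labels=list(self.group_labels), models=models,
                                   settings=dict(fit_kwargs))


@dataclass
class PairwiseLPDAResults:
    """All fitted pairwise hyperplanes plus the voting classifier."""

    group_labels: list
    models: dict            # (label_i, label_j) -> LPDAResults, i before j in label order
    settings: dict

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def p(self) -> int:
        return next(iter(self.models.values())).p

    def votes(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Per-point vote counts and summed winning margins, one column per label."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
        if pts.ndim != 2 or pts.shape[1] != self.p:
            raise ValidationError(f"points must be n x {self.p}, got shape {np.shape(points)}")
        n, k = pts.shape[0], len(self.group_labels)
        col = {lab: i for i, lab in enumerate(self.group_labels)}
        counts = np.zeros((n, k), dtype=int)
        margins = np.zeros((n, k))
        for (la, lb), res in self.models.items():
            s = res.decision_function(pts)  # >= 0 means la (ties go to the first label)
            wins_a = s >= 0.0
            counts[wins_a, col[la]] += 1
            counts[~wins_a, col[lb]] += 1
            margins[wins_a, col[la]] += s[wins_a]
            margins[~wins_a, col[lb]] += -s[~wins_a]
        return counts, margins

    def predict(self, points) -> np.ndarray:
        """Majority label over all pairwise comparisons, margin tie-break."""
        counts, margins = self.votes(points)
        out = np.empty(counts.shape[0], dtype=object)
        for i in range(counts.shape[0]):
            best = counts[i].max()
            tied = np.flatnonzero(counts[i] == best)
            if tied.size > 1:
                tied = tied[margins[i, tied] == margins[i, tied].max()]
            out[i] = self.group_labels[tied[0]]  # label order is the final tie-break
        return out

    def summary(self) -> str:
        k = len(self.group_labels)
        lines = [
            "Pairwise (one-vs-one) LP discriminant analysis",
            "=" * 48,
            f"groups: {k}  ({', '.join(map(repr, self.group_labels))})",
            f"pairwise hyperplanes: {self.n_models}",
        ]
        for (la, lb), res in self.models.items():
            lines.append(f"  {la!r} vs {lb!r}: v(P) = {res.objective:.6g}"
                         f"  separable = {res.separable}")
        return "\n".join(lines)


def fit_pairwise(groups, **fit_kwargs) -> PairwiseLPDAResults:
    """Fit from a list of ``(label, matrix)`` pairs with equal within-group weights."""
    labels = [lab for lab, _ in groups]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate group labels")
    feats = np.vstack([np.asarray(mat, dtype=float) for _, mat in groups])
    grp = np.concatenate([
        np.full(np.asarray(mat).shape[0], lab, dtype=object) for lab, mat in groups
    ])
    return PairwiseLPDA(feats, grp, group_order=labels).fit(**fit_kwargs)


def predict_vote(results: PairwiseLPDAResults, points) -> np.ndarray:
    """Functional alias for :meth:`PairwiseLPDAResults.predict`."""
    return results.predict(points)
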