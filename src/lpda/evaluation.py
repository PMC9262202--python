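"""Performance metrics and the repeated train/test evaluation protocol.

Sensitivity is the true-positive rate on the designated positive class (for
unbalanced problems, the minority class one wants to detect), specificity the
true-negative rate, and the classification error the overall misclassified
fraction.  Generalisation error is estimated by repeatedly drawing a
stratified test set (a fixed number of rows per group, without replacement),
refitting on the remainder — including any PCA reduction, which is refit on
training rows only — and averaging the per-repetition test errors with a
normal-approximation confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import LpdaError, ValidationError
from .model import LPDA
from .multiclass import PairwiseLPDA

__all__ = ["ConfusionStats", "CVResult", "confusion_stats", "mean_ci", "cross_validate"]


@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: object

    @property
    def sensitivity(self) -> float:
        """True-positive rate; nan when there are no positives."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp > 0 else float("nan")

    @property
    def classification_error(self) -> float:
        return (self.fp + self.fn) / (self.tp + self.fp + self.tn + self.fn)


def confusion_stats(true_labels, predicted_labels, positive_label) -> ConfusionStats:
    """Two-class confusion counts, treating every non-positive label as negative."""
    true = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if true.size == 0:
        raise ValidationError("empty label sequences")
    if true.shape != pred.shape:
        raise ValidationError(f"label sequences differ in length: {true.shape} vs {pred.shape}")
    if positive_label not in true and positive_label not in pred:
        raise ValidationError(f"positive label {positive_label!r} not in the label alphabet")
    t = true == positive_label
    p = pred == positive_label
    return ConfusionStats(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
        positive_label=positive_label,
    )


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Normal-approximation CI for a mean of error fractions, clipped to [0, 1].

    A single value yields a zero-width interval at that value.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValidationError("mean_ci needs at least one value")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0, 1), got {level}")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, mean, mean
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * vals.std(ddof=1) / np.sqrt(vals.size)
    return mean, float(np.clip(mean - half, 0.0, 1.0)), float(np.clip(mean + half, 0.0, 1.0))


@dataclass
class CVResult:
    """Per-repetition test errors and their aggregate."""

    per_rep_errors: np.ndarray
    mean_error: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int
    level: float
    test_design: str
    settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rep": np.arange(self.n_reps), "error": self.per_rep_errors})

    def to_dict(self) -> dict:
        return {
            "mean_error": self.mean_error,
            "ci": [self.ci_low, self.ci_high],
            "level": self.level,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "test_design": self.test_design,
            "settings": {k: v for k, v in self.settings.items()},
        }


def cross_validate(features, groups, n_test_per_group: int, n_reps: int,
                   seed: int, level: float = 0.95, weights=None,
                   **fit_kwargs) -> CVResult:
    """Repeated stratified train/test evaluation of the discriminant.

    Each repetition draws ``n_test_per_group`` rows per group uniformly
    without replacement into the test set, fits on the remaining rows (two
    groups -> :class:`LPDA`, more -> :class:`PairwiseLPDA`; PCA, when on, is
    refit per repetition on the training rows), and records the test error.
    Repetition-level RNG streams are spawned from the master seed so every
    repetition is individually reproducible.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 1:
        feats = feats[:, None]
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist(), key=str)
    idx_by_group = {lab: np.flatnonzero(groups == lab) for lab in labels}
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    for lab, idx in idx_by_group.items():
        if idx.size <= n_test_per_group:
            raise ValidationError(
                f"group {lab!r} has {idx.size} rows, not enough to hold out "
                f"{n_test_per_group} and still train"
            )

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    errors = np.empty(n_reps)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        test_idx = np.concatenate([
            rng.choice(idx_by_group[lab], size=n_test_per_group, replace=False)
            for lab in labels
        ])
        test_mask = np.zeros(feats.shape[0], dtype=bool)
        test_mask[test_idx] = True
        w_train = None if weights is None else np.asarray(weights, float)[~test_mask]
        try:
            cls = LPDA if len(labels) == 2 else PairwiseLPDA
            fitted = cls(feats[~test_mask], groups[~test_mask], w_train).fit(**fit_kwargs)
        except LpdaError as err:
            raise type(err)(f"repetition {rep}: {err}") from err
        pred = fitted.predict(feats[test_mask])
        errors[rep] = np.mean(pred != groups[test_mask])

    mean, low, high = mean_ci(errors, level)
    return CVResult(
        per_rep_errors=errors, mean_error=mean, ci_low=low, ci_high=high,
        n_reps=n_reps, seed=seed, level=level,
        test_design=f"stratified, {n_test_per_group} test rows per group, "
                    f"drawn without replacement",
        settings=dict(fit_kwargs),
    )
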