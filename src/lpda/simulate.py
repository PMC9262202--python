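"""Seeded synthetic-data generators for the three evaluation regimes.

Scenarios
---------
``separable_lowdim``
    Two well-separated Gaussian clusters in low dimension (default centroid
    distance 10 noise-sd units): strict separability is near-certain, so the
    LP optimum should hit zero.
``overlapping_lowdim``
    The same geometry with a small centroid distance, so the groups overlap
    and the optimum is strictly positive.
``unbalanced``
    A heavily unbalanced two-class sample (default 0.3% minority out of
    10,000 rows) with overlapping classes — the regime where per-group weight
    normalisation decides whether the minority class is detectable at all.
``highdim_latent``
    p >> n correlated data: per-sample scores on a few latent factors (the
    groups shifted along factor 1) mapped to p observed variables through a
    random loading matrix plus independent noise.  This emulates
    log-normalised expression data, where the group signal lives in a
    low-dimensional subspace and the remaining variation is noise.

Every generator is a pure function of its :class:`GeneratorSpec`; the seed
fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .core import TwoGroupData
from .exceptions import ValidationError

__all__ = ["SCENARIOS", "GeneratorSpec", "SimulatedTwoGroups",
           "generate_two_groups", "generate_multigroup", "to_dataframe"]

SCENARIOS = ("separable_lowdim", "overlapping_lowdim", "unbalanced", "highdim_latent")

_DEFAULTS = {
    # per-scenario study conditions: (n_per_group, n_total, minority_fraction,
    #                                 p, effect_size)
    "separable_lowdim":   dict(n_per_group=20, p=2, effect_size=10.0),
    "overlapping_lowdim": dict(n_per_group=50, p=2, effect_size=2.0),
    "unbalanced":         dict(n_total=10_000, minority_fraction=0.003, p=2, effect_size=3.0),
    "highdim_latent":     dict(n_per_group=30, p=500, effect_size=3.0),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic dataset; the seed fixes the draw."""

    scenario: str
    n_per_group: int | None = None
    n_total: int | None = None
    minority_fraction: float | None = None
    p: int | None = None
    effect_size: float | None = None      # centroid distance in noise-sd units
    n_factors: int = 4                    # highdim_latent only
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def resolved(self) -> "GeneratorSpec":
        """Fill scenario defaults for every field left as None."""
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; pick from {SCENARIOS}")
        filled = {k: v for k, v in _DEFAULTS[self.scenario].items()
                  if getattr(self, k) is None}
        out = replace(self, **filled)
        if out.effect_size is None or out.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if out.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if out.p is None or out.p < 1:
            raise ValidationError("p must be >= 1")
        if out.scenario == "unbalanced":
            if out.n_total is None or out.n_total < 4:
                raise ValidationError("unbalanced scenario needs n_total >= 4")
            if out.minority_fraction is None or not 0.0 < out.minority_fraction <= 0.5:
                raise ValidationError("minority_fraction must lie in (0, 0.5]")
        elif out.n_per_group is None or out.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if out.scenario == "highdim_latent" and out.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        return out

    def to_dict(self) -> dict:
        return asdict(self.resolved())


@dataclass(frozen=True)
class SimulatedTwoGroups:
    """Generated data plus, when the design defines one, the population
    direction along which the groups differ (unit vector, pointing toward
    the first group)."""

    data: TwoGroupData
    direction: np.ndarray | None
    spec: GeneratorSpec


def _gaussian_pair(rng, n1, n2, p, effect, sd, labels):
    u = np.ones(p) / np.sqrt(p)
    mu1 = 0.5 * effect * sd * u
    X = mu1 + rng.normal(scale=sd, size=(n1, p))
    Y = -mu1 + rng.normal(scale=sd, size=(n2, p))
    return TwoGroupData(X, Y, labels=labels), u


def generate_two_groups(spec: GeneratorSpec) -> SimulatedTwoGroups:
    """Draw one two-group dataset under the scenario's study conditions."""
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)

    if spec.scenario in ("separable_lowdim", "overlapping_lowdim"):
        data, u = _gaussian_pair(rng, spec.n_per_group, spec.n_per_group, spec.p,
                                 spec.effect_size, spec.noise_sd, ("A", "B"))
        return SimulatedTwoGroups(data, u, spec)

    if spec.scenario == "unbalanced":
        n_min = max(1, int(round(spec.n_total * spec.minority_fraction)))
        n_maj = spec.n_total - n_min
        data, u = _gaussian_pair(rng, n_min, n_maj, spec.p,
                                 spec.effect_size, spec.noise_sd, ("case", "control"))
        return SimulatedTwoGroups(data, u, spec)

    # highdim_latent: factor scores -> random loadings -> observed variables
    n, p, f = spec.n_per_group, spec.p, spec.n_factors
    loadings = rng.normal(scale=spec.loading_scale, size=(f, p))
    shift = np.zeros(f)
    shift[0] = 0.5 * spec.effect_size  # group contrast lives on factor 1
    SX = rng.standard_normal((n, f)) + shift
    SY = rng.standard_normal((n, f)) - shift
    X = SX @ loadings + rng.normal(scale=spec.noise_sd, size=(n, p))
    Y = SY @ loadings + rng.normal(scale=spec.noise_sd, size=(n, p))
    direction = loadings[0] / np.linalg.norm(loadings[0])
    return SimulatedTwoGroups(TwoGroupData(X, Y, labels=("A", "B")), direction, spec)


def _simplex_centroids(k: int, distance: float, p: int) -> np.ndarray:
    """k centroids in R^p with all pairwise distances equal to ``distance``."""
    if p < k - 1:
        raise ValidationError(f"p = {p} is too small to place {k} equidistant centroids")
    E = np.eye(k) * distance / np.sqrt(2.0)
    E -= E.mean(axis=0)
    # rotate the (k-1)-dim simplex into the first k-1 coordinates
    _, _, Vt = np.linalg.svd(E, full_matrices=False)
    C = np.zeros((k, p))
    C[:, : k - 1] = (E @ Vt.T)[:, : k - 1]
    return C


def generate_multigroup(k: int, spec: GeneratorSpec) -> list[tuple[str, np.ndarray]]:
    """k Gaussian clusters with centroids on a regular simplex scaled so every
    pairwise centroid distance equals ``effect_size * noise_sd``."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    spec = spec.resolved()
    if spec.n_per_group is None:
        raise ValidationError(f"scenario {spec.scenario!r} does not define n_per_group")
    rng = np.random.default_rng(spec.seed)
    C = _simplex_centroids(k, spec.effect_size * spec.noise_sd, spec.p)
    return [
        (f"G{i + 1}", C[i] + rng.normal(scale=spec.noise_sd, size=(spec.n_per_group, spec.p)))
        for i in range(k)
    ]


def to_dataframe(data: TwoGroupData) -> pd.DataFrame:
    """Tidy frame with a ``group`` column plus feature columns f1..fp."""
    feats = np.vstack([data.X, data.Y])
    df = pd.DataFrame(feats, columns=[f"f{i + 1}" for i in range(data.p)])
    df.insert(0, "group", [data.labels[0]] * data.n1 + [data.labels[1]] * data.n2)
    return df
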