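"""Shared test utilities: random instances and the grid-search oracle.

The oracle minimises the separation error f(a, b) directly over a dense
(a, b) grid, refined around the incumbent (f is convex, so coarse-to-fine
refinement homes in on the minimiser).  It never touches the LP machinery,
so it is an independent check of the LP optimum.
"""

from __future__ import annotations

import numpy as np

from lpda.core import TwoGroupData


def _grid_eval(data, center, hw, n_points):
    axes = [np.linspace(c - hw, c + hw, n_points) for c in center]
    mesh = np.meshgrid(*axes, indexing="ij")
    Z = np.stack([g.ravel() for g in mesh], axis=1)   # (G, p+1)
    A, b = Z[:, :-1], Z[:, -1]
    f = (np.maximum(b[:, None] + 1.0 - A @ data.X.T, 0.0) @ data.m
         + np.maximum(A @ data.Y.T - b[:, None] + 1.0, 0.0) @ data.w)
    i = int(np.argmin(f))
    return float(f[i]), Z[i]


def grid_min_separation_error(data: TwoGroupData, half_width: float = 5.0,
                              n_points: int = 21, max_iter: int = 40):
    """Minimum of f over an adaptively expanded and refined (a, b) grid.

    Starts on a box around the origin; when the incumbent sits on the box
    boundary (the minimiser may need a large ||a|| when the between-group gap
    is small) the box is enlarged, otherwise it is refined around the
    incumbent.  Convexity of f makes the coarse-to-fine search sound.  A
    final derivative-free simplex polish sharpens the incumbent — everything
    operates on f directly, never on the LP.  Returns ``(value, a, b)``.
    """
    from scipy.optimize import minimize

    def f(z):
        a, b = z[:-1], z[-1]
        return float(data.m @ np.maximum(b + 1.0 - data.X @ a, 0.0)
                     + data.w @ np.maximum(data.Y @ a - b + 1.0, 0.0))

    center = np.zeros(data.p + 1)
    hw = half_width
    best_val, best_z = np.inf, center
    for _ in range(max_iter):
        val, z = _grid_eval(data, center, hw, n_points)
        if val < best_val:
            best_val, best_z = val, z
        on_boundary = np.max(np.abs(z - center)) >= hw * (1 - 1e-9)
        center = z
        if best_val == 0.0:
            break
        if on_boundary:
            hw *= 3.0                      # minimiser may lie outside the box
        else:
            hw = 2.0 * hw / (n_points - 1)  # new box = one old grid cell each side
    if best_val > 0.0:
        res = minimize(f, best_z, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        for _ in range(3):  # restarts help on the non-smooth ridges
            res = minimize(f, res.x, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        if res.fun < best_val:
            best_val, best_z = float(res.fun), res.x
    return best_val, best_z[:-1], float(best_z[-1])


def random_instance(rng: np.random.Generator, p: int | None = None,
                    max_n: int = 5, shift: float | None = None) -> TwoGroupData:
    """Small random two-group instance with a random centroid shift."""
    if p is None:
        p = int(rng.integers(1, 3))
    n1 = int(rng.integers(1, max_n + 1))
    n2 = int(rng.integers(1, max_n + 1))
    if shift is None:
        shift = float(rng.uniform(0.0, 3.0))
    u = rng.standard_normal(p)
    u /= max(np.linalg.norm(u), 1e-12)
    X = 0.5 * shift * u + rng.normal(size=(n1, p))
    Y = -0.5 * shift * u + rng.normal(size=(n2, p))
    return TwoGroupData(X, Y, labels=("A", "B"))
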