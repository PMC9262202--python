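"""Two-group separating-hyperplane fitting by linear programming.

A hyperplane ``H = {x : a'x = b}`` strictly separates the point sets X and Y
when the margin system

    a'x_i >= b + 1   for every x_i in X
    a'y_j <= b - 1   for every y_j in Y

is consistent.  When it is not, the quality of a candidate ``(a, b)`` is
measured by the *separation error function*

    f(a, b) = sum_i m_i * max(b + 1 - a'x_i, 0)
            + sum_j w_j * max(a'y_j - b + 1, 0)

with per-group weights ``m`` and ``w`` each summing to one.  ``f`` is convex
and piecewise linear; its minimisation is equivalent to the linear program

    min  m'u + w'v
    s.t. u_i >= -a'x_i + b + 1,  u_i >= 0
         v_j >=  a'y_j - b + 1,  v_j >= 0

over free ``(a, b)`` and slack vectors ``u, v``.  The optimal value v(P) lies
in [0, 2] (the point a=0, b in [-1, 1], u = (b+1)1, v = (1-b)1 is always
feasible with objective 2) and v(P) = 0 exactly when the groups are strictly
separable.  Whenever the weighted centroids of the two groups differ, some
optimum has a != 0 and therefore defines a discriminant hyperplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import DegenerateDataError, SolverError, ValidationError

__all__ = [
    "TwoGroupData",
    "Hyperplane",
    "LPProblem",
    "LPSolution",
    "separation_error",
    "build_lp",
    "solve_lp",
    "fit_hyperplane",
    "centroids",
    "check_separability",
    "predict_binary",
]

#: default absolute tolerance for "a is zero" and "v(P) is zero" decisions
DEFAULT_TOL = 1e-8

_WEIGHT_SUM_TOL = 1e-10


def _as_matrix(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    if out.ndim != 2 or out.shape[0] < 1 or out.shape[1] < 1:
        raise ValidationError(f"{name} must be a non-empty 2-d array, got shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ValidationError(f"{name} contains non-finite entries")
    return out


def _normalized_weights(raw, n: int, name: str) -> np.ndarray:
    if raw is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(raw, dtype=float).ravel()
    if w.shape != (n,):
        raise ValidationError(f"{name} must have length {n}, got {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValidationError(f"{name} must be positive and finite")
    return w / w.sum()


@dataclass(frozen=True)
class TwoGroupData:
    """Two weighted point sets in R^p.

    Raw weights are accepted unnormalised and rescaled to sum to one within
    each group, as the theory behind the [0, 2] objective bound requires.
    """

    X: np.ndarray
    Y: np.ndarray
    m: np.ndarray = None
    w: np.ndarray = None
    labels: tuple = ("group1", "group2")

    def __post_init__(self):
        X = _as_matrix(self.X, "X")
        Y = _as_matrix(self.Y, "Y")
        if X.shape[1] != Y.shape[1]:
            raise ValidationError(
                f"X and Y must share a feature dimension: {X.shape[1]} != {Y.shape[1]}"
            )
        m = _normalized_weights(self.m, X.shape[0], "m")
        w = _normalized_weights(self.w, Y.shape[0], "w")
        labels = tuple(self.labels)
        if len(labels) != 2 or labels[0] == labels[1]:
            raise ValidationError(f"labels must be two distinct identifiers, got {labels!r}")
        assert abs(m.sum() - 1.0) < _WEIGHT_SUM_TOL and abs(w.sum() - 1.0) < _WEIGHT_SUM_TOL
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "labels", labels)

    @property
    def n1(self) -> int:
        return self.X.shape[0]

    @property
    def n2(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def swapped(self) -> "TwoGroupData":
        """Exchange the roles of the two groups."""
        return TwoGroupData(self.Y, self.X, self.w, self.m, (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class Hyperplane:
    """``H = {x : a'x = b}`` with a non-zero coefficient vector ``a``."""

    a: np.ndarray
    b: float
    atol: float = 1e-8

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float).ravel()
        if a.size < 1 or not np.all(np.isfinite(a)):
            raise ValidationError("hyperplane coefficients must be a finite non-empty vector")
        if float(np.linalg.norm(a)) <= self.atol:
            raise ValidationError("hyperplane coefficient vector is (numerically) zero")
        if not np.isfinite(self.b):
            raise ValidationError("hyperplane offset must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", float(self.b))

    @property
    def p(self) -> int:
        return self.a.size

    def signed_distance(self, points) -> np.ndarray:
        """Euclidean signed distance (a'x - b)/||a||; positive on the X side."""
        pts = self._check_points(points)
        return (pts @ self.a - self.b) / np.linalg.norm(self.a)

    def _check_points(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
        if pts.ndim != 2 or pts.shape[1] != self.p:
            raise ValidationError(
                f"points must be n x {self.p}, got shape {np.shape(points)}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("points contain non-finite entries")
        return pts


@dataclass(frozen=True)
class LPProblem:
    """Matrices of the LP in ``linprog`` form (A_ub z <= b_ub, bounds on z).

    Decision vector layout: z = (a_1..a_p, b, u_1..u_n1, v_1..v_n2).
    """

    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    bounds: list
    n1: int
    n2: int
    p: int
    data: TwoGroupData = field(repr=False)

    @property
    def n_variables(self) -> int:
        return self.c.size

    @property
    def n_constraints(self) -> int:
        return self.A_ub.shape[0]


@dataclass(frozen=True)
class LPSolution:
    """Optimal point of the LP and its diagnostics."""

    a: np.ndarray
    b: float
    u: np.ndarray
    v: np.ndarray
    objective: float
    solver_status: str  # "optimal" | "degenerate_zero_a" | "infeasible_unexpected"
    solver_message: str = ""


def separation_error(a, b: float, data: TwoGroupData) -> float:
    """Weighted sum of margin-constraint violations at ``(a, b)``.

    Zero exactly when ``(a, b)`` strictly separates the two groups with unit
    margin; equals 2 at ``a = 0`` for any ``b`` in [-1, 1].
    """
    a = np.asarray(a, dtype=float).ravel()
    if a.shape != (data.p,):
        raise ValidationError(f"a must have length {data.p}, got {a.shape}")
    if not (np.all(np.isfinite(a)) and np.isfinite(b)):
        raise ValidationError("a and b must be finite")
    x_side = np.maximum(b + 1.0 - data.X @ a, 0.0)
    y_side = np.maximum(data.Y @ a - b + 1.0, 0.0)
    return float(data.m @ x_side + data.w @ y_side)


def centroids(data: TwoGroupData) -> tuple[np.ndarray, np.ndarray]:
    """Weighted centroids (x-bar, y-bar) of the two groups."""
    return data.m @ data.X, data.w @ data.Y


def build_lp(data: TwoGroupData) -> LPProblem:
    """Assemble the LP matrices for the separation-error minimisation.

    p + 1 + n1 + n2 variables; n1 + n2 inequality rows (slack positivity is
    expressed through variable bounds).  Sign convention: every row is written
    as ``A z <= -1``.
    """
    n1, n2, p = data.n1, data.n2, data.p
    nvar = p + 1 + n1 + n2
    c = np.concatenate([np.zeros(p + 1), data.m, data.w])

    A = np.zeros((n1 + n2, nvar))
    # u_i >= -a'x_i + b + 1   ->   -a'x_i + b - u_i <= -1
    A[:n1, :p] = -data.X
    A[:n1, p] = 1.0
    A[np.arange(n1), p + 1 + np.arange(n1)] = -1.0
    # v_j >= a'y_j - b + 1    ->    a'y_j - b - v_j <= -1
    A[n1:, :p] = data.Y
    A[n1:, p] = -1.0
    A[n1 + np.arange(n2), p + 1 + n1 + np.arange(n2)] = -1.0

    b_ub = np.full(n1 + n2, -1.0)
    bounds = [(None, None)] * (p + 1) + [(0.0, None)] * (n1 + n2)
    return LPProblem(c=c, A_ub=A, b_ub=b_ub, bounds=bounds, n1=n1, n2=n2, p=p, data=data)


def _unpack(problem: LPProblem, z: np.ndarray, tol: float, message: str) -> LPSolution:
    p, n1, n2 = problem.p, problem.n1, problem.n2
    a = z[:p].copy()
    b = float(z[p])
    u = z[p + 1 : p + 1 + n1].copy()
    v = z[p + 1 + n1 :].copy()
    objective = float(problem.data.m @ u + problem.data.w @ v)
    status = "degenerate_zero_a" if np.linalg.norm(a) <= tol else "optimal"
    return LPSolution(a=a, b=b, u=u, v=v, objective=objective,
                      solver_status=status, solver_message=message)


def solve_lp(problem: LPProblem, tol: float = DEFAULT_TOL, method: str = "highs") -> LPSolution:
    """Solve the assembled LP with scipy's HiGHS backend."""
    res = linprog(problem.c, A_ub=problem.A_ub, b_ub=problem.b_ub,
                  bounds=problem.bounds, method=method)
    if res.status == 2:  # the LP is always feasible, so this is an internal error
        raise SolverError(f"solver reported infeasible_unexpected: {res.message}")
    if not res.success:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
    return _unpack(problem, res.x, tol, res.message)


def _resolve_degenerate(problem: LPProblem, sol: LPSolution, direction: np.ndarray,
                        tol: float) -> LPSolution:
    """Recover an optimal solution with a != 0 from a degenerate optimum.

    First re-solve with the dual simplex so a vertex (basic) optimum is
    returned; if that vertex still has a = 0, maximise a'(x-bar - y-bar) over
    the optimal face of the LP.  When the centroids differ, some optimum has
    a != 0, and any such optimum has a'(x-bar - y-bar) > 0 along the centroid
    gap, so the secondary LP finds one.
    """
    vertex = solve_lp(problem, tol=tol, method="highs-ds")
    if vertex.solver_status == "optimal":
        return vertex

    p = problem.p
    nvar = problem.n_variables
    # optimal-face constraint: c'z <= v(P) + tol
    face_row = problem.c[None, :]
    A_ub = np.vstack([problem.A_ub, face_row])
    b_ub = np.concatenate([problem.b_ub, [sol.objective + tol]])
    c2 = np.zeros(nvar)
    c2[:p] = -direction  # maximise a'direction
    # cap a'direction so the secondary LP is bounded even on an unbounded face
    cap = np.zeros(nvar)
    cap[:p] = direction
    A_ub = np.vstack([A_ub, cap[None, :]])
    b_ub = np.concatenate([b_ub, [1.0]])
    res = linprog(c2, A_ub=A_ub, b_ub=b_ub, bounds=problem.bounds, method="highs")
    if not res.success:
        raise SolverError(
            f"secondary LP over the optimal face failed (status {res.status}): {res.message}"
        )
    return _unpack(problem, res.x, tol, "recovered from degenerate optimum via optimal face")


def fit_hyperplane(data: TwoGroupData, tol: float = DEFAULT_TOL) -> tuple[Hyperplane, LPSolution]:
    """Minimise the separation error and return the discriminant hyperplane.

    Raises
    ------
    DegenerateDataError
        When the weighted centroids of the two groups coincide, in which case
        an optimal hyperplane is not guaranteed to exist.
    SolverError
        When the backend fails, or a nonzero-coefficient optimum cannot be
        recovered despite distinct centroids.
    """
    problem = build_lp(data)
    sol = solve_lp(problem, tol=tol)
    if sol.solver_status == "degenerate_zero_a":
        xbar, ybar = centroids(data)
        gap = xbar - ybar
        scale = max(1.0, float(np.linalg.norm(xbar) + np.linalg.norm(ybar)))
        if np.linalg.norm(gap) <= tol * scale:
            raise DegenerateDataError(
                "the weighted group centroids coincide; no discriminant hyperplane is "
                "guaranteed (move, reweight or drop samples so the centroids differ)"
            )
        sol = _resolve_degenerate(problem, sol, gap / np.linalg.norm(gap), tol)
        if sol.solver_status == "degenerate_zero_a":
            raise SolverError(
                "could not recover a nonzero coefficient vector at the LP optimum "
                f"(||a|| <= {tol}, v(P) = {sol.objective:.6g}) although the centroids differ"
            )
    return Hyperplane(sol.a, sol.b, atol=tol), sol


def check_separability(solution: LPSolution, tol: float = DEFAULT_TOL) -> bool:
    """True when the optimal objective certifies strict separability (v(P) <= tol)."""
    return solution.objective <= tol


def predict_binary(h: Hyperplane, points, labels: Sequence) -> np.ndarray:
    """Assign each point to the first label when a'x >= b, else the second.

    The exact tie a'x = b goes to the first label (the X side) by convention.
    """
    labels = tuple(labels)
    if len(labels) != 2:
        raise ValidationError(f"labels must be a pair, got {labels!r}")
    pts = h._check_points(points)
    score = pts @ h.a - h.b
    return np.where(score >= 0.0, labels[0], labels[1])
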