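"""Feasibility domains as explicit convex bodies in capture-rate space.

Three nested domains are built for a network and supply level Q:

* capture domain  D_C = {s >= 0, s.N0 <= Q}        (a simplex),
* initialization  D_I = D_C  cut by the feasibility cone n(s) > 0
                  (a convex polytope),
* maturation      D_M = D_I  cut by the steady-state energy cap
                  s.N*(s) <= Q   (polytope intersected with a quadric:
                  an "InterPolyQuad").

For a candidate community C the cone conditions come from the boundary-
equilibrium decomposition s = d + sum_{i in C} n_i sigma_i - sum_{i notin C}
n_i e_i, so one code path covers full and partial communities.  Strict
inequalities (s > 0, n_i > 0) are stored as closed rows for volume purposes
(their boundaries have measure zero); a strictness flag is retained for
membership tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linprog, minimize

from .network import (
    CandidateCommunity,
    EnergeticNetwork,
    NetworkInputError,
    SteadyStateOptions,
    is_dissipative,
    support_columns,
)

__all__ = [
    "HPolytope",
    "QuadraticConstraint",
    "InterPolyQuad",
    "capture_domain",
    "initialization_domain",
    "maturation_domain",
    "standardize",
    "chebyshev_center",
    "interior_point",
    "GeometryError",
]

#: absolute tolerance for strict-membership tests
STRICT_ATOL = 1e-12


class GeometryError(RuntimeError):
    """Geometric precondition violated (unbounded body, indefinite form...)."""


@dataclass(frozen=True)
class HPolytope:
    """Half-space representation {s : A s <= b}.

    ``strict`` marks rows that are open (<) in the mathematical definition;
    it affects membership tests only, never volumes.
    """

    A: np.ndarray
    b: np.ndarray
    strict: np.ndarray | None = None

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        b = np.asarray(self.b, dtype=float).reshape(-1)
        if A.shape[0] != b.shape[0]:
            raise NetworkInputError(f"A has {A.shape[0]} rows but b has {b.shape[0]}")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            raise NetworkInputError("polytope rows must be finite")
        strict = self.strict
        strict = np.zeros(A.shape[0], bool) if strict is None else np.asarray(strict, bool)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "strict", strict)

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    def contains(self, x, atol: float = STRICT_ATOL, honour_strict: bool = False) -> np.ndarray:
        """Vectorised membership; x may be (dim,) or (n, dim)."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        slack = self.b[None, :] - X @ self.A.T
        ok = slack >= -atol
        if honour_strict and self.strict.any():
            ok[:, self.strict] = slack[:, self.strict] > atol
        out = ok.all(axis=1)
        return out if np.ndim(x) > 1 else bool(out[0])

    def stack(self, other: "HPolytope") -> "HPolytope":
        return HPolytope(
            np.vstack([self.A, other.A]),
            np.concatenate([self.b, other.b]),
            np.concatenate([self.strict, other.strict]),
        )


@dataclass(frozen=True)
class QuadraticConstraint:
    """{s : s^T M s + v^T s <= c} with M symmetric (PSD for convex bodies)."""

    M: np.ndarray
    v: np.ndarray
    c: float

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        v = np.asarray(self.v, dtype=float).reshape(-1)
        if M.shape != (v.size, v.size):
            raise NetworkInputError("M must be square and match v")
        if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
            raise NetworkInputError("M must be symmetric")
        object.__setattr__(self, "M", (M + M.T) / 2.0)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "c", float(self.c))

    def value(self, x) -> np.ndarray:
        """q(x) = x^T M x + v^T x (membership iff q(x) <= c)."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        q = np.einsum("ni,ij,nj->n", X, self.M, X) + X @ self.v
        return q if np.ndim(x) > 1 else float(q[0])

    def contains(self, x, atol: float = STRICT_ATOL):
        q = self.value(x)
        return q <= self.c + atol


@dataclass(frozen=True)
class InterPolyQuad:
    """Intersection of a polytope and (optionally) one quadratic constraint,
    with bookkeeping for the whitening transform.

    In whitened coordinates y = L^T (x - center) the quadratic reads
    ||y||^2 <= radius^2.  ``log_jacobian`` is log|det T^-1|: volumes in
    original coordinates equal whitened volumes times exp(log_jacobian).
    """

    poly: HPolytope
    quad: QuadraticConstraint | None = None
    # whitening bookkeeping (identity unless produced by standardize())
    transform: np.ndarray | None = None       # T:  y = T (x - shift)
    shift: np.ndarray | None = None
    log_jacobian: float = 0.0
    whitened: bool = False

    @property
    def dim(self) -> int:
        return self.poly.dim

    def contains(self, x, atol: float = STRICT_ATOL, honour_strict: bool = False):
        ok = self.poly.contains(x, atol=atol, honour_strict=honour_strict)
        if self.quad is not None:
            ok = ok & self.quad.contains(x, atol=atol)
        return ok


def capture_domain(net: EnergeticNetwork, Q: float) -> HPolytope:
    """The simplex D_C = {s >= 0, s.N0 <= Q}: every way a total supply Q can
    be split at minimal biomass.  Vertices are the origin and (Q/N0_i) e_i."""
    if not Q > 0:
        raise NetworkInputError(f"supply Q must be > 0, got {Q}")
    S = net.S
    A = np.vstack([-np.eye(S), net.N0[None, :]])
    b = np.concatenate([np.zeros(S), [float(Q)]])
    return HPolytope(A, b)


def _cone_rows(
    net: EnergeticNetwork,
    community: CandidateCommunity | None,
    options: SteadyStateOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear rows expressing n_i(s) > eps-shifted positivity: with
    n(s) = B^-1 (s - d), positivity n >= eps is -B^-1 s <= -B^-1 d - eps."""
    S = net.S
    community = CandidateCommunity.full(S) if community is None else community
    B = support_columns(net, community)
    Binv = np.linalg.inv(B)
    eps = np.zeros(S)
    if options is not None:
        thr = options.thresholds(S)
        eps[list(community.members)] = thr[list(community.members)]
    A = -Binv
    b = -(Binv @ net.d) - eps
    return A, b, Binv


def initialization_domain(
    net: EnergeticNetwork,
    Q: float,
    community: CandidateCommunity | None = None,
    options: SteadyStateOptions | None = None,
) -> HPolytope:
    """D_I(C) = {s in the feasibility cone of C : s >= 0, s.N0 <= Q}.

    The cone conditions n_i(s) > 0 are linear in s; an empty polytope is a
    valid return (zero volume below the critical supply).
    """
    if not is_dissipative(net):
        raise GeometryError("initialization domain requires a dissipative sigma")
    base = capture_domain(net, Q)
    A, b, _ = _cone_rows(net, community, options)
    strict = np.concatenate([base.strict, np.ones(len(b), bool)])
    return HPolytope(np.vstack([base.A, A]), np.concatenate([base.b, b]), strict)


def maturation_quadratic(
    net: EnergeticNetwork, Q: float, community: CandidateCommunity | None = None
) -> QuadraticConstraint | None:
    """The steady-state energy cap s.N*_C(s) <= Q as a quadratic triple.

    N*_C(s) = P B^-1 (s - d) is affine (P projects onto community members),
    so the cap is s^T K s - (K d).s <= Q with K = P B^-1, symmetrized.
    Empty community: N* = 0 and the cap is inactive (returns None).
    """
    S = net.S
    community = CandidateCommunity.full(S) if community is None else community
    if community.size == 0:
        return None
    _, _, Binv = _cone_rows(net, community)
    K = np.zeros((S, S))
    members = list(community.members)
    K[members, :] = Binv[members, :]
    M = (K + K.T) / 2.0
    return QuadraticConstraint(M, -(K @ net.d), float(Q))


def maturation_domain(
    net: EnergeticNetwork,
    Q: float,
    community: CandidateCommunity | None = None,
    options: SteadyStateOptions | None = None,
) -> InterPolyQuad:
    """D_M(C) = D_I(C) intersected with the steady-state cap s.N*_C(s) <= Q.

    Dissipativity of sigma makes the full-community cap convex (M is the
    symmetrized inverse of sigma, positive definite); the body is then an
    InterPolyQuad amenable to whitening and multiphase Monte Carlo.
    """
    if not is_dissipative(net):
        raise GeometryError("maturation domain requires a dissipative sigma")
    poly = initialization_domain(net, Q, community, options)
    quad = maturation_quadratic(net, Q, community)
    return InterPolyQuad(poly=poly, quad=quad)


def standardize(body: InterPolyQuad) -> InterPolyQuad:
    """Whiten the quadratic constraint into a centered ball.

    Completing the square, q(x) <= c becomes (x - x_c)^T M (x - x_c) <= r^2
    with x_c = -M^-1 v / 2; the Cholesky factor M = L L^T then maps
    y = L^T (x - x_c) to ||y||^2 <= r^2.  Volumes transform by
    |det T^-1| = det(L)^-1 = det(M)^-1/2 (recorded as log_jacobian).
    """
    if body.quad is None:
        return replace(body, transform=np.eye(body.dim), shift=np.zeros(body.dim),
                       log_jacobian=0.0, whitened=True)
    M, v, c = body.quad.M, body.quad.v, body.quad.c
    eigmin = float(np.linalg.eigvalsh(M)[0])
    if eigmin <= 1e-12 * max(1.0, float(np.abs(M).max())):
        raise GeometryError(
            f"quadratic form is not positive definite (min eigenvalue {eigmin:.3e})"
        )
    L = np.linalg.cholesky(M)
    x_c = np.linalg.solve(M, -v / 2.0)
    # q(x_c) = -x_c^T M x_c at the completed-square center, so the ball
    # radius^2 is c - q(x_c) = c + x_c^T M x_c
    r2 = max(c + float(x_c @ M @ x_c), 0.0)
    T = L.T
    Tinv = np.linalg.inv(T)
    A_w = body.poly.A @ Tinv
    b_w = body.poly.b - body.poly.A @ x_c
    quad_w = QuadraticConstraint(np.eye(body.dim), np.zeros(body.dim), r2)
    log_jac = -float(np.sum(np.log(np.diag(L))))
    return InterPolyQuad(
        poly=HPolytope(A_w, b_w, body.poly.strict),
        quad=quad_w,
        transform=T,
        shift=x_c,
        log_jacobian=log_jac,
        whitened=True,
    )


def chebyshev_center(poly: HPolytope) -> tuple[np.ndarray, float]:
    """Center and radius of the largest inscribed ball, by the standard LP
    max r s.t. a_i.x + ||a_i|| r <= b_i.  Radius <= 0 signals an empty or
    lower-dimensional body."""
    A, b = poly.A, poly.b
    if A.shape[0] == 0:
        raise GeometryError("Chebyshev LP is unbounded: polytope has no rows")
    norms = np.linalg.norm(A, axis=1)
    A_lp = np.hstack([A, norms[:, None]])
    c = np.zeros(poly.dim + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=A_lp, b_ub=b, bounds=[(None, None)] * poly.dim + [(None, None)],
                  method="highs")
    if res.status == 3:
        raise GeometryError("Chebyshev LP unbounded: body lacks a bounding constraint")
    if not res.success:
        raise GeometryError(f"Chebyshev LP failed: {res.message}")
    return res.x[:-1], float(res.x[-1])


def _quad_minimizer_over_poly(poly: HPolytope, quad: QuadraticConstraint,
                              x_start: np.ndarray) -> np.ndarray:
    cons = [{"type": "ineq", "fun": lambda x, i=i: poly.b[i] - poly.A[i] @ x,
             "jac": lambda x, i=i: -poly.A[i]} for i in range(poly.n_rows)]
    res = minimize(
        lambda x: quad.value(x) - quad.c,
        x_start,
        jac=lambda x: 2.0 * quad.M @ x + quad.v,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return res.x


def interior_point(body: InterPolyQuad, margin: float = 1e-9) -> np.ndarray | None:
    """A point strictly inside every constraint, or ``None`` if the body is
    (numerically) empty.

    Starts from the polytope's Chebyshev center (which ignores the quadratic
    constraint); if the quadratic is violated there, moves along the segment
    toward the quadratic form's minimizer over the polytope, bisecting to a
    strictly feasible point.
    """
    if body.poly.n_rows == 0:
        if body.quad is None:
            raise GeometryError("body has no constraints")
        M, v = body.quad.M, body.quad.v
        x = np.linalg.solve(2.0 * M, -v)  # unconstrained quadratic minimizer
        return x if body.quad.value(x) < body.quad.c - margin else None
    center, radius = chebyshev_center(body.poly)
    if radius <= 1e-12:
        return None
    if body.quad is None or body.quad.value(center) < body.quad.c - margin:
        return center
    z = _quad_minimizer_over_poly(body.poly, body.quad, center)
    qz = body.quad.value(z)
    if not qz < body.quad.c - 1e-14:
        return None  # quadratic region misses the polytope interior
    lo, hi = 0.0, 1.0  # x(t) = center + t (z - center); t=1 satisfies quad
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        x = center + mid * (z - center)
        if body.quad.value(x) < body.quad.c - 1e-14:
            hi = mid
        else:
            lo = mid
    t = min(1.0, hi + 0.1 * (1.0 - hi))  # step past the crossing, strictly inside
    x = center + t * (z - center)
    if bool(np.all(body.poly.A @ x <= body.poly.b - 1e-14)) and \
            body.quad.value(x) < body.quad.c - 1e-14:
        return x
    # fall back to the quad minimizer nudged toward the Chebyshev center
    x = z + 1e-6 * (center - z)
    if body.contains(x, atol=0.0):
        return x
    return None


def prune_redundant_rows(poly: HPolytope, n_random: int = 0, seed: int = 0) -> HPolytope:
    """Drop rows never active at LP optima over +-coordinate directions (and
    optional random directions).  Conservative: keeps any row that is tight
    somewhere among the probed optima."""
    A, b = poly.A, poly.b
    dirs = np.vstack([np.eye(poly.dim), -np.eye(poly.dim)])
    if n_random:
        rng = np.random.default_rng(seed)
        extra = rng.standard_normal((n_random, poly.dim))
        dirs = np.vstack([dirs, extra / np.linalg.norm(extra, axis=1, keepdims=True)])
    keep = np.zeros(poly.n_rows, bool)
    for u in dirs:
        res = linprog(-u, A_ub=A, b_ub=b, bounds=[(None, None)] * poly.dim, method="highs")
        if res.success:
            keep |= (b - A @ res.x) < 1e-9 * (1.0 + np.abs(b))
    if keep.all() or not keep.any():
        return poly
    return HPolytope(A[keep], b[keep], poly.strict[keep])
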