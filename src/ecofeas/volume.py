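"""Volumes of feasibility domains: exact for polytopes, Monte Carlo otherwise.

Three routes, used as cross-checking oracles of one another in the tests:

* closed form for the capture simplex,  vol = Q^S / (S! prod_i N0_i);
* exact polytope volume by vertex enumeration (H -> V via Qhull half-space
  intersection) and convex-hull triangulation;
* multiphase Monte Carlo for polytope-and-quadric bodies: whiten the
  quadratic to a centered ball, anchor at the inscribed ball of an interior
  point, and telescope vol(body) = vol(Ball(r0)) * prod vol(K_{i+1})/vol(K_i)
  over balls of radius r_i = r0 * 2^(i/S), each ratio estimated by
  Hit-and-Run samples of the larger body counted against the smaller.

A rejection sampler against an envelope of known volume serves as a simple
low-dimensional validation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .geometry import (
    GeometryError,
    HPolytope,
    InterPolyQuad,
    chebyshev_center,
    interior_point,
    prune_redundant_rows,
    standardize,
)
from .network import EnergeticNetwork, NetworkInputError

__all__ = [
    "VolumeEstimate",
    "simplex_volume",
    "polytope_volume_exact",
    "hit_and_run_sample",
    "multiphase_volume",
    "rejection_volume",
    "SimplexEnvelope",
    "BoxEnvelope",
    "ball_volume",
]


@dataclass(frozen=True)
class VolumeEstimate:
    """A volume with provenance.

    ``standard_error`` is present iff the method is stochastic.  ``value``
    carries units of s-space volume, (power/mass)^S.
    """

    value: float
    method: str  # exact | multiphase_mc | rejection | analytic
    standard_error: float | None = None
    sample_count: int | None = None
    note: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("volume cannot be negative")


def ball_volume(dim: int, radius: float = 1.0) -> float:
    """Closed-form volume of the Euclidean ball."""
    return math.pi ** (dim / 2.0) / math.gamma(dim / 2.0 + 1.0) * radius ** dim


def simplex_volume(net: EnergeticNetwork, Q: float) -> VolumeEstimate:
    """Exact volume of the capture simplex, Q^S / (S! prod_i N0_i).

    Evaluated in log space so large S or Q cannot overflow.
    """
    if not Q > 0:
        raise NetworkInputError(f"supply Q must be > 0, got {Q}")
    S = net.S
    log_vol = S * math.log(Q) - math.lgamma(S + 1) - float(np.sum(np.log(net.N0)))
    return VolumeEstimate(value=math.exp(log_vol), method="analytic")


def polytope_volume_exact(poly: HPolytope, tol: float = 1e-10) -> VolumeEstimate:
    """Exact volume by H->V enumeration (Qhull) and hull triangulation.

    Empty or lower-dimensional bodies return 0 (with a dimensionality note);
    unbounded bodies raise :class:`GeometryError`.
    """
    center, radius = chebyshev_center(poly)  # raises on unbounded
    scale = max(1.0, float(np.max(np.abs(poly.b))))
    if radius <= tol * scale:
        note = "empty" if radius < -tol * scale else "degenerate (lower-dimensional)"
        return VolumeEstimate(value=0.0, method="exact", note=note)
    halfspaces = np.hstack([poly.A, -poly.b[:, None]])
    try:
        hs = HalfspaceIntersection(halfspaces, center)
        hull = ConvexHull(hs.intersections)
    except QhullError:
        pruned = prune_redundant_rows(poly, n_random=4 * poly.dim, seed=0)
        hs = HalfspaceIntersection(
            np.hstack([pruned.A, -pruned.b[:, None]]), center, qhull_options="QJ"
        )
        hull = ConvexHull(hs.intersections, qhull_options="QJ")
    return VolumeEstimate(value=float(hull.volume), method="exact")


def polytope_vertices(poly: HPolytope, tol: float = 1e-10) -> np.ndarray:
    """Vertex enumeration (V-representation) of a bounded full-dimensional
    polytope; empty array for empty/degenerate bodies."""
    return vertices_and_volume(poly, tol)[0]


def vertices_and_volume(poly: HPolytope, tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Vertices and exact volume in one H->V enumeration pass."""
    center, radius = chebyshev_center(poly)
    scale = max(1.0, float(np.max(np.abs(poly.b))))
    if radius <= tol * scale:
        return np.empty((0, poly.dim)), 0.0
    if poly.dim == 1:
        a = poly.A[:, 0]
        hi = float(np.min(poly.b[a > 0] / a[a > 0])) if np.any(a > 0) else np.inf
        lo = float(np.max(poly.b[a < 0] / a[a < 0])) if np.any(a < 0) else -np.inf
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise GeometryError("unbounded 1-D polytope")
        return np.array([[lo], [hi]]), hi - lo
    halfspaces = np.hstack([poly.A, -poly.b[:, None]])
    try:
        hs = HalfspaceIntersection(halfspaces, center)
        hull = ConvexHull(hs.intersections)
    except QhullError:
        pruned = prune_redundant_rows(poly, n_random=4 * poly.dim, seed=0)
        hs = HalfspaceIntersection(
            np.hstack([pruned.A, -pruned.b[:, None]]), center, qhull_options="QJ"
        )
        hull = ConvexHull(hs.intersections, qhull_options="QJ")
    return hs.intersections[hull.vertices], float(hull.volume)


# ---------------------------------------------------------------------------
# Hit-and-Run
# ---------------------------------------------------------------------------

_EPS_DIR = 1e-13


def _chord_linear(X, U, A, b, lo, hi):
    """Shrink per-chain chord [lo, hi] by every half-space a.x <= b."""
    if A.shape[0] == 0:
        return lo, hi
    AU = U @ A.T                       # (k, m)
    slack = b[None, :] - X @ A.T       # (k, m), >= 0 for interior points
    slack = np.maximum(slack, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = slack / AU
    hi = np.minimum(hi, np.min(np.where(AU > _EPS_DIR, ratio, np.inf), axis=1))
    lo = np.maximum(lo, np.max(np.where(AU < -_EPS_DIR, ratio, -np.inf), axis=1))
    return lo, hi


def _chord_quadratic(X, U, M, v, c, lo, hi):
    """Shrink chords by x^T M x + v.x <= c along x + t u.

    Convex case (u.M.u > 0) gives one interval; the indefinite case keeps the
    connected feasible interval containing the current (feasible) point.
    """
    alpha = np.einsum("ki,ij,kj->k", U, M, U)
    g = 2.0 * X @ M + v[None, :]
    beta = np.sum(g * U, axis=1)
    gamma = np.einsum("ki,ij,kj->k", X, M, X) + X @ v - c  # <= 0 inside
    gamma = np.minimum(gamma, 0.0)
    disc = beta * beta - 4.0 * alpha * gamma
    sq = np.sqrt(np.maximum(disc, 0.0))
    pos = alpha > _EPS_DIR
    with np.errstate(divide="ignore", invalid="ignore"):
        t_minus = (-beta - sq) / (2.0 * alpha)
        t_plus = (-beta + sq) / (2.0 * alpha)
    lo = np.where(pos, np.maximum(lo, t_minus), lo)
    hi = np.where(pos, np.minimum(hi, t_plus), hi)
    lin = np.abs(alpha) <= _EPS_DIR
    if np.any(lin):
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lin = -gamma / beta
        hi = np.where(lin & (beta > _EPS_DIR), np.minimum(hi, t_lin), hi)
        lo = np.where(lin & (beta < -_EPS_DIR), np.maximum(lo, t_lin), lo)
    neg = alpha < -_EPS_DIR
    if np.any(neg):
        # downward parabola: feasible t <= r_lo or t >= r_hi; keep the branch
        # containing t = 0 (the current point is feasible)
        r_lo = np.minimum(t_minus, t_plus)
        r_hi = np.maximum(t_minus, t_plus)
        no_roots = disc <= 0
        left = r_lo >= 0
        hi = np.where(neg & ~no_roots & left, np.minimum(hi, r_lo), hi)
        lo = np.where(neg & ~no_roots & ~left, np.maximum(lo, r_hi), lo)
    return lo, hi


def _chord_ball(X, U, z, r2, lo, hi):
    """Chord of the ball ||x - z||^2 <= r2 (fast path: M = I)."""
    D = X - z[None, :]
    beta = 2.0 * np.sum(D * U, axis=1)
    gamma = np.minimum(np.sum(D * D, axis=1) - r2, 0.0)
    sq = np.sqrt(np.maximum(beta * beta - 4.0 * gamma, 0.0))
    lo = np.maximum(lo, (-beta - sq) / 2.0)
    hi = np.minimum(hi, (-beta + sq) / 2.0)
    return lo, hi


class _SamplerBody:
    """Internal flat representation: linear rows + a list of quadratics.

    Quadratics with identity matrix (balls — e.g. every constraint after
    whitening) take a cheaper chord path.
    """

    def __init__(self, A, b, quads):
        self.A = np.asarray(A, float)
        self.b = np.asarray(b, float)
        self.quads = []
        self.balls = []
        for (M, v, c) in quads:
            M = np.asarray(M, float)
            v = np.asarray(v, float)
            if np.array_equal(M, np.eye(M.shape[0])):
                z = -v / 2.0
                self.balls.append((z, float(c) + float(z @ z)))
            else:
                self.quads.append((M, v, float(c)))

    @classmethod
    def from_body(cls, body: InterPolyQuad, extra_quads=()):
        quads = []
        if body.quad is not None:
            quads.append((body.quad.M, body.quad.v, body.quad.c))
        quads.extend(extra_quads)
        return cls(body.poly.A, body.poly.b, quads)

    def step(self, X, rng):
        k, S = X.shape
        U = rng.standard_normal((k, S))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        lo = np.full(k, -np.inf)
        hi = np.full(k, np.inf)
        lo, hi = _chord_linear(X, U, self.A, self.b, lo, hi)
        for z, r2 in self.balls:
            lo, hi = _chord_ball(X, U, z, r2, lo, hi)
        for M, v, c in self.quads:
            lo, hi = _chord_quadratic(X, U, M, v, c, lo, hi)
        width = hi - lo
        ok = np.isfinite(width) & (width > 1e-13)
        t = np.where(ok, lo + rng.random(k) * np.maximum(width, 0.0), 0.0)
        return X + t[:, None] * U

    def contains(self, X, atol=1e-10):
        ok = np.all(X @ self.A.T <= self.b[None, :] + atol, axis=1) if len(self.b) \
            else np.ones(len(X), bool)
        for z, r2 in self.balls:
            ok &= np.sum((X - z) ** 2, axis=1) <= r2 + atol
        for M, v, c in self.quads:
            q = np.einsum("ki,ij,kj->k", X, M, X) + X @ v
            ok &= q <= c + atol
        return ok


def _run_chains(sampler: _SamplerBody, start, count, thin, rng, chains, burn_in=0):
    S = start.size
    chains = max(1, min(chains, count))
    X = np.tile(np.asarray(start, float), (chains, 1))
    for _ in range(burn_in):
        X = sampler.step(X, rng)
    rounds = -(-count // chains)
    out = np.empty((rounds * chains, S))
    for r in range(rounds):
        for _ in range(thin):
            X = sampler.step(X, rng)
        out[r * chains:(r + 1) * chains] = X
    return out[:count]


def hit_and_run_sample(
    body: InterPolyQuad,
    start,
    count: int,
    thin: int = 1,
    rng_seed=None,
    chains: int = 1,
    burn_in: int = 0,
) -> np.ndarray:
    """Uniform samples of an InterPolyQuad by Hit-and-Run.

    Each retained point follows ``thin`` steps: draw a uniform direction,
    intersect the line with every half-space and quadratic to get the
    feasible chord, then jump to a uniform point on it.  ``chains`` parallel
    walkers (all started at ``start``) share the step loop; with the default
    ``chains=1`` the walk is the plain sequential sampler.  Deterministic
    under a fixed ``rng_seed``.
    """
    start = np.asarray(start, float).reshape(-1)
    if not bool(np.all(body.contains(start, atol=0.0))):
        raise GeometryError("Hit-and-Run start point is not strictly interior")
    rng = np.random.default_rng(rng_seed)
    sampler = _SamplerBody.from_body(body)
    return _run_chains(sampler, start, count, max(1, thin), rng, chains, burn_in)


# ---------------------------------------------------------------------------
# Multiphase Monte Carlo
# ---------------------------------------------------------------------------


def _inscribed_radius(body: InterPolyQuad, x0: np.ndarray) -> float:
    """Largest r with Ball(x0, r) inside the body (conservative for a
    non-whitened quadratic)."""
    r = np.inf
    if body.poly.n_rows:
        norms = np.linalg.norm(body.poly.A, axis=1)
        r = float(np.min((body.poly.b - body.poly.A @ x0) / norms))
    if body.quad is not None:
        M, v, c = body.quad.M, body.quad.v, body.quad.c
        q0 = body.quad.value(x0)
        g = float(np.linalg.norm(2.0 * M @ x0 + v))
        lam = max(float(np.linalg.eigvalsh(M)[-1]), 0.0)
        slack = c - q0
        if slack <= 0:
            return 0.0
        if lam <= 1e-15:
            r_q = slack / g if g > 0 else np.inf
        else:
            r_q = (-g + math.sqrt(g * g + 4.0 * lam * slack)) / (2.0 * lam)
        r = min(r, r_q)
    return float(r)


def _covering_radius(body: InterPolyQuad, x0: np.ndarray) -> float:
    """An R with body inside Ball(x0, R), from per-coordinate polytope
    extents and/or the quadratic's enclosing ball."""
    S = body.dim
    bounds = []
    if body.poly.n_rows:
        lohi = np.empty((S, 2))
        unbounded = False
        for j in range(S):
            e = np.zeros(S)
            e[j] = 1.0
            for k, sign in enumerate((1.0, -1.0)):
                res = linprog(-sign * e, A_ub=body.poly.A, b_ub=body.poly.b,
                              bounds=[(None, None)] * S, method="highs")
                if res.status == 3:
                    unbounded = True
                    break
                lohi[j, k] = sign * -res.fun if res.success else np.nan
            if unbounded:
                break
        if not unbounded and np.all(np.isfinite(lohi)):
            corners = np.abs(lohi - x0[:, None])
            bounds.append(float(np.linalg.norm(np.max(corners, axis=1))))
    if body.quad is not None:
        M, v, c = body.quad.M, body.quad.v, body.quad.c
        eigs = np.linalg.eigvalsh(M)
        if eigs[0] > 1e-12:
            x_c = np.linalg.solve(M, -v / 2.0)
            r2 = c + float(x_c @ M @ x_c)
            if r2 >= 0:
                bounds.append(math.sqrt(r2 / eigs[0]) + float(np.linalg.norm(x0 - x_c)))
    if not bounds:
        raise GeometryError("body is unbounded: no covering radius available")
    return min(bounds)


def multiphase_volume(
    body: InterPolyQuad,
    samples_per_phase: int = 2000,
    rng_seed=None,
    thin: int | None = None,
    chains: int = 64,
    r0_scale: float = 1.0,
    burn_in: int | None = None,
) -> VolumeEstimate:
    """Multiphase Monte Carlo volume of a polytope-and-quadric body.

    The body is whitened (quadratic -> centered ball) when the quadratic
    form is positive definite; phases are the nested bodies
    K_i = body intersect Ball(x0, r_i), r_i = r0 * 2^(i/S), anchored at the
    inscribed ball around an interior point x0 and capped at a covering
    radius.  Each ratio vol(K_i)/vol(K_{i+1}) is the fraction of Hit-and-Run
    samples of K_{i+1} landing in K_i; the product telescopes to the volume.
    ``r0_scale < 1`` starts the schedule below the inscribed radius, which
    keeps the estimator non-degenerate even when the body is itself a ball
    (used by the sphere validation).  A delta-method standard error is
    propagated across phases (sampler autocorrelation not included).
    """
    if samples_per_phase < 10:
        raise ValueError("samples_per_phase must be at least 10")
    rng = np.random.default_rng(rng_seed)
    work = body
    if body.quad is not None:
        eigmin = float(np.linalg.eigvalsh(body.quad.M)[0])
        if eigmin > 1e-12 * max(1.0, float(np.abs(body.quad.M).max())):
            work = standardize(body)
    log_jac = work.log_jacobian
    S = work.dim
    x0 = interior_point(work)
    if x0 is None:
        return VolumeEstimate(0.0, "multiphase_mc", standard_error=0.0,
                              sample_count=0, note="empty body")
    r0 = _inscribed_radius(work, x0)
    if r0 <= 0:
        return VolumeEstimate(0.0, "multiphase_mc", standard_error=0.0,
                              sample_count=0, note="zero inscribed radius")
    R = _covering_radius(work, x0)
    r_start = r0 * float(r0_scale)
    if R <= r_start * (1.0 + 1e-12):
        # the body coincides with its anchoring ball: the telescoping
        # product is empty and the result is the closed form
        value = ball_volume(S, min(r_start, R)) * math.exp(log_jac)
        return VolumeEstimate(value, "multiphase_mc", standard_error=0.0,
                              sample_count=0, note="body equals anchor ball")
    n_phases = max(1, math.ceil(S * math.log2(R / r_start)))
    radii = r_start * np.power(2.0, np.arange(n_phases + 1) / S)
    radii[-1] = R
    thin = 5 * S if thin is None else max(1, thin)
    burn_in = 10 * S if burn_in is None else burn_in
    log_vol = math.log(ball_volume(S, r_start))
    rel_var = 0.0
    total = 0
    for i in range(n_phases, 0, -1):
        ball = (np.eye(S), -2.0 * x0, radii[i] ** 2 - float(x0 @ x0))
        sampler = _SamplerBody.from_body(work, extra_quads=[ball])
        pts = _run_chains(sampler, x0, samples_per_phase, thin, rng,
                          chains, burn_in=burn_in)
        inside = np.linalg.norm(pts - x0[None, :], axis=1) <= radii[i - 1]
        f = float(np.mean(inside))
        total += samples_per_phase
        if f == 0.0:
            raise GeometryError(
                f"phase {i} ratio estimated as 0 with {samples_per_phase} samples; "
                "increase samples_per_phase"
            )
        log_vol -= math.log(f)
        rel_var += (1.0 - f) / (f * samples_per_phase)
    value = math.exp(log_vol + log_jac)
    se = value * math.sqrt(rel_var)
    return VolumeEstimate(value, "multiphase_mc", standard_error=se,
                          sample_count=total)


# ---------------------------------------------------------------------------
# Rejection oracle
# ---------------------------------------------------------------------------


class SimplexEnvelope:
    """The capture simplex {x >= 0, x.N0 <= Q} as a rejection envelope.

    Uniform sampling maps a Dirichlet(1,...,1) point of the standard simplex
    through x_i = Q w_i / N0_i.
    """

    def __init__(self, N0, Q: float):
        self.N0 = np.asarray(N0, float)
        self.Q = float(Q)
        S = self.N0.size
        self.volume = math.exp(S * math.log(self.Q) - math.lgamma(S + 1)
                               - float(np.sum(np.log(self.N0))))

    def sample(self, n: int, rng) -> np.ndarray:
        S = self.N0.size
        w = rng.dirichlet(np.ones(S + 1), size=n)[:, :S]
        return self.Q * w / self.N0[None, :]


class BoxEnvelope:
    """An axis-aligned box as a rejection envelope."""

    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, float)
        self.hi = np.asarray(hi, float)
        if np.any(self.hi <= self.lo):
            raise ValueError("box envelope must have hi > lo")
        self.volume = float(np.prod(self.hi - self.lo))

    def sample(self, n: int, rng) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * rng.random((n, self.lo.size))


def rejection_volume(body: InterPolyQuad, envelope, count: int,
                     rng_seed=None) -> VolumeEstimate:
    """Hit-fraction volume against an envelope of known exact volume.

    Validation oracle only — feasible in low dimension.  Zero hits return a
    zero estimate whose standard error is the one-sided binomial bound.
    """
    rng = np.random.default_rng(rng_seed)
    pts = envelope.sample(count, rng)
    hits = int(np.count_nonzero(body.contains(pts)))
    frac = hits / count
    value = frac * envelope.volume
    if hits == 0:
        se = envelope.volume * (3.0 / count)  # ~one-sided 95% bound
        return VolumeEstimate(0.0, "rejection", standard_error=se,
                              sample_count=count, note="zero hits")
    se = envelope.volume * math.sqrt(frac * (1.0 - frac) / count)
    return VolumeEstimate(value, "rejection", standard_error=se, sample_count=count)
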