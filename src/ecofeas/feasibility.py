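"""Feasibility probabilities, critical/optimal supply, and average diversity.

With the capture rates ``s`` uniform on the capture simplex, the
initialization and maturation probabilities of a candidate community are
volume ratios,

    P_I,M = vol(D_I,M) / vol(D_C),

computed exactly where possible (polytopes; quadratic cap provably inactive)
and by multiphase Monte Carlo otherwise.  For two populations a
deterministic slice-quadrature path removes Monte Carlo noise entirely.

The critical supply Q_c is the smallest total supply at which the
initialization domain becomes nonempty — the infimum of s.N0 over the
closed feasibility cone, a linear program over the equilibrium multipliers.
Q_opt is the supply maximizing the maturation probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.integrate import IntegrationWarning, quad as _quad_integrate
from scipy.optimize import linprog

from .geometry import (
    HPolytope,
    InterPolyQuad,
    QuadraticConstraint,
    initialization_domain,
    maturation_domain,
)
from .network import (
    CandidateCommunity,
    EnergeticNetwork,
    NetworkInputError,
    is_dissipative,
    support_columns,
)
from .volume import (
    multiphase_volume,
    polytope_vertices,
    simplex_volume,
    vertices_and_volume,
)

__all__ = [
    "EngineConfig",
    "ProbabilityPoint",
    "ProbabilityCurve",
    "EnergeticRegimeSummary",
    "DiversitySummary",
    "probability",
    "probability_curve",
    "critical_supply",
    "optimal_supply",
    "enumerate_communities",
    "average_diversity",
    "diversity_curve",
    "default_q_grid",
    "auto_q_grid",
]


@dataclass(frozen=True)
class EngineConfig:
    """Volume-engine settings shared by all probability computations.

    samples_per_phase : Hit-and-Run samples per multiphase ratio.
    thin              : steps between retained samples (default 5*S).
    chains            : parallel walkers inside the sampler.
    seed              : base seed; per-(Q, community) streams are spawned
                        deterministically from it.
    use_quadrature_2d : evaluate S=2 maturation probabilities by exact
                        slice integration instead of Monte Carlo.
    floor_rel         : volumes below floor_rel * vol(D_C) are reported as 0
                        (noise floor for the curve analyses).
    """

    samples_per_phase: int = 2000
    thin: int | None = None
    chains: int = 64
    seed: int | None = None
    use_quadrature_2d: bool = True
    floor_rel: float = 1e-12

    def rng_for(self, Q: float, community: CandidateCommunity | None) -> np.random.Generator:
        if self.seed is None:
            return np.random.default_rng()
        mask = 0 if community is None else sum(1 << i for i in community.members)
        q_key = int(np.float64(Q).view(np.uint64)) & 0xFFFFFFFF
        ss = np.random.SeedSequence([int(self.seed), mask, q_key])
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class ProbabilityPoint:
    Q: float
    community: CandidateCommunity | None
    p_init: float
    p_mat: float
    p_init_se: float = 0.0
    p_mat_se: float = 0.0
    init_method: str = "exact"
    mat_method: str = "exact"


@dataclass(frozen=True)
class ProbabilityCurve:
    """P_I(Q) and P_M(Q) on a strictly increasing Q grid."""

    Q: np.ndarray
    p_init: np.ndarray
    p_mat: np.ndarray
    p_init_se: np.ndarray
    p_mat_se: np.ndarray
    community: CandidateCommunity | None = None
    network_id: str = ""

    def __post_init__(self):
        Q = np.asarray(self.Q, float)
        if np.any(np.diff(Q) <= 0):
            raise NetworkInputError("Q grid must be strictly increasing")
        object.__setattr__(self, "Q", Q)
        for name in ("p_init", "p_mat", "p_init_se", "p_mat_se"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "Q": self.Q,
                "community": str(self.community) if self.community else "full",
                "D": -1 if self.community is None else self.community.size,
                "p_init": self.p_init,
                "p_init_se": self.p_init_se,
                "p_mat": self.p_mat,
                "p_mat_se": self.p_mat_se,
            }
        )


@dataclass(frozen=True)
class EnergeticRegimeSummary:
    """Critical and optimal supply for one (network, community) pair."""

    Q_c: float
    Q_opt: float
    p_mat_at_opt: float
    defined: bool = True


def default_q_grid(n: int = 500, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    """Logarithmically spaced supply grid, by default 500 points on [1, 100]."""
    return np.geomspace(lo, hi, n)


def auto_q_grid(net: EnergeticNetwork, n: int = 200,
                community: CandidateCommunity | None = None) -> np.ndarray:
    """Network-adapted grid [0.5 Q_c, 50 d.N0] covering the qualitative
    regimes (sub-critical, rise, decay) of the probability curves."""
    qc = critical_supply(net, community)
    hi = 50.0 * max(net.maintenance_supply(), 1e-6)
    lo = 0.5 * qc if math.isfinite(qc) and qc > 0 else 0.01 * hi
    if lo >= hi:
        lo = hi / 100.0
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------


def _interval_intersect_length(intervals) -> float:
    lo = max(i[0] for i in intervals)
    hi = min(i[1] for i in intervals)
    return max(0.0, hi - lo)


def _slice_measure_2d(x: float, poly: HPolytope, quad: QuadraticConstraint | None) -> float:
    """Length of {y : (x, y) in body}; constraints linear or quadratic in y."""
    lo, hi = -np.inf, np.inf
    for a, b in zip(poly.A, poly.b):
        if abs(a[1]) > 1e-14:
            t = (b - a[0] * x) / a[1]
            if a[1] > 0:
                hi = min(hi, t)
            else:
                lo = max(lo, t)
        elif a[0] * x > b + 1e-12:
            return 0.0
    if hi <= lo:
        return 0.0
    if quad is None:
        return hi - lo
    M, v, c = quad.M, quad.v, quad.c
    alpha = M[1, 1]
    beta = 2.0 * M[0, 1] * x + v[1]
    gamma = M[0, 0] * x * x + v[0] * x - c
    if abs(alpha) < 1e-14:
        if abs(beta) < 1e-14:
            return (hi - lo) if gamma <= 0 else 0.0
        t = -gamma / beta
        return _interval_intersect_length([(lo, hi), (-np.inf, t) if beta > 0 else (t, np.inf)])
    disc = beta * beta - 4.0 * alpha * gamma
    if disc <= 0:
        return 0.0 if alpha > 0 else hi - lo
    sq = math.sqrt(disc)
    r1, r2 = sorted(((-beta - sq) / (2 * alpha), (-beta + sq) / (2 * alpha)))
    if alpha > 0:
        return _interval_intersect_length([(lo, hi), (r1, r2)])
    # downward parabola: feasible outside (r1, r2)
    return _interval_intersect_length([(lo, hi), (-np.inf, r1)]) + \
        _interval_intersect_length([(lo, hi), (r2, np.inf)])


def _area_2d(body: InterPolyQuad) -> float:
    """Exact-up-to-quadrature area of a 2-D InterPolyQuad: the y-slice
    measure (computed in closed form per x) integrated adaptively over x."""
    verts = polytope_vertices(body.poly)
    if len(verts) == 0:
        return 0.0
    xs = np.unique(verts[:, 0])
    x_lo, x_hi = float(xs[0]), float(xs[-1])
    if x_hi - x_lo <= 0:
        return 0.0
    breaks = [float(x) for x in xs[1:-1]]
    with warnings.catch_warnings():
        # the slice measure is piecewise smooth with kinks at cone and
        # vertex abscissae; roundoff warnings there are expected and benign
        warnings.simplefilter("ignore", IntegrationWarning)
        val, _ = _quad_integrate(
            lambda x: _slice_measure_2d(x, body.poly, body.quad),
            x_lo, x_hi, points=breaks or None, limit=200,
        )
    return max(val, 0.0)


def _quad_inactive(body: InterPolyQuad, vertices: np.ndarray) -> bool:
    """True when the quadratic cap is provably inactive over the polytope:
    for a convex (PSD) form its maximum is attained at a vertex."""
    if body.quad is None:
        return True
    if len(vertices) == 0:
        return True
    eigmin = float(np.linalg.eigvalsh(body.quad.M)[0])
    if eigmin < -1e-10 * max(1.0, float(np.abs(body.quad.M).max())):
        return False  # indefinite form: vertex max is not a certificate
    return bool(np.max(body.quad.value(vertices)) <= body.quad.c + 1e-12)


def probability(
    net: EnergeticNetwork,
    Q: float,
    community: CandidateCommunity | None = None,
    config: EngineConfig | None = None,
) -> ProbabilityPoint:
    """Initialization and maturation probabilities at one supply level.

    P_I is always exact (polytope volume over simplex volume).  P_M is exact
    when the steady-state cap is inactive over the initialization polytope
    (vertex certificate) or when S=2 with the quadrature path enabled;
    otherwise it is a multiphase Monte Carlo estimate with standard error.
    """
    if not is_dissipative(net):
        raise NetworkInputError("probabilities require a dissipative network")
    config = config or EngineConfig()
    vol_C = simplex_volume(net, Q).value
    poly = initialization_domain(net, Q, community)
    verts, vol_I = vertices_and_volume(poly)
    p_init = vol_I / vol_C
    if p_init < config.floor_rel:
        p_init = 0.0
    if p_init == 0.0:
        return ProbabilityPoint(Q, community, 0.0, 0.0,
                                init_method="exact", mat_method="exact")
    body = maturation_domain(net, Q, community)
    if _quad_inactive(body, verts):
        return ProbabilityPoint(Q, community, p_init, p_init,
                                init_method="exact", mat_method="exact")
    if net.S == 2 and config.use_quadrature_2d:
        p_mat = _area_2d(body) / vol_C
        p_mat = 0.0 if p_mat < config.floor_rel else min(p_mat, p_init)
        return ProbabilityPoint(Q, community, p_init, p_mat,
                                init_method="exact", mat_method="quadrature")
    rng = config.rng_for(Q, community)
    est = multiphase_volume(
        body,
        samples_per_phase=config.samples_per_phase,
        rng_seed=rng,
        thin=config.thin,
        chains=config.chains,
    )
    p_mat = est.value / vol_C
    p_mat_se = (est.standard_error or 0.0) / vol_C
    if p_mat < config.floor_rel:
        p_mat = 0.0
    return ProbabilityPoint(Q, community, p_init, p_mat,
                            p_mat_se=p_mat_se,
                            init_method="exact", mat_method=est.method)


def probability_curve(
    net: EnergeticNetwork,
    Q_grid,
    community: CandidateCommunity | None = None,
    config: EngineConfig | None = None,
    network_id: str = "",
) -> ProbabilityCurve:
    """Evaluate :func:`probability` over a supply grid."""
    Q_grid = np.asarray(Q_grid, float)
    pts = [probability(net, float(Q), community, config) for Q in Q_grid]
    return ProbabilityCurve(
        Q=Q_grid,
        p_init=np.array([p.p_init for p in pts]),
        p_mat=np.array([p.p_mat for p in pts]),
        p_init_se=np.array([p.p_init_se for p in pts]),
        p_mat_se=np.array([p.p_mat_se for p in pts]),
        community=community,
        network_id=network_id,
    )


# ---------------------------------------------------------------------------
# critical and optimal supply
# ---------------------------------------------------------------------------


def critical_supply(net: EnergeticNetwork,
                    community: CandidateCommunity | None = None) -> float:
    """Infimum of s.N0 over the closed feasibility cone intersected with
    s >= 0 — the supply below which the initialization domain is empty.

    Linear program over the equilibrium multipliers n >= 0 with
    s = d + B n >= 0; always bounded below by 0 since N0 > 0.  Returns
    +inf when the cone misses the nonnegative orthant.  Satisfies
    Q_c <= d.N0 (n = 0 is feasible whenever d >= 0).
    """
    community = CandidateCommunity.full(net.S) if community is None else community
    B = support_columns(net, community)
    c = B.T @ net.N0
    res = linprog(c, A_ub=-B, b_ub=net.d, bounds=[(0, None)] * net.S, method="highs")
    if res.status == 2:
        return math.inf
    if not res.success:
        raise RuntimeError(f"critical-supply LP failed: {res.message}")
    return float(net.d @ net.N0 + res.fun)


def optimal_supply(
    curve: ProbabilityCurve,
    Q_c: float | None = None,
    evaluator=None,
    refine: bool = False,
) -> EnergeticRegimeSummary:
    """Locate Q_opt, the supply maximizing the maturation probability.

    Grid argmax over the curve, optionally refined by golden-section search
    on ``evaluator(Q) -> p_mat`` within the bracketing grid cells (useful
    with the deterministic quadrature path, where re-evaluation is noiseless).
    """
    if len(curve.Q) < 3:
        raise NetworkInputError("optimal_supply needs at least 3 grid points")
    if not np.any(curve.p_mat > 0):
        return EnergeticRegimeSummary(Q_c if Q_c is not None else math.nan,
                                      math.nan, 0.0, defined=False)
    k = int(np.argmax(curve.p_mat))
    Q_opt, p_opt = float(curve.Q[k]), float(curve.p_mat[k])
    if refine and evaluator is not None and 0 < k < len(curve.Q) - 1:
        a, b = math.log(curve.Q[k - 1]), math.log(curve.Q[k + 1])
        phi = (math.sqrt(5.0) - 1.0) / 2.0
        x1, x2 = b - phi * (b - a), a + phi * (b - a)
        f1, f2 = evaluator(math.exp(x1)), evaluator(math.exp(x2))
        for _ in range(40):
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + phi * (b - a)
                f2 = evaluator(math.exp(x2))
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - phi * (b - a)
                f1 = evaluator(math.exp(x1))
            if b - a < 1e-6:
                break
        x_best = 0.5 * (a + b)
        Q_ref = math.exp(x_best)
        p_ref = evaluator(Q_ref)
        if p_ref >= p_opt:
            Q_opt, p_opt = Q_ref, p_ref
    return EnergeticRegimeSummary(Q_c if Q_c is not None else math.nan,
                                  Q_opt, p_opt, defined=True)


# ---------------------------------------------------------------------------
# communities and diversity
# ---------------------------------------------------------------------------


def enumerate_communities(S: int, include_empty: bool = True):
    """All 2^S candidate communities, size-major then lexicographic."""
    if not 1 <= S <= 12:
        raise NetworkInputError("community enumeration is limited to 1 <= S <= 12")
    out = []
    for D in range(0 if include_empty else 1, S + 1):
        out.extend(CandidateCommunity(c) for c in combinations(range(S), D))
    return out


@dataclass(frozen=True)
class DiversitySummary:
    """Expected community size at one supply level.

    ``D_mean`` weights each size class D by its community count binom(S, D)
    times the mean maturation probability of that class, normalized by the
    total weight over nonempty communities; ``weighted_sum`` is the
    unnormalized variant sum_C |C| p_mat(C).
    """

    Q: float
    D_mean: float
    weighted_sum: float
    sizes: np.ndarray
    mean_p_mat_by_size: np.ndarray
    defined: bool = True


def average_diversity(
    net: EnergeticNetwork,
    Q: float,
    config: EngineConfig | None = None,
    normalized: bool = True,
) -> DiversitySummary:
    """Average diversity <D>: expected community size across all nonempty
    candidate communities, weighted by count and maturation probability."""
    S = net.S
    if S > 8:
        raise NetworkInputError("average_diversity budget guard: S <= 8")
    communities = enumerate_communities(S, include_empty=False)
    sizes = np.arange(1, S + 1)
    sums = np.zeros(S + 1)
    counts = np.zeros(S + 1)
    total_w = 0.0
    total_wd = 0.0
    for comm in communities:
        p = probability(net, Q, comm, config).p_mat
        sums[comm.size] += p
        counts[comm.size] += 1
        total_w += p
        total_wd += comm.size * p
    mean_by_size = np.divide(sums[1:], counts[1:], out=np.zeros(S), where=counts[1:] > 0)
    if total_w <= 0:
        return DiversitySummary(Q, math.nan, 0.0, sizes, mean_by_size, defined=False)
    D_mean = total_wd / total_w if normalized else total_wd
    return DiversitySummary(Q, D_mean, total_wd, sizes, mean_by_size)


def diversity_curve(net: EnergeticNetwork, Q_grid,
                    config: EngineConfig | None = None,
                    normalized: bool = True):
    """<D>(Q) over a supply grid; NaN where every p_mat is zero."""
    Q_grid = np.asarray(Q_grid, float)
    vals = [average_diversity(net, float(Q), config, normalized) for Q in Q_grid]
    return Q_grid, np.array([v.D_mean for v in vals]), vals
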