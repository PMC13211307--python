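"""Energetic Lotka-Volterra networks and their equilibria.

A network of ``S`` populations accumulates biomass according to

    mu_i dN_i/dt = N_i (s_i - d_i - sum_j sigma_ij N_j),

where ``s_i >= 0`` is the mass-specific energy capture rate, ``d_i`` the
maintenance demand, and ``sigma`` the energy-exchange matrix (positive
diagonal = self-limitation).  After rescaling time by the energy densities
``mu`` this is a generalized Lotka-Volterra system with growth vector
``s - d`` and interaction matrix ``sigma``, so feasibility questions reduce
to the geometry of ``s``-space.  This module holds the network container,
dissipativity checks, full and boundary equilibria, and the classification
of a capture vector ``s`` into the unique candidate community it supports.

Indices are 0-based throughout the Python API; file I/O and the CLI report
1-based population indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np

__all__ = [
    "EnergeticNetwork",
    "CandidateCommunity",
    "SteadyStateOptions",
    "NetworkInputError",
    "SingularSystemError",
    "DegenerateSupportError",
    "BoundaryTieError",
    "is_dissipative",
    "full_steady_state",
    "boundary_equilibrium",
    "classify_support",
]

#: relative tolerance for "strictly positive" equilibrium multipliers
MULTIPLIER_RTOL = 1e-9


class NetworkInputError(ValueError):
    """Invalid network parameters (shape, sign or finiteness violation)."""


class SingularSystemError(np.linalg.LinAlgError):
    """A linear system required by an equilibrium is numerically singular."""


class DegenerateSupportError(SingularSystemError):
    """The column system of a boundary equilibrium is singular."""


class BoundaryTieError(RuntimeError):
    """No candidate community has strictly positive multipliers: the capture
    vector lies (numerically) on a partition boundary."""


def _as_vector(x, S: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (S,):
        raise NetworkInputError(f"{name} must have length {S}, got shape {np.shape(x)}")
    if not np.all(np.isfinite(v)):
        raise NetworkInputError(f"{name} contains non-finite entries")
    return v


@dataclass(frozen=True)
class EnergeticNetwork:
    """The triple (sigma, d, N0) plus optional energy densities mu.

    Parameters
    ----------
    sigma : (S, S) array
        Energy-exchange matrix, units power * mass^-2.  Diagonal entries must
        be strictly positive (self-limitation).
    d : (S,) array
        Maintenance demands, power * mass^-1, nonnegative.
    N0 : (S,) array
        Minimal biomasses at initialization, mass, strictly positive.
    mu : (S,) array, optional
        Energy densities, energy * mass^-1, strictly positive.  Stored for
        forward-simulation completeness; every feasibility computation is
        invariant to ``mu`` (it only rescales time), so it defaults to ones.
    metadata : dict
        Free-form provenance (seeds, labels); not used in computations.
    """

    sigma: np.ndarray
    d: np.ndarray
    N0: np.ndarray
    mu: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise NetworkInputError(f"sigma must be square, got shape {sigma.shape}")
        if not np.all(np.isfinite(sigma)):
            raise NetworkInputError("sigma contains non-finite entries")
        S = sigma.shape[0]
        d = _as_vector(self.d, S, "d")
        N0 = _as_vector(self.N0, S, "N0")
        mu = np.ones(S) if self.mu is None else _as_vector(self.mu, S, "mu")
        if np.any(np.diag(sigma) <= 0):
            i = int(np.argmin(np.diag(sigma)))
            raise NetworkInputError(f"diagonal sigma[{i},{i}] = {sigma[i, i]} must be > 0")
        if np.any(d < 0):
            raise NetworkInputError("all demands d_i must be >= 0")
        if np.any(N0 <= 0):
            raise NetworkInputError("all minimal biomasses N0_i must be > 0")
        if np.any(mu <= 0):
            raise NetworkInputError("all energy densities mu_i must be > 0")
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "N0", N0)
        object.__setattr__(self, "mu", mu)

    @property
    def S(self) -> int:
        """Number of populations."""
        return self.sigma.shape[0]

    def maintenance_supply(self) -> float:
        """Total supply needed to pay every maintenance demand at minimal
        biomass, ``d^T N0`` — an upper bound for the critical supply Q_c."""
        return float(self.d @ self.N0)


@dataclass(frozen=True)
class CandidateCommunity:
    """A subset of population indices: the support of a boundary equilibrium."""

    members: tuple[int, ...]

    def __post_init__(self):
        members = tuple(sorted(set(int(i) for i in self.members)))
        if members and members[0] < 0:
            raise NetworkInputError(f"negative population index {members[0]}")
        object.__setattr__(self, "members", members)

    @classmethod
    def full(cls, S: int) -> "CandidateCommunity":
        return cls(tuple(range(S)))

    @classmethod
    def empty(cls) -> "CandidateCommunity":
        return cls(())

    @property
    def size(self) -> int:
        return len(self.members)

    def mask(self, S: int) -> np.ndarray:
        m = np.zeros(S, dtype=bool)
        m[list(self.members)] = True
        return m

    def validate(self, S: int) -> None:
        if self.members and self.members[-1] >= S:
            raise NetworkInputError(
                f"community member {self.members[-1]} out of range for S={S}"
            )

    def __str__(self) -> str:  # 1-based for display
        return "{" + ",".join(str(i + 1) for i in self.members) + "}"


@dataclass(frozen=True)
class SteadyStateOptions:
    """Biomass thresholds eps_i >= 0 for the feasibility condition
    ``N*_i > eps_i`` (default zero, the strict-positivity condition).

    Nonzero thresholds shift the cone constraints of the initialization
    polytope; they are honoured by the geometry builders but the default
    everywhere is zero.
    """

    epsilon: np.ndarray | float = 0.0

    def thresholds(self, S: int) -> np.ndarray:
        eps = np.asarray(self.epsilon, dtype=float)
        eps = np.full(S, float(eps)) if eps.ndim == 0 else eps.reshape(-1)
        if eps.shape != (S,):
            raise NetworkInputError(f"epsilon must be scalar or length {S}")
        if np.any(eps < 0):
            raise NetworkInputError("thresholds epsilon_i must be >= 0")
        return eps


def is_dissipative(net: EnergeticNetwork | np.ndarray, tolerance: float = 1e-10) -> bool:
    """True iff the symmetric part (sigma + sigma^T)/2 is positive definite.

    Volterra dissipativity guarantees a unique, globally stable equilibrium
    for every capture vector, which is what makes the feasibility partition
    of ``s``-space well defined.
    """
    sigma = net.sigma if isinstance(net, EnergeticNetwork) else np.asarray(net, float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise NetworkInputError(f"sigma must be square, got shape {sigma.shape}")
    if not np.all(np.isfinite(sigma)):
        raise NetworkInputError("sigma contains non-finite entries")
    sym = (sigma + sigma.T) / 2.0
    return bool(np.linalg.eigvalsh(sym)[0] > tolerance)


def _solve_checked(A: np.ndarray, rhs: np.ndarray, err: type) -> np.ndarray:
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise err(f"linear system is numerically singular (condition number {cond:.3e})")
    return np.linalg.solve(A, rhs)


def full_steady_state(net: EnergeticNetwork, s) -> np.ndarray:
    """Solve ``sigma N* = s - d`` for the full-coexistence equilibrium.

    No positivity is imposed; the sign pattern of the result is what the
    feasibility domains are about.
    """
    s = _as_vector(s, net.S, "s")
    return _solve_checked(net.sigma, s - net.d, SingularSystemError)


def support_columns(net: EnergeticNetwork, community: CandidateCommunity) -> np.ndarray:
    """Column system of the boundary-equilibrium decomposition
    ``s - d = B n``: column i is sigma_i for members and -e_i for
    non-members (the slack of population i's invasion condition)."""
    community.validate(net.S)
    B = -np.eye(net.S)
    for i in community.members:
        B[:, i] = net.sigma[:, i]
    return B


def boundary_equilibrium(
    net: EnergeticNetwork, community: CandidateCommunity, s
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary equilibrium supported on ``community``.

    Decomposes ``s = d + sum_{i in C} n_i sigma_i - sum_{i not in C} n_i e_i``
    and returns ``(N_star, n)`` where ``N_star_i = n_i`` for members and 0
    otherwise.  For non-members ``n_i`` is the slack of the invasion
    condition; the equilibrium is admissible iff all ``n_i > 0``.
    """
    s = _as_vector(s, net.S, "s")
    B = support_columns(net, community)
    n = _solve_checked(B, s - net.d, DegenerateSupportError)
    N_star = np.zeros(net.S)
    members = list(community.members)
    N_star[members] = n[members]
    return N_star, n


def _supports_by_cardinality(S: int) -> Iterable[tuple[int, ...]]:
    for k in range(S, -1, -1):
        yield from combinations(range(S), k)


def classify_support(
    net: EnergeticNetwork, s, tolerance: float = MULTIPLIER_RTOL
) -> CandidateCommunity:
    """The unique candidate community whose boundary equilibrium has all
    strictly positive multipliers at capture vector ``s``.

    Dissipativity makes this a linear complementarity problem with a unique
    solution; it is solved by enumerating supports in order of decreasing
    cardinality (cheap for S <= 12) with early exit.  Capture vectors on a
    partition boundary (some multiplier numerically zero) raise
    :class:`BoundaryTieError` rather than guessing.
    """
    s = _as_vector(s, net.S, "s")
    if net.S > 12:
        raise NetworkInputError("support enumeration is limited to S <= 12")
    best_tie = None
    for support in _supports_by_cardinality(net.S):
        community = CandidateCommunity(support)
        try:
            _, n = boundary_equilibrium(net, community, s)
        except DegenerateSupportError:
            continue
        scale = max(np.max(np.abs(n)), 1.0)
        if np.all(n > tolerance * scale):
            return community
        if np.all(n > -tolerance * scale):
            i = int(np.argmin(n))
            best_tie = (community, i, float(n[i]))
    if best_tie is not None:
        community, i, ni = best_tie
        raise BoundaryTieError(
            f"capture vector lies on a partition boundary: support {community} "
            f"has near-zero multiplier n[{i}] = {ni:.3e}"
        )
    raise BoundaryTieError(
        "no candidate community has all-positive multipliers within tolerance"
    )
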