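"""Constrained random ensembles of energetic networks.

Interaction matrices follow a four-step construction: (1) sample every
element from Normal(0, 1); (2) enforce energy-transfer efficiency <= 1 by
swapping absolute values of any opposite-sign pair (sigma_ij < 0 < sigma_ji)
whose gain exceeds its loss; (3) shift the diagonal so the minimum
eigenvalue of the symmetric part equals the dissipativity floor sigma_0;
(4) scale the whole matrix by s_sigma.  Demands and minimal biomasses are
normal draws centered at d_0 and N_0, resampled until positive.

Reference hyperparameters: s_sigma = 1.0, sigma_0 = 0.5, N_0 = 1.0,
d_0 = 1.0; ensembles of 100 networks at S = 8, down-sampled to smaller S by
taking leading principal submatrices (re-flooring the diagonal shift so the
analyzed submatrix is again dissipative at sigma_0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import EnergeticNetwork, NetworkInputError

__all__ = ["GeneratorConfig", "generate_network", "generate_ensemble", "downsample_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters of the constrained random-network generator.

    ``rel_sd`` is the standard deviation of the d and N0 draws relative to
    their centers (the positivity mechanism is resampling; with the default
    0.25 truncation is mild).
    """

    S: int = 8
    s_sigma: float = 1.0
    sigma_0: float = 0.5
    N_0: float = 1.0
    d_0: float = 1.0
    connectance: float = 1.0
    rel_sd: float = 0.25
    replicates: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.S < 1:
            raise NetworkInputError("S must be >= 1")
        if self.sigma_0 <= 0:
            raise NetworkInputError("sigma_0 must be > 0")
        if self.N_0 <= 0 or self.d_0 <= 0:
            raise NetworkInputError("N_0 and d_0 must be > 0")
        if not 0 < self.connectance <= 1:
            raise NetworkInputError("connectance must be in (0, 1]")


def _positive_normal(center: float, sd: float, size: int, rng) -> np.ndarray:
    """Normal(center, sd) draws resampled until strictly positive."""
    out = rng.normal(center, sd, size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(center, sd, int(bad.sum()))
    raise RuntimeError("positivity resampling did not converge")


def apply_efficiency_rule(sigma: np.ndarray) -> np.ndarray:
    """Swap absolute values of opposite-sign pairs so |sigma_ij| <= |sigma_ji|
    whenever sigma_ij < 0 < sigma_ji (a population cannot gain more energy
    than its partner loses)."""
    sigma = sigma.copy()
    S = sigma.shape[0]
    for i in range(S):
        for j in range(i + 1, S):
            a, b = sigma[i, j], sigma[j, i]
            if a < 0 < b and -a > b:
                sigma[i, j], sigma[j, i] = -b, -a
            elif b < 0 < a and -b > a:
                sigma[j, i], sigma[i, j] = -a, -b
    return sigma


def floor_dissipativity(sigma: np.ndarray, sigma_0: float) -> np.ndarray:
    """Shift the diagonal so the minimum eigenvalue of the symmetric part is
    exactly sigma_0."""
    sym = (sigma + sigma.T) / 2.0
    lam_min = float(np.linalg.eigvalsh(sym)[0])
    return sigma + (sigma_0 - lam_min) * np.eye(sigma.shape[0])


def generate_network(config: GeneratorConfig, rng: np.random.Generator) -> EnergeticNetwork:
    """One constrained random network: sample -> (mask) -> efficiency ->
    dissipativity floor -> scale; then positive d and N0 draws.

    The step order is normative: flooring before scaling makes the
    symmetric-part minimum eigenvalue exactly sigma_0 * s_sigma.
    """
    S = config.S
    sigma = rng.standard_normal((S, S))
    if config.connectance < 1.0:
        # symmetric-pair masking keeps the opposite-sign pair semantics intact
        keep = rng.random((S, S)) < config.connectance
        keep = np.triu(keep, 1)
        mask = keep | keep.T | np.eye(S, dtype=bool)
        sigma = np.where(mask, sigma, 0.0)
    sigma = apply_efficiency_rule(sigma)
    sigma = floor_dissipativity(sigma, config.sigma_0)
    sigma = config.s_sigma * sigma
    d = _positive_normal(config.d_0, config.rel_sd * config.d_0, S, rng)
    N0 = _positive_normal(config.N_0, config.rel_sd * config.N_0, S, rng)
    return EnergeticNetwork(sigma, d, N0)


def downsample_network(net: EnergeticNetwork, S_target: int,
                       sigma_0: float | None = None) -> EnergeticNetwork:
    """Leading principal submatrix of sigma with the leading entries of d
    and N0.  If ``sigma_0`` is given and the submatrix's symmetric-part
    minimum eigenvalue fell below it, the diagonal floor is re-applied so
    the analyzed network is dissipative again."""
    if not 1 <= S_target <= net.S:
        raise NetworkInputError(f"cannot down-sample S={net.S} to {S_target}")
    sigma = net.sigma[:S_target, :S_target].copy()
    if sigma_0 is not None:
        lam_min = float(np.linalg.eigvalsh((sigma + sigma.T) / 2.0)[0])
        if lam_min < sigma_0:
            sigma = floor_dissipativity(sigma, sigma_0)
    meta = dict(net.metadata)
    meta["downsampled_from"] = net.S
    return EnergeticNetwork(sigma, net.d[:S_target], net.N0[:S_target],
                            net.mu[:S_target], metadata=meta)


def generate_ensemble(config: GeneratorConfig):
    """Replicate networks from independent child seeds, plus a manifest
    sufficient for bit-exact regeneration."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates)
    nets = []
    child_states = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        net = generate_network(config, rng)
        net = replace(net, metadata={"replicate": k, "seed_entropy": child.entropy,
                                     "spawn_key": child.spawn_key})
        nets.append(net)
        child_states.append({"replicate": k, "spawn_key": list(child.spawn_key)})
    manifest = {
        "generator": {
            "S": config.S, "s_sigma": config.s_sigma, "sigma_0": config.sigma_0,
            "N_0": config.N_0, "d_0": config.d_0, "connectance": config.connectance,
            "rel_sd": config.rel_sd, "replicates": config.replicates,
            "seed": config.seed,
        },
        "children": child_states,
    }
    return nets, manifest
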