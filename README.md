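# ecofeas

Energetic feasibility analysis of ecological networks: how much external
energy supply a community needs to assemble, and how much is too much.

## The problem

For a network of `S` populations with energy-based Lotka–Volterra dynamics

    mu_i dN_i/dt = N_i ( s_i - d_i - sum_j sigma_ij N_j ),

the question is which energy-capture configurations `s` a total supply `Q`
admits, and with what probability a random configuration lets the
community start growing (*initialization*) and persist at steady state
within the supply limit (*maturation*). `ecofeas` builds the three nested
feasibility domains in `s`-space —

* the capture simplex `D_C = { s >= 0, s.N0 <= Q }`,
* the initialization polytope `D_I = { s in D_C : N*(s) > 0 }`,
* the maturation body `D_M = { s in D_I : s.N*(s) <= Q }`,

— and computes the feasibility probabilities as volume ratios
`P_I,M = vol(D_I,M)/vol(D_C)`: exactly for polytopes (vertex enumeration),
by deterministic quadrature for `S = 2`, and by Hit-and-Run + multiphase
Monte Carlo for quadratic-capped bodies in higher dimension. On top of
that it derives the critical supply `Q_c` (below which nothing is
feasible), the optimal supply `Q_opt` (where maturation is most likely),
feasibility partitions over all `2^S` candidate subcommunities, average
diversity curves `<D>(Q)`, constrained random-network ensembles, and
logit-space functional data analysis of replicate curves. It is written
for theoretical ecologists and anyone studying feasibility/structural
stability of interaction networks under system-level resource constraints.

## Worked example

The packaged two-population network (`d = (1.20, 1.80)`,
`sigma = ((1.45, 1.77), (0.45, 1.98))`, `N0 = (1.00, 1.20)`):

```python
import numpy as np
import ecofeas as ef

net = ef.example_two_population_network()
print(ef.is_dissipative(net))          # True
print(ef.critical_supply(net))         # 3.36  (= d.N0; displays as 3.4)

curve = ef.probability_curve(net, np.geomspace(3, 30, 60))
s = ef.optimal_supply(curve, Q_c=3.36,
                      evaluator=lambda Q: ef.probability(net, Q).p_mat,
                      refine=True)
print(round(s.Q_opt, 1), round(s.p_mat_at_opt, 3))   # 9.9 0.106

p7, p15 = ef.probability(net, 7.0), ef.probability(net, 15.0)
print(round(p7.p_init, 3), round(p7.p_mat, 3))       # 0.082 0.082
print(round(p15.p_init, 3), round(p15.p_mat, 3))     # 0.182 0.081
```

Reading: below `Q_c = 3.36` both probabilities are zero — the supply
cannot cover maintenance at minimal biomass. Raising the supply from
`Q = 7` to `Q = 15` makes initialization more likely (0.082 → 0.182) but
maturation slightly *less* likely (0.0816 → 0.0813): the steady-state
energy cap tightens as biomass grows with supply. Maturation probability
peaks at `Q_opt ≈ 9.9` (10 to two significant figures) — a bounded
energetic window rather than "more energy is always better".

The same analyses run from the shell:

```sh
ecofeas single --out runs/example              # curves + Q_c, Q_opt
ecofeas ensemble -S 2 -S 4 --replicates 20 --out runs/ens
ecofeas partitions --size 6 --out runs/parts   # all 63 subcommunities
ecofeas validate-volume --out runs/spheres     # sampler benchmark
```

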