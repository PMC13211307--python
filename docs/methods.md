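# Methods

## The energetic model

`ecofeas` analyzes networks of `S` interacting populations whose biomass
dynamics follow an energy balance,

    mu_i dN_i/dt = N_i ( s_i - d_i - sum_j sigma_ij N_j ),

with mass-specific capture rates `s_i >= 0` (power/mass), maintenance
demands `d_i >= 0` (power/mass), an energy-exchange matrix `sigma`
(power/mass^2, positive diagonal = self-limitation, off-diagonals = energy
removal/addition between populations), and energy densities `mu_i > 0`
(energy/mass). Rescaling time by `mu` turns this into a generalized
Lotka–Volterra system with growth vector `s - d` and interaction matrix
`sigma`; `mu` therefore never enters any feasibility computation and is
stored only for completeness.

Throughout, `sigma` is assumed **Volterra dissipative** — the symmetric
part `(sigma + sigma^T)/2` is positive definite — which guarantees a
unique, globally stable equilibrium for every `s` and makes coexistence
equivalent to feasibility (positivity of the equilibrium).

## Feasibility domains

A total energy supply `Q` (power) bounds what the environment can provide.
Three nested convex bodies in `s`-space encode progressively stronger
requirements on a community:

* **capture domain** `D_C = { s >= 0, s.N0 <= Q }` — the simplex of supply
  allocations at the minimal biomasses `N0 > 0` (mass);
* **initialization domain** `D_I = { s in D_C : N*(s) > 0 }` — additionally
  requires positive equilibrium biomass; a convex polytope;
* **maturation domain** `D_M = { s in D_I : s.N*(s) <= Q }` — additionally
  requires the steady-state energy capture to stay within the supply; the
  cap is quadratic in `s`, and dissipativity makes `D_M` convex (a
  polytope intersected with an ellipsoidal constraint — an
  "InterPolyQuad").

For a candidate community `C` (any subset of populations) the same
construction runs through the boundary-equilibrium decomposition
`s = d + sum_{i in C} n_i sigma_i - sum_{i not in C} n_i e_i`: the
feasibility cell of `C` is where all multipliers `n_i` are positive
(members' multipliers are their biomasses, non-members' are invasion
slacks). Across all `2^S` communities these cells tile `s`-space, which
the package verifies exactly (the cells' initialization probabilities sum
to 1). Strict inequalities are stored as closed rows for volume purposes
(boundaries have measure zero); a strictness flag is kept for membership
tests with absolute tolerance `1e-12`.

Nonzero biomass thresholds `eps_i` (condition `N*_i > eps_i`) shift the
cone rows of `D_I`; the default is `eps = 0` and nothing else in the
pipeline depends on `eps`, so nonzero thresholds are supported but not
propagated into any reported result.

## Probabilities

Treating `s` as uniform on `D_C`, the probabilities of initialization and
maturation are volume ratios,

    P_I,M = vol(D_I,M) / vol(D_C).

`vol(D_C) = Q^S / (S! prod_i N0_i)` in closed form (evaluated in log
space). `vol(D_I)` is always computed exactly: vertex enumeration from the
H-representation (Qhull half-space intersection seeded with the Chebyshev
center) and convex-hull triangulation. `vol(D_M)` is exact whenever the
quadratic cap is provably inactive — for a convex (PSD) form its maximum
over the polytope is attained at a vertex, so a vertex sweep certifies
`D_M = D_I`, which removes all Monte Carlo noise in the low-`Q` regime.
Otherwise:

* `S = 2`: deterministic slice quadrature. The measure of each `y`-slice of
  the body is available in closed form (interval intersections of linear
  and quadratic constraints), and its integral over `x` is computed by
  adaptive quadrature with breakpoints at vertex abscissae. This is the
  default 2-D path; it makes the worked example fully deterministic.
* `S >= 3`: multiphase Monte Carlo (below).

Volumes below `1e-12 * vol(D_C)` are floored to zero so that downstream
curve analyses are not driven by noise-dominated ratios.

## Multiphase Monte Carlo volume estimation

For a body with a positive definite quadratic constraint, the constraint is
first **whitened**: completing the square and mapping through the Cholesky
factor `L` of the (symmetrized) quadratic matrix turns it into a centered
ball; volumes transform by `|det L|^-1`. For partial communities the
restricted quadratic form can be only positive semidefinite; such bodies
are sampled unwhitened (the chord intersection handles general quadratics,
keeping the feasible segment through the current point).

An interior point `x0` is the polytope's Chebyshev center, bisected toward
the quadratic form's minimizer over the polytope when the cap cuts the
center off. The estimator anchors at the inscribed ball around `x0`
(radius `r0`) and telescopes

    vol(body) = vol(Ball(r0)) * prod_i vol(K_i+1) / vol(K_i),
    K_i = body ∩ Ball(x0, r_i),   r_i = r0 * 2^(i/S),

capped at a covering radius from per-coordinate polytope extents and/or
the quadratic's enclosing ball. Each ratio is estimated by Hit-and-Run
samples of the larger body (the lower-variance direction), counting the
fraction inside the smaller. Standard errors are propagated by the delta
method across phases; sampler autocorrelation is not included in the
nominal SE, which is why validation tolerances are set against realized
errors rather than nominal SEs alone.

Hit-and-Run draws a uniform direction, intersects the line with every
half-space and quadratic to get the feasible chord, and jumps to a uniform
point on it. Defaults: thinning `5S` steps between retained samples,
burn-in `10S`, and parallel chains (vectorised steps; `chains=1` recovers
the plain sequential walk). All randomness flows from one seed; estimates
are bit-for-bit reproducible.

**Degenerate anchor.** When the body coincides with its own inscribed ball
(e.g. a pure ball after whitening), the telescoping product is empty and
the result would be exact by construction. The sphere-validation suite
therefore starts the schedule below the inscribed radius
(`r0_scale = 0.75`, forcing five genuine phases at `S = 12`), which
exercises the sampler and ratio estimator while keeping the phase count —
and hence the telescoped variance — low. At a ~1e6-sample budget this
recovers the unit 12-ball volume `pi^6/720` with realized relative errors
under 1% across seeds (nominal SE ~0.5%).

## Critical and optimal supply

The **critical supply** `Q_c` is the infimum of `s.N0` over the closure of
the feasibility cone intersected with `s >= 0` — the supply at which the
initialization domain first becomes nonempty. It is a linear program over
the multipliers (`minimize N0.(d + B n)` s.t. `n >= 0`, `d + B n >= 0`),
bounded below by zero because `N0 > 0`. Since `n = 0` is feasible whenever
`d >= 0`, always `Q_c <= d.N0`; equality holds whenever no multiplier
direction lowers the objective (e.g. all-positive `sigma` columns), which
is the typical case in the random ensembles. For the packaged
two-population example, `Q_c = d.N0 = 3.36` (3.4 at one-decimal display).

The **optimal supply** `Q_opt` maximizes `P_M(Q)`: grid argmax, optionally
refined by golden-section search in log `Q` when a noiseless evaluator is
available (the 2-D quadrature path). For the two-population example the
refined peak sits at `Q_opt ≈ 9.9` with the default grids placing the
argmax at ~10.1 — i.e. 10 to two significant figures — and the curve is
exactly zero below `Q_c`, rises on `[3.4, ~10]`, and decays beyond.

## Random-network ensembles

The generator reproduces a constrained random-matrix ensemble: elements of
`sigma` drawn from Normal(0, 1); opposite-sign pairs adjusted so the
gaining side never exceeds the losing side in magnitude (transfer
efficiency <= 1), implemented by swapping absolute values; diagonal
shifted so the symmetric part's minimum eigenvalue equals the floor
`sigma_0`; then the whole matrix scaled by `s_sigma`. Step order is
normative — flooring before scaling leaves the final minimum eigenvalue at
`sigma_0 * s_sigma` exactly. Defaults: `s_sigma = 1.0`, `sigma_0 = 0.5`,
and `d`, `N0` drawn from normals centered at `d_0 = 1.0`, `N_0 = 1.0`.

Two quantities the construction leaves open are fixed here and exposed in
the config: the standard deviation of the `d` and `N0` draws is
`0.25 x center` (mild truncation), and positivity is enforced by
resampling non-positive draws. Connectance `< 1` is applied by symmetric
pair masking (both `sigma_ij` and `sigma_ji` zeroed together) before the
efficiency step, keeping the pair semantics coherent. Ensembles generate
at `S = 8` and down-sample to smaller sizes by taking leading principal
submatrices of `sigma` (and leading entries of `d`, `N0`); because a
submatrix can lose the eigenvalue floor, the diagonal shift is re-applied
when needed so every analyzed network is dissipative — a deliberate
choice, recorded here, since the alternative (raw submatrices) can violate
the dissipativity precondition of the whole pipeline.

What the generator emulates: dense, disordered energy-exchange networks
with bounded transfer efficiency and guaranteed global stability. What it
does not: empirical food-web topology, trophic hierarchy, correlated
pairwise interactions, or parameter distributions fitted to data — so
passing ensemble tests demonstrates the geometric mechanism (saturating
initialization, unimodal maturation, size-ordered energetic windows), not
quantitative predictions for any real ecosystem.

## Curve analysis

Replicate probability curves are summarized by pointwise functional data
analysis in logit space: interpolate each curve linearly in `(log Q, p)`
onto a common log-spaced grid (extrapolation refused), clamp to
`[eps, 1 - eps]` with `eps = 1e-3`, logit-transform, take the pointwise
mean and standard deviation (`n - 1` denominator), and map the mean and
mean +/- SD back through the inverse logit. Diversity curves are averaged
on their original scale. The common grid defaults to 200 points
(configurable; 500 matches the reference analyses at triple the runtime).

Average diversity at supply `Q` is the expected community size over all
nonempty candidate communities, each size class `D` weighted by its count
`binom(S, D)` times its mean maturation probability; the unnormalized
variant `sum_C |C| p_mat(C)` is available behind a flag because either
reading of "expected community size weighted by counts and probabilities"
is defensible. The empty community is excluded from the average (its
"size" is zero and it would dominate the low-`Q` limit where nothing else
is feasible).

Shape scores are diagnostic plumbing of this package (their published
counterparts are not reproducible from available material): the
*saturation score* is the Spearman correlation of `p` with `Q` times a
terminal-flatness factor (1 minus the normalized mean slope over the last
10% of the log-`Q` grid); the *unimodality score* is
`1 - SSE(best up-down isotonic fit) / SSE(best monotone isotonic fit)`.
Both are ~1 for clean saturating / unimodal curves, <= 0 or ~0 otherwise,
and (0, 0) for constant curves.

## Problem sizes used in the test suite

The full reference-scale ensemble analysis (100 replicates x 4 network
sizes x 500-point grids with 1e5+ samples per volume) is a cluster-scale
computation. The package's own validation uses scaled designs chosen to
keep every qualitative conclusion testable: 20 replicates at `S in {2, 4}`
on a 100-point grid (S=2 via the deterministic quadrature path, S=4 with
200 samples per phase across ~200 chains), one `S = 6` network with all 63
communities on a 12-point grid for the size-ordered energetic windows, and
the 12-ball benchmark at the full ~1e6-sample budget. The acceptance
script (`scripts/acceptance.py`) recomputes the two headline quantities —
the worked example's `Q_c` and the 12-ball relative error — from scratch
at those budgets.

## Numerical choices and limitations

* Support classification solves the linear complementarity problem by
  support enumeration in decreasing cardinality (exact for `S <= 12`);
  multipliers must clear `1e-9` relative to the max-norm, and ties raise
  an error instead of guessing a cell.
* Linear programs (Chebyshev centers, critical supply, extents, quadratic
  inactivity probes) use HiGHS via SciPy; the interior-point refinement
  under an active quadratic uses SLSQP plus bisection.
* Exact polytope volumes require bounded, full-dimensional bodies;
  degenerate bodies return volume 0 with a dimensionality note, unbounded
  ones raise.
* The multiphase estimator's nominal SE ignores chain autocorrelation;
  thinning (`5S`) and burn-in (`10S`) defaults were chosen so realized
  errors track nominal SEs on ball and cube benchmarks.
* Indices are 0-based in the Python API and 1-based in files and display
  strings.
* Time integration of the dynamics, non-point attractors, saturating
  (density-dependent) capture rates, and assembly/disassembly dynamics
  across partition cells are out of scope.
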