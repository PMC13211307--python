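"""Exact, Hit-and-Run and multiphase volume computations."""

import numpy as np
import pytest

from ecofeas import (
    BoxEnvelope,
    EnergeticNetwork,
    HPolytope,
    InterPolyQuad,
    QuadraticConstraint,
    SimplexEnvelope,
    ball_volume,
    capture_domain,
    hit_and_run_sample,
    interior_point,
    maturation_domain,
    multiphase_volume,
    polytope_volume_exact,
    rejection_volume,
    simplex_volume,
    standardize,
)
from ecofeas.geometry import GeometryError


def cube(dim, lo=0.0, hi=1.0):
    A = np.vstack([np.eye(dim), -np.eye(dim)])
    b = np.concatenate([np.full(dim, hi), np.full(dim, -lo)])
    return HPolytope(A, b)


class TestSimplexVolume:
    def test_closed_form(self, two_pop):
        est = simplex_volume(two_pop, 7.0)
        assert est.method == "analytic"
        assert est.value == pytest.approx(49.0 / 2.4, rel=1e-12)

    def test_matches_rejection_fraction(self, two_pop, rng):
        """The simplex fills about half its bounding box at S=2."""
        Q = 7.0
        pts = rng.random((20000, 2)) * np.array([Q, Q / 1.2])
        frac = np.mean(pts @ two_pop.N0 <= Q)
        box = Q * (Q / 1.2)
        assert simplex_volume(two_pop, Q).value == pytest.approx(frac * box, rel=0.03)

    def test_homogeneity_degree_S(self, two_pop):
        v1 = simplex_volume(two_pop, 3.0).value
        v2 = simplex_volume(two_pop, 6.0).value
        assert v2 / v1 == pytest.approx(2.0 ** 2)

    def test_log_space_no_overflow(self):
        net = EnergeticNetwork(np.eye(12), np.zeros(12), np.full(12, 1e-3))
        assert np.isfinite(simplex_volume(net, 1e6).value)


class TestExactPolytopeVolume:
    def test_unit_cube(self):
        assert polytope_volume_exact(cube(3)).value == pytest.approx(1.0, rel=1e-9)

    def test_capture_simplex_cross_method(self, two_pop):
        poly = capture_domain(two_pop, 7.0)
        assert polytope_volume_exact(poly).value == pytest.approx(
            simplex_volume(two_pop, 7.0).value, rel=1e-9
        )

    def test_empty_is_zero(self):
        poly = HPolytope([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]],
                         [0.0, -1.0, 1.0, 0.0])
        est = polytope_volume_exact(poly)
        assert est.value == 0.0 and "empty" in est.note

    def test_degenerate_is_zero_with_note(self):
        # the segment x=0.5 in the square: lower-dimensional
        poly = HPolytope([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]],
                         [0.5, -0.5, 1.0, 0.0])
        est = polytope_volume_exact(poly)
        assert est.value == 0.0 and "degenerate" in est.note


class TestHitAndRun:
    def test_uniform_on_square(self):
        body = InterPolyQuad(cube(2))
        pts = hit_and_run_sample(body, np.array([0.3, 0.7]), 10000, thin=3,
                                 rng_seed=11, chains=20)
        se = 1.0 / np.sqrt(12 * len(pts))
        assert np.all(np.abs(pts.mean(axis=0) - 0.5) < 4 * se)

    def test_disk_radial_moment(self):
        """Uniform on the unit disk has E[r^2] = 1/2."""
        body = InterPolyQuad(HPolytope(np.empty((0, 2)), np.empty(0)),
                             QuadraticConstraint(np.eye(2), np.zeros(2), 1.0))
        pts = hit_and_run_sample(body, np.zeros(2), 10000, thin=3,
                                 rng_seed=13, chains=20)
        r2 = np.sum(pts ** 2, axis=1)
        assert r2.mean() == pytest.approx(0.5, abs=4 * r2.std() / np.sqrt(len(r2)))

    def test_all_samples_satisfy_constraints(self, two_pop):
        body = maturation_domain(two_pop, 12.0)
        x0 = interior_point(body)
        pts = hit_and_run_sample(body, x0, 2000, thin=4, rng_seed=7, chains=8)
        assert np.all(body.contains(pts, atol=1e-10))

    def test_non_interior_start_rejected(self):
        body = InterPolyQuad(cube(2))
        with pytest.raises(GeometryError):
            hit_and_run_sample(body, np.array([2.0, 0.5]), 10, rng_seed=0)

    def test_seed_determinism(self):
        body = InterPolyQuad(cube(3))
        a = hit_and_run_sample(body, np.full(3, 0.5), 500, thin=2, rng_seed=42, chains=4)
        b = hit_and_run_sample(body, np.full(3, 0.5), 500, thin=2, rng_seed=42, chains=4)
        np.testing.assert_array_equal(a, b)


class TestMultiphase:
    def test_cube_against_exact(self):
        body = InterPolyQuad(cube(3))
        est = multiphase_volume(body, samples_per_phase=4000, rng_seed=3)
        assert est.standard_error is not None
        assert abs(est.value - 1.0) < 3 * est.standard_error + 0.02

    def test_random_low_dim_polytopes_vs_exact(self, rng):
        """Exact vs multiphase within 5% on random 2-4D polytopes."""
        for k in range(12):
            dim = 2 + k % 3
            A = rng.standard_normal((3 * dim, dim))
            A /= np.linalg.norm(A, axis=1, keepdims=True)
            b = np.full(3 * dim, 1.0)
            poly = HPolytope(np.vstack([A, np.eye(dim), -np.eye(dim)]),
                             np.concatenate([b, np.full(2 * dim, 2.0)]))
            exact = polytope_volume_exact(poly).value
            est = multiphase_volume(InterPolyQuad(poly), samples_per_phase=6000,
                                    rng_seed=100 + k)
            assert abs(est.value - exact) / exact < 0.05

    def test_ball_with_jacobian_consistency(self):
        """Whitening maps an ellipsoid to a ball; volumes agree through the
        Jacobian."""
        M = np.array([[2.0, 0.3], [0.3, 1.0]])
        body = InterPolyQuad(HPolytope(np.empty((0, 2)), np.empty(0)),
                             QuadraticConstraint(M, np.array([0.5, -0.2]), 1.0))
        w = standardize(body)
        truth = ball_volume(2, np.sqrt(w.quad.c)) * np.exp(w.log_jacobian)
        est = multiphase_volume(body, samples_per_phase=6000, rng_seed=5, r0_scale=0.5)
        assert est.value == pytest.approx(truth, rel=0.06)

    def test_translation_invariance(self, rng):
        poly = cube(3)
        shifted = HPolytope(poly.A, poly.b + poly.A @ np.array([5.0, -2.0, 1.0]))
        e1 = multiphase_volume(InterPolyQuad(poly), samples_per_phase=4000, rng_seed=9)
        e2 = multiphase_volume(InterPolyQuad(shifted), samples_per_phase=4000, rng_seed=9)
        err = 3 * (e1.standard_error + e2.standard_error)
        assert abs(e1.value - e2.value) < err + 0.02

    def test_seed_determinism(self):
        body = InterPolyQuad(cube(3))
        a = multiphase_volume(body, samples_per_phase=1000, rng_seed=21)
        b = multiphase_volume(body, samples_per_phase=1000, rng_seed=21)
        assert a.value == b.value and a.standard_error == b.standard_error

    def test_empty_body_zero(self):
        poly = HPolytope([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]],
                         [0.0, -1.0, 1.0, 0.0])
        est = multiphase_volume(InterPolyQuad(poly), samples_per_phase=100, rng_seed=0)
        assert est.value == 0.0

    @pytest.mark.parametrize("dim", [2, 5, 8])
    def test_ball_dimension_sweep(self, dim):
        """Unit-ball volumes across dimensions within a few percent."""
        body = InterPolyQuad(HPolytope(np.empty((0, dim)), np.empty(0)),
                             QuadraticConstraint(np.eye(dim), np.zeros(dim), 1.0))
        est = multiphase_volume(body, samples_per_phase=8000, rng_seed=dim,
                                r0_scale=0.5)
        assert abs(est.value - ball_volume(dim)) / ball_volume(dim) < 0.05


class TestRejection:
    def test_envelope_equals_body(self, two_pop):
        Q = 7.0
        body = InterPolyQuad(capture_domain(two_pop, Q))
        env = SimplexEnvelope(two_pop.N0, Q)
        est = rejection_volume(body, env, 2000, rng_seed=1)
        assert est.value == pytest.approx(env.volume, rel=1e-12)

    def test_half_square(self):
        # x <= 0.5 inside the unit square
        body = InterPolyQuad(HPolytope([[1.0, 0.0]], [0.5]))
        env = BoxEnvelope([0, 0], [1, 1])
        est = rejection_volume(body, env, 10000, rng_seed=2)
        assert abs(est.value - 0.5) < 4 * est.standard_error

    def test_initialization_polytope_cross_method(self, two_pop):
        from ecofeas import initialization_domain

        Q = 7.0
        poly = initialization_domain(two_pop, Q)
        exact = polytope_volume_exact(poly).value
        est = rejection_volume(InterPolyQuad(poly), SimplexEnvelope(two_pop.N0, Q),
                               40000, rng_seed=3)
        assert abs(est.value - exact) < 4 * est.standard_error

    def test_zero_hits_one_sided(self, two_pop):
        body = InterPolyQuad(HPolytope([[1.0, 0.0], [-1.0, 0.0]], [-50.0, 51.0]))
        env = BoxEnvelope([0, 0], [1, 1])
        est = rejection_volume(body, env, 1000, rng_seed=4)
        assert est.value == 0.0 and est.standard_error > 0
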