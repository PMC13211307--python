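"""Domain construction, whitening, Chebyshev centers, interior points."""

import numpy as np
import pytest

from ecofeas import (
    CandidateCommunity,
    EnergeticNetwork,
    HPolytope,
    InterPolyQuad,
    QuadraticConstraint,
    capture_domain,
    chebyshev_center,
    hit_and_run_sample,
    initialization_domain,
    interior_point,
    maturation_domain,
    standardize,
)
from ecofeas.geometry import GeometryError
from ecofeas.network import NetworkInputError
from ecofeas.volume import polytope_vertices


def unit_square():
    return HPolytope(np.vstack([np.eye(2), -np.eye(2)]), [1.0, 1.0, 0.0, 0.0])


class TestCaptureDomain:
    def test_simplex_vertices(self, two_pop):
        poly = capture_domain(two_pop, 7.0)
        verts = polytope_vertices(poly)
        expected = {(0.0, 0.0), (7.0, 0.0), (0.0, 7.0 / 1.2)}
        got = {tuple(np.round(v, 6)) for v in verts}
        assert got == {tuple(np.round(v, 6)) for v in expected}

    def test_one_dimensional_segment(self):
        net = EnergeticNetwork([[1.0]], [0.0], [1.0])
        verts = polytope_vertices(capture_domain(net, 1.0))
        assert sorted(float(v) for v in verts.ravel()) == [0.0, 1.0]

    def test_vertices_scale_linearly_in_Q(self, two_pop):
        v1 = np.sort(polytope_vertices(capture_domain(two_pop, 5.0)), axis=0)
        v2 = np.sort(polytope_vertices(capture_domain(two_pop, 10.0)), axis=0)
        np.testing.assert_allclose(2.0 * v1, v2, atol=1e-9)

    def test_rejects_nonpositive_supply(self, two_pop):
        with pytest.raises(NetworkInputError):
            capture_domain(two_pop, 0.0)


class TestInitializationDomain:
    def test_empty_below_critical_supply(self, two_pop):
        poly = initialization_domain(two_pop, 3.0)
        _, radius = chebyshev_center(poly)
        assert radius <= 1e-9

    def test_contains_small_cone_point(self, two_pop):
        s = two_pop.d + two_pop.sigma @ np.full(2, 0.01)
        poly = initialization_domain(two_pop, 7.0)
        assert poly.contains(s)
        assert s @ two_pop.N0 < 7.0

    def test_empty_community_cell_is_below_demand(self, two_pop):
        poly = initialization_domain(two_pop, 10.0, CandidateCommunity.empty())
        inside = 0.9 * two_pop.d
        outside = two_pop.d + [0.2, 0.2]
        assert poly.contains(inside)
        assert not poly.contains(outside)

    def test_monotone_growth_in_Q(self, two_pop, rng):
        """Only the supply-cap row changes with Q, so D_I(Q1) <= D_I(Q2)."""
        p1 = initialization_domain(two_pop, 5.0)
        p2 = initialization_domain(two_pop, 9.0)
        pts = rng.random((500, 2)) * 8.0
        in1 = p1.contains(pts)
        assert np.all(p2.contains(pts)[in1])


class TestMaturationDomain:
    def test_membership_arithmetic(self, two_pop):
        # s = d + sigma.(1,1) has N* = (1,1): s.N* = 8.65, s.N0 = 9.496
        s = np.array([4.42, 4.23])
        for Q, inside in [(9.6, True), (9.0, False), (8.0, False)]:
            body = maturation_domain(two_pop, Q)
            assert bool(body.contains(s)) is inside
        # between 8.65 and 9.496 the quadratic holds but the supply cap fails
        body = maturation_domain(two_pop, 9.0)
        assert body.quad.value(s) <= body.quad.c

    def test_empty_community_has_no_quadratic(self, two_pop):
        body = maturation_domain(two_pop, 5.0, CandidateCommunity.empty())
        assert body.quad is None

    def test_strictly_smaller_than_initialization_at_high_Q(self, two_pop, rng):
        Q = 15.0
        init = initialization_domain(two_pop, Q)
        body = maturation_domain(two_pop, Q)
        pts = rng.random((4000, 2)) * np.array([Q, Q / 1.2])
        n_init = int(np.count_nonzero(init.contains(pts)))
        n_mat = int(np.count_nonzero(body.contains(pts)))
        assert 0 < n_mat < n_init

    def test_refuses_non_dissipative(self):
        net = EnergeticNetwork([[0.1, 5.0], [-5.0, 0.1]], [1, 1], [1, 1])
        # symmetric part is 0.1*I here; make it genuinely indefinite
        bad = EnergeticNetwork([[0.1, 5.0], [5.0, 0.1]], [1, 1], [1, 1])
        with pytest.raises(GeometryError):
            maturation_domain(bad, 5.0)

    def test_nesting_on_sampled_points(self, two_pop):
        """Maturation samples lie in the initialization polytope, which lies
        in the capture simplex."""
        Q = 12.0
        body = maturation_domain(two_pop, Q)
        x0 = interior_point(body)
        pts = hit_and_run_sample(body, x0, 1000, thin=5, rng_seed=1, chains=10)
        init = initialization_domain(two_pop, Q)
        cap = capture_domain(two_pop, Q)
        assert np.all(init.contains(pts, atol=1e-9))
        assert np.all(cap.contains(pts, atol=1e-9))


class TestStandardize:
    def test_identity_quadratic_untouched(self):
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.eye(2), np.zeros(2), 4.0))
        w = standardize(body)
        assert w.log_jacobian == pytest.approx(0.0)
        np.testing.assert_allclose(w.quad.c, 4.0)

    def test_diagonal_whitening_jacobian(self):
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.diag([4.0, 1.0]), np.zeros(2), 1.0))
        w = standardize(body)
        np.testing.assert_allclose(w.quad.M, np.eye(2))
        assert np.exp(w.log_jacobian) == pytest.approx(0.5)  # |det T^-1| = 1/2

    def test_whitened_membership_equivalent(self, two_pop, rng):
        body = maturation_domain(two_pop, 12.0)
        w = standardize(body)
        pts = rng.random((300, 2)) * 10.0
        mapped = (pts - w.shift) @ w.transform.T
        np.testing.assert_array_equal(body.contains(pts), w.contains(mapped))

    def test_rejects_indefinite_form(self):
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.diag([1.0, -1.0]), np.zeros(2), 1.0))
        with pytest.raises(GeometryError, match="eigenvalue"):
            standardize(body)


class TestChebyshevAndInterior:
    def test_unit_square_center(self):
        center, radius = chebyshev_center(unit_square())
        np.testing.assert_allclose(center, [0.5, 0.5], atol=1e-9)
        assert radius == pytest.approx(0.5)

    def test_right_isoceles_simplex_inradius(self):
        poly = HPolytope([[-1, 0], [0, -1], [1, 1]], [0, 0, 1])
        center, radius = chebyshev_center(poly)
        r = 1.0 / (2.0 + np.sqrt(2.0))
        assert radius == pytest.approx(r, rel=1e-9)
        np.testing.assert_allclose(center, [r, r], atol=1e-8)

    def test_empty_polytope_flagged(self):
        poly = HPolytope([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]],
                         [0.0, -1.0, 1.0, 0.0])
        _, radius = chebyshev_center(poly)
        assert radius <= 0

    def test_unbounded_raises(self):
        poly = HPolytope([[-1.0, 0.0], [0.0, -1.0]], [0.0, 0.0])
        with pytest.raises(GeometryError, match="unbounded"):
            chebyshev_center(poly)

    def test_interior_point_inactive_quadratic(self):
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.eye(2), np.zeros(2), 100.0))
        np.testing.assert_allclose(interior_point(body), [0.5, 0.5], atol=1e-9)

    def test_interior_point_active_quadratic(self):
        # disk of radius 0.6 centered at the origin clips the unit square
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.eye(2), np.zeros(2), 0.36))
        x = interior_point(body)
        assert x is not None
        assert bool(body.contains(x, atol=0.0))
        assert np.all(x > 0) and np.linalg.norm(x) < 0.6

    def test_empty_intersection_signalled(self):
        # disk far from the square: empty body, no exception
        body = InterPolyQuad(unit_square(),
                             QuadraticConstraint(np.eye(2), np.array([-20.0, -20.0]), -199.0))
        assert interior_point(body) is None
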