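"""Geodesic shooting, varifold metric, and surface-matching checks.

The adjoint (reverse-mode) gradients of the RK4-discretized EPDiff system are
validated against central finite differences; geodesics are validated by
Hamiltonian conservation and time-reversibility; matching by recovery of
known transformations.
"""

import numpy as np
import pytest
import trimesh

from mtlmorph import lddmm
from mtlmorph.surface import TriSurface, surface_volume, surface_area


class TestKernelApply:
    def test_single_momentum_at_origin(self):
        pts = np.zeros((1, 3))
        p = np.array([[0.0, 0.0, 1.0]])
        v = lddmm.kernel_apply(pts, pts, p, sigma=1.0)
        assert np.allclose(v, [[0, 0, 1]])   # K(0) = 1 convention

    def test_far_field_decays(self):
        src = np.zeros((1, 3))
        p = np.array([[1.0, 0.0, 0.0]])
        far = np.array([[20.0, 0.0, 0.0]])
        v = lddmm.kernel_apply(far, src, p, sigma=1.0)
        assert np.linalg.norm(v) < 1e-10

    def test_opposite_momenta_cancel_at_midpoint(self):
        src = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        p = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        v = lddmm.kernel_apply(np.zeros((1, 3)), src, p, sigma=1.0)
        assert np.allclose(v, 0.0)

    def test_gram_positive_definite(self, rng):
        pts = rng.normal(size=(15, 3))
        K = lddmm.gauss_kernel(pts, pts, 0.7)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > 0


class TestShoot:
    def test_zero_momentum_identity(self, rng):
        x = rng.normal(size=(12, 3))
        state = lddmm.GeodesicState(x, np.zeros_like(x), lddmm.KernelParams(1.0, 0.5))
        flow = lddmm.shoot(state)
        assert np.allclose(flow.traj_x, x[None])
        assert flow.hamiltonian_drift() == 0.0

    def test_hamiltonian_conserved(self, rng):
        x = rng.normal(size=(25, 3)) * 2
        p = rng.normal(size=(25, 3)) * 0.3
        state = lddmm.GeodesicState(x, p, lddmm.KernelParams(1.0, 0.5), n_steps=10)
        flow = lddmm.shoot(state)
        assert flow.hamiltonian_drift() < 1e-3

    def test_wide_kernel_gives_rigid_translation(self, rng):
        x = rng.normal(size=(10, 3))          # extent ~ 2
        p_each = np.array([0.2, -0.1, 0.3])
        p = np.tile(p_each, (10, 1))
        state = lddmm.GeodesicState(x, p, lddmm.KernelParams(500.0, 1.0))
        flow = lddmm.shoot(state)
        # v = K(0) * sum p = N * p_each everywhere; displacement N*p_each*T
        expected = x + 10 * p_each
        assert np.allclose(flow.endpoint, expected, atol=1e-4)

    def test_reverse_shooting_returns_start(self, rng):
        x = rng.normal(size=(15, 3))
        p = rng.normal(size=(15, 3)) * 0.2
        state = lddmm.GeodesicState(x, p, lddmm.KernelParams(1.0, 0.5), n_steps=15)
        fwd = lddmm.shoot(state)
        back = lddmm.shoot(lddmm.GeodesicState(
            fwd.endpoint, -fwd.traj_p[-1], state.kernel, 15))
        assert np.allclose(back.endpoint, x, atol=1e-4)

    def test_blowup_raises(self):
        x = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        p = np.array([[1e8, 0, 0], [-1e8, 0, 0]])
        with pytest.raises(FloatingPointError):
            lddmm.integrate(x, p, 0.5, 10)


class TestAdjointGradients:
    """Hand-derived reverse-mode VJPs against central finite differences."""

    def test_rhs_vjp_matches_finite_differences(self, rng):
        n, sig, eps = 6, 0.8, 1e-6
        x = rng.normal(size=(n, 3))
        p = rng.normal(size=(n, 3)) * 0.3
        a = rng.normal(size=(n, 3))
        b = rng.normal(size=(n, 3))
        cx, cp = lddmm._rhs_vjp(x, p, a, b, sig)

        def f(xx, pp):
            xd, pd = lddmm._rhs(xx, pp, sig)
            return np.sum(a * xd) + np.sum(b * pd)

        for i in range(n):
            for d in range(3):
                dx = np.zeros_like(x)
                dx[i, d] = eps
                assert (f(x + dx, p) - f(x - dx, p)) / (2 * eps) == pytest.approx(
                    cx[i, d], abs=1e-6)
                assert (f(x, p + dx) - f(x, p - dx)) / (2 * eps) == pytest.approx(
                    cp[i, d], abs=1e-6)

    def test_integrate_vjp_matches_finite_differences(self, rng):
        n, sig, eps = 5, 0.8, 1e-6
        x = rng.normal(size=(n, 3))
        p = rng.normal(size=(n, 3)) * 0.3
        c = rng.normal(size=(n, 3))
        xs, ps = lddmm.integrate(x, p, sig, 5)
        _, gp0 = lddmm.integrate_vjp(xs, ps, sig, 1.0, c)

        def F(p0):
            return np.sum(c * lddmm.integrate(x, p0, sig, 5)[0][-1])

        for i in range(n):
            for d in range(3):
                dp = np.zeros_like(p)
                dp[i, d] = eps
                assert (F(p + dp) - F(p - dp)) / (2 * eps) == pytest.approx(
                    gp0[i, d], abs=1e-6)

    def test_flow_jacobian_matches_finite_differences(self, rng):
        m = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
        xs = np.asarray(m.vertices)
        p0 = rng.normal(size=xs.shape) * 0.05
        probe = np.array([[0.5, 0.2, 0.1], [1.0, -0.4, 0.3]])
        _, A = lddmm.flow_points(xs, p0, probe, 0.8, 10, with_jacobian=True)
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = 1e-5
            fd = (lddmm.flow_points(xs, p0, probe + dp, 0.8, 10)
                  - lddmm.flow_points(xs, p0, probe - dp, 0.8, 10)) / 2e-5
            assert np.allclose(A[:, :, d], fd, atol=1e-8)


class TestVarifold:
    def test_self_distance_zero(self, small_sphere, sphere_kernel):
        assert lddmm.varifold_distance(small_sphere, small_sphere,
                                       sphere_kernel) == pytest.approx(0.0, abs=1e-8)

    def test_cell_order_invariance(self, small_sphere, sphere_kernel, rng):
        perm = rng.permutation(small_sphere.n_faces)
        shuffled = TriSurface(small_sphere.vertices, small_sphere.faces[perm])
        d = lddmm.varifold_distance(small_sphere, shuffled, sphere_kernel)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_orientation_flip_invariance(self, small_sphere, sphere_kernel):
        flipped = TriSurface(small_sphere.vertices, small_sphere.faces[:, ::-1])
        assert lddmm.varifold_distance(small_sphere, flipped,
                                       sphere_kernel) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, small_sphere, sphere_kernel):
        other = small_sphere.with_vertices(small_sphere.vertices * 0.8 + 1.0)
        d12 = lddmm.varifold_distance(small_sphere, other, sphere_kernel)
        d21 = lddmm.varifold_distance(other, small_sphere, sphere_kernel)
        assert d12 == pytest.approx(d21, rel=1e-10)
        assert d12 > 0

    def test_far_surfaces_approach_sum_of_self_energies(self):
        m = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        s1 = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        params = lddmm.KernelParams(1.0, 0.4)
        s2 = s1.with_vertices(s1.vertices + np.array([5 * 0.4 * 10, 0, 0]))
        c1, N1, _ = lddmm._cell_reps(s1.vertices, s1.faces)
        e_self = lddmm._vf_inner(c1, N1, c1, N1, params.sigma_w)
        d = lddmm.varifold_distance(s1, s2, params)
        assert d == pytest.approx(2 * e_self, rel=1e-6)

    def test_triangle_inequality_spot_check(self, rng):
        m = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
        base = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        params = lddmm.KernelParams(1.0, 0.8)
        for _ in range(5):
            a = base.with_vertices(base.vertices + rng.normal(0, 0.3, base.vertices.shape))
            b = base.with_vertices(base.vertices + rng.normal(0, 0.3, base.vertices.shape))
            c = base.with_vertices(base.vertices + rng.normal(0, 0.3, base.vertices.shape))
            dab = np.sqrt(lddmm.varifold_distance(a, b, params))
            dbc = np.sqrt(lddmm.varifold_distance(b, c, params))
            dac = np.sqrt(lddmm.varifold_distance(a, c, params))
            assert dac <= dab + dbc + 1e-9

    def test_gradient_matches_finite_differences(self, rng):
        m = trimesh.creation.icosphere(subdivisions=1)
        s = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        target = TriSurface(np.asarray(m.vertices) * 1.1 + 0.2, np.asarray(m.faces))
        params = lddmm.KernelParams(0.5, 0.4)
        _, g = lddmm.varifold_distance_and_grad(s.vertices, s.faces, target, params)
        eps = 1e-6
        for i in range(0, s.n_vertices, 5):
            for d in range(3):
                v = s.vertices.copy()
                v[i, d] += eps
                dp, _ = lddmm.varifold_distance_and_grad(v, s.faces, target, params)
                v[i, d] -= 2 * eps
                dm, _ = lddmm.varifold_distance_and_grad(v, s.faces, target, params)
                assert (dp - dm) / (2 * eps) == pytest.approx(g[i, d], abs=1e-6)


class TestMatchSurface:
    def test_identity_target_zero_momentum(self, small_sphere, sphere_kernel):
        res = lddmm.match_surface(small_sphere, small_sphere, sphere_kernel,
                                  max_iter=50)
        assert np.abs(res.state.momentum).max() < 1e-6
        assert res.energy == pytest.approx(0.0, abs=1e-8)

    def test_translation_recovery(self, small_sphere, sphere_kernel):
        target = small_sphere.with_vertices(small_sphere.vertices + [1.0, 0, 0])
        res = lddmm.match_surface(small_sphere, target, sphere_kernel, max_iter=200)
        err = np.linalg.norm(res.deformed.vertices - target.vertices, axis=1).mean()
        assert err < 0.05
        assert all(np.diff(res.energy_trace) <= 1e-9)   # monotone accepted energy

    def test_scale_recovery_volume(self, small_sphere, sphere_kernel):
        target = small_sphere.with_vertices(small_sphere.vertices * 0.9)
        res = lddmm.match_surface(small_sphere, target, sphere_kernel, max_iter=150)
        v_t = surface_volume(target)
        v_d = surface_volume(TriSurface(res.deformed.vertices, small_sphere.faces))
        assert v_d == pytest.approx(v_t, rel=0.02)


class TestJacobianMarkers:
    def test_identity_flow(self, small_sphere, sphere_kernel):
        state = lddmm.GeodesicState(small_sphere.vertices,
                                    np.zeros_like(small_sphere.vertices),
                                    sphere_kernel)
        flow = lddmm.shoot(state)
        log_det, area_ratio = lddmm.jacobian_markers(flow, small_sphere)
        assert np.allclose(log_det, 0.0, atol=1e-10)
        assert np.allclose(area_ratio, 1.0, atol=1e-10)

    def test_shoot_contraction_consistent_with_total_area(self, small_sphere,
                                                          sphere_kernel):
        # inward radial momentum produces a contraction; summed per-cell area
        # change must match the total area change of the deformed surface
        x = small_sphere.vertices
        c = x.mean(axis=0)
        p = -(x - c) * 0.002
        state = lddmm.GeodesicState(x, p, sphere_kernel)
        flow = lddmm.shoot(state)
        _, area_ratio = lddmm.jacobian_markers(flow, small_sphere)
        from mtlmorph.surface import face_area_normals
        a0 = np.linalg.norm(face_area_normals(x, small_sphere.faces), axis=1)
        deformed = TriSurface(flow.endpoint, small_sphere.faces)
        assert np.sum(area_ratio * a0) == pytest.approx(
            surface_area(deformed), rel=0.01)
        assert surface_area(deformed) < surface_area(small_sphere)

    def test_synthetic_uniform_scaling_closed_form(self, small_sphere, sphere_kernel):
        # a synthetic flow that scales by s has log-det 3 ln s, area ratio s^2
        s = 0.9
        scaled = small_sphere.with_vertices(small_sphere.vertices * s)
        from mtlmorph.surface import face_area_normals
        a0 = np.linalg.norm(face_area_normals(small_sphere.vertices,
                                              small_sphere.faces), axis=1)
        a1 = np.linalg.norm(face_area_normals(scaled.vertices,
                                              small_sphere.faces), axis=1)
        assert np.allclose(a1 / a0, s ** 2, rtol=1e-10)
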