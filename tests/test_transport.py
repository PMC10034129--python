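"""Particle-measure transport, grid resampling, surface projection, and
Laplace-Beltrami smoothing; feature mass is conserved through the chain."""

import numpy as np
import pytest
import trimesh

from mtlmorph import transport as tp
from mtlmorph.nft import Detection, DetectionSet
from mtlmorph.surface import TriSurface, surface_area


@pytest.fixture
def simple_measure(rng):
    pos = rng.uniform(0, 5, (30, 3))
    w = rng.uniform(0.1, 1.0, 30)
    f = rng.integers(0, 5, 30).astype(float)
    return tp.ParticleMeasure(pos, w, f, provenance=np.zeros(30, dtype=int))


class TestParticlesFromSections:
    def test_counts_and_areas_conserved(self):
        mask = np.zeros((32, 32), bool)
        mask[4:28, 4:28] = True
        dets = DetectionSet(0, [Detection(10.0, 10.0, 3)] * 10, 0.1)
        m = tp.particles_from_sections([dets], [mask], 0.1, [2.0], cell_px=8)
        assert m.total_feature == 10.0
        assert m.total_weight == pytest.approx(mask.sum() * 0.01)
        assert np.all(m.positions[:, 2] == 2.0)

    def test_detections_land_in_one_cell(self):
        mask = np.ones((16, 16), bool)
        dets = DetectionSet(0, [Detection(2.0, 2.0, 3)] * 7, 1.0)
        m = tp.particles_from_sections([dets], [mask], 1.0, [0.0], cell_px=8)
        assert sorted(m.features.tolist())[-1] == 7.0
        assert np.sum(m.features > 0) == 1


class TestPushforward:
    def test_identity(self, simple_measure):
        out = tp.pushforward(simple_measure)
        assert np.allclose(out.positions, simple_measure.positions)
        assert out.total_feature == simple_measure.total_feature

    def test_rigid_translation(self, simple_measure):
        R = np.eye(3)
        t = np.array([1.0, -2.0, 3.0])
        out = tp.pushforward(simple_measure, rigid=(R, t))
        assert np.allclose(out.positions, simple_measure.positions + t)
        assert np.array_equal(out.weights, simple_measure.weights)
        assert np.array_equal(out.features, simple_measure.features)

    def test_inplane_scaling_with_jacobian_reweight(self, simple_measure):
        s = 1.7
        out = tp.pushforward(
            simple_measure,
            slice_maps={0: lambda xy: xy * s},
            jacobian_fn=lambda sid, xy: np.full(len(xy), s * s),
            jacobian_reweight=True)
        assert np.allclose(out.weights, simple_measure.weights * s * s)
        # densities f/w scale by s^-2; feature totals conserved exactly
        assert out.total_feature == simple_measure.total_feature
        nz = simple_measure.weights > 0
        assert np.allclose(out.densities()[nz],
                           simple_measure.densities()[nz] / (s * s))

    def test_mass_semantics_without_reweight(self, simple_measure):
        out = tp.pushforward(simple_measure,
                             slice_maps={0: lambda xy: xy * 2.0},
                             jacobian_fn=lambda sid, xy: np.full(len(xy), 4.0),
                             jacobian_reweight=False)
        assert np.array_equal(out.weights, simple_measure.weights)


class TestResampleGrid:
    def test_weight_conservation(self, simple_measure):
        wg, dens, lost = tp.resample_grid(simple_measure, (-1, -1, -1),
                                          (0.5, 0.5, 0.5), (16, 16, 16), 0.4)
        assert lost == 0.0
        assert wg.sum() == pytest.approx(simple_measure.total_weight, rel=1e-6)

    def test_small_bandwidth_concentrates_on_node(self):
        m = tp.ParticleMeasure(np.array([[1.0, 1.0, 1.0]]), [2.0], [6.0])
        wg, dens, _ = tp.resample_grid(m, (0, 0, 0), (1, 1, 1), (4, 4, 4), 0.01)
        assert wg[1, 1, 1] == pytest.approx(2.0)
        assert dens[1, 1, 1] == pytest.approx(3.0)

    def test_constant_density_preserved(self, rng):
        pos = rng.uniform(1, 3, (40, 3))
        w = rng.uniform(0.5, 2.0, 40)
        m = tp.ParticleMeasure(pos, w, 4.0 * w)   # density f/w = 4 everywhere
        wg, dens, _ = tp.resample_grid(m, (0, 0, 0), (0.5, 0.5, 0.5),
                                       (9, 9, 9), 0.5)
        occupied = wg > 1e-9
        assert np.allclose(dens[occupied], 4.0, atol=1e-9)

    def test_invalid_bandwidth(self, simple_measure):
        with pytest.raises(ValueError):
            tp.resample_grid(simple_measure, (0, 0, 0), (1, 1, 1), (4, 4, 4), 0.0)


class TestProjectToSurface:
    def test_totals_conserved(self, simple_measure, small_sphere):
        g_tau, g_a = tp.project_to_surface(simple_measure, small_sphere)
        assert g_tau.sum() == pytest.approx(simple_measure.total_feature)
        assert g_a.sum() == pytest.approx(simple_measure.total_weight)

    def test_nearest_vertex_assignment(self, small_sphere):
        v0 = small_sphere.vertices[5]
        m = tp.ParticleMeasure(v0[None] + 0.01, [0.7], [3.0])
        g_tau, g_a = tp.project_to_surface(m, small_sphere)
        assert g_tau[5] == 3.0
        assert g_a[5] == pytest.approx(0.7)

    def test_equidistant_tie_goes_to_lowest_index(self):
        surf = TriSurface(np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 2.0, 0]]),
                          np.array([[0, 1, 2]]))
        m = tp.ParticleMeasure(np.array([[1.0, 0.0, 0.0]]), [1.0], [1.0])
        g_tau, _ = tp.project_to_surface(m, surf)
        assert g_tau[0] == 1.0 and g_tau[1] == 0.0

    def test_region_restriction(self, simple_measure, small_sphere):
        sel = simple_measure.features > 1
        g_tau, _ = tp.project_to_surface(simple_measure, small_sphere,
                                         region_mask=sel)
        assert g_tau.sum() == pytest.approx(simple_measure.features[sel].sum())


class TestLaplaceBeltrami:
    @pytest.fixture(scope="class")
    def sphere_field(self):
        m = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        surf = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        return tp.SurfaceField(surf, n_basis=surf.n_vertices)

    def test_vertex_masses_sum_to_area(self, sphere_field):
        assert sphere_field.vertex_masses.sum() == pytest.approx(
            surface_area(sphere_field.surface), rel=1e-9)

    def test_first_eigenpair_constant(self, sphere_field):
        evals, evecs = sphere_field.eigenbasis()
        assert evals[0] == pytest.approx(0.0, abs=1e-8)
        assert np.ptp(evecs[:, 0]) < 1e-6 * np.abs(evecs[:, 0]).mean() + 1e-8

    def test_identity_at_k_zero_full_basis(self, sphere_field, rng):
        g = rng.normal(size=sphere_field.surface.n_vertices)
        out = tp.lb_smooth(sphere_field, g, k=0.0)
        assert np.allclose(out, g, atol=1e-9)

    def test_constant_field_unchanged(self, sphere_field):
        g = np.full(sphere_field.surface.n_vertices, 2.5)
        for k in (0.0, 2.0, 50.0):
            assert np.allclose(tp.lb_smooth(sphere_field, g, k), 2.5, atol=1e-8)

    def test_surface_integral_preserved(self, sphere_field, rng):
        g = rng.normal(size=sphere_field.surface.n_vertices)
        w = sphere_field.vertex_masses
        out = tp.lb_smooth(sphere_field, g, k=2.0)
        assert np.sum(w * out) == pytest.approx(np.sum(w * g), rel=1e-9)

    def test_high_frequency_energy_never_increases(self, sphere_field, rng):
        g = rng.normal(size=sphere_field.surface.n_vertices)
        evals, evecs = sphere_field.eigenbasis()
        w = sphere_field.vertex_masses
        for k in (0.5, 2.0, 10.0):
            out = tp.lb_smooth(sphere_field, g, k)
            c_in = evecs.T @ (w * g)
            c_out = evecs.T @ (w * out)
            assert np.all(np.abs(c_out) <= np.abs(c_in) + 1e-12)

    def test_ratio_invariance_of_constant_density(self, sphere_field, rng):
        g_a = rng.uniform(0.5, 2.0, sphere_field.surface.n_vertices)
        c = 3.7
        g_tau = c * g_a
        dens = tp.smoothed_density(sphere_field, g_tau, g_a, k=2.0)
        assert np.allclose(dens, c, atol=1e-6)

    def test_patch_ranking_preserved_at_default_k(self, sphere_field):
        # high/low density patches (northern vs southern cap) keep their
        # ordering under the default smoothing constant
        surf = sphere_field.surface
        g_a = np.ones(surf.n_vertices)
        g_tau = np.where(surf.vertices[:, 2] > 0, 10.0, 1.0)
        dens = tp.smoothed_density(sphere_field, g_tau, g_a, k=2.0)
        north = surf.vertices[:, 2] > 2.5
        south = surf.vertices[:, 2] < -2.5
        assert dens[north].mean() > dens[south].mean()

    def test_truncated_basis_clipped(self):
        m = trimesh.creation.icosphere(subdivisions=1)
        surf = TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
        fld = tp.SurfaceField(surf, n_basis=10 * surf.n_vertices)
        evals, evecs = fld.eigenbasis()
        assert evecs.shape[1] <= surf.n_vertices


class TestChainConservation:
    def test_feature_mass_exact_through_chain(self, rng):
        # sections -> particles -> pushforward -> surface projection keeps
        # integer feature totals exactly
        mask = np.ones((24, 24), bool)
        dets = [DetectionSet(i, [Detection(*rng.uniform(2, 22, 2), 3)
                                 for _ in range(rng.integers(3, 9))], 0.25)
                for i in range(3)]
        m = tp.particles_from_sections(dets, [mask] * 3, 0.25, [0.0, 1.0, 2.0])
        total = sum(d.count for d in dets)
        assert m.total_feature == total
        pushed = tp.pushforward(m, rigid=(np.eye(3), np.array([1.0, 2, 3])))
        assert pushed.total_feature == total
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
        surf = TriSurface(np.asarray(sphere.vertices) + 3.0,
                          np.asarray(sphere.faces))
        g_tau, g_a = tp.project_to_surface(pushed, surf)
        assert g_tau.sum() == total
        assert g_a.sum() == pytest.approx(pushed.total_weight)
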