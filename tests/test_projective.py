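"""Section-to-volume registration: projection, scattering, contrast, EM,
rigid alignment, and full-stack recovery on phantoms."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from mtlmorph import projective as proj, synthetic as syn


class TestProjectVolume:
    def test_constant_volume(self):
        vol = np.full((5, 8, 8), 7.0)
        sl = proj.project_volume(vol, (1, 1, 1), (0, 0, 0), 2.3)
        assert np.allclose(sl, 7.0)

    def test_linear_ramp_interpolation_exact(self):
        vol = np.arange(6, dtype=float)[:, None, None] * np.ones((6, 4, 4))
        sl = proj.project_volume(vol, (1, 1, 1), (0, 0, 0), 3.5)
        assert np.allclose(sl, 3.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            proj.project_volume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0), 9.0)

    def test_phantom_round_trip_without_deformation(self):
        spec = syn.HistoPhantomSpec(seed=2, n_sections=3, noise_sd=0.0,
                                    densities={k: 0.0 for k in syn.REGION_IDS})
        ph = syn.generate_histology_phantom(spec)
        for n, sec in enumerate(ph.sections):
            sl = proj.project_volume(ph.intensity_volume,
                                     (spec.section_spacing, spec.pixel_size,
                                      spec.pixel_size), (0, 0, 0), sec.z_mm)
            assert np.allclose(sl, sec.image, atol=1e-12)


class TestScattering:
    def test_constant_image_channels(self):
        chans = proj.scattering_features(np.full((48, 48), 3.0))
        assert np.allclose(chans[0], 3.0)
        assert np.abs(chans[1:]).max() < 1e-8   # zero-mean wavelets

    def test_offset_invariance_of_modulus_channels(self, rng):
        img = rng.normal(0.5, 0.2, (48, 48))
        c1 = proj.scattering_features(img)
        c2 = proj.scattering_features(img + 10.0)
        assert np.allclose(c1[1:], c2[1:], atol=1e-8)

    def test_oriented_grating_maximal_in_matching_channel(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        freq = 1.0 / 4.0                   # matches the scale-1 wavelet
        horizontal = np.sin(2 * np.pi * freq * xx)   # varies along x: theta=0
        chans = proj.scattering_features(horizontal, n_orientations=4,
                                         scales=(1.0,))
        responses = [chans[1 + k][16:-16, 16:-16].mean() for k in range(4)]
        assert int(np.argmax(responses)) == 0

    def test_channel_count_reduced_bank(self):
        chans = proj.scattering_features(np.zeros((32, 32)), depth=2,
                                         n_orientations=4, scales=(1.0, 2.0))
        # 1 lowpass + 8 first order + 4 same-orientation scale pairs
        assert chans.shape[0] == 13


class TestFitContrast:
    def test_reference_equals_channel(self, rng):
        chans = np.stack([rng.normal(size=(24, 24)) for _ in range(5)])
        cp = proj.fit_contrast(chans, chans[2], n_components=5)
        assert cp.residual_norm < 1e-6
        assert np.allclose(cp.predict(chans), chans[2], atol=1e-8)

    def test_affine_combination_recovered(self, rng):
        chans = np.stack([rng.normal(size=(24, 24)) for _ in range(4)])
        ref = 2.0 * chans[1] + 3.0
        cp = proj.fit_contrast(chans, ref, n_components=4)
        assert cp.residual_norm < 1e-6
        assert np.allclose(cp.predict(chans), ref, atol=1e-7)

    def test_matches_normal_equations_residual(self, rng):
        chans = np.stack([rng.normal(size=(16, 16)) for _ in range(6)])
        ref = rng.normal(size=(16, 16))
        cp = proj.fit_contrast(chans, ref, n_components=6)
        # brute-force weighted LS on the same (full-rank) feature space
        X = np.column_stack([c.ravel() for c in chans] + [np.ones(256)])
        beta, *_ = np.linalg.lstsq(X, ref.ravel(), rcond=None)
        brute = np.linalg.norm(ref.ravel() - X @ beta)
        assert cp.residual_norm == pytest.approx(brute, rel=1e-6)


class TestEMPixelWeights:
    def test_three_plateaus_classified(self, rng):
        img = np.concatenate([rng.normal(0.1, 0.01, 400),
                              rng.normal(0.5, 0.01, 400),
                              rng.normal(0.9, 0.01, 400)]).reshape(40, 30)
        w = proj.em_pixel_weights(img)
        labels = np.argmax(w.posteriors.reshape(-1, 3), axis=1)
        truth = np.repeat([0, 1, 2], 400)
        assert np.mean(labels == truth) > 0.99

    def test_loglik_nondecreasing(self, rng):
        img = rng.normal(0.5, 0.2, (32, 32))
        w = proj.em_pixel_weights(img)
        assert np.all(np.diff(w.log_likelihood_trace) >= -1e-6)

    def test_constant_image_degenerate_uniform(self):
        w = proj.em_pixel_weights(np.full((16, 16), 0.4))
        assert np.all(np.isfinite(w.posteriors))
        assert np.allclose(w.posteriors, 1.0 / 3.0, atol=0.05)

    def test_posteriors_sum_to_one(self, rng):
        w = proj.em_pixel_weights(rng.uniform(0, 1, (20, 20)))
        assert np.allclose(w.posteriors.sum(axis=-1), 1.0)

    def test_phantom_foreground_identified(self):
        ph = syn.generate_histology_phantom(syn.HistoPhantomSpec(seed=1, n_sections=1))
        w = proj.em_pixel_weights(ph.sections[0].image)
        tissue = ph.label_volume[0] > 0
        interior = ndi.binary_erosion(tissue, iterations=3)
        assert w.foreground[interior].mean() > 0.6
        blobs = ph.blob_table
        at_blobs = w.foreground[np.round(blobs.y_px).astype(int),
                                np.round(blobs.x_px).astype(int)]
        assert at_blobs.mean() < 0.4        # tangles are not foreground tissue


class TestRigidAlign:
    @pytest.fixture(scope="class")
    def smooth_volume(self):
        rng = np.random.default_rng(0)
        return ndi.gaussian_filter(rng.normal(size=(32, 32, 32)), 3.0)

    def test_rotation_recovered(self, smooth_volume):
        ang = np.deg2rad(10)
        R = proj._rot(ang, 2)
        center = (np.array(smooth_volume.shape) - 1) / 2
        rot = ndi.affine_transform(smooth_volume, R, offset=center - R @ center,
                                   order=1, mode="nearest")
        res = proj.rigid_align(smooth_volume, rot, mode="volume")
        # recovered transform undoes the applied rotation
        assert abs(abs(np.rad2deg(res["params"][2])) - 10) < 0.5
        assert res["correlation"] > 0.99

    def test_translation_recovered(self, smooth_volume):
        moved = ndi.shift(smooth_volume, (3, 1, 2), order=1, mode="nearest")
        res = proj.rigid_align(smooth_volume, moved, mode="volume")
        assert np.allclose(res["translation"], [3, 1, 2], atol=0.1)

    def test_identity_for_identical_inputs(self, smooth_volume):
        res = proj.rigid_align(smooth_volume, smooth_volume, mode="volume")
        assert np.allclose(res["params"], 0.0, atol=1e-4)

    def test_surfaces_icp(self, small_sphere):
        moved = small_sphere.vertices + np.array([0.5, -0.3, 0.2])
        res = proj.rigid_align(small_sphere.vertices, moved, mode="surface")
        recovered = moved @ res["rotation"].T + res["translation"]
        assert np.abs(recovered - small_sphere.vertices).max() < 0.05

    def test_contrastless_volume_rejected(self):
        with pytest.raises(ValueError):
            proj.rigid_align(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)))


class TestRegisterStack:
    @pytest.fixture(scope="class")
    def phantom(self):
        spec = syn.HistoPhantomSpec(seed=1, n_sections=3, image_shape=(96, 96),
                                    deformation_mm=0.05)
        return spec, syn.generate_histology_phantom(spec)

    def test_known_deformation_recovered_subpixel(self, phantom):
        spec, ph = phantom
        spacing = (spec.section_spacing, spec.pixel_size, spec.pixel_size)
        reg = proj.register_stack(ph.intensity_volume, spacing, (0, 0, 0),
                                  ph.sections, outer_rounds=4,
                                  slice_iterations=40)
        # objective non-increasing across outer rounds
        assert all(b <= a + 1e-9 for a, b in zip(reg.objective_trace,
                                                 reg.objective_trace[1:]))
        for n in range(len(ph.sections)):
            est = reg.slice_maps[n].displacement(ph.sections[n].image.shape)
            true = ph.true_displacements_px[n]
            tissue = ph.label_volume[n] > 0
            rms = np.sqrt(np.mean(np.sum((est - true)[tissue] ** 2, axis=-1)))
            assert rms < 1.0
            assert reg.slice_maps[n].jacobian_positive(ph.sections[n].image.shape)

    def test_unwarped_matching_contrast_near_identity(self):
        spec = syn.HistoPhantomSpec(seed=3, n_sections=2, image_shape=(64, 64),
                                    deformation_mm=0.0, noise_sd=0.002,
                                    densities={k: 0.0 for k in syn.REGION_IDS})
        ph = syn.generate_histology_phantom(spec)
        spacing = (spec.section_spacing, spec.pixel_size, spec.pixel_size)
        reg = proj.register_stack(ph.intensity_volume, spacing, (0, 0, 0),
                                  ph.sections, outer_rounds=2,
                                  slice_iterations=20, use_scattering=False,
                                  use_em_weights=False)
        for m in reg.slice_maps:
            disp = m.displacement((64, 64))
            assert np.sqrt((disp ** 2).sum(-1)).mean() < 0.2

    def test_em_weighting_near_neutral_without_artifacts(self, phantom):
        # artifact-free, matched-contrast stack: weighting changes the final
        # objective by < 5 % relative to unweighted on tissue
        spec = syn.HistoPhantomSpec(seed=5, n_sections=2, image_shape=(64, 64),
                                    densities={k: 0.0 for k in syn.REGION_IDS})
        ph = syn.generate_histology_phantom(spec)
        spacing = (spec.section_spacing, spec.pixel_size, spec.pixel_size)
        kw = dict(outer_rounds=2, slice_iterations=15, use_scattering=False)
        r_w = proj.register_stack(ph.intensity_volume, spacing, (0, 0, 0),
                                  ph.sections, use_em_weights=True, **kw)
        r_u = proj.register_stack(ph.intensity_volume, spacing, (0, 0, 0),
                                  ph.sections, use_em_weights=False, **kw)
        # compare unweighted residual of both solutions on tissue pixels
        def unweighted_obj(reg):
            total = 0.0
            for n, sec in enumerate(ph.sections):
                sm = reg.slice_maps[n].sampling_map(sec.image.shape)
                tpl = proj.project_volume(ph.intensity_volume, spacing,
                                          (0, 0, 0), sec.z_mm)
                warped = ndi.map_coordinates(tpl, np.moveaxis(sm, -1, 0),
                                             order=1, mode="nearest")
                tissue = ph.label_volume[n] > 0
                total += float(np.sum((sec.image - warped)[tissue] ** 2))
            return total

        # with nothing to suppress, both solutions reach the additive-noise
        # floor and the estimated maps are interchangeable
        n_tissue = sum(int((ph.label_volume[n] > 0).sum())
                       for n in range(len(ph.sections)))
        floor = spec.noise_sd ** 2 * n_tissue
        assert unweighted_obj(r_w) < 2.5 * floor
        assert unweighted_obj(r_u) < 2.5 * floor
        for mw, mu in zip(r_w.slice_maps, r_u.slice_maps):
            dd = mw.displacement((64, 64)) - mu.displacement((64, 64))
            assert np.sqrt((dd ** 2).sum(-1)).mean() < 0.5

    def test_single_section_rejected(self, phantom):
        spec, ph = phantom
        with pytest.raises(ValueError):
            proj.register_stack(ph.intensity_volume,
                                (spec.section_spacing, spec.pixel_size,
                                 spec.pixel_size), (0, 0, 0),
                                proj.SectionStack(ph.sections[:1]))
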