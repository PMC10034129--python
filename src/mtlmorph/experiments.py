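"""Parameter-recovery and error-control experiments on synthetic data.

These are the package's headline validation studies: familywise-error
calibration of the permutation test, cohort-level recovery of group atrophy
rates by the full longitudinal pipeline, staining-scale calibration recovery,
and recovery of the histology arm's deformations and densities on section
phantoms.  All randomness derives from a single integer seed.
"""

from __future__ import annotations

import time
import numpy as np
from scipy import ndimage as _ndi
from scipy.stats import spearmanr

from . import longitudinal as _long
from . import nft as _nft
from . import projective as _proj
from . import stats as _stats
from . import synthetic as _syn
from . import transport as _trans
from .pipeline import dice_score
from .surface import mesh_from_mask, surface_volume


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1000 + k) % (2 ** 31)


# ---------------------------------------------------------------------------
# familywise error calibration


def fwer_study(seed: int, n_replicates: int = 200, n_subjects: int = 34,
               n_vertices: int = 200, n_perm: int = 500,
               alpha: float = 0.05) -> dict:
    """Empirical FWER of the residual-permutation max-statistic test.

    Per-vertex Gaussian markers are simulated with intercept, sex, age and
    log-ICV effects, spatially correlated noise, and no group effect; the
    fraction of replicates with a nonempty significant set estimates the
    realized familywise error at the nominal level.
    """
    idx = np.arange(n_vertices)
    cov = 0.09 * np.exp(-np.abs(np.subtract.outer(idx, idx)) / 10.0)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_vertices))
    rejections = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng([_sub_seed(seed, 1), rep])
        sex = rng.integers(0, 2, n_subjects).astype(float)
        icv = rng.normal(14.2, 0.12, n_subjects)
        age = rng.normal(72.0, 5.0, n_subjects)
        group = np.zeros(n_subjects)
        group[: n_subjects // 2] = 1.0
        base = 0.05 - 0.02 * sex + 0.3 * (icv - 14.2) - 0.004 * (age - 72.0)
        noise = rng.normal(size=(n_subjects, n_vertices)) @ chol.T
        mm = _stats.MarkerMatrix(base[:, None] + noise, sex, icv, age, group)
        res = _stats.permutation_fwer(mm, n_perm=n_perm, seed=rep, alpha=alpha)
        if res.significant.any():
            rejections += 1
    return {"fwer": rejections / n_replicates, "n_replicates": n_replicates,
            "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates))}


# ---------------------------------------------------------------------------
# longitudinal rate recovery


GROUP_ROWS = {
    # (structure, mean, sd) from the three-group atrophy-rate table
    "amygdala_mci_dat": ("amygdala", 11.6, 5.8),
    "amygdala_cu_cu": ("amygdala", 1.5, 2.0),
    "amygdala_cu_mci": ("amygdala", 6.8, 4.1),
    "erc_mci_dat": ("erc_tec", 7.0, 3.4),
    "erc_cu_cu": ("erc_tec", 1.1, 1.6),
    "erc_cu_mci": ("erc_tec", 3.8, 1.9),
}


def rate_recovery_study(row: str, seed: int, n_subjects: int = 12,
                        n_scans: int = 4, period_years: float = 2.0,
                        max_iter: int = 25, register_max_iter: int = 15,
                        verbose: bool = False) -> dict:
    """Cohort-mean atrophy-rate recovery by the full longitudinal pipeline.

    Generates a single-group cohort whose true per-subject rates are drawn
    (antithetically, so the drawn cohort mean equals the specified mean) from
    the named group row, fits every subject by longitudinal geodesic
    shooting, and reports the cohort mean of the per-subject least-squares
    percent rates.
    """
    structure, mean, sd = GROUP_ROWS[row]
    noise = 0.05 if structure == "amygdala" else 0.03
    spec = _syn.CohortSpec(
        groups={"G": _syn.GroupSpec(n_subjects, mean, sd)},
        structure=structure, scans_range=(n_scans, n_scans),
        period_range=(period_years, period_years), noise_level=noise,
        seed=_sub_seed(seed, 2 + list(GROUP_ROWS).index(row)),
        rate_sampling="antithetic")
    cohort = _syn.generate_longitudinal_cohort(spec)
    params = _syn.cohort_kernel_params(cohort)
    measure_fn = (surface_volume if structure == "amygdala"
                  else _syn.sheet_thickness_measure)
    fitted, truth = [], []
    for sub in cohort.subjects:
        t0 = time.time()
        series = _long.SeriesInput(sub.subject_id, sub.times_years,
                                   sub.surfaces, cohort.hypertemplate)
        traj = _long.fit_series(series, params, measure_fn=measure_fn,
                                n_substeps=1, max_iter=max_iter,
                                register_max_iter=register_max_iter)
        rate = _long.subject_rate(traj.fitted_measures, traj.times_years)
        fitted.append(rate)
        truth.append(sub.true_rate)
        if verbose:
            print(f"  {sub.subject_id}: true {sub.true_rate:6.2f} "
                  f"fitted {rate:6.2f} ({time.time() - t0:.0f}s)", flush=True)
    fitted = np.asarray(fitted)
    truth = np.asarray(truth)
    return {"estimated_mean": float(fitted.mean()),
            "generating_mean": mean,
            "drawn_mean": float(truth.mean()),
            "per_subject_error": (fitted - truth).tolist(),
            "n_subjects": n_subjects}


# ---------------------------------------------------------------------------
# staining-scale calibration recovery


def calibration_study(seed: int, scale_factor: float = 2.7) -> dict:
    """Original/replicate detection-count ratio on a thinned phantom pair."""
    base, repl = _syn.calibration_phantom_specs(_sub_seed(seed, 9),
                                                scale_factor=scale_factor)
    ph_o = _syn.generate_histology_phantom(base)
    ph_r = _syn.generate_histology_phantom(repl)

    def counts(ph):
        return [_nft.instance_segment(_nft.probability_map(s),
                                      s.pixel_size, i).count
                for i, s in enumerate(ph.sections)]

    orig, rep = counts(ph_o), counts(ph_r)
    return {"ratio": _nft.replicate_ratio(orig, rep),
            "injected": scale_factor,
            "original_counts": orig, "replicate_counts": rep,
            "n_sections": len(orig)}


# ---------------------------------------------------------------------------
# histology-arm end-to-end recovery


def histology_recovery_study(seed: int, n_sections: int = 5,
                             image_shape=(96, 96), deformation_mm: float = 0.05,
                             outer_rounds: int = 4,
                             slice_iterations: int = 40) -> dict:
    """Registration, overlap, and density-map recovery on a section phantom.

    Reports per-slice RMS displacement error (px at working resolution),
    per-region Dice between mapped 3D labels and ground-truth 2D labels, and
    the rank correlation between the smoothed surface density and the planted
    rostral-high truth.
    """
    spec = _syn.HistoPhantomSpec(seed=_sub_seed(seed, 10),
                                 n_sections=n_sections,
                                 image_shape=image_shape,
                                 deformation_mm=deformation_mm,
                                 density_axial_gradient=1.5)
    ph = _syn.generate_histology_phantom(spec)
    ny, nx = image_shape
    spacing = (spec.section_spacing, spec.pixel_size, spec.pixel_size)
    reg = _proj.register_stack(ph.intensity_volume, spacing, (0, 0, 0),
                               ph.sections, outer_rounds=outer_rounds,
                               slice_iterations=slice_iterations)

    rms, dices = [], []
    gy, gx = np.mgrid[0:ny, 0:nx].astype(float)
    for n in range(n_sections):
        est_disp = reg.slice_maps[n].displacement((ny, nx))
        tissue = ph.label_volume[n] > 0
        err = est_disp - ph.true_displacements_px[n]
        rms.append(float(np.sqrt(np.mean(np.sum(err[tissue] ** 2, axis=-1)))))
        est_map = reg.slice_maps[n].sampling_map((ny, nx))
        mapped3d = _ndi.map_coordinates(ph.label_volume[n].astype(float),
                                        np.moveaxis(est_map, -1, 0), order=0)
        true_map = np.stack([gy + ph.true_displacements_px[n][..., 0],
                             gx + ph.true_displacements_px[n][..., 1]])
        true2d = _ndi.map_coordinates(ph.label_volume[n].astype(float),
                                      true_map, order=0)
        for rid in ph.region_ids.values():
            dices.append(dice_score(mapped3d == rid, true2d == rid))

    # detection -> particles -> surface density against the planted gradient
    dets, masks = [], []
    for i, s in enumerate(ph.sections):
        dets.append(_nft.instance_segment(_nft.probability_map(s),
                                          s.pixel_size, i))
        masks.append(_nft.foreground_mask(s)[0])
    zs = [s.z_mm for s in ph.sections]
    measure = _trans.particles_from_sections(dets, masks, spec.pixel_size, zs,
                                             cell_px=8)

    def region_of(p):
        iz = int(np.clip(round(p[2] / spec.section_spacing), 0, n_sections - 1))
        iy = int(np.clip(round(p[1] / spec.pixel_size), 0, ny - 1))
        ix = int(np.clip(round(p[0] / spec.pixel_size), 0, nx - 1))
        return ph.label_volume[iz, iy, ix]

    regions = np.array([region_of(p) for p in measure.positions])
    amy = ph.region_ids["amygdala"]
    surf = mesh_from_mask(ph.label_volume.transpose(2, 1, 0),
                          spacing=(spec.pixel_size, spec.pixel_size,
                                   spec.section_spacing),
                          label=amy, target_vertices=None, smooth_iterations=5)
    g_tau, g_a = _trans.project_to_surface(measure, surf,
                                           region_mask=regions == amy)
    fld = _trans.SurfaceField(surf, n_basis=80)
    dens = _trans.smoothed_density(fld, g_tau, g_a, k=2.0)
    zmax = (n_sections - 1) * spec.section_spacing
    z_frac = surf.vertices[:, 2] / max(zmax, 1e-12)
    true_dens = ph.densities["amygdala"] * np.maximum(
        1.0 - spec.density_axial_gradient * (z_frac - 0.5), 0.0)
    rho = float(spearmanr(dens, true_dens)[0])
    return {"rms_px": rms, "dice_min": float(np.min(dices)),
            "dice_mean": float(np.mean(dices)),
            "surface_rank_corr": rho,
            "n_sections": n_sections}
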