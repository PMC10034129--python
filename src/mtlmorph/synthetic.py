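"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* a longitudinal cohort of triangulated surfaces (superellipsoid "amygdala"
  phantoms for volume structures; paired laminar sheets for thickness
  structures) whose ground-truth percent atrophy rates are drawn per subject
  from group-specific distributions, with covariates;
* a serial-section histology phantom: a companion 3D volume sliced at known
  z-positions, warped in-plane by known smooth deformations, carrying
  compact bright blobs ("tangles") at region-specific Poisson densities,
  staining-scale differences, and artifact regions.

All randomness flows from one integer seed; per-subject/per-section
substreams are derived by counter so generation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .surface import TriSurface, surface_volume, thickness
from .projective import SectionImage, SectionStack

# sheet vertex-label convention: odd = inner sheet, even = outer sheet
INNER_ERC, OUTER_ERC, INNER_TEC, OUTER_TEC = 1, 2, 3, 4


# ---------------------------------------------------------------------------
# cohort specification


@dataclass
class GroupSpec:
    """One diagnostic group: size and true atrophy-rate distribution (%/year)."""

    n: int
    rate_mean: float
    rate_sd: float
    age_mean: float = 72.3
    age_sd: float = 5.5
    sex_female_prop: float = 0.5
    log_icv_mean: float = 14.2
    log_icv_sd: float = 0.12

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group sizes must be at least 2")
        if self.rate_sd < 0:
            raise ValueError("rate SD must be nonnegative")


@dataclass
class CohortSpec:
    """Synthetic longitudinal cohort specification.

    Defaults reproduce the study conditions of the three-group design:
    group sizes 33/16/18 with amygdala volume-loss rates 1.5+/-2.0,
    6.8+/-4.1 and 11.6+/-5.8 %/year (or entorhinal thickness rates
    1.1+/-1.6, 3.8+/-1.9, 7.0+/-3.4 %/year for the sheet structure).
    """

    groups: Dict[str, GroupSpec]
    structure: str = "amygdala"           # "amygdala" (volume) | "erc_tec" (thickness)
    scans_range: Tuple[int, int] = (3, 5)
    period_range: Tuple[float, float] = (1.0, 3.0)
    noise_level: float = 0.05             # fraction of structure scale
    seed: int = 0
    mesh_subdivisions: int = 3
    semi_axes: Tuple[float, float, float] = (9.0, 6.0, 5.0)   # mm
    superell_exponent: float = 2.5
    atrophy_weight_amplitude: float = 0.0  # spatial (medial>lateral) weighting
    subject_scale_sd: float = 0.05
    sheet_size: Tuple[float, float] = (14.0, 10.0)   # mm
    sheet_grid: Tuple[int, int] = (12, 9)
    sheet_thickness: float = 2.5           # mm
    sheet_curvature: float = 0.015         # 1/mm
    rate_sampling: str = "iid"             # "iid" | "antithetic"

    def __post_init__(self):
        if self.rate_sampling not in ("iid", "antithetic"):
            raise ValueError("rate_sampling must be 'iid' or 'antithetic'")
        if self.structure not in ("amygdala", "erc_tec"):
            raise ValueError("structure must be 'amygdala' or 'erc_tec'")
        if self.scans_range[0] < 3 or self.scans_range[1] > 7 \
                or self.scans_range[0] > self.scans_range[1]:
            raise ValueError("scans-per-subject range must lie in 3..7")
        if self.period_range[0] <= 0 or self.period_range[0] > self.period_range[1]:
            raise ValueError("invalid scan-period range")
        if self.noise_level < 0:
            raise ValueError("noise level must be nonnegative")

    @classmethod
    def amygdala_three_group(cls, **kw) -> "CohortSpec":
        groups = {
            "CU-CU": GroupSpec(33, 1.5, 2.0, age_mean=72.3, age_sd=5.5,
                               sex_female_prop=0.455),
            "CU-MCI": GroupSpec(16, 6.8, 4.1, age_mean=74.6, age_sd=5.2,
                                sex_female_prop=0.75),
            "MCI-DAT": GroupSpec(18, 11.6, 5.8, age_mean=72.8, age_sd=6.6,
                                 sex_female_prop=0.611),
        }
        return cls(groups=groups, structure="amygdala", **kw)

    @classmethod
    def erc_tec_three_group(cls, **kw) -> "CohortSpec":
        groups = {
            "CU-CU": GroupSpec(33, 1.1, 1.6, age_mean=72.3, age_sd=5.5,
                               sex_female_prop=0.455),
            "CU-MCI": GroupSpec(16, 3.8, 1.9, age_mean=74.6, age_sd=5.2,
                                sex_female_prop=0.75),
            "MCI-DAT": GroupSpec(18, 7.0, 3.4, age_mean=72.8, age_sd=6.6,
                                 sex_female_prop=0.611),
        }
        return cls(groups=groups, structure="erc_tec", **kw)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    times_years: np.ndarray
    surfaces: List[TriSurface]
    true_rate: float              # % loss per year (positive = loss)
    sex: int
    age: float
    log_icv: float


@dataclass
class Cohort:
    subjects: List[SubjectRecord]
    hypertemplate: TriSurface
    covariates: pd.DataFrame
    truth: pd.DataFrame
    structure: str


def cohort_kernel_params(cohort: "Cohort"):
    """Structure-appropriate kernel widths: laminar sheets need a matching
    kernel narrower than the inter-sheet separation to resolve thickness."""
    from .lddmm import KernelParams
    frac = 0.05 if cohort.structure == "erc_tec" else 0.1
    return KernelParams.for_surface(cohort.hypertemplate, sigma_w_frac=frac)


# ---------------------------------------------------------------------------
# base phantoms


def superellipsoid_surface(semi_axes=(9.0, 6.0, 5.0), exponent=2.5,
                           subdivisions=3) -> TriSurface:
    """Star-shaped superellipsoid mesh from a radially mapped icosphere."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    u = np.asarray(ico.vertices)
    a = np.asarray(semi_axes, float)
    p = float(exponent)
    r = np.sum(np.abs(u / a) ** p, axis=1) ** (-1.0 / p)
    return TriSurface(u * r[:, None], np.asarray(ico.faces))


def laminar_sheets(size=(14.0, 10.0), grid=(12, 9), thickness_mm=2.5,
                   curvature=0.015) -> TriSurface:
    """Two offset gently curved sheets with exact vertex correspondence.

    Inner sheet z = curvature * rho^2; outer sheet offset along the inner
    vertex normals by the requested thickness.  Vertex labels encode sheet
    membership (odd=inner, even=outer) and region (ERC for x below midline,
    TEC above).
    """
    lx, ly = size
    nx, ny = grid
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = curvature * ((X - lx / 2) ** 2 + (Y - ly / 2) ** 2)
    inner = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    faces = np.asarray(faces)
    inner_surf = TriSurface(inner, faces)
    normals = inner_surf.vertex_normals()
    # orient normals consistently upward
    sgn = np.sign(normals[:, 2])
    sgn[sgn == 0] = 1.0
    normals *= sgn[:, None]
    outer = inner + thickness_mm * normals
    n = len(inner)
    verts = np.vstack([inner, outer])
    all_faces = np.vstack([faces, faces[:, ::-1] + n])
    erc = inner[:, 0] < lx / 2
    labels = np.empty(2 * n, dtype=np.int64)
    labels[:n] = np.where(erc, INNER_ERC, INNER_TEC)
    labels[n:] = np.where(erc, OUTER_ERC, OUTER_TEC)
    return TriSurface(verts, all_faces, vertex_labels=labels)


def split_sheets(surface: TriSurface) -> Tuple[TriSurface, TriSurface]:
    """Split a combined laminar surface into (inner, outer) sheets."""
    if surface.vertex_labels is None:
        raise ValueError("combined sheet surface requires vertex labels")
    lab = surface.vertex_labels
    inner_sel = lab % 2 == 1

    def extract(sel):
        idx = np.flatnonzero(sel)
        remap = -np.ones(surface.n_vertices, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        fsel = np.all(sel[surface.faces], axis=1)
        return TriSurface(surface.vertices[idx], remap[surface.faces[fsel]],
                          vertex_labels=lab[idx])

    return extract(inner_sel), extract(~inner_sel)


def sheet_thickness_measure(surface: TriSurface, method: str = "normal_flow") -> float:
    """Composite ERC+TEC mean thickness of a combined laminar surface."""
    inner, outer = split_sheets(surface)
    tf = thickness(inner, outer, method=method)
    means = []
    for inner_lab in (INNER_ERC, INNER_TEC):
        sel = inner.vertex_labels == inner_lab
        if np.any(sel):
            means.append(float(np.mean(tf.thickness[sel])))
    return float(np.mean(means))


# ---------------------------------------------------------------------------
# longitudinal cohort generation


def _medial_weight(base: TriSurface, amplitude: float) -> np.ndarray:
    """Spatial atrophy weights: medial (negative-x) side atrophies more."""
    if amplitude == 0:
        return np.ones(base.n_vertices)
    c = base.vertices.mean(0)
    u = base.vertices[:, 0] - c[0]
    u = u / max(np.abs(u).max(), 1e-12)
    return 1.0 - amplitude * u    # amplitude in [0, 1): medial > lateral


def _radial_shrink(base: TriSurface, weight: np.ndarray,
                   volume_factor: float) -> np.ndarray:
    """Vertices of the base shrunk radially (about the centroid, weighted) so
    that the enclosed volume is ``volume_factor`` times the base volume."""
    c = base.vertices.mean(0)
    rel = base.vertices - c

    def verts(a):
        return c + rel * (1.0 - a * weight[:, None])

    if np.allclose(weight, weight[0]):
        a = 1.0 - volume_factor ** (1.0 / 3.0) / weight[0] if weight[0] else 0.0
        return verts(a)
    v0 = surface_volume(base)

    def f(a):
        return surface_volume(base.with_vertices(verts(a))) / v0 - volume_factor

    a = brentq(f, -0.5, 0.9, xtol=1e-12)
    return verts(a)


def generate_longitudinal_cohort(spec: CohortSpec) -> Cohort:
    """Generate per-subject surface time-series with known atrophy rates.

    The measured quantity (enclosed volume for the amygdala phantom; composite
    sheet thickness for the laminar phantom) declines linearly in time at the
    subject's drawn rate, so the percent-change-per-year formula and the OLS
    rate both recover the drawn rate exactly in the noiseless case.
    """
    if spec.structure == "amygdala":
        template = superellipsoid_surface(spec.semi_axes, spec.superell_exponent,
                                          spec.mesh_subdivisions)
    else:
        template = laminar_sheets(spec.sheet_size, spec.sheet_grid,
                                  spec.sheet_thickness, spec.sheet_curvature)
    weight = _medial_weight(template, spec.atrophy_weight_amplitude)
    subjects: List[SubjectRecord] = []
    rows = []
    counter = 0
    for g_index, (gname, g) in enumerate(spec.groups.items()):
        if spec.rate_sampling == "antithetic":
            # paired +/- draws about the group mean: each rate is still
            # marginally Normal(mean, sd), but the cohort's drawn mean equals
            # the specified mean exactly (for even group sizes), so recovery
            # experiments measure pipeline error rather than draw noise
            grng = np.random.default_rng([spec.seed % (2 ** 31),
                                          777000 + g_index])
            eps = grng.normal(0.0, g.rate_sd, (g.n + 1) // 2)
            paired = np.stack([g.rate_mean + eps, g.rate_mean - eps],
                              axis=1).ravel()[: g.n]
            group_rates = paired
        else:
            group_rates = None
        for j in range(g.n):
            rng = np.random.default_rng([spec.seed % (2 ** 31), counter])
            sid = f"{gname}_{j:03d}"
            rate = (float(group_rates[j]) if group_rates is not None
                    else float(rng.normal(g.rate_mean, g.rate_sd)))
            k = int(rng.integers(spec.scans_range[0], spec.scans_range[1] + 1))
            period = float(rng.uniform(*spec.period_range))
            times = np.linspace(0.0, period, k)
            if k > 2:
                jitter = rng.uniform(-0.2, 0.2, k - 2) * (period / (k - 1))
                times[1:-1] += jitter
            times = np.sort(times)
            scale = float(rng.normal(1.0, spec.subject_scale_sd))
            sex = int(rng.random() < g.sex_female_prop)
            age = float(rng.normal(g.age_mean, g.age_sd))
            licv = float(rng.normal(g.log_icv_mean, g.log_icv_sd))
            surfaces = []
            for t in times:
                factor = 1.0 - rate * t / 100.0
                if factor <= 0.05:
                    factor = 0.05
                if spec.structure == "amygdala":
                    base = template.with_vertices(template.vertices * scale)
                    v = _radial_shrink(base, weight, factor)
                    noise_scale = np.linalg.norm(
                        base.vertices - base.vertices.mean(0), axis=1).mean()
                    s = TriSurface(v, template.faces.copy())
                else:
                    s = _sheet_at_thickness(spec, scale, factor)
                    noise_scale = spec.sheet_thickness * scale
                if spec.noise_level > 0:
                    s = s.with_vertices(
                        s.vertices + rng.normal(
                            0.0, spec.noise_level * noise_scale, s.vertices.shape))
                if spec.structure == "erc_tec":
                    s.vertex_labels = template.vertex_labels.copy()
                surfaces.append(s)
            subjects.append(SubjectRecord(sid, gname, times, surfaces, rate,
                                          sex, age, licv))
            rows.append(dict(subject_id=sid, group=gname, true_rate=rate,
                             n_scans=k, period_years=period, sex=sex, age=age,
                             log_icv=licv))
            counter += 1
    df = pd.DataFrame(rows)
    covariates = df[["subject_id", "group", "sex", "age", "log_icv"]].copy()
    truth = df[["subject_id", "group", "true_rate", "n_scans", "period_years"]].copy()
    return Cohort(subjects, template, covariates, truth, spec.structure)


def _sheet_at_thickness(spec: CohortSpec, scale: float, factor: float) -> TriSurface:
    s = laminar_sheets(tuple(np.asarray(spec.sheet_size) * scale), spec.sheet_grid,
                       spec.sheet_thickness * scale * factor,
                       spec.sheet_curvature / scale)
    return s


# ---------------------------------------------------------------------------
# histology phantom


@dataclass
class HistoPhantomSpec:
    """Serial-section phantom specification.

    Sections are slices of a companion volume at ~1 mm spacing, warped by
    known smooth in-plane deformations, with blob "tangles" at region-specific
    Poisson densities (counts per mm^2 of tissue).
    """

    n_sections: int = 6
    section_spacing: float = 1.0          # mm
    pixel_size: float = 0.032             # mm (working registration resolution)
    image_shape: Tuple[int, int] = (128, 128)
    densities: Dict[str, float] = field(default_factory=lambda: {
        "amygdala": 12.0, "erc": 8.0, "ca1": 4.0, "subiculum": 2.0})
    deformation_mm: float = 0.0
    staining_scale: float = 1.0           # multiplies blob/tissue contrast
    blob_thinning: float = 1.0            # keep each blob with prob 1/thinning
    density_axial_gradient: float = 0.0   # rostral-high multiplier slope along z
    artifact_fraction: float = 0.0
    blob_sigma_px: float = 1.2
    blob_amplitude: float = 0.45
    tissue_intensity: float = 0.55
    background_intensity: float = 0.12
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_sections < 1 or self.section_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("invalid sectioning geometry")
        if any(d < 0 for d in self.densities.values()):
            raise ValueError("densities must be nonnegative")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact fraction must lie in [0, 1]")
        if self.blob_thinning < 1.0:
            raise ValueError("blob_thinning must be >= 1")


REGION_IDS = {"amygdala": 1, "erc": 2, "ca1": 3, "subiculum": 4}


@dataclass
class HistoPhantom:
    sections: SectionStack
    label_volume: np.ndarray              # (nz, ny, nx) region ids
    intensity_volume: np.ndarray          # (nz, ny, nx) blob-free tissue contrast
    true_displacements_px: List[np.ndarray]   # (ny, nx, 2) sampling maps y+u
    blob_table: pd.DataFrame              # true blob coordinates and regions
    artifact_masks: List[np.ndarray]
    densities: Dict[str, float]
    true_density_table: Optional[pd.DataFrame] = None  # per section x region
    region_ids: Dict[str, int] = field(default_factory=lambda: dict(REGION_IDS))


def _region_labels(shape, pixel_size, z_frac) -> np.ndarray:
    """Four phantom compartments inside an elliptical tissue cross-section."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ry = 0.42 * ny * (0.85 + 0.3 * z_frac)
    rx = 0.40 * nx * (0.9 + 0.2 * z_frac)
    tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=np.int64)
    upper, left = yy < cy, xx < cx
    labels[tissue & upper & left] = REGION_IDS["amygdala"]
    labels[tissue & upper & ~left] = REGION_IDS["erc"]
    labels[tissue & ~upper & left] = REGION_IDS["ca1"]
    labels[tissue & ~upper & ~left] = REGION_IDS["subiculum"]
    return labels


def _smooth_displacement(shape, magnitude_px, rng) -> np.ndarray:
    """Smooth random in-plane displacement field with RMS ~ magnitude_px."""
    if magnitude_px <= 0:
        return np.zeros(shape + (2,))
    u = rng.normal(size=shape + (2,))
    for d in range(2):
        u[..., d] = ndi.gaussian_filter(u[..., d], sigma=min(shape) / 8.0)
    rms = np.sqrt(np.mean(np.sum(u ** 2, axis=-1)))
    return u * (magnitude_px / max(rms, 1e-12))


def generate_histology_phantom(spec: HistoPhantomSpec) -> HistoPhantom:
    """Render a serial-section stack with complete ground truth."""
    ny, nx = spec.image_shape
    nz = spec.n_sections
    label_volume = np.stack([
        _region_labels((ny, nx), spec.pixel_size, z / max(nz - 1, 1))
        for z in range(nz)])
    intensity_volume = np.where(
        label_volume > 0,
        spec.tissue_intensity + 0.03 * label_volume,
        spec.background_intensity).astype(float)
    # soften tissue/region edges in-plane so slices carry no blob-scale band
    # energy, and add smooth intra-tissue texture (real tissue is not flat;
    # the texture travels with the warp and is what registration locks onto);
    # the companion volume stores the final contrast so that a
    # zero-deformation section equals its volume slice exactly
    vol_rng = np.random.default_rng([spec.seed % (2 ** 31), 999983])
    for n in range(nz):
        intensity_volume[n] = ndi.gaussian_filter(intensity_volume[n], 2.0)
        texture = ndi.gaussian_filter(vol_rng.normal(size=(ny, nx)), 5.0)
        texture *= 0.08 / max(texture.std(), 1e-12)
        intensity_volume[n] += texture * (label_volume[n] > 0)

    sections = []
    disp_list, blob_rows, artifact_masks, dens_rows = [], [], [], []
    area_px = spec.pixel_size ** 2
    for n in range(nz):
        rng = np.random.default_rng([spec.seed % (2 ** 31), n])
        labels = label_volume[n]
        plane = intensity_volume[n].copy()

        # artifact regions: out-of-model bright patches over tissue
        art = np.zeros((ny, nx), dtype=bool)
        if spec.artifact_fraction > 0:
            tissue_px = int((labels > 0).sum())
            target = spec.artifact_fraction * tissue_px
            yy, xx = np.mgrid[0:ny, 0:nx]
            while art.sum() < target:
                cy0 = rng.uniform(0, ny)
                cx0 = rng.uniform(0, nx)
                r = rng.uniform(0.04, 0.1) * min(ny, nx)
                art |= ((yy - cy0) ** 2 + (xx - cx0) ** 2 <= r * r) & (labels > 0)
            soft = ndi.gaussian_filter(art.astype(float), 2.0)
            plane = plane * (1 - soft) + 0.95 * soft

        # plant blobs at Poisson counts per region; an optional axial
        # gradient makes early (rostral) sections denser
        z_frac = n / max(nz - 1, 1)
        axial = max(1.0 - spec.density_axial_gradient * (z_frac - 0.5), 0.0)
        for rname, dens in spec.densities.items():
            rid = REGION_IDS[rname]
            mask = labels == rid
            n_px = int(mask.sum())
            dens_rows.append(dict(section=n, region=rname,
                                  true_density=dens * axial))
            if n_px == 0 or dens <= 0:
                continue
            lam = dens * axial * n_px * area_px
            count = rng.poisson(lam)
            if spec.blob_thinning > 1.0:
                count = rng.binomial(count, 1.0 / spec.blob_thinning)
            if count == 0:
                continue
            idx = np.flatnonzero(mask.ravel())
            pick = rng.choice(idx, size=count)
            py, px = np.unravel_index(pick, mask.shape)
            py = py + rng.uniform(-0.5, 0.5, count)
            px = px + rng.uniform(-0.5, 0.5, count)
            for yy0, xx0 in zip(py, px):
                _stamp_gaussian(plane, yy0, xx0, spec.blob_sigma_px,
                                spec.blob_amplitude * spec.staining_scale)
                blob_rows.append(dict(section=n, region=rname, y_px=yy0,
                                      x_px=xx0, z_mm=n * spec.section_spacing))

        # render the section: sample the plane through the known warp
        disp = _smooth_displacement((ny, nx), spec.deformation_mm / spec.pixel_size, rng)
        if spec.deformation_mm > 0:
            gy, gx = np.mgrid[0:ny, 0:nx].astype(float)
            coords = np.stack([gy + disp[..., 0], gx + disp[..., 1]])
            img = ndi.map_coordinates(plane, coords, order=1, mode="nearest")
        else:
            img = plane
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        sections.append(SectionImage(img, spec.pixel_size,
                                     n * spec.section_spacing, stack_id="phantom"))
        disp_list.append(disp)
        artifact_masks.append(art)

    blob_table = pd.DataFrame(
        blob_rows, columns=["section", "region", "y_px", "x_px", "z_mm"])
    return HistoPhantom(SectionStack(sections), label_volume, intensity_volume,
                        disp_list, blob_table, artifact_masks,
                        dict(spec.densities), pd.DataFrame(dens_rows))


def calibration_phantom_specs(seed: int, scale_factor: float = 2.7,
                              n_sections: int = 12,
                              image_shape: Tuple[int, int] = (320, 320),
                              pixel_size: float = 0.032):
    """Paired original/replicate stack specs for staining-scale calibration.

    The replicate stack is identical except that each planted blob survives
    with probability 1/scale_factor (proportional thinning), emulating a
    weaker stain on re-processed sections.  Calibration stacks use a wide
    field with sparse tangles so that individual objects stay well separated
    and counting stays near-linear in the true count.
    """
    densities = {"amygdala": 3.0, "erc": 2.0, "ca1": 1.0, "subiculum": 0.5}
    base = HistoPhantomSpec(seed=seed, n_sections=n_sections,
                            image_shape=image_shape, pixel_size=pixel_size,
                            densities=dict(densities))
    repl = HistoPhantomSpec(seed=seed, n_sections=n_sections,
                            image_shape=image_shape, pixel_size=pixel_size,
                            densities=dict(densities),
                            blob_thinning=scale_factor)
    return base, repl


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float,
                    amplitude: float):
    r = int(np.ceil(3 * sigma))
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, img.shape[0])
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, img.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
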