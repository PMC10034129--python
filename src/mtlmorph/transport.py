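"""Transport of 2D density measurements into 3D reference space.

Section-plane detections become weighted particles {x_i, w_i, f_i}: positions
in mm, tissue-area weights (mm^2), and feature values (tangle counts).  The
measures are pushed through the estimated maps, resampled on regular grids by
normalized Gaussian splatting, projected to subregion surfaces with a
nearest-vertex kernel, and smoothed in the Laplace-Beltrami eigenbasis.
Feature mass (total count) is conserved exactly through the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .surface import TriSurface, cell_geometry
from .nft import DetectionSet


@dataclass
class ParticleMeasure:
    """Weighted feature-carrying particles.

    positions : (N, 3) mm; weights w_i >= 0 (mm^2 of tissue represented);
    features f_i (counts represented); provenance: section id per particle.
    """

    positions: np.ndarray
    weights: np.ndarray
    features: np.ndarray
    provenance: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, float).ravel()
        self.features = np.asarray(self.features, float).ravel()
        n = len(self.positions)
        if len(self.weights) != n or len(self.features) != n:
            raise ValueError("weights/features must be conformal with positions")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def total_feature(self) -> float:
        return float(self.features.sum())

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def densities(self) -> np.ndarray:
        """f_i / w_i where defined, else 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.weights > 0, self.features / self.weights, 0.0)


def particles_from_sections(detections: Sequence[DetectionSet],
                            fg_masks: Sequence[np.ndarray],
                            pixel_size: float, z_positions: Sequence[float],
                            cell_px: int = 8) -> ParticleMeasure:
    """One particle per coarse grid cell per section.

    w_i = foreground tissue area within the cell (mm^2); f_i = number of
    detection centroids in the cell; position = cell center at (x, y, z_n).
    """
    pos, w, f, prov = [], [], [], []
    area_px = pixel_size ** 2
    for det, mask, z in zip(detections, fg_masks, z_positions):
        ny, nx = mask.shape
        cents = det.centroids_px()
        for y0 in range(0, ny, cell_px):
            for x0 in range(0, nx, cell_px):
                sub = mask[y0:y0 + cell_px, x0:x0 + cell_px]
                wij = float(sub.sum()) * area_px
                if len(cents):
                    inside = ((cents[:, 0] >= y0) & (cents[:, 0] < y0 + cell_px)
                              & (cents[:, 1] >= x0) & (cents[:, 1] < x0 + cell_px))
                    fij = float(inside.sum())
                else:
                    fij = 0.0
                if wij == 0 and fij == 0:
                    continue
                cy = (y0 + min(cell_px, ny - y0) / 2.0) * pixel_size
                cx = (x0 + min(cell_px, nx - x0) / 2.0) * pixel_size
                pos.append([cx, cy, z])
                w.append(wij)
                f.append(fij)
                prov.append(det.section_id)
    return ParticleMeasure(np.array(pos).reshape(-1, 3), np.array(w),
                           np.array(f), np.array(prov))


def pushforward(measure: ParticleMeasure,
                slice_maps: Optional[Dict[int, Callable]] = None,
                volume_map: Optional[Callable] = None,
                rigid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                jacobian_reweight: bool = True,
                jacobian_fn: Optional[Callable] = None) -> ParticleMeasure:
    """Carry a particle measure through slice maps, a 3D map, and a rigid move.

    ``slice_maps[section_id]`` maps (N, 2) in-plane mm coordinates; the
    optional ``volume_map`` and rigid (R, t) act on 3D positions.  Feature
    totals are conserved exactly.  With ``jacobian_reweight``, weights are
    multiplied by the local area Jacobian of the in-plane map (from
    ``jacobian_fn(section_id, xy)``) so that physical densities transform
    consistently; without it, weights are transported as-is (mass semantics).
    """
    pos = measure.positions.copy()
    w = measure.weights.copy()
    if slice_maps:
        prov = measure.provenance
        if prov is None:
            raise ValueError("slice maps require per-particle provenance")
        for sid, fn in slice_maps.items():
            sel = prov == sid
            if not np.any(sel):
                continue
            xy = pos[sel, :2]
            pos[sel, :2] = fn(xy)
            if jacobian_reweight and jacobian_fn is not None:
                w[sel] = w[sel] * jacobian_fn(sid, xy)
    if volume_map is not None:
        pos = volume_map(pos)
    if rigid is not None:
        R, t = rigid
        pos = pos @ np.asarray(R, float).T + np.asarray(t, float)
    if not np.all(np.isfinite(pos)):
        bad = ~np.all(np.isfinite(pos), axis=1)
        raise ValueError(f"{int(bad.sum())} particles mapped outside the domain")
    return ParticleMeasure(pos, w, measure.features.copy(),
                           None if measure.provenance is None
                           else measure.provenance.copy())


def resample_grid(measure: ParticleMeasure, grid_origin, grid_spacing,
                  grid_shape, bandwidth: float):
    """Normalized Gaussian splat of a particle measure onto a regular grid.

    Each particle's weight is distributed over grid nodes with Gaussian
    fractions normalized to sum to one (partition of unity over the grid), so
    total weight is conserved to rounding.  Returns (weights_grid,
    feature_density_grid): per-node tissue weight and the weight-averaged
    conditional feature density f/w.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    origin = np.asarray(grid_origin, float)
    spacing = np.asarray(grid_spacing, float)
    shape = tuple(grid_shape)
    wgrid = np.zeros(shape)
    fgrid = np.zeros(shape)
    half = max(int(np.ceil(3 * bandwidth / spacing.min())), 1)
    lost = 0.0
    for x, w, f in zip(measure.positions, measure.weights, measure.features):
        idx = (x - origin) / spacing
        lo = np.maximum(np.floor(idx).astype(int) - half, 0)
        hi = np.minimum(np.floor(idx).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            lost += w
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        axes = [np.arange(a, b) for a, b in zip(lo, hi)]
        d2 = sum(((ax * s + o - xi) ** 2)[(...,) + (None,) * (2 - k)]
                 for k, (ax, s, o, xi) in enumerate(zip(axes, spacing, origin, x)))
        g = np.exp(-d2 / (2 * bandwidth ** 2))
        tot = g.sum()
        if tot <= 0:
            lost += w
            continue
        g /= tot
        wgrid[sl] += w * g
        fgrid[sl] += f * g
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(wgrid > 0, fgrid / wgrid, 0.0)
    return wgrid, dens, float(lost)


def project_to_surface(measure: ParticleMeasure, surface: TriSurface,
                       region_mask: Optional[np.ndarray] = None):
    """Nearest-vertex projection of particles onto a surface.

    Each particle is assigned wholly to its nearest surface vertex
    (equidistant ties go to the lowest vertex index); returns per-vertex
    feature counts g_tau and tissue areas g_a with totals conserved.
    """
    sel = np.ones(len(measure.positions), bool) if region_mask is None \
        else np.asarray(region_mask, bool)
    g_tau = np.zeros(surface.n_vertices)
    g_a = np.zeros(surface.n_vertices)
    if sel.any():
        tree = cKDTree(surface.vertices)
        _, idx = tree.query(measure.positions[sel])
        np.add.at(g_tau, idx, measure.features[sel])
        np.add.at(g_a, idx, measure.weights[sel])
    return g_tau, g_a


# ---------------------------------------------------------------------------
# Laplace-Beltrami smoothing


@dataclass
class SurfaceField:
    """Per-vertex scalar fields on a surface with a cached LB eigenbasis.

    The discrete operator is the cotangent stiffness matrix with lumped
    (barycentric) vertex masses w(.); eigenpairs solve S b = lambda M b.
    The first eigenvalue is 0 with a constant eigenvector.
    """

    surface: TriSurface
    n_basis: int = 100
    _eig: Optional[tuple] = field(default=None, repr=False)

    @property
    def vertex_masses(self) -> np.ndarray:
        areas, _ = cell_geometry(self.surface, warn_degenerate=False)
        w = np.zeros(self.surface.n_vertices)
        for k in range(3):
            np.add.at(w, self.surface.faces[:, k], areas / 3.0)
        return w

    def eigenbasis(self):
        if self._eig is None:
            nv = self.surface.n_vertices
            n = min(self.n_basis, nv)
            S = cotangent_stiffness(self.surface)
            m = self.vertex_masses
            if n >= nv - 1:
                # full dense basis via symmetric whitening
                inv_sqrt = 1.0 / np.sqrt(m)
                Lsym = inv_sqrt[:, None] * S.toarray() * inv_sqrt[None, :]
                Lsym = 0.5 * (Lsym + Lsym.T)
                evals, y = np.linalg.eigh(Lsym)
                evecs = inv_sqrt[:, None] * y
                evals, evecs = evals[:n], evecs[:, :n]
            else:
                M = sp.diags(m)
                evals, evecs = spla.eigsh(S.tocsc(), k=n, M=M.tocsc(),
                                          sigma=-1e-6, which="LM")
            evals = np.maximum(evals, 0.0)
            self._eig = (evals, evecs)
        return self._eig


def cotangent_stiffness(surface: TriSurface) -> sp.csr_matrix:
    """Standard cotangent-weight stiffness matrix (positive semidefinite)."""
    v, f = surface.vertices, surface.faces
    n = len(v)
    I, J, W = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
        I += [i, j]
        J += [j, i]
        W += [-0.5 * cot, -0.5 * cot]
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    S = sp.coo_matrix((W, (I, J)), shape=(n, n)).tocsr()
    S = S - sp.diags(np.asarray(S.sum(axis=1)).ravel())
    return S


def lb_smooth(fld: SurfaceField, values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Spectral smoothing: minimize |g^ - g|^2 + k |grad g^|^2 on the surface.

    Expanding g in the mass-orthonormal LB eigenbasis, the minimizer shrinks
    each coefficient by 1/(1 + k lambda_i); k=0 returns g up to spectral
    truncation, and the constant (lambda=0) mode passes unchanged so the
    surface integral of g is preserved when it is included.
    """
    if k < 0:
        raise ValueError("smoothing constant must be nonnegative")
    evals, evecs = fld.eigenbasis()
    w = fld.vertex_masses
    g = np.asarray(values, float)
    coefs = evecs.T @ (w * g)
    shrunk = coefs / (1.0 + k * evals)
    return evecs @ shrunk


def smoothed_density(fld: SurfaceField, g_tau: np.ndarray, g_a: np.ndarray,
                     k: float = 2.0) -> np.ndarray:
    """Smoothed density = smoothed counts / smoothed areas, with a floor on
    the area to avoid division blow-up where no tissue projects."""
    st = lb_smooth(fld, g_tau, k)
    sa = lb_smooth(fld, g_a, k)
    floor = max(1e-9, 1e-6 * np.abs(sa).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.abs(sa) > floor, st / sa, 0.0)
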