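"""Alignment of serial 2D sections to a 3D volume.

Each section J_n is modeled as a warped slice of a template volume:
J_n = phi_n . P_n I + noise, where P_n restricts the volume to the plane
z = z_n and phi_n is an in-plane smooth deformation independent per section.
Contrast differences between stained sections and the volume are bridged by
an affine predictor on wavelet-scattering channels of the section; pixels are
soft-classified into foreground tissue / background / artifact by a Gaussian
mixture, and the matching term is weighted by the foreground posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize as _opt
from scipy.signal import fftconvolve


# ---------------------------------------------------------------------------
# section containers


@dataclass
class SectionImage:
    """One 2D section: intensities, pixel size (mm), axial position z (mm)."""

    image: np.ndarray
    pixel_size: float
    z_mm: float
    stack_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, float)
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("section intensities must be finite")


@dataclass
class SectionStack:
    sections: List[SectionImage]

    def __post_init__(self):
        zs = [s.z_mm for s in self.sections]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("section z-positions must be strictly increasing")

    def __len__(self):
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    def __getitem__(self, i):
        return self.sections[i]

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z_mm for s in self.sections])


# ---------------------------------------------------------------------------
# projection


def project_volume(volume: np.ndarray, spacing: Sequence[float],
                   origin: Sequence[float], z_mm: float,
                   out_shape: Optional[Tuple[int, int]] = None,
                   out_pixel_size: Optional[float] = None,
                   order: int = 1) -> np.ndarray:
    """Trilinear restriction of a volume to the plane z = z_mm.

    Volume axes are (z, y, x) with world = origin + index * spacing.  The
    output grid defaults to the volume's own in-plane grid.
    """
    volume = np.asarray(volume, float)
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    iz = (z_mm - origin[0]) / spacing[0]
    if iz < -1e-9 or iz > volume.shape[0] - 1 + 1e-9:
        raise ValueError(f"plane z={z_mm} outside volume extent")
    if out_shape is None:
        out_shape = volume.shape[1:]
    if out_pixel_size is None:
        sy, sx = spacing[1], spacing[2]
    else:
        sy = sx = out_pixel_size
    gy, gx = np.mgrid[0:out_shape[0], 0:out_shape[1]].astype(float)
    coords = np.stack([np.full(out_shape, iz),
                       gy * sy / spacing[1], gx * sx / spacing[2]])
    return ndi.map_coordinates(volume, coords, order=order, mode="nearest")


# ---------------------------------------------------------------------------
# scattering features


def _gabor_bank(n_orientations: int, scales: Sequence[float]):
    kernels = []
    for s in scales:
        for k in range(n_orientations):
            theta = np.pi * k / n_orientations
            sigma = 2.0 * s
            freq = 1.0 / (4.0 * s)
            half = int(np.ceil(3 * sigma))
            yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
            rot = xx * np.cos(theta) + yy * np.sin(theta)
            env = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
            kern = env * np.exp(2j * np.pi * freq * rot)
            kern -= kern.mean()          # zero-mean: offset invariance
            kernels.append((s, theta, kern))
    return kernels


def scattering_features(image: np.ndarray, depth: int = 2,
                        n_orientations: int = 4,
                        scales: Sequence[float] = (1.0, 2.0),
                        lowpass_sigma: float = 2.0,
                        second_order: str = "same") -> np.ndarray:
    """Wavelet-scattering channels of a section image.

    Channel 0 is the low-passed image; first-order channels are low-passed
    moduli of complex wavelet (Gabor) responses; at depth 2, moduli are
    re-filtered at coarser scales ("same" orientation pairs by default).
    Returns an array (C, ny, nx); modulus channels are nonnegative.
    """
    image = np.asarray(image, float)
    bank = _gabor_bank(n_orientations, scales)

    def conv(im, kern):
        # symmetric padding so zero-mean wavelets see no spurious borders
        half = kern.shape[0] // 2
        padded = np.pad(im, half, mode="symmetric")
        return fftconvolve(padded, kern, mode="same")[half:-half, half:-half]

    chans = [ndi.gaussian_filter(image, lowpass_sigma)]
    first = []
    for s, theta, kern in bank:
        u = np.abs(conv(image, kern))
        first.append((s, theta, u))
        chans.append(ndi.gaussian_filter(u, lowpass_sigma))
    if depth >= 2:
        for s1, th1, u in first:
            for s2, th2, kern in bank:
                if s2 <= s1:
                    continue
                if second_order == "same" and th2 != th1:
                    continue
                v = np.abs(conv(u, kern))
                chans.append(ndi.gaussian_filter(v, lowpass_sigma))
    return np.stack(chans)


# ---------------------------------------------------------------------------
# contrast prediction


@dataclass
class ContrastPredictor:
    """Affine predictor on principal components of scattering channels."""

    components: np.ndarray        # (d, C) PCA loadings
    channel_mean: np.ndarray      # (C,)
    alpha: np.ndarray             # (d + 1,) coefficients incl. constant
    residual_norm: float

    def predict(self, channels: np.ndarray) -> np.ndarray:
        C, ny, nx = channels.shape
        X = channels.reshape(C, -1).T - self.channel_mean
        scores = X @ self.components.T
        out = scores @ self.alpha[:-1] + self.alpha[-1]
        return out.reshape(ny, nx)


def fit_contrast(channels: np.ndarray, reference: np.ndarray,
                 weights: Optional[np.ndarray] = None,
                 n_components: int = 7, ridge: float = 0.0) -> ContrastPredictor:
    """Weighted least-squares affine fit of scattering components to a
    reference slice.  Falls back to a small ridge penalty if the weighted
    normal equations are ill-conditioned."""
    C, ny, nx = channels.shape
    X = channels.reshape(C, -1).T
    y = np.asarray(reference, float).ravel()
    w = np.ones_like(y) if weights is None else np.asarray(weights, float).ravel()
    # weighted, standardized PCA: weighting makes the components reflect the
    # pixels that matter (tissue); per-channel standardization stops the
    # large-magnitude modulus channels from monopolizing the leading
    # components and squeezing out the low-contrast intensity direction
    wsum = max(w.sum(), 1e-12)
    mu = (w[:, None] * X).sum(axis=0) / wsum
    Xc = X - mu
    sd = np.sqrt((w[:, None] * Xc ** 2).sum(axis=0) / wsum) + 1e-12
    d = min(n_components, C)
    Xs = Xc / sd
    cov = (Xs * w[:, None]).T @ Xs / wsum
    evals, evecs = np.linalg.eigh(cov)
    comp = (evecs[:, ::-1][:, :d] / sd[:, None]).T   # acts directly on X - mu
    scores = Xc @ comp.T
    A = np.column_stack([scores, np.ones(len(scores))])
    Aw = A * w[:, None]
    G = A.T @ Aw
    rhs = Aw.T @ y
    if ridge <= 0 and np.linalg.cond(G) > 1e10:
        import warnings
        warnings.warn("ill-conditioned contrast fit; applying ridge fallback")
        ridge = 1e-8 * np.trace(G) / G.shape[0]
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    alpha = np.linalg.solve(G, rhs)
    resid = y - A @ alpha
    rn = float(np.sqrt(np.sum(w * resid ** 2)))
    return ContrastPredictor(comp, mu, alpha, rn)


# ---------------------------------------------------------------------------
# EM pixel weighting


@dataclass
class PixelClassWeights:
    """Per-pixel posteriors over (background, foreground tissue, artifact).

    Classes are identified after fitting: background is the lowest-mean
    component, foreground tissue the highest-mixing remaining component
    (tissue dominates the pixel population), and artifact the rest;
    posteriors are returned in (background, foreground, artifact) order."""

    posteriors: np.ndarray        # (ny, nx, n_classes)
    means: np.ndarray
    variances: np.ndarray
    mixing: np.ndarray
    log_likelihood_trace: np.ndarray

    @property
    def foreground(self) -> np.ndarray:
        return self.posteriors[..., 1]


def em_pixel_weights(image: np.ndarray, n_classes: int = 3, n_iter: int = 60,
                     tol: float = 1e-8, var_floor_frac: float = 1e-4) -> PixelClassWeights:
    """EM for a 1D Gaussian mixture on pixel intensities.

    Deterministic quantile initialization; a variance floor prevents component
    collapse on (near-)constant images.  The log-likelihood is non-decreasing
    across iterations up to the floor's interference.
    """
    x = np.asarray(image, float).ravel()
    n = len(x)
    span = float(np.var(x))
    floor = max(var_floor_frac * max(span, 1e-12), 1e-12)
    # one seed near each intensity extreme: rare bright objects (tangles,
    # artifacts) only get their own component if a mean starts out there
    qs = np.linspace(0.05, 0.5, n_classes - 1).tolist() + [0.999]
    means = np.quantile(x, qs)
    variances = np.full(n_classes, max(span / n_classes, floor))
    mixing = np.full(n_classes, 1.0 / n_classes)
    trace = []
    resp = np.full((n, n_classes), 1.0 / n_classes)
    for _ in range(n_iter):
        # E step
        logp = (-0.5 * np.log(2 * np.pi * variances)[None, :]
                - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
                + np.log(mixing)[None, :])
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        denom = p.sum(axis=1, keepdims=True)
        resp = p / denom
        ll = float(np.sum(m[:, 0] + np.log(denom[:, 0])))
        if trace and abs(ll - trace[-1]) < tol * (1 + abs(trace[-1])):
            trace.append(ll)
            break
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0) + 1e-12
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, floor)
        mixing = nk / n
    by_mean = np.argsort(means)
    bg = by_mean[0]
    rest = [i for i in range(n_classes) if i != bg]
    # tissue is both populous and tight; a broad mixture component sweeping
    # up edges/objects can carry more mass but has much larger variance
    score = mixing[rest] / np.sqrt(variances[rest])
    top = np.argsort(score)[::-1]
    if len(top) > 1 and score[top[1]] > 0.8 * score[top[0]]:
        # near-tie: the lower-mean candidate is tissue, the brighter one
        # an artifact/object class
        fg = rest[top[0]] if means[rest[top[0]]] <= means[rest[top[1]]] \
            else rest[top[1]]
    else:
        fg = rest[top[0]]
    order = np.array([bg, fg] + [i for i in rest if i != fg])
    resp = resp[:, order]
    return PixelClassWeights(resp.reshape(image.shape + (n_classes,)),
                             means[order], variances[order], mixing[order],
                             np.asarray(trace))


# ---------------------------------------------------------------------------
# per-slice deformations


@dataclass
class SliceDeformation:
    """Kernel-parameterized smooth in-plane map, integrated in small steps.

    The map sends target pixel coordinates y to template-slice sampling
    coordinates psi(y) = flow of the stationary field u(y) = sum_j K(y, c_j) m_j,
    so psi plays the role of phi_n^{-1} in J_n = (P_n I) o phi_n^{-1}.
    """

    control_points: np.ndarray    # (M, 2) pixel coords
    momenta: np.ndarray           # (M, 2)
    sigma_px: float
    n_steps: int = 5

    def _field(self, pts: np.ndarray) -> np.ndarray:
        d2 = (np.sum(pts ** 2, 1)[:, None] + np.sum(self.control_points ** 2, 1)[None, :]
              - 2.0 * pts @ self.control_points.T)
        K = np.exp(-np.maximum(d2, 0) / (2 * self.sigma_px ** 2))
        return K @ self.momenta

    def sampling_map(self, shape: Tuple[int, int]) -> np.ndarray:
        gy, gx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        pts = np.stack([gy.ravel(), gx.ravel()], axis=1)
        y = pts.copy()
        for _ in range(self.n_steps):
            y = y + self._field(y) / self.n_steps
        return y.reshape(shape + (2,))

    def displacement(self, shape: Tuple[int, int]) -> np.ndarray:
        gy, gx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        return self.sampling_map(shape) - np.stack([gy, gx], axis=-1)

    def jacobian_positive(self, shape: Tuple[int, int]) -> bool:
        disp = self.displacement(shape)
        dyy = np.gradient(disp[..., 0], axis=0) + 1.0
        dyx = np.gradient(disp[..., 0], axis=1)
        dxy = np.gradient(disp[..., 1], axis=0)
        dxx = np.gradient(disp[..., 1], axis=1) + 1.0
        return bool(np.all(dyy * dxx - dyx * dxy > 0))


# ---------------------------------------------------------------------------
# rigid alignment


def rigid_align(a, b, mode: str = "volume", seed: int = 0,
                max_iter: int = 200):
    """6-dof alignment of b onto a.

    ``volume``: maximizes intensity correlation over rotations (Euler angles)
    and translation with Powell iterations from a deterministic multi-start.
    ``surface``: iterative closest point on vertex sets (via trimesh).
    Returns a dict with rotation matrix R, translation t (and for volumes the
    transform acts in voxel coordinates about the volume center).
    """
    if mode == "surface":
        import trimesh.registration as treg
        matrix, _, cost = treg.icp(np.asarray(b, float), np.asarray(a, float),
                                   max_iterations=max_iter)
        return {"rotation": matrix[:3, :3], "translation": matrix[:3, 3],
                "cost": float(cost)}
    va, vb = np.asarray(a, float), np.asarray(b, float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("cannot align volumes without intensity contrast")
    center = (np.array(vb.shape) - 1) / 2.0

    def transform(params):
        ax, ay, az, tx, ty, tz = params
        Rz = _rot(az, 2)
        Ry = _rot(ay, 1)
        Rx = _rot(ax, 0)
        R = Rz @ Ry @ Rx
        offset = center - R @ center + np.array([tx, ty, tz])
        return ndi.affine_transform(vb, R, offset=offset, order=1, mode="nearest")

    def neg_corr(params):
        w = transform(params)
        wa = va.ravel() - va.mean()
        wb = w.ravel() - w.mean()
        denom = np.linalg.norm(wa) * np.linalg.norm(wb)
        if denom == 0:
            return 1.0
        return -float(wa @ wb / denom)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)] + [rng.normal(0, 0.05, 6) for _ in range(2)]
    best = None
    for s0 in starts:
        res = _opt.minimize(neg_corr, s0, method="Powell",
                            options={"maxiter": max_iter, "xtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    ax, ay, az, tx, ty, tz = best.x
    R = _rot(az, 2) @ _rot(ay, 1) @ _rot(ax, 0)
    return {"rotation": R, "translation": np.array([tx, ty, tz]),
            "correlation": -float(best.fun), "params": best.x}


def _rot(angle, axis):
    c, s = np.cos(angle), np.sin(angle)
    R = np.eye(3)
    i, j = [k for k in range(3) if k != axis]
    R[i, i], R[i, j], R[j, i], R[j, j] = c, -s, s, c
    return R


# ---------------------------------------------------------------------------
# stack registration


@dataclass
class StackRegistration:
    slice_maps: List[SliceDeformation]
    contrast: List[ContrastPredictor]
    weights: List[PixelClassWeights]
    objective_trace: List[float]
    per_slice_residuals: np.ndarray
    volume_transform: Optional[dict] = None


def register_stack(volume: np.ndarray, spacing: Sequence[float],
                   origin: Sequence[float], stack: SectionStack,
                   sigma_2d_mm: float = 0.5, control_spacing_mm: float = 0.5,
                   outer_rounds: int = 5, slice_iterations: int = 40,
                   n_components: int = 7, use_scattering: bool = True,
                   use_em_weights: bool = True,
                   lowpass_sigma: float = 2.0) -> StackRegistration:
    """Alternating estimation of per-slice contrast, class weights, and 2D maps.

    The total weighted matching objective is tracked after every outer round
    and is non-increasing (each block either solves its subproblem exactly or
    takes only objective-decreasing steps).  The 3D map is held at identity;
    phantom stacks are generated without a 3D deformation and real use would
    precede this with ``rigid_align``.
    """
    if len(stack) < 2:
        raise ValueError("need at least two sections")
    ny, nx = stack[0].image.shape
    px = stack[0].pixel_size
    sigma_px = sigma_2d_mm / px
    step_px = max(int(round(control_spacing_mm / px)), 2)
    cy = np.arange(step_px // 2, ny, step_px)
    cx = np.arange(step_px // 2, nx, step_px)
    CY, CX = np.meshgrid(cy, cx, indexing="ij")
    controls = np.stack([CY.ravel(), CX.ravel()], axis=1).astype(float)

    templates = [project_volume(volume, spacing, origin, s.z_mm,
                                out_shape=(ny, nx), out_pixel_size=px)
                 for s in stack]
    if use_scattering:
        # the scattering contrast prediction lives at the lowpass scale;
        # compare against the template at the same scale
        templates = [ndi.gaussian_filter(t, lowpass_sigma) for t in templates]
    grads = [np.stack(np.gradient(t)) for t in templates]

    weights = []
    for s in stack:
        if use_em_weights:
            weights.append(em_pixel_weights(s.image))
        else:
            weights.append(None)
    # minimum-filter the foreground posterior so the halo of a non-tissue
    # object (tangle, artifact) is suppressed together with its core
    wmaps = [np.ones((ny, nx)) if w is None
             else ndi.minimum_filter(w.foreground, size=5) for w in weights]

    chans = [scattering_features(s.image, lowpass_sigma=lowpass_sigma)
             if use_scattering else np.stack([s.image]) for s in stack]
    maps = [SliceDeformation(controls.copy(), np.zeros_like(controls), sigma_px)
            for _ in stack]
    contrast: List[Optional[ContrastPredictor]] = [None] * len(stack)

    def slice_objective_with(smap_obj, n, pred_img):
        sm = smap_obj.sampling_map((ny, nx))
        warped = ndi.map_coordinates(templates[n], np.moveaxis(sm, -1, 0),
                                     order=1, mode="nearest")
        r = pred_img - warped
        return float(np.sum(wmaps[n] * r * r)), warped, sm

    def slice_objective(n, pred_img):
        return slice_objective_with(maps[n], n, pred_img)

    _pts = np.stack(np.mgrid[0:ny, 0:nx], axis=-1).reshape(-1, 2).astype(float)
    _d2 = (np.sum(_pts ** 2, 1)[:, None] + np.sum(controls ** 2, 1)[None, :]
           - 2 * _pts @ controls.T)
    Kmat = np.exp(-np.maximum(_d2, 0) / (2 * sigma_px ** 2))

    trace = []
    pred = [s.image.copy() for s in stack]
    for rnd in range(outer_rounds):
        total = 0.0
        for n in range(len(stack)):
            # (1) contrast toward the currently warped template slice
            smap = maps[n].sampling_map((ny, nx))
            warped = ndi.map_coordinates(templates[n], np.moveaxis(smap, -1, 0),
                                         order=1, mode="nearest")
            cp = fit_contrast(chans[n], warped, weights=wmaps[n],
                              n_components=n_components)
            contrast[n] = cp
            pred[n] = cp.predict(chans[n])
            # (2) slice map by gradient descent with backtracking
            E, warped, smap = slice_objective(n, pred[n])
            mom = maps[n].momenta
            step = 0.5
            for _ in range(slice_iterations):
                r = pred[n] - warped
                g_img = np.moveaxis(np.stack([
                    ndi.map_coordinates(grads[n][0], np.moveaxis(smap, -1, 0),
                                        order=1, mode="nearest"),
                    ndi.map_coordinates(grads[n][1], np.moveaxis(smap, -1, 0),
                                        order=1, mode="nearest")]), 0, -1)
                resid_vec = (-2.0 * wmaps[n] * r)[..., None] * g_img   # dE/d psi
                grad_m = Kmat.T @ resid_vec.reshape(-1, 2)
                gnorm = np.linalg.norm(grad_m)
                if gnorm < 1e-12:
                    break
                improved = False
                while step > 1e-7:
                    trial = SliceDeformation(controls.copy(), mom - step * grad_m / gnorm,
                                             sigma_px)
                    E_t, warped_t, smap_t = slice_objective_with(trial, n, pred[n])
                    if E_t < E:
                        maps[n] = trial
                        mom = trial.momenta
                        E, warped, smap = E_t, warped_t, smap_t
                        step *= 1.5
                        improved = True
                        break
                    step *= 0.5
                if not improved:
                    break
            total += E
        trace.append(total)
        if len(trace) > 1 and trace[-2] - trace[-1] < 1e-9 * (1 + trace[-2]):
            break

    per_slice = np.array([slice_objective(n, pred[n])[0] for n in range(len(stack))])
    return StackRegistration(maps, contrast, weights, trace, per_slice)
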