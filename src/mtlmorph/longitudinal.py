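"""Longitudinal geodesic fitting of a subject's surface time-series.

One smooth geodesic trajectory is fitted through each subject's scans: a
common hypertemplate is registered onto the series at an insertion time t*,
and a single interface momentum rho shoots the subject template backward
(t < t*) and forward (t >= t*) through the remaining scans.  The fitted
trajectory acts as a filter on per-scan measures (volume, thickness),
and its first-to-last-scan flow yields per-triangle deformation markers
that are vertex-corresponded across subjects through the hypertemplate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy import optimize as _opt

from . import lddmm as _ld
from .surface import TriSurface, face_area_normals, surface_volume


@dataclass
class SeriesInput:
    """A subject's ordered scan series plus the common hypertemplate."""

    subject_id: str
    times_years: np.ndarray
    surfaces: List[TriSurface]
    hypertemplate: TriSurface

    def __post_init__(self):
        self.times_years = np.asarray(self.times_years, float)
        if len(self.times_years) != len(self.surfaces):
            raise ValueError("one scan time per surface required")
        if len(self.surfaces) < 3:
            raise ValueError("at least three scans are required")
        if np.any(np.diff(self.times_years) <= 0):
            raise ValueError("scan times must be strictly increasing")


@dataclass
class SubjectTrajectory:
    """Fitted longitudinal object for one subject."""

    subject_id: str
    t_star: float
    t_star_index: int
    norm_times: np.ndarray
    times_years: np.ndarray
    template_at_tstar: TriSurface     # subject-specific template S_t*^temp
    rho: np.ndarray                   # interface momentum at t*
    kernel: _ld.KernelParams
    n_substeps: int
    smoothed_surfaces: List[TriSurface]
    fitted_measures: np.ndarray
    objective: float
    converged: bool = True


def normalize_times(years: np.ndarray, eps: float = 0.05) -> np.ndarray:
    """Affine map of raw scan years onto [eps, 1-eps], preserving spacing."""
    years = np.asarray(years, float)
    span = years[-1] - years[0]
    if span <= 0:
        raise ValueError("degenerate scan times")
    return eps + (1.0 - 2.0 * eps) * (years - years[0]) / span


def _branch_value_and_grad(x_star: np.ndarray, faces: np.ndarray,
                           p0: np.ndarray, targets: Sequence[TriSurface],
                           durations: Sequence[float], n_sub: int,
                           params: _ld.KernelParams, data_weight: float,
                           keep_surfaces: bool = False):
    """Chained-segment geodesic branch: data term at each checkpoint.

    ``durations`` are successive positive time increments away from t*;
    ``targets[i]`` is matched at cumulative time sum(durations[:i+1]).
    Returns (E_data, grad wrt p0, grad wrt x_star, checkpoint vertex arrays).
    """
    sig = params.sigma_v
    segs = []
    x, p = x_star, p0
    E = 0.0
    cot_checkpoints = []
    surfaces = []
    for tgt, dur in zip(targets, durations):
        xs, ps = _ld.integrate(x, p, sig, n_sub, dur)
        d2, g = _ld.varifold_distance_and_grad(xs[-1], faces, tgt, params)
        E += data_weight * d2
        segs.append((xs, ps, dur))
        cot_checkpoints.append(data_weight * g)
        if keep_surfaces:
            surfaces.append(xs[-1])
        x, p = xs[-1], ps[-1]
    # reverse accumulation through the chain
    ax = np.zeros_like(x_star)
    ap = np.zeros_like(p0)
    for (xs, ps, dur), cot in zip(reversed(segs), reversed(cot_checkpoints)):
        ax = ax + cot
        ax, ap = _ld.integrate_vjp(xs, ps, sig, dur, ax, ap)
    return E, ap, ax, surfaces


def _series_objective(x_star: np.ndarray, faces: np.ndarray, rho: np.ndarray,
                      norm_times: np.ndarray, m: int,
                      surfaces: Sequence[TriSurface], n_sub: int,
                      params: _ld.KernelParams, data_weight: float,
                      keep_surfaces: bool = False):
    """Full Eq-style objective |rho|_K^2 + sum_i |S_ti - phi_ti . S*|_W^2.

    Returns (E, grad_rho, grad_xstar, smoothed vertex arrays per scan).
    """
    sig = params.sigma_v
    K0 = _ld.gauss_kernel(x_star, x_star, sig)
    reg = float(np.einsum("ij,ij->", K0 @ rho, rho))
    grad_rho = 2.0 * (K0 @ rho)
    # d reg / d x*  =  2 * dH/dx  = -2 * pdot(x*, rho)
    _, pdot = _ld._rhs(x_star, rho, sig)
    grad_x = -2.0 * pdot

    # data term at the insertion scan itself (identity flow)
    d2_0, g0 = _ld.varifold_distance_and_grad(x_star, faces, surfaces[m], params)
    E = reg + data_weight * d2_0
    grad_x = grad_x + data_weight * g0
    checkpoints: dict = {m: x_star}

    # forward branch over scans m+1..k
    fwd_idx = list(range(m + 1, len(norm_times)))
    if fwd_idx:
        durs = np.diff(norm_times[m:])
        Ef, gp, gx, surfs = _branch_value_and_grad(
            x_star, faces, rho, [surfaces[i] for i in fwd_idx], durs,
            n_sub, params, data_weight, keep_surfaces)
        E += Ef
        grad_rho = grad_rho + gp
        grad_x = grad_x + gx
        for i, s in zip(fwd_idx, surfs):
            checkpoints[i] = s
    # backward branch over scans m-1..0 (momentum -rho, time reversed)
    bwd_idx = list(range(m - 1, -1, -1))
    if bwd_idx:
        durs = np.diff(norm_times[: m + 1])[::-1]
        Eb, gp, gx, surfs = _branch_value_and_grad(
            x_star, faces, -rho, [surfaces[i] for i in bwd_idx], durs,
            n_sub, params, data_weight, keep_surfaces)
        E += Eb
        grad_rho = grad_rho - gp
        grad_x = grad_x + gx
        for i, s in zip(bwd_idx, surfs):
            checkpoints[i] = s
    smoothed = [checkpoints[i] for i in range(len(norm_times))] if keep_surfaces else None
    return E, grad_rho, grad_x, smoothed


def _fit_rho(x_star, faces, norm_times, m, surfaces, n_sub, params,
             data_weight, rho0, max_iter, tol=1e-7, compute_dtype=np.float64):
    shape = x_star.shape
    xc = x_star.astype(compute_dtype)

    def fg(rflat):
        try:
            E, gr, _, _ = _series_objective(xc, faces,
                                            rflat.reshape(shape).astype(compute_dtype),
                                            norm_times, m, surfaces, n_sub,
                                            params, data_weight)
            return float(E), gr.ravel().astype(np.float64)
        except FloatingPointError:
            # over-long line-search step blew up the integrator: return a
            # smooth convex barrier so the search backtracks toward zero
            return 1e12 * (1.0 + float(np.sum(rflat ** 2))), 2e12 * rflat

    res = _opt.minimize(fg, rho0.ravel(), jac=True, method="L-BFGS-B",
                        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
    return res.x.reshape(shape), float(res.fun), bool(res.success)


def default_data_weight(template: TriSurface) -> float:
    areas = np.linalg.norm(face_area_normals(template.vertices, template.faces), axis=1)
    return 1e4 / max(float(np.sum(areas ** 2)) / max(len(areas), 1), 1e-12)


def fit_series(series: SeriesInput, params: Optional[_ld.KernelParams] = None,
               measure_fn: Optional[Callable[[TriSurface], float]] = None,
               tstar: "str | int" = "medoid", n_substeps: int = 2,
               outer_rounds: int = 1, max_iter: int = 50,
               search_max_iter: int = 10, register_template: bool = True,
               data_weight: Optional[float] = None,
               register_n_steps: int = 5, register_max_iter: Optional[int] = None,
               compute_dtype=np.float32) -> SubjectTrajectory:
    """Fit one geodesic trajectory through a subject's scan series.

    Block-coordinate optimization: (a) register the common hypertemplate onto
    the scan at the candidate insertion time, (b) fit the interface momentum
    rho against all scans; repeated for ``outer_rounds``.  The insertion time
    t* is selected by grid search over the normalized scan times (short fits),
    then the best candidate is refined.
    """
    if params is None:
        params = _ld.KernelParams.for_surface(series.hypertemplate)
    if measure_fn is None:
        measure_fn = surface_volume
    if data_weight is None:
        data_weight = default_data_weight(series.hypertemplate)
    norm_times = normalize_times(series.times_years)
    faces = series.hypertemplate.faces
    k = len(norm_times)

    _reg_warm = {"p0": None}

    def register(m, max_it):
        if register_template:
            mr = _ld.match_surface(series.hypertemplate, series.surfaces[m],
                                   params, max_iter=max_it,
                                   p0_init=_reg_warm["p0"],
                                   n_steps=register_n_steps,
                                   compute_dtype=compute_dtype)
            _reg_warm["p0"] = mr.state.momentum
            return mr.deformed.vertices
        return series.hypertemplate.vertices

    if tstar == "search":
        candidates = range(k)
        best = None
        reg_cache = {}
        for m in candidates:
            x_star = register(m, max_iter if m == 0 else max_iter // 2)
            reg_cache[m] = x_star
            rho, E, _ = _fit_rho(x_star, faces, norm_times, m, series.surfaces,
                                 n_substeps, params, data_weight,
                                 np.zeros_like(x_star), search_max_iter,
                                 compute_dtype=compute_dtype)
            if best is None or E < best[0]:
                best = (E, m, rho)
        _, m, rho = best
        x_star = reg_cache[m]
    else:
        if tstar == "medoid":
            # cheap insertion-time choice: the scan whose surface is closest
            # (in varifold distance) to all others; the full grid search over
            # the fitting objective is available via tstar="search"
            dists = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    d = _ld.varifold_distance(series.surfaces[i],
                                              series.surfaces[j], params)
                    dists[i, j] = dists[j, i] = d
            m = int(np.argmin(dists.sum(axis=1)))
        else:
            m = int(tstar)
        x_star = register(m, register_max_iter or max_iter)
        rho = np.zeros_like(x_star)

    converged = True
    E = np.inf
    for _ in range(max(outer_rounds, 1)):
        rho, E, ok = _fit_rho(x_star, faces, norm_times, m, series.surfaces,
                              n_substeps, params, data_weight, rho, max_iter,
                              compute_dtype=compute_dtype)
        converged = converged and ok
        if register_template and outer_rounds > 1:
            # refine the subject template against the full-series objective
            x_star = _refine_template(x_star, faces, rho, norm_times, m,
                                      series.surfaces, n_substeps, params,
                                      data_weight, max_iter=max_iter // 2)

    E, _, _, smoothed = _series_objective(x_star, faces, rho, norm_times, m,
                                          series.surfaces, n_substeps, params,
                                          data_weight, keep_surfaces=True)
    template_surface = TriSurface(x_star, faces.copy(),
                                  None if series.hypertemplate.vertex_labels is None
                                  else series.hypertemplate.vertex_labels.copy(),
                                  None if series.hypertemplate.cell_labels is None
                                  else series.hypertemplate.cell_labels.copy())
    smoothed_surfaces = [template_surface.with_vertices(v) for v in smoothed]
    measures = np.array([measure_fn(s) for s in smoothed_surfaces])
    return SubjectTrajectory(series.subject_id, float(norm_times[m]), m,
                             norm_times, series.times_years, template_surface,
                             rho, params, n_substeps, smoothed_surfaces,
                             measures, float(E), converged)


def _refine_template(x_star, faces, rho, norm_times, m, surfaces, n_sub,
                     params, data_weight, max_iter=30, step0=1.0):
    """Gradient descent with backtracking on the subject-template vertices
    against the full-series objective (template-flow block of the joint fit)."""
    E, _, g, _ = _series_objective(x_star, faces, rho, norm_times, m, surfaces,
                                   n_sub, params, data_weight)
    step = step0 / max(np.linalg.norm(g.ravel(), np.inf), 1e-12)
    x = x_star
    for _ in range(max_iter):
        x_new = x - step * g
        E_new, _, g_new, _ = _series_objective(x_new, faces, rho, norm_times, m,
                                               surfaces, n_sub, params, data_weight)
        if E_new < E:
            x, E, g = x_new, E_new, g_new
            step *= 1.3
        else:
            step *= 0.5
            if step * np.linalg.norm(g.ravel(), np.inf) < 1e-10:
                break
    return x


def resample_trajectory(traj: SubjectTrajectory, times: Sequence[float],
                        n_substeps: Optional[int] = None) -> List[TriSurface]:
    """Evaluate the fitted trajectory at arbitrary normalized times in [0, 1]."""
    times = np.asarray(times, float)
    if np.any((times < 0) | (times > 1)):
        raise ValueError("requested times must lie in [0, 1]")
    n_sub = n_substeps or max(traj.n_substeps, 3)
    out = []
    x0 = traj.template_at_tstar.vertices
    sig = traj.kernel.sigma_v
    for t in times:
        dt = float(t - traj.t_star)
        if abs(dt) < 1e-12:
            out.append(traj.template_at_tstar.copy())
            continue
        p0 = traj.rho if dt > 0 else -traj.rho
        xs, _ = _ld.integrate(x0, p0, sig, n_sub, abs(dt))
        out.append(traj.template_at_tstar.with_vertices(xs[-1]))
    return out


def subject_rate(measures: Sequence[float], times_years: Sequence[float]) -> float:
    """Percent loss of a measure per year by least squares.

    OLS slope of measure vs. years, as a percent of the fitted baseline value;
    positive = loss (atrophy).
    """
    m = np.asarray(measures, float)
    t = np.asarray(times_years, float)
    if len(m) < 3:
        raise ValueError("at least three time points required")
    if np.ptp(t) <= 0:
        raise ValueError("degenerate scan times")
    A = np.stack([np.ones_like(t), t], axis=1)
    (b0, b1), *_ = np.linalg.lstsq(A, m, rcond=None)
    baseline = b0 + b1 * t[0]
    if baseline <= 0:
        raise ValueError("fitted baseline measure must be positive")
    return float(-100.0 * b1 / baseline)


def deformation_marker(traj: SubjectTrajectory):
    """Per-triangle deformation markers of the first-to-last-scan flow, per year.

    Computed on the subject template's cells (vertex-corresponded to the common
    hypertemplate).  Returns (log_det_per_year, pct_area_loss_per_year): the
    log-determinant of the 3D Jacobian of the composed map from t_1 to t_k
    divided by the elapsed years, and the percent change in per-cell surface
    area per year (positive = loss).
    """
    x0 = traj.template_at_tstar.vertices
    faces = traj.template_at_tstar.faces
    centers = x0[faces].mean(axis=1)
    sig = traj.kernel.sigma_v
    n_sub = max(traj.n_substeps * (len(traj.norm_times) - 1), 3)
    dt_f = float(traj.norm_times[-1] - traj.t_star)
    dt_b = float(traj.t_star - traj.norm_times[0])
    years = float(traj.times_years[-1] - traj.times_years[0])

    def flow_jac(p0, dur):
        if dur < 1e-12:
            n = len(centers)
            return centers.copy(), np.tile(np.eye(3), (n, 1, 1)), x0.copy()
        y, A = _ld.flow_points(x0, p0, centers, sig, n_sub, dur, with_jacobian=True)
        verts = _ld.flow_points(x0, p0, x0, sig, n_sub, dur)
        return y, A, verts

    _, A_f, v_f = flow_jac(traj.rho, dt_f)
    _, A_b, v_b = flow_jac(-traj.rho, dt_b)
    # map t1 -> tk has Jacobian A_f A_b^{-1} at corresponding points
    J = np.einsum("iab,ibc->iac", A_f, np.linalg.inv(A_b))
    log_det = np.log(np.linalg.det(J)) / years

    a1 = np.linalg.norm(face_area_normals(v_b, faces), axis=1)
    ak = np.linalg.norm(face_area_normals(v_f, faces), axis=1)
    pct_area_loss = -100.0 * (ak / a1 - 1.0) / years
    return log_det, pct_area_loss
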