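"""Group statistics on per-triangle deformation markers.

Per vertex v, nested Gaussian linear models are compared:

    H0: J_v(s) = a + c*sex(s) + d*logicv(s) + e*age(s) + eps
    H1: H0 + b * 1_group(s)

with the log-likelihood-ratio statistic S_v = l_v(H1) - l_v(H0).  Familywise
error over the surface is controlled by permuting H0 residuals (one
subject-level permutation shared across vertices per replicate, preserving
spatial dependence), refitting, and thresholding the observed S_v at the 95th
percentile q* of the permutation distribution of S* = max_v S_v.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

S_CAP = 1e6  # sentinel for perfectly separated (zero-residual) fits


@dataclass
class MarkerMatrix:
    """Subjects x vertices marker array with per-subject covariates."""

    markers: np.ndarray          # (n_subjects, n_vertices)
    sex: np.ndarray
    log_icv: np.ndarray
    age: np.ndarray
    group: np.ndarray            # binary indicator of the non-reference group

    def __post_init__(self):
        self.markers = np.asarray(self.markers, float)
        for name in ("sex", "log_icv", "age", "group"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (self.markers.shape[0],):
                raise ValueError(f"{name} must have one entry per subject")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)
        if not np.all(np.isfinite(self.markers)):
            raise ValueError("markers contain non-finite values")

    @property
    def design_h0(self) -> np.ndarray:
        return np.stack([np.ones(len(self.sex)), self.sex, self.log_icv,
                         self.age], axis=1)

    @property
    def design_h1(self) -> np.ndarray:
        return np.column_stack([self.design_h0, self.group])


@dataclass
class PermutationResult:
    s_observed: np.ndarray       # per-vertex S_v
    s_max: float                 # observed S* = max_v S_v
    null_s_max: np.ndarray       # permutation sample of S*
    q_star: float                # 95th percentile threshold
    significant: np.ndarray      # boolean set D = {v : S_v >= q*}
    p_value: float


@dataclass
class ROCResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


def _check_rank(X: np.ndarray, names: Sequence[str]):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify an offending column by leave-one-out rank (later columns
        # first, so a covariate rather than the intercept gets named)
        for j in range(X.shape[1] - 1, -1, -1):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == r:
                raise np.linalg.LinAlgError(
                    f"design is rank deficient; column '{names[j]}' is collinear")
        raise np.linalg.LinAlgError("design is rank deficient")


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares per column of Y under OLS on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return np.einsum("ij,ij->j", R, R)


def _loglik_ratio(rss0: np.ndarray, rss1: np.ndarray, n: int) -> np.ndarray:
    """Gaussian ML log-likelihood difference S_v = l1 - l0 = n/2 log(RSS0/RSS1)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 0.5 * n * np.log(rss0 / rss1)
    # numerically perfect H1 fit = separation; report the finite sentinel
    perfect = rss1 <= 1e-10 * np.maximum(rss0, 1e-30)
    s = np.where(perfect, S_CAP, s)
    s = np.where(rss0 <= 0, 0.0, s)
    return np.minimum(np.maximum(s, 0.0), S_CAP)


def fit_lfe(markers: MarkerMatrix, vertex: Optional[int] = None):
    """Fit H0/H1 at one vertex (or all) and return the statistic S_v.

    Returns (beta0, beta1, S_v); with ``vertex=None``, S_v is the full
    per-vertex array and betas are (p, V) matrices.
    """
    X0, X1 = markers.design_h0, markers.design_h1
    n = X0.shape[0]
    if n <= X1.shape[1]:
        raise ValueError("more parameters than subjects")
    _check_rank(X1, ["intercept", "sex", "log_icv", "age", "group"])
    Y = markers.markers if vertex is None else markers.markers[:, [vertex]]
    beta0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
    beta1, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    rss0 = np.einsum("ij,ij->j", Y - X0 @ beta0, Y - X0 @ beta0)
    rss1 = np.einsum("ij,ij->j", Y - X1 @ beta1, Y - X1 @ beta1)
    s = _loglik_ratio(rss0, rss1, n)
    if vertex is not None:
        return beta0[:, 0], beta1[:, 0], float(s[0])
    return beta0, beta1, s


def permutation_fwer(markers: MarkerMatrix, n_perm: int = 1000,
                     seed: int = 0, alpha: float = 0.05) -> PermutationResult:
    """Residual-permutation max-statistic test with FWER control.

    H0 residuals are permuted at the subject level (pi shared across vertices
    within a replicate), responses reconstructed as fitted-H0 + permuted
    residuals, and both models refitted; the observed S_v are thresholded at
    the (1-alpha) quantile q* of the null S* = max_v S_v sample.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X0, X1 = markers.design_h0, markers.design_h1
    n = X0.shape[0]
    _check_rank(X1, ["intercept", "sex", "log_icv", "age", "group"])
    Y = markers.markers
    beta0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
    fitted0 = X0 @ beta0
    resid0 = Y - fitted0
    rss1_obs = _rss(X1, Y)
    rss0_obs = np.einsum("ij,ij->j", resid0, resid0)
    s_obs = _loglik_ratio(rss0_obs, rss1_obs, n)
    s_max_obs = float(np.max(s_obs))

    # orthonormal bases of the design column spaces: RSS = |Y|^2 - |Q^T Y|^2
    Q0, _ = np.linalg.qr(X0)
    Q1, _ = np.linalg.qr(X1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pi = rng.permutation(n)
        Yb = fitted0 + resid0[pi]
        yy = np.einsum("ij,ij->j", Yb, Yb)
        q0 = Q0.T @ Yb
        q1 = Q1.T @ Yb
        rss0 = yy - np.einsum("ij,ij->j", q0, q0)
        rss1 = yy - np.einsum("ij,ij->j", q1, q1)
        null[b] = np.max(_loglik_ratio(np.maximum(rss0, 0), np.maximum(rss1, 0), n))
    q_star = float(np.quantile(null, 1.0 - alpha))
    significant = s_obs >= q_star
    p_value = float((1 + np.sum(null >= s_max_obs)) / (n_perm + 1))
    return PermutationResult(s_obs, s_max_obs, null, q_star, significant, p_value)


def roc_threshold(rates_negative: Sequence[float],
                  rates_positive: Sequence[float]) -> ROCResult:
    """Empirical ROC of a scalar rate separating two groups.

    AUC in the Mann-Whitney form; the operating threshold maximizes Youden's
    J = sensitivity + specificity - 1, ties broken toward higher specificity.
    Positives are classified by rate >= threshold.
    """
    from scipy.stats import rankdata

    neg = np.asarray(rates_negative, float)
    pos = np.asarray(rates_positive, float)
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both samples must be nonempty")
    # Mann-Whitney AUC via midranks (tie-corrected, O(n log n))
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    auc = float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))

    candidates = np.unique(np.concatenate([neg, pos]))
    mids = np.concatenate([[candidates[0] - 1.0],
                           0.5 * (candidates[1:] + candidates[:-1]),
                           [candidates[-1] + 1.0]])
    # classify positive when rate >= threshold
    sens = 1.0 - np.searchsorted(np.sort(pos), mids, side="left") / len(pos)
    spec = np.searchsorted(np.sort(neg), mids, side="left") / len(neg)
    j = sens + spec - 1.0
    # ties in Youden's J broken toward higher specificity
    best = np.lexsort((spec, np.round(j, 12)))[-1]
    return ROCResult(auc, float(mids[best]), float(sens[best]), float(spec[best]))
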