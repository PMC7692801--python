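"""Stage 1: per-marker restricted maximum likelihood in the rotated space.

After rotation by the kinship eigenvectors the covariance of the phenotype
is ``V = x_Q x_Q^T * omega_g + V0`` with ``V0 = Lambda * omega_u + I``
diagonal, where ``omega_g = sigma_g^2 / sigma_n^2`` is the focal marker's
variance ratio and ``omega_u`` the polygenic one.  Every quantity involving
``V^{-1}`` is evaluated through the Sherman-Morrison identity and ``|V|``
through the matrix determinant lemma, so a likelihood evaluation costs
O(n c^2) instead of O(n^3).

The profiled restricted log-likelihood maximised over ``omega_g`` is

    L_r(omega) = -1/2 log|V| - 1/2 log|F_Q^T V^-1 F_Q|
                 - (n - c)/2 * log(y_Q^T S y_Q)

with ``S = V^-1 - V^-1 F_Q (F_Q^T V^-1 F_Q)^-1 F_Q^T V^-1``.  The marker
effect, its variance, the Wald statistic and the chi-square(1) p-value
follow in closed form from the maximiser.

Two optimisers are provided: a quasi-Newton (L-BFGS-B) fit of a single
marker over log10(omega) with a central finite-difference gradient, and a
vectorised bracketed golden-section search used by :func:`scan` that
optimises all markers simultaneously on the same parameterisation.  The two
agree to optimizer tolerance; the vectorised path exists because a
genome-wide scan spends its time in Python/optimizer overhead otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from hrepml.io_formats import GenotypeTable
from hrepml.kinship import SpectralBasis, rotate_vector

__all__ = [
    "NullFit",
    "MarkerFit",
    "ScanContext",
    "restricted_loglik",
    "null_restricted_loglik",
    "fit_null",
    "fit_marker_reml",
    "scan",
    "screen_markers",
    "RemlConvergenceError",
    "DegenerateFitError",
]

#: Box bounds for log10(omega) in both the null and per-marker optimisations.
_LOG10_BOUNDS = (-10.0, 10.0)
#: Slack used when deciding a likelihood is flat / tied with the zero boundary.
_TIE_TOL = 1e-9


class RemlConvergenceError(RuntimeError):
    """The variance-ratio optimiser failed to converge; carries the trace."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


class DegenerateFitError(ValueError):
    """The residual quadratic form y_Q^T S y_Q is non-positive."""


@dataclass
class NullFit:
    """No-marker model fit: polygenic variance ratio and diagonal V0."""

    omega_u_hat: float
    V0_diag: np.ndarray
    null_restricted_loglik: float


@dataclass
class MarkerFit:
    """Single-marker REML output.

    ``status`` is ``"ok"`` for a fitted marker and ``"skipped_monomorphic"``
    for a zero-variance marker, whose statistics are undefined.  At the
    boundary ``omega_g_hat = 0`` the effect, Wald statistic and variance all
    collapse to zero and the p-value is 1 by continuity.
    """

    omega_g_hat: float
    beta_hat: float
    var_beta: float
    sigma_n2_hat: float
    wald: float
    p_value: float
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _design_stats(y_Q, F_Q, d):
    """Shared diagonal-space products for a given diagonal covariance d."""
    dinv = 1.0 / d
    Fd = F_Q * dinv[:, None]
    A0 = F_Q.T @ Fd
    a0y = Fd.T @ y_Q
    yDy = float(y_Q @ (dinv * y_Q))
    logdetD = float(np.log(d).sum())
    return dinv, Fd, A0, a0y, yDy, logdetD


def _loglik_core(omega, s, q, B, A0, a0y, yDy, logdetD, n, c):
    """Vectorised L_r for per-marker omega (scalars broadcast).

    ``s = x^T D^-1 x``, ``q = x^T D^-1 y``, ``B = F^T D^-1 x`` are the
    rank-one sufficient statistics per marker; all V^-1 products use the
    Sherman-Morrison identity and |V| the determinant lemma.
    Returns (loglik, ySy, M, FVy) so callers can reuse the pieces.
    """
    omega = np.asarray(omega, dtype=float)
    denom = 1.0 + omega * s
    r = omega / denom
    yVy = yDy - r * q * q
    FVy = a0y[:, None] - (r * q)[None, :] * B  # (c, m)
    if A0.shape[0] == 1:
        M = A0[0, 0] - r * B[0] * B[0]
        logdetM = np.log(M)
        ySy = yVy - FVy[0] * FVy[0] / M
    else:
        outer = np.einsum("im,jm->mij", B, B)
        M = A0[None, :, :] - r[:, None, None] * outer
        _, logdetM = np.linalg.slogdet(M)
        sol = np.linalg.solve(M, np.moveaxis(FVy, 1, 0)[..., None])[..., 0]  # (m, c)
        ySy = yVy - np.einsum("mc,cm->m", sol, FVy)
    logdetV = logdetD + np.log1p(omega * s)
    with np.errstate(invalid="ignore", divide="ignore"):
        loglik = -0.5 * logdetV - 0.5 * logdetM - 0.5 * (n - c) * np.log(ySy)
    return loglik, ySy, M, FVy


def restricted_loglik(omega_g, x_Q, y_Q, F_Q, V0_diag) -> float:
    """Profiled restricted log-likelihood of one marker at ``omega_g``.

    Raises :class:`DegenerateFitError` when the residual quadratic form is
    non-positive.
    """
    x_Q = np.asarray(x_Q, dtype=float).reshape(-1)
    y_Q = np.asarray(y_Q, dtype=float).reshape(-1)
    F_Q = np.atleast_2d(np.asarray(F_Q, dtype=float))
    d = np.asarray(V0_diag, dtype=float)
    n, c = F_Q.shape
    dinv, Fd, A0, a0y, yDy, logdetD = _design_stats(y_Q, F_Q, d)
    s = np.array([float(x_Q @ (dinv * x_Q))])
    q = np.array([float(x_Q @ (dinv * y_Q))])
    B = (Fd.T @ x_Q)[:, None]
    ll, ySy, _, _ = _loglik_core(np.array([float(omega_g)]), s, q, B, A0, a0y, yDy, logdetD, n, c)
    if not np.all(np.asarray(ySy) > 1e-12 * max(yDy, 1.0)):
        raise DegenerateFitError("y_Q^T S y_Q <= 0: degenerate restricted likelihood")
    return float(ll[0])


def null_restricted_loglik(omega_u, y_Q, F_Q, eigenvalues) -> float:
    """Restricted log-likelihood of the no-marker model with V = Lambda*omega_u + I."""
    y_Q = np.asarray(y_Q, dtype=float).reshape(-1)
    F_Q = np.atleast_2d(np.asarray(F_Q, dtype=float))
    lam = np.asarray(eigenvalues, dtype=float)
    n, c = F_Q.shape
    d = lam * float(omega_u) + 1.0
    dinv, Fd, A0, a0y, yDy, logdetD = _design_stats(y_Q, F_Q, d)
    sign, logdetA = np.linalg.slogdet(A0)
    if sign <= 0:
        raise DegenerateFitError("F_Q^T V^-1 F_Q is not positive definite")
    ySy = yDy - float(a0y @ np.linalg.solve(A0, a0y))
    if ySy <= 1e-12 * max(yDy, 1.0):
        raise DegenerateFitError("y_Q^T S y_Q <= 0 in the null model")
    return float(-0.5 * logdetD - 0.5 * logdetA - 0.5 * (n - c) * np.log(ySy))


def _central_diff_grad(fun, step_scale=1e-6):
    def grad(t):
        t0 = float(t[0])
        h = max(step_scale, step_scale * abs(t0))
        return np.array([(fun([t0 + h]) - fun([t0 - h])) / (2.0 * h)])

    return grad


def _maximize_log10(neg_obj, t0: float):
    """L-BFGS-B over log10(omega) with a central finite-difference gradient."""
    res = optimize.minimize(
        neg_obj,
        x0=np.array([t0]),
        jac=_central_diff_grad(neg_obj),
        method="L-BFGS-B",
        bounds=[_LOG10_BOUNDS],
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RemlConvergenceError(f"variance-ratio optimiser failed: {res.message}", res)
    return res


def fit_null(y_Q, F_Q, eigenvalues) -> NullFit:
    """Estimate the polygenic variance ratio omega_u under the null model.

    The search runs over log10(omega_u) in [-10, 10] starting from
    omega_u = 1; flat likelihoods tie-break toward omega_u = 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)

    def neg(t):
        return -null_restricted_loglik(10.0 ** float(t[0]), y_Q, F_Q, lam)

    res = _maximize_log10(neg, t0=0.0)
    ll_hat = -float(res.fun)
    ll_zero = null_restricted_loglik(0.0, y_Q, F_Q, lam)
    if ll_zero >= ll_hat - _TIE_TOL:
        omega = 0.0
        ll_hat = ll_zero
    else:
        omega = 10.0 ** float(res.x[0])
    return NullFit(
        omega_u_hat=omega,
        V0_diag=lam * omega + 1.0,
        null_restricted_loglik=ll_hat,
    )


@dataclass
class ScanContext:
    """Precomputed rotated data shared by every per-marker fit."""

    basis: SpectralBasis
    null: NullFit
    y_Q: np.ndarray = field(init=False)
    F_Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.basis.rotated_phenotype is None or self.basis.rotated_covariates is None:
            raise ValueError("basis must carry rotated phenotype/covariates (call rotate first)")
        self.y_Q = self.basis.rotated_phenotype
        self.F_Q = np.atleast_2d(self.basis.rotated_covariates)

    @property
    def n(self) -> int:
        return self.y_Q.size

    @property
    def c(self) -> int:
        return self.F_Q.shape[1]


def _marker_stats_at(omega, s, q, B, A0, a0y, yDy, logdetD, n, c):
    """Effect, variance, Wald and p-value at the fitted omega (vectorised)."""
    omega = np.asarray(omega, dtype=float)
    _, ySy, M, FVy = _loglik_core(omega, s, q, B, A0, a0y, yDy, logdetD, n, c)
    denom = 1.0 + omega * s
    if A0.shape[0] == 1:
        sol_B = B[0] / M  # M is (m,), B is (1, m)
        xSy = (q - sol_B * FVy[0]) / denom
    else:
        solF = np.linalg.solve(M, np.moveaxis(FVy, 1, 0)[..., None])[..., 0]  # (m, c)
        xSy = (q - np.einsum("im,mi->m", B, solF)) / denom
    beta = omega * xSy
    sigma_n2 = ySy / (n - c)
    var_beta = omega * sigma_n2 / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(var_beta > 0, beta * beta / np.where(var_beta > 0, var_beta, 1.0), 0.0)
    pval = chi2.sf(wald, df=1)
    return beta, var_beta, sigma_n2, wald, pval


def fit_marker_reml(x, context: ScanContext, rotated: bool = False) -> MarkerFit:
    """REML fit of a single marker by L-BFGS-B over log10(omega_g).

    Monomorphic markers (zero variance in the raw calls) are returned with
    ``status='skipped_monomorphic'`` instead of raising.  The optimiser is
    initialised at the null polygenic ratio and never returns a solution
    worse than the omega_g = 0 boundary.
    """
    xv = np.asarray(x, dtype=float).reshape(-1)
    if not rotated and np.ptp(xv) == 0.0:
        return MarkerFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "skipped_monomorphic")
    x_Q = rotate_vector(xv, context.basis) if not rotated else xv
    d = context.null.V0_diag
    y_Q, F_Q = context.y_Q, context.F_Q
    n, c = context.n, context.c

    def neg(t):
        return -restricted_loglik(10.0 ** float(t[0]), x_Q, y_Q, F_Q, d)

    t0 = np.log10(max(context.null.omega_u_hat, 1e-6))
    res = _maximize_log10(neg, t0=float(np.clip(t0, *_LOG10_BOUNDS)))
    # the profile likelihood can be multimodal (boundary plateau plus an
    # interior maximum); restart from the best coarse-grid point when the
    # quasi-Newton run got caught on the wrong branch
    grid = np.linspace(*_LOG10_BOUNDS, 41)
    grid_vals = np.array([neg([t]) for t in grid])
    t_best = grid[int(np.argmin(grid_vals))]
    if grid_vals.min() < float(res.fun) - _TIE_TOL:
        res = _maximize_log10(neg, t0=float(t_best))
    ll_hat = -float(res.fun)
    ll_zero = restricted_loglik(0.0, x_Q, y_Q, F_Q, d)
    omega = 0.0 if ll_zero >= ll_hat - _TIE_TOL else 10.0 ** float(res.x[0])
    return _finalize_single(omega, x_Q, context)


def _finalize_single(omega: float, x_Q, context: ScanContext) -> MarkerFit:
    d = context.null.V0_diag
    dinv, Fd, A0, a0y, yDy, logdetD = _design_stats(context.y_Q, context.F_Q, d)
    s = np.array([float(x_Q @ (dinv * x_Q))])
    q = np.array([float(x_Q @ (dinv * context.y_Q))])
    B = (Fd.T @ x_Q)[:, None]
    beta, var_beta, sig2, wald, pval = _marker_stats_at(
        np.array([omega]), s, q, B, A0, a0y, yDy, logdetD, context.n, context.c
    )
    if omega == 0.0:
        return MarkerFit(0.0, 0.0, 0.0, float(sig2[0]), 0.0, 1.0)
    return MarkerFit(
        omega_g_hat=float(omega),
        beta_hat=float(beta[0]),
        var_beta=float(var_beta[0]),
        sigma_n2_hat=float(sig2[0]),
        wald=float(wald[0]),
        p_value=float(pval[0]),
    )


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def scan(G, context: ScanContext, grid_points: int = 41, refine_iter: int = 30) -> list[MarkerFit]:
    """REML-fit every marker of a genotype table; order preserved.

    All markers are optimised simultaneously over log10(omega_g): a coarse
    grid on [-10, 10] brackets each marker's maximum and a golden-section
    refinement sharpens it, the whole search running on vectorised
    likelihood evaluations.  Monomorphic markers are reported as skipped.
    """
    if isinstance(G, GenotypeTable):
        Z = G.sample_major()
    else:
        Z = np.asarray(G, dtype=float)
        if Z.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples by markers)")
    n, m_total = Z.shape
    if n != context.n:
        raise ValueError("genotype sample count does not match the rotated data")
    poly = np.ptp(Z, axis=0) > 0.0
    fits: list[MarkerFit] = [
        MarkerFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "skipped_monomorphic")
        for _ in range(m_total)
    ]
    if not poly.any():
        return fits
    X_Q = context.basis.eigenvectors.T @ Z[:, poly]
    d = context.null.V0_diag
    dinv, Fd, A0, a0y, yDy, logdetD = _design_stats(context.y_Q, context.F_Q, d)
    s = np.einsum("nm,nm->m", X_Q, dinv[:, None] * X_Q)
    q = X_Q.T @ (dinv * context.y_Q)
    B = Fd.T @ X_Q  # (c, m)
    n_, c_ = context.n, context.c

    def ll(omega):
        return _loglik_core(omega, s, q, B, A0, a0y, yDy, logdetD, n_, c_)[0]

    lo, hi = _LOG10_BOUNDS
    grid = np.linspace(lo, hi, grid_points)
    best_ll = np.full(s.shape, -np.inf)
    best_t = np.full(s.shape, lo)
    for t in grid:
        vals = ll(np.full(s.shape, 10.0**t))
        better = vals > best_ll
        best_ll = np.where(better, vals, best_ll)
        best_t = np.where(better, t, best_t)
    half = (hi - lo) / (grid_points - 1)
    a = np.clip(best_t - half, lo, hi)
    b = np.clip(best_t + half, lo, hi)
    t1 = b - _GOLDEN * (b - a)
    t2 = a + _GOLDEN * (b - a)
    f1 = ll(10.0**t1)
    f2 = ll(10.0**t2)
    for _ in range(refine_iter):
        move_right = f1 < f2
        a = np.where(move_right, t1, a)
        b = np.where(move_right, b, t2)
        t1_new = np.where(move_right, t2, b - _GOLDEN * (b - a))
        t2_new = np.where(move_right, a + _GOLDEN * (b - a), t1)
        f_old1, f_old2 = f1, f2
        t1, t2 = t1_new, t2_new
        # one fresh point per marker per iteration; the other is inherited
        t_eval = np.where(move_right, t2, t1)
        f_eval = ll(10.0**t_eval)
        f1 = np.where(move_right, f_old2, f_eval)
        f2 = np.where(move_right, f_eval, f_old1)
    t_hat = np.where(f1 > f2, t1, t2)
    ll_hat = np.maximum(f1, f2)
    ll_hat = np.maximum(ll_hat, best_ll)
    t_hat = np.where(best_ll > np.maximum(f1, f2), best_t, t_hat)
    omega = 10.0**t_hat
    ll_zero = ll(np.zeros_like(omega))
    at_zero = ll_zero >= ll_hat - _TIE_TOL
    omega = np.where(at_zero, 0.0, omega)
    beta, var_beta, sig2, wald, pval = _marker_stats_at(
        omega, s, q, B, A0, a0y, yDy, logdetD, n_, c_
    )
    beta = np.where(at_zero, 0.0, beta)
    var_beta = np.where(at_zero, 0.0, var_beta)
    wald = np.where(at_zero, 0.0, wald)
    pval = np.where(at_zero, 1.0, pval)
    idx = np.flatnonzero(poly)
    for k, j in enumerate(idx):
        fits[j] = MarkerFit(
            omega_g_hat=float(omega[k]),
            beta_hat=float(beta[k]),
            var_beta=float(var_beta[k]),
            sigma_n2_hat=float(sig2[k]),
            wald=float(wald[k]),
            p_value=float(pval[k]),
        )
    return fits


def screen_markers(fits, p_cutoff: float, max_survivors: int | None = None) -> np.ndarray:
    """Indices of markers with p <= cutoff, sorted by ascending p-value.

    ``max_survivors`` optionally caps the survivor count (keeping the
    smallest p-values) so the multi-locus stage stays overdetermined.
    """
    p = np.array([f.p_value if f.ok else np.inf for f in fits])
    keep = np.flatnonzero(p <= p_cutoff)
    order = np.lexsort((keep, p[keep]))
    keep = keep[order]
    if max_survivors is not None:
        keep = keep[:max_survivors]
    return keep
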