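"""REML fit of the reduced (no-genotype) multi-tissue mixed model.

Under the null hypothesis of no genotype effect the expression vector
vec(Y) (subject-major, tissue-fastest) follows

    Y_H0 = J alpha + M lam + A u + D x + xi

with J the nt x t tissue-intercept design, M = vec(m) the methylation
column, A the nt x n subject-intercept design (u ~ N(0, tau I_n)), D the
stacked tissue-methylation design carrying the per-subject random
methylation slopes (x ~ N(0, theta I)), and xi ~ N(0, eps I_nt).  Because
every random effect is independent across subjects, the marginal
covariance is block diagonal with per-subject t x t blocks

    Sigma_i = eps I_t + tau 1 1^T + theta diag(m_i o m_i),

a diagonal matrix plus a rank-1 intercept term, inverted in closed form by
Sherman-Morrison — so nothing of size nt x nt is ever formed and every
solve is O(n t).

Variance components (tau, theta, eps) are estimated by restricted maximum
likelihood; (alpha, lam) are profiled out by GLS at each variance iterate.
"""

from __future__ import annotations

import math
from typing import Callable, NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = ["NullModel", "fit_null", "sigma_inverse_apply", "variance_se"]

_LOG2PI = math.log(2.0 * math.pi)
# objective value returned when a variance iterate is numerically singular;
# kept moderate so the line search can interpolate back into the feasible region
_PENALTY = 1e7


class _SigmaOps(NamedTuple):
    """Blockwise solver and log-determinant for a fixed (tau, theta, eps)."""

    solve: Callable[[np.ndarray], np.ndarray]
    logdet: float


def _make_sigma_ops(
    tau: float, theta: float, eps: float, m: np.ndarray | None, n: int, t: int
) -> _SigmaOps:
    # per-subject blocks Sigma_i = diag(d_i) + tau 1 1^T with
    # d_ij = eps + theta m_ij^2; Sherman-Morrison on the intercept term
    if m is not None and theta > 0.0:
        d = eps + theta * m**2  # (n, t)
    else:
        d = np.full((n, t), eps)
    dinv = 1.0 / d
    s = dinv.sum(axis=1)  # 1^T D_i^{-1} 1, shape (n,)
    denom = 1.0 + tau * s
    coef = (tau / denom)[:, None] * dinv  # tau/(1+tau s_i) * D_i^{-1} 1

    def solve(v: np.ndarray) -> np.ndarray:
        dv = v * dinv
        return dv - coef * dv.sum(axis=-1, keepdims=True)

    logdet = float(np.log(d).sum() + np.log(denom).sum())
    return _SigmaOps(solve=solve, logdet=logdet)


class _GlsFit(NamedTuple):
    coef: np.ndarray
    resid: np.ndarray  # (n, t)
    si_resid: np.ndarray  # Sigma^{-1} resid, (n, t)
    xtsix: np.ndarray
    si_x: np.ndarray  # (p, n, t)
    logdet_x: float  # log |X^T Sigma^{-1} X|
    neg2_reml: float
    loglik: float


def _gls_profile(
    ops: _SigmaOps, xcols: np.ndarray, y: np.ndarray
) -> _GlsFit:
    p = xcols.shape[0]
    n, t = y.shape
    si_x = ops.solve(xcols)
    si_y = ops.solve(y)
    xtsix = np.einsum("ant,bnt->ab", xcols, si_x)
    xtsiy = np.einsum("ant,nt->a", xcols, si_y)
    try:
        coef = np.linalg.solve(xtsix, xtsiy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X^T Sigma^{-1} X is singular: degenerate fixed-effect design"
        ) from exc
    resid = y - np.einsum("a,ant->nt", coef, xcols)
    si_resid = si_y - np.einsum("a,ant->nt", coef, si_x)
    quad = float((resid * si_resid).sum())
    sign, logdet_x = np.linalg.slogdet(xtsix)
    if sign <= 0:
        raise np.linalg.LinAlgError("X^T Sigma^{-1} X not positive definite")
    neg2 = ops.logdet + logdet_x + quad
    loglik = -0.5 * neg2 - 0.5 * (n * t - p) * _LOG2PI
    return _GlsFit(coef, resid, si_resid, xtsix, si_x, logdet_x, neg2, loglik)


class NullModel(BaseEstimator):
    """REML estimator of the null multi-tissue expression model.

    Parameters
    ----------
    include_methylation : bool
        If True, fit Y = J alpha + M lam + A u + D x + xi.  If False, fit the
        methylation-free null Y = J alpha + A u + xi (used by the
        genotype + G x T comparator test), fixing lam = theta = 0.
    max_iter : int
        Maximum optimizer iterations.
    tol : float
        Relative-objective convergence tolerance.
    var_floor : float
        Lower bound for each variance component (boundary estimates land here).

    Attributes
    ----------
    alpha_ : ndarray of shape (t,)
        GLS tissue intercepts at the REML variances.
    lam_ : float
        Overall methylation slope (0 when ``include_methylation=False``).
    tau_, theta_, eps_ : float
        REML variance components (subject, tissue-methylation, residual).
    residuals_ : ndarray of shape (n, t)
        GLS residuals Y - J alpha_ - M lam_.
    loglik_ : float
        Restricted log-likelihood at the optimum.
    converged_ : bool
    loglik_path_ : list of float
        Objective values at accepted optimizer iterates (non-decreasing).
    """

    def __init__(
        self,
        include_methylation: bool = True,
        max_iter: int = 200,
        tol: float = 1e-8,
        var_floor: float = 1e-8,
    ):
        self.include_methylation = include_methylation
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor

    # ------------------------------------------------------------------ fit

    def fit(self, y: np.ndarray, m: np.ndarray | None = None) -> "NullModel":
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be an n x t matrix")
        n, t = y.shape
        if n < 3 or t < 2:
            raise ValueError(f"need n >= 3 subjects and t >= 2 tissues, got {n} x {t}")
        if not np.isfinite(y).all():
            raise ValueError("y contains missing or non-finite values")
        if self.include_methylation:
            if m is None:
                raise ValueError("methylation matrix m is required")
            m = np.asarray(m, dtype=float)
            if m.shape != (n, t):
                raise ValueError(f"m must have shape ({n}, {t}), got {m.shape}")
            if not np.isfinite(m).all():
                raise ValueError("m contains missing or non-finite values")
            if np.ptp(m) == 0.0:
                raise ValueError("degenerate design: methylation is constant")
        else:
            m = None

        xcols = self._design(n, t, m)
        # quick rank check on the raw design
        if np.linalg.matrix_rank(xcols.reshape(xcols.shape[0], -1).T) < xcols.shape[0]:
            raise ValueError("degenerate fixed-effect design (rank deficient)")

        self.n_subjects_, self.n_tissues_ = n, t
        self._m = m
        self._xcols = xcols
        self._y = y

        # Profile out the residual scale: with Sigma = eps * V(r) and
        # r = (tau/eps, theta/eps), the REML-optimal eps has the closed form
        # eps-hat(r) = quad_V / (nt - p), leaving a well-conditioned
        # optimization over the log variance ratios alone.
        p = xcols.shape[0]
        dof = n * t - p
        path: list[float] = []

        def profiled(logr: np.ndarray) -> tuple[float, float]:
            r_tau, r_theta = self._unpack_ratios(logr)
            try:
                ops = _make_sigma_ops(r_tau, r_theta, 1.0, m, n, t)
                gls = _gls_profile(ops, xcols, y)
            except np.linalg.LinAlgError:
                return _PENALTY, np.nan
            quad = gls.neg2_reml - ops.logdet - gls.logdet_x
            eps_hat = max(quad / dof, self.var_floor)
            val = (
                dof * (math.log(eps_hat) + quad / (dof * eps_hat))
                + ops.logdet
                + gls.logdet_x
            )
            return (val, eps_hat) if np.isfinite(val) else (_PENALTY, np.nan)

        def objective(logr: np.ndarray) -> float:
            return profiled(logr)[0]

        x0 = self._init_logratios(xcols, y)
        lb, ub = math.log(1e-8), math.log(1e8)
        bounds = [(lb, ub)] * len(x0)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            callback=lambda xk: path.append(-0.5 * objective(xk)),
            options={"maxiter": self.max_iter, "ftol": self.tol * 1e-2},
        )
        stalled = res.jac is not None and np.abs(res.jac).max() > 1.0
        if (not res.success) or stalled or res.fun >= _PENALTY:
            # gradient-based search can stall against the singular corners of
            # the ratio space; a direct-search pass is slower but immune
            res_nm = minimize(
                objective, x0, method="Nelder-Mead", bounds=bounds,
                options={"maxiter": 50 * self.max_iter, "fatol": self.tol,
                         "xatol": 1e-8},
            )
            if res_nm.fun <= res.fun:
                res = res_nm
        r_tau, r_theta = self._unpack_ratios(res.x)
        eps = profiled(res.x)[1]
        self.tau_, self.theta_, self.eps_ = r_tau * eps, r_theta * eps, eps
        self.converged_ = bool(res.success and np.isfinite(eps))
        self.loglik_path_ = path
        tau, theta = self.tau_, self.theta_

        self._ops = _make_sigma_ops(tau, theta, eps, m, n, t)
        gls = _gls_profile(self._ops, xcols, y)
        self.alpha_ = gls.coef[:t].copy()
        self.lam_ = float(gls.coef[t]) if self.include_methylation else 0.0
        self.residuals_ = gls.resid
        self._si_resid = gls.si_resid
        self._si_x = gls.si_x
        self._xtsix = gls.xtsix
        self._xtsix_cho = cho_factor(gls.xtsix)
        self.loglik_ = gls.loglik
        return self

    # ------------------------------------------------------------- helpers

    @staticmethod
    def _design(n: int, t: int, m: np.ndarray | None) -> np.ndarray:
        """Fixed design as stacked (p, n, t) arrays: tissue indicators + vec(m)."""
        cols = [np.tile((np.arange(t) == j).astype(float), (n, 1)) for j in range(t)]
        if m is not None:
            cols.append(m)
        return np.stack(cols)

    def _unpack_ratios(self, logr: np.ndarray) -> tuple[float, float]:
        """Variance ratios (tau/eps, theta/eps) from the optimizer vector."""
        if self.include_methylation:
            r_tau, r_theta = np.exp(logr)
        else:
            (r_tau,) = np.exp(logr)
            r_theta = 0.0
        return float(r_tau), float(r_theta)

    def _init_logratios(self, xcols: np.ndarray, y: np.ndarray) -> np.ndarray:
        # the residual scale is profiled out, so only the ratios need a start
        start = [0.3, 0.15] if self.include_methylation else [0.3]
        return np.log(start)

    # ------------------------------------------------------------- queries

    def solve_sigma(self, v: np.ndarray) -> np.ndarray:
        """Apply Sigma-hat^{-1} blockwise; accepts (n, t), flat nt, or batches
        shaped (..., n, t)."""
        v = np.asarray(v, dtype=float)
        n, t = self.n_subjects_, self.n_tissues_
        if v.ndim == 1:
            if v.size != n * t:
                raise ValueError(f"vector must have length {n * t}")
            return self._ops.solve(v.reshape(n, t)).ravel()
        return self._ops.solve(v)

    def project(self, v: np.ndarray) -> np.ndarray:
        """Apply the projected precision P0 = Sigma^{-1} - Sigma^{-1} X
        (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1} to batches shaped (..., n, t)."""
        si_v = self._ops.solve(np.asarray(v, dtype=float))
        xtsiv = np.einsum("ant,...nt->...a", self._xcols, si_v)
        w = cho_solve(self._xtsix_cho, xtsiv.reshape(-1, xtsiv.shape[-1]).T).T
        w = w.reshape(xtsiv.shape)
        return si_v - np.einsum("...a,ant->...nt", w, self._si_x)

    def gls_residuals(self, y: np.ndarray) -> np.ndarray:
        """GLS residuals of a new response at the fitted variance components
        (the fixed effects are re-profiled; Sigma-hat stays frozen)."""
        y = np.asarray(y, dtype=float)
        gls = _gls_profile(self._ops, self._xcols, y)
        return gls.resid

    def restricted_loglik(self, tau: float, theta: float, eps: float) -> float:
        """Restricted log-likelihood at arbitrary variance values (with the
        fixed effects profiled out); used for diagnostics and cross-checks."""
        ops = _make_sigma_ops(tau, theta if self.include_methylation else 0.0,
                              eps, self._m, self.n_subjects_, self.n_tissues_)
        return _gls_profile(ops, self._xcols, self._y).loglik

    def sigma_blocks(self) -> np.ndarray:
        """Per-subject t x t covariance blocks of Sigma-hat, shape (n, t, t)."""
        n, t = self.n_subjects_, self.n_tissues_
        base = self.eps_ * np.eye(t) + self.tau_ * np.ones((t, t))
        blocks = np.broadcast_to(base, (n, t, t)).copy()
        if self._m is not None and self.theta_ > 0:
            idx = np.arange(t)
            blocks[:, idx, idx] += self.theta_ * self._m**2
        return blocks

    def sigma_matrix(self) -> np.ndarray:
        """Dense nt x nt Sigma-hat (diagnostics / small problems only)."""
        n, t = self.n_subjects_, self.n_tissues_
        sigma = np.zeros((n * t, n * t))
        for i, block in enumerate(self.sigma_blocks()):
            sigma[i * t : (i + 1) * t, i * t : (i + 1) * t] = block
        return sigma

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "alpha": self.alpha_.tolist(),
            "lambda": self.lam_,
            "tau": self.tau_,
            "theta": self.theta_,
            "eps": self.eps_,
            "loglik": self.loglik_,
            "converged": self.converged_,
            "n_subjects": self.n_subjects_,
            "n_tissues": self.n_tissues_,
        }


def fit_null(y: np.ndarray, m: np.ndarray, **kwargs) -> NullModel:
    """Fit the null model (with methylation) by REML; see :class:`NullModel`."""
    return NullModel(include_methylation=True, **kwargs).fit(y, m)


def sigma_inverse_apply(fit: NullModel, v: np.ndarray) -> np.ndarray:
    """Apply the fitted Sigma-hat^{-1} to an nt-vector (or n x t matrix)."""
    return fit.solve_sigma(v)


def variance_se(fit: NullModel, rel_step: float = 1e-3) -> np.ndarray:
    """Asymptotic standard errors of the REML variance components from the
    observed information (numerical Hessian of the restricted log-likelihood
    on the variance scale).  Order: (tau, theta, eps), or (tau, eps) for a
    methylation-free fit."""
    if fit.include_methylation:
        v0 = np.array([fit.tau_, fit.theta_, fit.eps_])
        ll = lambda v: fit.restricted_loglik(v[0], v[1], v[2])
    else:
        v0 = np.array([fit.tau_, fit.eps_])
        ll = lambda v: fit.restricted_loglik(v[0], 0.0, v[1])
    k = len(v0)
    h = rel_step * (np.abs(v0) + 1e-2)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                vp, vm = v0.copy(), v0.copy()
                vp[i] += h[i]
                vm[i] -= h[i]
                hess[i, i] = (ll(vp) - 2.0 * ll(v0) + ll(vm)) / h[i] ** 2
            else:
                vpp, vpm, vmp, vmm = (v0.copy() for _ in range(4))
                vpp[[i, j]] += h[[i, j]]
                vpm[i] += h[i]
                vpm[j] -= h[j]
                vmp[i] -= h[i]
                vmp[j] += h[j]
                vmm[[i, j]] -= h[[i, j]]
                hess[i, j] = hess[j, i] = (
                    ll(vpp) - ll(vpm) - ll(vmp) + ll(vmm)
                ) / (4.0 * h[i] * h[j])
    info = -hess
    cov = np.linalg.inv(info)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))
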