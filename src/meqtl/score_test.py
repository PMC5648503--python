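"""Joint variance-component score test for multi-tissue eQTL with methylation.

Given a REML null fit (no genotype terms), four efficient scores are
evaluated at the null — with Y-hat the GLS residuals and Sigma-hat the
fitted covariance:

    U_beta  = Y-hat^T Sigma^{-1} (G - G-bar)                 additive genetic
    U_phi   = Y-hat^T Sigma^{-1} (MG - MG-bar)               G x M
    U_gamma = 1/2 Y-hat^T Sigma^{-1} B B^T Sigma^{-1} Y-hat  G x T
    U_delta = 1/2 Y-hat^T Sigma^{-1} C C^T Sigma^{-1} Y-hat  G x M x T

where G is the genotype expanded over tissue slots, MG its elementwise
product with vec(m), B the nt x t stacked-genotype design and C the stacked
methylation x genotype design.  The joint statistic is the weighted sum

    U_zeta = a_beta U_beta^2 + a_phi U_phi^2 + a_gamma U_gamma + a_delta U_delta

which is a single quadratic form Y^T P0 K P0 Y in the data with
P0 = Sigma^{-1} - Sigma^{-1} X (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1} the
precision projected off the null fixed design X.  Since P0 Sigma P0 = P0,
the null moments are E = tr(P0 K) and Var = 2 tr(P0 K P0 K), computed
through the rank <= 2t + 2 structure of K.  U_zeta is approximated by a
Satterthwaite scaled chi-square, kappa = Var / (2 E), nu = 2 E^2 / Var.

Each weight standardizes its component to unit null standard deviation
(a normalization convention: the components live on different scales, and
the null SDs come from the same P0-trace machinery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .null_model import NullModel

__all__ = [
    "ScoreComponents",
    "JointStatistic",
    "efficient_scores",
    "null_moments",
    "combine_and_test",
    "jaguar_style_test",
    "JointScoreTest",
    "JaguarScoreTest",
]

_VAR_DEGENERATE = 1e-12  # Var < this * E^2 is treated as a point mass


@dataclass
class ScoreComponents:
    """Efficient scores and the centered/stacked designs they involve.

    The linear components ``u_beta``/``u_phi`` are signed; the quadratic
    components ``u_gamma``/``u_delta`` are non-negative by construction.
    Designs are kept in subject x tissue layout: ``g_centered`` and
    ``mg_centered`` are the (n, t) centered genotype and genotype x
    methylation arrays; column j of the nt x t stacked designs B and C is
    recovered by zeroing all tissue slots except j of ``b_cols``/``c_cols``.
    """

    u_beta: float
    u_phi: float
    u_gamma: float
    u_delta: float
    g_centered: np.ndarray
    mg_centered: np.ndarray | None
    b_cols: np.ndarray  # (n, t): g_i replicated, column j feeds B[:, j]
    c_cols: np.ndarray | None  # (n, t): m_ij * g_i, column j feeds C[:, j]
    degenerate: bool = False


@dataclass
class JointStatistic:
    """Joint score statistic with its Satterthwaite null approximation."""

    u_zeta: float
    weights: dict[str, float]
    e_null: float
    var_null: float
    kappa: float
    nu: float
    p_value: float
    degenerate: bool = False
    components: ScoreComponents | None = None
    component_p: dict[str, float] = field(default_factory=dict)


def _check_genotype(fit: NullModel, g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != (fit.n_subjects_,):
        raise ValueError(f"genotype must have shape ({fit.n_subjects_},)")
    if not np.isfinite(g).all():
        raise ValueError("genotype contains missing or non-finite values")
    return g


def efficient_scores(
    fit: NullModel, g: np.ndarray, m: np.ndarray | None = None,
    resid: np.ndarray | None = None,
) -> ScoreComponents:
    """Evaluate the efficient scores at a null fit.

    ``m`` defaults to the methylation stored in the fit; for a
    methylation-free fit the G x M and G x M x T scores are zero and their
    designs are None.  ``resid`` overrides the fit's residuals (used when a
    frozen null fit is re-applied to a new response).
    """
    g = _check_genotype(fit, g)
    n, t = fit.n_subjects_, fit.n_tissues_
    if m is None:
        m = fit._m
    elif not fit.include_methylation:
        raise ValueError("fit was built without methylation terms")
    if resid is None:
        resid = fit.residuals_
    si_resid = fit.solve_sigma(resid)  # Sigma^{-1} Y-hat, (n, t)

    degenerate = bool(np.ptp(g) == 0.0)
    g_exp = np.repeat(g[:, None], t, axis=1)  # (n, t), genotype per tissue slot
    g_centered = g_exp - g_exp.mean()
    u_beta = float((si_resid * g_centered).sum())
    # B^T Sigma^{-1} Y-hat: column j of B holds g_i in tissue slot j
    bt = (g[:, None] * si_resid).sum(axis=0)
    u_gamma = 0.5 * float(bt @ bt)

    if m is not None:
        mg = m * g[:, None]
        mg_centered = mg - mg.mean()
        u_phi = float((si_resid * mg_centered).sum())
        ct = (mg * si_resid).sum(axis=0)
        u_delta = 0.5 * float(ct @ ct)
        c_cols = mg
    else:
        mg_centered, c_cols = None, None
        u_phi, u_delta = 0.0, 0.0

    return ScoreComponents(
        u_beta=u_beta,
        u_phi=u_phi,
        u_gamma=u_gamma,
        u_delta=u_delta,
        g_centered=g_centered,
        mg_centered=mg_centered,
        b_cols=g_exp,
        c_cols=c_cols,
        degenerate=degenerate,
    )


# --------------------------------------------------------------- kernel algebra


def _kernel_columns(sc: ScoreComponents) -> tuple[np.ndarray, dict[str, slice]]:
    """Stack the kernel factors L = [gc | mgc | B | C] as (k, n, t) arrays.

    K = L diag(w) L^T with w = (a_beta, a_phi, a_gamma/2 * 1_t, a_delta/2 * 1_t).
    """
    n, t = sc.b_cols.shape
    cols = [sc.g_centered]
    slices = {"beta": slice(0, 1)}
    pos = 1
    if sc.mg_centered is not None:
        cols.append(sc.mg_centered)
        slices["phi"] = slice(pos, pos + 1)
        pos += 1
    b = np.zeros((t, n, t))
    for j in range(t):
        b[j, :, j] = sc.b_cols[:, j]
    cols.extend(b)
    slices["gamma"] = slice(pos, pos + t)
    pos += t
    if sc.c_cols is not None:
        c = np.zeros((t, n, t))
        for j in range(t):
            c[j, :, j] = sc.c_cols[:, j]
        cols.extend(c)
        slices["delta"] = slice(pos, pos + t)
        pos += t
    return np.stack(cols), slices


def _projected_gram(fit: NullModel, cols: np.ndarray) -> np.ndarray:
    """Q = L^T P0 L for stacked columns L, via blockwise solves only."""
    p0_cols = fit.project(cols)
    return np.einsum("ant,bnt->ab", cols, p0_cols)


def _component_moments(q: np.ndarray, slices: dict[str, slice]) -> dict[str, tuple[float, float]]:
    """Null (mean, variance) of each component statistic from Q = L^T P0 L.

    U_beta^2 and U_phi^2: U ~ N(0, q) so E = q, Var = 2 q^2.  U_gamma and
    U_delta with gram block Qb: E = tr(Qb)/2, Var = tr(Qb^2)/2.
    """
    out = {}
    for name in ("beta", "phi"):
        if name in slices:
            qv = float(q[slices[name], slices[name]][0, 0])
            out[name] = (qv, 2.0 * qv**2)
    for name in ("gamma", "delta"):
        if name in slices:
            qb = q[slices[name], slices[name]]
            out[name] = (0.5 * float(np.trace(qb)), 0.5 * float(np.trace(qb @ qb)))
    return out


def _default_weights(moments: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Standardize each component to unit null SD; a component whose null
    variance vanishes (e.g. a monomorphic genotype) gets weight 0."""
    weights = {}
    for name, (_, var) in moments.items():
        sd = np.sqrt(var)
        weights[name] = 1.0 / sd if sd > 1e-300 else 0.0
    return weights


def _weight_vector(
    weights: dict[str, float], slices: dict[str, slice], k: int
) -> np.ndarray:
    w = np.zeros(k)
    for name, sl in slices.items():
        scale = weights.get(name, 0.0)
        w[sl] = scale if name in ("beta", "phi") else 0.5 * scale
    return w


def null_moments(
    fit: NullModel, sc: ScoreComponents, weights: dict[str, float]
) -> tuple[float, float]:
    """Null mean and variance of U_zeta for given component weights.

    Uses the combined kernel, so covariances between all four components
    (exact under Gaussianity) are included: E = tr(P0 K),
    Var = 2 tr(P0 K P0 K) through Q = L^T P0 L.
    """
    cols, slices = _kernel_columns(sc)
    q = _projected_gram(fit, cols)
    w = _weight_vector(weights, slices, q.shape[0])
    wq = w[:, None] * q
    e = float(np.trace(wq))
    var = 2.0 * float(np.einsum("ij,ji->", wq, wq))
    return e, var


def _satterthwaite(u: float, e: float, var: float) -> tuple[float, float, float, bool]:
    """Moment-matched scaled chi-square tail probability."""
    if e <= 0.0 or var <= 0.0 or var < _VAR_DEGENERATE * e**2:
        return np.nan, np.nan, 1.0, True
    kappa = var / (2.0 * e)
    nu = 2.0 * e**2 / var
    p = float(stats.chi2.sf(u / kappa, nu))
    return kappa, nu, p, False


def combine_and_test(
    fit: NullModel, sc: ScoreComponents, weights: dict[str, float] | None = None
) -> JointStatistic:
    """Assemble U_zeta, its Satterthwaite null approximation and p-value.

    A monomorphic genotype (or any degenerate kernel) yields p = 1 with the
    degenerate flag set.  Per-component marginal p-values (each component
    against its own Satterthwaite reference) are reported alongside.
    """
    cols, slices = _kernel_columns(sc)
    q = _projected_gram(fit, cols)
    comp_moments = _component_moments(q, slices)
    if weights is None:
        weights = _default_weights(comp_moments)

    stats_by_name = {
        "beta": sc.u_beta**2,
        "phi": sc.u_phi**2,
        "gamma": sc.u_gamma,
        "delta": sc.u_delta,
    }
    u_zeta = float(sum(weights.get(k, 0.0) * stats_by_name[k] for k in slices))

    w = _weight_vector(weights, slices, q.shape[0])
    wq = w[:, None] * q
    e = float(np.trace(wq))
    var = 2.0 * float(np.einsum("ij,ji->", wq, wq))

    component_p = {}
    for name, (ce, cvar) in comp_moments.items():
        *_, cp, cdeg = _satterthwaite(stats_by_name[name], ce, cvar)
        component_p[name] = 1.0 if cdeg else cp

    if sc.degenerate:
        return JointStatistic(
            u_zeta=u_zeta, weights=weights, e_null=e, var_null=var,
            kappa=np.nan, nu=np.nan, p_value=1.0, degenerate=True,
            components=sc, component_p=component_p,
        )
    kappa, nu, p, deg = _satterthwaite(u_zeta, e, var)
    return JointStatistic(
        u_zeta=u_zeta, weights=weights, e_null=e, var_null=var,
        kappa=kappa, nu=nu, p_value=p, degenerate=deg,
        components=sc, component_p=component_p,
    )


def jaguar_style_test(fit_nometh: NullModel, g: np.ndarray) -> JointStatistic:
    """Joint genotype + G x T score test without methylation terms.

    This is the multi-tissue comparator: the null model is refit without the
    methylation fixed effect and tissue-methylation variance (lam = theta = 0)
    and only a_beta U_beta^2 + a_gamma U_gamma is combined, with the same
    Satterthwaite machinery.
    """
    if fit_nometh.include_methylation:
        raise ValueError("jaguar_style_test requires a methylation-free null fit "
                         "(NullModel(include_methylation=False))")
    sc = efficient_scores(fit_nometh, g)
    return combine_and_test(fit_nometh, sc)


# ------------------------------------------------------------------ estimators


class JointScoreTest(BaseEstimator):
    """Joint score test of any genotype effect on multi-tissue expression.

    ``fit(y, m)`` estimates the nuisance parameters once by REML; ``test(g)``
    then scores any number of SNPs against the same fit (the per-pair
    estimation that makes a cis scan cheap).

    Parameters
    ----------
    weights : dict or None
        Optional fixed component weights {"beta", "phi", "gamma", "delta"};
        by default each component is standardized to unit null SD.

    Attributes
    ----------
    null_model_ : NullModel
        The fitted null model (REML variance components, GLS residuals).
    """

    def __init__(self, weights: dict[str, float] | None = None):
        self.weights = weights

    def fit(self, y: np.ndarray, m: np.ndarray) -> "JointScoreTest":
        self.null_model_ = NullModel(include_methylation=True).fit(y, m)
        if not self.null_model_.converged_:
            warnings.warn("null model REML did not report convergence", stacklevel=2)
        return self

    def test(self, g: np.ndarray) -> JointStatistic:
        sc = efficient_scores(self.null_model_, g)
        return combine_and_test(self.null_model_, sc, weights=self.weights)

    def pvalue(self, g: np.ndarray) -> float:
        return self.test(g).p_value


class JaguarScoreTest(BaseEstimator):
    """Genotype + G x T joint score test (no methylation terms)."""

    def fit(self, y: np.ndarray, m: np.ndarray | None = None) -> "JaguarScoreTest":
        # m accepted and ignored so the comparators share a call signature
        self.null_model_ = NullModel(include_methylation=False).fit(y)
        return self

    def test(self, g: np.ndarray) -> JointStatistic:
        return jaguar_style_test(self.null_model_, g)

    def pvalue(self, g: np.ndarray) -> float:
        return self.test(g).p_value
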