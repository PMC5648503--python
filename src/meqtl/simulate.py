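"""Generative model for multi-tissue gene expression at a single locus.

For subject i (i = 1..n) and tissue j (j = 1..t), expression of one target
transcript is generated as

    y_ij = alpha_j + beta * g_i + lam * m_ij + phi * m_ij * g_i
           + a_i + b_j * g_i + c_j * m_ij * g_i + d_j * m_ij + xi_ij

with genotype g_i ~ Binomial(2, MAF) (minor-allele counts under HWE),
methylation rows m_i ~ MVN(0, meth_cov), and independent random effects

    a_i  ~ N(0, tau)      subject intercept
    b_ij ~ N(0, gamma)    tissue-specific genotype effect           (G x T)
    c_ij ~ N(0, delta)    tissue-specific genotype x methylation    (G x M x T)
    d_ij ~ N(0, theta)    tissue-specific methylation effect        (M x T)
    xi   ~ N(0, eps)      residual noise.

All random effects are independent across subjects (each subject draws its
own t-vector of tissue-level effects), so subjects are i.i.d. and the
marginal covariance of vec(Y) is block diagonal — the structure the null
model fits.

Interaction variances are usually specified through the proportion of random
variance they explain, PVE_gamma = gamma / (theta + tau + eps + gamma + delta)
and likewise PVE_delta; see :func:`pve_to_variances`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "SimParams",
    "SimulatedDataset",
    "compound_symmetric",
    "gen_genotypes",
    "gen_methylation",
    "pve_to_variances",
    "gen_expression",
    "simulate_dataset",
]


def compound_symmetric(t: int, rho: float = 0.5, var: float = 1.0) -> np.ndarray:
    """Compound-symmetric t x t covariance: unit (or `var`) diagonal, common
    off-diagonal correlation `rho`. PD for -1/(t-1) < rho < 1."""
    if not -1.0 / (t - 1) < rho < 1.0:
        raise ValueError(f"rho={rho} gives a non-PD compound-symmetric matrix for t={t}")
    return var * ((1.0 - rho) * np.eye(t) + rho * np.ones((t, t)))


@dataclass
class SimParams:
    """Parameters of the single-locus generative model.

    Fixed effects: tissue intercepts ``alpha`` (length t), additive genotype
    effect ``beta``, overall methylation slope ``lam``, genotype x methylation
    interaction ``phi``. Variance components: ``tau`` (subject), ``gamma``
    (G x T), ``delta`` (G x M x T), ``theta`` (tissue methylation), ``eps``
    (residual). ``meth_cov`` is the cross-tissue methylation covariance.
    """

    n_subjects: int
    n_tissues: int
    maf: float = 0.3
    alpha: np.ndarray | None = None
    beta: float = 0.0
    lam: float = 0.0
    phi: float = 0.0
    tau: float = 1.0
    gamma: float = 0.0
    delta: float = 0.0
    theta: float = 1.0
    eps: float = 1.0
    meth_cov: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_tissues < 1:
            raise ValueError("n_subjects and n_tissues must be positive")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        for name in ("tau", "gamma", "delta", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        t = self.n_tissues
        if self.alpha is None:
            self.alpha = np.zeros(t)
        else:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if self.alpha.shape != (t,):
                raise ValueError(f"alpha must have length t={t}")
        if self.meth_cov is None:
            self.meth_cov = compound_symmetric(t, 0.5) if t > 1 else np.eye(1)
        else:
            self.meth_cov = np.asarray(self.meth_cov, dtype=float)
        _validate_cov(self.meth_cov, t)

    @classmethod
    def from_pve(
        cls,
        n_subjects: int,
        n_tissues: int,
        pve_gxt: float = 0.0,
        pve_gxmxt: float = 0.0,
        **kwargs,
    ) -> "SimParams":
        """Build parameters with (gamma, delta) derived from PVE percentages,
        holding the nuisance variances (tau, theta, eps) at their values in
        ``kwargs`` (default 1 each)."""
        tau = kwargs.get("tau", 1.0)
        theta = kwargs.get("theta", 1.0)
        eps = kwargs.get("eps", 1.0)
        gamma, delta = pve_to_variances(pve_gxt, pve_gxmxt, tau=tau, theta=theta, eps=eps)
        return cls(n_subjects, n_tissues, gamma=gamma, delta=delta, **kwargs)


def _validate_cov(cov: np.ndarray, t: int) -> np.ndarray:
    if cov.shape != (t, t):
        raise ValueError(f"meth_cov must be {t}x{t}, got {cov.shape}")
    if not np.allclose(cov, cov.T):
        raise ValueError("meth_cov must be symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "meth_cov is not positive definite (Cholesky factorization failed)"
        ) from exc


class SimulatedDataset(NamedTuple):
    """One simulated locus: genotype (n,), methylation (n, t), expression (n, t)."""

    g: np.ndarray
    m: np.ndarray
    y: np.ndarray


def gen_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n minor-allele counts i.i.d. Binomial(2, maf) (HWE)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=n)


def gen_methylation(
    n: int, t: int, meth_cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x t methylation matrix with rows i.i.d. MVN(0, meth_cov)."""
    meth_cov = np.asarray(meth_cov, dtype=float)
    chol = _validate_cov(meth_cov, t)
    return rng.standard_normal((n, t)) @ chol.T


def pve_to_variances(
    pve_gamma: float,
    pve_delta: float,
    tau: float = 1.0,
    theta: float = 1.0,
    eps: float = 1.0,
) -> tuple[float, float]:
    """Solve for (gamma, delta) given PVE percentages of the G x T and
    G x M x T components.

    Both definitions share the denominator theta + tau + eps + gamma + delta,
    so with s0 = tau + theta + eps and fractions p_g, p_d the total is
    T = s0 / (1 - p_g - p_d) and gamma = p_g * T, delta = p_d * T.
    """
    if pve_gamma < 0 or pve_delta < 0:
        raise ValueError("PVE values must be >= 0")
    p_g, p_d = pve_gamma / 100.0, pve_delta / 100.0
    if p_g + p_d >= 1.0:
        raise ValueError(
            f"pve_gamma + pve_delta = {pve_gamma + pve_delta} >= 100 is infeasible"
        )
    s0 = tau + theta + eps
    total = s0 / (1.0 - p_g - p_d)
    return p_g * total, p_d * total


@dataclass
class RandomEffects:
    """Per-dataset random-effect draws (exposed for exchangeability checks).

    Every subject draws its own tissue-level effects, so all arrays are
    per-subject and permuting subject indices permutes the draws."""

    a: np.ndarray  # (n,)  subject intercepts
    b: np.ndarray  # (n, t) tissue genotype slopes
    c: np.ndarray  # (n, t) tissue genotype x methylation slopes
    d: np.ndarray  # (n, t) tissue methylation slopes
    xi: np.ndarray  # (n, t) residuals


def _draw_effects(p: SimParams, rng: np.random.Generator) -> RandomEffects:
    n, t = p.n_subjects, p.n_tissues
    return RandomEffects(
        a=np.sqrt(p.tau) * rng.standard_normal(n),
        b=np.sqrt(p.gamma) * rng.standard_normal((n, t)),
        c=np.sqrt(p.delta) * rng.standard_normal((n, t)),
        d=np.sqrt(p.theta) * rng.standard_normal((n, t)),
        xi=np.sqrt(p.eps) * rng.standard_normal((n, t)),
    )


def _assemble(
    p: SimParams, g: np.ndarray, m: np.ndarray, eff: RandomEffects
) -> np.ndarray:
    gcol = np.asarray(g, dtype=float)[:, None]
    fixed = p.alpha[None, :] + p.beta * gcol + p.lam * m + p.phi * m * gcol
    random = eff.a[:, None] + eff.b * gcol + eff.c * m * gcol + eff.d * m
    return fixed + random + eff.xi


def gen_expression(
    p: SimParams, g: np.ndarray, m: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Generate the n x t expression matrix for given genotype/methylation."""
    g = np.asarray(g)
    m = np.asarray(m, dtype=float)
    n, t = p.n_subjects, p.n_tissues
    if g.shape != (n,):
        raise ValueError(f"genotype must have shape ({n},), got {g.shape}")
    if m.shape != (n, t):
        raise ValueError(f"methylation must have shape ({n}, {t}), got {m.shape}")
    return _assemble(p, g, m, _draw_effects(p, rng))


def simulate_dataset(p: SimParams, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate one complete locus (genotype, methylation, expression).

    A fresh generator seeded with ``p.seed`` is used unless ``rng`` is given,
    so identical parameters reproduce bit-identical data.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    g = gen_genotypes(p.n_subjects, p.maf, rng)
    m = gen_methylation(p.n_subjects, p.n_tissues, p.meth_cov, rng)
    y = gen_expression(p, g, m, rng)
    return SimulatedDataset(g=g, m=m, y=y)
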