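"""Shared fixtures and dense-matrix reference constructions.

The dense helpers build the nt x nt covariance and the stacked designs
explicitly (subject-major, tissue-fastest ordering) so that every blockwise
computation in the package can be checked against brute-force linear
algebra on small instances.
"""

import numpy as np
import pytest

import meqtl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dense_sigma(tau: float, theta: float, eps: float, m: np.ndarray) -> np.ndarray:
    """Brute-force nt x nt covariance: per-subject blocks
    eps I + tau 1 1^T + theta diag(m_i o m_i)."""
    n, t = m.shape
    sigma = np.zeros((n * t, n * t))
    for i in range(n):
        block = eps * np.eye(t) + tau * np.ones((t, t)) + theta * np.diag(m[i] ** 2)
        sigma[i * t : (i + 1) * t, i * t : (i + 1) * t] = block
    return sigma


def dense_null_design(m: np.ndarray | None, n: int, t: int) -> np.ndarray:
    """Fixed design [J | vec(m)]: tissue indicators plus the methylation column."""
    cols = t + (0 if m is None else 1)
    x = np.zeros((n * t, cols))
    for j in range(t):
        x[j::t, j] = 1.0
    if m is not None:
        x[:, t] = m.ravel()
    return x


def dense_score_designs(g: np.ndarray, m: np.ndarray | None, t: int):
    """Centered genotype/product vectors and the stacked B, C designs."""
    n = g.shape[0]
    g = g.astype(float)
    gexp = np.repeat(g, t)
    gc = gexp - gexp.mean()
    b = np.zeros((n * t, t))
    for j in range(t):
        b[j::t, j] = g
    if m is None:
        return gc, None, b, None
    mg = m.ravel() * gexp
    mgc = mg - mg.mean()
    c = np.zeros((n * t, t))
    for j in range(t):
        c[j::t, j] = m[:, j] * g
    return gc, mgc, b, c


def dense_projected_precision(sigma: np.ndarray, x: np.ndarray) -> np.ndarray:
    """P0 = Sigma^{-1} - Sigma^{-1} X (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1}."""
    si = np.linalg.inv(sigma)
    return si - si @ x @ np.linalg.inv(x.T @ si @ x) @ x.T @ si


@pytest.fixture
def small_dataset():
    """A small simulated locus with all nuisance effects present."""
    params = meqtl.SimParams(
        n_subjects=40, n_tissues=3, lam=0.3, tau=0.8, theta=0.6, eps=1.0, seed=42
    )
    return meqtl.simulate_dataset(params)


@pytest.fixture
def small_fit(small_dataset):
    return meqtl.fit_null(small_dataset.y, small_dataset.m)
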