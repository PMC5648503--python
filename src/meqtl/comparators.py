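"""Tissue-by-tissue regression baselines with min-p summarization.

TBT-eQTL fits, separately in each tissue, the simple regression

    y_j = b0 + b1 * g + e

and takes the two-sided t-test p-value for b1.  TBTm-eQTL adds methylation
as a covariate and a genotype x methylation interaction,

    y_j = a + m_j * alpha + g * beta + (g * m_j) * phi + e,

and tests the joint null (beta, phi) = 0 with a 2-df F-test, so it can pick
up both additive and interaction signal.  Either way the multi-tissue
statistic is the minimum p-value across tissues, declared significant at a
Bonferroni threshold alpha / t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["TbtResult", "tbt_eqtl", "tbtm_eqtl", "TissueByTissueTest"]


@dataclass
class TbtResult:
    """Per-tissue p-values and the min-p multi-tissue summary."""

    per_tissue_p: np.ndarray
    min_p: float
    n_tissues: int

    def significant_at(self, alpha: float) -> bool:
        """Bonferroni rule: min-p at level alpha / t."""
        return bool(self.min_p <= alpha / self.n_tissues)


def _validate(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be an n x t matrix")
    if g.shape != (y.shape[0],):
        raise ValueError("genotype length must match the number of subjects")
    return y, g


def tbt_eqtl(y: np.ndarray, g: np.ndarray) -> TbtResult:
    """Genotype-only per-tissue OLS; two-sided t-test on the slope."""
    y, g = _validate(y, g)
    n, t = y.shape
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0 or n <= 2:
        return TbtResult(np.ones(t), 1.0, t)
    yc = y - y.mean(axis=0)
    b1 = (gc @ yc) / sxx
    rss = (yc**2).sum(axis=0) - b1**2 * sxx
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
        tstat = np.where(se > 0, b1 / se, np.inf * np.sign(b1))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(np.isnan(p), 1.0, p)
    return TbtResult(p, float(p.min()), t)


def tbtm_eqtl(y: np.ndarray, g: np.ndarray, m: np.ndarray) -> TbtResult:
    """Per-tissue regression with methylation covariate; joint 2-df F-test of
    the genotype main effect and the genotype x methylation interaction."""
    y, g = _validate(y, g)
    m = np.asarray(m, dtype=float)
    if m.shape != y.shape:
        raise ValueError("methylation matrix must match y's shape")
    n, t = y.shape
    if np.ptp(g) == 0.0:
        return TbtResult(np.ones(t), 1.0, t)
    dof = n - 4
    p = np.ones(t)
    ones = np.ones(n)
    for j in range(t):
        x_full = np.column_stack([ones, m[:, j], g, g * m[:, j]])
        x_null = x_full[:, :2]
        coef1, rss1, rank1, _ = np.linalg.lstsq(x_full, y[:, j], rcond=None)
        if rank1 < 4 or dof <= 0:
            warnings.warn(
                f"rank-deficient design in tissue {j}; p set to 1", stacklevel=2
            )
            continue
        coef0, rss0, _, _ = np.linalg.lstsq(x_null, y[:, j], rcond=None)
        rss1 = float(rss1[0]) if rss1.size else float(((y[:, j] - x_full @ coef1) ** 2).sum())
        rss0 = float(rss0[0]) if rss0.size else float(((y[:, j] - x_null @ coef0) ** 2).sum())
        if rss1 <= 0.0:
            p[j] = 0.0
            continue
        f = ((rss0 - rss1) / 2.0) / (rss1 / dof)
        p[j] = float(stats.f.sf(max(f, 0.0), 2, dof))
    return TbtResult(p, float(p.min()), t)


class TissueByTissueTest(BaseEstimator):
    """Estimator wrapper around the per-tissue baselines.

    Parameters
    ----------
    variant : {"tbt", "tbtm"}
        Genotype-only regression, or regression with methylation covariate
        plus G x M interaction (joint 2-df test).
    """

    def __init__(self, variant: str = "tbt"):
        self.variant = variant

    def fit(self, y: np.ndarray, m: np.ndarray | None = None) -> "TissueByTissueTest":
        if self.variant not in ("tbt", "tbtm"):
            raise ValueError("variant must be 'tbt' or 'tbtm'")
        if self.variant == "tbtm" and m is None:
            raise ValueError("variant 'tbtm' requires a methylation matrix")
        self.y_ = np.asarray(y, dtype=float)
        self.m_ = None if m is None else np.asarray(m, dtype=float)
        self.n_tissues_ = self.y_.shape[1]
        return self

    def test(self, g: np.ndarray) -> TbtResult:
        if self.variant == "tbt":
            return tbt_eqtl(self.y_, g)
        return tbtm_eqtl(self.y_, g, self.m_)

    def pvalue(self, g: np.ndarray) -> float:
        return self.test(g).min_p
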