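"""Monte-Carlo evaluation harness and multiple-testing utilities.

``run_power_study`` reproduces the type-I error / power experiments: per
grid cell it simulates replicate loci (500 subjects x 5 tissues at
MAF 0.3 by default), applies the requested tests and reports empirical
rejection rates with binomial Monte-Carlo standard errors.  Replicate
seeds are ``base_seed + replicate``, so cells are paired across
configurations and independently reproducible.

Rejection rules follow the simulation design: the joint and
genotype + G x T (jaguar-style) tests reject at p <= alpha; the
tissue-by-tissue baselines reject when min-p <= alpha / t.

``qvalues`` implements Storey-style FDR adjustment: pi0 is estimated by a
cubic smoother of pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a
lambda grid, evaluated at the largest lambda, falling back to pi0 = 1
(plain Benjamini-Hochberg) whenever the estimate leaves (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparators import tbt_eqtl, tbtm_eqtl
from .null_model import NullModel
from .score_test import combine_and_test, efficient_scores, jaguar_style_test
from .simulate import SimParams, pve_to_variances, simulate_dataset

__all__ = ["PowerCell", "table1_grid", "run_power_study", "qvalues", "plot_power_curves"]


@dataclass(frozen=True)
class PowerCell:
    """One simulation configuration: which fixed effects are on and the PVE
    (percent) of the two interaction variance components."""

    additive: bool = False
    gxm: bool = False
    pve_gxmxt: float = 0.0
    pve_gxt: float = 0.0

    def label(self) -> str:
        return (
            f"{'YES' if self.additive else 'NO'}-{'YES' if self.gxm else 'NO'}"
            f"-{self.pve_gxmxt:g}-{self.pve_gxt:g}"
        )


def table1_grid() -> list[PowerCell]:
    """The full 36-cell grid: additive on/off x G x M on/off x
    PVE_GxMxT in {0, 7, 10} x PVE_GxT in {0, 7, 10}."""
    return [
        PowerCell(additive, gxm, pd_, pg)
        for additive in (False, True)
        for gxm in (False, True)
        for pd_ in (0.0, 7.0, 10.0)
        for pg in (0.0, 7.0, 10.0)
    ]


def _rejections(
    data, methods: tuple[str, ...], alpha: float, t: int
) -> dict[str, bool]:
    out = {}
    joint_fit = jaguar_fit = None
    for method in methods:
        if method == "joint":
            if joint_fit is None:
                joint_fit = NullModel(include_methylation=True).fit(data.y, data.m)
            res = combine_and_test(joint_fit, efficient_scores(joint_fit, data.g))
            out[method] = res.p_value <= alpha
        elif method == "jaguar":
            if jaguar_fit is None:
                jaguar_fit = NullModel(include_methylation=False).fit(data.y)
            out[method] = jaguar_style_test(jaguar_fit, data.g).p_value <= alpha
        elif method == "tbt":
            out[method] = tbt_eqtl(data.y, data.g).significant_at(alpha)
        elif method == "tbtm":
            out[method] = tbtm_eqtl(data.y, data.g, data.m).significant_at(alpha)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def run_power_study(
    grid: list[PowerCell],
    methods: tuple[str, ...] = ("tbtm", "joint"),
    n: int = 500,
    t: int = 5,
    maf: float = 0.3,
    n_reps: int = 1000,
    base_seed: int = 0,
    alpha: float = 0.05,
    beta: float = 0.3,
    phi: float = 0.3,
    lam: float = 0.3,
    tau: float = 1.0,
    theta: float = 1.0,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Empirical rejection rates over a configuration grid.

    ``beta``/``phi`` are the fixed-effect magnitudes used when a cell turns
    the additive or G x M effect on; ``lam`` is the overall methylation slope
    (always present); (tau, theta, eps) are the nuisance variances from which
    gamma and delta are derived via the cell's PVE values.  Replicates whose
    model fit fails are excluded from numerator and denominator and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    known = {"joint", "jaguar", "tbt", "tbtm"}
    if unknown := set(methods) - known:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {sorted(known)}")
    rows = []
    for cell in grid:
        gamma, delta = pve_to_variances(cell.pve_gxt, cell.pve_gxmxt, tau, theta, eps)
        hits = {method: 0 for method in methods}
        n_failed = 0
        for rep in range(n_reps):
            params = SimParams(
                n_subjects=n,
                n_tissues=t,
                maf=maf,
                beta=beta if cell.additive else 0.0,
                phi=phi if cell.gxm else 0.0,
                lam=lam,
                tau=tau,
                gamma=gamma,
                delta=delta,
                theta=theta,
                eps=eps,
                seed=base_seed + rep,
            )
            data = simulate_dataset(params)
            try:
                rej = _rejections(data, methods, alpha, t)
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            for method in methods:
                hits[method] += rej[method]
        n_eff = n_reps - n_failed
        if n_failed > 0.01 * n_reps:
            warnings.warn(
                f"{n_failed}/{n_reps} replicates failed in cell {cell.label()}",
                stacklevel=2,
            )
        for method in methods:
            rate = hits[method] / n_eff if n_eff else np.nan
            rows.append(
                {
                    "additive": cell.additive,
                    "gxm": cell.gxm,
                    "pve_gxmxt": cell.pve_gxmxt,
                    "pve_gxt": cell.pve_gxt,
                    "method": method,
                    "rejection_rate": rate,
                    "n_reps": n_eff,
                    "n_failed": n_failed,
                    "mc_se": np.sqrt(rate * (1.0 - rate) / n_eff) if n_eff else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- q-values


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey pi0 estimate via a cubic smoother of pi0(lambda), evaluated at
    the largest lambda; falls back to 1 when the fit leaves (0, 1]."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        coefs = np.polyfit(lambdas, pi0_lam, deg=3)
        pi0 = float(np.polyval(coefs, lambdas.max()))
    except np.linalg.LinAlgError:  # pragma: no cover
        pi0 = 1.0
    if not 0.0 < pi0 <= 1.0:
        pi0 = 1.0
    return pi0


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey-style q-values.

    q_i = min over {p_j >= p_i} of pi0 * m * p_j / rank(p_j), clipped to
    [0, 1]; with ``pi0=1`` this is exactly the Benjamini-Hochberg adjusted
    p-value.  Monotone in p by construction.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def plot_power_curves(df: pd.DataFrame, path: str | None = None):
    """Power curves against PVE_GxT, one line per method, panelled by
    PVE_GxMxT (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = sorted(df["pve_gxmxt"].unique())
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.5),
                             sharey=True, squeeze=False)
    for ax, pd_ in zip(axes[0], panels):
        sub = df[df["pve_gxmxt"] == pd_]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("pve_gxt")
            ax.errorbar(grp["pve_gxt"], grp["rejection_rate"],
                        yerr=grp["mc_se"], marker="o", capsize=3, label=method)
        ax.set_xlabel("PVE G x T (%)")
        ax.set_title(f"PVE G x M x T = {pd_:g}%")
    axes[0][0].set_ylabel("power")
    axes[0][0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
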