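"""Cis-triplet genome scan: pair transcripts with promoter CpGs and cis-SNPs,
then run any of the implemented tests over all triplets with FDR control.

A candidate triplet joins a transcript with (a) every CpG strictly within
1.5 kb of its transcription start site and (b) every SNP within 100 kb of
the TSS (inclusive), on the same chromosome.  Each (transcript, CpG) pair
shares one REML null fit across all of its cis-SNPs; p-values are pooled
over the whole scan into q-values.  Tissue-by-tissue scans instead compute
per-tissue q-values and summarize by the minimum q across tissues, declared
significant at fdr / n_tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparators import tbt_eqtl, tbtm_eqtl
from .null_model import NullModel
from .score_test import combine_and_test, efficient_scores, jaguar_style_test
from .study import qvalues

__all__ = [
    "read_annotations",
    "pair_cis",
    "FeatureMatrixStore",
    "GenotypeStore",
    "read_feature_matrix",
    "read_genotype_matrix",
    "read_genotypes_vcf",
    "scan",
]

logger = logging.getLogger(__name__)

SNP_WINDOW_BP = 100_000
CPG_WINDOW_BP = 1_500

_ANNOT_COLS = ["feature_id", "chromosome", "position", "kind"]


def read_annotations(path) -> pd.DataFrame:
    """Read a 4-column annotation TSV (feature_id, chromosome, position, kind)
    with 1-based coordinates; kind is one of transcript / cpg / snp."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    bad = set(df["kind"]) - {"transcript", "cpg", "snp"}
    if bad:
        raise ValueError(f"unknown annotation kinds: {sorted(bad)}")
    if (df["position"] < 1).any():
        raise ValueError("annotation positions must be 1-based (>= 1)")
    return df[_ANNOT_COLS]


def _check_features(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    df = pd.DataFrame(df)
    for col in ("feature_id", "chromosome", "position"):
        if col not in df.columns:
            raise ValueError(f"{kind} table needs a '{col}' column")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate {kind} ids: {dups}")
    return df


def pair_cis(
    transcripts: pd.DataFrame,
    cpgs: pd.DataFrame,
    snps: pd.DataFrame,
    snp_window_bp: int = SNP_WINDOW_BP,
    cpg_window_bp: int = CPG_WINDOW_BP,
) -> pd.DataFrame:
    """Enumerate cis (transcript, cpg, snp) triplets.

    A triplet is kept iff, on the same chromosome as the transcript,
    |snp_pos - tss| <= snp_window_bp (the window is inclusive: a SNP exactly
    100 kb away still counts) and |cpg_pos - tss| < cpg_window_bp (strict:
    a CpG exactly 1.5 kb away does not).  Every surviving (transcript, cpg)
    pair combines with each of the transcript's cis-SNPs.
    """
    transcripts = _check_features(transcripts, "transcript")
    cpgs = _check_features(cpgs, "cpg")
    snps = _check_features(snps, "snp")

    tx = transcripts.rename(
        columns={"feature_id": "transcript_id", "position": "tss"}
    )[["transcript_id", "chromosome", "tss"]]
    cg = cpgs.rename(columns={"feature_id": "cpg_id", "position": "cpg_pos"})[
        ["cpg_id", "chromosome", "cpg_pos"]
    ]
    sp = snps.rename(columns={"feature_id": "snp_id", "position": "snp_pos"})[
        ["snp_id", "chromosome", "snp_pos"]
    ]

    tx_cg = tx.merge(cg, on="chromosome")
    tx_cg = tx_cg[(tx_cg["cpg_pos"] - tx_cg["tss"]).abs() < cpg_window_bp]
    tx_sp = tx.merge(sp, on="chromosome")
    tx_sp = tx_sp[(tx_sp["snp_pos"] - tx_sp["tss"]).abs() <= snp_window_bp]

    out = tx_cg.merge(tx_sp, on=["transcript_id", "chromosome", "tss"])
    return out[["transcript_id", "cpg_id", "snp_id"]].reset_index(drop=True)


# ------------------------------------------------------------------- stores


@dataclass
class FeatureMatrixStore:
    """Per-feature subject x tissue matrices with a shared sample order."""

    matrices: dict[str, np.ndarray]
    samples: list[str]
    tissues: list[str]

    def get(self, feature_id: str) -> np.ndarray:
        return self.matrices[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.matrices


@dataclass
class GenotypeStore:
    """Per-SNP dosage vectors (0/1/2, NaN for missing calls)."""

    dosages: dict[str, np.ndarray]
    samples: list[str]

    def get(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.dosages


def read_feature_matrix(path) -> FeatureMatrixStore:
    """Read a long-format TSV with 'feature_id' and 'tissue' columns followed
    by one column per sample; rows are feature x tissue."""
    df = pd.read_csv(path, sep="\t")
    for col in ("feature_id", "tissue"):
        if col not in df.columns:
            raise ValueError(f"feature matrix needs a '{col}' column")
    samples = [c for c in df.columns if c not in ("feature_id", "tissue")]
    tissues = list(dict.fromkeys(df["tissue"]))
    matrices = {}
    for fid, grp in df.groupby("feature_id", sort=False):
        grp = grp.set_index("tissue").reindex(tissues)
        matrices[fid] = grp[samples].to_numpy(dtype=float).T  # samples x tissues
    return FeatureMatrixStore(matrices, samples, tissues)


def read_genotype_matrix(path) -> GenotypeStore:
    """Read a TSV with a 'feature_id' column and one 0/1/2 dosage column per
    sample (blank / NA entries become missing)."""
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        raise ValueError("genotype matrix needs a 'feature_id' column")
    samples = [c for c in df.columns if c != "feature_id"]
    dosages = {
        row["feature_id"]: row[samples].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }
    return GenotypeStore(dosages, samples)


def read_genotypes_vcf(path) -> tuple[GenotypeStore, pd.DataFrame]:
    """Read a VCF into 0/1/2 minor-allele dosages plus an annotation table
    (kind 'snp'); missing genotypes become NaN.  Requires pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    dosages: dict[str, np.ndarray] = {}
    annot_rows = []
    for rec in vf:
        sid = rec.id or f"{rec.chrom}:{rec.pos}"
        dose = np.full(len(samples), np.nan)
        for k, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dose[k] = float(sum(1 for a in gt if a != 0))
        dosages[sid] = dose
        annot_rows.append(
            {"feature_id": sid, "chromosome": str(rec.chrom), "position": rec.pos,
             "kind": "snp"}
        )
    return GenotypeStore(dosages, samples), pd.DataFrame(annot_rows)


# --------------------------------------------------------------------- scan

_RESULT_COLS = [
    "transcript_id", "cpg_id", "snp_id", "p_value", "q_value", "significant",
]
_JOINT_EXTRA = [
    "u_zeta", "p_beta", "p_phi", "p_gamma", "p_delta",
    "driver_additive", "driver_gxm", "driver_gxt", "driver_gxmxt",
]


def _complete_genotype(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isfinite(g)
    return g[mask], mask


def scan(
    expr_store: FeatureMatrixStore,
    meth_store: FeatureMatrixStore | None,
    geno_store: GenotypeStore,
    triplets: pd.DataFrame,
    method: str = "joint",
    fdr: float = 0.05,
    driver_alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a test over all cis triplets with scan-wide FDR control.

    For the mixed-model tests ('joint', 'jaguar') one null fit per
    (transcript, CpG) pair — per transcript for 'jaguar' — is reused across
    the pair's SNPs, p-values are pooled into Storey q-values and, within
    q <= fdr hits of the joint test, driver flags mark which score components
    are marginally significant at ``driver_alpha``.  For 'tbt'/'tbtm' the
    per-tissue p-values get per-tissue q-values; the row summary is the
    minimum q across tissues, significant at fdr / n_tissues.

    SNPs with missing genotype calls are tested on their complete cases
    (the null model is refit on the subset); missing features are skipped
    with a logged warning; monomorphic SNPs get p = 1.
    """
    if method not in ("joint", "jaguar", "tbt", "tbtm"):
        raise ValueError(f"unknown method {method!r}")
    needs_meth = method in ("joint", "tbtm")
    if needs_meth and meth_store is None:
        raise ValueError(f"method {method!r} requires a methylation store")
    cols = _RESULT_COLS + (_JOINT_EXTRA if method == "joint" else [])
    if len(triplets) == 0:
        return pd.DataFrame(columns=cols)

    rows: list[dict] = []
    per_tissue: list[np.ndarray] = []

    group_keys = ["transcript_id", "cpg_id"] if method in ("joint", "tbtm") else ["transcript_id"]
    for keys, grp in triplets.groupby(group_keys, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        tid = keys[0]
        cid = keys[1] if len(keys) > 1 else None
        if tid not in expr_store:
            logger.warning("transcript %s missing from expression store; skipped", tid)
            continue
        if needs_meth and cid not in meth_store:
            logger.warning("CpG %s missing from methylation store; skipped", cid)
            continue
        y = expr_store.get(tid)
        m = meth_store.get(cid) if needs_meth else None

        fit = None
        fit_subset: dict[tuple, NullModel] = {}
        if method in ("joint", "jaguar"):
            fit = NullModel(include_methylation=(method == "joint")).fit(y, m)

        for _, trip in grp.iterrows():
            sid = trip["snp_id"]
            if sid not in geno_store:
                logger.warning("SNP %s missing from genotype store; skipped", sid)
                continue
            g_raw = geno_store.get(sid)
            g, mask = _complete_genotype(g_raw)
            if g.size < y.shape[0]:
                logger.warning(
                    "SNP %s: %d missing calls, per-SNP complete-case analysis",
                    sid, int((~mask).sum()),
                )
            row = {"transcript_id": tid, "cpg_id": trip.get("cpg_id"), "snp_id": sid}
            if method in ("joint", "jaguar"):
                if mask.all():
                    use_fit = fit
                else:
                    key = tuple(np.flatnonzero(mask))
                    if key not in fit_subset:
                        fit_subset[key] = NullModel(
                            include_methylation=(method == "joint")
                        ).fit(y[mask], None if m is None else m[mask])
                    use_fit = fit_subset[key]
                if method == "joint":
                    res = combine_and_test(use_fit, efficient_scores(use_fit, g))
                    row.update(
                        p_value=res.p_value,
                        u_zeta=res.u_zeta,
                        p_beta=res.component_p.get("beta", np.nan),
                        p_phi=res.component_p.get("phi", np.nan),
                        p_gamma=res.component_p.get("gamma", np.nan),
                        p_delta=res.component_p.get("delta", np.nan),
                    )
                else:
                    row["p_value"] = jaguar_style_test(use_fit, g).p_value
            elif method == "tbt":
                res = tbt_eqtl(y[mask], g)
                row["p_value"] = res.min_p
                per_tissue.append(res.per_tissue_p)
            else:
                res = tbtm_eqtl(y[mask], g, m[mask])
                row["p_value"] = res.min_p
                per_tissue.append(res.per_tissue_p)
            rows.append(row)

    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)

    if method in ("joint", "jaguar"):
        out["q_value"] = qvalues(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] <= fdr
        if method == "joint":
            sig = out["significant"]
            out["driver_additive"] = sig & (out["p_beta"] <= driver_alpha)
            out["driver_gxm"] = sig & (out["p_phi"] <= driver_alpha)
            out["driver_gxt"] = sig & (out["p_gamma"] <= driver_alpha)
            out["driver_gxmxt"] = sig & (out["p_delta"] <= driver_alpha)
    else:
        pmat = np.vstack(per_tissue)  # rows x tissues
        qmat = np.column_stack(
            [qvalues(pmat[:, j]) for j in range(pmat.shape[1])]
        )
        out["q_value"] = qmat.min(axis=1)  # min q across tissues
        out["significant"] = out["q_value"] <= fdr / pmat.shape[1]
    return out[cols + [c for c in out.columns if c not in cols]]
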