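"""Cis-pairing and genome-scan tests: window boundary conventions, triplet
combinatorics, planted-signal recovery and FDR behaviour under the null."""

import logging

import numpy as np
import pandas as pd
import pytest

import meqtl
from meqtl.genome_scan import (
    FeatureMatrixStore,
    GenotypeStore,
    pair_cis,
    read_annotations,
    read_feature_matrix,
    read_genotype_matrix,
    read_genotypes_vcf,
    scan,
)


def _annot(rows):
    return pd.DataFrame(rows, columns=["feature_id", "chromosome", "position"])


class TestPairCis:
    def test_snp_window_inclusive_boundary(self):
        tx = _annot([("t1", "1", 1_000_000)])
        cg = _annot([("c1", "1", 1_000_100)])
        inside = pair_cis(tx, cg, _annot([("s1", "1", 1_100_000)]))
        outside = pair_cis(tx, cg, _annot([("s1", "1", 1_100_001)]))
        assert len(inside) == 1 and len(outside) == 0

    def test_cpg_window_strict_boundary(self):
        tx = _annot([("t1", "1", 1_000_000)])
        sp = _annot([("s1", "1", 1_000_500)])
        at_limit = pair_cis(tx, _annot([("c1", "1", 1_001_500)]), sp)
        just_in = pair_cis(tx, _annot([("c1", "1", 1_001_499)]), sp)
        assert len(at_limit) == 0 and len(just_in) == 1

    def test_pairs_times_snps_combinatorics(self):
        tx = _annot([("t1", "1", 500_000), ("t2", "1", 900_000)])
        cg = _annot([(f"c{k}", "1", 500_000 + 100 * k) for k in (1, 2)]
                    + [(f"d{k}", "1", 900_000 + 100 * k) for k in (1, 2)])
        sp = _annot([(f"s{k}", "1", 520_000 + k) for k in range(3)]
                    + [(f"r{k}", "1", 920_000 + k) for k in range(3)])
        trip = pair_cis(tx, cg, sp)
        # per transcript: 2 CpGs x 3 SNPs; transcripts do not cross-pair
        assert len(trip) == 12
        assert (trip.groupby("transcript_id").size() == 6).all()

    def test_chromosome_separation(self):
        tx = _annot([("t1", "1", 100_000)])
        cg = _annot([("c1", "2", 100_100)])
        sp = _annot([("s1", "2", 100_200)])
        assert len(pair_cis(tx, cg, sp)) == 0

    def test_duplicate_ids_rejected(self):
        tx = _annot([("t1", "1", 1000), ("t1", "1", 2000)])
        with pytest.raises(ValueError, match="duplicate"):
            pair_cis(tx, _annot([("c1", "1", 1000)]), _annot([("s1", "1", 1000)]))


def _stores_from_sim(datasets: dict[str, meqtl.SimulatedDataset], t: int):
    """Build in-memory stores for one CpG and one SNP per transcript."""
    n = next(iter(datasets.values())).y.shape[0]
    samples = [f"s{i}" for i in range(n)]
    tissues = [f"tis{j}" for j in range(t)]
    expr = FeatureMatrixStore({k: v.y for k, v in datasets.items()}, samples, tissues)
    meth = FeatureMatrixStore(
        {f"cpg_{k}": v.m for k, v in datasets.items()}, samples, tissues
    )
    geno = GenotypeStore(
        {f"snp_{k}": v.g.astype(float) for k, v in datasets.items()}, samples
    )
    triplets = pd.DataFrame(
        {
            "transcript_id": list(datasets),
            "cpg_id": [f"cpg_{k}" for k in datasets],
            "snp_id": [f"snp_{k}" for k in datasets],
        }
    )
    return expr, meth, geno, triplets


class TestScan:
    def test_empty_triplets_give_empty_result(self):
        expr = FeatureMatrixStore({}, [], [])
        geno = GenotypeStore({}, [])
        out = scan(expr, expr, geno, pd.DataFrame(
            columns=["transcript_id", "cpg_id", "snp_id"]))
        assert len(out) == 0
        assert "q_value" in out.columns

    def test_planted_signal_is_top_ranked(self):
        """A single triplet carrying a real genotype effect (additive +
        G x M x T) wins the scan's smallest p-value in nearly every run."""
        n, t, n_null = 300, 4, 59
        _, delta = meqtl.pve_to_variances(0.0, 30.0, tau=1, theta=1, eps=1)
        wins = 0
        runs = 20
        for run in range(runs):
            datasets = {}
            for k in range(n_null):
                p = meqtl.SimParams(n_subjects=n, n_tissues=t, lam=0.3,
                                    seed=700_000 + run * 1000 + k)
                datasets[f"null{k}"] = meqtl.simulate_dataset(p)
            p = meqtl.SimParams(n_subjects=n, n_tissues=t, lam=0.3, beta=0.5,
                                delta=delta, seed=700_000 + run * 1000 + 999)
            datasets["planted"] = meqtl.simulate_dataset(p)
            expr, meth, geno, trip = _stores_from_sim(datasets, t)
            out = scan(expr, meth, geno, trip, method="joint")
            wins += out.loc[out["p_value"].idxmin(), "transcript_id"] == "planted"
        assert wins >= int(0.9 * runs)

    def test_no_discoveries_under_global_null(self):
        n, t = 150, 3
        clean_runs = 0
        for run in range(4):
            datasets = {
                f"g{k}": meqtl.simulate_dataset(
                    meqtl.SimParams(n_subjects=n, n_tissues=t, lam=0.3,
                                    seed=800_000 + run * 1000 + k)
                )
                for k in range(300)
            }
            expr, meth, geno, trip = _stores_from_sim(datasets, t)
            out = scan(expr, meth, geno, trip, method="joint", fdr=0.05)
            clean_runs += int(out["significant"].sum()) == 0
        assert clean_runs >= 3

    def test_order_invariance(self):
        datasets = {
            f"g{k}": meqtl.simulate_dataset(
                meqtl.SimParams(n_subjects=60, n_tissues=3, lam=0.3, seed=900 + k)
            )
            for k in range(8)
        }
        expr, meth, geno, trip = _stores_from_sim(datasets, 3)
        out1 = scan(expr, meth, geno, trip, method="joint")
        out2 = scan(expr, meth, geno, trip.iloc[::-1].reset_index(drop=True),
                    method="joint")
        merged = out1.merge(out2, on=["transcript_id", "cpg_id", "snp_id"],
                            suffixes=("_a", "_b"))
        assert np.allclose(merged["p_value_a"], merged["p_value_b"])
        assert np.allclose(merged["q_value_a"], merged["q_value_b"])

    def test_qvalue_monotone_in_p(self):
        datasets = {
            f"g{k}": meqtl.simulate_dataset(
                meqtl.SimParams(n_subjects=50, n_tissues=3, lam=0.3, seed=77 + k)
            )
            for k in range(10)
        }
        expr, meth, geno, trip = _stores_from_sim(datasets, 3)
        out = scan(expr, meth, geno, trip, method="joint").sort_values("p_value")
        assert np.all(np.diff(out["q_value"].to_numpy()) >= -1e-12)

    def test_tbt_mode_min_q_summary(self):
        datasets = {
            f"g{k}": meqtl.simulate_dataset(
                meqtl.SimParams(n_subjects=60, n_tissues=4, lam=0.3, seed=55 + k)
            )
            for k in range(6)
        }
        expr, meth, geno, trip = _stores_from_sim(datasets, 4)
        out = scan(expr, meth, geno, trip, method="tbtm", fdr=0.05)
        assert len(out) == 6
        # significance is min-q at the Bonferroni-adjusted FDR level
        assert (out["significant"] == (out["q_value"] <= 0.05 / 4)).all()

    def test_missing_feature_skipped_and_logged(self, caplog):
        datasets = {
            "g0": meqtl.simulate_dataset(
                meqtl.SimParams(n_subjects=40, n_tissues=3, lam=0.3, seed=5)
            )
        }
        expr, meth, geno, trip = _stores_from_sim(datasets, 3)
        trip = pd.concat(
            [trip, pd.DataFrame([{"transcript_id": "g0", "cpg_id": "cpg_g0",
                                  "snp_id": "snp_absent"}])],
            ignore_index=True,
        )
        with caplog.at_level(logging.WARNING, logger="meqtl.genome_scan"):
            out = scan(expr, meth, geno, trip, method="joint")
        assert len(out) == 1
        assert "snp_absent" in caplog.text

    def test_monomorphic_snp_gets_p_one(self):
        datasets = {
            "g0": meqtl.simulate_dataset(
                meqtl.SimParams(n_subjects=40, n_tissues=3, lam=0.3, seed=6)
            )
        }
        expr, meth, geno, trip = _stores_from_sim(datasets, 3)
        geno.dosages["snp_g0"] = np.zeros(40)
        out = scan(expr, meth, geno, trip, method="joint")
        assert out["p_value"].iloc[0] == 1.0

    def test_missing_calls_use_complete_cases(self):
        d = meqtl.simulate_dataset(
            meqtl.SimParams(n_subjects=60, n_tissues=3, lam=0.3, seed=8)
        )
        datasets = {"g0": d}
        expr, meth, geno, trip = _stores_from_sim(datasets, 3)
        g = geno.dosages["snp_g0"].copy()
        g[:5] = np.nan
        geno.dosages["snp_g0"] = g
        out = scan(expr, meth, geno, trip, method="joint")
        # equals a scan on the 55 complete samples
        fit = meqtl.fit_null(d.y[5:], d.m[5:])
        ref = meqtl.combine_and_test(fit, meqtl.efficient_scores(fit, d.g[5:]))
        assert np.isclose(out["p_value"].iloc[0], ref.p_value, rtol=1e-8)


class TestFileIO:
    def test_feature_matrix_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "feature_id": ["f1", "f1", "f2", "f2"],
                "tissue": ["a", "b", "a", "b"],
                "s1": [1.0, 2.0, 3.0, 4.0],
                "s2": [5.0, 6.0, 7.0, 8.0],
            }
        )
        path = tmp_path / "expr.tsv"
        df.to_csv(path, sep="\t", index=False)
        store = read_feature_matrix(path)
        assert store.samples == ["s1", "s2"] and store.tissues == ["a", "b"]
        assert np.array_equal(store.get("f1"), np.array([[1.0, 2.0], [5.0, 6.0]]))

    def test_genotype_matrix_reader(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text("feature_id\ts1\ts2\ts3\nsnpA\t0\t1\t2\nsnpB\t2\t\t0\n")
        store = read_genotype_matrix(path)
        assert np.array_equal(store.get("snpA"), [0.0, 1.0, 2.0])
        assert np.isnan(store.get("snpB")[1])

    def test_annotation_reader_validation(self, tmp_path):
        path = tmp_path / "annot.tsv"
        pd.DataFrame(
            {"feature_id": ["x"], "chromosome": ["1"], "position": [100],
             "kind": ["gene"]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="unknown annotation kinds"):
            read_annotations(path)

    def test_vcf_dosages(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t150\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t900\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1\n"
        )
        store, annot = read_genotypes_vcf(vcf)
        assert store.samples == ["A", "B", "C"]
        assert np.array_equal(store.get("rs1"), [0.0, 1.0, 2.0])
        assert np.isnan(store.get("rs2")[0]) and store.get("rs2")[2] == 1.0
        assert annot.loc[annot.feature_id == "rs2", "position"].item() == 900
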