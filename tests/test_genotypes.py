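"""Genotype containers, QC, allele frequencies, HWE and the GRM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import repgwas as rg
from repgwas.errors import DataError, EmptyGenotypeError


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadVcf:
    def test_dosages_and_missing(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/1\t0/0\n"
        )
        gm = rg.read_vcf(write_vcf(tmp_path / "a.vcf", body))
        assert list(gm.individual_ids) == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(gm.dosages[:, 0], [1, 0, 2])
        assert np.isnan(gm.dosages[0, 1])
        np.testing.assert_array_equal(gm.dosages[1:, 1], [1, 0])
        assert list(gm.snp_ids) == ["rs1", "rs2"]

    def test_multiallelic_skipped(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        gm = rg.read_vcf(write_vcf(tmp_path / "b.vcf", body))
        assert gm.n_snps == 1 and list(gm.snp_ids) == ["rs2"]

    def test_round_trip_dosages(self, tmp_path):
        # fixture written by the test, read back: identical dosage matrix
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        want = np.array([[0, 2], [1, 1], [2, 0]], dtype=float)
        body = "".join(
            f"1\t{100 + j}\tv{j}\tA\tG\t.\t.\t.\tGT\t"
            + "\t".join(gt[int(want[i, j])] for i in range(3))
            + "\n"
            for j in range(2)
        )
        gm = rg.read_vcf(write_vcf(tmp_path / "c.vcf", body))
        np.testing.assert_array_equal(gm.dosages, want)

    def test_empty_errors(self, tmp_path):
        with pytest.raises(EmptyGenotypeError):
            rg.read_vcf(write_vcf(tmp_path / "d.vcf", ""))


class TestDosageTable:
    def test_round_trip(self, tmp_path, small_gm):
        gm = small_gm.subset_snps(np.arange(20))
        dos = gm.dosages.copy()
        dos[2, 3] = np.nan
        gm = rg.GenotypeMatrix(dos, gm.individual_ids, gm.snp_meta)
        path = tmp_path / "d.tsv"
        rg.write_dosage_table(gm, path)
        back = rg.read_dosage_table(path)
        np.testing.assert_array_equal(back.dosages, gm.dosages)
        np.testing.assert_array_equal(back.individual_ids, gm.individual_ids)

    def test_small_matrix_and_na(self, tmp_path):
        (tmp_path / "t.tsv").write_text("id\ta\tb\ni1\t0\t2\ni2\t1\tNA\n")
        gm = rg.read_dosage_table(tmp_path / "t.tsv")
        np.testing.assert_array_equal(gm.dosages[0], [0, 2])
        assert gm.dosages[1, 0] == 1 and np.isnan(gm.dosages[1, 1])

    def test_bad_entry_names_cell(self, tmp_path):
        (tmp_path / "t.tsv").write_text("id\ta\tb\ni1\t0\t3\n")
        with pytest.raises(DataError, match="i1.*'b'|'b'.*i1"):
            rg.read_dosage_table(tmp_path / "t.tsv")


class TestAlleleFreq:
    def test_simple_cases(self):
        gm = rg.GenotypeMatrix(np.array([[0.0, 2.0], [1.0, 2.0], [2.0, 2.0],
                                         [np.nan, 2.0]]),
                               ["a", "b", "c", "d"])
        freq = rg.allele_freq(gm)
        assert freq[0] == pytest.approx(0.5)
        assert freq[1] == pytest.approx(1.0)
        assert gm.maf[1] == pytest.approx(0.0)

    def test_matches_counting_loop(self):
        rng = np.random.default_rng(3)
        dos = rng.choice([0.0, 1.0, 2.0, np.nan], size=(200, 5),
                         p=[0.3, 0.3, 0.3, 0.1])
        dos[:, 4] = rng.choice([0.0, 1.0, 2.0], size=200)  # ensure one complete SNP
        gm = rg.GenotypeMatrix(dos, [f"i{k}" for k in range(200)])
        freq = rg.allele_freq(gm)
        for j in range(5):
            alt = tot = 0
            for v in dos[:, j]:
                if not np.isnan(v):
                    alt += v
                    tot += 2
            assert freq[j] == pytest.approx(alt / tot, abs=1e-12)

    def test_invariant_under_reordering(self, small_gm):
        perm = np.random.default_rng(0).permutation(small_gm.n_individuals)
        gm2 = rg.GenotypeMatrix(small_gm.dosages[perm],
                                small_gm.individual_ids[perm], small_gm.snp_meta)
        np.testing.assert_allclose(rg.allele_freq(gm2), rg.allele_freq(small_gm))


class TestHwe:
    def test_perfect_equilibrium(self):
        assert rg.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_maximal_disequilibrium(self):
        assert rg.hwe_test(50, 0, 50) < 1e-10

    def test_monomorphic_convention(self):
        assert rg.hwe_test(100, 0, 0) == 1.0

    def test_hand_computed_chi_square(self):
        # counts (30, 40, 30): p-hat = 0.5, expected (25, 50, 25)
        stat = (30 - 25) ** 2 / 25 + (40 - 50) ** 2 / 50 + (30 - 25) ** 2 / 25
        assert rg.hwe_test(30, 40, 30) == pytest.approx(stats.chi2.sf(stat, 1),
                                                        abs=1e-12)

    def test_uniform_under_null(self):
        # HWE genotypes at n=500: p-values approximately uniform
        rng = np.random.default_rng(4)
        n, m = 500, 2000
        p = rng.uniform(0.1, 0.5, size=m)
        dos = rng.binomial(2, p, size=(n, m))
        pvals = np.array([
            rg.hwe_test(int((dos[:, j] == 0).sum()), int((dos[:, j] == 1).sum()),
                        int((dos[:, j] == 2).sum()))
            for j in range(m)
        ])
        assert 0.03 <= (pvals < 0.05).mean() <= 0.07


class TestQcFilter:
    def planted(self):
        rng = np.random.default_rng(5)
        n, m = 300, 100
        p = rng.uniform(0.2, 0.5, size=m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        dos[: int(n * 0.1), :10] = np.nan       # SNPs 0-9: call rate 0.90
        dos[:, 10:20] = 0.0
        dos[0, 10:20] = 1.0                      # SNPs 10-19: maf ~0.0017
        dos[:, 20:25] = 1.0                      # SNPs 20-24: all het, HWE fails
        return rg.GenotypeMatrix(dos, [f"i{k}" for k in range(n)])

    def test_thresholds_and_counts(self):
        gm = self.planted()
        kept, report = rg.qc_filter(gm)
        assert report.n_failed_call_rate >= 10
        assert report.n_failed_maf >= 10
        assert report.n_failed_hwe >= 5
        # independent per-rule recount
        from repgwas.genotypes import _hwe_pvalues

        keep = ((gm.call_rate >= 0.95) & (gm.maf >= 0.01)
                & (_hwe_pvalues(gm) > 0.001))
        assert report.n_passed == keep.sum() == kept.n_snps
        assert report.n_input_snps == 100

    def test_idempotent(self):
        kept, _ = rg.qc_filter(self.planted())
        kept2, rep2 = rg.qc_filter(kept)
        assert rep2.n_passed == kept.n_snps
        np.testing.assert_array_equal(kept2.dosages, kept.dosages)

    def test_all_removed_errors(self):
        gm = rg.GenotypeMatrix(np.ones((50, 3)), [f"i{k}" for k in range(50)])
        with pytest.raises(EmptyGenotypeError):
            rg.qc_filter(gm)  # all het -> HWE failure everywhere


class TestGrm:
    def test_single_snp_closed_form(self):
        gm = rg.GenotypeMatrix(np.array([[0.0], [2.0]]), ["a", "b"])
        G = rg.compute_grm(gm).values
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_duplicate_rows(self):
        rng = np.random.default_rng(6)
        row = rng.choice([0.0, 1.0, 2.0], size=30)
        other = rng.choice([0.0, 1.0, 2.0], size=30)
        gm = rg.GenotypeMatrix(np.vstack([row, row, other]), ["a", "b", "c"])
        G = rg.compute_grm(gm).values
        assert G[0, 1] == pytest.approx(G[0, 0]) == pytest.approx(G[1, 1])

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(7)
        dos = rng.choice([0.0, 1.0, 2.0, np.nan], size=(20, 50),
                         p=[0.3, 0.35, 0.3, 0.05])
        gm = rg.GenotypeMatrix(dos, [f"i{k}" for k in range(20)])
        G = rg.compute_grm(gm).values
        # naive double loop with per-SNP mean imputation and 2p centering
        freq = np.array([np.nanmean(dos[:, j]) / 2 for j in range(50)])
        W = np.where(np.isnan(dos), 2 * freq, dos) - 2 * freq
        denom = 2 * np.sum(freq * (1 - freq))
        for i in range(20):
            for j in range(20):
                expected = sum(W[i, k] * W[j, k] for k in range(50)) / denom
                assert G[i, j] == pytest.approx(expected, abs=1e-10)

    def test_permutation_equivariance(self, small_gm):
        G = rg.compute_grm(small_gm).values
        perm = np.random.default_rng(8).permutation(small_gm.n_individuals)
        gm2 = rg.GenotypeMatrix(small_gm.dosages[perm],
                                small_gm.individual_ids[perm], small_gm.snp_meta)
        G2 = rg.compute_grm(gm2).values
        np.testing.assert_allclose(G2, G[np.ix_(perm, perm)], atol=1e-10)

    def test_monomorphic_errors(self):
        gm = rg.GenotypeMatrix(np.full((5, 4), 2.0), [f"i{k}" for k in range(5)])
        with pytest.raises(DataError):
            rg.compute_grm(gm)

    def test_grm_tsv_round_trip(self, tmp_path, small_grm):
        rg.write_grm(small_grm, tmp_path / "g.tsv")
        back = rg.read_grm(tmp_path / "g.tsv")
        np.testing.assert_allclose(back.values, small_grm.values, atol=1e-6)
        np.testing.assert_array_equal(back.individual_ids, small_grm.individual_ids)


class TestSimulateGenotypes:
    def test_deterministic(self):
        a = rg.simulate_genotypes(n_families=5, n_unrelated=5, n_snps=50, seed=9)
        b = rg.simulate_genotypes(n_families=5, n_unrelated=5, n_snps=50, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_sib_relatedness_near_half(self):
        gm = rg.simulate_genotypes(n_families=50, sibs_per_family=2, n_snps=1000,
                                   seed=10)
        G = rg.compute_grm(gm).values
        sib_pairs = [G[2 * f, 2 * f + 1] for f in range(50)]
        assert 0.4 <= np.mean(sib_pairs) <= 0.6

    def test_unrelated_offdiagonal_vanishes(self):
        gm = rg.simulate_genotypes(n_unrelated=30, n_snps=5000, seed=11)
        G = rg.compute_grm(gm).values
        off = G[~np.eye(30, dtype=bool)]
        assert np.abs(off).mean() <= 0.05

    def test_argument_validation(self):
        with pytest.raises(DataError):
            rg.simulate_genotypes(n_unrelated=10, n_snps=5, maf_low=0.6)
        with pytest.raises(DataError):
            rg.simulate_genotypes(n_unrelated=0, n_families=0, n_snps=5)
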