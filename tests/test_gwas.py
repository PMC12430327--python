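"""QC, kinship, LD, mixed-model scan and candidate-window checks."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nitroscreen as ns
from nitroscreen.gwas import (
    EmptyPanelError,
    em_haplotype_freqs,
    read_dosage_tsv,
    read_vcf,
    write_dosage_tsv,
    write_vcf,
    _dprime,
)

from conftest import make_geno


class TestQC:
    def test_monomorphic_column_removed(self):
        g = make_geno([[0, 1], [0, 2], [0, 1], [0, 0]])
        out, rep = ns.qc_filter(g)
        assert out.snp_map["snp_id"].tolist() == ["s1"]
        assert rep.n_removed_maf == 1

    def test_missingness_threshold_is_inclusive(self):
        d = np.array([[np.nan, 1], [1, 2], [0, 1], [1, 0]], dtype=float)
        out, rep = ns.qc_filter(make_geno(d), miss_max=0.20)
        # 25% missing >= 20% -> removed
        assert out.snp_map["snp_id"].tolist() == ["s1"]
        assert rep.n_removed_missing == 1

    def test_toy_panel_hand_count(self):
        """10 SNPs, 3 planted violations (monomorphic, rare, too missing)
        -> exactly 7 survive."""
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 10)).astype(float)
        d[:, 0] = 0.0  # monomorphic
        d[:, 1] = 0.0
        d[0, 1] = 1.0  # MAF = 1/40 = 0.025 <= 0.05
        d[:5, 2] = np.nan  # 25% missing
        out, rep = ns.qc_filter(make_geno(d))
        assert out.n_snps == 7
        assert rep.n_kept == 7

    def test_idempotent(self, small_cohort):
        g1, _ = ns.qc_filter(small_cohort[0])
        g2, rep2 = ns.qc_filter(g1)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert rep2.n_removed_maf == 0 and rep2.n_removed_missing == 0

    def test_imputation_fills_missing_with_column_mean(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [np.nan, 1]], dtype=float)
        out, _ = ns.qc_filter(make_geno(d), miss_max=0.5)
        assert out.dosages[3, 0] == pytest.approx(1.0)

    def test_all_removed_raises(self):
        g = make_geno([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(EmptyPanelError):
            ns.qc_filter(g)


class TestKinship:
    def test_duplicate_lines_share_diagonal(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(5, 40)).astype(float)
        d[1] = d[0]
        K = ns.kinship(make_geno(d))
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-9)

    def test_matches_centered_crossproduct_formula(self):
        d = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1]], dtype=float)
        K = ns.kinship(make_geno(d))
        p = d.mean(axis=0) / 2
        z = d - 2 * p
        expected = z @ z.T / np.sum(2 * p * (1 - p))
        np.testing.assert_allclose(K, expected, atol=1e-9)

    def test_permutation_equivariance(self, small_cohort):
        geno, _ = ns.qc_filter(small_cohort[0])
        K = ns.kinship(geno)
        perm = np.random.default_rng(2).permutation(geno.n_lines)
        geno_p = ns.GenotypeMatrix(geno.dosages[perm], [geno.line_ids[i] for i in perm], geno.snp_map)
        K_p = ns.kinship(geno_p)
        np.testing.assert_allclose(K_p, K[np.ix_(perm, perm)], atol=1e-9)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(8, 30)).astype(float)
        K1 = ns.kinship(make_geno(d))
        d2 = d.copy()
        d2[:, 5] = 2 - d2[:, 5]
        K2 = ns.kinship(make_geno(d2))
        np.testing.assert_allclose(K1, K2, atol=1e-9)

    def test_monomorphic_panel_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ns.kinship(make_geno([[0, 0], [0, 0], [0, 0]]))


class TestLD:
    def test_duplicated_snp_perfect_ld(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=50).astype(float)
        g = make_geno(np.column_stack([col, col]), positions=[100, 200])
        res = ns.ld_stats(g, max_dist_bp=1000)
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert res.pairs["dprime"].iloc[0] == pytest.approx(1.0)

    def test_equilibrium_pair_zero_ld(self):
        # 25/25/25/25 haplotype counts paired into unambiguous diplotypes
        haps = [(1, 1), (1, 0), (0, 1), (0, 0)] * 25
        g1 = np.array([2 * a for a, _ in haps[::2]], dtype=float) / 2
        # build 50 individuals by pairing identical haplotypes
        d = np.array([[2 * a, 2 * b] for a, b in [(1, 1), (1, 0), (0, 1), (0, 0)]] * 25, dtype=float)
        hap = em_haplotype_freqs(d[:, 0], d[:, 1])
        np.testing.assert_allclose(hap, [0.25, 0.25, 0.25, 0.25], atol=1e-6)
        assert _dprime(hap) == pytest.approx(0.0, abs=1e-6)
        r = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        assert r**2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle_40_10_10_40(self):
        """Haplotype counts (AB, Ab, aB, ab) = (40, 10, 10, 40) paired into
        phase-unambiguous individuals: D = 0.4 - 0.25 = 0.15, r^2 = 0.36,
        D' = 0.15 / 0.25 = 0.6."""
        blocks = [((1, 1), 20), ((1, 0), 5), ((0, 1), 5), ((0, 0), 20)]
        d = np.concatenate([[[2 * a, 2 * b]] * n for (a, b), n in blocks]).astype(float)
        hap = em_haplotype_freqs(d[:, 0], d[:, 1])
        np.testing.assert_allclose(hap, [0.4, 0.1, 0.1, 0.4], atol=1e-8)
        assert _dprime(hap) == pytest.approx(0.6, abs=1e-8)
        g = make_geno(d, positions=[100, 300])
        res = ns.ld_stats(g, max_dist_bp=1000)
        assert res.pairs["r2"].iloc[0] == pytest.approx(0.36, abs=1e-8)
        assert res.pairs["dprime"].iloc[0] == pytest.approx(0.6, abs=1e-8)

    def test_single_snp_chromosome_empty_result(self):
        g = make_geno([[0], [1], [2]])
        with pytest.warns(UserWarning, match="fewer than two"):
            res = ns.ld_stats(g, max_dist_bp=1000)
        assert res.pairs.empty and res.decay_distance is None

    def test_decay_curve_bins(self, small_cohort):
        geno, _ = ns.qc_filter(small_cohort[0])
        res = ns.ld_stats(geno, max_dist_bp=100_000, bins=5)
        assert not res.decay.empty
        assert ((res.pairs["r2"] >= 0) & (res.pairs["r2"] <= 1)).all()
        assert ((res.pairs["dprime"] >= 0) & (res.pairs["dprime"] <= 1)).all()


class TestMLMScan:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(30, 20)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=30)
        fit = ns.mlm_scan(y, g, Q=None, K=np.eye(30))
        for j in range(20):
            res = stats.linregress(d[:, j], y)
            assert abs(np.log10(fit.table["p"].iloc[j]) - np.log10(res.pvalue)) < 1e-8

    def test_matches_brute_force_gls_oracle(self):
        """Explicit per-SNP GLS with a dense inverse of sg2 K + se2 I,
        using the same null variance components, agrees to < 1e-6 in
        -log10 p."""
        cfg = ns.SimulationConfig(seed=7, n_lines=20, n_snps=50)
        geno, _, _ = ns.simulate_genotypes(cfg)
        geno, _ = ns.qc_filter(geno)
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        A = rng.normal(size=(20, 20))
        K = A @ A.T / 20
        fit = ns.mlm_scan(y, geno, Q=None, K=K)
        V = fit.sigma_g2 * K + fit.sigma_e2 * np.eye(20)
        Vi = np.linalg.inv(V)
        for j in range(geno.n_snps):
            X = np.column_stack([np.ones(20), geno.dosages[:, j]])
            C = np.linalg.inv(X.T @ Vi @ X)
            bh = C @ X.T @ Vi @ y
            r = y - X @ bh
            s2 = r @ Vi @ r / (20 - 2)
            F = (bh[1] / np.sqrt(s2 * C[1, 1])) ** 2
            p_oracle = stats.f.sf(F, 1, 18)
            assert abs(np.log10(p_oracle) - np.log10(fit.table["p"].iloc[j])) < 1e-6

    def test_collinear_structure_columns_dropped_with_warning(self, small_cohort):
        geno, Q, _, _ = small_cohort
        geno, _ = ns.qc_filter(geno)
        y = np.random.default_rng(0).normal(size=geno.n_lines)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.warns(UserWarning, match="collinear"):
                ns.mlm_scan(y, geno, Q=Q, K=ns.kinship(geno))

    def test_asymmetric_kinship_rejected(self):
        g = make_geno([[0, 1], [1, 2], [2, 0]])
        K = np.array([[1, 0.5, 0], [0.1, 1, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ns.mlm_scan(np.zeros(3), g, K=K)


class TestHitsAndCandidates:
    @staticmethod
    def _fit_from_pvalues(pvals):
        tab = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(pvals))],
                "chrom": ["chr1"] * len(pvals),
                "pos": np.arange(1, len(pvals) + 1) * 1000,
                "beta": 0.1,
                "se": 0.1,
                "stat": 1.0,
                "p": pvals,
            }
        )
        return ns.MixedModelFit(table=tab, sigma_g2=1.0, sigma_e2=1.0)

    def test_threshold_boundary_inclusive(self):
        fit = self._fit_from_pvalues([1e-5, 2e-5, 1e-6, 0.5])
        hits = ns.call_hits(fit, p_max=1e-5)
        assert set(hits["snp_id"]) == {"s0", "s2"}

    def test_planted_hits_enumerated(self):
        fit = self._fit_from_pvalues([0.5, 1e-7, 1e-8, 0.2, 9e-6])
        hits = ns.call_hits(fit, p_max=1e-5, trait="index", nitrogen_level="N1")
        assert len(hits) == 3
        assert (hits["trait"] == "index").all()

    def test_plots_written(self, tmp_path):
        fit = self._fit_from_pvalues(list(np.random.default_rng(0).uniform(size=50)))
        ns.call_hits(fit, plot_prefix=str(tmp_path / "scan"))
        assert (tmp_path / "scan_manhattan.png").exists()
        assert (tmp_path / "scan_qq.png").exists()

    @staticmethod
    def _toy_genes():
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
                "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2", "chr2"],
                "start": [1000, 400_000, 510_000, 900_000, 1000, 5000],
                "end": [2000, 401_000, 515_000, 901_000, 2000, 6000],
            }
        )

    @staticmethod
    def _hit(chrom, pos, snp="snpX"):
        return pd.DataFrame([{"snp_id": snp, "chrom": chrom, "pos": pos, "p": 1e-6}])

    def test_boundary_gene_included_closed_interval(self):
        genes = pd.DataFrame(
            [{"gene_id": "edge", "chrom": "chr1", "start": 510_000, "end": 520_000}]
        )
        out = ns.candidate_genes(self._hit("chr1", 10_000), genes, window_bp=500_000)
        assert out["gene_id"].tolist() == ["edge"]  # starts exactly at pos + window

    def test_window_truncated_at_position_one(self):
        out = ns.candidate_genes(self._hit("chr1", 10_000), self._toy_genes(), window_bp=500_000)
        # interval is [1, 510000]: g1, g2 and g3 (start 510000) match
        assert out["gene_id"].tolist() == ["g1", "g2", "g3"]

    def test_two_hit_hand_oracle(self):
        hits = pd.concat([self._hit("chr1", 450_000, "a"), self._hit("chr2", 1500, "b")])
        out = ns.candidate_genes(hits, self._toy_genes(), window_bp=100_000)
        expected = {("g2", "a"), ("g3", "a"), ("g5", "b"), ("g6", "b")}
        assert set(zip(out["gene_id"], out["anchor_snp"])) == expected
        d = out.set_index(["gene_id", "anchor_snp"])["distance_bp"]
        assert d[("g5", "b")] == 0  # overlapping
        assert d[("g6", "b")] == 3500

    def test_gff_order_invariance(self):
        genes = self._toy_genes()
        shuffled = genes.sample(frac=1.0, random_state=1).reset_index(drop=True)
        h = self._hit("chr1", 450_000)
        pd.testing.assert_frame_equal(
            ns.candidate_genes(h, genes, 100_000), ns.candidate_genes(h, shuffled, 100_000)
        )

    def test_missing_chromosome_warns_and_skips(self):
        with pytest.warns(UserWarning, match="absent"):
            out = ns.candidate_genes(self._hit("chr9", 100), self._toy_genes(), 1000)
        assert out.empty


class TestGenotypeIO:
    def test_vcf_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(6, 12)).astype(float)
        d[2, 3] = np.nan
        g = make_geno(d)
        path = tmp_path / "g.vcf"
        write_vcf(g, str(path))
        back = read_vcf(str(path))
        np.testing.assert_array_equal(np.isnan(back.dosages), np.isnan(d))
        np.testing.assert_array_equal(back.dosages[~np.isnan(d)], d[~np.isnan(d)])
        assert back.line_ids == g.line_ids

    def test_dosage_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        g = make_geno(rng.integers(0, 3, size=(4, 6)).astype(float))
        write_dosage_tsv(g, tmp_path / "d.tsv", tmp_path / "m.tsv")
        back = read_dosage_tsv(tmp_path / "d.tsv", tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.dosages, g.dosages)
        assert back.snp_map["snp_id"].tolist() == g.snp_map["snp_id"].tolist()

    def test_gff3_reader(self, tmp_path):
        from nitroscreen.gwas import read_gff3_genes
        from nitroscreen.synthetic import write_gff3

        genes = pd.DataFrame(
            {"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr2"], "start": [100, 200], "end": [500, 900]}
        )
        write_gff3(genes, str(tmp_path / "a.gff3"))
        back = read_gff3_genes(str(tmp_path / "a.gff3"))
        pd.testing.assert_frame_equal(back.sort_values("gene_id").reset_index(drop=True), genes)
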