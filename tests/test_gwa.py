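"""GWA tests: MAF filtering, covariate adjustment, GRM, mixed-model
association, annotation and overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matescan import gwa
from matescan import synthetic_data as sd
from matescan.datatypes import GenotypeMatrix, InversionBlock

from conftest import genotype_matrix_from_freqs


class TestMafFilter:
    def test_strict_threshold_and_folding(self):
        # 64 lines, dyadic alt frequencies so folding is float-exact:
        # 1/64, 2/64, 4/64, 32/64, 62/64 (folded MAF 2/64)
        g = genotype_matrix_from_freqs(
            np.array([1, 2, 4, 32, 62]) / 64, 64
        )
        out = gwa.maf_filter(g, 2 / 64)
        # keeps only MAF strictly above 2/64; the 62/64 variant folds to
        # exactly 2/64 and is removed by the strict inequality
        assert set(out.maf()) == {4 / 64, 32 / 64}

    def test_idempotent(self):
        g = genotype_matrix_from_freqs(np.linspace(0.01, 0.5, 30), 60, seed=1)
        once = gwa.maf_filter(g, 0.05)
        twice = gwa.maf_filter(once, 0.05)
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(2)
        dosage = rng.choice([0.0, 2.0], size=(50, 200), p=[0.8, 0.2])
        dosage[rng.random(dosage.shape) < 0.05] = np.nan
        variants = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, 201), "ref": "A", "alt": "T"})
        g = GenotypeMatrix([f"L{i}" for i in range(50)], variants, dosage)
        out = gwa.maf_filter(g, 0.1)
        survivors = 0
        for j in range(200):
            col = dosage[:, j]
            col = col[~np.isnan(col)]
            p = col.mean() / 2
            if min(p, 1 - p) > 0.1:
                survivors += 1
        assert out.n_variants == survivors


class TestAdjustPhenotype:
    def _cov(self, n, karyo=None, wolb=None):
        idx = [f"L{i}" for i in range(n)]
        df = pd.DataFrame(index=idx)
        df["wolbachia"] = wolb if wolb is not None else "n"
        if karyo is not None:
            df["In(3R)K"] = karyo
        return df

    def test_constant_covariates_identity(self):
        s = pd.Series([0.1, 0.2, 0.3, 0.4], index=[f"L{i}" for i in range(4)])
        adj = gwa.adjust_phenotype(s, self._cov(4, karyo=["ST/ST"] * 4))
        pd.testing.assert_series_equal(adj, s, check_names=False)

    def test_recovers_karyotype_shift(self):
        rng = np.random.default_rng(3)
        n = 60
        karyo = ["ST/INV" if i < 20 else "ST/ST" for i in range(n)]
        base = rng.normal(0.1, 0.01, n)
        y = base + 0.2 * (np.array(karyo) == "ST/INV")
        s = pd.Series(y, index=[f"L{i}" for i in range(n)])
        adj = gwa.adjust_phenotype(s, self._cov(n, karyo=karyo))
        # class re-centred: no residual class difference
        diff = adj[np.array(karyo) == "ST/INV"].mean() - adj[np.array(karyo) == "ST/ST"].mean()
        assert abs(diff) < 0.01
        assert adj.mean() == pytest.approx(s.mean())
        assert adj.var() <= s.var() + 1e-12

    def test_skip_inversions_flag(self):
        n = 10
        karyo = ["ST/INV"] * 5 + ["ST/ST"] * 5
        s = pd.Series(np.arange(n, dtype=float), index=[f"L{i}" for i in range(n)])
        adj = gwa.adjust_phenotype(s, self._cov(n, karyo=karyo), include_inversions=False)
        pd.testing.assert_series_equal(adj, s, check_names=False)

    def test_missing_covariate_rows_error(self):
        s = pd.Series([0.1, 0.2, 0.3], index=["L0", "L1", "LX"])
        with pytest.raises(ValueError, match="LX"):
            gwa.adjust_phenotype(s, self._cov(2))


class TestGrm:
    def test_identical_lines_share_relatedness(self):
        rng = np.random.default_rng(4)
        base = rng.choice([0.0, 2.0], size=300, p=[0.6, 0.4])
        dosage = np.vstack([base, base, rng.choice([0.0, 2.0], size=300)])
        variants = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, 301), "ref": "A", "alt": "T"})
        g = GenotypeMatrix(["A", "B", "C"], variants, dosage)
        K = gwa.compute_grm(g)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_symmetric_psd_expected_diagonal(self):
        rng = np.random.default_rng(5)
        # Hardy-Weinberg dosages: E[diag] = 1 under 2pq scaling
        p = rng.uniform(0.1, 0.5, 2000)
        hwe = rng.binomial(2, p, size=(80, 2000)).astype(float)
        variants = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, 2001), "ref": "A", "alt": "T"})
        g_hwe = GenotypeMatrix([f"L{i}" for i in range(80)], variants, hwe)
        K = gwa.compute_grm(g_hwe)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        se = np.std(np.diag(K), ddof=1) / np.sqrt(K.shape[0])
        assert abs(np.diag(K).mean() - 1.0) < 3 * se + 0.05
        # fully inbred {0,2} coding doubles the realized variance: E[diag] = 2
        g_inbred = genotype_matrix_from_freqs(rng.uniform(0.1, 0.5, 2000), 80, seed=6)
        Ki = gwa.compute_grm(g_inbred)
        sei = np.std(np.diag(Ki), ddof=1) / np.sqrt(Ki.shape[0])
        assert abs(np.diag(Ki).mean() - 2.0) < 3 * sei + 0.05

    def test_zero_variants_error(self):
        variants = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        g = GenotypeMatrix(["A", "B"], variants, np.empty((2, 0)))
        with pytest.raises(ValueError):
            gwa.compute_grm(g)


class TestLmmAssociation:
    def _random_panel(self, n=60, m=80, seed=7):
        return genotype_matrix_from_freqs(
            np.random.default_rng(seed).uniform(0.1, 0.5, m), n, seed=seed + 1
        )

    def test_identity_kinship_equals_ols(self):
        g = self._random_panel()
        rng = np.random.default_rng(8)
        y = rng.normal(size=g.n_lines)
        assoc = gwa.lmm_association(y, g, np.eye(g.n_lines))
        for j in [0, 13, 47]:
            res = stats.linregress(g.dosage[:, j], y)
            assert assoc["p"][j] == pytest.approx(res.pvalue, rel=1e-9)
            assert assoc["beta"][j] == pytest.approx(res.slope, rel=1e-9)

    def test_large_delta_limit_is_ols(self):
        g = self._random_panel(seed=9)
        rng = np.random.default_rng(10)
        y = rng.normal(size=g.n_lines)
        K = gwa.compute_grm(g)
        assoc = gwa.lmm_association(y, g, K, delta=1e10)
        for j in [2, 31]:
            res = stats.linregress(g.dosage[:, j], y)
            assert assoc["p"][j] == pytest.approx(res.pvalue, rel=1e-5)

    def test_invariant_to_line_permutation(self):
        g = self._random_panel(seed=11)
        rng = np.random.default_rng(12)
        y = rng.normal(size=g.n_lines)
        K = gwa.compute_grm(g)
        assoc = gwa.lmm_association(y, g, K)
        perm = rng.permutation(g.n_lines)
        g2 = GenotypeMatrix([g.line_ids[i] for i in perm], g.variants, g.dosage[perm])
        assoc2 = gwa.lmm_association(y[perm], g2, K[np.ix_(perm, perm)])
        np.testing.assert_allclose(assoc["p"], assoc2["p"], rtol=1e-8)

    def test_missing_dosage_lines_excluded(self):
        g = self._random_panel(seed=13)
        D = g.dosage.copy()
        D[:5, 0] = np.nan
        g2 = GenotypeMatrix(g.line_ids, g.variants, D)
        rng = np.random.default_rng(14)
        y = rng.normal(size=g.n_lines)
        assoc = gwa.lmm_association(y, g2, np.eye(g.n_lines))
        assert assoc["n"][0] == g.n_lines - 5
        res = stats.linregress(D[5:, 0], y[5:])
        assert assoc["p"][0] == pytest.approx(res.pvalue, rel=1e-6)

    def test_power_causal_variant_ranks_high(self):
        hits = 0
        n_sims = 25
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            g = genotype_matrix_from_freqs(rng.uniform(0.1, 0.5, 400), 205, seed=2000 + s)
            causal = 57
            x = g.dosage[:, causal]
            gvar = x.var()
            beta = np.sqrt(0.2 / gvar / 0.8)  # 20% of total variance
            y = x * beta + rng.normal(size=205)
            K = gwa.compute_grm(g)
            assoc = gwa.lmm_association(y, g, K)
            rank = assoc["p"].rank().iloc[causal]
            hits += rank <= 10
        assert hits / n_sims >= 0.9

    def test_constant_phenotype_errors(self):
        g = self._random_panel(seed=15)
        with pytest.raises(ValueError):
            gwa.lmm_association(np.zeros(g.n_lines), g, np.eye(g.n_lines))

    def test_adjusted_scan_reduces_inversion_inflation(self):
        rng = np.random.default_rng(16)
        panel = sd.simulate_founders(
            120, 800, seed=17, wolbachia_rate=0.4,
            inversion_spec={"In(3R)K": InversionBlock("3R", 2_000_000, 18_000_000, 0.25)},
        )
        karyo = panel.karyotypes
        eff = karyo["In(3R)K"].map({"ST/ST": 0.0, "ST/INV": 0.08, "INV/INV": 0.16})
        means = pd.Series(
            0.05 + eff.to_numpy() + rng.normal(0, 0.02, panel.n_lines),
            index=pd.Index(panel.line_ids, name="line"),
        )
        cov = karyo.copy()
        cov["wolbachia"] = np.where(panel.wolbachia, "y", "n")
        g = gwa.maf_filter(panel.genotypes, 0.05)
        K = gwa.compute_grm(g)
        lam = {}
        for adj in (True, False):
            y = gwa.adjust_phenotype(means, cov, include_inversions=adj)
            assoc = gwa.lmm_association(y, g, K)
            lam[adj] = gwa.genomic_lambda(assoc["p"])
        assert abs(lam[True] - 1.0) < abs(lam[False] - 1.0)


class TestThresholdAnnotationOverlap:
    def test_bonferroni(self):
        assert gwa.bonferroni_threshold(0.05, 1) == 0.05
        assert gwa.bonferroni_threshold(0.1, 10) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            gwa.bonferroni_threshold(0.05, 0)

    def test_gene_body_and_window_boundary(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["2L"], "start": [1000], "end": [2000]}
        )
        for pos, expected in [(1500, "g1"), (900, "g1"), (899, "intergenic"),
                              (2100, "g1"), (2101, "intergenic")]:
            rec = pd.DataFrame({"chrom": ["2L"], "pos": [pos]})
            out = gwa.annotate_variants(rec, genes, window=100)
            assert out["gene_id"].iloc[0] == expected

    def test_matches_bruteforce_interval_scan(self):
        rng = np.random.default_rng(18)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "chrom": rng.choice(["2L", "3R"], 30),
                "start": rng.integers(0, 90_000, 30),
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 20_000, 30)
        recs = pd.DataFrame(
            {"chrom": rng.choice(["2L", "3R"], 200), "pos": rng.integers(0, 110_000, 200)}
        )
        window = 500
        out = gwa.annotate_variants(recs, genes, window=window)
        for i, row in recs.iterrows():
            expected = {
                g["gene_id"]
                for _, g in genes.iterrows()
                if g["chrom"] == row["chrom"]
                and g["start"] - window <= row["pos"] <= g["end"] + window
            } or {"intergenic"}
            got = set(out[(out["chrom"] == row["chrom"]) & (out["pos"] == row["pos"])]["gene_id"])
            assert expected <= got

    def test_malformed_interval_errors(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["2L"], "start": [10], "end": [5]})
        with pytest.raises(ValueError):
            gwa.annotate_variants(pd.DataFrame({"chrom": ["2L"], "pos": [7]}), genes)

    def test_gene_overlap_two_and_three_sets(self):
        assert gwa.gene_overlap({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}}) == {
            "shared": 2, "unique_A": 1, "unique_B": 1,
        }
        same = gwa.gene_overlap({"x": {"a"}, "y": {"a"}})
        assert same["shared"] == 1 and same["unique_x"] == 0
        res = gwa.gene_overlap({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 4, 5}})
        assert res["all_three"] == 1
        assert res["only_A"] == 1
        assert sum(res.values()) == 5  # |A u B u C|
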