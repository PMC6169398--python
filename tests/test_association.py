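"""BLUPs, kinship, mixed-model scans and outlier selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinalscan import (LandscapeConfig, estimate_blups, glm_scan, kinship,
                        mlm_scan, mlmm_scan, select_outliers,
                        simulate_landscape)

from conftest import make_gm


class TestBlups:
    def test_balanced_single_garden_matches_closed_form(self, rng):
        n_acc, r = 40, 5
        g = rng.normal(0, 2, n_acc)
        rows = [(f"a{i:02d}", "g1", 10 + g[i] + rng.normal())
                for i in range(n_acc) for _ in range(r)]
        df = pd.DataFrame(rows, columns=["accession", "garden", "value"])
        bt = estimate_blups(df)
        lam = r * bt.var_accession / (r * bt.var_accession + bt.var_residual)
        means = df.groupby("accession")["value"].mean()
        expect = bt.mu + lam * (means - df["value"].mean())
        got = bt.series().sort_index()
        assert np.allclose(got.to_numpy(), expect.sort_index().to_numpy(),
                           atol=1e-8)

    def test_null_trait_blups_collapse_to_mu(self, rng):
        rows = [(f"a{i}", f"g{j}", rng.normal(5.0, 1.0))
                for i in range(30) for j in range(3)]
        df = pd.DataFrame(rows, columns=["accession", "garden", "value"])
        bt = estimate_blups(df)
        spread_blup = bt.series().std()
        spread_mean = df.groupby("accession")["value"].mean().std()
        assert spread_blup < 0.5 * spread_mean  # heavy shrinkage toward mu

    def test_shrinkage_property_balanced(self, rng):
        rows = [(f"a{i}", "g1", rng.normal(i % 5, 1.0))
                for i in range(20) for _ in range(3)]
        df = pd.DataFrame(rows, columns=["accession", "garden", "value"])
        bt = estimate_blups(df)
        means = df.groupby("accession")["value"].mean()
        dev_blup = (bt.series() - bt.mu).abs().sort_index()
        dev_mean = (means - df["value"].mean()).abs().sort_index()
        assert (dev_blup <= dev_mean + 1e-8).all()

    def test_blup_beats_pooled_mean_with_garden_offsets(self):
        from clinalscan import simulate_phenotypes

        wins = 0
        for seed in range(10):
            gm, _, truth = simulate_landscape(LandscapeConfig(
                n_samples=150, n_snps=400, n_clinal_loci=0, seed=70 + seed))
            rec = simulate_phenotypes(truth, gm, h2=0.4, garden_effects=8.0,
                                      seed=seed, n_gardens=3)
            # unbalance the design: drop a third of records
            rec = rec.sample(frac=0.67, random_state=seed)
            g = np.asarray(truth.genetic_values["trait"])
            order = {s: i for i, s in enumerate(gm.sample_ids)}
            bt = estimate_blups(rec)
            idx = [order[a] for a in bt.table["accession_id"]]
            r_blup = np.corrcoef(bt.table["blup"], g[idx])[0, 1]
            raw = rec.groupby("accession")["value"].mean()
            r_raw = np.corrcoef(raw.to_numpy(),
                                g[[order[a] for a in raw.index]])[0, 1]
            wins += r_blup >= r_raw
        assert wins >= 8


class TestKinship:
    def test_duplicated_samples_share_diagonal_value(self, rng):
        p = rng.uniform(0.2, 0.8, 100)
        a = rng.binomial(2, p)
        d = np.vstack([a, a, rng.binomial(2, p)])
        K, ids = kinship(make_gm(d))
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-10)

    def test_panmictic_off_diagonal_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 2000)
        d = rng.binomial(2, p, size=(200, 2000))
        K, _ = kinship(make_gm(d, positions=list(range(1, 2001))))
        off = K[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_matches_double_loop_oracle(self, rng):
        p = rng.uniform(0.2, 0.8, 50)
        d = rng.binomial(2, p, size=(15, 50))
        K, _ = kinship(make_gm(d))
        ph = d.mean(axis=0) / 2
        denom = 2 * np.sum(ph * (1 - ph))
        for i in range(15):
            for j in range(15):
                z = np.sum((d[i] - 2 * ph) * (d[j] - 2 * ph))
                assert K[i, j] == pytest.approx(z / denom, abs=1e-10)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            kinship(make_gm(np.zeros((5, 3), dtype=int)))


class TestMlmScan:
    def test_identity_kinship_collapses_to_ols(self, rng):
        gm, _, _ = simulate_landscape(LandscapeConfig(
            n_samples=80, n_snps=300, n_clinal_loci=0, seed=31))
        y = rng.normal(size=80)
        scan = mlm_scan(gm, y, None, np.eye(80), min_maf=0.05)
        tab = scan.table
        for _, row in tab.sample(10, random_state=1).iterrows():
            j = gm.variant_ids.index(row["id"])
            x = gm.dosages[:, j].astype(float)
            res = stats.linregress(x, y)
            assert row["p_value"] == pytest.approx(res.pvalue, abs=1e-6)

    def test_planted_qtl_top_ranked(self, rng):
        from clinalscan import allele_stats, pca

        gm, _, _ = simulate_landscape(LandscapeConfig(
            n_samples=300, n_snps=3000, n_clinal_loci=0, seed=33, n_qtl=0))
        st = allele_stats(gm)
        q = int(np.flatnonzero(st["maf"] > 0.2)[10])
        g = gm.dosages[:, q].astype(float)
        g -= g.mean()
        y = g + rng.normal(0, np.sqrt(g.var() * 4), 300)  # 20% of variance
        K, _ = kinship(gm)
        pcs = pca(gm, min_maf=0.05)
        scan = mlm_scan(gm, y, pcs.scores[:, :3], K, min_maf=0.03)
        top = scan.table.loc[scan.table["p_value"].idxmin(), "id"]
        assert top == gm.variant_ids[q]

    def test_maf_filter_applied(self, rng):
        gm, _, _ = simulate_landscape(LandscapeConfig(
            n_samples=100, n_snps=500, n_clinal_loci=0, seed=35))
        scan = mlm_scan(gm, rng.normal(size=100), None, np.eye(100),
                        min_maf=0.03)
        assert (scan.table["maf"] >= 0.03).all()


class TestMlmmScan:
    def test_null_trait_selects_no_cofactors(self, rng):
        from clinalscan import pca

        gm, _, _ = simulate_landscape(LandscapeConfig(
            n_samples=150, n_snps=1000, n_clinal_loci=0, seed=37))
        K, _ = kinship(gm)
        pcs = pca(gm, min_maf=0.05)
        y = rng.normal(size=150)
        scan = mlmm_scan(gm, y, pcs.scores[:, :3], K, min_maf=0.03)
        assert scan.cofactor_path == []

    def test_two_qtls_in_cofactor_path(self, rng):
        from clinalscan import allele_stats, pca

        gm, _, _ = simulate_landscape(LandscapeConfig(
            n_samples=300, n_snps=3000, n_clinal_loci=0, seed=39, n_qtl=0))
        st = allele_stats(gm)
        common = np.flatnonzero(st["maf"] > 0.2)
        q1, q2 = int(common[5]), int(common[50])
        g1 = gm.dosages[:, q1].astype(float)
        g2 = gm.dosages[:, q2].astype(float)
        g1 = (g1 - g1.mean()) / g1.std()
        g2 = (g2 - g2.mean()) / g2.std()
        y = g1 + g2 + rng.normal(0, np.sqrt(2 * 0.7 / 0.3), 300)
        K, _ = kinship(gm)
        pcs = pca(gm, min_maf=0.05)
        scan = mlmm_scan(gm, y, pcs.scores[:, :3], K, max_cofactors=3,
                         min_maf=0.03)
        assert {gm.variant_ids[q1], gm.variant_ids[q2]} <= set(
            scan.cofactor_path)

    def test_path_deterministic(self, rng):
        from clinalscan import pca

        gm, _, truth = simulate_landscape(LandscapeConfig(
            n_samples=200, n_snps=1500, n_clinal_loci=0, seed=41))
        from clinalscan import simulate_phenotypes

        rec = simulate_phenotypes(truth, gm, h2=0.6, garden_effects=0.0,
                                  seed=4, n_gardens=1)
        y = rec.groupby("accession")["value"].mean().reindex(
            gm.sample_ids).to_numpy()
        K, _ = kinship(gm)
        pcs = pca(gm, min_maf=0.05)
        s1 = mlmm_scan(gm, y, pcs.scores[:, :3], K, min_maf=0.03)
        s2 = mlmm_scan(gm, y, pcs.scores[:, :3], K, min_maf=0.03)
        assert s1.cofactor_path == s2.cofactor_path


class TestGlmScan:
    def test_exact_linear_env_slope_recovered(self):
        d = np.array([[0, 0], [1, 0], [1, 2], [2, 2], [0, 1], [2, 1]])
        gm = make_gm(d)
        env = 3.0 + 2.0 * d[:, 0]
        scan = glm_scan(gm, env, min_maf=0.0)
        row = scan.table.set_index("id").loc["v0"]
        assert row["effect"] == pytest.approx(2.0, abs=1e-10)
        assert row["p_value"] < 1e-10

    def test_toy_matches_closed_form_least_squares(self):
        d = np.array([[0], [1], [1], [2]])
        env = np.array([1.0, 2.0, 3.0, 4.0])
        scan = glm_scan(make_gm(d), env, min_maf=0.0)
        x = d[:, 0].astype(float)
        res = stats.linregress(x, env)
        row = scan.table.iloc[0]
        assert row["effect"] == pytest.approx(res.slope, abs=1e-12)
        assert row["p_value"] == pytest.approx(res.pvalue, abs=1e-12)

    def test_permuted_env_gives_uniform_p(self, rng):
        gm, table, _ = simulate_landscape(LandscapeConfig(
            n_samples=150, n_snps=3000, n_clinal_loci=200, seed=43))
        env = rng.permutation(table.data["bio12"].to_numpy())
        scan = glm_scan(gm, env, min_maf=0.05)
        ks = stats.kstest(scan.p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_rejects_nonfinite_env(self, random_gm):
        env = np.full(random_gm.n_samples, np.nan)
        with pytest.raises(ValueError):
            glm_scan(random_gm, env)


class TestOutliers:
    def test_exact_count_without_ties(self, rng, random_gm):
        scan = glm_scan(random_gm, rng.normal(size=random_gm.n_samples),
                        min_maf=0.0)
        n = len(scan.table)
        scan = select_outliers(scan, quantile=10 / n)
        assert int(scan.table["outlier"].sum()) == 10

    def test_all_ties_all_flagged(self):
        from clinalscan.association import ScanResult

        tab = pd.DataFrame({"id": [f"v{i}" for i in range(20)],
                            "chrom": "Chr01", "pos": range(1, 21),
                            "maf": 0.2, "effect": 0.0, "stderr": 1.0,
                            "p_value": 0.5})
        scan = select_outliers(ScanResult(tab, "glm", "x"), 0.01)
        assert scan.table["outlier"].all()

    def test_matches_sort_and_slice_oracle(self, rng):
        from clinalscan.association import ScanResult

        p = rng.random(500)
        tab = pd.DataFrame({"id": [f"v{i}" for i in range(500)],
                            "chrom": "Chr01", "pos": range(1, 501),
                            "maf": 0.2, "effect": 0.0, "stderr": 1.0,
                            "p_value": p})
        scan = select_outliers(ScanResult(tab, "glm", "x"), 0.01)
        cut = np.sort(p)[4]  # 5th smallest of 500 = 1% quantile
        assert set(scan.table.loc[scan.table["outlier"], "id"]) == set(
            tab.loc[p <= cut, "id"])
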