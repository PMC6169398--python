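"""Population-genetic statistics against independently coded oracles."""

import numpy as np
import pytest

from clinalscan import (MISSING, allele_stats, filter_variants, ld_decay,
                        nucleotide_diversity_windows, sample_qc,
                        tajima_constants, tajima_d_windows,
                        weir_cockerham_fst)
from clinalscan.popgen_stats import pairwise_r2, tajima_d_value

from conftest import make_gm


# ---------------------------------------------------------------------------
# Independent oracles (straight transcriptions, scalar loops)
# ---------------------------------------------------------------------------

def wc_oracle(dosages, labels):
    """Weir & Cockerham (1984) per-site components, scalar code."""
    out = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        ns, ps, hs = [], [], []
        for g in sorted(set(labels)):
            sub = col[(np.asarray(labels) == g) & (col != MISSING)]
            if len(sub):
                ns.append(len(sub))
                ps.append(sub.sum() / (2 * len(sub)))
                hs.append((sub == 1).mean())
        r = len(ns)
        if r < 2:
            out.append((np.nan, np.nan, np.nan))
            continue
        ns, ps, hs = map(np.asarray, (ns, ps, hs))
        nbar = ns.mean()
        if nbar <= 1:
            out.append((np.nan, np.nan, np.nan))
            continue
        nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            out.append((np.nan, np.nan, np.nan))
            continue
        pbar = (ns * ps).sum() / (r * nbar)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return np.asarray(out)


def pi_oracle_pairwise(col):
    """Average pairwise difference among observed alleles, enumerated."""
    alleles = []
    for d in col:
        if d == MISSING:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(d)]
    n = len(alleles)
    if n < 2:
        return 0.0
    diffs = sum(alleles[i] != alleles[j]
                for i in range(n) for j in range(i + 1, n))
    return diffs / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Filtering and allele stats
# ---------------------------------------------------------------------------

class TestFilter:
    def test_missingness_rule(self):
        col = [0] * 3 + [MISSING]  # 25% missing
        gm = make_gm(np.array([col, [1, 1, 0, 0]]).T)
        out, rep = filter_variants(gm, max_missing=0.2,
                                   drop_monomorphic=False)
        assert rep.n_missingness == 1 and out.n_variants == 1

    def test_singleton_removed_at_mac3(self):
        d = np.zeros((10, 1), dtype=int)
        d[0, 0] = 1
        out, rep = filter_variants(make_gm(d), min_mac=3)
        assert out.n_variants == 0 and rep.n_mac == 1

    def test_toy_matrix_matches_hand_enumeration(self):
        # 10 sites over 10 samples with known per-rule fates
        n = 10
        cols, fates = [], []
        cols.append([0] * n); fates.append("mono")
        cols.append([2] * n); fates.append("mono")
        cols.append([1] + [0] * 9); fates.append("mac")          # mac 1
        cols.append([1, 1] + [0] * 8); fates.append("mac")       # mac 2
        cols.append([1, 1, 1] + [0] * 7); fates.append("keep")   # mac 3
        cols.append([2, 2] + [0] * 8); fates.append("keep")      # maf .2
        cols.append([MISSING] * 3 + [1] * 7); fates.append("miss")  # 30% miss
        cols.append([MISSING] * 2 + [1] * 8); fates.append("keep")  # 20% ok
        cols.append([1] * n); fates.append("keep")
        cols.append([0, 1, 2, 0, 1, 2, 0, 1, 2, 0]); fates.append("keep")
        gm = make_gm(np.array(cols).T)
        out, rep = filter_variants(gm, max_missing=0.2, min_mac=3)
        assert rep.n_missingness == 1
        assert rep.n_mac == 2
        assert rep.n_monomorphic == 2
        expected_kept = [f"v{i}" for i, f in enumerate(fates) if f == "keep"]
        assert out.variant_ids == expected_kept

    def test_maf_rule_gwas_setting(self):
        d = np.zeros((100, 2), dtype=int)
        d[:2, 0] = 1   # freq 0.01
        d[:10, 1] = 1  # freq 0.05
        out, rep = filter_variants(make_gm(d), min_maf=0.03,
                                   drop_monomorphic=False)
        assert out.variant_ids == ["v1"] and rep.n_maf == 1


class TestAlleleStats:
    def test_basic_frequencies(self):
        st = allele_stats(make_gm(np.array([[0, 0], [1, 0],
                                            [2, MISSING]])))
        assert st["alt_freq"][0] == 0.5 and st["maf"][0] == 0.5
        assert st["alt_freq"][1] == 0.0
        assert st["missing_rate"][1] == pytest.approx(1 / 3)

    def test_matches_per_site_loop(self, rng):
        d = rng.integers(0, 3, size=(30, 100))
        d[rng.random(d.shape) < 0.1] = MISSING
        st = allele_stats(make_gm(d))
        for j in rng.choice(100, 25, replace=False):
            col = d[:, j][d[:, j] != MISSING]
            assert st["alt_freq"][j] == pytest.approx(
                col.sum() / (2 * len(col)))
            assert st["mac"][j] == min(col.sum(), 2 * len(col) - col.sum())


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

class TestPi:
    def test_monomorphic_window_zero(self):
        ws = nucleotide_diversity_windows(make_gm([[0, 2], [0, 2]]), 1000)
        assert ws[0].value == 0.0

    def test_hand_example_two_diploids(self):
        # one site, p=0.5, 4 alleles, window 1000
        ws = nucleotide_diversity_windows(make_gm([[0], [2]]), 1000)
        assert ws[0].value == pytest.approx((2 * 0.25 * 4 / 3) / 1000)

    def test_equals_average_pairwise_difference_oracle(self, rng):
        d = rng.integers(0, 3, size=(12, 40))
        d[rng.random(d.shape) < 0.15] = MISSING
        gm = make_gm(d, positions=list(range(1, 41)))
        ws = nucleotide_diversity_windows(gm, 1000)
        expect = sum(pi_oracle_pairwise(d[:, j]) for j in range(40)) / 1000
        assert ws[0].value == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_sample_order_and_allele_swap(self, random_gm):
        ws = nucleotide_diversity_windows(random_gm, 10**6)
        perm = np.random.default_rng(1).permutation(random_gm.n_samples)
        ws_p = nucleotide_diversity_windows(random_gm.take_samples(perm),
                                            10**6)
        swapped = make_gm(2 - random_gm.dosages,
                          positions=random_gm.positions.tolist())
        ws_s = nucleotide_diversity_windows(swapped, 10**6)
        assert ws[0].value == pytest.approx(ws_p[0].value, abs=1e-12)
        assert ws[0].value == pytest.approx(ws_s[0].value, abs=1e-12)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def test_fixed_difference_is_one(self):
        d = np.concatenate([np.zeros((5, 1)), np.full((5, 1), 2)]).astype(int)
        per_site, theta = weir_cockerham_fst(make_gm(d), [0] * 5 + [1] * 5)
        assert per_site[0] == pytest.approx(1.0) and theta == pytest.approx(1.0)

    def test_panmictic_null_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 5000)
        d = rng.binomial(2, p, size=(60, 5000))
        _, theta = weir_cockerham_fst(
            make_gm(d, positions=list(range(1, 5001))), np.arange(60) % 2)
        assert abs(theta) < 0.01

    def test_requires_two_groups(self, random_gm):
        with pytest.raises(ValueError):
            weir_cockerham_fst(random_gm, [0] * random_gm.n_samples)

    def test_matches_component_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n_pops = int(rng.integers(2, 5))
            n_per = int(rng.integers(3, 9))
            m = int(rng.integers(3, 10))
            n = n_pops * n_per
            labels = np.repeat(np.arange(n_pops), n_per)
            d = rng.integers(0, 3, size=(n, m))
            d[rng.random(d.shape) < 0.1] = MISSING
            gm = make_gm(d, positions=list(range(1, m + 1)))
            per_site, theta = weir_cockerham_fst(gm, labels)
            comp = wc_oracle(d, labels)
            a, b, c = comp[:, 0], comp[:, 1], comp[:, 2]
            with np.errstate(invalid="ignore"):
                expect = a / (a + b + c)
            for j in range(m):
                if np.isnan(expect[j]) or (a + b + c)[j] == 0:
                    continue
                assert per_site[j] == pytest.approx(expect[j], abs=1e-12)
            ok = np.isfinite(a + b + c)
            if ok.any() and np.nansum((a + b + c)[ok]) != 0:
                assert theta == pytest.approx(
                    np.nansum(a[ok]) / np.nansum((a + b + c)[ok]), abs=1e-12)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimaD:
    def test_empty_window_missing(self):
        ws = tajima_d_windows(make_gm([[0], [0]]), 1000)
        assert ws[0].value is None

    def test_four_haplotype_hand_example(self):
        H = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]])
        ws = tajima_d_windows(H, 10**6, ploidy=1)
        # direct evaluation of the 1989 formulas, coded independently
        n, S = 4, 3
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
        pi_sum = (1 * 3 + 2 * 2 + 3 * 1) / 6
        D = (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert ws[0].value == pytest.approx(D, abs=1e-12)

    def test_constants_small_n(self):
        k = tajima_constants(4)
        assert k["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)

    def test_zero_variance_returns_missing(self):
        assert tajima_d_value(0.0, 0, 10) is None

    def test_diploid_matches_haploid_expansion(self, rng):
        # diploid dosages carry the same allele counts as the expanded
        # haplotype matrix when the chromosome count matches
        d = rng.integers(0, 3, size=(8, 30))
        gm = make_gm(d, positions=list(range(1, 31)))
        ws_d = tajima_d_windows(gm, 10**6)
        H = np.zeros((16, 30), dtype=int)
        for i in range(8):
            for j in range(30):
                H[2 * i, j] = 1 if d[i, j] == 2 else 0
                H[2 * i + 1, j] = 1 if d[i, j] >= 1 else 0
        ws_h = tajima_d_windows(H, 10**6, ploidy=1)
        assert ws_d[0].value == pytest.approx(ws_h[0].value, abs=1e-12)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

class TestLDDecay:
    def test_duplicated_variant_r2_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        assert pairwise_r2(col, col) == pytest.approx(1.0)

    def test_independent_sites_low_r2(self, rng):
        p = rng.uniform(0.2, 0.8, 200)
        d = rng.binomial(2, p, size=(500, 200))
        gm = make_gm(d, positions=sorted(rng.choice(10**5, 200,
                                                    replace=False)))
        curve = ld_decay(gm, max_dist_bp=50_000, bin_bp=5000)
        assert np.nanmean(curve.mean_r2) < 0.01

    def test_r2_invariant_to_dosage_flip(self, rng):
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        assert pairwise_r2(x, y) == pytest.approx(pairwise_r2(2 - x, y),
                                                  abs=1e-12)

    def test_block_construction_crossing_near_block_length(self, rng):
        # blocks of near-copies: within-block r2 high, between-block ~0
        block_bp, n, m = 20_000, 300, 120
        base_positions = np.sort(rng.choice(240_000, m, replace=False)) + 1
        d = np.empty((n, m), dtype=int)
        block_id = (base_positions - 1) // block_bp
        for b in np.unique(block_id):
            idx = np.flatnonzero(block_id == b)
            p = rng.uniform(0.3, 0.7)
            proto = rng.binomial(2, p, size=n)
            for j in idx:
                flip = rng.random(n) < 0.05
                col = proto.copy()
                col[flip] = rng.binomial(2, p, size=flip.sum())
                d[:, j] = col
        gm = make_gm(d, positions=base_positions.tolist())
        curve = ld_decay(gm, max_dist_bp=100_000, bin_bp=5000)
        cross = curve.crossings[0.1]
        assert cross is not None
        assert cross <= block_bp + 5000
        sm = curve.smoothed_r2[np.isfinite(curve.smoothed_r2)]
        assert sm[0] > 0.5 > sm[-1]


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

class TestSampleQC:
    def test_all_homozygous_sample(self):
        d = np.array([[0, 2, 0, 2], [0, 1, 1, 2], [1, 1, 0, 0]])
        qc = sample_qc(make_gm(d))
        assert qc[0].observed_het == 0.0
        assert qc[0].inbreeding_f == pytest.approx(1.0)

    def test_half_het_sample(self):
        d = np.array([[0, 1, 1, 2], [0, 1, 2, 1], [2, 1, 0, 1]])
        qc = sample_qc(make_gm(d))
        assert qc[0].observed_het == 0.5

    def test_inbreeding_recovers_selfing_rate(self):
        from clinalscan import LandscapeConfig, simulate_landscape

        fs = []
        for seed in range(3):
            gm, _, _ = simulate_landscape(LandscapeConfig(
                n_samples=150, n_snps=2000, n_clinal_loci=0,
                seed=40 + seed))
            qc = sample_qc(gm)
            fs.append(np.mean([q.inbreeding_f for q in qc]))
        assert np.mean(fs) == pytest.approx(0.8, abs=0.05)
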