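import numpy as np
import pandas as pd
import pytest

from hsqtl import scan as scanmod
from hsqtl.genoqc import GenotypeMatrix
from hsqtl.scan import (ScanResult, SignificanceThreshold, assoc_scan, call_qtls,
                        colocate, ld_r2, permutation_threshold, phewas_lookup,
                        qtl_interval)
from hsqtl.varcomp import compute_loco_grms


def geno(X, chroms, positions, ids=None):
    m = X.shape[1]
    snps = pd.DataFrame({"chrom": chroms, "pos": positions,
                         "id": ids or [f"s{j}" for j in range(m)],
                         "ref": ["A"] * m, "alt": ["C"] * m})
    return GenotypeMatrix(ids=[f"i{k}" for k in range(X.shape[0])],
                          snps=snps, dosages=X)


def random_geno(n, m, n_chrom=2, seed=0, maf_low=0.15):
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, 0.5, m)
    X = rng.binomial(2, p, size=(n, m)).astype(float)
    chroms = [str(1 + j * n_chrom // m) for j in range(m)]
    positions = [(j % (m // n_chrom) + 1) * 10_000 for j in range(m)]
    return geno(X, chroms, positions)


def scan_fixture(rows):
    rec = pd.DataFrame(rows, columns=["chrom", "pos", "id", "neglog10_p"])
    rec["beta"] = 0.1
    rec["se"] = 0.02
    return ScanResult(trait="t", records=rec[["chrom", "pos", "id", "beta",
                                              "se", "neglog10_p"]])


class TestAssocScan:
    def test_null_pvalues_uniform_without_structure(self):
        G = random_geno(250, 2400, seed=1)
        loco = compute_loco_grms(G)
        y = np.random.default_rng(2).standard_normal(250)
        res = assoc_scan(y, G, loco, variance_components=(0.0, 1.0))
        frac = np.mean(res.records["neglog10_p"] > -np.log10(0.05))
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_conditioning_snp_marked_untestable(self, small_cohort, small_loco):
        _, G, pheno, _ = small_cohort
        loco, ws = small_loco
        sid = str(G.snps["id"].iloc[5])
        res = assoc_scan(pheno["consumption"].to_numpy(), G, loco,
                         conditioning_snps=[sid], workspace=ws)
        row = res.records[res.records["id"] == sid].iloc[0]
        assert np.isnan(row["neglog10_p"])

    def test_missing_phenotypes_fall_back_to_complete_cases(self, small_cohort, small_loco):
        _, G, pheno, truth = small_cohort
        loco, ws = small_loco
        y = pheno["consumption"].to_numpy().copy()
        y[:10] = np.nan
        res = assoc_scan(y, G, loco, workspace=ws)
        assert res.max_record()["id"] == truth["qtls"][0]["snp_id"]

    def test_planted_qtl_is_genome_wide_peak(self, small_cohort, small_loco):
        _, G, pheno, truth = small_cohort
        loco, ws = small_loco
        res = assoc_scan(pheno["consumption"].to_numpy(), G, loco, workspace=ws)
        assert res.max_record()["id"] == truth["qtls"][0]["snp_id"]


class TestPermutationThreshold:
    def test_quantile_monotone_in_alpha_and_seed_deterministic(self, small_cohort, small_loco):
        _, G, pheno, _ = small_cohort
        loco, ws = small_loco
        y = np.random.default_rng(3).standard_normal(G.n_individuals)
        t05 = permutation_threshold(y, G, loco, n_perm=40, alpha=0.05, seed=9,
                                    workspace=ws)
        t_all = permutation_threshold(y, G, loco, n_perm=40, alpha=1.0, seed=9,
                                      workspace=ws)
        assert t_all.value == pytest.approx(np.min(t05.maxima))
        assert t05.value >= t_all.value
        again = permutation_threshold(y, G, loco, n_perm=40, alpha=0.05, seed=9,
                                      workspace=ws)
        np.testing.assert_array_equal(t05.maxima, again.maxima)

    def test_too_few_permutations_rejected(self, small_cohort, small_loco):
        _, G, pheno, _ = small_cohort
        loco, ws = small_loco
        with pytest.raises(ValueError):
            permutation_threshold(pheno["consumption"].to_numpy(), G, loco,
                                  n_perm=5, workspace=ws)


class TestLd:
    def test_self_and_perfect_negative(self):
        X = np.array([[0, 2.0], [1, 1], [2, 0], [0, 2]])
        G = geno(X, ["1", "1"], [100, 200])
        assert ld_r2(G, "s0", "s0") == pytest.approx(1.0)
        assert ld_r2(G, "s0", "s1") == pytest.approx(1.0)  # r = -1 squared

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.4, size=(1000, 2)).astype(float)
        G = geno(X, ["1", "1"], [100, 200])
        assert ld_r2(G, "s0", "s1") < 0.01

    def test_monomorphic_undefined(self):
        X = np.column_stack([np.zeros(10), np.random.default_rng(5).binomial(2, .4, 10)])
        G = geno(X.astype(float), ["1", "1"], [100, 200])
        assert np.isnan(ld_r2(G, "s0", "s1"))


class TestCallQtls:
    def test_supported_peak_reported(self):
        s = scan_fixture([("11", 35_000_000, "p", 7.0),
                          ("11", 35_200_000, "q", 6.2),
                          ("11", 36_000_000, "r", 3.0)])
        peaks = call_qtls(s, 5.58)
        assert [p["id"] for p in peaks] == ["p"]
        assert peaks[0]["support_count"] == 1

    def test_unsupported_peak_rejected(self):
        s = scan_fixture([("1", 35_000_000, "p", 7.0),
                          ("1", 35_200_000, "q", 4.9)])  # 4.9 < 7.0 - 2
        assert call_qtls(s, 5.58) == []

    def test_boundaries_inclusive(self):
        s = scan_fixture([("1", 35_000_000, "p", 7.0),
                          ("1", 35_500_000, "q", 5.0)])  # exactly peak-2, 0.5 Mb
        peaks = call_qtls(s, 4.0)
        assert peaks and peaks[0]["id"] == "p"

    def test_support_snp_need_not_pass_threshold(self):
        s = scan_fixture([("1", 10_000_000, "p", 6.0),
                          ("1", 10_100_000, "q", 4.5)])  # below 5.58, within 2
        assert call_qtls(s, 5.58)[0]["support_count"] == 1

    def test_tie_breaks_toward_lower_position(self):
        s = scan_fixture([("1", 20_000_000, "b", 7.0),
                          ("1", 10_000_000, "a", 7.0),
                          ("1", 10_200_000, "c", 6.5)])
        assert call_qtls(s, 5.0)[0]["id"] == "a"

    def test_one_candidate_per_chromosome(self):
        s = scan_fixture([("1", 1_000_000, "a", 7.0), ("1", 1_100_000, "a2", 6.5),
                          ("2", 5_000_000, "b", 8.0), ("2", 5_050_000, "b2", 7.9)])
        assert [p["id"] for p in call_qtls(s, 5.0)] == ["a", "b"]


def ld_block_geno(seed=6):
    """Chromosome with engineered LD to the middle (peak) SNP."""
    rng = np.random.default_rng(seed)
    n = 600
    base = rng.binomial(2, 0.5, n).astype(float)

    def flip(x, k):
        y = x.copy()
        idx = rng.choice(n, k, replace=False)
        y[idx] = rng.binomial(2, 0.5, k)
        return y

    cols = {
        "far_low": flip(base, 450),    # r2 well below 0.6
        "left_hi": flip(base, 60),     # r2 above 0.6
        "peak": base,
        "right_hi": flip(base, 80),
        "right_low": flip(base, 500),
    }
    X = np.column_stack(list(cols.values()))
    pos = [1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000]
    return geno(X, ["7"] * 5, pos, ids=list(cols)), cols


class TestQtlInterval:
    def test_boundaries_are_outermost_high_ld_snps(self):
        G, _ = ld_block_geno()
        assert ld_r2(G, "peak", "left_hi") >= 0.6
        assert ld_r2(G, "peak", "right_hi") >= 0.6
        assert ld_r2(G, "peak", "far_low") < 0.6
        assert ld_r2(G, "peak", "right_low") < 0.6
        assert qtl_interval(G, "peak") == (2_000_000, 4_000_000)

    def test_no_neighbor_gives_zero_width(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.4, size=(500, 3)).astype(float)
        G = geno(X, ["1"] * 3, [1_000, 2_000, 3_000])
        assert qtl_interval(G, "s1") == (2_000, 2_000)

    def test_interval_contains_peak_and_shrinks_with_r2(self, small_cohort):
        _, G, _, truth = small_cohort
        peak = truth["qtls"][0]["snp_id"]
        pos = truth["qtls"][0]["pos"]
        lo = qtl_interval(G, peak, r2_min=0.4)
        hi = qtl_interval(G, peak, r2_min=0.9)
        assert lo[0] <= pos <= lo[1]
        assert lo[0] <= hi[0] and hi[1] <= lo[1]

    def test_contiguity_not_required(self):
        G, _ = ld_block_geno()
        # insert a low-LD SNP between peak and right_hi: interval unchanged
        assert qtl_interval(G, "peak")[1] == 4_000_000


class TestColocPhewas:
    def annotation(self):
        return pd.DataFrame({
            "snp_id": ["left_hi", "far_low", "absent"],
            "chrom": ["7", "7", "7"],
            "pos": [2_000_000, 1_000_000, 3_500_000],
            "gene": ["Brwd1", "Pcp4", "Sh3bgr"],
            "tissue": ["brain"] * 3,
            "modality": ["coding", "eQTL", "sQTL"],
        })

    def make_qtl(self):
        return scanmod.Qtl(trait="t", chrom="7", peak_snp="peak",
                           peak_pos=3_000_000, peak_neglog10_p=7.0,
                           support_count=1, interval_start_bp=2_000_000,
                           interval_end_bp=4_000_000, conditioning_round=0)

    def test_window_and_strong_ld_classification(self):
        G, _ = ld_block_geno()
        out = colocate(self.make_qtl(), self.annotation(), G, window=1_500_000)
        assert set(out["snp_id"]) == {"left_hi", "absent"}  # far_low fine, absent ok
        strong = out.set_index("snp_id")["strong_ld"]
        assert strong["left_hi"]
        assert np.isnan(out.set_index("snp_id")["r2"]["absent"])

    def test_distant_annotation_excluded(self):
        G, _ = ld_block_geno()
        ann = self.annotation()
        ann.loc[0, "pos"] = 7_000_000  # 4 Mb away
        out = colocate(self.make_qtl(), ann, G, window=3_000_000)
        assert "left_hi" not in set(out["snp_id"])

    def test_phewas_identity_and_missing(self):
        s1 = scan_fixture([("1", 100, "x", 6.0)])
        s1.trait = "own"
        s2 = scan_fixture([("1", 200, "y", 3.0)])
        s2.trait = "other"
        out = phewas_lookup("x", [s1, s2])
        assert out.iloc[0]["trait"] == "own"
        assert out.iloc[0]["neglog10_p"] == pytest.approx(6.0)
        assert np.isnan(out.set_index("trait").loc["other", "neglog10_p"])
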