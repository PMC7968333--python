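"""ssGWAS back-solving, window scan, region merging and trajectory clusters."""

import numpy as np
import pandas as pd
import pytest

from reactnorm import gwas


def _map(m, n_chrom=2):
    per = m // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)[:m]
    bp = np.concatenate([np.arange(1, (chrom == c).sum() + 1) * 1000
                         for c in np.unique(chrom)])
    return pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": chrom, "bp": bp})


@pytest.fixture
def geno(rng):
    return rng.binomial(2, rng.uniform(0.2, 0.5, 120), size=(60, 120)).astype(float)


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self, geno):
        n = geno.shape[0]
        G = np.eye(n)
        eff = gwas.backsolve_snp_effects(
            np.zeros(n), np.zeros(n), geno, G, _map(120))
        assert np.allclose(eff.intercept, 0) and np.allclose(eff.slope, 0)

    def test_linearity_in_gebv(self, rng, geno):
        n = geno.shape[0]
        from reactnorm.kinship import vanraden_G

        G0, _, _ = vanraden_G(geno)
        G = G0 + 1e-6 * np.eye(n)
        g0, g1 = rng.normal(size=n), rng.normal(size=n)
        e1 = gwas.backsolve_snp_effects(g0, g1, geno, G, _map(120))
        e2 = gwas.backsolve_snp_effects(3 * g0, 3 * g1, geno, G, _map(120))
        assert np.allclose(e2.intercept, 3 * e1.intercept)
        assert np.allclose(e2.slope, 3 * e1.slope)

    def test_projection_identity_with_more_animals_than_snps(self, rng):
        """With m < n and gEBVs in the marker span, M u reproduces them."""
        m, n = 40, 100
        g = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
        M, freqs, scale = gwas.center_genotypes(g)
        from reactnorm.kinship import vanraden_G

        G0, _, _ = vanraden_G(g)
        G = G0 + 1e-8 * np.eye(n)
        u_true = rng.normal(size=(m, 2))
        ghat = M @ u_true
        eff = gwas.backsolve_snp_effects(ghat[:, 0], ghat[:, 1], g, G, _map(m))
        back = M @ np.column_stack([eff.intercept, eff.slope])
        assert np.corrcoef(back[:, 0], ghat[:, 0])[0, 1] > 0.999
        assert np.corrcoef(back[:, 1], ghat[:, 1])[0, 1] > 0.999


class TestWindowScan:
    def _effects(self, m, slope=None, intercept=None, n_chrom=2):
        return gwas.SnpEffectSet(
            intercept=np.zeros(m) if intercept is None else intercept,
            slope=np.zeros(m) if slope is None else slope,
            snp_map=_map(m, n_chrom),
        )

    def test_single_active_window_carries_all_variance(self, rng, geno):
        m = 120
        inter = np.zeros(m)
        inter[30:35] = 2.0
        eff = self._effects(m, intercept=inter)
        M, _, _ = gwas.center_genotypes(geno)
        tot = float(np.var(M @ inter, ddof=1))
        scan = gwas.window_scan(eff, geno, {"intercept": tot, "slope": 1.0},
                                window=20, top_frac=0.05)
        t = scan.table
        covering = t[(t["first_snp"] <= 30) & (t["last_snp"] >= 34)]
        assert covering["pct_intercept"].max() == pytest.approx(100.0, rel=0.01)
        outside = t[(t["last_snp"] < 30) | (t["first_snp"] > 34)]
        assert outside["pct_intercept"].max() < 1.0

    def test_top_fraction_count_follows_snp_count(self, rng, geno):
        eff = self._effects(120, slope=rng.normal(size=120),
                            intercept=rng.normal(size=120))
        scan = gwas.window_scan(eff, geno, {"intercept": 5.0, "slope": 5.0},
                                window=20, top_frac=0.05)
        # 5% of 120 SNPs -> 6 flagged windows per term
        assert int(scan.table["top_intercept"].sum()) == 6
        assert int(scan.table["top_slope"].sum()) == 6

    def test_cluster_size_arithmetic_matches_snp_panel(self):
        # the fraction applies to the SNP count: 0.5% of 111,068 -> 555
        assert gwas._top_count(111_068, 0.005) == 555

    def test_windows_never_span_chromosomes(self, rng, geno):
        eff = self._effects(120, slope=rng.normal(size=120))
        scan = gwas.window_scan(eff, geno, {"intercept": 1.0, "slope": 1.0},
                                window=20)
        t = scan.table
        for c, sub in t.groupby("chrom"):
            assert sub["last_snp"].max() - sub["first_snp"].min() <= 59
        assert set(t["chrom"]) == {1, 2}

    def test_short_chromosome_skipped_with_warning(self, rng):
        g = rng.binomial(2, 0.4, size=(40, 30)).astype(float)
        snp_map = _map(30, n_chrom=1)
        snp_map.loc[snp_map.index[-5:], "chrom"] = 9  # 5-SNP chromosome
        eff = gwas.SnpEffectSet(np.zeros(30), rng.normal(size=30), snp_map)
        with pytest.warns(UserWarning, match="fewer than"):
            gwas.window_scan(eff, g, {"intercept": 1.0, "slope": 1.0}, window=20)

    def test_centering_invariance(self, rng, geno):
        """Window percentages are unchanged by adding a constant to codes."""
        eff = self._effects(120, slope=rng.normal(size=120),
                            intercept=rng.normal(size=120))
        s1 = gwas.window_scan(eff, geno, {"intercept": 2.0, "slope": 2.0})
        s2 = gwas.window_scan(eff, geno + 1.0, {"intercept": 2.0, "slope": 2.0})
        pd.testing.assert_series_equal(s1.table["pct_intercept"],
                                       s2.table["pct_intercept"])

    def test_unlinked_snps_partition_variance(self, rng):
        """Disjoint windows of independent SNPs sum close to the total."""
        n, m = 2000, 100
        g = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        u = rng.normal(size=m)
        M, _, _ = gwas.center_genotypes(g)
        tot = float(np.var(M @ u, ddof=1))
        eff = gwas.SnpEffectSet(u, np.zeros(m), _map(m, n_chrom=1))
        scan = gwas.window_scan(eff, g, {"intercept": tot, "slope": 1.0},
                                window=20)
        disjoint = scan.table.iloc[::20]["pct_intercept"].sum()
        assert disjoint == pytest.approx(100.0, rel=0.15)


class TestMergeRegions:
    def _scan_with_flags(self, flags, chrom=None):
        m = len(flags)
        t = pd.DataFrame({
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "first_snp": np.arange(m),
            "last_snp": np.arange(m) + 19,
            "start_bp": np.arange(m) * 1000,
            "end_bp": (np.arange(m) + 19) * 1000,
            "pct_intercept": np.linspace(1, 2, m),
            "top_intercept": flags,
        })
        return gwas.WindowScan(t, 20, 0.005, {})

    def test_overlapping_windows_merge(self):
        scan = self._scan_with_flags([True, True, False, False])
        out = gwas.merge_regions(scan, "intercept")
        assert len(out) == 1
        assert out["n_windows"].iloc[0] == 2

    def test_different_chromosomes_never_merge(self):
        scan = self._scan_with_flags([True, True], chrom=np.array([1, 2]))
        out = gwas.merge_regions(scan, "intercept")
        assert len(out) == 2

    def test_disjoint_flagged_windows_stay_separate(self):
        flags = [False] * 60
        flags[5] = flags[50] = True
        scan = self._scan_with_flags(flags)
        out = gwas.merge_regions(scan, "intercept")
        assert len(out) == 2


class TestClusters:
    def test_sizes_and_direction_low_favorable(self, rng):
        m = 1000
        slope = rng.normal(size=m)
        eff = gwas.SnpEffectSet(rng.normal(size=m), slope, _map(m))
        out = gwas.cluster_trajectories(eff, np.linspace(0, 1, 5),
                                        top_frac=0.005, favorable="low")
        c1 = out.assignments[out.assignments["cluster"] == "C1"]["snp_index"]
        c2 = out.assignments[out.assignments["cluster"] == "C2"]["snp_index"]
        c3 = out.assignments[out.assignments["cluster"] == "C3"]["snp_index"]
        assert len(c1) == len(c2) == len(c3) == 5
        # favorable "low": C1 holds the most negative slopes
        assert slope[c1].max() < slope[c2].min()
        assert np.abs(slope[c3]).max() <= np.partition(np.abs(slope), 5)[5]

    def test_direction_flips_for_high_favorable(self, rng):
        m = 400
        slope = rng.normal(size=m)
        eff = gwas.SnpEffectSet(np.zeros(m), slope, _map(m))
        low = gwas.cluster_trajectories(eff, [0, 1], top_frac=0.01, favorable="low")
        high = gwas.cluster_trajectories(eff, [0, 1], top_frac=0.01, favorable="high")
        c1_low = set(low.assignments.query("cluster == 'C1'")["snp_index"])
        c2_high = set(high.assignments.query("cluster == 'C2'")["snp_index"])
        assert c1_low == c2_high

    def test_constant_slopes_degenerate_but_c3_defined(self, rng):
        m = 200
        eff = gwas.SnpEffectSet(rng.normal(size=m), np.zeros(m), _map(m))
        out = gwas.cluster_trajectories(eff, [0, 0.5, 1], top_frac=0.01)
        assert out.degenerate
        assert (out.assignments["cluster"] == "C3").sum() == 2

    def test_c3_split_by_mean_effect_sign(self, rng):
        m = 500
        inter = rng.normal(size=m)
        eff = gwas.SnpEffectSet(inter, rng.normal(size=m) * 1e-3, _map(m))
        out = gwas.cluster_trajectories(eff, [0, 1], top_frac=0.02)
        c3 = out.assignments[out.assignments["cluster"] == "C3"]
        for _, row in c3.iterrows():
            mean_eff = eff.trajectory([0, 1])[row["snp_index"]].mean()
            expected = "C3_neg" if mean_eff < 0 else "C3_pos"
            assert row["subgroup"] == expected

    def test_boundary_ties_broken_by_map_order(self):
        m = 10
        slope = np.zeros(m)
        eff = gwas.SnpEffectSet(np.arange(m, dtype=float), slope, _map(m))
        out = gwas.cluster_trajectories(eff, [0, 1], top_frac=0.2)
        c1 = sorted(out.assignments.query("cluster == 'C1'")["snp_index"])
        assert c1 == [0, 1]  # first in map order among all-tied slopes


class TestAnnotationStub:
    def _intervals(self):
        return pd.DataFrame({
            "chrom": [1, 1, 2],
            "start": [1000, 5000, 1000],
            "end": [3000, 6000, 2000],
            "name": ["geneA", "geneB", "geneC"],
        })

    def test_half_open_interval_convention(self):
        snp_map = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": [1, 1, 1],
                                "bp": [1000, 2999, 3000]})
        hits = gwas.map_snps_to_intervals(snp_map, self._intervals())
        assert set(hits["snp"]) == {"a", "b"}  # end is exclusive, start inclusive

    def test_shared_counts_match_construction(self):
        snp_map = _map(20)
        clusters = {"AFC": [0, 1], "IFL": [0, 4], "CR": [4]}
        iv = pd.DataFrame({"chrom": [1], "start": [500], "end": [2500],
                           "name": ["g1"]})
        out = gwas.shared_features(clusters, snp_map, iv)
        both = out[(out["trait_a"] == "AFC") & (out["trait_b"] == "IFL")]
        assert both["n_shared"].iloc[0] == 1  # g1 via snp bp 1000/2000

    def test_missing_annotation_unavailable(self):
        with pytest.raises(ValueError, match="annotation"):
            gwas.shared_features({"AFC": [0]}, _map(10), None)

    def test_empty_overlap_zero(self):
        snp_map = _map(20)
        clusters = {"AFC": [10], "IFL": [11]}
        iv = self._intervals()
        out = gwas.shared_features(clusters, snp_map, iv)
        assert (out["n_shared"] == 0).all()
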