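import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repscan.io_core import GenomeLayout, RepscanError, ValidationError
from repscan import windowed_stats as ws


class TestDxySite:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.5, 0.5, 0.5),       # maximal heterozygosity
        (1.0, 0.0, 1.0),       # fixed difference
        (0.2, 0.7, 0.62),      # direct arithmetic
        (0.0, 0.0, 0.0),
    ])
    def test_formula(self, p1, p2, expected):
        assert ws.dxy_site(p1, p2) == pytest.approx(expected)

    @given(p1=st.floats(0, 1), p2=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, p1, p2):
        d = ws.dxy_site(p1, p2)
        assert d == pytest.approx(ws.dxy_site(p2, p1))
        assert -1e-12 <= d <= 1.0 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ws.dxy_site(1.2, 0.5)


class TestFstSite:
    def test_equal_frequencies_negative_numerator(self):
        # p1=p2=0.5, n=20: numerator = -2 * 0.25/19
        num, den = ws.fst_site(10, 20, 10, 20)
        assert num == pytest.approx(-2 * 0.25 / 19)
        assert den == pytest.approx(0.5)

    def test_fixed_difference_is_one(self):
        num, den = ws.fst_site(20, 20, 0, 20)
        assert (num, den) == (1.0, 1.0)

    def test_shared_monomorphic_site_contributes_nothing(self):
        num, den = ws.fst_site(0, 20, 0, 20)
        assert num <= 0
        assert den == 0.0

    def test_small_samples_masked(self):
        num, den = ws.fst_site(1, 1, 0, 20)
        assert np.isnan(num) and np.isnan(den)


def _sites_df(chrom, pos, ac1, n1, ac2, n2):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ac1": ac1, "n1": n1,
                         "ac2": ac2, "n2": n2})


class TestWindowFst:
    def test_fixed_differences_give_one(self, small_layout):
        df = _sites_df("chr1", [10, 20, 150_000], [20, 20, 20], 20, [0, 0, 0], 20)
        out = ws.window_fst(df, small_layout).set_index(["chrom", "start"])
        assert out.loc[("chr1", 0), "fst"] == pytest.approx(1.0)
        assert out.loc[("chr1", 100_000), "fst"] == pytest.approx(1.0)

    def test_identical_frequencies_give_nonpositive(self, small_layout):
        df = _sites_df("chr1", [10, 20, 30], [10, 5, 15], 20, [10, 5, 15], 20)
        out = ws.window_fst(df, small_layout).set_index(["chrom", "start"])
        assert out.loc[("chr1", 0), "fst"] <= 0

    def test_clamping_option(self, small_layout):
        df = _sites_df("chr1", [10], [10], 20, [10], 20)
        out = ws.window_fst(df, small_layout, clamp_negative=True)
        assert out["fst"].dropna().min() >= 0

    def test_matches_per_site_brute_force(self, small_layout, rng):
        """Vectorized window F_ST equals an explicit per-site loop."""
        n = 80
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), n, replace=False))
        df = _sites_df("chr1", pos, rng.integers(0, 21, n), 20,
                       rng.integers(0, 31, n), 30)
        out = ws.window_fst(df, small_layout).set_index(["chrom", "start"])
        # independent oracle: plain python accumulation
        sums = {}
        for _, row in df.iterrows():
            p1, p2 = row.ac1 / row.n1, row.ac2 / row.n2
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / 19 - p2 * (1 - p2) / 29
            den = p1 * (1 - p2) + p2 * (1 - p1)
            w = ((row.pos - 1) // 100_000) * 100_000
            a, b = sums.get(w, (0.0, 0.0))
            sums[w] = (a + num, b + den)
        for w, (a, b) in sums.items():
            if b != 0:
                assert out.loc[("chr1", w), "fst"] == pytest.approx(a / b)

    def test_balding_nichols_recovery_small(self):
        """Hudson ratio-of-averages is nearly unbiased for the planted F."""
        from repscan.synthetic_data import SimConfig, simulate_site_counts
        layout = GenomeLayout((("chr1", 2_000_000),), 100_000)
        cfg = SimConfig(seed=7, snps_per_window=200, n_alleles=50)
        targets = pd.Series(0.1, index=layout.window_index())
        sites, _ = simulate_site_counts(targets, layout, cfg)
        out = ws.window_fst(sites, layout)
        assert out["fst"].mean() == pytest.approx(0.1, abs=0.02)


class TestCallableSites:
    def test_depth_filter_bounds(self):
        layout = GenomeLayout((("chr1", 100_000),), 100_000)
        # mean depth is 30 by construction: thresholds are [30, 90]
        depth = pd.DataFrame({
            "chrom": "chr1",
            "pos": [1, 2, 3, 4, 5],
            "depth": [29, 91, 30, 90, -90],  # -90 keeps mean at 30
        })
        counts = ws.callable_sites(depth, sample_size=10, layout=layout)
        # 29 < 3*10 excluded; 91 > 3*30 excluded; -90 excluded; 30 and 90 kept
        assert counts.loc[("chr1", 0)] == 2

    def test_uniform_depth_full_window(self):
        layout = GenomeLayout((("chr1", 1000),), 1000)
        depth = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 1001),
                              "depth": 40})
        counts = ws.callable_sites(depth, sample_size=10, layout=layout)
        assert counts.loc[("chr1", 0)] == 1000

    def test_empty_table_rejected(self, small_layout):
        with pytest.raises(RepscanError):
            ws.callable_sites(pd.DataFrame(columns=["chrom", "pos", "depth"]),
                              10, small_layout)


class TestWindowDxy:
    def _profile(self, layout, count):
        return pd.Series(count, index=layout.window_index())

    def test_sum_over_callable(self, small_layout):
        df = _sites_df("chr1", [10, 20], [20, 20], 20, [0, 0], 20)  # dxy=1 each
        prof = self._profile(small_layout, 10_000)
        out = ws.window_dxy(df, prof, small_layout).set_index(["chrom", "start"])
        assert out.loc[("chr1", 0), "dxy"] == pytest.approx(2e-4)

    def test_no_snps_is_zero_not_missing(self, small_layout):
        out = ws.window_dxy(_sites_df("chr1", [], [], [], [], []),
                            self._profile(small_layout, 10_000), small_layout)
        assert (out["dxy"] == 0).all()

    def test_low_callable_window_missing(self, small_layout):
        df = _sites_df("chr1", [10], [20], 20, [0], 20)
        out = ws.window_dxy(df, self._profile(small_layout, 4000),
                            small_layout).set_index(["chrom", "start"])
        assert np.isnan(out.loc[("chr1", 0), "dxy"])

    def test_snp_in_uncallable_window_is_inconsistency(self, small_layout):
        df = _sites_df("chr1", [10], [20], 20, [0], 20)
        with pytest.raises(RepscanError):
            ws.window_dxy(df, self._profile(small_layout, 0), small_layout)

    def test_matches_haplotype_enumeration_oracle(self, rng):
        """Window d_XY equals mean pairwise between-population difference
        per callable site computed by direct haplotype enumeration."""
        layout = GenomeLayout((("chr1", 100),), 100)
        n1, n2, S = 6, 4, 100
        h1 = rng.integers(0, 2, size=(n1, S))
        h2 = rng.integers(0, 2, size=(n2, S))
        ac1, ac2 = h1.sum(axis=0), h2.sum(axis=0)
        df = _sites_df("chr1", np.arange(1, S + 1), ac1, n1, ac2, n2)
        prof = pd.Series(S, index=layout.window_index())
        out = ws.window_dxy(df, prof, layout, min_sites=0)
        # oracle: enumerate all cross-population haplotype pairs
        total = sum(np.sum(a != b) for a in h1 for b in h2)
        oracle = total / (n1 * n2) / S
        assert out["dxy"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_split_recombine_invariance(self, small_layout, rng):
        """Window d_XY is invariant to splitting the SNP list and recombining."""
        n = 40
        pos = np.sort(rng.choice(np.arange(1, 100_001), n, replace=False))
        df = _sites_df("chr1", pos, rng.integers(0, 21, n), 20,
                       rng.integers(0, 21, n), 20)
        prof = pd.Series(10_000, index=small_layout.window_index())
        full = ws.window_dxy(df, prof, small_layout)
        a = ws.window_dxy(df.iloc[:17], prof, small_layout)
        b = ws.window_dxy(df.iloc[17:], prof, small_layout)
        combined = a["dxy"] + b["dxy"]
        pd.testing.assert_series_equal(full["dxy"], combined, check_names=False)


class TestWindowLd:
    def test_midpoint_assignment(self, small_layout):
        pairs = pd.DataFrame({"chrom": ["chr1"], "pos1": [10_000],
                              "pos2": [30_000], "r2": [0.5]})
        out = ws.window_ld(pairs, small_layout)
        assert out.loc[("chr1", 0)] == pytest.approx(0.5)

    def test_distant_pairs_excluded(self, small_layout):
        pairs = pd.DataFrame({"chrom": ["chr1"], "pos1": [10_000],
                              "pos2": [130_001], "r2": [0.5]})
        out = ws.window_ld(pairs, small_layout)
        assert out.isna().all()

    def test_window_mean(self, small_layout):
        pairs = pd.DataFrame({"chrom": "chr1", "pos1": [10_000, 20_000],
                              "pos2": [30_000, 40_000], "r2": [0.1, 0.3]})
        out = ws.window_ld(pairs, small_layout)
        assert out.loc[("chr1", 0)] == pytest.approx(0.2)


class TestHarmonize:
    def _table(self, layout, stat, missing_starts=()):
        win = layout.windows()
        win[stat] = 0.5
        key = list(zip(win["chrom"], win["start"]))
        win.loc[[k in set(missing_starts) for k in key], stat] = np.nan
        return win

    def test_intersection_of_nonmissing(self, small_layout):
        a = self._table(small_layout, "fst", [("chr1", 0)])
        b = self._table(small_layout, "fst", [("chr2", 0)])
        common, kept = ws.harmonize({"a": a, "b": b}, "fst")
        assert ("chr1", 0) not in common and ("chr2", 0) not in common
        assert len(common) == len(small_layout.window_index()) - 2
        assert kept == ["a", "b"]

    def test_all_missing_pair_dropped_with_warning(self, small_layout):
        a = self._table(small_layout, "dxy")
        b = self._table(small_layout, "dxy")
        c = self._table(small_layout, "dxy")
        c["dxy"] = np.nan  # reduced-representation pair without d_XY
        with pytest.warns(UserWarning, match="dropped"):
            common, kept = ws.harmonize({"a": a, "b": b, "c": c}, "dxy")
        assert kept == ["a", "b"]
        assert len(common) == len(small_layout.window_index())

    def test_disjoint_layouts_rejected(self, small_layout):
        a = self._table(small_layout, "fst")
        other = GenomeLayout((("chrX", 200_000),))
        b = self._table(other, "fst")
        with pytest.raises(RepscanError, match="disjoint"):
            ws.harmonize({"a": a, "b": b}, "fst")
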