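import math

import numpy as np
import pandas as pd
import pytest

from methylout.cohort_statistics import (
    annotate_tiles,
    dhs_enrichment,
    observed_sharing,
    permutation_enrichment,
    select_background_tiles,
    sharing_summary_from_counts,
    tile_sample_zscores,
)


def _ped(families):
    rows = [(f, s, "0", "0", 1, 2) for f, ss in families.items() for s in ss]
    return pd.DataFrame(rows, columns=["family_id", "sample_id", "father_id",
                                       "mother_id", "sex", "phenotype"])


def _calls(rows):
    """rows: (sample, chrom, tile_start)"""
    return pd.DataFrame([{"sample_id": s, "phasing_mode": "hap1", "chrom": c,
                          "tile_start": t, "mean_z": 4.0} for s, c, t in rows])


class TestObservedSharing:
    def test_trio_sharing_counts_both_carriers(self):
        ped = _ped({"f1": ["child", "father", "mother"], "f2": ["solo"]})
        calls = _calls([("child", "chr1", 1000), ("father", "chr1", 1000)])
        n_obs, n_shared = observed_sharing(calls, ped)
        assert (n_obs, n_shared) == (2, 2)

    def test_unshared_call_counted_not_shared(self):
        ped = _ped({"f1": ["child", "father"]})
        calls = _calls([("child", "chr1", 1000)])
        assert observed_sharing(calls, ped) == (1, 0)

    def test_singleton_cohort_undefined(self):
        ped = _ped({"f1": ["a"], "f2": ["b"]})
        calls = _calls([("a", "chr1", 1000)])
        assert observed_sharing(calls, ped) == (None, None)

    def test_phasing_modes_collapse_to_one_observation(self):
        ped = _ped({"f1": ["child", "father"]})
        calls = pd.concat([_calls([("child", "chr1", 1000)])] * 2)
        calls["phasing_mode"] = ["hap1", "hap2"]
        assert observed_sharing(calls, ped) == (1, 0)


class TestPermutationEnrichment:
    def test_printed_count_summary(self):
        out = sharing_summary_from_counts(290, 2465, perm_mean=94.2)
        assert out["percent_shared"] == pytest.approx(11.8)
        assert out["fold"] == pytest.approx(3.079)

    def test_two_samples_one_family_degenerate(self):
        ped = _ped({"f1": ["a", "b"]})
        calls = _calls([("a", "chr1", 1000), ("b", "chr1", 1000)])
        s = permutation_enrichment(calls, ped, n_perm=50, seed=0)
        assert s.fold == pytest.approx(1.0)
        assert s.p_perm == pytest.approx(1.0)

    def test_seed_reproducible(self):
        ped = _ped({f"f{i}": [f"a{i}", f"b{i}"] for i in range(6)})
        rows = [(f"a{i}", "chr1", 200 * j) for i in range(6) for j in range(3)]
        rows += [(f"b{i}", "chr1", 0) for i in range(3)]
        calls = _calls(rows)
        s1 = permutation_enrichment(calls, ped, n_perm=200, seed=42)
        s2 = permutation_enrichment(calls, ped, n_perm=200, seed=42)
        assert s1.perm_distribution == s2.perm_distribution
        assert s1.p_perm == s2.p_perm

    def test_planted_heritability_detected(self, study_bundle, study_result):
        """Events copied to a parent yield significant familial sharing."""
        s = study_result.sharing
        assert s is not None
        assert s.n_shared > 0
        assert s.fold > 1.5
        assert s.p_perm < 0.05

    def test_fold_near_one_without_familial_correlation(self):
        # calls assigned to random samples across many 2-person families
        rng = np.random.default_rng(3)
        ped = _ped({f"f{i}": [f"a{i}", f"b{i}"] for i in range(15)})
        samples = ped["sample_id"].tolist()
        folds = []
        for rep in range(20):
            rows = [(samples[i], "chr1", 200 * int(rng.integers(40)))
                    for i in rng.integers(0, len(samples), size=25)]
            calls = _calls(rows).drop_duplicates(["sample_id", "tile_start"])
            s = permutation_enrichment(calls, ped, n_perm=60, seed=rep)
            if s.perm_mean > 0:
                folds.append(s.fold)
        assert abs(np.mean(folds) - 1.0) < 0.5


class TestBackgroundTiles:
    def _tile_stats(self, rows):
        """rows: (sample, tile_start, mean_z)"""
        return pd.DataFrame([{"sample_id": s, "chrom": "chr1",
                              "tile_start": t, "mean_z": z, "n_cpgs": 3}
                             for s, t, z in rows])

    def test_min_samples_excludes_sparse_tile(self):
        stats = self._tile_stats([(f"s{i}", 1000, 0.1) for i in range(4)]
                                 + [(f"s{i}", 2000, 0.1) for i in range(5)])
        out = select_background_tiles(stats, min_samples=5, n_select=10)
        assert out["tile_start"].tolist() == [2000]

    def test_z_band_rule(self):
        zs = [0.5, -0.3, 0.9, 0.1, -0.8]
        stats = self._tile_stats([(f"s{i}", 1000, z) for i, z in enumerate(zs)])
        out = select_background_tiles(stats, min_samples=5, n_select=10)
        assert out["tile_start"].tolist() == [1000]

    def test_pool_smaller_than_request_warns(self):
        stats = self._tile_stats([(f"s{i}", 1000, 0.0) for i in range(5)])
        with pytest.warns(UserWarning):
            out = select_background_tiles(stats, min_samples=5, n_select=100)
        assert len(out) == 1

    def test_seeded_and_duplicate_free(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", 200 * t, float(rng.normal(0, 0.3)))
                for t in range(50) for i in range(6)]
        stats = self._tile_stats(rows)
        a = select_background_tiles(stats, n_select=10, seed=5)
        b = select_background_tiles(stats, n_select=10, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(["chrom", "tile_start"]).any()


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


class TestDhsEnrichment:
    def _tiles(self, starts):
        return pd.DataFrame({"chrom": "chr1", "tile_start": starts})

    def _elements(self, intervals, component="lymphoid"):
        return pd.DataFrame([{"chrom": "chr1", "start": a, "end": b,
                              "component": component} for a, b in intervals])

    def test_counts_fold_and_exact_p(self):
        # 47/50 outliers overlap, 20/50 background
        out_tiles = self._tiles([200 * i for i in range(50)])
        bg_tiles = self._tiles([200 * i for i in range(100, 150)])
        elements = self._elements(
            [(200 * i, 200 * i + 50) for i in range(47)]
            + [(200 * i, 200 * i + 50) for i in range(100, 120)])
        res = dhs_enrichment(out_tiles, bg_tiles, elements)
        row = res[res["component"] == "any"].iloc[0]
        assert (row["n_outlier_overlap"], row["n_background_overlap"]) == (47, 20)
        assert row["fold"] == pytest.approx(2.35)
        assert row["p"] == pytest.approx(fisher_oracle(47, 3, 20, 30), rel=1e-6)

    def test_identical_sets_fold_one_p_one(self):
        tiles = self._tiles([200 * i for i in range(20)])
        elements = self._elements([(0, 2000)])
        res = dhs_enrichment(tiles, tiles, elements)
        row = res[res["component"] == "any"].iloc[0]
        assert row["fold"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_published_fractions_give_twofold(self):
        # 94% vs 41% overlap fractions at n=100 each
        out_tiles = self._tiles([200 * i for i in range(100)])
        bg_tiles = self._tiles([200 * i for i in range(200, 300)])
        elements = self._elements(
            [(200 * i, 200 * i + 50) for i in range(94)]
            + [(200 * i, 200 * i + 50) for i in range(200, 241)])
        res = dhs_enrichment(out_tiles, bg_tiles, elements)
        row = res[res["component"] == "any"].iloc[0]
        assert row["fold"] == pytest.approx(94 / 41, rel=1e-6)
        assert 2.0 < row["fold"] < 2.5

    @pytest.mark.parametrize("table", [
        (5, 5, 2, 8), (1, 9, 9, 1), (10, 20, 15, 15), (0, 10, 5, 5),
    ])
    def test_fisher_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        out_tiles = self._tiles([200 * i for i in range(a + b)])
        bg_tiles = self._tiles([200 * i for i in range(1000, 1000 + c + d)])
        elements = self._elements(
            [(200 * i, 200 * i + 10) for i in range(a)]
            + [(200 * i, 200 * i + 10) for i in range(1000, 1000 + c)])
        res = dhs_enrichment(out_tiles, bg_tiles, elements)
        row = res[res["component"] == "any"].iloc[0]
        assert row["p"] == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)

    def test_zero_background_overlap_fold_undefined(self):
        out_tiles = self._tiles([0])
        bg_tiles = self._tiles([10000])
        elements = self._elements([(0, 100)])
        row = dhs_enrichment(out_tiles, bg_tiles, elements).iloc[0]
        assert math.isnan(row["fold"])
        assert not math.isnan(row["p"])


class TestAnnotateTiles:
    def _tss(self, positions):
        return pd.DataFrame([{"chrom": "chr1", "start": p, "end": p + 1,
                              "name": f"G{i}"} for i, p in enumerate(positions)])

    def test_promoter_flag_within_window(self):
        tiles = pd.DataFrame({"chrom": ["chr1"], "tile_start": [1000]})
        # TSS 300 bp downstream of the tile end
        out = annotate_tiles(tiles, self._tss([1500]), promoter_window=1000)
        assert bool(out["promoter"].iloc[0])
        assert out["tss_distance"].iloc[0] == pytest.approx(301)

    def test_window_edge_is_closed(self):
        tiles = pd.DataFrame({"chrom": ["chr1"], "tile_start": [1000]})
        out = annotate_tiles(tiles, self._tss([2199]), promoter_window=1000)
        assert bool(out["promoter"].iloc[0])  # tile end-1 = 1199 = tss - 1000
        out2 = annotate_tiles(tiles, self._tss([2200]), promoter_window=1000)
        assert not bool(out2["promoter"].iloc[0])

    def test_signed_distance_upstream_negative(self):
        tiles = pd.DataFrame({"chrom": ["chr1"], "tile_start": [1000]})
        out = annotate_tiles(tiles, self._tss([400, 5000]))
        assert out["tss_distance"].iloc[0] == pytest.approx(-600)
        assert out["nearest_tss"].iloc[0] == "G0"

    def test_chromosome_without_genes_undefined(self):
        tiles = pd.DataFrame({"chrom": ["chr2"], "tile_start": [1000]})
        out = annotate_tiles(tiles, self._tss([400]))
        assert math.isnan(out["tss_distance"].iloc[0])


class TestTileSampleZscores:
    def test_min_cpg_presence_rule(self):
        z = pd.DataFrame({
            "sample_id": ["s1", "s1", "s2"], "phasing_mode": "combined",
            "chrom": "chr1", "pos": [1010, 1050, 1010], "coverage": 30,
            "meth_fraction": 0.1, "z": [0.5, -0.5, 1.0]})
        out = tile_sample_zscores(z)
        assert len(out) == 1  # s2 has a single CpG in the tile
        assert out["mean_z"].iloc[0] == pytest.approx(0.0)
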