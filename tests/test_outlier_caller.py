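import numpy as np
import pandas as pd
import pytest

from methylout.methylation_io import MethylationTable
from methylout.outlier_caller import (
    CallerConfig,
    assess_allele_specificity,
    call_tiles,
    classify_extent,
    classify_rarity,
    flag_cpgs,
)


def _ztable(rows):
    """rows: (sample, mode, chrom, pos, frac, z)"""
    return pd.DataFrame(rows, columns=["sample_id", "phasing_mode", "chrom",
                                       "pos", "meth_fraction", "z"]).assign(
        coverage=30)


def _stats(rows):
    """rows: (chrom, pos, sd, q95, q5)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "sd", "q95", "q5"])
    df["mean"] = (df["q95"] + df["q5"]) / 2
    df["n_samples"] = 10
    return df


def _ped(families):
    """families: {family_id: [sample_ids]}"""
    rows = [(f, s, "0", "0", 1, 2) for f, ss in families.items() for s in ss]
    return pd.DataFrame(rows, columns=["family_id", "sample_id", "father_id",
                                       "mother_id", "sex", "phenotype"])


class TestFlagCpgs:
    def test_hyper_when_exceeding_q95_plus_3sd(self):
        z = _ztable([("s1", "combined", "chr1", 100, 0.80, 3.5)])
        flags = flag_cpgs(z, _stats([("chr1", 100, 0.05, 0.6, 0.2)]))
        assert flags["status"].iloc[0] == "hyper"  # 0.80 > 0.6 + 0.15

    def test_hypo_when_below_q5_minus_3sd(self):
        z = _ztable([("s1", "combined", "chr1", 100, 0.04, -3.5)])
        flags = flag_cpgs(z, _stats([("chr1", 100, 0.05, 0.6, 0.2)]))
        assert flags["status"].iloc[0] == "hypo"  # 0.04 < 0.2 - 0.15

    def test_boundary_is_strict(self):
        z = _ztable([("s1", "combined", "chr1", 100, 0.75, 3.0)])
        flags = flag_cpgs(z, _stats([("chr1", 100, 0.05, 0.6, 0.2)]))
        assert flags["status"].iloc[0] == "normal"  # exactly q95 + 3*sd

    def test_raising_multiplier_never_adds_flags(self):
        rng = np.random.default_rng(5)
        rows = [("s1", "combined", "chr1", 100 + 2 * i, rng.uniform(), 0.0)
                for i in range(200)]
        stats = _stats([("chr1", 100 + 2 * i, 0.05, 0.6, 0.2)
                        for i in range(200)])
        f3 = flag_cpgs(_ztable(rows), stats, sd_multiplier=3)
        f4 = flag_cpgs(_ztable(rows), stats, sd_multiplier=4)
        hyper3 = set(f3[f3["status"] == "hyper"]["pos"])
        hyper4 = set(f4[f4["status"] == "hyper"]["pos"])
        assert hyper4 <= hyper3


class TestCallTiles:
    def _flags(self, statuses, zs=None, sample="s1", mode="hap1"):
        zs = zs or [3.0] * len(statuses)
        df = _ztable([(sample, mode, "chr1", 1000 + 2 * i, 0.8, z)
                      for i, z in enumerate(zs)])
        df["status"] = statuses
        return df

    def test_two_hyper_no_hypo_is_candidate(self):
        cand = call_tiles(self._flags(["hyper", "hyper", "normal"]))
        assert len(cand) == 1
        assert cand["tile_start"].iloc[0] == 1000

    def test_hypo_vetoes_tile(self):
        cand = call_tiles(self._flags(["hyper", "hyper", "hyper", "hypo"]))
        assert len(cand) == 0

    def test_single_hyper_not_candidate(self):
        cand = call_tiles(self._flags(["hyper", "normal"]))
        assert len(cand) == 0

    def test_mean_z_uses_all_covered_cpgs(self):
        cand = call_tiles(self._flags(["hyper", "hyper", "normal"],
                                      zs=[6.0, 6.0, 0.0]))
        assert cand["mean_z"].iloc[0] == pytest.approx(4.0)

    def test_sex_chromosomes_excluded(self):
        df = self._flags(["hyper", "hyper"])
        df["chrom"] = "chrX"
        assert len(call_tiles(df)) == 0


class TestClassifyRarity:
    def _cand(self, carriers):
        """carriers: [(sample, mean_z)] all at the same tile."""
        return pd.DataFrame([
            {"sample_id": s, "phasing_mode": "hap1", "chrom": "chr1",
             "tile_start": 1000, "n_hyper": 2, "n_hypo": 0, "n_cpgs": 3,
             "mean_z": z} for s, z in carriers])

    def test_two_unrelated_carriers_path_a(self):
        ped = _ped({"f1": ["s1"], "f2": ["s2"]})
        out = classify_rarity(self._cand([("s1", 2.5), ("s2", 2.2)]), ped)
        assert len(out) == 2
        assert set(out["rarity_path"]) == {"A"}

    def test_path_a_mean_z_floor(self):
        ped = _ped({"f1": ["s1"], "f2": ["s2"]})
        out = classify_rarity(self._cand([("s1", 2.5), ("s2", 1.5)]), ped)
        assert out["sample_id"].tolist() == ["s1"]

    def test_path_b_separated_top_carrier_kept(self):
        ped = _ped({"f1": ["s1"], "f2": ["s2"], "f3": ["s3"]})
        out = classify_rarity(
            self._cand([("s1", 6.2), ("s2", 2.8), ("s3", 1.1)]), ped)
        assert out["sample_id"].tolist() == ["s1"]
        assert set(out["rarity_path"]) == {"B"}

    def test_path_b_no_separation_reports_none(self):
        ped = _ped({"f1": ["s1"], "f2": ["s2"], "f3": ["s3"]})
        out = classify_rarity(
            self._cand([("s1", 5.5), ("s2", 5.4), ("s3", 5.2)]), ped)
        assert len(out) == 0

    def test_path_b_two_separated_carriers_kept(self):
        ped = _ped({"f1": ["s1"], "f2": ["s2"], "f3": ["s3"]})
        out = classify_rarity(
            self._cand([("s1", 9.0), ("s2", 8.0), ("s3", 1.0)]), ped)
        assert sorted(out["sample_id"]) == ["s1", "s2"]

    def test_family_counts_once(self):
        # two carriers in one family + one unrelated = 2 families -> path A
        ped = _ped({"f1": ["s1", "s2"], "f2": ["s3"]})
        out = classify_rarity(
            self._cand([("s1", 2.5), ("s2", 2.4), ("s3", 2.2)]), ped)
        assert set(out["rarity_path"]) == {"A"}
        assert len(out) == 3

    def test_missing_sample_is_singleton_family(self):
        ped = _ped({"f1": ["s1"]})
        with pytest.warns(UserWarning):
            out = classify_rarity(self._cand([("s1", 2.5), ("s9", 2.4)]), ped)
        assert len(out) == 2

    def test_paths_are_disjoint_per_tile(self, study_result):
        calls = study_result.calls
        by_tile = calls.groupby(["chrom", "tile_start"])["rarity_path"].nunique()
        assert (by_tile == 1).all()

    def test_reported_calls_satisfy_path_z_bounds(self, study_result):
        calls = study_result.calls
        a = calls[calls["rarity_path"] == "A"]
        b = calls[calls["rarity_path"] == "B"]
        assert (a["mean_z"] > 2).all()
        assert (b["mean_z"] > 5).all()


class TestAlleleSpecificity:
    def _setup(self, hap1_cand=True, hap2_cand=False, other_cov=30):
        call = pd.DataFrame([{"sample_id": "s1", "phasing_mode": "hap1",
                              "chrom": "chr1", "tile_start": 1000,
                              "n_hyper": 2, "n_hypo": 0, "mean_z": 4.0,
                              "rarity_path": "A"}])
        cand_rows = []
        for mode, is_c in (("hap1", hap1_cand), ("hap2", hap2_cand)):
            if is_c:
                cand_rows.append({"sample_id": "s1", "phasing_mode": mode,
                                  "chrom": "chr1", "tile_start": 1000})
        cands = pd.DataFrame(cand_rows, columns=["sample_id", "phasing_mode",
                                                 "chrom", "tile_start"])
        tables = {"s1": {m: MethylationTable("s1", m, pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [1010, 1050, 1090],
            "coverage": [other_cov] * 3, "meth_fraction": [0.1] * 3}))
            for m in ("hap1", "hap2")}}
        return call, cands, tables

    def test_one_haplotype_with_covered_other_is_allele_specific(self):
        call, cands, tables = self._setup()
        out = assess_allele_specificity(call, cands, tables)
        assert out["allele_specificity"].iloc[0] == "allele_specific"

    def test_both_haplotypes_candidate_is_biallelic(self):
        call, cands, tables = self._setup(hap2_cand=True)
        out = assess_allele_specificity(call, cands, tables)
        assert out["allele_specificity"].iloc[0] == "biallelic"

    def test_undercovered_other_haplotype_is_undetermined(self):
        call, cands, tables = self._setup(other_cov=5)
        out = assess_allele_specificity(call, cands, tables)
        assert out["allele_specificity"].iloc[0] == "undetermined"


class TestClassifyExtent:
    def _calls(self, tile_starts, sample="s1"):
        return pd.DataFrame([{"sample_id": sample, "phasing_mode": "hap1",
                              "chrom": "chr1", "tile_start": t,
                              "mean_z": 4.0} for t in tile_starts])

    def test_isolated_tile_regular(self):
        out = classify_extent(self._calls([1000]))
        assert out["extent"].iloc[0] == "regular"

    def test_two_adjacent_tiles_regular(self):
        out = classify_extent(self._calls([1000, 1200]))
        assert set(out["extent"]) == {"regular"}

    def test_three_adjacent_tiles_all_large(self):
        out = classify_extent(self._calls([1000, 1200, 1400]))
        assert set(out["extent"]) == {"large"}

    def test_gap_splits_runs(self):
        out = classify_extent(self._calls([1000, 1200, 1600]))
        assert out.set_index("tile_start")["extent"].to_dict() == {
            1000: "regular", 1200: "regular", 1600: "regular"}

    def test_flag_flips_two_tile_boundary(self):
        out = classify_extent(self._calls([1000, 1200]), two_tiles_large=True)
        assert set(out["extent"]) == {"large"}
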