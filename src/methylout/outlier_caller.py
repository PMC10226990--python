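"""Hypermethylation-outlier calling on a fixed 200 bp autosomal tile grid.

The calling cascade:

1. ``flag_cpgs`` — a CpG is *hyper* for a sample/mode when its methylation
   fraction exceeds the population Q95 by more than 3 population SDs, *hypo*
   when it falls below Q5 by more than 3 SDs (strict inequalities).
2. ``call_tiles`` — CpGs are grouped into fixed tiles [200k, 200(k+1)); a
   tile is a candidate for a sample/mode when it holds >= 2 hyper CpGs and no
   hypo CpG.  The tile's mean_z averages the z-scores of *all* covered CpGs
   in the tile, not only the flagged ones.
3. ``classify_rarity`` — candidates are pooled across the cohort and kept by
   one of two rarity paths.  Path A: the tile is carried by at most 2
   unrelated families (any phasing mode); carriers with mean_z > 2 are
   reported.  Path B: 3+ families carry the tile; unrelated carriers are
   ranked by mean_z and at most 2 with mean_z > 5 are kept, provided the
   lowest kept carrier exceeds the highest dropped one by >= 3 z-units.
4. ``assess_allele_specificity`` and ``classify_extent`` annotate each call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROMS = {"chrX", "chrY", "chrM", "X", "Y", "M", "MT"}

TILE_WIDTH = 200


@dataclass
class CallerConfig:
    """Thresholds of the calling cascade, defaulting to the published values."""

    sd_multiplier: float = 3.0      # hyper/hypo exceedance over Q95/Q5 in SD units
    tile_width: int = TILE_WIDTH    # bp
    min_hyper: int = 2              # hyper CpGs per candidate tile
    path_a_z: float = 2.0           # mean_z floor, rare-tile path
    path_b_z: float = 5.0           # mean_z floor, dynamic-tile path
    path_b_separation: float = 3.0  # z-units between kept and dropped carriers
    max_unrelated_carriers: int = 2 # family count cutoff between the paths
    min_coverage: int = 10          # per-mode coverage floor (set upstream)
    large_min_run: int = 3          # adjacent tiles making a "large" event
    autosomes_only: bool = True


def flag_cpgs(z_table: pd.DataFrame, stats: pd.DataFrame,
              sd_multiplier: float = 3.0) -> pd.DataFrame:
    """Assign hyper/hypo/normal status to every z-scored CpG record.

    hyper: meth_fraction > q95 + m*sd;  hypo: meth_fraction < q5 - m*sd
    (both strict).  Returns the z-table with a ``status`` column.
    """
    merged = z_table.merge(stats[["chrom", "pos", "sd", "q95", "q5"]],
                           on=["chrom", "pos"], how="left")
    frac = merged["meth_fraction"]
    status = np.where(
        frac > merged["q95"] + sd_multiplier * merged["sd"], "hyper",
        np.where(frac < merged["q5"] - sd_multiplier * merged["sd"], "hypo",
                 "normal"),
    )
    out = z_table.copy()
    out["status"] = status
    return out


def call_tiles(flags: pd.DataFrame, config: CallerConfig | None = None) -> pd.DataFrame:
    """Aggregate flagged CpGs into candidate hyper-mCpG tiles.

    Parameters
    ----------
    flags
        Output of :func:`flag_cpgs` (one row per sample/mode/CpG with z and
        status).
    Returns
    -------
    One row per (sample_id, phasing_mode, chrom, tile_start) candidate with
    n_hyper >= min_hyper and n_hypo == 0; columns include mean_z over all
    covered tile CpGs and n_cpgs.
    """
    config = config or CallerConfig()
    df = flags
    if config.autosomes_only:
        df = df[~df["chrom"].isin(SEX_CHROMS)]
    if df.empty:
        return pd.DataFrame(columns=["sample_id", "phasing_mode", "chrom",
                                     "tile_start", "n_hyper", "n_hypo",
                                     "n_cpgs", "mean_z"])
    df = df.copy()
    df["tile_start"] = (df["pos"] // config.tile_width) * config.tile_width
    df["is_hyper"] = (df["status"] == "hyper").astype(np.int64)
    df["is_hypo"] = (df["status"] == "hypo").astype(np.int64)
    grp = df.groupby(["sample_id", "phasing_mode", "chrom", "tile_start"],
                     sort=True, observed=True)
    agg = grp.agg(
        n_hyper=("is_hyper", "sum"),
        n_hypo=("is_hypo", "sum"),
        n_cpgs=("status", "size"),
        mean_z=("z", "mean"),
    ).reset_index()
    cand = agg[(agg["n_hyper"] >= config.min_hyper) & (agg["n_hypo"] == 0)]
    return cand.reset_index(drop=True)


def _family_map(pedigree: pd.DataFrame) -> dict[str, str]:
    return dict(zip(pedigree["sample_id"].astype(str),
                    pedigree["family_id"].astype(str)))


def classify_rarity(candidates: pd.DataFrame, pedigree: pd.DataFrame,
                    config: CallerConfig | None = None) -> pd.DataFrame:
    """Apply the two rarity paths across the pooled cohort candidates.

    Carriers are counted as distinct *families*: multiple carriers within a
    family, or several phasing modes of one sample, count once toward the
    rarity cutoffs.  Samples missing from the pedigree are treated as their
    own singleton family (with a warning).

    Returns the kept candidate rows with a ``rarity_path`` column ('A'/'B').
    """
    config = config or CallerConfig()
    if candidates.empty:
        out = candidates.copy()
        out["rarity_path"] = pd.Series(dtype=str)
        return out
    fam = _family_map(pedigree)
    missing = sorted(set(candidates["sample_id"].astype(str)) - set(fam))
    if missing:
        warnings.warn(f"samples absent from pedigree treated as singleton "
                      f"families: {missing}")
    df = candidates.copy()
    df["family_id"] = df["sample_id"].astype(str).map(lambda s: fam.get(s, f"_solo_{s}"))

    kept_chunks = []
    for (_chrom, _tile), tile_df in df.groupby(["chrom", "tile_start"], sort=True):
        n_families = tile_df["family_id"].nunique()
        if n_families <= config.max_unrelated_carriers:
            keep = tile_df[tile_df["mean_z"] > config.path_a_z].copy()
            keep["rarity_path"] = "A"
        else:
            # one representative (best mean_z) per family
            reps = (tile_df.sort_values("mean_z", ascending=False, kind="mergesort")
                    .drop_duplicates("family_id"))
            z = reps["mean_z"].to_numpy()
            m = min(config.max_unrelated_carriers, int((z[:config.max_unrelated_carriers] > config.path_b_z).sum()))
            while m > 0:
                if z[m - 1] <= config.path_b_z:
                    m -= 1
                    continue
                if m < len(z) and z[m - 1] - z[m] < config.path_b_separation:
                    m -= 1
                    continue
                break
            if m == 0:
                continue
            kept_fams = set(reps["family_id"].iloc[:m])
            kept_samples = set(reps["sample_id"].iloc[:m])
            keep = tile_df[
                tile_df["family_id"].isin(kept_fams)
                & tile_df["sample_id"].isin(kept_samples)
                & (tile_df["mean_z"] > config.path_b_z)
            ].copy()
            keep["rarity_path"] = "B"
        if len(keep):
            kept_chunks.append(keep)
    if not kept_chunks:
        out = df.iloc[0:0].copy()
        out["rarity_path"] = pd.Series(dtype=str)
        return out.drop(columns=["family_id"])
    out = pd.concat(kept_chunks, ignore_index=True).drop(columns=["family_id"])
    return out


def assess_allele_specificity(
    calls: pd.DataFrame,
    candidates: pd.DataFrame,
    hap_tables: dict[str, dict[str, "object"]],
    config: CallerConfig | None = None,
    min_covered_cpgs: int = 2,
) -> pd.DataFrame:
    """Label each call allele_specific / biallelic / undetermined.

    allele_specific: the tile is a candidate on exactly one haplotype and the
    *other* haplotype has >= ``min_covered_cpgs`` tile CpGs at or above the
    coverage floor without being a candidate.  biallelic: candidate on both
    haplotypes.  Anything else (e.g. the other haplotype under-covered, or a
    combined-only call) is undetermined.
    """
    config = config or CallerConfig()
    cand_keys = set(
        zip(candidates["sample_id"], candidates["phasing_mode"],
            candidates["chrom"], candidates["tile_start"])
    )

    def other_hap_covered(sample: str, mode: str, chrom: str, tile_start: int) -> bool:
        modes = hap_tables.get(sample, {})
        table = modes.get(mode)
        if table is None:
            return False
        d = table.data
        in_tile = d[(d["chrom"] == chrom) & (d["pos"] >= tile_start)
                    & (d["pos"] < tile_start + config.tile_width)
                    & (d["coverage"] >= config.min_coverage)]
        return len(in_tile) >= min_covered_cpgs

    labels = []
    for row in calls.itertuples(index=False):
        s, chrom, tile = row.sample_id, row.chrom, row.tile_start
        hap1 = (s, "hap1", chrom, tile) in cand_keys
        hap2 = (s, "hap2", chrom, tile) in cand_keys
        if hap1 and hap2:
            labels.append("biallelic")
        elif hap1 != hap2:
            other = "hap2" if hap1 else "hap1"
            if other_hap_covered(s, other, chrom, tile):
                labels.append("allele_specific")
            else:
                labels.append("undetermined")
        else:
            labels.append("undetermined")
    out = calls.copy()
    out["allele_specificity"] = labels
    return out


def classify_extent(calls: pd.DataFrame, config: CallerConfig | None = None,
                    two_tiles_large: bool = False) -> pd.DataFrame:
    """Label runs of adjacent called tiles 'regular' or 'large' per sample/mode.

    Maximal runs of adjacent tiles (no gap) shorter than ``large_min_run``
    (default 3) are 'regular'; longer runs are 'large'.  ``two_tiles_large``
    flips the boundary so that 2-tile runs are already 'large'.
    """
    config = config or CallerConfig()
    min_run = 2 if two_tiles_large else config.large_min_run
    if calls.empty:
        out = calls.copy()
        out["extent"] = pd.Series(dtype=str)
        return out
    out = calls.copy()
    out["extent"] = "regular"
    for (_s, _m, _c), idx in out.groupby(
            ["sample_id", "phasing_mode", "chrom"], sort=False).groups.items():
        sub = out.loc[idx].sort_values("tile_start")
        starts = sub["tile_start"].to_numpy()
        breaks = np.flatnonzero(np.diff(starts) != config.tile_width)
        run_bounds = np.concatenate(([0], breaks + 1, [len(starts)]))
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            if b - a >= min_run:
                out.loc[sub.index[a:b], "extent"] = "large"
    return out


def write_calls(calls: pd.DataFrame, path, tile_width: int = TILE_WIDTH) -> None:
    """Write calls as a TSV with explicit tile_end (BED6-projectable)."""
    out = calls.copy()
    out["tile_end"] = out["tile_start"] + tile_width
    cols = ["chrom", "tile_start", "tile_end", "sample_id", "phasing_mode",
            "n_hyper", "n_hypo", "mean_z"]
    for opt in ("rarity_path", "allele_specificity", "extent"):
        if opt in out.columns:
            cols.append(opt)
    out[cols].to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df
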