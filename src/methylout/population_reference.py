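"""Per-CpG population reference statistics and per-sample z-scores.

The reference distribution for every CpG is computed from the *combined*
phasing mode of all cohort samples: mean, sample SD (denominator n-1),
empirical 95th and 5th quantiles (linear interpolation between order
statistics, i.e. the "type 7" rule) and the number of contributing samples.
Haplotype-mode methylation rates are z-scored against this same combined-mode
reference, which is what makes mono-allelic events stand out: a fully
methylated single allele sits far above the population distribution of total
methylation at an otherwise unmethylated CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylout.methylation_io import MethylationTable

STATS_COLUMNS = ["chrom", "pos", "mean", "sd", "q95", "q5", "n_samples"]


def compute_population_stats(
    tables: list[MethylationTable],
    exclude_samples: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Per-CpG mean, SD, Q95, Q5 and sample count over a cohort.

    Parameters
    ----------
    tables
        Combined-mode tables, one per sample, already coverage-filtered.
    exclude_samples
        Optional sample ids to leave out of the reference (by default the
        reference includes every sequenced sample, relatives and probands
        alike).

    Returns
    -------
    DataFrame with columns chrom, pos, mean, sd, q95, q5, n_samples.  A CpG
    observed in a single sample gets sd = 0.
    """
    kept = [t for t in tables if t.sample_id not in exclude_samples]
    if len(kept) < 2:
        raise ValueError("need at least 2 samples for a population reference")
    long = pd.concat(
        (t.data[["chrom", "pos", "meth_fraction"]] for t in kept),
        ignore_index=True,
    )
    if long.empty:
        return pd.DataFrame(columns=STATS_COLUMNS)
    grp = long.groupby(["chrom", "pos"], sort=True)["meth_fraction"]
    stats = grp.agg(mean="mean", sd="std", n_samples="size").reset_index()
    # linear-interpolation ("type 7") empirical quantiles
    q95 = grp.quantile(0.95).rename("q95").reset_index()
    q5 = grp.quantile(0.05).rename("q5").reset_index()
    stats = stats.merge(q95, on=["chrom", "pos"]).merge(q5, on=["chrom", "pos"])
    stats = stats[["chrom", "pos", "mean", "sd", "q95", "q5", "n_samples"]]
    stats["sd"] = stats["sd"].fillna(0.0)
    stats["n_samples"] = stats["n_samples"].astype(np.int64)
    return stats


@dataclass
class ZScoreResult:
    """Z-score table plus the count of records excluded for sd = 0 / no stats."""

    table: pd.DataFrame  # sample_id, phasing_mode, chrom, pos, coverage, meth_fraction, z
    n_excluded_sd0: int
    n_excluded_no_stats: int


def compute_zscores(table: MethylationTable, stats: pd.DataFrame) -> ZScoreResult:
    """z = (meth_fraction - mean) / sd against the population reference.

    Records at CpGs with sd = 0 or absent from the reference are excluded
    and counted, not z-scored.
    """
    merged = table.data.merge(stats, on=["chrom", "pos"], how="left")
    no_stats = merged["mean"].isna()
    sd0 = (~no_stats) & (merged["sd"] == 0)
    ok = ~(no_stats | sd0)
    out = merged.loc[ok, ["chrom", "pos", "coverage", "meth_fraction"]].copy()
    out["z"] = (
        merged.loc[ok, "meth_fraction"] - merged.loc[ok, "mean"]
    ) / merged.loc[ok, "sd"]
    out.insert(0, "phasing_mode", table.phasing_mode)
    out.insert(0, "sample_id", table.sample_id)
    return ZScoreResult(
        table=out.reset_index(drop=True),
        n_excluded_sd0=int(sd0.sum()),
        n_excluded_no_stats=int(no_stats.sum()),
    )


def zscore_cohort(
    tables_by_sample: dict[str, dict[str, MethylationTable]],
    stats: pd.DataFrame,
) -> pd.DataFrame:
    """Z-score every sample and phasing mode against one reference.

    ``tables_by_sample`` maps sample_id -> {phasing_mode -> MethylationTable}.
    Returns a single long table over all samples and modes.
    """
    frames = []
    for modes in tables_by_sample.values():
        for table in modes.values():
            frames.append(compute_zscores(table, stats).table)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "phasing_mode", "chrom", "pos", "coverage",
                     "meth_fraction", "z"]
        )
    return pd.concat(frames, ignore_index=True)


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(STATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
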