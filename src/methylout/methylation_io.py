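"""Per-CpG methylation tables: reading, filtering, writing and concordance QC.

A methylation table holds one sample's per-CpG read coverage and methylation
fraction for one *phasing mode*: ``combined`` (all reads), ``hap1`` or
``hap2`` (reads assigned to one haplotype).  Coordinates are 0-based single
CpG positions, strands combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASING_MODES = ("combined", "hap1", "hap2")

PILEUP_COLUMNS = ["chrom", "start", "end", "coverage", "meth_fraction", "phasing_mode"]


class PileupParseError(ValueError):
    """Raised when a pileup file contains a malformed or invalid row."""


@dataclass
class MethylationTable:
    """Per-CpG methylation records for one sample in one phasing mode.

    ``data`` columns: chrom (str), pos (int, 0-based), coverage (int),
    meth_fraction (float in [0, 1]).  Rows are unique on (chrom, pos) and
    sorted by (chrom, pos).
    """

    sample_id: str
    phasing_mode: str
    data: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        if self.phasing_mode not in PHASING_MODES:
            raise ValueError(f"unknown phasing mode {self.phasing_mode!r}")
        self.data = validate_methylation_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def filter_coverage(self, min_coverage: int) -> "MethylationTable":
        """Return a copy keeping records with coverage >= min_coverage."""
        kept = self.data[self.data["coverage"] >= min_coverage].reset_index(drop=True)
        return MethylationTable(self.sample_id, self.phasing_mode, kept)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "coverage": pd.Series(dtype=np.int64),
            "meth_fraction": pd.Series(dtype=float),
        }
    )


def validate_methylation_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate, sort and type-normalize a per-CpG methylation frame."""
    if df.empty:
        return _empty_frame()
    df = df[["chrom", "pos", "coverage", "meth_fraction"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    df["meth_fraction"] = df["meth_fraction"].astype(float)
    if (df["coverage"] < 0).any():
        raise PileupParseError("negative coverage")
    bad = ~df["meth_fraction"].between(0.0, 1.0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise PileupParseError(
            f"meth_fraction out of [0,1] at {df['chrom'].iat[i]}:{df['pos'].iat[i]}"
        )
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"], keep=False)].iloc[0]
        raise PileupParseError(f"duplicate CpG position {dup['chrom']}:{dup['pos']}")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_cpg_pileup(
    path,
    min_coverage: int = 10,
    sample_id: str | None = None,
    phasing_mode: str | None = None,
) -> MethylationTable:
    """Read a per-CpG pileup TSV, keeping records at ``coverage >= min_coverage``.

    Expected columns: chrom, start, end, coverage, methylated_fraction,
    phasing_mode (header required).  The coverage-10 default mirrors the
    per-mode read-depth floor used when haplotype-resolved methylation calls
    are emitted upstream.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PileupParseError(f"cannot parse {path}: {exc}") from exc
    rename = {
        "start": "pos",
        "methylated_fraction": "meth_fraction",
    }
    df = df.rename(columns=rename)
    required = {"chrom", "pos", "coverage", "meth_fraction"}
    if not required.issubset(df.columns):
        raise PileupParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if phasing_mode is None:
        modes = df["phasing_mode"].unique() if "phasing_mode" in df else []
        phasing_mode = str(modes[0]) if len(modes) else "combined"
    if "phasing_mode" in df.columns and len(df):
        extra = set(df["phasing_mode"].unique()) - {phasing_mode}
        if extra:
            raise PileupParseError(f"{path}: mixed phasing modes {extra}")
    if sample_id is None:
        sample_id = str(path)
    table = MethylationTable(sample_id, phasing_mode, df)
    return table.filter_coverage(min_coverage)


def read_bedmethyl(path, min_coverage: int = 10, sample_id: str | None = None,
                   phasing_mode: str = "combined") -> MethylationTable:
    """Read a 9+-column bedMethyl file (percentage column divided by 100)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 11:
        raise PileupParseError(f"{path}: bedMethyl needs >= 11 columns, got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "pos": df[1],
            "coverage": df[9],
            "meth_fraction": df[10] / 100.0,
        }
    )
    table = MethylationTable(sample_id or str(path), phasing_mode, out)
    return table.filter_coverage(min_coverage)


def write_cpg_pileup(table: MethylationTable, path) -> None:
    """Write a methylation table as a pileup TSV (round-trips with the reader)."""
    out = pd.DataFrame(
        {
            "chrom": table.data["chrom"],
            "start": table.data["pos"],
            "end": table.data["pos"] + 1,
            "coverage": table.data["coverage"],
            "methylated_fraction": table.data["meth_fraction"],
            "phasing_mode": table.phasing_mode,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _shared_cpgs(table_a: MethylationTable, table_b: MethylationTable,
                 min_coverage: int) -> pd.DataFrame:
    a = table_a.data[table_a.data["coverage"] > min_coverage]
    b = table_b.data[table_b.data["coverage"] > min_coverage]
    return a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))


def sample_wise_concordance(
    table_a: MethylationTable,
    table_b: MethylationTable,
    min_coverage: int = 20,
) -> float:
    """Pearson r between two platforms' methylation fractions for one sample.

    Only CpGs strictly above ``min_coverage`` in *both* tables enter the
    correlation.  Returns NaN when fewer than 3 CpGs are shared or either
    vector is constant.
    """
    merged = _shared_cpgs(table_a, table_b, min_coverage)
    if len(merged) < 3:
        return float("nan")
    x = merged["meth_fraction_a"].to_numpy()
    y = merged["meth_fraction_b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def top_variable_cpg_concordance(
    cohort_a: list[MethylationTable],
    cohort_b: list[MethylationTable],
    n_top: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-CpG cross-platform correlation at the most variable CpGs.

    Selects the ``n_top`` CpGs with the highest across-sample SD of the
    methylation fraction in ``cohort_a``, then for each selected CpG computes
    the Pearson r between the paired samples' fractions in the two cohorts,
    plus a control r after a seeded shuffle of cohort_b's sample labels.

    Parameters
    ----------
    cohort_a, cohort_b
        Paired, same-ordered per-sample tables (combined mode).
    n_top
        Number of top-SD CpGs; ties broken by (chrom, pos). Constant CpGs
        (zero SD) never rank.

    Returns
    -------
    DataFrame with columns chrom, pos, r, r_shuffled.
    """
    if len(cohort_a) != len(cohort_b):
        raise ValueError("cohorts must be paired sample-by-sample")
    if len(cohort_a) < 3:
        raise ValueError("need at least 3 paired samples")

    def _wide(cohort: list[MethylationTable]) -> pd.DataFrame:
        frames = []
        for i, t in enumerate(cohort):
            f = t.data[["chrom", "pos", "meth_fraction"]].copy()
            f["sample"] = i
            frames.append(f)
        long = pd.concat(frames, ignore_index=True)
        return long.pivot_table(index=["chrom", "pos"], columns="sample",
                                values="meth_fraction")

    wide_a = _wide(cohort_a)
    wide_b = _wide(cohort_b)
    sd = wide_a.std(axis=1, ddof=1)
    sd = sd[sd > 0]
    if len(sd) < n_top:
        warnings.warn(f"only {len(sd)} variable CpGs available, using all")
    ranked = (
        sd.rename("sd")
        .reset_index()
        .sort_values(["sd", "chrom", "pos"], ascending=[False, True, True],
                     kind="mergesort")
        .head(n_top)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, pos in zip(ranked["chrom"], ranked["pos"]):
        if (chrom, pos) not in wide_b.index:
            continue
        xa = wide_a.loc[(chrom, pos)].to_numpy(dtype=float)
        xb = wide_b.loc[(chrom, pos)].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < 3:
            continue
        xa, xb = xa[ok], xb[ok]
        r = np.nan
        if np.std(xa) > 0 and np.std(xb) > 0:
            r = float(np.corrcoef(xa, xb)[0, 1])
        xb_shuf = rng.permutation(xb)
        r_shuf = np.nan
        if np.std(xa) > 0 and np.std(xb_shuf) > 0:
            r_shuf = float(np.corrcoef(xa, xb_shuf)[0, 1])
        rows.append({"chrom": chrom, "pos": pos, "r": r, "r_shuffled": r_shuf})
    return pd.DataFrame(rows, columns=["chrom", "pos", "r", "r_shuffled"])
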