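"""Cohort-level statistics on outlier calls.

Three analyses live here:

* familial sharing — how often an outlier tile called in one member of an
  enrolled family is also called in a relative, against a permutation null
  that shuffles family labels;
* regulatory-element enrichment — overlap of outlier tiles with a
  component-labelled DNase-hypersensitivity (DHS) BED, against a background
  of well-covered, unremarkable tiles (present in >= 5 samples, tile mean z
  inside a band around 0), Fisher-exact tested per component;
* annotation — nearest TSS (signed distance), nearest disease gene, and a
  proximal-promoter flag for each tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats as sps


# ---------------------------------------------------------------------------
# familial sharing

@dataclass
class SharingSummary:
    """Observed vs permuted familial sharing of outlier tiles."""

    n_calls_with_relative: int
    n_shared: int
    percent_shared: float
    perm_mean: float
    perm_min: int
    perm_max: int
    fold: float
    p_perm: float
    n_perm: int
    seed: int
    perm_distribution: list[int] = field(default_factory=list, repr=False)


def _dedupe_observations(calls: pd.DataFrame) -> pd.DataFrame:
    """One observation per (sample, tile position), any phasing mode."""
    return calls.drop_duplicates(["sample_id", "chrom", "tile_start"])[
        ["sample_id", "chrom", "tile_start"]
    ].reset_index(drop=True)


def _families_with_relatives(pedigree: pd.DataFrame) -> dict[str, str]:
    """sample -> family for samples whose family has >= 2 enrolled members."""
    fam = pedigree.groupby("family_id")["sample_id"].apply(list)
    out: dict[str, str] = {}
    for family_id, members in fam.items():
        if len(members) >= 2:
            for s in members:
                out[str(s)] = str(family_id)
    return out


def _count_shared(sample_idx: np.ndarray, tile_idx: np.ndarray,
                  fam_of_sample: np.ndarray) -> int:
    """Observations whose (tile, family) key occurs for >= 2 samples.

    Observations are unique per (sample, tile), so a key multiplicity >= 2
    implies at least two distinct family members share the tile.
    """
    key = tile_idx.astype(np.int64) * (fam_of_sample.max() + 1) + fam_of_sample[sample_idx]
    _, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    return int((counts[inv] >= 2).sum())


def observed_sharing(calls: pd.DataFrame, pedigree: pd.DataFrame
                     ) -> tuple[int, int]:
    """(n observations in samples with an enrolled relative, n shared).

    An observation is one (sample, tile) call; it is *shared* when any
    relative of the sample also carries a call at the same tile position in
    any phasing mode.  Returns (0, 0)-like undefined marker (None, None)
    when no sample has a relative.
    """
    fam = _families_with_relatives(pedigree)
    if not fam:
        return None, None
    obs = _dedupe_observations(calls)
    obs = obs[obs["sample_id"].astype(str).isin(fam)]
    if obs.empty:
        return 0, 0
    obs = obs.copy()
    obs["family_id"] = obs["sample_id"].astype(str).map(fam)
    obs["tile_key"] = obs["chrom"].astype(str) + ":" + obs["tile_start"].astype(str)
    counts = obs.groupby(["tile_key", "family_id"])["sample_id"].transform("size")
    return int(len(obs)), int((counts >= 2).sum())


def permutation_enrichment(calls: pd.DataFrame, pedigree: pd.DataFrame,
                           n_perm: int = 1000, seed: int = 0) -> SharingSummary:
    """Permutation test for excess familial sharing of outlier tiles.

    Family labels are shuffled among the call-carrying samples that have
    enrolled relatives, holding each sample's call set fixed; the shared
    count is recomputed per permutation.  fold = observed / mean(permuted);
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fam = _families_with_relatives(pedigree)
    if not fam:
        raise ValueError("no sample has an enrolled relative")
    obs = _dedupe_observations(calls)
    obs = obs[obs["sample_id"].astype(str).isin(fam)].copy()
    n_obs, n_shared = observed_sharing(calls, pedigree)

    samples = sorted(obs["sample_id"].astype(str).unique())
    fam_labels = np.array([fam[s] for s in samples])
    fam_codes = pd.factorize(fam_labels)[0]
    sample_to_idx = {s: i for i, s in enumerate(samples)}
    sample_idx = obs["sample_id"].astype(str).map(sample_to_idx).to_numpy()
    tile_codes = pd.factorize(
        obs["chrom"].astype(str) + ":" + obs["tile_start"].astype(str))[0]

    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        shuffled = rng.permutation(fam_codes)
        perm_counts[p] = _count_shared(sample_idx, tile_codes, shuffled)
    perm_mean = float(perm_counts.mean())
    fold = n_shared / perm_mean if perm_mean > 0 else float("nan")
    p_perm = float((1 + (perm_counts >= n_shared).sum()) / (1 + n_perm))
    return SharingSummary(
        n_calls_with_relative=n_obs,
        n_shared=n_shared,
        percent_shared=100.0 * n_shared / n_obs if n_obs else float("nan"),
        perm_mean=perm_mean,
        perm_min=int(perm_counts.min()),
        perm_max=int(perm_counts.max()),
        fold=fold,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
        perm_distribution=perm_counts.tolist(),
    )


def sharing_summary_from_counts(n_shared: int, n_with_relative: int,
                                perm_mean: float) -> dict:
    """Percent shared and fold excess from already-tabulated sharing counts.

    Useful for summarizing a finished run (or a published count table)
    without re-running permutations: percent = 100*shared/with_relative
    (one decimal), fold = shared/perm_mean (three decimals).
    """
    if n_with_relative < n_shared or n_with_relative <= 0:
        raise ValueError("need 0 <= n_shared <= n_with_relative, n_with_relative > 0")
    return {
        "percent_shared": round(100.0 * n_shared / n_with_relative, 1),
        "fold": round(n_shared / perm_mean, 3),
    }


# ---------------------------------------------------------------------------
# background tiles and DHS enrichment

def tile_sample_zscores(z_table: pd.DataFrame, tile_width: int = 200,
                        min_cpgs: int = 2) -> pd.DataFrame:
    """Per (sample, chrom, tile): mean z and covered-CpG count.

    'Present' means at least ``min_cpgs`` CpGs with a defined z (i.e. at the
    calling coverage basis) in the tile for that sample.
    """
    df = z_table.copy()
    df["tile_start"] = (df["pos"] // tile_width) * tile_width
    agg = (df.groupby(["sample_id", "chrom", "tile_start"], sort=True)
           .agg(mean_z=("z", "mean"), n_cpgs=("z", "size")).reset_index())
    return agg[agg["n_cpgs"] >= min_cpgs].reset_index(drop=True)


def select_background_tiles(tile_stats: pd.DataFrame, min_samples: int = 5,
                            z_low: float = -1.0, z_high: float = 1.0,
                            n_select: int = 50000, seed: int = 0) -> pd.DataFrame:
    """Seeded random draw of unremarkable, well-covered tiles.

    A tile qualifies when >= ``min_samples`` samples have it covered and the
    tile-level mean of the per-sample mean z lies inside [z_low, z_high].
    Returns up to ``n_select`` distinct (chrom, tile_start) rows.
    """
    per_tile = (tile_stats.groupby(["chrom", "tile_start"])
                .agg(n_samples=("sample_id", "nunique"), tile_z=("mean_z", "mean"))
                .reset_index())
    pool = per_tile[(per_tile["n_samples"] >= min_samples)
                    & per_tile["tile_z"].between(z_low, z_high)]
    if pool.empty:
        raise ValueError("no tile satisfies the background criteria")
    pool = pool.sort_values(["chrom", "tile_start"]).reset_index(drop=True)
    if len(pool) <= n_select:
        if len(pool) < n_select:
            warnings.warn(f"background pool has only {len(pool)} tiles "
                          f"(< n_select={n_select}); returning all")
        return pool[["chrom", "tile_start"]].copy()
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool), size=n_select, replace=False)
    return (pool.iloc[np.sort(pick)][["chrom", "tile_start"]]
            .reset_index(drop=True))


def _tiles_to_pyranges(tiles: pd.DataFrame, tile_width: int) -> pr.PyRanges:
    return pr.PyRanges(pd.DataFrame({
        "Chromosome": tiles["chrom"].astype(str),
        "Start": tiles["tile_start"].astype(np.int64),
        "End": tiles["tile_start"].astype(np.int64) + tile_width,
        "tile_id": tiles["chrom"].astype(str) + ":" + tiles["tile_start"].astype(str),
    }))


def _n_overlapping(tiles: pd.DataFrame, elements: pd.DataFrame,
                   tile_width: int) -> int:
    """Distinct tiles with >= 1 bp intersection with any element."""
    if tiles.empty or elements.empty:
        return 0
    g = _tiles_to_pyranges(tiles, tile_width)
    e = pr.PyRanges(pd.DataFrame({
        "Chromosome": elements["chrom"].astype(str),
        "Start": elements["start"].astype(np.int64),
        "End": elements["end"].astype(np.int64),
    }))
    ov = g.overlap(e)
    if len(ov) == 0:
        return 0
    return int(ov.df["tile_id"].nunique())


def dhs_enrichment(outlier_tiles: pd.DataFrame, background_tiles: pd.DataFrame,
                   elements: pd.DataFrame, tile_width: int = 200) -> pd.DataFrame:
    """Regulatory-element overlap enrichment, per component and overall.

    ``elements`` needs columns chrom, start, end, component.  For each
    component (and the pooled 'any' row): counts of overlapping outlier and
    background tiles, fold = ratio of overlap fractions, and a two-sided
    Fisher exact p on the 2x2 overlap table.
    """
    out_t = outlier_tiles.drop_duplicates(["chrom", "tile_start"])
    bg_t = background_tiles.drop_duplicates(["chrom", "tile_start"])
    n_out, n_bg = len(out_t), len(bg_t)
    rows = []
    groups = [("any", elements)] + [
        (comp, sub) for comp, sub in elements.groupby("component", sort=True)
    ]
    for label, sub in groups:
        k_out = _n_overlapping(out_t, sub, tile_width)
        k_bg = _n_overlapping(bg_t, sub, tile_width)
        table = [[k_out, n_out - k_out], [k_bg, n_bg - k_bg]]
        _, p = sps.fisher_exact(table, alternative="two-sided")
        f_out = k_out / n_out if n_out else float("nan")
        f_bg = k_bg / n_bg if n_bg else float("nan")
        fold = f_out / f_bg if f_bg > 0 else float("nan")
        rows.append({"component": label, "n_outlier_overlap": k_out,
                     "n_outlier_total": n_out, "n_background_overlap": k_bg,
                     "n_background_total": n_bg, "fold": fold, "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation

def _nearest_signed(points: np.ndarray, start: int, end: int) -> tuple[float, int]:
    """Signed distance from tile [start, end) to the nearest point.

    0 when a point falls inside the tile; positive when the nearest point is
    downstream of the tile end, negative when upstream of the start.
    Returns (distance, index-of-point).
    """
    i = np.searchsorted(points, start)
    best = (float("inf"), -1)
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(points):
            p = points[j]
            if start <= p < end:
                d = 0.0
            elif p < start:
                d = float(p - start)  # negative: upstream
            else:
                d = float(p - (end - 1))
            if abs(d) < abs(best[0]):
                best = (d, j)
    return best


def annotate_tiles(tiles: pd.DataFrame, tss_bed: pd.DataFrame,
                   disease_gene_bed: pd.DataFrame | None = None,
                   promoter_window: int = 1000,
                   tile_width: int = 200) -> pd.DataFrame:
    """Nearest TSS, nearest disease gene and proximal-promoter flag per tile.

    ``tss_bed`` needs chrom, start (TSS position), name.  The promoter flag
    is set when the tile intersects the closed window [TSS - w, TSS + w].
    """
    tss_sorted = {c: sub.sort_values("start").reset_index(drop=True)
                  for c, sub in tss_bed.groupby("chrom")}
    dg_sorted = {}
    if disease_gene_bed is not None and len(disease_gene_bed):
        dg_sorted = {c: sub.sort_values("start").reset_index(drop=True)
                     for c, sub in disease_gene_bed.groupby("chrom")}
    rows = []
    for row in tiles.drop_duplicates(["chrom", "tile_start"]).itertuples(index=False):
        chrom, start = str(row.chrom), int(row.tile_start)
        end = start + tile_width
        rec = {"chrom": chrom, "tile_start": start}
        sub = tss_sorted.get(chrom)
        if sub is None or sub.empty:
            rec.update(tss_distance=float("nan"), nearest_tss=None, promoter=False)
        else:
            pts = sub["start"].to_numpy(dtype=np.int64)
            d, j = _nearest_signed(pts, start, end)
            tss = int(pts[j])
            rec.update(
                tss_distance=d,
                nearest_tss=str(sub["name"].iloc[j]) if "name" in sub else str(tss),
                # closed-window intersection: tile [start,end) vs [tss-w, tss+w]
                promoter=(start <= tss + promoter_window) and (end - 1 >= tss - promoter_window),
            )
        sub = dg_sorted.get(chrom)
        if not dg_sorted:
            rec.update(nearest_disease_gene=None, disease_gene_distance=float("nan"))
        elif sub is None or sub.empty:
            rec.update(nearest_disease_gene=None, disease_gene_distance=float("nan"))
        else:
            pts = sub["start"].to_numpy(dtype=np.int64)
            d, j = _nearest_signed(pts, start, end)
            rec.update(nearest_disease_gene=str(sub["name"].iloc[j]) if "name" in sub else None,
                       disease_gene_distance=d)
        rows.append(rec)
    return pd.DataFrame(rows)
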