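"""Linking outlier tiles to nearby rare variants.

For every hyper-mCpG tile call, the carrier's nearest rare variant distance
is ranked against the distances obtained by running the identical query for
the same tile in every other sample; a low percentile rank means the carrier
harbours a rare variant unusually close to its outlier tile.  Binned mean
ranks form an empirical q curve over distance, and haplotype-resolved calls
paired with phased variants yield a cis/trans assignment tested with an
exact binomial.

Rarity filters follow the population-frequency cutoffs used for the calls:
SNVs are retained below 0.5% MAF, structural variants below 1%.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

SNV_KINDS = {"SNV"}
SV_KINDS = {"DEL", "INS", "DUP", "INV", "BND", "repeat-expansion"}

VARIANT_COLUMNS = ["variant_id", "sample_id", "chrom", "pos", "end", "kind",
                   "maf", "haplotype"]


def load_rare_variants(vcf_path, sample_id: str | None = None,
                       snv_maf: float = 0.005, sv_maf: float = 0.01) -> pd.DataFrame:
    """Read a (single-sample) VCF into a rare-variant frame.

    Expects an INFO/MAF annotation and a phased GT (1|0 = variant on hap1,
    0|1 = on hap2; unphased or homozygous calls map to 'unphased').  SVs are
    recognized from INFO/SVTYPE (END used as the second breakend); records
    failing the MAF cutoff for their class are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else str(vcf_path)
    rows = []
    for rec in vcf:
        maf = rec.INFO.get("MAF")
        if maf is None:
            continue
        svtype = rec.INFO.get("SVTYPE")
        if svtype:
            kind = str(svtype)
        elif len(rec.REF) == 1 and all(len(a) == 1 for a in rec.ALT):
            kind = "SNV"
        else:
            kind = "DEL" if len(rec.REF) > max(map(len, rec.ALT or ["N"])) else "INS"
        end = rec.INFO.get("END", rec.end)
        gts = rec.genotypes
        hap = "unphased"
        if gts:
            a, b, phased = gts[0][0], gts[0][1], gts[0][-1]
            if phased and a != b:
                hap = "hap1" if a != 0 else "hap2"
        rows.append({"variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "sample_id": sample_id, "chrom": rec.CHROM,
                     "pos": rec.POS - 1, "end": int(end), "kind": kind,
                     "maf": float(maf), "haplotype": hap})
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return filter_rare(df, snv_maf=snv_maf, sv_maf=sv_maf)


def filter_rare(variants: pd.DataFrame, snv_maf: float = 0.005,
                sv_maf: float = 0.01) -> pd.DataFrame:
    """Keep SNVs with maf < snv_maf and SVs with maf < sv_maf."""
    if variants.empty:
        return variants.copy()
    is_snv = variants["kind"].isin(SNV_KINDS)
    keep = (is_snv & (variants["maf"] < snv_maf)) | (~is_snv & (variants["maf"] < sv_maf))
    return variants[keep].reset_index(drop=True)


def nearest_rare_variant(chrom: str, tile_start: int, tile_end: int,
                         variants: pd.DataFrame) -> tuple[float, str | None]:
    """Distance (bp) from a tile to the sample's closest rare variant.

    Distance is measured from the nearest tile edge to the nearest variant
    breakend, 0 when overlapping.  Returns (nan, None) when the chromosome
    carries no variant for the sample.
    """
    on_chrom = variants[variants["chrom"] == chrom]
    if on_chrom.empty:
        return float("nan"), None
    vpos = on_chrom["pos"].to_numpy(dtype=np.int64)
    vend = on_chrom["end"].to_numpy(dtype=np.int64) if "end" in on_chrom else vpos + 1
    vend = np.maximum(vend, vpos + 1)
    d = np.maximum(np.maximum(tile_start - vend, vpos - tile_end), 0)
    i = int(np.argmin(d))
    return float(d[i]), str(on_chrom["variant_id"].iloc[i])


def percentile_rank(carrier_distance: float, other_distances) -> float:
    """Add-one empirical percentile of the carrier's distance among the others.

    rank = (1 + #{others <= carrier}) / (1 + #others); ties count as <=.
    Returns NaN on an empty comparison set.
    """
    others = np.asarray([d for d in other_distances if not math.isnan(d)], dtype=float)
    if others.size == 0 or math.isnan(carrier_distance):
        return float("nan")
    return float((1 + (others <= carrier_distance).sum()) / (1 + others.size))


def link_tiles_to_variants(calls: pd.DataFrame,
                           variants_by_sample: dict[str, pd.DataFrame],
                           tile_width: int = 200) -> pd.DataFrame:
    """Build the tile-variant link table across the cohort.

    For each call, the carrier's nearest-variant distance is ranked against
    the distances for the same tile in every other sample (the population
    null for that locus).  Haplotype-resolved calls get a cis/trans phase
    relation from the nearest variant's haplotype.
    """
    rows = []
    samples = list(variants_by_sample)
    uniq = calls.drop_duplicates(["sample_id", "chrom", "tile_start"])
    for row in uniq.itertuples(index=False):
        chrom, start = row.chrom, int(row.tile_start)
        end = start + tile_width
        carrier = str(row.sample_id)
        if carrier not in variants_by_sample:
            continue
        d, vid = nearest_rare_variant(chrom, start, end, variants_by_sample[carrier])
        if math.isnan(d):
            continue
        others = [nearest_rare_variant(chrom, start, end, variants_by_sample[s])[0]
                  for s in samples if s != carrier]
        pr_ = percentile_rank(d, others)
        v = variants_by_sample[carrier]
        vrow = v[v["variant_id"] == vid].iloc[0]
        mode = getattr(row, "phasing_mode", "combined")
        phase = assign_phase(mode, vrow["haplotype"])
        rows.append({"chrom": chrom, "tile_start": start, "sample_id": carrier,
                     "variant_id": vid, "kind": vrow["kind"], "distance": d,
                     "percentile_rank": pr_, "phase_relation": phase,
                     "phasing_mode": mode})
    return pd.DataFrame(rows, columns=["chrom", "tile_start", "sample_id",
                                       "variant_id", "kind", "distance",
                                       "percentile_rank", "phase_relation",
                                       "phasing_mode"])


def empirical_q_curve(links: pd.DataFrame, distance_bins=None,
                      q_threshold: float = 0.1,
                      min_links_per_bin: int = 5) -> tuple[pd.DataFrame, float]:
    """Mean percentile rank per distance bin, and the q < threshold distance.

    ``q(bin)`` is the mean percentile rank of links whose nearest-variant
    distance falls in the bin; the returned threshold is the largest bin
    midpoint with q below ``q_threshold`` (NaN when no bin qualifies).  Bins
    holding fewer than ``min_links_per_bin`` links are reported in the curve
    but excluded from the threshold determination — a mean over one or two
    ranks is not a stable q estimate.  The curve also carries an
    isotonically pooled column (q must not decrease with distance) for
    plotting; the threshold uses the raw means.
    """
    if distance_bins is None:
        distance_bins = np.concatenate(([0.0], np.logspace(2, 6, 13)))
    if len(links) < 20:
        warnings.warn("fewer than 20 links; the empirical q curve is unstable")
    edges = np.asarray(distance_bins, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    d = links["distance"].to_numpy(dtype=float)
    r = links["percentile_rank"].to_numpy(dtype=float)
    idx = np.digitize(d, edges) - 1
    q = np.full(len(mids), np.nan)
    n = np.zeros(len(mids), dtype=int)
    for b in range(len(mids)):
        m = idx == b
        n[b] = int(m.sum())
        if n[b]:
            q[b] = float(np.nanmean(r[m]))
    # isotonic pooling (pool-adjacent-violators, weighted by bin counts)
    q_iso = q.copy()
    pop = np.flatnonzero(n > 0)
    if pop.size:
        # blocks of (value, weight, n_bins) merged until non-decreasing
        blocks = [[float(q[b]), float(n[b]), 1] for b in pop]
        i = 0
        while i < len(blocks) - 1:
            if blocks[i][0] > blocks[i + 1][0] + 1e-12:
                v0, w0, k0 = blocks[i]
                v1, w1, k1 = blocks[i + 1]
                blocks[i] = [(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1, k0 + k1]
                del blocks[i + 1]
                i = max(i - 1, 0)
            else:
                i += 1
        pos = 0
        for v, _w, k in blocks:
            for b in pop[pos:pos + k]:
                q_iso[b] = v
            pos += k
    curve = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                          "bin_mid": mids, "n": n, "q": q, "q_isotonic": q_iso})
    below = curve[(curve["n"] >= min_links_per_bin) & (curve["q"] < q_threshold)]
    threshold = float(below["bin_mid"].max()) if len(below) else float("nan")
    return curve, threshold


def assign_phase(call_mode: str, variant_haplotype: str) -> str:
    """cis when the call's haplotype matches the variant's, trans otherwise.

    Combined-mode calls and unphased variants cannot be assigned and return
    'unphased' (routed to manual curation downstream).
    """
    if call_mode not in ("hap1", "hap2") or variant_haplotype not in ("hap1", "hap2"):
        return "unphased"
    return "cis" if call_mode == variant_haplotype else "trans"


def cis_trans_binomial(n_cis: int, n_total: int) -> float:
    """Two-sided exact binomial p for a cis count under a fair cis/trans null.

    Doubles the smaller one-sided tail at p0 = 0.5 and caps at 1.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_cis > n_total or n_cis < 0:
        raise ValueError("n_cis must be in [0, n_total]")
    upper = sps.binom.sf(n_cis - 1, n_total, 0.5)
    lower = sps.binom.cdf(n_cis, n_total, 0.5)
    return float(min(1.0, 2.0 * min(upper, lower)))


def local_variant_fraction(links: pd.DataFrame, calls: pd.DataFrame,
                           within: float = 1000.0) -> pd.DataFrame:
    """Per extent class: fraction of calls with a rare variant within ``within`` bp.

    Joins calls (carrying an ``extent`` label) to their link rows and counts,
    per class, how many have nearest-variant distance < within.  Percentages
    are rounded to the nearest integer, matching how such rates are reported.
    """
    merged = calls.drop_duplicates(["sample_id", "chrom", "tile_start"]).merge(
        links[["sample_id", "chrom", "tile_start", "distance"]],
        on=["sample_id", "chrom", "tile_start"], how="left")
    rows = []
    for extent, sub in merged.groupby("extent"):
        n = len(sub)
        k = int((sub["distance"] < within).sum())
        rows.append({"extent": extent, "n_with_local_variant": k, "n_total": n,
                     "fraction": k / n if n else float("nan"),
                     "percent": int(round(100.0 * k / n)) if n else None})
    return pd.DataFrame(rows)


def write_links(links: pd.DataFrame, path, tile_width: int = 200) -> None:
    out = links.copy()
    out["tile_end"] = out["tile_start"] + tile_width
    out.to_csv(path, sep="\t", index=False)
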