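"""End-to-end orchestration: stats -> z -> flags -> tiles -> rarity ->
allele-specificity -> extent -> variant links -> q curve -> sharing ->
enrichment -> annotation -> expression.

Each stage writes its TSV into the output directory so stages can be re-run
individually; a JSON run manifest records the configuration hash, the seed
and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methylout import (
    allelic_expression,
    cohort_statistics,
    methylation_io,
    outlier_caller,
    population_reference,
    synthetic_cohort,
    variant_linker,
)
from methylout.outlier_caller import CallerConfig

log = logging.getLogger("methylout")


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run (defaults = published values)."""

    bundle_dir: str = ""          # directory produced by write_bundle
    output_dir: str = "methylout_out"
    min_coverage: int = 10
    tile_width: int = 200
    sd_multiplier: float = 3.0
    path_a_z: float = 2.0
    path_b_z: float = 5.0
    path_b_separation: float = 3.0
    snv_maf: float = 0.005
    sv_maf: float = 0.01
    q_threshold: float = 0.1
    promoter_window: int = 1000
    ratio_bound: float = 0.45
    min_expression_reads: int = 10
    background_min_samples: int = 5
    background_z: float = 1.0
    n_background: int = 50000
    n_perm: int = 1000
    seed: int = 0

    def caller_config(self) -> CallerConfig:
        return CallerConfig(
            sd_multiplier=self.sd_multiplier, tile_width=self.tile_width,
            path_a_z=self.path_a_z, path_b_z=self.path_b_z,
            path_b_separation=self.path_b_separation,
            min_coverage=self.min_coverage)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    config: RunConfig
    stats: pd.DataFrame
    z_table: pd.DataFrame
    calls: pd.DataFrame
    links: pd.DataFrame
    q_curve: pd.DataFrame
    q_distance_threshold: float
    sharing: object | None
    enrichment: pd.DataFrame
    annotations: pd.DataFrame
    expression_summary: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 bundle: synthetic_cohort.CohortBundle | None = None
                 ) -> PipelineResult:
    """Run every stage on a cohort bundle (in-memory or from ``bundle_dir``).

    Writes per-stage TSVs plus ``run_manifest.json`` into
    ``config.output_dir`` and returns the in-memory results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is not None:
        tables = bundle.methylation
        pedigree = bundle.pedigree
        variants = bundle.variants
        regulatory = bundle.regulatory
        tss, disease = bundle.tss, bundle.disease_genes
        expression = bundle.expression
    else:
        if not config.bundle_dir:
            raise ValueError("bundle_dir required when no in-memory bundle given")
        d = Path(config.bundle_dir)
        if not d.exists():
            raise FileNotFoundError(f"stage=input: bundle dir {d} missing")
        tables = synthetic_cohort.read_bundle_methylation(d)
        pedigree = synthetic_cohort.read_pedigree(d / "cohort.ped")
        vframes = []
        for s in sorted(tables):
            vcf = d / f"{s}.vcf"
            if vcf.exists():
                vframes.append(variant_linker.load_rare_variants(
                    vcf, sample_id=s, snv_maf=1.0, sv_maf=1.0))
        variants = (pd.concat(vframes, ignore_index=True) if vframes
                    else pd.DataFrame(columns=variant_linker.VARIANT_COLUMNS))
        regulatory = synthetic_cohort.read_bed(d / "regulatory_elements.bed",
                                               component=True)
        tss = synthetic_cohort.read_bed(d / "tss.bed")
        disease = synthetic_cohort.read_bed(d / "disease_genes.bed")
        exp_path = d / "expression_counts.tsv"
        expression = (pd.read_csv(exp_path, sep="\t", dtype={"chrom": str})
                      if exp_path.exists() else pd.DataFrame())

    ped_samples = set(pedigree["sample_id"].astype(str))
    offenders = sorted(set(tables) - ped_samples)
    if not tables:
        raise ValueError("stage=input: no samples with methylation tables")
    if offenders:
        raise ValueError(f"stage=input: samples missing from pedigree: {offenders}")

    cc = config.caller_config()

    # population reference from combined-mode tables at the coverage floor
    combined = [tables[s]["combined"].filter_coverage(config.min_coverage)
                for s in sorted(tables)]
    stats = population_reference.compute_population_stats(combined)
    log.info("stats: %d CpGs", len(stats))
    population_reference.write_stats(stats, out / "population_stats.tsv")

    filtered = {
        s: {m: t.filter_coverage(config.min_coverage)
            for m, t in tables[s].items()}
        for s in sorted(tables)
    }
    z_table = population_reference.zscore_cohort(filtered, stats)
    log.info("zscores: %d records", len(z_table))

    flags = outlier_caller.flag_cpgs(z_table, stats, cc.sd_multiplier)
    candidates = outlier_caller.call_tiles(flags, cc)
    calls = outlier_caller.classify_rarity(candidates, pedigree, cc)
    calls = outlier_caller.assess_allele_specificity(calls, candidates,
                                                     filtered, cc)
    calls = outlier_caller.classify_extent(calls, cc)
    log.info("calls: %d (from %d candidates)", len(calls), len(candidates))
    outlier_caller.write_calls(calls, out / "outlier_calls.tsv", cc.tile_width)

    rare = variant_linker.filter_rare(variants, config.snv_maf, config.sv_maf)
    by_sample = {s: g for s, g in rare.groupby("sample_id")}
    for s in sorted(tables):
        by_sample.setdefault(s, rare.iloc[0:0])
    links = variant_linker.link_tiles_to_variants(calls, by_sample,
                                                  cc.tile_width)
    variant_linker.write_links(links, out / "tile_variant_links.tsv",
                               cc.tile_width)
    if len(links):
        q_curve, q_thr = variant_linker.empirical_q_curve(
            links, q_threshold=config.q_threshold)
    else:
        q_curve, q_thr = pd.DataFrame(), float("nan")
    q_curve.to_csv(out / "empirical_q_curve.tsv", sep="\t", index=False)

    sharing = None
    try:
        sharing = cohort_statistics.permutation_enrichment(
            calls, pedigree, n_perm=config.n_perm, seed=config.seed)
    except ValueError:
        log.info("sharing: no family structure, skipped")

    tile_stats = cohort_statistics.tile_sample_zscores(z_table, cc.tile_width)
    try:
        background = cohort_statistics.select_background_tiles(
            tile_stats, min_samples=config.background_min_samples,
            z_low=-config.background_z, z_high=config.background_z,
            n_select=config.n_background, seed=config.seed)
        enrichment = cohort_statistics.dhs_enrichment(
            calls, background, regulatory, cc.tile_width)
    except ValueError:
        enrichment = pd.DataFrame()
    enrichment.to_csv(out / "dhs_enrichment.tsv", sep="\t", index=False)

    annotations = cohort_statistics.annotate_tiles(
        calls, tss, disease, config.promoter_window, cc.tile_width)
    annotations.to_csv(out / "tile_annotations.tsv", sep="\t", index=False)

    if len(expression):
        exp_summary = allelic_expression.summarize_carriers(
            expression.rename(columns={"n_ref": "n_allele1",
                                       "n_alt": "n_allele2"}),
            min_total=config.min_expression_reads,
            ratio_bound=config.ratio_bound)
    else:
        exp_summary = pd.DataFrame()
    exp_summary.to_csv(out / "expression_summary.tsv", sep="\t", index=False)

    summary = summarize_counts(calls)
    summary["stage_records"] = {
        "cpg_stats": len(stats), "zscores": len(z_table),
        "candidates": len(candidates), "calls": len(calls),
        "links": len(links)}
    if sharing is not None:
        summary["sharing"] = {
            "n_calls_with_relative": sharing.n_calls_with_relative,
            "n_shared": sharing.n_shared,
            "fold": sharing.fold if np.isfinite(sharing.fold) else None,
            "p_perm": sharing.p_perm}
    summary["q_distance_threshold"] = q_thr
    manifest = {"config": dataclasses.asdict(config),
                "config_hash": _config_hash(config), "seed": config.seed,
                "summary_counts": summary["per_sample"],
                "stage_records": summary["stage_records"]}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return PipelineResult(config=config, stats=stats, z_table=z_table,
                          calls=calls, links=links, q_curve=q_curve,
                          q_distance_threshold=q_thr, sharing=sharing,
                          enrichment=enrichment, annotations=annotations,
                          expression_summary=exp_summary, summary=summary)


def summarize_counts(calls: pd.DataFrame) -> dict:
    """Per-sample and cohort call counts by rarity path / specificity / extent."""
    per_sample: dict[str, dict] = {}
    if len(calls):
        for s, sub in calls.groupby("sample_id"):
            per_sample[str(s)] = {
                "n_calls": int(len(sub)),
                "by_path": sub["rarity_path"].value_counts().to_dict()
                if "rarity_path" in sub else {},
                "by_specificity": sub["allele_specificity"].value_counts().to_dict()
                if "allele_specificity" in sub else {},
                "by_extent": sub["extent"].value_counts().to_dict()
                if "extent" in sub else {},
            }
    n_unique = (int(calls.drop_duplicates(["chrom", "tile_start"]).shape[0])
                if len(calls) else 0)
    return {"per_sample": per_sample, "n_calls": int(len(calls)),
            "n_unique_tiles": n_unique}


def recovery_table(calls: pd.DataFrame, truth_events: pd.DataFrame,
                   tile_width: int = 200) -> pd.DataFrame:
    """Match calls against planted ground truth (per planted carrier copy).

    A planted (event, sample) copy is *recovered* when the sample has a call
    at a tile overlapping the event interval; ``correct_haplotype`` further
    requires a call in the planted phasing mode (any mode qualifies for
    biallelic events).
    """
    rows = []
    for ev in truth_events.itertuples(index=False):
        sub = calls[(calls["sample_id"] == ev.sample_id)
                    & (calls["chrom"] == ev.chrom)
                    & (calls["tile_start"] < ev.end)
                    & (calls["tile_start"] + tile_width > ev.start)]
        recovered = len(sub) > 0
        if ev.haplotype in ("hap1", "hap2"):
            correct = bool((sub["phasing_mode"] == ev.haplotype).any())
        else:
            correct = recovered
        rows.append({"event_id": ev.event_id, "sample_id": ev.sample_id,
                     "recovered": recovered, "correct_haplotype": correct})
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "recovered",
                                       "correct_haplotype"])


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(name)s %(levelname)s %(message)s")
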