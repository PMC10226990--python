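"""Synthetic cohorts with planted hypermethylation events and ground truth.

The generator emulates the statistical structure the outlier analysis
assumes, without simulating reads or chemistry:

* per CpG, per sample, per haplotype, a true methylation rate is drawn
  Beta(alpha, beta) — low-mean defaults mimic the hypomethylated regulatory
  regions where rare hypermethylation is visible;
* planted events shift the true rate toward 1 by ``effect_delta`` on the
  stated haplotype(s) over a genomic interval, optionally copied to a parent
  to model heritable epivariants;
* per-haplotype read coverage is Poisson(coverage_mean) and the observed
  methylation fraction is Binomial(coverage, rate)/coverage; the combined
  phasing mode sums the two haplotypes' reads;
* rare variants (planted cis variants at configured distances from events,
  plus background variants) come with MAF and haplotype labels; families are
  trios; regulatory elements, TSS/disease-gene annotations and allelic
  expression counts round out a complete input bundle.

Everything is keyed by a single seed: identical config -> byte-identical
bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methylout.methylation_io import (
    MethylationTable,
    read_cpg_pileup,
    write_cpg_pileup,
)

DHS_COMPONENTS = [
    "tissue_invariant", "lymphoid", "myeloid_erythroid", "placental",
    "cancer_epithelial", "digestive", "cardiac", "musculoskeletal",
    "neural", "organ_devel_renal", "pulmonary_devel", "renal_cancer",
    "stromal_a", "stromal_b", "vascular_endothelial", "primitive_embryonic",
]

HAPLOTYPES = ("hap1", "hap2", "both")
VARIANT_KINDS = ("SNV", "DEL", "INS", "DUP", "repeat-expansion")


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations (bad intervals, overlaps)."""


@dataclass
class PlantedEvent:
    """A ground-truth hypermethylation event assigned to specific samples."""

    event_id: str
    sample_ids: list[str]
    haplotype: str  # hap1 | hap2 | both
    chrom: str
    start: int  # 0-based half-open
    end: int
    effect_delta: float  # methylation-fraction shift toward 1, in (0, 1]
    heritable: bool = False

    def __post_init__(self) -> None:
        if self.haplotype not in HAPLOTYPES:
            raise ConfigurationError(f"bad haplotype {self.haplotype!r}")
        if not (0 < self.effect_delta <= 1):
            raise ConfigurationError("effect_delta must be in (0, 1]")
        if self.end <= self.start:
            raise ConfigurationError("empty event interval")


@dataclass
class PlantedVariant:
    """A ground-truth rare variant, optionally linked in cis to an event."""

    variant_id: str
    sample_id: str
    chrom: str
    pos: int  # 0-based
    kind: str
    maf: float
    haplotype: str  # hap1 | hap2
    linked_event_id: str | None = None
    length: int = 1  # bp footprint (SVs)

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ConfigurationError(f"bad variant kind {self.kind!r}")
        if not (0 <= self.maf < 1):
            raise ConfigurationError("maf must be in [0, 1)")


@dataclass
class CohortConfig:
    """Everything the generator needs; the seed fully determines the output."""

    n_samples: int = 50
    n_families: int = 10          # trios; remaining samples are singletons
    n_cpgs: int = 20000
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    baseline_alpha: float = 1.5   # Beta shape: mean 0.1, SD ~0.075
    baseline_beta: float = 13.5
    coverage_mean: float = 20.0   # reads per CpG per haplotype
    planted_events: list = field(default_factory=list)
    planted_variants: list = field(default_factory=list)
    background_variants_per_sample: int = 20  # ~1 rare variant / 50 kb
    background_variant_maf: float = 0.004
    n_regulatory_elements: int = 300
    re_width_range: tuple = (150, 1000)
    re_cover_planted_prob: float = 0.9
    tss_spacing: int = 10_000
    disease_gene_every: int = 5
    expression_depth: float = 200.0  # FLNC reads per informative transcript
    expression_minor_fraction: float = 0.1
    expression_promoter_window: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if 3 * self.n_families > self.n_samples:
            raise ConfigurationError("too many trio families for n_samples")
        for ev in self.planted_events:
            if ev.chrom not in self.chrom_lengths:
                raise ConfigurationError(f"{ev.event_id}: unknown chromosome")
            if ev.start < 0 or ev.end > self.chrom_lengths[ev.chrom]:
                raise ConfigurationError(f"{ev.event_id}: interval outside genome")
        seen: dict[tuple, list] = {}
        for ev in self.planted_events:
            haps = ("hap1", "hap2") if ev.haplotype == "both" else (ev.haplotype,)
            for s in ev.sample_ids:
                for h in haps:
                    for (c, a, b) in seen.get((s, h), []):
                        if c == ev.chrom and ev.start < b and a < ev.end:
                            raise ConfigurationError(
                                f"overlapping planted events on {s}/{h}")
                    seen.setdefault((s, h), []).append((ev.chrom, ev.start, ev.end))


@dataclass
class CohortBundle:
    """A complete synthetic cohort plus its ground-truth manifest."""

    config: CohortConfig
    samples: list[str]
    pedigree: pd.DataFrame
    cpg_positions: dict  # chrom -> np.ndarray of positions
    methylation: dict    # sample -> {phasing_mode -> MethylationTable}
    variants: pd.DataFrame
    regulatory: pd.DataFrame
    tss: pd.DataFrame
    disease_genes: pd.DataFrame
    expression: pd.DataFrame
    truth_events: pd.DataFrame
    truth_variants: pd.DataFrame


def _make_pedigree(config: CohortConfig) -> pd.DataFrame:
    rows = []
    s = 0
    for f in range(config.n_families):
        fam = f"F{f + 1:03d}"
        child, father, mother = (f"S{s + i + 1:03d}" for i in range(3))
        rows.append((fam, father, "0", "0", 1, 1))
        rows.append((fam, mother, "0", "0", 2, 1))
        rows.append((fam, child, father, mother, 1, 2))
        s += 3
    while s < config.n_samples:
        sid = f"S{s + 1:03d}"
        rows.append((f"F{config.n_families + (s - 3 * config.n_families) + 1:03d}",
                     sid, "0", "0", 1, 2))
        s += 1
    ped = pd.DataFrame(rows, columns=["family_id", "sample_id", "father_id",
                                      "mother_id", "sex", "phenotype"])
    # pedigree order: fathers/mothers inserted before child; reorder by id
    return ped.sort_values("sample_id").reset_index(drop=True)


def _place_cpgs(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Uniform CpG positions with minimum spacing 2 bp, per chromosome."""
    total = sum(config.chrom_lengths.values())
    out = {}
    for chrom, length in sorted(config.chrom_lengths.items()):
        n = int(round(config.n_cpgs * length / total))
        grid = length // 2
        if n > grid:
            raise ConfigurationError("too many CpGs for chromosome length")
        picks = rng.choice(grid, size=n, replace=False)
        out[chrom] = np.sort(picks) * 2
    return out


def _parent_of(pedigree: pd.DataFrame, sample: str, rng: np.random.Generator) -> str | None:
    row = pedigree[pedigree["sample_id"] == sample]
    if row.empty:
        return None
    father, mother = row["father_id"].iloc[0], row["mother_id"].iloc[0]
    parents = [p for p in (father, mother) if p != "0"]
    if not parents:
        return None
    return parents[int(rng.integers(len(parents)))]


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full synthetic cohort from a validated configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pedigree = _make_pedigree(config)
    samples = pedigree["sample_id"].tolist()
    cpgs = _place_cpgs(config, rng)

    # expand heritable events to one (seeded) parent per carrier child
    events: list[PlantedEvent] = []
    truth_rows = []
    for ev in config.planted_events:
        carriers = list(ev.sample_ids)
        if ev.heritable:
            for s in list(carriers):
                parent = _parent_of(pedigree, s, rng)
                if parent and parent not in carriers:
                    carriers.append(parent)
        expanded = dataclasses.replace(ev, sample_ids=carriers)
        events.append(expanded)
        for s in carriers:
            truth_rows.append({"event_id": ev.event_id, "sample_id": s,
                               "chrom": ev.chrom, "start": ev.start,
                               "end": ev.end, "haplotype": ev.haplotype,
                               "effect_delta": ev.effect_delta,
                               "heritable": ev.heritable,
                               "inherited_copy": s not in ev.sample_ids})
    truth_events = pd.DataFrame(
        truth_rows, columns=["event_id", "sample_id", "chrom", "start", "end",
                             "haplotype", "effect_delta", "heritable",
                             "inherited_copy"])

    sample_index = {s: i for i, s in enumerate(samples)}
    methylation: dict[str, dict[str, MethylationTable]] = {s: {} for s in samples}
    for chrom, pos in cpgs.items():
        n_cpg = len(pos)
        n = config.n_samples
        rates = rng.beta(config.baseline_alpha, config.baseline_beta,
                         size=(n, 2, n_cpg))
        for ev in events:
            if ev.chrom != chrom or len(ev.sample_ids) == 0:
                continue
            in_ev = (pos >= ev.start) & (pos < ev.end)
            if in_ev.sum() < 2:
                raise ConfigurationError(
                    f"{ev.event_id}: interval covers fewer than 2 CpGs")
            haps = (0, 1) if ev.haplotype == "both" else (0 if ev.haplotype == "hap1" else 1,)
            for s in ev.sample_ids:
                for h in (haps if isinstance(haps, tuple) else (haps,)):
                    rates[sample_index[s], h, in_ev] = np.minimum(
                        1.0, rates[sample_index[s], h, in_ev] + ev.effect_delta)
        cov = rng.poisson(config.coverage_mean, size=(n, 2, n_cpg))
        meth = rng.binomial(cov, rates)
        for s, i in sample_index.items():
            for h, mode in ((0, "hap1"), (1, "hap2")):
                c = cov[i, h]
                keep = c > 0
                frame = pd.DataFrame({
                    "chrom": chrom, "pos": pos[keep], "coverage": c[keep],
                    "meth_fraction": meth[i, h][keep] / c[keep]})
                _append_mode(methylation[s], s, mode, frame)
            c = cov[i, 0] + cov[i, 1]
            keep = c > 0
            frame = pd.DataFrame({
                "chrom": chrom, "pos": pos[keep], "coverage": c[keep],
                "meth_fraction": (meth[i, 0] + meth[i, 1])[keep] / c[keep]})
            _append_mode(methylation[s], s, "combined", frame)

    variants = _make_variants(config, events, samples, rng)
    truth_variants = variants[variants["planted"].astype(bool)].drop(
        columns=["planted"]).copy()
    regulatory = _make_regulatory(config, events, rng)
    tss, disease_genes = _make_genes(config)
    expression = _make_expression(config, events, tss, samples, rng)

    return CohortBundle(
        config=config, samples=samples, pedigree=pedigree, cpg_positions=cpgs,
        methylation=methylation, variants=variants.drop(columns=["planted"]),
        regulatory=regulatory, tss=tss, disease_genes=disease_genes,
        expression=expression, truth_events=truth_events,
        truth_variants=truth_variants)


def _append_mode(modes: dict, sample: str, mode: str, frame: pd.DataFrame) -> None:
    if mode in modes:
        frame = pd.concat([modes[mode].data.rename(columns={}), frame],
                          ignore_index=True)
    modes[mode] = MethylationTable(sample, mode, frame)


def _make_variants(config: CohortConfig, events: list[PlantedEvent],
                   samples: list[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    event_by_id = {ev.event_id: ev for ev in events}
    for pv in config.planted_variants:
        end = pv.pos + max(1, pv.length)
        rows.append({"variant_id": pv.variant_id, "sample_id": pv.sample_id,
                     "chrom": pv.chrom, "pos": pv.pos, "end": end,
                     "kind": pv.kind, "maf": pv.maf, "haplotype": pv.haplotype,
                     "linked_event_id": pv.linked_event_id, "planted": True})
    k = 0
    for s in samples:
        for chrom, length in sorted(config.chrom_lengths.items()):
            n_bg = config.background_variants_per_sample
            if n_bg == 0:
                continue
            pos = np.sort(rng.integers(0, length, size=n_bg))
            mafs = rng.uniform(0, config.background_variant_maf, size=n_bg)
            haps = rng.integers(1, 3, size=n_bg)
            for p, m, h in zip(pos, mafs, haps):
                k += 1
                rows.append({"variant_id": f"bg{k:06d}", "sample_id": s,
                             "chrom": chrom, "pos": int(p), "end": int(p) + 1,
                             "kind": "SNV", "maf": float(m),
                             "haplotype": f"hap{h}", "linked_event_id": None,
                             "planted": False})
    return pd.DataFrame(rows, columns=["variant_id", "sample_id", "chrom",
                                       "pos", "end", "kind", "maf",
                                       "haplotype", "linked_event_id",
                                       "planted"])


def place_cis_variant(event: PlantedEvent, sample_id: str, distance: int,
                      variant_id: str, maf: float = 0.001,
                      kind: str = "SNV") -> PlantedVariant:
    """Convenience: a rare variant ``distance`` bp downstream of an event,
    on the event's haplotype (hap1 when the event is biallelic)."""
    hap = event.haplotype if event.haplotype in ("hap1", "hap2") else "hap1"
    return PlantedVariant(
        variant_id=variant_id, sample_id=sample_id, chrom=event.chrom,
        pos=event.end - 1 + distance, kind=kind, maf=maf, haplotype=hap,
        linked_event_id=event.event_id)


def _make_regulatory(config: CohortConfig, events: list[PlantedEvent],
                     rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.re_width_range
    for chrom, length in sorted(config.chrom_lengths.items()):
        n = max(1, int(round(config.n_regulatory_elements * length
                             / sum(config.chrom_lengths.values()))))
        starts = np.sort(rng.integers(0, max(1, length - hi), size=n))
        widths = rng.integers(lo, hi + 1, size=n)
        comps = rng.choice(len(DHS_COMPONENTS), size=n)
        for st, w, ci in zip(starts, widths, comps):
            rows.append({"chrom": chrom, "start": int(st), "end": int(st + w),
                         "component": DHS_COMPONENTS[int(ci)]})
    for ev in events:
        if rng.random() < config.re_cover_planted_prob:
            pad = int(rng.integers(0, 100))
            rows.append({"chrom": ev.chrom, "start": max(0, ev.start - pad),
                         "end": ev.end + pad,
                         "component": DHS_COMPONENTS[int(rng.integers(len(DHS_COMPONENTS)))]})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "component"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _make_genes(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    tss_rows, dg_rows = [], []
    g = 0
    for chrom, length in sorted(config.chrom_lengths.items()):
        for pos in range(config.tss_spacing, length, config.tss_spacing):
            g += 1
            name = f"GENE{g:04d}"
            tss_rows.append({"chrom": chrom, "start": pos, "end": pos + 1,
                             "name": name})
            if g % config.disease_gene_every == 0:
                dg_rows.append({"chrom": chrom, "start": pos, "end": pos + 1,
                                "name": name})
    return (pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name"]),
            pd.DataFrame(dg_rows, columns=["chrom", "start", "end", "name"]))


def _make_expression(config: CohortConfig, events: list[PlantedEvent],
                     tss: pd.DataFrame, samples: list[str],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Allelic read counts at one heterozygous SNV per promoter-linked event.

    Carriers of an event within the promoter window of a TSS express the
    linked transcript with a silenced allele (minor fraction
    ``expression_minor_fraction``); all

    other samples serve as balanced controls (minor fraction 0.5).
    """
    rows = []
    w = config.expression_promoter_window
    for ev in events:
        near = tss[(tss["chrom"] == ev.chrom)
                   & (tss["start"] >= ev.start - w)
                   & (tss["start"] <= ev.end - 1 + w)]
        if near.empty:
            continue
        gene = near.iloc[0]
        snv_pos = int(gene["start"]) + 150
        for s in samples:
            depth = max(1, int(rng.poisson(config.expression_depth)))
            if s in ev.sample_ids:
                minor = config.expression_minor_fraction
                group = "carrier"
            else:
                minor = 0.5
                group = "control"
            n_alt = int(rng.binomial(depth, minor))
            rows.append({"sample": s, "region_id": gene["name"],
                         "chrom": ev.chrom, "pos": snv_pos, "ref": "A",
                         "alt": "G", "n_ref": depth - n_alt, "n_alt": n_alt,
                         "linked_tile_id": f"{ev.chrom}:{(ev.start // 200) * 200}",
                         "group": group, "event_id": ev.event_id})
    return pd.DataFrame(rows, columns=["sample", "region_id", "chrom", "pos",
                                       "ref", "alt", "n_ref", "n_alt",
                                       "linked_tile_id", "group", "event_id"])


# ---------------------------------------------------------------------------
# study-scale configuration factory

def make_study_config(seed: int = 0, n_samples: int = 50, n_families: int = 10,
                      n_cpgs: int = 20000, genome_bp: int = 1_000_000,
                      coverage_mean: float = 20.0, n_events: int = 30,
                      effect_delta: float = 0.5, event_width: int = 400,
                      haplotype: str = "random",
                      cis_variant_distance: int | None = 500,
                      heritable_fraction: float = 0.0,
                      n_promoter_events: int = 3) -> CohortConfig:
    """A ready-made cohort configuration at the scale used for validation.

    Plants ``n_events`` non-overlapping allele-specific events of
    ``event_width`` bp in distinct samples (haplotype drawn at random unless
    fixed), each optionally accompanied by a cis rare SNV at
    ``cis_variant_distance`` bp.  Defaults model a 50-sample cohort (10
    trios + 20 singletons) with 20k CpGs over 1 Mb at 20x per haplotype.
    """
    rng = np.random.default_rng(seed)
    config = CohortConfig(n_samples=n_samples, n_families=n_families,
                          n_cpgs=n_cpgs, chrom_lengths={"chr1": genome_bp},
                          coverage_mean=coverage_mean, seed=seed,
                          # keep the genome-wide rare-variant spacing (~1/50 kb)
                          background_variants_per_sample=max(5, genome_bp // 50_000))
    ped = _make_pedigree(config)
    samples = ped["sample_id"].tolist()
    children = set(ped.loc[ped["father_id"] != "0", "sample_id"])
    # non-overlapping event slots on a coarse grid, away from each other
    slot_w = genome_bp // max(1, n_events)
    if slot_w < 3 * event_width:
        raise ConfigurationError("genome too small for requested events")
    events, variants = [], []
    for i in range(n_events):
        start = i * slot_w + int(rng.integers(event_width, slot_w - 2 * event_width))
        if i < n_promoter_events:
            # anchor the first events on a TSS so allelic-expression
            # validation has promoter-linked ground truth
            tss = ((i * slot_w + event_width) // config.tss_spacing + 1) * config.tss_spacing
            if tss + event_width < (i + 1) * slot_w:
                start = max(i * slot_w, tss - event_width // 2)
        hap = haplotype
        if haplotype == "random":
            hap = "hap1" if rng.random() < 0.5 else "hap2"
        heritable = rng.random() < heritable_fraction
        carrier = samples[int(rng.integers(len(samples)))]
        if heritable:  # heritability only demonstrable for trio children
            carrier = sorted(children)[int(rng.integers(len(children)))]
        ev = PlantedEvent(event_id=f"ev{i + 1:03d}", sample_ids=[carrier],
                          haplotype=hap, chrom="chr1", start=start,
                          end=start + event_width, effect_delta=effect_delta,
                          heritable=heritable)
        events.append(ev)
        if cis_variant_distance is not None:
            variants.append(place_cis_variant(
                ev, carrier, cis_variant_distance, f"cis{i + 1:03d}"))
    config.planted_events = events
    config.planted_variants = variants
    return config


# ---------------------------------------------------------------------------
# serialization

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _write_vcf(variants: pd.DataFrame, sample: str, chrom_lengths: dict,
               path: Path) -> None:
    contigs = "".join(f"##contig=<ID={c},length={l}>\n"
                      for c, l in sorted(chrom_lengths.items()))
    lines = [VCF_HEADER.format(contigs=contigs, sample=sample)]
    sub = variants[variants["sample_id"] == sample].sort_values(["chrom", "pos"])
    for v in sub.itertuples(index=False):
        if v.kind == "SNV":
            ref, alt, info = "A", "G", f"MAF={v.maf:.6g}"
        else:
            svtype = "INS" if v.kind == "repeat-expansion" else v.kind
            ref, alt = "N", f"<{svtype}>"
            info = f"MAF={v.maf:.6g};SVTYPE={svtype};END={int(v.end)}"
        gt = "1|0" if v.haplotype == "hap1" else ("0|1" if v.haplotype == "hap2" else "0/1")
        lines.append(f"{v.chrom}\t{v.pos + 1}\t{v.variant_id}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gt}\n")
    path.write_text("".join(lines))


def write_bundle(bundle: CohortBundle, directory) -> dict:
    """Write the bundle as plain-text files; returns the path manifest.

    Layout: per-sample pileup TSVs (one per phasing mode), one VCF per
    sample, cohort.ped, regulatory_elements.bed, tss.bed, disease_genes.bed,
    expression_counts.tsv, truth_events.tsv / truth_variants.tsv and a
    config.json.  All files round-trip through the package readers.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"samples": bundle.samples, "pileups": {},
                                   "vcfs": {}}
    for s in bundle.samples:
        manifest["pileups"][s] = {}
        for mode, table in bundle.methylation[s].items():
            p = d / f"{s}.{mode}.pileup.tsv"
            write_cpg_pileup(table, p)
            manifest["pileups"][s][mode] = p.name
        vp = d / f"{s}.vcf"
        _write_vcf(bundle.variants, s, bundle.config.chrom_lengths, vp)
        manifest["vcfs"][s] = vp.name
    bundle.pedigree.to_csv(d / "cohort.ped", sep="\t", index=False, header=False)
    bundle.regulatory.to_csv(d / "regulatory_elements.bed", sep="\t",
                             index=False, header=False)
    bundle.tss.to_csv(d / "tss.bed", sep="\t", index=False, header=False)
    bundle.disease_genes.to_csv(d / "disease_genes.bed", sep="\t", index=False,
                                header=False)
    bundle.expression.to_csv(d / "expression_counts.tsv", sep="\t", index=False)
    bundle.truth_events.to_csv(d / "truth_events.tsv", sep="\t", index=False)
    bundle.truth_variants.to_csv(d / "truth_variants.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["planted_events"] = [dataclasses.asdict(e) for e in bundle.config.planted_events]
    cfg["planted_variants"] = [dataclasses.asdict(v) for v in bundle.config.planted_variants]
    (d / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_pedigree(path) -> pd.DataFrame:
    """Read a PED-like file (family, sample, father, mother, sex, phenotype)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["family_id", "sample_id", "father_id", "mother_id",
                            "sex", "phenotype"], dtype=str)
    return df


def read_bed(path, component: bool = False) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["component"] if component else ["name"])
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     dtype={"chrom": str})
    return df


def read_bundle_methylation(directory, min_coverage: int = 0) -> dict:
    """Read back all per-sample pileups written by :func:`write_bundle`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    out: dict[str, dict[str, MethylationTable]] = {}
    for s, modes in manifest["pileups"].items():
        out[s] = {}
        for mode, name in modes.items():
            out[s][mode] = read_cpg_pileup(d / name, min_coverage=min_coverage,
                                           sample_id=s, phasing_mode=mode)
    return out
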