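"""End-to-end pipeline driver: simulate -> detect -> aei -> stats -> mir.

A single config object holds every stage's parameters; a run manifest records
the config hash, input/output checksums and every sample exclusion so a run
can be replayed and verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd
import yaml

from . import circdetect, cohortstats, editidx, io, mirtools, synthgen

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            val = _from_mapping(f.type, val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    chrom_length: int = 60_000
    n_genes: int = 18
    circ_gene_fraction: float = 0.5
    n_per_group: int = 3
    regions: tuple = ("SN", "MTG", "AMG")
    conditions: tuple = ("CT", "PD")
    n_reads: int = 20_000
    read_len: int = 100
    error_rate: float = 0.002
    unspliced_fraction: float = 0.15
    editing_alpha: float = 2.0
    editing_beta: float = 48.0
    pd_circ_effect: float = 1.3         # PD multiplier on circ_fraction
    pd_editing_effect: float = 0.8      # PD multiplier on editing rates
    age_slope: float = 0.02             # per-year circ multiplier slope
    age_region: str = "SN"
    sample_sigma: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate out of range [0, 0.05)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass
class DetectConfig:
    anchor_len: int = 20
    max_span: int = 100_000
    breakpoint_ambiguity_max: int = 2
    require_gt_ag: bool = True
    max_mismatch_extend: int = 2
    min_support: int = 2
    min_detected: int = 0
    detected_unit: str = "junctions"    # 'junctions' | 'reads'
    tissue_min_reads: int = 5

    def params(self) -> circdetect.DetectParams:
        return circdetect.DetectParams(
            anchor_len=self.anchor_len, max_span=self.max_span,
            breakpoint_ambiguity_max=self.breakpoint_ambiguity_max,
            require_gt_ag=self.require_gt_ag,
            max_mismatch_extend=self.max_mismatch_extend)


@dataclass
class AeiConfig:
    windows: tuple = (1000, 5000, 10000)
    min_coverage: int = 1
    subtract_exons: bool = True


@dataclass
class StatsConfig:
    fdr: float = 0.05
    de_method: str = "t"
    celltype_fold: float = 10.0
    celltype_sd_mult: float = 5.0


@dataclass
class MirConfig:
    min_sites: int = 3


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    aei: AeiConfig = field(default_factory=AeiConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    mir: MirConfig = field(default_factory=MirConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        sub = {
            "simulate": SimulateConfig, "detect": DetectConfig,
            "aei": AeiConfig, "stats": StatsConfig, "mir": MirConfig,
        }
        kwargs: dict = {}
        for key, val in data.items():
            if key in sub:
                kwargs[key] = _from_mapping(sub[key], val or {})
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)   # stage -> {file: checksum}
    exclusions: dict = field(default_factory=dict)

    def record(self, stage: str, paths: dict) -> None:
        self.stages[stage] = {name: _sha256(p) for name, p in paths.items()}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute every stage in dependency order, writing all outputs to outdir."""
    from . import __version__

    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__)
    sc = config.simulate

    # --- simulate ---------------------------------------------------------
    gconf = synthgen.GenomeConfig(
        chrom_lengths=(sc.chrom_length,), n_genes=sc.n_genes,
        circ_gene_fraction=sc.circ_gene_fraction)
    genome = synthgen.build_genome(gconf, seed=config.seed)
    editing = synthgen.build_editing_model(
        genome, seed=config.seed + 1, alpha=sc.editing_alpha,
        beta=sc.editing_beta)
    design = synthgen.default_cohort_design(
        n_per_group=sc.n_per_group, regions=tuple(sc.regions),
        conditions=tuple(sc.conditions), seed=config.seed,
        effects={("condition", "PD"): synthgen.GroupEffect(
            circ=sc.pd_circ_effect, editing=sc.pd_editing_effect)},
        age_slope=sc.age_slope, age_region=sc.age_region,
        sample_sigma=sc.sample_sigma)
    cohort = synthgen.simulate_cohort(
        genome, design, editing=editing, n_reads=sc.n_reads,
        read_len=sc.read_len, error_rate=sc.error_rate,
        unspliced_fraction=sc.unspliced_fraction)

    genome_fa = os.path.join(outdir, "genome.fa")
    gtf = os.path.join(outdir, "genes.gtf")
    alu_bed = os.path.join(outdir, "alu.bed")
    meta_tsv = os.path.join(outdir, "meta.tsv")
    io.write_fasta(genome_fa, genome.chromosomes)
    io.write_gtf(gtf, genome.genes)
    io.write_alu_bed(alu_bed, genome.alus)
    io.write_meta(meta_tsv, design.samples)
    sample_paths = cohort.write(outdir)
    sim_files = {"genome.fa": genome_fa, "genes.gtf": gtf,
                 "alu.bed": alu_bed, "meta.tsv": meta_tsv}
    for sid, d in sample_paths.items():
        sim_files[f"{sid}.fastq"] = d["fastq"]
        sim_files[f"{sid}.truth.sam"] = d["sam"]
    manifest.record("simulate", sim_files)

    meta = io.read_meta(meta_tsv)

    # --- detect -----------------------------------------------------------
    try:
        matrix = circdetect.call_junctions(
            {sid: d["fastq"] for sid, d in sample_paths.items()},
            genome, config.detect.params(),
            min_support=config.detect.min_support, meta=meta)
        matrix = circdetect.qc_filter_samples(
            matrix, config.detect.min_detected, config.detect.detected_unit)
        matrix = circdetect.filter_by_tissue(
            matrix, meta, config.detect.tissue_min_reads)
    except Exception as exc:
        raise RuntimeError(f"stage 'detect' failed: {exc}") from exc
    excluded = [s for s in sample_paths if s not in matrix.counts.columns]
    manifest.exclusions["detect"] = {
        s: f"< {config.detect.min_detected} detected "
           f"{config.detect.detected_unit}" for s in excluded}
    counts_tsv = os.path.join(outdir, "counts.tsv")
    io.write_counts_tsv(counts_tsv, matrix)
    manifest.record("detect", {"counts.tsv": counts_tsv})

    # --- aei --------------------------------------------------------------
    try:
        rows = []
        for sid in matrix.counts.columns:
            pile = editidx.pileup_from_sam(sample_paths[sid]["sam"], genome)
            rep = editidx.regional_editing_report(
                pile, genome, genome.alus, genome.genes, matrix.junctions,
                windows=config.aei.windows,
                min_coverage=config.aei.min_coverage,
                subtract_exons=config.aei.subtract_exons)
            rep.insert(0, "sample_id", sid)
            rows.append(rep)
        aei_table = pd.concat(rows, ignore_index=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'aei' failed: {exc}") from exc
    aei_tsv = os.path.join(outdir, "aei.tsv")
    io.write_tsv(aei_tsv, aei_table)
    manifest.record("aei", {"aei.tsv": aei_tsv})

    # --- stats ------------------------------------------------------------
    try:
        totals = cohortstats.circ_totals_per_sample(
            matrix, mode="distinct", normalized=False)
        norm_reads = cohortstats.circ_totals_per_sample(
            matrix, mode="reads", normalized=True)
        aei_global = (
            aei_table[(aei_table.region_label == "global")
                      & (aei_table.mismatch == "A>G")]
            .set_index("sample_id")["index_percent"])

        comp_rows = []
        for region in sorted(meta.region.unique()):
            sel = [s for s in matrix.counts.columns
                   if meta.at[s, "region"] == region]
            conds = sorted(meta.loc[sel, "condition"].unique())
            if len(conds) != 2:
                continue
            g0 = [s for s in sel if meta.at[s, "condition"] == conds[0]]
            g1 = [s for s in sel if meta.at[s, "condition"] == conds[1]]
            if min(len(g0), len(g1)) < 2:
                continue
            for label, series, method in (
                    ("circ_totals", norm_reads, "t"),
                    ("aei_global", aei_global, "wilcoxon")):
                gc = cohortstats.two_group_test(
                    series[g0], series[g1], method=method,
                    feature=f"{label}:{region}",
                    group_a=conds[0], group_b=conds[1])
                comp_rows.append(vars(gc))
        comp = pd.DataFrame(comp_rows)
        if len(comp):
            comp["q_value"] = cohortstats.bh_adjust(comp["p_value"])

        corr_rows = []
        for region in sorted(meta.region.unique()):
            for cond in sorted(meta.condition.unique()):
                sel = [s for s in matrix.counts.columns
                       if meta.at[s, "region"] == region
                       and meta.at[s, "condition"] == cond]
                if len(sel) < 3:
                    continue
                cr = cohortstats.pearson_correlation(
                    meta.loc[sel, "age"], norm_reads[sel])
                corr_rows.append({"kind": "age_vs_circ", "region": region,
                                  "condition": cond, "r": cr.r,
                                  "p_value": cr.p_value, "n": cr.n})
        common = [s for s in matrix.counts.columns if s in aei_global.index]
        if len(common) >= 3:
            cr = cohortstats.pearson_correlation(
                aei_global[common], norm_reads[common])
            corr_rows.append({"kind": "aei_vs_circ", "region": "all",
                              "condition": "all", "r": cr.r,
                              "p_value": cr.p_value, "n": cr.n})
        corr = pd.DataFrame(corr_rows)

        expressed = matrix.tissue_expressed
        sharing = cohortstats.sharing_summary(expressed)
        share_rows = [{"cell": "+".join(sorted(k)), "count": v}
                      for k, v in sorted(sharing.cells.items(),
                                         key=lambda kv: sorted(kv[0]))]
        share = pd.DataFrame(share_rows)

        de = cohortstats.simple_de(matrix, meta, group_col="condition",
                                   method=config.stats.de_method)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
    totals_df = (totals.rename("total").to_frame()
                 .assign(normalized_reads=norm_reads)
                 .rename_axis("sample_id").reset_index())
    stats_files = {}
    for name, df in (("totals.tsv", totals_df),
                     ("comparisons.tsv", comp), ("correlations.tsv", corr),
                     ("sharing.tsv", share), ("de.tsv", de.reset_index())):
        p = os.path.join(outdir, name)
        io.write_tsv(p, df)
        stats_files[name] = p
    manifest.record("stats", stats_files)

    # --- mir --------------------------------------------------------------
    try:
        circle = mirtools.synthetic_circslc8a1()
        sites = mirtools.scan_seed_sites(circle, mirtools.MIR_128)
        site_rows = [{"target": "synthetic_circSLC8A1",
                      "mirna_id": mirtools.MIR_128.mirna_id,
                      "position": s.position, "site_class": s.site_class,
                      "spans_junction": s.spans_junction} for s in sites]
        for j in matrix.junctions:
            seq = genome.chromosomes[j.chrom][j.start:j.end]
            if j.strand == "-":
                from ._seq import revcomp
                seq = revcomp(seq)
            for s in mirtools.scan_seed_sites(seq, mirtools.MIR_128):
                site_rows.append({
                    "target": j.key,
                    "mirna_id": mirtools.MIR_128.mirna_id,
                    "position": s.position, "site_class": s.site_class,
                    "spans_junction": s.spans_junction})
        mir_df = pd.DataFrame(site_rows)
    except Exception as exc:
        raise RuntimeError(f"stage 'mir' failed: {exc}") from exc
    mir_tsv = os.path.join(outdir, "mir_sites.tsv")
    io.write_tsv(mir_tsv, mir_df)
    manifest.record("mir", {"mir_sites.tsv": mir_tsv})

    manifest.write(os.path.join(outdir, "manifest.json"))
    logger.info("pipeline complete: %d junctions, %d samples",
                len(matrix.junctions), matrix.counts.shape[1])
    return manifest
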