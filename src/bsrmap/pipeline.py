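"""End-to-end orchestration: simulate/read -> filter -> statistics ->
thresholds -> regions -> annotation, as one configured, reproducible run.

A run is described by a :class:`RunConfig` (typically loaded from YAML).
Input is either a two-bulk VCF or a simulation block; every stage's
parameters have documented defaults which are echoed into the run
manifest so no default is silent.  All randomness flows from the single
``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bsrmap import __version__ as _pkg_version
from bsrmap import annotation as ann
from bsrmap import bsa_stats, regions as regions_mod, thresholds as thr
from bsrmap import synthetic, variant_io


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    # input: either a VCF path or a simulation block
    vcf: str | None = None
    simulation: dict | None = None
    gff3: str | None = None
    cds_fasta: str | None = None
    term_map: str | None = None
    bulk_high: str = "bulk_high"
    bulk_low: str = "bulk_low"
    multiallelic: str = "drop"
    # hard filters
    qd_min: float = 4.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    gq_min: float = 20.0
    cluster_window: int = 4
    cluster_size: int = 3
    # marker filters
    depth_min: int = 10
    depth_max: int = 500
    index_low: float = 0.3
    index_high: float = 0.7
    # statistics
    half_width: float = 1_000_000.0
    smooth_delta: bool = True
    smooth_ed5: bool = True
    ed_mode: str = "frequency"
    # thresholds
    n_sims: int = 10_000
    levels: tuple[float, ...] = (0.95, 0.99)
    call_level: float = 0.95
    n_depth_grid: int = 6
    # regions
    merge_gap: int = 500_000
    min_methods: int = 3
    # run
    seed: int = 0
    outdir: str | None = None
    label: str = "run"
    plot: bool = True


@dataclass
class PipelineResult:
    """In-memory outputs of one run."""

    config: RunConfig
    markers_raw: pd.DataFrame
    markers: pd.DataFrame
    stats: pd.DataFrame
    threshold_tables: dict[str, thr.ThresholdTable]
    intervals: dict[float, dict[str, list]]
    candidate_regions: dict[float, list]
    hard_report: variant_io.FilterReport
    marker_report: variant_io.FilterReport
    truth: synthetic.SyntheticTruth | None = None
    genes_by_region: dict[float, list[list]] | None = None
    enrichment: list | None = None


def validate_config(config: dict | RunConfig) -> RunConfig:
    """Normalize a raw mapping into a :class:`RunConfig`.

    Fills documented defaults and raises :class:`ConfigError` listing one
    message per violation.
    """
    if isinstance(config, RunConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            raise ConfigError(
                [f"unknown config key: {k}" for k in sorted(unknown)])
        cfg = RunConfig(**config)
    errors = []
    if cfg.vcf is None and cfg.simulation is None:
        errors.append("either 'vcf' or a 'simulation' block is required")
    if cfg.vcf is not None and cfg.simulation is not None:
        errors.append("'vcf' and 'simulation' are mutually exclusive")
    if cfg.multiallelic not in ("drop", "split"):
        errors.append("multiallelic must be 'drop' or 'split'")
    if cfg.ed_mode not in ("frequency", "depth"):
        errors.append("ed_mode must be 'frequency' or 'depth'")
    if not 0 <= cfg.index_low < cfg.index_high <= 1:
        errors.append("need 0 <= index_low < index_high <= 1")
    if not 1 <= cfg.depth_min <= cfg.depth_max:
        errors.append("need 1 <= depth_min <= depth_max")
    if cfg.half_width <= 0:
        errors.append("half_width must be positive")
    if cfg.n_sims < 100:
        errors.append("n_sims must be >= 100")
    cfg.levels = tuple(sorted(float(lv) for lv in cfg.levels))
    if any(not 0 < lv < 1 for lv in cfg.levels):
        errors.append("levels must be in (0, 1)")
    if cfg.call_level not in cfg.levels:
        errors.append("call_level must be one of levels")
    if cfg.merge_gap < 0:
        errors.append("merge_gap must be >= 0")
    if not 1 <= cfg.min_methods <= 3:
        errors.append("min_methods must be in 1..3")
    if cfg.n_depth_grid < 1:
        errors.append("n_depth_grid must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def _simulate_markers(cfg: RunConfig):
    sim = dict(cfg.simulation or {})
    model = synthetic.PopulationModel(
        kind=sim.get("population", "F2"),
        n_per_bulk=int(sim.get("n_per_bulk", 42)),
        background_alt_freq=float(sim.get("background_alt_freq", 0.5)))
    qtls = [synthetic.QtlSpec(**q) for q in sim.get("qtls", [])]
    depth_model = synthetic.DepthModel(
        min_depth=int(sim.get("min_depth", 20)),
        max_depth=int(sim.get("max_depth", 100)),
        low_fraction=float(sim.get("low_depth_fraction", 0.0)),
        high_fraction=float(sim.get("high_depth_fraction", 0.0)))
    metrics = synthetic.SiteMetricModel(
        fail_fraction=float(sim.get("metric_fail_fraction", 0.0)))
    markers, truth = synthetic.generate_dataset(
        model=model, qtls=qtls,
        n_markers_per_lg=int(sim.get("n_markers_per_lg", 2000)),
        n_linkage_groups=int(sim.get("n_linkage_groups", 24)),
        depth_model=depth_model, seed=cfg.seed,
        lg_length=int(sim.get("lg_length", 25_000_000)),
        metrics=metrics,
        indel_fraction=float(sim.get("indel_fraction", 0.05)))
    return markers, truth, model


def _population_model(cfg: RunConfig) -> synthetic.PopulationModel:
    sim = dict(cfg.simulation or {})
    return synthetic.PopulationModel(
        kind=sim.get("population", "F2"),
        n_per_bulk=int(sim.get("n_per_bulk", 42)),
        background_alt_freq=float(sim.get("background_alt_freq", 0.5)))


def compute_thresholds(stats: pd.DataFrame, cfg: RunConfig,
                       model: synthetic.PopulationModel,
                       ) -> tuple[pd.DataFrame, dict[str, thr.ThresholdTable]]:
    """Simulated index bands, G' p/q values, and ED^5 quantiles.

    Returns the stats table with ``p_value``/``q_value`` columns added and
    the per-method threshold tables.  Index bands are simulated on an
    ``n_depth_grid``-point grid spanning the observed per-marker mean
    depths and interpolated linearly between grid points.
    """
    depth = 0.5 * (stats["ref_high"] + stats["alt_high"]
                   + stats["ref_low"] + stats["alt_low"]).to_numpy()
    lo, hi = int(np.floor(depth.min())), int(np.ceil(depth.max()))
    grid = np.unique(np.round(np.linspace(lo, hi, cfg.n_depth_grid))
                     .astype(int))
    band_table = thr.simulate_index_bands(
        model, grid, n_sims=cfg.n_sims, levels=cfg.levels, seed=cfg.seed + 1)
    stats = stats.copy()
    stats["p_value"] = thr.gprime_null_pvalues(stats["g_prime"].to_numpy())
    stats["q_value"] = thr.bh_fdr(stats["p_value"].to_numpy())
    ed5_col = "ed5_smooth" if "ed5_smooth" in stats else "ed5"
    ed5_table = thr.ed5_quantile_thresholds(stats[ed5_col].to_numpy(),
                                            levels=cfg.levels)
    tables = {"SNP_INDEX": band_table,
              "G_PRIME": thr.gprime_thresholds(cfg.levels),
              "ED5": ed5_table}
    return stats, tables


def run_core(markers: pd.DataFrame, cfg: RunConfig,
             model: synthetic.PopulationModel,
             truth: synthetic.SyntheticTruth | None = None,
             ) -> PipelineResult:
    """Filter -> statistics -> thresholds -> regions on an in-memory
    marker table (no file output); the workhorse behind
    :func:`run_pipeline`."""
    filtered, hard_report = variant_io.apply_hard_filters(
        markers, qd_min=cfg.qd_min, fs_max=cfg.fs_max, mq_min=cfg.mq_min,
        gq_min=cfg.gq_min, cluster_window=cfg.cluster_window,
        cluster_size=cfg.cluster_size, label=cfg.label)
    filtered, marker_report = variant_io.apply_marker_filters(
        filtered, depth_min=cfg.depth_min, depth_max=cfg.depth_max,
        index_low=cfg.index_low, index_high=cfg.index_high, label=cfg.label)
    if len(filtered) == 0:
        raise RuntimeError("stage marker_filters: no markers survived")

    stats = bsa_stats.compute_stats(
        filtered, half_width=cfg.half_width,
        smooth_delta=cfg.smooth_delta, smooth_ed5=cfg.smooth_ed5,
        ed_mode=cfg.ed_mode)
    stats, tables = compute_thresholds(stats, cfg, model)

    intervals: dict[float, dict[str, list]] = {}
    cand: dict[float, list] = {}
    for lv in cfg.levels:
        by_method = {
            m: regions_mod.call_method_intervals(
                stats, tables[m], m, level=lv, merge_gap=cfg.merge_gap)
            for m in regions_mod.METHODS}
        intervals[lv] = by_method
        cand[lv] = regions_mod.intersect_methods(
            by_method, min_methods=cfg.min_methods, stats=stats, level=lv)
    return PipelineResult(config=cfg, markers_raw=markers, markers=filtered,
                          stats=stats, threshold_tables=tables,
                          intervals=intervals, candidate_regions=cand,
                          hard_report=hard_report,
                          marker_report=marker_report, truth=truth)


def run_pipeline(config: dict | RunConfig) -> PipelineResult:
    """Execute a full configured run and write its outputs.

    Emits, under ``outdir`` (if set): the filtered marker TSV, per-marker
    statistics TSV, threshold tables (TSV + YAML metadata), per-method
    interval TSVs, the intersected candidate-region table and BED, filter
    reports, optional gene lists / effect calls / enrichment, Manhattan
    plots per statistic, and a manifest recording every parameter.
    """
    cfg = validate_config(config)
    if cfg.simulation is not None:
        markers, truth, model = _simulate_markers(cfg)
    else:
        records = variant_io.read_bulk_vcf(cfg.vcf, cfg.bulk_high,
                                           cfg.bulk_low,
                                           multiallelic=cfg.multiallelic)
        markers = variant_io.markers_to_frame(records)
        truth, model = None, _population_model(cfg)

    result = run_core(markers, cfg, model, truth=truth)
    result.genes_by_region, result.enrichment = _annotate(result, cfg)

    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _annotate(result: PipelineResult, cfg: RunConfig):
    if cfg.gff3 is None:
        return None, None
    genes = ann.read_gff3(cfg.gff3)
    genes_by_region = {
        lv: ann.genes_in_regions(genes, regs)
        for lv, regs in result.candidate_regions.items()}
    enrichment = None
    if cfg.term_map is not None:
        term_map = ann.read_term_map(cfg.term_map)
        background = [g.gene_id for g in genes]
        candidate = sorted({g.gene_id
                            for lists in genes_by_region[cfg.call_level]
                            for g in lists})
        if candidate:
            enrichment = ann.hypergeometric_enrichment(
                candidate, background, term_map)
    return genes_by_region, enrichment


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    from bsrmap import plots

    cfg = result.config
    outdir.mkdir(parents=True, exist_ok=True)
    result.markers.to_csv(outdir / "markers_filtered.tsv", sep="\t",
                          index=False)
    result.stats.to_csv(outdir / "stats.tsv", sep="\t", index=False)
    pd.concat([result.hard_report.to_frame(),
               result.marker_report.to_frame()]).to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False)
    meta = {}
    for name, table in result.threshold_tables.items():
        table.to_frame().to_csv(outdir / f"thresholds_{name}.tsv",
                                sep="\t", index=False)
        meta[name] = table.meta
    (outdir / "thresholds_meta.yaml").write_text(yaml.safe_dump(meta))
    for lv, by_method in result.intervals.items():
        for m, regs in by_method.items():
            regions_mod.region_table(regs, label=cfg.label).to_csv(
                outdir / f"intervals_{m}_{lv:g}.tsv", sep="\t", index=False)
    for lv, regs in result.candidate_regions.items():
        regions_mod.region_table(regs, label=cfg.label).to_csv(
            outdir / f"regions_{lv:g}.tsv", sep="\t", index=False)
        regions_mod.regions_to_bed(regs).to_csv(
            outdir / f"regions_{lv:g}.bed", sep="\t", index=False,
            header=False)
    if result.genes_by_region is not None:
        rows = []
        for lv, lists in result.genes_by_region.items():
            for region, genes in zip(result.candidate_regions[lv], lists):
                for g in genes:
                    rows.append({"level": lv,
                                 "linkage_group": region.linkage_group,
                                 "region_start": region.start,
                                 "region_end": region.end,
                                 "gene_id": g.gene_id})
        pd.DataFrame(rows).to_csv(outdir / "candidate_genes.tsv", sep="\t",
                                  index=False)
    if result.enrichment is not None:
        ann.enrichment_table(result.enrichment).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False)
    if cfg.plot:
        lv95, lv99 = (cfg.levels + cfg.levels)[:2]
        band = result.threshold_tables["SNP_INDEX"]
        mean_depth = float(0.5 * (
            result.stats["ref_high"] + result.stats["alt_high"]
            + result.stats["ref_low"] + result.stats["alt_low"]).mean())
        delta_col = ("delta_smooth" if "delta_smooth" in result.stats
                     else "delta_index")
        lines = {}
        for lv, color_label in ((lv95, "95%"), (lv99, "99%")):
            _, hi = band.delta_band(mean_depth, lv)
            lines[color_label] = float(hi)
        plots.manhattan(result.stats, delta_col,
                        outdir / "manhattan_delta_index.png", lines=lines,
                        title="Delta(SNP-index)")
        plots.manhattan(result.stats, "g_prime",
                        outdir / "manhattan_g_prime.png", title="G'")
        ed5 = result.threshold_tables["ED5"]
        ed5_col = "ed5_smooth" if "ed5_smooth" in result.stats else "ed5"
        plots.manhattan(result.stats, ed5_col,
                        outdir / "manhattan_ed5.png",
                        lines={f"{lv:g}": ed5.ed5_cutoff(lv)
                               for lv in cfg.levels},
                        title="ED^5")
    manifest = {"bsrmap_version": _pkg_version,
                "config": dataclasses.asdict(cfg)}
    manifest["config"]["levels"] = list(cfg.levels)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
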