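"""End-to-end orchestration: peaks -> annotation -> overlap -> expression.

``run_pipeline`` executes every stage from a single flat YAML config and
writes peak BEDs, annotated peak tables, bedGraph browser tracks, and one
machine-readable JSON run report whose every count can be reproduced by
re-running the named stage on the logged inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import build_index, read_gene_models, read_ncrnas
from .annotate import annotate_peaks, associate_ncrnas
from .config import PipelineConfig
from .expression import (
    ExpressionTable,
    GeneSet,
    classify_direct_targets,
    dependent_genes,
    intersect_sets,
)
from .overlap import location_distribution, merge_peaks, venn_counts
from .peaks import background_filter, call_peaks, estimate_fdr, write_peaks_bed
from .simulate import SimulationParams, simulate_expression, simulate_genome, simulate_tags
from .tags import norm_factor, read_tags, window_counts, write_bedgraph, write_tags

__all__ = ["RunReport", "run_pipeline", "export_browser_tracks"]


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str = __version__
    peak_counts: dict = field(default_factory=dict)
    fdr_estimates: dict = field(default_factory=dict)
    location_distributions: dict = field(default_factory=dict)
    venn: dict = field(default_factory=dict)
    ncrna: dict | None = None
    gene_sets: dict = field(default_factory=dict)
    intersections: dict = field(default_factory=dict)
    direct_targets: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "peak_counts": self.peak_counts,
            "fdr_estimates": self.fdr_estimates,
            "location_distributions": self.location_distributions,
            "venn": self.venn,
            "ncrna": self.ncrna,
            "gene_sets": self.gene_sets,
            "intersections": self.intersections,
            "direct_targets": self.direct_targets,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def _read_chrom_sizes(path: str | Path) -> dict:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> RunReport:
    """Execute every stage from one config; see the module docstring.

    The config either names input files (``inputs:`` block) or requests a
    full synthetic run (``simulate: true``), in which case the generated
    inputs are written alongside the outputs.
    """
    cfg = _load_config(config)
    constants = PipelineConfig.from_dict(cfg.get("constants", {}))
    seed = int(cfg.get("seed", constants.rng_seed))
    outdir = Path(outdir or cfg.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.get("simulate", False):
        sim_params = SimulationParams(**cfg.get("simulation", {}))
        simdir = outdir / "sim"
        genome = simulate_genome(sim_params, seed)
        paths = genome.write(simdir)
        factor_libs = {}
        for factor in sim_params.n_sites:
            lib = simulate_tags(genome.truth, sim_params, factor, seed)
            write_tags(lib, simdir / f"tags_{factor}.bed", sim_params.read_len)
            factor_libs[factor] = lib
        bg_lib = simulate_tags(genome.truth, sim_params, "SRF_KO", seed)
        write_tags(bg_lib, simdir / "tags_SRF_KO.bed", sim_params.read_len)
        expr = simulate_expression(genome.truth, sim_params, seed)
        expr.to_tsv(simdir / "expression.tsv")
        genes, ncrnas = genome.genes, genome.ncrnas
        chrom_sizes = genome.truth.chrom_sizes
        background_for = ["SRF"]
        kd_map = {"SRF": "SRF_kd", "MKL12": "MKL12_kd", "ELK4": "ELK4_kd"}
        ns_condition = "NS"
        peak_factor_of_kd = {"SRF": "SRF", "MKL12": "MKL1", "ELK4": "ELK4"}
    else:
        inputs = cfg.get("inputs", {})
        for key in ("genes", "factors"):
            if key not in inputs:
                raise ValueError(f"config inputs missing required key {key!r}")
        genes_path = Path(inputs["genes"])
        if not genes_path.exists():
            raise FileNotFoundError(f"gene annotation not found: {genes_path}")
        genes = read_gene_models(genes_path, inputs.get("genes_format", "bed12"))
        ncrnas = read_ncrnas(inputs["ncrnas"]) if inputs.get("ncrnas") else []
        factor_libs = {}
        for factor, path in inputs["factors"].items():
            if not Path(path).exists():
                raise FileNotFoundError(f"tag file for {factor} not found: {path}")
            factor_libs[factor] = read_tags(path, factor)
        bg_lib = read_tags(inputs["background"], "background") if inputs.get("background") else None
        expr = (
            ExpressionTable.from_tsv(inputs["expression"])
            if inputs.get("expression")
            else None
        )
        chrom_sizes = (
            _read_chrom_sizes(inputs["chrom_sizes"]) if inputs.get("chrom_sizes") else None
        )
        background_for = inputs.get("background_for", ["SRF"])
        kd_map = inputs.get("kd_conditions", {})
        ns_condition = inputs.get("ns_condition", "NS")
        peak_factor_of_kd = inputs.get("kd_peak_factors", {k: k for k in kd_map})

    report = RunReport(config=cfg, seed=seed)
    index = build_index(genes, ncrnas, constants.promoter_window)

    # --- peak calling per factor -------------------------------------------
    peaks_by_factor: dict[str, list] = {}
    tracks = {}
    bg_track = None
    bg_norm = None
    if bg_lib is not None:
        bg_track = window_counts(bg_lib, constants.window_size, constants.fragment_len, chrom_sizes)
        bg_norm = norm_factor(bg_lib.total_tags, constants.norm_target)
    for factor, lib in factor_libs.items():
        track = window_counts(lib, constants.window_size, constants.fragment_len, chrom_sizes)
        tracks[factor] = (track, lib)
        f = norm_factor(lib.total_tags, constants.norm_target)
        peaks = call_peaks(track, f, constants.peak_threshold, factor)
        if bg_track is not None and factor in background_for:
            peaks = background_filter(
                peaks, bg_track, bg_norm, constants.bg_ratio, constants.bg_pseudocount
            )
        peaks_by_factor[factor] = peaks
        report.peak_counts[factor] = len(peaks)
        if chrom_sizes is not None:
            report.fdr_estimates[factor] = estimate_fdr(
                lib,
                chrom_sizes,
                constants.peak_threshold,
                n_shuffles=int(cfg.get("n_shuffles", 5)),
                seed=seed,
                window_size=constants.window_size,
                fragment_len=constants.fragment_len,
                norm_target=constants.norm_target,
            )
        write_peaks_bed(peaks, outdir / f"peaks_{factor}.bed")

    # --- annotation + location distributions -------------------------------
    annotated = {}
    for factor, peaks in peaks_by_factor.items():
        table = annotate_peaks(peaks, index, constants.promoter_window)
        table.to_csv(outdir / f"annotated_{factor}.tsv", sep="\t", index=False)
        annotated[factor] = table
        counts, fractions = location_distribution(list(table["location"]))
        report.location_distributions[factor] = {"counts": counts, "fractions": fractions}

    # --- factor overlap ----------------------------------------------------
    if len(peaks_by_factor) >= 2:
        usable = {f: p for f, p in peaks_by_factor.items() if p}
        if 2 <= len(usable) <= 3:
            for ref in usable:
                report.venn[ref] = venn_counts(usable, ref).to_dict()

    # --- ncRNA association for intergenic SRF peaks -------------------------
    srf_label = "SRF" if "SRF" in peaks_by_factor else next(iter(peaks_by_factor), None)
    if srf_label is not None and ncrnas:
        table = annotated[srf_label]
        intergenic = [
            p
            for p, loc in zip(peaks_by_factor[srf_label], table["location"])
            if loc == "intergenic"
        ]
        rep = associate_ncrnas(intergenic, index, constants.ncrna_window)
        report.ncrna = rep.to_dict()

    # --- expression dependency ---------------------------------------------
    if expr is not None and kd_map:
        sets_down = {}
        for factor, cond in kd_map.items():
            down = dependent_genes(
                expr, cond, ns_condition, constants.fc_cutoff, "down", f"{factor}_down"
            )
            up = dependent_genes(
                expr, cond, ns_condition, constants.fc_cutoff, "up", f"{factor}_up"
            )
            sets_down[factor] = down
            report.gene_sets[f"{factor}_down"] = len(down)
            report.gene_sets[f"{factor}_up"] = len(up)
        if "SRF" in sets_down:
            for factor, gs in sets_down.items():
                if factor == "SRF":
                    continue
                inter = intersect_sets(sets_down["SRF"], gs)
                report.intersections[f"SRF&{factor}"] = len(inter)
        for factor, down in sets_down.items():
            pf = peak_factor_of_kd.get(factor)
            if pf not in annotated:
                continue
            peak_genes = GeneSet.from_symbols(
                f"{pf}_peak_genes",
                [g for g in annotated[pf]["gene"] if g != "."],
            )
            direct, indirect = classify_direct_targets(down, peak_genes)
            report.direct_targets[factor] = {
                "direct": len(direct),
                "indirect": len(indirect),
            }

    report.to_json(outdir / "run_report.json")
    export_browser_tracks(peaks_by_factor, {f: t for f, (t, _l) in tracks.items()},
                          {f: norm_factor(l.total_tags, constants.norm_target)
                           for f, (_t, l) in tracks.items()},
                          outdir / "browser")
    return report


def export_browser_tracks(
    peaks_by_factor: dict,
    tracks: dict,
    norm_factors: dict,
    outdir: str | Path,
) -> list[str]:
    """Write normalized bedGraph tracks and peak BEDs for genome-browser
    inspection; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for factor, track in tracks.items():
        p = outdir / f"{factor}.bedgraph"
        write_bedgraph(track, p, scale=norm_factors.get(factor, 1.0), name=f"{factor} normalized tags")
        written.append(str(p))
    for factor, peaks in peaks_by_factor.items():
        p = outdir / f"{factor}_peaks.bed"
        write_peaks_bed(peaks, p)
        written.append(str(p))
    return written
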