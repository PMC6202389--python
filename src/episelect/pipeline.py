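"""End-to-end pipeline runner with plain-file handoff between stages.

Stages run in dependency order: simulate (or load) -> coverage filter ->
MPD + DMC calling per genotype -> DMR consolidation + gene summaries ->
resampling enrichment -> GO grid.  Every stage writes TSV/JSON into the
output directory, so any stage can be re-run in isolation from its
persisted inputs; a manifest records parameters, seeds, and row counts.
A stage failure halts the run but keeps the partial outputs plus a
machine-readable error record.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dmc import dmc_table, merge_dmrs_by_chromosome
from .diversity import mpd_table
from .genomic_context import context_proportions, summarize_gene_dmcs
from .io import filter_by_coverage
from .resampling import colocalization_test, neighbor_distance_test
from .simulate import (GroundTruth, SimulationConfig, simulate_annotation,
                       simulate_methylomes)


@dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    min_avg_coverage: float = 5.0
    max_avg_coverage: float = 100.0
    dmr_min_dmc: int = 3
    dmr_max_gap: int = 100
    enrichment_draws: int = 500
    enrichment_seed: int = 7
    stages: tuple[str, ...] = ("simulate", "filter", "mpd", "dmc", "dmr",
                               "annotate", "enrich")


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.simulation.seed,
        "parameters": {
            "alpha": config.alpha,
            "coverage_band": [config.min_avg_coverage, config.max_avg_coverage],
            "dmr": [config.dmr_min_dmc, config.dmr_max_gap],
            "enrichment_draws": config.enrichment_draws,
            "enrichment_seed": config.enrichment_seed,
        },
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            record = _STAGES[stage](config, state, out)
            manifest["stages"][stage] = {"status": "complete", **record}
            _write_manifest(out, manifest)
    except Exception as exc:  # keep partial outputs + machine-readable error
        manifest["stages"][stage] = {
            "status": "failed", "error": str(exc),
            "traceback": traceback.format_exc(),
        }
        _write_manifest(out, manifest)
        raise
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_simulate(config, state, out):
    truth = GroundTruth()
    annotation = simulate_annotation(config.simulation)
    table, design, _ = simulate_methylomes(annotation, config.simulation, truth)
    state.update(annotation=annotation, table=table, design=design, truth=truth)
    annotation.to_gff3(out / "annotation.gff3")
    design.to_tsv(out / "design.tsv")
    truth.to_tsv(out / "truth_dmcs.tsv")
    config.simulation.to_yaml(out / "simulation.yaml")
    return {"n_sites": table.n_sites, "n_samples": len(table.samples)}


def _stage_filter(config, state, out):
    filtered = {}
    for g in state["design"].genotypes:
        filtered[g] = filter_by_coverage(
            state["table"], state["design"],
            config.min_avg_coverage, config.max_avg_coverage, genotype=g)
    state["filtered"] = filtered
    return {g: t.n_sites for g, t in filtered.items()}


def _stage_mpd(config, state, out):
    frames = []
    for g, t in state["filtered"].items():
        frames.append(mpd_table(t, state["design"].subset(g), genome_wide=True))
    mpd = pd.concat(frames, ignore_index=True)
    mpd.to_csv(out / "mpd.tsv", sep="\t", index=False)
    state["mpd"] = mpd
    return {"rows": len(mpd)}

def _stage_dmc(config, state, out):
    results = {}
    for g, t in state["filtered"].items():
        res = dmc_table(t, state["design"], genotype=g, alpha=config.alpha)
        res.to_csv(out / f"dmc_{g}.tsv", sep="\t", index=False)
        results[g] = res
    state["dmc"] = results
    return {g: int(r["is_dmc"].sum()) for g, r in results.items()}


def _stage_dmr(config, state, out):
    counts = {}
    state["dmr"] = {}
    for g, res in state["dmc"].items():
        dmrs = merge_dmrs_by_chromosome(res[res["is_dmc"]],
                                        config.dmr_min_dmc, config.dmr_max_gap)
        bed = dmrs.copy()
        if len(bed):
            bed["start"] -= 1  # BED half-open
        bed.to_csv(out / f"dmr_{g}.bed", sep="\t", index=False, header=False)
        state["dmr"][g] = dmrs
        counts[g] = len(dmrs)
    return counts


def _stage_annotate(config, state, out):
    summaries = {}
    for g, res in state["dmc"].items():
        dmcs = res[res["is_dmc"]]
        summary = summarize_gene_dmcs(dmcs, state["annotation"])
        summary.to_csv(out / f"gene_dmcs_{g}.tsv", sep="\t", index=False)
        summaries[g] = summary
    state["gene_summaries"] = summaries
    props = {g: context_proportions(res[res["is_dmc"]]) if res["is_dmc"].any() else None
             for g, res in state["dmc"].items()}
    return {g: len(s) for g, s in summaries.items()} | {"dmc_context": str(props)}


def _stage_enrich(config, state, out):
    report = {}
    sirna = state["annotation"].of_class("sirna_target")
    regions = sirna[["chrom", "start", "end"]]
    for g, res in state["dmc"].items():
        dmcs = res[res["is_dmc"]]
        tested = res[~res["skipped"]]
        entry = {}
        if len(dmcs) >= 2:
            test, _ = neighbor_distance_test(
                dmcs["pos"].to_numpy(), tested["pos"].to_numpy(),
                config.enrichment_draws, config.enrichment_seed)
            entry["neighbor_distance"] = test.to_dict()
            if len(regions):
                pair = colocalization_test(
                    dmcs, regions, tested, n_draws=config.enrichment_draws,
                    stratify_by=("context",), seed=config.enrichment_seed)
                entry["sirna_cooccurrence"] = pair["cooccurrence"].to_dict()
                entry["sirna_distance"] = pair["distance"].to_dict()
        report[g] = entry
    (out / "enrichment.json").write_text(json.dumps(report, indent=2))
    return {g: sorted(e) for g, e in report.items()}


_STAGES = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "mpd": _stage_mpd,
    "dmc": _stage_dmc,
    "dmr": _stage_dmr,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
}
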