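"""End-to-end orchestration: simulate -> normalize -> call -> merge ->
annotate -> overlap -> vst -> report.

Each stage is a thin wrapper over the library modules; ``run_pipeline``
chains them from a single config, writes every intermediate artifact as
TSV/JSON into the output directory, and returns the in-memory results.
The summary report only contains numbers that can be recomputed from the
emitted per-region files.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import calling, divergence, regions, simulate
from .errors import InputDataError, ParameterError
from .windows import (
    GenomeLayout,
    NormalizedDepthMatrix,
    make_window_grid,
    normalize_depth,
    read_depth_matrix,
    read_genome_layout,
    write_depth_matrix,
)

log = logging.getLogger("cnvpop.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "make_summary_report"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Unknown keys are rejected."""

    outdir: str = "cnvpop_out"
    seed: int = 0
    window_size: int = 800
    # inputs (ignored when simulate is on: the simulator writes them first)
    depth: str | None = None
    genome: str | None = None
    popmap: str | None = None
    gff3: str | None = None
    qtl_bed: str | None = None
    term_map: str | None = None
    external_bed: str | None = None
    simulate: dict[str, Any] | None = None
    calling: dict[str, Any] = dc_field(default_factory=dict)
    merging: dict[str, Any] = dc_field(default_factory=dict)
    annotation: dict[str, Any] = dc_field(default_factory=dict)
    divergence: dict[str, Any] = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise InputDataError(f"config field {name!r} is required but missing")


def _stage(name: str, **counts: Any) -> None:
    log.info("stage %s: %s", name, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns artifacts keyed by stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}

    # --- simulate (optional) ------------------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        genome_kw = {
            k: sim.pop(k)
            for k in ("n_chromosomes", "chrom_length", "n_genes", "n_qtls", "lengths")
            if k in sim
        }
        noise = sim.pop("noise", "poisson")
        mean_depth = sim.pop("mean_depth", 7.0)
        dispersion = sim.pop("dispersion", 0.1)
        genome, genes, qtls = simulate.simulate_genome(
            window_size=config.window_size, seed=config.seed, **genome_kw
        )
        grid = make_window_grid(genome, config.window_size)
        truth = simulate.simulate_populations(genome, grid, seed=config.seed + 1, **sim)
        raw = simulate.simulate_depth(
            truth, grid, mean_depth=mean_depth, noise=noise,
            dispersion=dispersion, seed=config.seed + 2,
        )
        config.depth = str(out / "depth.tsv")
        config.genome = str(out / "genome.tsv")
        config.popmap = str(out / "popmap.tsv")
        config.gff3 = str(out / "genes.gff3")
        config.qtl_bed = str(out / "qtls.bed")
        write_depth_matrix(raw, config.depth)
        with open(config.genome, "w") as fh:
            for name in genome.names:
                fh.write(f"{name}\t{genome.lengths[name]}\n")
        simulate.write_population_map(truth, config.popmap)
        simulate.write_gff3(genes, config.gff3)
        simulate.write_bed(qtls, config.qtl_bed)
        simulate.write_truth_bed(truth, out / "truth.bed")
        artifacts["truth"] = truth
        _stage("simulate", windows=grid.n_windows, planted=len(truth.regions))

    # --- normalize ----------------------------------------------------------
    config.require("depth", "genome", "popmap")
    genome = read_genome_layout(config.genome)
    grid = make_window_grid(genome, config.window_size)
    raw = read_depth_matrix(config.depth, grid)
    norm = normalize_depth(raw, config.calling.get("normalization", "global-median"))
    popmap = divergence.read_population_map(config.popmap)
    missing = [i for i in norm.individuals if i not in popmap]
    if missing:
        raise InputDataError(f"individuals missing from population map: {missing}")
    artifacts["norm"] = norm
    write_depth_matrix(norm, out / "normalized_depth.tsv")
    _stage("normalize", windows=grid.n_windows, individuals=len(norm.individuals))

    # --- call (per population and pooled) ----------------------------------
    params_kw = {
        k: v
        for k, v in config.calling.items()
        if k in calling.CallingParams.__dataclass_fields__
    }
    params = calling.CallingParams(**params_kw)
    states = calling.classify_windows(norm, params)
    exclude = calling.low_coverage_mask(raw, params.low_coverage_fraction)
    pops = sorted(set(popmap.values()))
    groups: dict[str, list[str]] = {
        p: [i for i in norm.individuals if popmap[i] == p] for p in pops
    }
    groups["ALL"] = list(norm.individuals)
    segments: dict[str, list[calling.CNVSegment]] = {}
    events: dict[str, list[calling.IndividualCNVEvent]] = {}
    for name, members in groups.items():
        cand = calling.candidate_windows(states, norm, params, members, exclude)
        segs = calling.merge_adjacent_windows(cand, norm, params.merge_alpha, members)
        segments[name] = segs
        events[name] = calling.call_individual_events(segs, norm, params, members)
        _stage(f"call[{name}]", candidates=len(cand), segments=len(segs),
               events=len(events[name]))
    event_rows = [
        {
            "group": g,
            "individual": e.individual,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "direction": e.direction_name,
            "mean_rd": e.mean_rd,
        }
        for g, evs in events.items()
        for e in evs
    ]
    events_df = pd.DataFrame(
        event_rows,
        columns=["group", "individual", "chrom", "start", "end", "direction", "mean_rd"],
    )
    events_df.to_csv(out / "events.tsv", sep="\t", index=False)
    artifacts.update(states=states, segments=segments, events=events,
                     events_df=events_df, params=params, popmap=popmap)

    # --- merge into CNVRs ---------------------------------------------------
    gap_fraction = config.merging.get("gap_fraction", 0.2)
    alpha = config.merging.get("alpha", 0.01)
    cnvrs: dict[str, list[regions.CNVR]] = {}
    for name, segs in segments.items():
        members = groups[name]
        cnvrs[name] = regions.merge_calls_to_cnvrs(
            segs, norm, gap_fraction, alpha,
            population=None if name == "ALL" else name, individuals=members,
        )
        _stage(f"merge[{name}]", cnvrs=len(cnvrs[name]))
    cnvr_frames = []
    for name, rs in cnvrs.items():
        tbl = regions.cnvr_table(rs)
        tbl.insert(0, "group", name)
        cnvr_frames.append(tbl)
    cnvrs_df = pd.concat(cnvr_frames, ignore_index=True) if cnvr_frames else pd.DataFrame()
    cnvrs_df.to_csv(out / "cnvrs.tsv", sep="\t", index=False)
    popsets = (
        regions.population_cnvr_sets({p: cnvrs[p] for p in pops})
        if len(pops) >= 2
        else None
    )
    artifacts.update(cnvrs=cnvrs, cnvrs_df=cnvrs_df, popsets=popsets)

    # --- annotate -----------------------------------------------------------
    union = cnvrs["ALL"]
    if config.gff3:
        genes = ann.read_gff3_genes(config.gff3)
        index = ann.GeneIndex(genes)
        min_fraction = config.annotation.get("min_fraction", 0.5)
        contexts = [
            ann.classify_genic_context((r.chrom, r.start, r.end), index) for r in union
        ]
        gene_hits = [
            [g.gene_id for g in ann.overlapping_genes((r.chrom, r.start, r.end), index, min_fraction)]
            for r in union
        ]
        ann_df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in union],
                "start": [r.start for r in union],
                "end": [r.end for r in union],
                "type": [r.cnvr_type for r in union],
                "context": [c.value for c in contexts],
                "genes": [",".join(g) or "." for g in gene_hits],
            }
        )
        ann_df.to_csv(out / "annotation.tsv", sep="\t", index=False)
        artifacts["annotation_df"] = ann_df
        if config.term_map:
            tmap = ann.read_term_map(config.term_map)
            hit_genes = sorted({g for gs in gene_hits for g in gs})
            background = sorted({g.gene_id for g in genes})
            enr = ann.enrichment_test(
                [g for g in hit_genes if g in set(background)], tmap, background
            )
            enr_df = pd.DataFrame([vars(r) for r in enr])
            enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            artifacts["enrichment"] = enr
        _stage("annotate", cnvrs=len(union), genic=sum(1 for c in contexts
               if c != ann.GenicContext.INTERGENIC))

    # --- overlap ------------------------------------------------------------
    if config.qtl_bed:
        qtls = ann.read_bed_intervals(config.qtl_bed)
        pairs, n_c, n_q = ann.qtl_overlap(union, qtls)
        pairs.to_csv(out / "qtl_overlap.tsv", sep="\t", index=False)
        artifacts["qtl_overlap"] = (pairs, n_c, n_q)
        _stage("overlap[qtl]", cnvrs=n_c, qtls=n_q)
    if config.external_bed:
        ext = ann.read_bed_intervals(config.external_bed)
        count, pct = ann.cross_study_overlap(union, ext)
        artifacts["cross_study"] = (count, pct)
        _stage("overlap[external]", count=count, percent=pct)

    # --- vst ----------------------------------------------------------------
    vst_kw = dict(
        value_mode=config.divergence.get("value_mode", "rd"),
        top_k=config.divergence.get("top_k", 5),
        top_fraction=config.divergence.get("top_fraction", 0.01),
    )
    vst_results: dict[tuple[str, str], divergence.VstScanResult] = {}
    for p1, p2 in itertools.combinations(pops, 2):
        res = divergence.vst_scan(union, norm, popmap, (p1, p2), **vst_kw)
        vst_results[(p1, p2)] = res
        res.as_table().to_csv(out / f"vst_{p1}_vs_{p2}.tsv", sep="\t", index=False)
        _stage(f"vst[{p1}-{p2}]", regions=len(res.records), mean=round(res.mean_vst, 4))
    artifacts["vst"] = vst_results

    # --- report -------------------------------------------------------------
    report = make_summary_report(
        genome=genome,
        popmap=popmap,
        events=events,
        cnvrs=cnvrs,
        popsets=popsets,
        qtl_overlap=artifacts.get("qtl_overlap"),
        cross_study=artifacts.get("cross_study"),
        vst_results=vst_results,
        annotation_df=artifacts.get("annotation_df"),
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    artifacts["report"] = report
    _stage("report", sections=len(report))
    return artifacts


def _event_summary(events: Mapping[str, Sequence[calling.IndividualCNVEvent]]) -> list[dict]:
    rows = []
    for group in sorted(events):
        evs = events[group]
        total_bp = sum(e.length for e in evs)
        rows.append(
            {
                "group": group,
                "count": len(evs),
                "duplication": sum(1 for e in evs if e.direction == calling.GAIN),
                "deletion": sum(1 for e in evs if e.direction == calling.LOSS),
                "total_length_mb": round(total_bp / 1e6, 4),
                "mean_length_kb": round(total_bp / len(evs) / 1e3, 2) if evs else 0.0,
            }
        )
    return rows


def _cnvr_summary(
    cnvrs: Mapping[str, Sequence[regions.CNVR]], genome: GenomeLayout
) -> list[dict]:
    rows = []
    for group in sorted(cnvrs):
        rs = cnvrs[group]
        total_bp = sum(r.length for r in rs)
        rows.append(
            {
                "group": group,
                "count": len(rs),
                "duplication": sum(1 for r in rs if r.cnvr_type == "GAIN"),
                "deletion": sum(1 for r in rs if r.cnvr_type == "LOSS"),
                "both": sum(1 for r in rs if r.cnvr_type == "BOTH"),
                "total_length_mb": round(total_bp / 1e6, 4),
                "mean_length_kb": round(total_bp / len(rs) / 1e3, 2) if rs else 0.0,
                "genome_fraction_pct": round(total_bp / genome.total_length * 100, 2),
            }
        )
    return rows


def make_summary_report(
    genome: GenomeLayout,
    popmap: Mapping[str, str],
    events: Mapping[str, Sequence[calling.IndividualCNVEvent]],
    cnvrs: Mapping[str, Sequence[regions.CNVR]],
    popsets: regions.PopulationSetResult | None,
    qtl_overlap: tuple | None = None,
    cross_study: tuple[int, float] | None = None,
    vst_results: Mapping[tuple[str, str], divergence.VstScanResult] | None = None,
    annotation_df: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Tables-style summary; every number is recomputable from the artifacts."""
    report: dict[str, Any] = {
        "events": _event_summary(events),
        "cnvrs": _cnvr_summary(cnvrs, genome),
    }
    union = list(cnvrs.get("ALL", []))
    if union:
        report["cnvr_size_bins"] = {
            k: round(v, 4)
            for k, v in regions.summarize_sizes(
                [r.length for r in union], regions.CNVR_SIZE_BINS_KB
            ).items()
        }
        per_chrom = {c: 0 for c in genome.names}
        for r in union:
            per_chrom[r.chrom] += 1
        report["cnvrs_per_chromosome"] = per_chrom
        if len(genome) >= 3 and np.ptp([genome.lengths[c] for c in genome.names]) > 0:
            slope, intercept, r2 = regions.chromosome_count_regression(
                per_chrom, genome.lengths
            )
            report["chromosome_count_regression"] = {
                "slope": slope,
                "intercept": intercept,
                "r_squared": round(r2, 4),
            }
    else:
        report["no_regions"] = True
    all_events = [e for evs in events.values() for e in evs]
    if all_events:
        report["event_size_bins"] = {
            k: round(v, 4)
            for k, v in regions.summarize_sizes(
                [e.length for e in all_events], regions.CNV_SIZE_BINS_KB
            ).items()
        }
    if popsets is not None:
        report["venn"] = {"+".join(k): v for k, v in sorted(popsets.venn.items())}
        report["n_union_regions"] = popsets.n_union
    if qtl_overlap is not None:
        _, n_c, n_q = qtl_overlap
        report["qtl_overlap"] = {"n_cnvrs": n_c, "n_qtls": n_q}
    if cross_study is not None:
        report["cross_study_overlap"] = {
            "count": cross_study[0],
            "percent": cross_study[1],
        }
    if vst_results:
        report["vst"] = {
            f"{p1}_vs_{p2}": {
                "mean_vst": round(res.mean_vst, 4),
                "top": [
                    {
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "vst": round(r.vst, 4),
                    }
                    for r in res.top_k
                ],
            }
            for (p1, p2), res in vst_results.items()
        }
    if annotation_df is not None and len(annotation_df):
        report["genic_context_counts"] = (
            annotation_df["context"].value_counts().to_dict()
        )
    report["populations"] = sorted(set(popmap.values()))
    return report
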