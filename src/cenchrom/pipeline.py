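"""End-to-end pipeline orchestration from a single declarative config.

A run executes the requested stages in dependency order — simulate (or load
inputs) → call CDRs → learn fiber thresholds → co-occupancy → dosage →
remodeling against a second condition — and writes every output next to a
manifest entry recording parameters, package version, and seed. The same
config and seed always produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .cdr import PRESETS, CdrCallerConfig, call_subcdrs, summarize_cdr
from .dosage import haplotype_dosage_metrics
from .fiber import (
    FiberConfig,
    cooccupancy_analysis,
    learn_density_threshold,
    read_region_density,
    sample_background_windows,
)
from .io import (
    GenomicInterval,
    load_intervals_bed,
    load_methylation_bedgraph,
    load_read_records,
    write_intervals_bed,
    write_methylation_bedgraph,
    write_read_records,
)
from .remodeling import display_round, match_subcdr_sets, remodeling_summary
from .synthetic import (
    ArraySpec,
    PlantedDomain,
    ReadModel,
    generate_methylation_track,
    generate_read_set,
    ipsc_array_spec,
    random_domain_layout,
)

import numpy as np


class StageError(RuntimeError):
    pass


def _cdr_config(cfg: dict) -> CdrCallerConfig:
    preset = cfg.get("preset", "ipsc")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return PRESETS[preset](**cfg.get("overrides", {}))


def simulate_fixture(outdir: Path, seed: int, cfg: Optional[dict] = None) -> dict:
    """Write a self-contained synthetic fixture (bedGraph, truth BED, reads)."""
    cfg = cfg or {}
    rng = np.random.default_rng(seed)
    preset = cfg.get("preset", "lcl")
    spec_kwargs = {
        k: cfg[k]
        for k in ("contig_name", "length_bp", "cpg_spacing_bp", "noise_sd_pct")
        if k in cfg
    }
    spec = ipsc_array_spec(**spec_kwargs) if preset == "ipsc" else ArraySpec(**spec_kwargs)
    depth_range = (25.0, 30.0) if preset == "ipsc" else (35.0, 50.0)
    domains = random_domain_layout(spec, rng, depth_range=depth_range)
    track = generate_methylation_track(spec, domains, seed)
    model = ReadModel(**cfg.get("read_model", {}))
    reads = generate_read_set(track, domains, model, cfg.get("n_reads", 300), seed + 1)

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bedgraph": outdir / "methylation.bedgraph",
        "truth_bed": outdir / "planted_domains.bed",
        "reads": outdir / "reads.tsv",
        "array_bed": outdir / "array.bed",
    }
    write_methylation_bedgraph([track], paths["bedgraph"])
    write_intervals_bed(
        [
            GenomicInterval(
                spec.contig_name,
                d.start,
                d.end,
                name="cenpa" if d.cenpa_enriched else "planted",
                score=d.dip_depth_pct,
            )
            for d in domains
        ],
        paths["truth_bed"],
    )
    write_read_records(reads, paths["reads"])
    write_intervals_bed([spec.interval()], paths["array_bed"])
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }

    # --- inputs: simulate or load -----------------------------------------
    if "simulate" in config:
        inputs = simulate_fixture(outdir / "fixture", seed, config["simulate"])
        manifest["stages"]["simulate"] = {"outputs": inputs}
    elif "inputs" in config:
        inputs = dict(config["inputs"])
    else:
        raise StageError("pipeline needs either a 'simulate' block or an 'inputs' block")

    stages = config.get("stages", ["call_cdr", "thresholds", "cooccupancy", "dosage"])

    tracks = load_methylation_bedgraph(inputs["bedgraph"])
    arrays = (
        {a.contig: a for a in load_intervals_bed(inputs["array_bed"])}
        if inputs.get("array_bed")
        else {}
    )

    subcdr_sets = {}
    if "call_cdr" in stages:
        cdr_cfg = _cdr_config(config.get("cdr", {}))
        out_bed = outdir / "subcdrs.bed"
        all_domains = []
        for contig, track in sorted(tracks.items()):
            sset = call_subcdrs(track, arrays.get(contig), cdr_cfg)
            subcdr_sets[contig] = sset
            all_domains.extend(sset.intervals())
        write_intervals_bed(all_domains, out_bed)
        manifest["stages"]["call_cdr"] = {
            "outputs": {"subcdrs": str(out_bed)},
            "params": asdict(cdr_cfg),
            "summary": {
                c: summarize_cdr(s, tier_filter=None) for c, s in sorted(subcdr_sets.items())
            },
        }

    reads = None
    fiber_cfg = FiberConfig(**config.get("fiber", {}))
    models = {}
    if "thresholds" in stages:
        if not subcdr_sets:
            raise StageError("stage 'thresholds' requires stage 'call_cdr' output")
        if "reads" not in inputs:
            raise StageError("stage 'thresholds' requires a reads input")
        reads = load_read_records(inputs["reads"])
        rows = []
        for mod in ("6mA", "5mC"):
            cdr_d, bg_d = [], []
            for contig, sset in sorted(subcdr_sets.items()):
                array = arrays.get(contig) or GenomicInterval(
                    contig, 0, int(tracks[contig].positions[-1]) + 1
                )
                bg_windows = sample_background_windows(
                    array, sset.intervals(), fiber_cfg, seed
                )
                for read in reads:
                    if read.contig != contig:
                        continue
                    for region in sset.intervals():
                        d = read_region_density(read, region, mod, fiber_cfg)
                        if d is not None:
                            cdr_d.append(d.density)
                    for region in bg_windows:
                        d = read_region_density(read, region, mod, fiber_cfg)
                        if d is not None:
                            bg_d.append(d.density)
            model = learn_density_threshold(cdr_d, bg_d, mod_type=mod)
            models[mod] = model
            rows.append(asdict(model))
        out_tsv = outdir / "thresholds.tsv"
        _write_tsv(out_tsv, rows)
        manifest["stages"]["thresholds"] = {
            "outputs": {"thresholds": str(out_tsv)},
            "params": asdict(fiber_cfg),
        }

    if "cooccupancy" in stages:
        if not models:
            raise StageError("stage 'cooccupancy' requires stage 'thresholds' output")
        all_subcdrs = [iv for s in subcdr_sets.values() for iv in s.intervals()]
        summary = cooccupancy_analysis(reads, all_subcdrs, models["6mA"], models["5mC"], fiber_cfg)
        out = outdir / "cooccupancy.tsv"
        _write_tsv(
            out,
            [
                {
                    "n_reads": summary.n_reads,
                    "n_overlapping": summary.n_overlapping,
                    "n_spanning_2plus": summary.n_spanning_2plus,
                    "frac_mcpg_depleted_all": summary.frac_mcpg_depleted_all,
                    "frac_cenpa_multi": summary.frac_cenpa_multi,
                }
            ],
        )
        manifest["stages"]["cooccupancy"] = {"outputs": {"summary": str(out)}}

    if "dosage" in stages:
        if not subcdr_sets:
            raise StageError("stage 'dosage' requires stage 'call_cdr' output")
        if reads is None:
            if "reads" not in inputs:
                raise StageError("stage 'dosage' requires a reads input")
            reads = load_read_records(inputs["reads"])
        metrics = haplotype_dosage_metrics(reads, list(subcdr_sets.values()), "6mA", fiber_cfg)
        out = outdir / "dosage.tsv"
        _write_tsv(
            out,
            [
                {
                    "chromosome": m.chromosome,
                    "haplotype": m.haplotype,
                    "mean_density": m.mean_density,
                    "aggregate_length_bp": m.aggregate_length_bp,
                    "dosage_proxy": m.dosage_proxy,
                }
                for m in metrics
            ],
        )
        manifest["stages"]["dosage"] = {"outputs": {"metrics": str(out)}}

    if "remodel" in stages:
        if "condition_b" not in config:
            raise StageError("stage 'remodel' requires a 'condition_b' block")
        b_bed = config["condition_b"].get("subcdrs_bed")
        if b_bed:
            b_domains = load_intervals_bed(b_bed)
        else:
            b_tracks = load_methylation_bedgraph(config["condition_b"]["bedgraph"])
            cdr_cfg = _cdr_config(config.get("cdr", {}))
            b_domains = []
            for contig, track in sorted(b_tracks.items()):
                b_domains.extend(call_subcdrs(track, arrays.get(contig), cdr_cfg).intervals())
        if not subcdr_sets:
            raise StageError("stage 'remodel' requires stage 'call_cdr' output")
        rows = []
        for contig, sset in sorted(subcdr_sets.items()):
            report = match_subcdr_sets(
                sset.intervals(), [d for d in b_domains if d.contig == contig]
            )
            summary = display_round(remodeling_summary(report))
            rows.append({"contig": contig, **report.counts(), **summary})
        out = outdir / "remodeling.tsv"
        _write_tsv(out, rows)
        manifest["stages"]["remodel"] = {"outputs": {"report": str(out)}}

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _write_tsv(path, rows: list[dict]) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("\n")
            return
        keys = list(rows[0])
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[k]) for k in keys) + "\n")


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
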