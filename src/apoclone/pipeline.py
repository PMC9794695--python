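"""End-to-end stage drivers: simulation of a study-like dataset and the
select-markers -> landscape -> crossovers -> clonality -> summarize chain."""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import vcfio
from .clonality import assess_clonality, summarize_event
from .config import RunConfig, stage_seed
from .core import ChromosomeMap, Haplotype, ObservationMatrix, ProgenyGenome
from .flow import call_ploidy
from .landscape import build_landscape, consolidate, detect_crossovers, make_windows
from .markers import select_informative_markers, sites_in_masks
from .simulate import (FlowSimConfig, ReproductionConfig, SeqSimConfig,
                       endosperm_cvalue_mix, make_f1, make_marker_map,
                       marker_density_counts, simulate_flow_histogram,
                       simulate_observations, simulate_progeny,
                       PARENT_MEAN_DEPTH)

log = logging.getLogger("apoclone")

LEAF_G2_FRACTION = 0.15  # G2/M share of leaf nuclei in simulated histograms


def _homozygous_parent(markers, origin: int) -> ProgenyGenome:
    hap = Haplotype(
        origins={c: np.full(len(markers.positions_for(c)), origin, dtype=np.int8)
                 for c in markers.chrom_map.names},
        breakpoints={c: np.empty(0, dtype=np.int64) for c in markers.chrom_map.names},
    )
    return ProgenyGenome(ploidy=2, haplotypes=[hap, hap], mode_of_origin="SEXUAL")


def simulate_study(outdir, mode: str = "MIME_BBM1", n: int = 24, p: float = 0.95,
                   depth: float = 1.9, error: float = 0.002, seed: int = 0,
                   chrom_scale: float = 0.02, markers_per_mb: float = 718.0,
                   fc: FlowSimConfig = FlowSimConfig()) -> dict:
    """Simulate a full study-like dataset and write it to ``outdir``.

    Produces parents (two replicates each) and F1 (two replicates) at 14.3x,
    ``n`` progeny at ``depth``x, per-progeny leaf flow histograms, a truth
    table, and a ready-to-run pipeline config.  ``chrom_scale`` shrinks the
    rice chromosomes so the default dataset stays desk-sized.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(stage_seed(seed, "simulate"))
    chrom_map = ChromosomeMap.rice(scale=chrom_scale)
    markers = make_marker_map(chrom_map, marker_density_counts(chrom_map, markers_per_mb), rng)
    f1 = make_f1(markers)
    rc = ReproductionConfig(mode=mode, parthenogenesis_rate=p)
    progeny = simulate_progeny(f1, markers, rc, n, rng)

    parent_genomes = [_homozygous_parent(markers, 0)] * 2 + \
                     [_homozygous_parent(markers, 1)] * 2 + [f1] * 2
    parent_ids = ["P1_1", "P1_2", "P2_1", "P2_2", "F1_1", "F1_2"]
    progeny_ids = [f"T1_{i + 1:03d}" for i in range(n)]
    obs_parents = simulate_observations(parent_genomes, markers,
                                        SeqSimConfig(PARENT_MEAN_DEPTH, error), rng,
                                        parent_ids)
    obs_progeny = simulate_observations(progeny, markers,
                                        SeqSimConfig(depth, error), rng, progeny_ids)
    obs = ObservationMatrix(
        sample_ids=parent_ids + progeny_ids,
        reads_p1=np.vstack([obs_parents.reads_p1, obs_progeny.reads_p1]),
        reads_p2=np.vstack([obs_parents.reads_p2, obs_progeny.reads_p2]),
    )

    manifest = pd.DataFrame({
        "sample_id": parent_ids + progeny_ids,
        "role": ["P1", "P1", "P2", "P2", "F1", "F1"] + ["PROGENY"] * n,
        "replicate": [1, 2, 1, 2, 1, 2] + [1] * n,
        "generation": ["P"] * 4 + ["F1"] * 2 + ["T1"] * n,
        "event": ["-"] * 6 + ["sim_event"] * n,
    })

    prov = dict(seed=seed, mode=mode, n=n, p=p, depth=depth, error=error)
    vcfio.write_chrom_table(outdir / "chroms.tsv", chrom_map, **prov)
    vcfio.write_manifest(outdir / "manifest.tsv", manifest, **prov)
    vcfio.write_marker_tsv(outdir / "markers_true.tsv", markers, **prov)
    vcfio.write_observations_vcf(outdir / "observations.vcf", markers, obs, **prov)
    vcfio.write_truth_tsv(outdir / "truth.tsv", parent_ids + progeny_ids,
                          parent_genomes + progeny, **prov)

    hist_dir = outdir / "histograms"
    control_channel = 2.0 * fc.channels_per_c
    flow_rng = np.random.default_rng(stage_seed(seed, "flow"))
    for sid, genome in zip(progeny_ids, progeny):
        g1_c = genome.ploidy  # 2C for diploids, 4C for tetraploids
        mix = [(g1_c, 1.0 - LEAF_G2_FRACTION), (2 * g1_c, LEAF_G2_FRACTION)]
        hist = simulate_flow_histogram(mix, fc, flow_rng)
        vcfio.write_histogram_tsv(hist_dir / f"{sid}.tsv", hist, **prov)
    endo_hist = simulate_flow_histogram(endosperm_cvalue_mix(mode), fc, flow_rng)
    vcfio.write_histogram_tsv(hist_dir / "endosperm.tsv", endo_hist, **prov)

    config_text = f"""\
seed: {seed}
output_dir: {outdir.as_posix()}/pipeline_out
vcf: {(outdir / 'observations.vcf').as_posix()}
manifest: {(outdir / 'manifest.tsv').as_posix()}
chrom_table: {(outdir / 'chroms.tsv').as_posix()}
histograms_dir: {hist_dir.as_posix()}
control_2c_channel: {control_channel}
"""
    (outdir / "demo.yaml").write_text(config_text)
    return {"outdir": outdir, "markers": markers, "manifest": manifest,
            "progeny": progeny, "config": outdir / "demo.yaml"}


def run_select_markers(cfg: RunConfig) -> dict:
    cfg.require_paths("vcf", "manifest")
    out = Path(cfg.output_dir)
    manifest = vcfio.read_manifest(cfg.manifest)
    obs, sites = vcfio.read_vcf_observations(cfg.vcf)
    keep = np.ones(len(sites), dtype=bool)
    if cfg.masks:
        cfg.require_paths("masks")
        masks = vcfio.read_masks_bed(cfg.masks)
        keep = ~sites_in_masks(sites, masks, cfg.marker_filter.mask_flank)
        log.info("masks removed %d of %d candidate sites", int((~keep).sum()), len(sites))

    def reps_for(role: str) -> np.ndarray:
        ids = manifest.loc[manifest["role"] == role, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"manifest contains no {role} samples")
        rows = [obs.sample_ids.index(s) for s in ids]
        return np.stack([np.stack([obs.reads_p1[r][keep], obs.reads_p2[r][keep]], axis=1)
                         for r in rows])

    chrom_map = vcfio.read_chrom_table(cfg.chrom_table) if cfg.chrom_table else None
    markers, audit = select_informative_markers(
        reps_for("P1"), reps_for("P2"), reps_for("F1"),
        sites.loc[keep].reset_index(drop=True),
        cfg.marker_filter, chrom_map)
    log.info("kept %d of %d unmasked candidate sites as markers",
             markers.n_markers, int(keep.sum()))
    vcfio.write_marker_tsv(out / "markers.tsv", markers, seed=cfg.seed)
    vcfio._write_tsv(out / "marker_audit.tsv", audit, seed=cfg.seed)
    return {"markers": markers, "audit": audit}


def run_landscape(cfg: RunConfig, markers=None) -> dict:
    cfg.require_paths("vcf", "manifest")
    out = Path(cfg.output_dir)
    if markers is None:
        path = cfg.markers or out / "markers.tsv"
        chrom_map = vcfio.read_chrom_table(cfg.chrom_table) if cfg.chrom_table else None
        markers = vcfio.read_marker_tsv(path, chrom_map)
    manifest = vcfio.read_manifest(cfg.manifest)
    progeny_ids = manifest.loc[manifest["role"] == "PROGENY", "sample_id"].tolist()
    obs, _ = vcfio.read_vcf_observations(cfg.vcf, progeny_ids, markers)
    windows = make_windows(markers.chrom_map, cfg.window, cfg.step)
    landscapes = [build_landscape(s, *obs.row(s), markers, windows,
                                  cfg.thresholds, cfg.window, cfg.step)
                  for s in progeny_ids]
    vcfio.write_landscape_tsv(out / "landscape.tsv", landscapes, seed=cfg.seed)
    return {"markers": markers, "landscapes": landscapes}


def run_crossovers(cfg: RunConfig, landscapes=None) -> dict:
    out = Path(cfg.output_dir)
    if landscapes is None:
        landscapes = vcfio.read_landscape_tsv(out / "landscape.tsv")
    segments = {ls.sample_id: consolidate(ls, smooth=cfg.smooth) for ls in landscapes}
    events = {sid: detect_crossovers(segs, cfg.step) for sid, segs in segments.items()}
    vcfio.write_segments_bed(out / "segments.bed", segments, seed=cfg.seed)
    vcfio.write_events_bed(out / "events.bed", events, seed=cfg.seed)
    return {"segments": segments, "events": events}


def run_clonality(cfg: RunConfig, landscapes=None, events=None) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    if landscapes is None:
        landscapes = vcfio.read_landscape_tsv(out / "landscape.tsv")
    if events is None:
        segments = {ls.sample_id: consolidate(ls, smooth=cfg.smooth) for ls in landscapes}
        events = {sid: detect_crossovers(segs, cfg.step) for sid, segs in segments.items()}
    reports = [assess_clonality(ls, events[ls.sample_id], cfg.clonal_min_het)
               for ls in landscapes]
    frame = pd.DataFrame([r.__dict__ for r in reports])
    vcfio._write_tsv(out / "clonality.tsv", frame, seed=cfg.seed)
    return frame


def run_ploidy(cfg: RunConfig) -> pd.DataFrame:
    cfg.require_paths("manifest", "histograms_dir")
    if cfg.control_2c_channel is None:
        raise ValueError("control_2c_channel is required to call ploidy")
    out = Path(cfg.output_dir)
    manifest = vcfio.read_manifest(cfg.manifest)
    progeny = manifest.loc[manifest["role"] == "PROGENY"]
    rows = []
    for _, row in progeny.iterrows():
        path = Path(cfg.histograms_dir) / f"{row['sample_id']}.tsv"
        if not path.exists():
            log.warning("no histogram for %s; skipping", row["sample_id"])
            continue
        hist = vcfio.read_histogram_tsv(path)
        call = call_ploidy(hist, cfg.control_2c_channel, cfg.ploidy_params,
                           sample_id=str(row["sample_id"]))
        event = row["event"] if "event" in progeny.columns else cfg.event_of.get(
            str(row["sample_id"]), "all")
        rows.append({"sample_id": call.sample_id, "event_id": event, "call": call.call})
    frame = pd.DataFrame(rows)
    vcfio._write_tsv(out / "ploidy_calls.tsv", frame, seed=cfg.seed)
    return frame


def run_summarize(cfg: RunConfig, ploidy_calls: pd.DataFrame | None = None) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    if ploidy_calls is None:
        ploidy_calls, _ = vcfio._read_tsv(out / "ploidy_calls.tsv")
    rows = []
    for event_id, sub in ploidy_calls.groupby("event_id", sort=False):
        summary = summarize_event(sub["call"].tolist(), str(event_id), cfg.chimeric_as)
        rows.append(summary.__dict__)
    frame = pd.DataFrame(rows)
    vcfio._write_tsv(out / "event_summary.tsv", frame, seed=cfg.seed)
    return frame


def run_pipeline(cfg: RunConfig) -> dict:
    """select-markers -> landscape -> crossovers -> clonality -> summarize."""
    Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if cfg.markers:
        results["markers"] = None
    else:
        results.update(run_select_markers(cfg))
    results.update(run_landscape(cfg, results.get("markers")))
    results.update(run_crossovers(cfg, results["landscapes"]))
    results["clonality"] = run_clonality(cfg, results["landscapes"], results["events"])
    if cfg.histograms_dir and cfg.control_2c_channel:
        calls = run_ploidy(cfg)
        if len(calls):
            results["ploidy_calls"] = calls
            results["event_summary"] = run_summarize(cfg, calls)
    return results
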