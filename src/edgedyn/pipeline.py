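"""End-to-end driver: movie -> masks, boundaries, heatmaps, events, summaries."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from edgedyn import io
from edgedyn.colocalization import build_coloc_heatmap, coloc_event_summary, make_edge_band
from edgedyn.config import PipelineConfig, config_hash
from edgedyn.coupling import coupling_map, normalize_across_cells
from edgedyn.dynamics import build_velocity_heatmap, extract_events, summarize_events
from edgedyn.segmentation import discretize_sectors, extract_boundary, segment_cell, track_sectors
from edgedyn.synthetic import Movie

log = logging.getLogger("edgedyn")


@dataclasses.dataclass
class PipelineResult:
    masks: list
    boundaries: list
    velocity: object
    coloc: object
    coupling: object
    membrane_events: list
    coloc_events: list
    membrane_summary: object
    coloc_summary: object


def analyze_movie(movie: Movie, cfg: PipelineConfig) -> PipelineResult:
    """Run segmentation, sectorization, all three heatmaps and event stages."""
    seg_channel = 1 if movie.data.shape[1] > 1 else 0
    masks = [
        segment_cell(movie.data[f, seg_channel], cfg.pixel_size_um, frame_index=f)
        for f in range(movie.n_frames)
    ]
    boundaries = [extract_boundary(m) for m in masks]
    boundaries[0] = discretize_sectors(boundaries[0], cfg.sector_length_um)
    n_sectors = boundaries[0].n_sectors
    for b in boundaries[1:]:
        discretize_sectors(b, cfg.sector_length_um, n_sectors=n_sectors)
    log.info("sectorized %d frames at N=%d sectors", len(boundaries), n_sectors)

    displacements = [
        track_sectors(boundaries[f], boundaries[f + 1], cfg.max_sector_motion_um)
        for f in range(len(boundaries) - 1)
    ]
    velocity = build_velocity_heatmap(displacements, cfg.frame_interval_s)
    membrane_events = extract_events(
        velocity, cfg.velocity_event_threshold, cfg.event_min_area, signed=True
    )
    membrane_summary = summarize_events(membrane_events, movie.duration_s)

    coloc = None
    coloc_events = []
    coloc_summary = None
    coupling = None
    if movie.data.shape[1] > 1:
        bands = [
            make_edge_band(masks[f], boundaries[f], cfg.band_depth_um)
            for f in range(movie.n_frames)
        ]
        coloc = build_coloc_heatmap(
            movie.data[:, 0], movie.data[:, 1], bands, masks,
            cfg.frame_interval_s, min_pixels=cfg.min_region_pixels,
        )
        coloc_events = extract_events(
            coloc, cfg.coloc_event_threshold, cfg.event_min_area, signed=False
        )
        coloc_summary = coloc_event_summary(coloc_events, movie.duration_s)
        coupling = normalize_across_cells([coupling_map(velocity, coloc)])[0]
    log.info(
        "N=%d, t=%d, membrane events=%d, coloc events=%d",
        n_sectors, movie.n_frames, len(membrane_events), len(coloc_events),
    )
    return PipelineResult(
        masks=masks,
        boundaries=boundaries,
        velocity=velocity,
        coloc=coloc,
        coupling=coupling,
        membrane_events=membrane_events,
        coloc_events=coloc_events,
        membrane_summary=membrane_summary,
        coloc_summary=coloc_summary,
    )


def write_results(result: PipelineResult, cfg: PipelineConfig, out_dir: Path | str) -> Path:
    """Write all stage outputs plus a provenance manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    stages: dict[str, str] = {}

    mask_stack = np.stack([m.mask for m in result.masks])
    io.write_mask_tiff(mask_stack, out / "masks.tif")
    stages["masks"] = "masks.tif"

    io.write_table(io.boundary_frame(result.boundaries), out / "boundaries.csv", h)
    stages["boundaries"] = "boundaries.csv"

    io.write_table(io.heatmap_frame(result.velocity.normalized), out / "velocity_heatmap.csv", h)
    io.render_heatmap(result.velocity.normalized, out / "velocity_heatmap.png",
                      "velocity", cfg.frame_interval_s)
    stages["velocity_heatmap"] = "velocity_heatmap.csv"

    io.write_table(io.events_frame(result.membrane_events), out / "membrane_events.csv", h)
    stages["membrane_events"] = "membrane_events.csv"

    if result.coloc is not None:
        io.write_table(io.heatmap_frame(result.coloc.raw), out / "coloc_heatmap.csv", h)
        io.render_heatmap(result.coloc.normalized, out / "coloc_heatmap.png",
                          "coloc", cfg.frame_interval_s)
        stages["coloc_heatmap"] = "coloc_heatmap.csv"
        io.write_table(io.events_frame(result.coloc_events), out / "coloc_events.csv", h)
        stages["coloc_events"] = "coloc_events.csv"
        io.write_table(io.heatmap_frame(result.coupling.normalized),
                       out / "coupling_heatmap.csv", h)
        io.render_heatmap(result.coupling.normalized, out / "coupling_heatmap.png",
                          "coupling", cfg.frame_interval_s)
        stages["coupling_heatmap"] = "coupling_heatmap.csv"

    summaries = []
    for name, s in (("membrane", result.membrane_summary), ("coloc", result.coloc_summary)):
        if s is None:
            continue
        summaries.append(
            {
                "kind": name,
                "count": s.count,
                "events_per_minute": s.events_per_minute,
                "mean_duration_s": s.mean_duration_s,
                "mean_angle_deg": s.mean_angle_deg,
                "percent_traveling_waves": s.percent_traveling_waves,
                "defined": s.defined,
            }
        )
    io.write_table(pd.DataFrame(summaries), out / "summaries.csv", h)
    stages["summaries"] = "summaries.csv"

    return io.write_manifest(out, cfg, stages)


def run_pipeline(
    movie: Movie, cfg: PipelineConfig, out_dir: Path | str
) -> PipelineResult:
    result = analyze_movie(movie, cfg)
    write_results(result, cfg, out_dir)
    return result
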