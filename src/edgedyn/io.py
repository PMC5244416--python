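"""Readers/writers: TIFF stacks, CSV tables with provenance, rendered heatmaps."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
from matplotlib.colors import LinearSegmentedColormap

from edgedyn.config import config_hash, to_dict
from edgedyn.segmentation import BoundaryFrame
from edgedyn.synthetic import Movie

# colour encodings: velocity red/green/blue = protrusion/quiescence/retraction;
# colocalization blue (low) to red (high); coupling five-colour legend
VELOCITY_CMAP = LinearSegmentedColormap.from_list("velocity", ["blue", "green", "red"])
COLOC_CMAP = LinearSegmentedColormap.from_list("coloc", ["blue", "red"])
COUPLING_CMAP = LinearSegmentedColormap.from_list(
    "coupling", ["blue", "cyan", "green", "orange", "red"]
)


def write_movie_tiff(movie: Movie, path: Path | str) -> None:
    """ImageJ-compatible multi-page TIFF, axes TCYX."""
    tifffile.imwrite(
        str(path),
        movie.data.astype(np.float32),
        imagej=True,
        metadata={
            "axes": "TCYX",
            "finterval": movie.frame_interval_s,
            "unit": "um",
        },
        resolution=(1.0 / movie.pixel_size_um, 1.0 / movie.pixel_size_um),
    )


def read_movie_tiff(
    path: Path | str, pixel_size_um: float, frame_interval_s: float
) -> Movie:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as (T, C, Y, X)")
    return Movie(
        data=np.asarray(data, dtype=np.float32),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


def write_mask_tiff(masks: np.ndarray, path: Path | str) -> None:
    tifffile.imwrite(str(path), np.asarray(masks, dtype=np.uint8), imagej=True,
                     metadata={"axes": "TYX" if masks.ndim == 3 else "YX"})


def write_table(df: pd.DataFrame, path: Path | str, cfg_hash: str) -> None:
    """CSV with a provenance comment line carrying the config hash."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def heatmap_frame(matrix: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(matrix)
    df.insert(0, "sector", np.arange(matrix.shape[0]))
    df.columns = ["sector"] + [f"t{j}" for j in range(matrix.shape[1])]
    return df


def boundary_frame(boundaries: Sequence[BoundaryFrame]) -> pd.DataFrame:
    rows = []
    for b in boundaries:
        sid = b.sector_id if b.sector_id is not None else np.full(len(b.xy_um), -1)
        for v, ((x, y), s) in enumerate(zip(b.xy_um, sid)):
            rows.append((b.frame_index, v, x, y, int(s)))
    return pd.DataFrame(rows, columns=["frame", "vertex", "x_um", "y_um", "sector_id"])


def render_heatmap(
    matrix: np.ndarray,
    path: Path | str,
    kind: str,
    frame_interval_s: float = 1.0,
    vlim: Optional[float] = None,
) -> None:
    """Render one heatmap PNG with the kind's colour encoding."""
    cmaps = {"velocity": VELOCITY_CMAP, "coloc": COLOC_CMAP, "coupling": COUPLING_CMAP}
    if kind not in cmaps:
        raise ValueError(f"unknown heatmap kind {kind!r}")
    if kind == "coloc":
        vmin, vmax = 0.0, 1.0
    else:
        v = vlim if vlim is not None else 1.0
        vmin, vmax = -v, v
    fig, ax = plt.subplots(figsize=(7, 3.2))
    im = ax.imshow(
        matrix, aspect="auto", origin="lower", cmap=cmaps[kind],
        vmin=vmin, vmax=vmax, interpolation="nearest",
        extent=(0, matrix.shape[1] * frame_interval_s, 0, matrix.shape[0]),
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("boundary sector")
    fig.colorbar(im, ax=ax, label=kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def events_frame(events) -> pd.DataFrame:
    rows = [
        {
            "polarity": e.polarity,
            "area_cells": e.area,
            "duration_s": e.duration_s,
            "angle_deg": e.angle_deg,
            "is_traveling_wave": e.is_traveling_wave,
            "frame_start": e.frame_range[0],
            "frame_end": e.frame_range[1],
            "sector_min": e.sector_range[0],
            "sector_max": e.sector_range[1],
            "mean_value": e.mean_value,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "polarity", "area_cells", "duration_s", "angle_deg",
            "is_traveling_wave", "frame_start", "frame_end",
            "sector_min", "sector_max", "mean_value",
        ],
    )


def write_manifest(out_dir: Path | str, cfg, stages: dict[str, str]) -> Path:
    """Machine-readable run manifest: config, hash, versions, stage outputs."""
    import edgedyn

    out = Path(out_dir) / "manifest.json"
    payload = {
        "config": to_dict(cfg),
        "config_hash": config_hash(cfg),
        "versions": {
            "edgedyn": edgedyn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": stages,
    }
    out.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
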