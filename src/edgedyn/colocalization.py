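"""Two-channel colocalization in the 2 um edge band of the cell.

The band is the set of cell pixels within ``depth_um`` of the boundary,
realized by thresholding the interior distance transform (sub-pixel, so the
depth is calibration independent rather than an integer structuring
element).  Band pixels inherit the region id of the nearest boundary
sector, giving the colocalization heatmap the same rows as the velocity
heatmap so the two can be paired elementwise.

Per region and frame the colocalization coefficient is

    coloc = Cov(G - mu_G, R - mu_R) / sqrt(Var(G - mu_G) * Var(R - mu_R))

on background-subtracted pixel pairs — algebraically the Pearson
correlation of (G, R) within the region, invariant to per-channel affine
intensity transforms with positive gain.  The background of each channel
defaults to the mean intensity outside a 2 um dilation of the cell mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from edgedyn.dynamics import EventSummary, MembraneEvent, summarize_events
from edgedyn.segmentation import BoundaryFrame, CellMask


class ColocalizationError(RuntimeError):
    pass


@dataclass
class EdgeBand:
    """Edge-band mask of one frame with per-pixel region ids."""

    band: np.ndarray  # (H, W) bool
    region_id: np.ndarray  # (H, W) int, -1 outside the band
    depth_um: float
    n_regions: int
    pixel_size_um: float


@dataclass
class RegionSignals:
    """Paired, background-subtracted pixel values of one band region."""

    green: np.ndarray
    red: np.ndarray
    background_green: float
    background_red: float

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("green and red pixel vectors must be paired")


@dataclass
class ColocHeatmap:
    """Region x time matrix of colocalization coefficients."""

    raw: np.ndarray  # (N, T) signed correlations in [-1, 1]; NaN where missing
    normalized: np.ndarray  # (N, T) display scale: negatives clipped to 0
    missing: np.ndarray  # (N, T) bool
    frame_interval_s: float


def estimate_background(
    frame: np.ndarray, mask: np.ndarray, pixel_size_um: float, margin_um: float = 2.0
) -> float:
    """Mean intensity of pixels farther than ``margin_um`` outside the mask."""
    dist_out = ndimage.distance_transform_edt(~mask, sampling=pixel_size_um)
    region = dist_out > margin_um
    if not region.any():
        raise ColocalizationError("no background region outside the dilated cell mask")
    return float(frame[region].mean())


def make_edge_band(
    cell: CellMask, boundary: BoundaryFrame, depth_um: float = 2.0
) -> EdgeBand:
    """Band = cell pixels within ``depth_um`` of the boundary, sector-labelled."""
    if boundary.n_sectors == 0:
        raise ValueError("boundary must be sectorized before building the band")
    px = cell.pixel_size_um
    if depth_um < 2 * px:
        raise ColocalizationError(
            f"band depth {depth_um} um is below two pixels at {px} um/px"
        )
    dist_in = ndimage.distance_transform_edt(cell.mask, sampling=px)
    if not (dist_in > depth_um).any():
        raise ColocalizationError(
            f"cell thinner than twice the band depth ({depth_um} um); erosion empties it"
        )
    band = cell.mask & (dist_in <= depth_um)

    region_id = np.full(cell.mask.shape, -1, dtype=int)
    rows, cols = np.nonzero(band)
    pts = np.column_stack([cols * px, rows * px])  # (x, y) um of band pixels
    tree = cKDTree(boundary.xy_um)
    _, idx = tree.query(pts)
    region_id[rows, cols] = boundary.sector_id[idx]
    return EdgeBand(
        band=band,
        region_id=region_id,
        depth_um=depth_um,
        n_regions=boundary.n_sectors,
        pixel_size_um=px,
    )


def region_coloc(sig: RegionSignals, min_pixels: int = 10) -> float:
    """Colocalization coefficient of one region; NaN when undefined.

    Returns NaN (never 0) when the region has too few pixels or either
    channel has zero variance.  The result is clipped to [-1, 1] to absorb
    floating-point overshoot on perfectly dependent channels.
    """
    g = np.asarray(sig.green, dtype=float) - sig.background_green
    r = np.asarray(sig.red, dtype=float) - sig.background_red
    if g.size < min_pixels:
        return float("nan")
    gc = g - g.mean()
    rc = r - r.mean()
    var_g = np.mean(gc * gc)
    var_r = np.mean(rc * rc)
    if var_g == 0 or var_r == 0:
        return float("nan")
    cov = np.mean(gc * rc)
    r = float(np.clip(cov / np.sqrt(var_g * var_r), -1.0, 1.0))
    # perfectly dependent channels can miss +/-1 by ~1 ulp; saturate within
    # 1e-13 so exact linear dependence reads exactly +/-1
    if abs(abs(r) - 1.0) < 1e-13:
        r = math.copysign(1.0, r)
    return r


def build_coloc_heatmap(
    green_frames: Sequence[np.ndarray],
    red_frames: Sequence[np.ndarray],
    bands: Sequence[EdgeBand],
    masks: Sequence[CellMask],
    frame_interval_s: float,
    min_pixels: int = 10,
    background: Optional[tuple[float, float]] = None,
) -> ColocHeatmap:
    """Colocalization coefficient per band region per frame.

    The display normalization clips negative correlations to 0, matching a
    0 (low) to 1 (high) colour scale; raw signed values are retained.
    """
    t = len(bands)
    if not (len(green_frames) == len(red_frames) == len(masks) == t):
        raise ValueError("green, red, band and mask sequences must have equal length")
    n_regions = bands[0].n_regions
    raw = np.full((n_regions, t), np.nan)
    for f in range(t):
        g_img = np.asarray(green_frames[f], dtype=float)
        r_img = np.asarray(red_frames[f], dtype=float)
        if g_img.shape != r_img.shape:
            raise ValueError(f"channel shape mismatch in frame {f}")
        if background is None:
            bg_g = estimate_background(g_img, masks[f].mask, masks[f].pixel_size_um)
            bg_r = estimate_background(r_img, masks[f].mask, masks[f].pixel_size_um)
        else:
            bg_g, bg_r = background
        band = bands[f]
        if band.n_regions != n_regions:
            raise ValueError("region count differs across frames")
        for region in range(n_regions):
            sel = band.region_id == region
            sig = RegionSignals(
                green=g_img[sel], red=r_img[sel],
                background_green=bg_g, background_red=bg_r,
            )
            raw[region, f] = region_coloc(sig, min_pixels=min_pixels)
    missing = ~np.isfinite(raw)
    normalized = np.clip(raw, 0.0, 1.0)
    normalized[missing] = np.nan
    return ColocHeatmap(
        raw=raw, normalized=normalized, missing=missing,
        frame_interval_s=frame_interval_s,
    )


def coloc_event_summary(
    events: Sequence[MembraneEvent], movie_duration_s: float
) -> EventSummary:
    """Summary of colocalization events (same contract as membrane events)."""
    return summarize_events(events, movie_duration_s)
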