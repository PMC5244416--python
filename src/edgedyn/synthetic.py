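"""Synthetic two-channel time-lapse movies with planted ground truth.

The simulated cell is star-convex: its boundary is a radial function
r(theta, t) around a fixed centroid, which cannot self-intersect and gives
an invertible ground truth.  Kinematic pulses define a *normal-velocity
field* on the boundary,

    v(theta, f) = s * profile(theta - theta_c(f)),   start <= f < end,

with ``s`` the signed speed (protrusion positive), ``profile`` a unit
plateau with cosine-tapered edges, and the pulse centre drifting at a
configured number of sectors per frame (a lateral drift plants a traveling
wave of space-time angle atan(drift)).  Radii are integrated frame to frame,
so the planted per-sector velocities are known exactly.

Channel correlation in the 2 um edge band is imposed with a shared latent
field.  For target correlation rho, band fluctuation scale sigma_b and
detector noise sigma_n, both channels receive ``sqrt(c) * Z`` of a shared
standard normal Z plus independent residuals, where

    c = |rho| * (sigma_b**2 + sigma_n**2)        (c <= sigma_b**2 required)

so that the *rendered* pixel pairs, detector noise included, have Pearson
correlation rho.  All randomness flows from one generator seeded by
``SimConfig.seed``; identical configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from edgedyn.config import AdhesionSpec, KinematicPulse, SimConfig

_N_THETA = 2048  # angular samples of the radial boundary function


class SimulationError(RuntimeError):
    """Raised when a configuration produces invalid geometry."""


@dataclass
class Movie:
    """Calibrated pixel time series, axes (T, C, H, W)."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("green", "red")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class GroundTruth:
    """Planted quantities the analysis is expected to recover."""

    pixel_size_um: float = 0.0
    frame_interval_s: float = 0.0
    thetas: Optional[np.ndarray] = None  # (_N_THETA,)
    radii_um: Optional[np.ndarray] = None  # (n_frames, _N_THETA)
    centroid_um: Optional[tuple[float, float]] = None
    n_sectors: int = 0
    sector_velocity_um_per_frame: Optional[np.ndarray] = None  # (N, n_frames-1)
    region_rho: Optional[np.ndarray] = None  # (N, n_frames)
    events: Optional[pd.DataFrame] = None
    adhesion_sites: Optional[pd.DataFrame] = None
    adhesion_mask: Optional[np.ndarray] = None
    leading_edge_y_um: Optional[float] = None
    track_table: Optional[pd.DataFrame] = None
    track_positions: Optional[np.ndarray] = None  # (n_tracks, n_frames, 2)
    wound_area_um2: Optional[np.ndarray] = None
    wound_time_h: Optional[np.ndarray] = None

    def boundary_xy_um(self, frame: int) -> np.ndarray:
        """Planted boundary polyline of one frame as (x, y) in um."""
        r = self.radii_um[frame]
        cx, cy = self.centroid_um
        return np.column_stack(
            [cx + r * np.cos(self.thetas), cy + r * np.sin(self.thetas)]
        )

    @property
    def sector_velocity_um_per_s(self) -> np.ndarray:
        return self.sector_velocity_um_per_frame / self.frame_interval_s


def _pulse_profile(dtheta: np.ndarray, half_width: float, taper: float) -> np.ndarray:
    """Unit plateau with raised-cosine shoulders; dtheta wrapped to [-pi, pi]."""
    d = np.abs((dtheta + np.pi) % (2 * np.pi) - np.pi)
    out = np.zeros_like(d)
    plateau = half_width - taper
    out[d <= plateau] = 1.0
    shoulder = (d > plateau) & (d < half_width)
    out[shoulder] = 0.5 * (1 + np.cos(np.pi * (d[shoulder] - plateau) / taper))
    return out


def n_sectors_for(cfg: SimConfig, sector_length_um: float = 10.0) -> int:
    """Sector count the analysis will use on the undeformed cell."""
    return max(4, round(2 * math.pi * cfg.cell_radius_um / sector_length_um))


def _velocity_field(cfg: SimConfig, thetas: np.ndarray, n_sectors: int) -> np.ndarray:
    """Planted normal-velocity field v[f, theta] in um/frame, f = 0..n_frames-2."""
    v = np.zeros((cfg.n_frames - 1, thetas.size))
    sector_angle = 2 * math.pi / n_sectors
    r0 = cfg.cell_radius_um
    for pulse in cfg.boundary_kinematics:
        half_width = 0.5 * pulse.width_um / r0
        taper = min(0.35 * half_width, 2.0 / r0)  # shoulder arc capped at 2 um
        theta0 = pulse.center_arclength_um / r0
        step = pulse.signed_speed * cfg.frame_interval_s
        for f in range(pulse.start_frame, min(pulse.end_frame, cfg.n_frames - 1)):
            theta_c = theta0 + pulse.drift_sectors_per_frame * sector_angle * (
                f - pulse.start_frame
            )
            v[f] += step * _pulse_profile(thetas - theta_c, half_width, taper)
    return v


def _boundary_radii(cfg: SimConfig, thetas: np.ndarray, vfield: np.ndarray) -> np.ndarray:
    """Integrate the velocity field into per-frame radii; validate geometry."""
    radii = np.empty((cfg.n_frames, thetas.size))
    radii[0] = cfg.cell_radius_um
    for f in range(cfg.n_frames - 1):
        radii[f + 1] = radii[f] + vfield[f]
    h, w = cfg.image_shape
    max_r = 0.5 * min(h, w) * cfg.pixel_size_um - 2.0
    if radii.min() < 1.0:
        raise SimulationError(
            "boundary kinematics collapse the cell (radius < 1 um); "
            "reduce retraction speed or duration"
        )
    if radii.max() > max_r:
        raise SimulationError(
            f"boundary kinematics push the cell outside the field of view "
            f"(radius {radii.max():.1f} um > {max_r:.1f} um limit)"
        )
    return radii


def _pixel_grid_um(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.image_shape
    px = cfg.pixel_size_um
    y, x = np.mgrid[0:h, 0:w]
    return x * px, y * px


def _interp_radius(thetas: np.ndarray, radii: np.ndarray, theta_px: np.ndarray) -> np.ndarray:
    return np.interp(theta_px, thetas, radii, period=2 * math.pi)


def generate_cell_movie(cfg: SimConfig) -> tuple[Movie, GroundTruth]:
    """Render a two-channel movie of one deforming cell plus its ground truth.

    Channel 0 ("green") is the marker of interest, channel 1 ("red") the
    actin reporter used for segmentation.  Both share the edge-band
    correlated fluctuations with target Pearson correlation
    ``cfg.coloc_rho``; ``cfg.noise_sd`` Gaussian detector noise is added
    everywhere.  Ground truth (boundaries, per-sector velocities, event
    table, per-region correlation) is computed analytically before any
    random draw, so noise never perturbs it.
    """
    rng = np.random.default_rng(cfg.seed)
    thetas = np.linspace(0, 2 * math.pi, _N_THETA, endpoint=False)
    n_sec = n_sectors_for(cfg)
    vfield = _velocity_field(cfg, thetas, n_sec)
    radii = _boundary_radii(cfg, thetas, vfield)

    h, w = cfg.image_shape
    px = cfg.pixel_size_um
    cx, cy = (w - 1) / 2 * px, (h - 1) / 2 * px
    xg, yg = _pixel_grid_um(cfg)
    theta_px = np.arctan2(yg - cy, xg - cx) % (2 * math.pi)
    rho_px = np.hypot(xg - cx, yg - cy)

    sigma_b = cfg.band_amplitude
    sigma_n = cfg.noise_sd
    rho_extreme = max(
        [abs(cfg.coloc_rho)] + [abs(p.rho) for p in cfg.coloc_patches], default=0.0
    )
    if rho_extreme * (sigma_b**2 + sigma_n**2) > sigma_b**2 + 1e-12:
        raise SimulationError(
            "target correlation unreachable: detector noise too large relative "
            "to band_amplitude"
        )

    def rho_at(f: int, theta: np.ndarray) -> np.ndarray:
        rho = np.full(theta.shape, cfg.coloc_rho)
        r0 = cfg.cell_radius_um
        for patch in cfg.coloc_patches:
            if patch.start_frame <= f < patch.end_frame:
                dtheta = (theta - patch.center_arclength_um / r0 + math.pi) % (
                    2 * math.pi
                ) - math.pi
                rho[np.abs(dtheta) <= 0.5 * patch.width_um / r0] = patch.rho
        return rho

    # static latent fields: the band texture is a frozen spatial pattern, so a
    # static cell without patches and noise_sd = 0 renders identical frames
    z_field = rng.standard_normal((h, w))
    e1_field = rng.standard_normal((h, w))
    e2_field = rng.standard_normal((h, w))

    data = np.empty((cfg.n_frames, 2, h, w), dtype=np.float32)
    for f in range(cfg.n_frames):
        r_at_px = _interp_radius(thetas, radii[f], theta_px)
        mask = rho_px <= r_at_px
        band = mask & (rho_px >= r_at_px - 2.0)
        green = np.full((h, w), cfg.background_level)
        red = np.full((h, w), cfg.background_level)
        green[mask] += cfg.cell_level - cfg.background_level
        red[mask] += cfg.cell_level - cfg.background_level
        rho_band = rho_at(f, theta_px[band])
        shared = np.minimum(np.abs(rho_band) * (sigma_b**2 + sigma_n**2), sigma_b**2)
        shared_sd = np.sqrt(shared)
        resid = np.sqrt(sigma_b**2 - shared)
        sign = np.where(rho_band >= 0, 1.0, -1.0)
        green[band] += 1.5 * sigma_b + shared_sd * z_field[band] + resid * e1_field[band]
        red[band] += 1.5 * sigma_b + sign * shared_sd * z_field[band] + resid * e2_field[band]
        if sigma_n > 0:
            green += rng.normal(0, sigma_n, (h, w))
            red += rng.normal(0, sigma_n, (h, w))
        data[f, 0] = green
        data[f, 1] = red

    movie = Movie(data, px, cfg.frame_interval_s)

    sector_centers = (np.arange(n_sec) + 0.5) * 2 * math.pi / n_sec
    v_sector = np.empty((n_sec, cfg.n_frames - 1))
    for f in range(cfg.n_frames - 1):
        v_sector[:, f] = np.interp(sector_centers, thetas, vfield[f], period=2 * math.pi)
    region_rho = np.column_stack(
        [rho_at(f, sector_centers) for f in range(cfg.n_frames)]
    )

    events = pd.DataFrame(
        [
            {
                "kind": p.kind,
                "start_frame": p.start_frame,
                "end_frame": p.end_frame,
                "duration_s": (min(p.end_frame, cfg.n_frames - 1) - p.start_frame)
                * cfg.frame_interval_s,
                "angle_deg": p.planted_angle_deg,
                "speed_um_per_s": p.signed_speed,
                "center_sector": (p.center_arclength_um / cfg.cell_radius_um)
                / (2 * math.pi / n_sec),
                "width_sectors": (p.width_um / cfg.cell_radius_um) / (2 * math.pi / n_sec),
                "drift_sectors_per_frame": p.drift_sectors_per_frame,
            }
            for p in cfg.boundary_kinematics
        ],
        columns=[
            "kind",
            "start_frame",
            "end_frame",
            "duration_s",
            "angle_deg",
            "speed_um_per_s",
            "center_sector",
            "width_sectors",
            "drift_sectors_per_frame",
        ],
    )

    gt = GroundTruth(
        pixel_size_um=px,
        frame_interval_s=cfg.frame_interval_s,
        thetas=thetas,
        radii_um=radii,
        centroid_um=(cx, cy),
        n_sectors=n_sec,
        sector_velocity_um_per_frame=v_sector,
        region_rho=region_rho,
        events=events,
    )
    return movie, gt


# per-orientation pulse durations (frame pairs) keeping moment-based angle
# recovery within 5 degrees of the planted value on discretized heatmaps:
# slow drifts need longer averaging, steep drifts a bounded sector footprint
_EVENT_DURATIONS = {0.0: (6, 9), 5.0: (10, 12), 15.0: (8, 10), 45.0: (6, 7)}


def random_event_config(
    seed: int,
    angles_deg: tuple[float, ...] = (0.0, 5.0, 15.0, 45.0),
    n_frames: int = 26,
    image_shape: tuple[int, int] = (360, 360),
) -> SimConfig:
    """Randomized movie config with non-overlapping planted membrane events.

    Pulses are placed in disjoint time windows and disjoint sector blocks
    (shoulders included) so each planted event maps to exactly one connected
    heatmap region.  Orientations are drawn from ``angles_deg`` by setting
    the lateral drift to tan(angle); steep events get most of the movie to
    themselves since their sector footprint grows with drift * duration.
    """
    rng = np.random.default_rng(seed)
    r0 = 20.0
    cfg_probe = SimConfig(cell_radius_um=r0, n_frames=n_frames, image_shape=image_shape)
    n_sec = n_sectors_for(cfg_probe)
    sector_um = 2 * math.pi * r0 / n_sec
    width_sectors = 2.5

    k = int(rng.integers(1, 4))
    pulses: list[KinematicPulse] = []
    speed = float(rng.uniform(0.08, 0.16))  # shared so normalization keeps all events
    next_frame = 1
    next_sector = float(rng.uniform(0, 1))
    for _ in range(k):
        angle = float(rng.choice(angles_deg))
        lo, hi = _EVENT_DURATIONS[angle]
        duration = int(rng.integers(lo, hi + 1))
        drift = math.tan(math.radians(angle)) * (1 if rng.random() < 0.5 else -1)
        footprint = width_sectors + abs(drift) * duration + 2.0  # + shoulders
        if next_frame + duration > n_frames - 1 or next_sector + footprint > n_sec - 0.5:
            break
        center_start = (
            next_sector + 1.0 + width_sectors / 2
            + (abs(drift) * duration if drift < 0 else 0.0)
        )
        pulses.append(
            KinematicPulse(
                kind="protrusion" if rng.random() < 0.5 else "retraction",
                start_frame=next_frame,
                end_frame=next_frame + duration,
                center_arclength_um=center_start * sector_um,
                width_um=width_sectors * sector_um,
                speed_um_per_s=speed,
                drift_sectors_per_frame=drift,
            )
        )
        next_frame += duration + 2
        next_sector += footprint + 1.0
    return SimConfig(
        cell_radius_um=r0,
        n_frames=n_frames,
        image_shape=image_shape,
        seed=seed,
        boundary_kinematics=pulses,
    )


def ground_truth_velocity_heatmap(cfg: SimConfig):
    """Planted sector-velocity heatmap of a config, without rendering pixels."""
    from edgedyn.dynamics import VelocityHeatmap

    thetas = np.linspace(0, 2 * math.pi, _N_THETA, endpoint=False)
    n_sec = n_sectors_for(cfg)
    vfield = _velocity_field(cfg, thetas, n_sec)
    centers = (np.arange(n_sec) + 0.5) * 2 * math.pi / n_sec
    v = np.column_stack(
        [np.interp(centers, thetas, vfield[f], period=2 * math.pi)
         for f in range(cfg.n_frames - 1)]
    )
    vmax = float(np.abs(v).max())
    if vmax == 0:
        normalized = np.zeros_like(v)
    else:
        normalized = v / vmax
    return VelocityHeatmap(
        raw=v,
        normalized=normalized,
        missing=np.zeros_like(v, dtype=bool),
        frame_interval_s=cfg.frame_interval_s,
        norm_constant=vmax if vmax else 1.0,
    )


def generate_adhesion_frame(cfg: SimConfig) -> tuple[Movie, GroundTruth]:
    """Render a single-channel frame of elliptical adhesion puncta.

    The cell occupies the lower three quarters of the field; its straight
    top edge is the leading-edge membrane.  Ground-truth site morphology
    (area, longest axis, centroid distance to the edge) is measured on the
    noiseless rasterized union of the planted ellipses, so overlapping
    sites appear as one merged object.
    """
    if not cfg.adhesion_sites:
        raise SimulationError("adhesion_sites is empty")
    from skimage import measure

    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    px = cfg.pixel_size_um
    xg, yg = _pixel_grid_um(cfg)
    edge_y = 0.25 * h * px
    cell_mask = yg >= edge_y

    site_mask = np.zeros((h, w), dtype=bool)
    frame = np.full((h, w), cfg.background_level)
    for site in cfg.adhesion_sites:
        sx, sy = site.center_um
        a, b = site.semi_axes_um
        phi = math.radians(site.angle_deg)
        u = (xg - sx) * math.cos(phi) + (yg - sy) * math.sin(phi)
        v = -(xg - sx) * math.sin(phi) + (yg - sy) * math.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not inside.any():
            raise SimulationError(f"adhesion site at {site.center_um} renders no pixels")
        if (inside & ~cell_mask).any():
            raise SimulationError(
                f"adhesion site at {site.center_um} lies outside the cell mask"
            )
        site_mask |= inside
        frame[inside] += site.intensity
    if cfg.noise_sd > 0:
        frame += rng.normal(0, cfg.noise_sd, (h, w))

    labels = measure.label(site_mask, connectivity=2)
    rows = []
    for rp in measure.regionprops(labels):
        cyx = rp.centroid  # (row, col)
        cx_um, cy_um = cyx[1] * px, cyx[0] * px
        rows.append(
            {
                "label": rp.label,
                "area_um2": rp.area * px**2,
                "major_axis_um": rp.axis_major_length * px,
                "centroid_x_um": cx_um,
                "centroid_y_um": cy_um,
                "distance_to_membrane_um": cy_um - edge_y,
            }
        )
    table = pd.DataFrame(rows).sort_values("label", ignore_index=True)

    movie = Movie(frame[None, None], px, cfg.frame_interval_s, channel_names=("paxillin",))
    gt = GroundTruth(
        pixel_size_um=px,
        frame_interval_s=cfg.frame_interval_s,
        adhesion_sites=table,
        adhesion_mask=site_mask,
        leading_edge_y_um=edge_y,
    )
    return movie, gt


def generate_tracks(cfg: SimConfig, n_tracks: int) -> tuple[np.ndarray, GroundTruth]:
    """Correlated random walks; returns positions (n_tracks, n_frames, 2) in um.

    Step direction is a persistence-weighted blend of the previous direction
    and a fresh uniform direction; persistence 1 gives straight tracks
    (meandering index exactly 1), persistence 0 an uncorrelated walk.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.track_persistence
    pos = np.zeros((n_tracks, cfg.n_frames, 2))
    pos[:, 0] = rng.uniform(0, 100.0, (n_tracks, 2))
    heading = rng.uniform(0, 2 * math.pi, n_tracks)
    direction = np.column_stack([np.cos(heading), np.sin(heading)])
    for f in range(1, cfg.n_frames):
        phi = rng.uniform(0, 2 * math.pi, n_tracks)
        fresh = np.column_stack([np.cos(phi), np.sin(phi)])
        blend = p * direction + (1 - p) * fresh
        norm = np.linalg.norm(blend, axis=1, keepdims=True)
        degenerate = norm[:, 0] < 1e-12
        blend[degenerate] = fresh[degenerate]
        norm[degenerate] = 1.0
        direction = blend / norm
        pos[:, f] = pos[:, f - 1] + cfg.track_step_um * direction

    steps = np.linalg.norm(np.diff(pos, axis=1), axis=2)
    path = steps.sum(axis=1)
    disp = np.linalg.norm(pos[:, -1] - pos[:, 0], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(path > 0, disp / path, np.nan)
    table = pd.DataFrame(
        {"track_id": np.arange(n_tracks), "meandering_index": mi,
         "displacement_um": disp, "path_length_um": path}
    )
    gt = GroundTruth(
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_s=cfg.frame_interval_s,
        track_table=table,
        track_positions=pos,
    )
    return pos, gt


def generate_wound_series(cfg: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Binary cell-occupancy masks with a central wound stripe closing linearly.

    The stripe's area shrinks by ``wound_closure_rate`` of its initial area
    per hour; ground-truth wound areas are the exact pixel counts of the
    cell-free region.
    """
    h, w = cfg.image_shape
    px = cfg.pixel_size_um
    cx = (w - 1) / 2
    half_w0 = 0.2 * w  # initial stripe half-width, px
    t_h = np.arange(cfg.n_frames) * cfg.frame_interval_s / 3600.0
    masks = np.empty((cfg.n_frames, h, w), dtype=bool)
    areas = np.empty(cfg.n_frames)
    cols = np.arange(w)
    for f in range(cfg.n_frames):
        frac_open = max(0.0, 1.0 - cfg.wound_closure_rate * t_h[f])
        half_wf = half_w0 * frac_open
        wound_cols = np.abs(cols - cx) < half_wf
        mask = np.ones((h, w), dtype=bool)
        mask[:, wound_cols] = False
        masks[f] = mask
        areas[f] = (~mask).sum() * px**2
    gt = GroundTruth(
        pixel_size_um=px,
        frame_interval_s=cfg.frame_interval_s,
        wound_area_um2=areas,
        wound_time_h=t_h,
    )
    return masks, gt
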