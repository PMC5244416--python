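"""Configuration dataclasses and YAML (de)serialization.

All physical quantities are in micrometres and seconds.  Configs are plain
dataclasses so they round-trip losslessly through YAML and hash stably for
run manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


@dataclass(frozen=True)
class KinematicPulse:
    """One planted protrusion or retraction on the simulated boundary.

    The pulse pushes the boundary outward (protrusion) or inward (retraction)
    at ``speed_um_per_s`` along the local normal, over boundary arclength
    ``width_um`` centred at ``center_arclength_um``, active from
    ``start_frame`` (inclusive) to ``end_frame`` (exclusive end of motion:
    the boundary moves between frame pairs start..end-1).  A nonzero
    ``drift_sectors_per_frame`` slides the pulse laterally along the
    boundary, planting a traveling wave whose space-time angle is
    ``atan(drift_sectors_per_frame)`` in heatmap-cell units.
    """

    kind: str  # "protrusion" | "retraction"
    start_frame: int
    end_frame: int
    center_arclength_um: float
    width_um: float
    speed_um_per_s: float
    drift_sectors_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("protrusion", "retraction"):
            raise ConfigError(f"pulse kind must be protrusion|retraction, got {self.kind!r}")
        if not self.start_frame < self.end_frame:
            raise ConfigError("pulse requires start_frame < end_frame")
        if self.width_um <= 0:
            raise ConfigError("pulse width_um must be > 0")
        if self.speed_um_per_s <= 0:
            raise ConfigError("speed_um_per_s is an unsigned magnitude; must be > 0")

    @property
    def signed_speed(self) -> float:
        """Normal speed with protrusion positive, retraction negative."""
        return self.speed_um_per_s if self.kind == "protrusion" else -self.speed_um_per_s

    @property
    def planted_angle_deg(self) -> float:
        """Space-time orientation of the planted event, folded to [0, 90]."""
        import math

        return abs(math.degrees(math.atan(self.drift_sectors_per_frame)))


@dataclass(frozen=True)
class ColocPatch:
    """A planted spatiotemporal window of elevated channel correlation."""

    start_frame: int
    end_frame: int
    center_arclength_um: float
    width_um: float
    rho: float

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ConfigError("patch requires start_frame < end_frame")
        if self.width_um <= 0:
            raise ConfigError("patch width_um must be > 0")
        if abs(self.rho) > 1:
            raise ConfigError("patch rho must lie in [-1, 1]")


@dataclass(frozen=True)
class AdhesionSpec:
    """A planted elliptical adhesion site (axes are semi-axes in um)."""

    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]  # (a, b); major = 2*max
    intensity: float = 400.0
    angle_deg: float = 0.0  # rotation of the a-axis from +x


@dataclass
class SimConfig:
    """Parameters of the synthetic movie generator.

    Defaults emulate a 63x confocal at 0.2 um/px with a 5 s frame interval.
    The same seed always yields bit-identical movies and ground truth.
    """

    pixel_size_um: float = 0.2
    frame_interval_s: float = 5.0
    n_frames: int = 30
    image_shape: tuple[int, int] = (512, 512)
    seed: int = 0
    cell_radius_um: float = 20.0
    boundary_kinematics: list[KinematicPulse] = field(default_factory=list)
    coloc_rho: float = 0.0
    coloc_patches: list[ColocPatch] = field(default_factory=list)
    background_level: float = 100.0
    cell_level: float = 300.0
    band_amplitude: float = 60.0
    noise_sd: float = 0.0
    adhesion_sites: list[AdhesionSpec] = field(default_factory=list)
    track_persistence: float = 0.7
    track_step_um: float = 1.0
    wound_closure_rate: float = 0.1  # fraction of initial wound area closed per hour

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if abs(self.coloc_rho) > 1:
            raise ConfigError("coloc_rho must lie in [-1, 1]")
        if not 0 <= self.track_persistence <= 1:
            raise ConfigError("track_persistence must lie in [0, 1]")
        if self.wound_closure_rate < 0:
            raise ConfigError("wound_closure_rate must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters; physical defaults match the method."""

    pixel_size_um: float = 0.2
    frame_interval_s: float = 5.0
    sector_length_um: float = 10.0
    band_depth_um: float = 2.0
    velocity_event_threshold: float = 0.3
    coloc_event_threshold: float = 0.5
    event_min_area: int = 6
    adhesion_min_area_um2: float = 0.1
    adhesion_smooth_sigma_um: float = 0.1
    max_sector_motion_um: float = 5.0
    min_region_pixels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pixel_size_um",
            "frame_interval_s",
            "sector_length_um",
            "band_depth_um",
            "max_sector_motion_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.event_min_area < 1:
            raise ConfigError("event_min_area must be >= 1")


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_as_plain(v) for v in obj]
    return obj


def to_dict(cfg) -> dict:
    """Dataclass config -> plain dict of YAML/JSON-safe types."""
    return _as_plain(cfg)


def config_hash(cfg) -> str:
    """Stable short hash of a config for output provenance."""
    payload = json.dumps(to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_config(cfg, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=True))


def _build_sim(d: dict) -> SimConfig:
    d = dict(d)
    pulses = [
        KinematicPulse(**p) if not isinstance(p, KinematicPulse) else p
        for p in d.pop("boundary_kinematics", [])
    ]
    patches = [
        ColocPatch(**p) if not isinstance(p, ColocPatch) else p
        for p in d.pop("coloc_patches", [])
    ]
    sites = []
    for s in d.pop("adhesion_sites", []):
        if isinstance(s, AdhesionSpec):
            sites.append(s)
        else:
            s = dict(s)
            s["center_um"] = tuple(s["center_um"])
            s["semi_axes_um"] = tuple(s["semi_axes_um"])
            sites.append(AdhesionSpec(**s))
    if "image_shape" in d:
        d["image_shape"] = tuple(d["image_shape"])
    return SimConfig(
        boundary_kinematics=pulses, coloc_patches=patches, adhesion_sites=sites, **d
    )


def load_sim_config(path: Path | str) -> SimConfig:
    return _build_sim(yaml.safe_load(Path(path).read_text()) or {})


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    return PipelineConfig(**(yaml.safe_load(Path(path).read_text()) or {}))
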