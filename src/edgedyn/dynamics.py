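"""Membrane-velocity heatmaps and protrusion/retraction event extraction.

The raw velocity of sector i over the frame pair (t, t+1) is the projection
of the tracked boundary displacement onto the sector's outward normal,
V_raw[i, t] = d(i, t) . n(i, t), in um/frame.  The normalized map divides by
the maximum absolute raw velocity over the analysis set, so protrusion maps
to +1, retraction to -1 and quiescence to 0.

Events are connected heatmap regions of like-signed velocity above a
threshold, with 8-connectivity and circular wraparound in the sector
dimension (the boundary is closed).  Each event carries area, duration and
the orientation of its major axis relative to the time axis (from second
central moments, folded to [0, 90] degrees); events steeper than 10 degrees
are classified as traveling waves (strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from edgedyn.segmentation import SectorDisplacement

TRAVELING_WAVE_ANGLE_DEG = 10.0


@dataclass
class VelocityHeatmap:
    """Sector x time matrix of normal boundary velocities."""

    raw: np.ndarray  # (N, T-1) um/frame; NaN where missing
    normalized: np.ndarray  # (N, T-1) in [-1, 1]
    missing: np.ndarray  # (N, T-1) bool
    frame_interval_s: float
    norm_constant: float  # um/frame mapped to |V| = 1

    @property
    def n_sectors(self) -> int:
        return self.raw.shape[0]

    @property
    def raw_um_per_s(self) -> np.ndarray:
        return self.raw / self.frame_interval_s


@dataclass
class MembraneEvent:
    """One connected protrusion/retraction (or colocalization) region."""

    polarity: str  # "protrusion" | "retraction" | "coloc"
    cells: np.ndarray  # (k, 2) (sector, frame) member indices
    area: int
    duration_s: float
    angle_deg: float
    frame_range: tuple[int, int]
    sector_range: tuple[int, int]
    mean_value: float

    @property
    def is_traveling_wave(self) -> bool:
        return self.angle_deg > TRAVELING_WAVE_ANGLE_DEG


@dataclass
class EventSummary:
    count: int
    events_per_minute: float
    mean_duration_s: float  # NaN when count == 0
    mean_angle_deg: float  # NaN when count == 0
    percent_traveling_waves: float  # NaN when count == 0
    defined: bool  # False when count == 0


def build_velocity_heatmap(
    displacements: Sequence[SectorDisplacement],
    frame_interval_s: float,
    norm_constant: Optional[float] = None,
) -> VelocityHeatmap:
    """Assemble V_raw[i, t] = d . n and its sign-preserving normalization.

    ``norm_constant`` overrides the per-movie maximum |V_raw| when maps from
    several cells must share one scale (pass the set-wide maximum).
    """
    if not displacements:
        raise ValueError("no displacement frames given")
    n_sec = displacements[0].d_um.shape[0]
    t = len(displacements)
    raw = np.full((n_sec, t), np.nan)
    missing = np.zeros((n_sec, t), dtype=bool)
    for j, disp in enumerate(displacements):
        if disp.d_um.shape[0] != n_sec:
            raise ValueError("inconsistent sector counts across frames")
        v = np.einsum("ij,ij->i", disp.d_um, disp.normals)
        raw[:, j] = np.where(disp.valid, v, np.nan)
        missing[:, j] = ~disp.valid
        if not disp.valid.any():
            raise ValueError(f"all sectors missing in frame pair {j}")
    if norm_constant is None:
        norm_constant = float(np.nanmax(np.abs(raw)))
    if norm_constant == 0:
        normalized = np.zeros_like(raw)
        normalized[missing] = np.nan
    else:
        normalized = raw / norm_constant
    return VelocityHeatmap(
        raw=raw,
        normalized=normalized,
        missing=missing,
        frame_interval_s=frame_interval_s,
        norm_constant=float(norm_constant),
    )


def _wraparound_label(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling with rows wrapping (sector axis is circular)."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, 0
    n_rows = binary.shape[0]
    if n_rows < 2:
        return labels, n
    # merge labels adjacent across the row 0 / row N-1 seam (incl. diagonals)
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    top, bot = labels[0], labels[-1]
    t_cols = binary.shape[1]
    for j in range(t_cols):
        if top[j] == 0:
            continue
        for dj in (-1, 0, 1):
            jj = j + dj
            if 0 <= jj < t_cols and bot[jj] != 0:
                union(top[j], bot[jj])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    next_id = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if remap[root] == 0:
            next_id += 1
            remap[root] = next_id
        remap[lab] = remap[root]
    return remap[labels], next_id


def _region_angle_deg(rows: np.ndarray, cols: np.ndarray, n_rows: int, wraps: bool) -> float:
    """Major-axis orientation from the time axis via second central moments."""
    r = rows.astype(float)
    if wraps:
        # unwrap: shift rows so the region is contiguous
        present = np.zeros(n_rows, dtype=bool)
        present[rows] = True
        gaps = np.flatnonzero(~present)
        if gaps.size:
            shift = n_rows - gaps[-1] - 1  # rotate so the largest gap ends the axis
            r = (r + shift) % n_rows
    x = cols.astype(float) - cols.mean()  # time axis
    y = r - r.mean()  # sector axis
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    if mu20 == mu02 and mu11 == 0:
        return 0.0
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)  # in (-pi/2, pi/2]
    return abs(math.degrees(theta))


def extract_events(
    heatmap: Union[VelocityHeatmap, "object"],
    value_threshold: float = 0.3,
    min_area: int = 6,
    signed: bool = True,
) -> list[MembraneEvent]:
    """Segment a heatmap into connected above-threshold events.

    For velocity maps (``signed=True``) protrusions (V >= threshold) and
    retractions (V <= -threshold) are labeled separately; for colocalization
    maps pass ``signed=False`` to threshold the normalized values one-sided.
    Components smaller than ``min_area`` heatmap cells are dropped.
    """
    values = heatmap.normalized
    missing = getattr(heatmap, "missing", None)
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    if not np.isfinite(values[~missing]).all():
        raise ValueError("heatmap contains non-finite values outside the missing mask")
    interval = heatmap.frame_interval_s

    work = np.where(missing, 0.0, values)
    passes: list[tuple[str, np.ndarray]] = []
    if signed:
        passes.append(("protrusion", work >= value_threshold))
        passes.append(("retraction", work <= -value_threshold))
    else:
        passes.append(("coloc", work >= value_threshold))

    events: list[MembraneEvent] = []
    n_rows = values.shape[0]
    for polarity, binary in passes:
        labels, n = _wraparound_label(binary)
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            if rows.size < min_area:
                continue
            wraps = (0 in rows) and (n_rows - 1 in rows)
            angle = _region_angle_deg(rows, cols, n_rows, wraps)
            f0, f1 = int(cols.min()), int(cols.max())
            events.append(
                MembraneEvent(
                    polarity=polarity,
                    cells=np.column_stack([rows, cols]),
                    area=int(rows.size),
                    duration_s=(f1 - f0 + 1) * interval,
                    angle_deg=angle,
                    frame_range=(f0, f1),
                    sector_range=(int(rows.min()), int(rows.max())),
                    mean_value=float(values[rows, cols].mean()),
                )
            )
    events.sort(key=lambda e: (e.frame_range[0], e.sector_range[0], e.polarity))
    return events


def summarize_events(events: Sequence[MembraneEvent], movie_duration_s: float) -> EventSummary:
    """Per-cell event statistics; means are NaN-flagged when no events exist."""
    if movie_duration_s <= 0:
        raise ValueError("movie_duration_s must be > 0")
    count = len(events)
    rate = count / (movie_duration_s / 60.0)
    if count == 0:
        return EventSummary(
            count=0,
            events_per_minute=rate,
            mean_duration_s=float("nan"),
            mean_angle_deg=float("nan"),
            percent_traveling_waves=float("nan"),
            defined=False,
        )
    durations = np.array([e.duration_s for e in events])
    angles = np.array([e.angle_deg for e in events])
    waves = np.array([e.is_traveling_wave for e in events])
    return EventSummary(
        count=count,
        events_per_minute=rate,
        mean_duration_s=float(durations.mean()),
        mean_angle_deg=float(angles.mean()),
        percent_traveling_waves=float(100.0 * waves.mean()),
        defined=True,
    )
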