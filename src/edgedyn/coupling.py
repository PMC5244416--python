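"""Coupling between membrane velocity and edge-band colocalization.

The coupling map is the elementwise product C_raw[i, t] = V[i, t] *
coloc[i, t] of the normalized velocity and colocalization heatmaps, so the
sign of C encodes the direction of coupled motion: +1 protrusion with high
colocalization, -1 retraction with high colocalization, 0 quiescence.

Maps from different cells are made comparable by one symmetric scale
factor s = max(|max|, |min|) over the whole analysis set: C = C_raw / s
maps the set-wide extreme to +/-1 while preserving signs and zeros.  A
scalar per-cell summary (the mean of C_raw over defined cells) is also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from edgedyn.colocalization import ColocHeatmap
from edgedyn.dynamics import VelocityHeatmap

# legend anchors: (value, meaning)
INTERPRETATION_SCALE = (
    (1.0, "coupled protrusion, high colocalization"),
    (0.5, "coupled protrusion, low colocalization"),
    (0.0, "quiescence, low colocalization"),
    (-0.5, "coupled retraction, low colocalization"),
    (-1.0, "coupled retraction, high colocalization"),
)


@dataclass
class CouplingHeatmap:
    """Region x time coupling matrix; ``normalized`` is None until scaled."""

    raw: np.ndarray  # (N, T) product map; NaN where either parent missing
    missing: np.ndarray  # (N, T) bool
    frame_interval_s: float
    normalized: np.ndarray | None = None
    scale: float | None = None

    @property
    def mean_coupling(self) -> float:
        """Scalar per-cell summary: mean of C_raw over defined cells."""
        defined = self.raw[~self.missing]
        return float(defined.mean()) if defined.size else float("nan")


def coupling_map(velocity: VelocityHeatmap, coloc: ColocHeatmap) -> CouplingHeatmap:
    """Elementwise product of the two normalized heatmaps.

    The velocity map has one fewer column than the colocalization map when
    both come from the same movie (T-1 frame pairs vs T frames); the
    colocalization column at the pair's first frame is used.  Cells missing
    in either parent are masked.
    """
    v = velocity.normalized
    c = coloc.normalized
    c_missing = coloc.missing
    if c.shape[0] != v.shape[0]:
        raise ValueError(
            f"row mismatch: velocity has {v.shape[0]} sectors, coloc {c.shape[0]}"
        )
    if c.shape[1] == v.shape[1] + 1:
        c = c[:, :-1]
        c_missing = c_missing[:, :-1]
    elif c.shape[1] != v.shape[1]:
        raise ValueError(
            f"column mismatch: velocity {v.shape[1]}, coloc {c.shape[1]}"
        )
    missing = velocity.missing | c_missing
    raw = np.where(missing, np.nan, v * c)
    return CouplingHeatmap(
        raw=raw, missing=missing, frame_interval_s=velocity.frame_interval_s
    )


def normalize_across_cells(maps: Sequence[CouplingHeatmap]) -> list[CouplingHeatmap]:
    """Divide every map by one symmetric set-wide scale factor.

    s = max(|set max|, |set min|) over all defined cells of all maps;
    preserves zeros and signs.  An all-zero set is returned unchanged with a
    warning.
    """
    if not maps:
        raise ValueError("need at least one coupling map")
    extremes = []
    for m in maps:
        defined = m.raw[~m.missing]
        if defined.size:
            extremes.append((defined.max(), defined.min()))
    scale = max((max(abs(hi), abs(lo)) for hi, lo in extremes), default=0.0)
    if scale == 0.0:
        warnings.warn("all coupling values are zero; maps returned unnormalized")
        out = []
        for m in maps:
            out.append(
                CouplingHeatmap(
                    raw=m.raw, missing=m.missing,
                    frame_interval_s=m.frame_interval_s,
                    normalized=m.raw.copy(), scale=1.0,
                )
            )
        return out
    out = []
    for m in maps:
        out.append(
            CouplingHeatmap(
                raw=m.raw, missing=m.missing,
                frame_interval_s=m.frame_interval_s,
                normalized=m.raw / scale, scale=float(scale),
            )
        )
    return out


def interpretation_label(value: float) -> str:
    """Nearest legend meaning for one normalized coupling value."""
    if not np.isfinite(value):
        return "undefined"
    anchor, label = min(INTERPRETATION_SCALE, key=lambda al: abs(al[0] - value))
    return label
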