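"""Cell-motility metrics: meandering index, wound closure, C:N ratio."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class MotilityError(RuntimeError):
    pass


@dataclass
class Track:
    """One cell trajectory: ordered (x, y) positions in um per frame."""

    positions_um: np.ndarray  # (T, 2)
    frame_interval_s: float
    track_id: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise MotilityError("track needs at least two (x, y) positions")
        if not np.isfinite(pos).all():
            raise MotilityError("track positions must be finite")
        self.positions_um = pos


@dataclass
class WoundSeries:
    """Wound (cell-free) area per timepoint."""

    time_h: np.ndarray
    area_um2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        a = np.asarray(self.area_um2, dtype=float)
        if t.shape != a.shape:
            raise MotilityError("time and area vectors must align")
        if (a < 0).any():
            raise MotilityError("wound areas must be >= 0")
        if t.size == 0 or t[0] != 0:
            raise MotilityError("wound series must start at t = 0")
        self.time_h, self.area_um2 = t, a


@dataclass
class CompartmentMasks:
    """Nucleus and cytoplasm masks of one cell (disjoint, both non-empty)."""

    nucleus: np.ndarray
    cytoplasm: np.ndarray

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nucleus, dtype=bool)
        cyt = np.asarray(self.cytoplasm, dtype=bool)
        if nuc.shape != cyt.shape:
            raise MotilityError("compartment masks must share a shape")
        if (nuc & cyt).any():
            raise MotilityError("nucleus and cytoplasm masks overlap")
        if not nuc.any() or not cyt.any():
            raise MotilityError("both compartment masks must be non-empty")
        self.nucleus, self.cytoplasm = nuc, cyt


def meandering_index(track: Track) -> float:
    """Net displacement over summed step lengths, in [0, 1]; NaN if no path."""
    pos = track.positions_um
    path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    if path == 0:
        return float("nan")
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    return displacement / path


def wound_closure(series: WoundSeries) -> np.ndarray:
    """Percent of the initial wound area closed at each timepoint.

    percent(t) = 100 * (area(0) - area(t)) / area(0), clipped below at 0 so
    transient wound growth reads as 0% closed rather than negative.
    """
    a0 = series.area_um2[0]
    if a0 <= 0:
        raise MotilityError("initial wound area must be > 0")
    percent = 100.0 * (a0 - series.area_um2) / a0
    return np.clip(percent, 0.0, None)


def cn_ratio(frame: np.ndarray, masks: CompartmentMasks) -> float:
    """Cytoplasmic-to-nuclear mean-intensity ratio; NaN if the nuclear mean is 0."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != masks.nucleus.shape:
        raise MotilityError("frame and masks must share a shape")
    nuclear = float(frame[masks.nucleus].mean())
    cytoplasmic = float(frame[masks.cytoplasm].mean())
    if nuclear == 0:
        return float("nan")
    return cytoplasmic / nuclear


def interpolate_gaps(positions_um: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Fill missing frames of a track by linear interpolation.

    ``frames`` are the integer frame indices at which ``positions_um`` were
    observed; returns positions on the full contiguous frame range.
    """
    frames = np.asarray(frames)
    full = np.arange(frames[0], frames[-1] + 1)
    x = np.interp(full, frames, positions_um[:, 0])
    y = np.interp(full, frames, positions_um[:, 1])
    return np.column_stack([x, y])
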