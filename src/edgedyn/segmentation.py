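"""Cell segmentation, boundary extraction, sectorization and sector tracking.

The segmenter is deliberately simple (between-class-variance global
threshold, hole fill, largest component): the movies this package targets
are high-contrast single-cell fields, and the segmenter is pluggable — any
routine producing a :class:`CellMask` can feed the rest of the pipeline.

Boundaries are sub-pixel closed polylines in micrometres, resampled to
uniform arclength, with outward unit normals.  The boundary is divided into
N = round(perimeter / sector_length) contiguous equal-arclength sectors
(~10 um by default); sector 0 is anchored where the ray from the cell
centroid along +x crosses the boundary, so heatmap rows are comparable
across frames.  Frame-to-frame sector correspondence is by normal-ray
casting from sector midpoints with a nearest-point fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage import filters, measure


class SegmentationError(RuntimeError):
    pass


@dataclass
class CellMask:
    """Single-frame binary cell mask with calibration."""

    mask: np.ndarray  # (H, W) bool
    pixel_size_um: float
    frame_index: int = 0


@dataclass
class BoundaryFrame:
    """Closed cell boundary of one frame.

    ``xy_um`` is an ordered closed polyline (first vertex not repeated),
    uniformly spaced in arclength; ``normals`` are outward unit vectors per
    vertex; ``arclength_um`` is cumulative arclength at each vertex;
    ``sector_id`` (once sectorized) assigns each vertex to one of
    ``n_sectors`` contiguous equal-length sectors.
    """

    xy_um: np.ndarray  # (M, 2)
    normals: np.ndarray  # (M, 2)
    arclength_um: np.ndarray  # (M,)
    perimeter_um: float
    pixel_size_um: float
    frame_index: int = 0
    sector_id: Optional[np.ndarray] = None
    n_sectors: int = 0

    def sector_midpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions and outward normals at sector arclength midpoints."""
        if self.n_sectors == 0:
            raise ValueError("boundary has not been sectorized")
        length = self.perimeter_um / self.n_sectors
        s_mid = (np.arange(self.n_sectors) + 0.5) * length
        x = np.interp(s_mid, self.arclength_um, self.xy_um[:, 0], period=self.perimeter_um)
        y = np.interp(s_mid, self.arclength_um, self.xy_um[:, 1], period=self.perimeter_um)
        nx = np.interp(s_mid, self.arclength_um, self.normals[:, 0], period=self.perimeter_um)
        ny = np.interp(s_mid, self.arclength_um, self.normals[:, 1], period=self.perimeter_um)
        n = np.column_stack([nx, ny])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return np.column_stack([x, y]), n


@dataclass
class SectorDisplacement:
    """Per-sector boundary displacement between consecutive frames."""

    d_um: np.ndarray  # (N, 2) displacement vectors, um
    normals: np.ndarray  # (N, 2) matched outward normals at frame t
    valid: np.ndarray  # (N,) False where no correspondence was found


def segment_cell(
    frame: np.ndarray, pixel_size_um: float, frame_index: int = 0,
    threshold: Optional[float] = None,
) -> CellMask:
    """Threshold one intensity frame into a single filled cell mask.

    Uses Otsu's between-class-variance threshold unless ``threshold`` is
    given, fills holes and keeps the largest connected component.  Fails
    with a frame-identifying message when no cell is found or when a second
    comparably sized component makes the field ambiguous.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if np.ptp(frame) == 0:
            raise SegmentationError(f"no cell found in frame {frame_index}: image is flat")
        threshold = filters.threshold_otsu(frame)
    binary = frame > threshold
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise SegmentationError(f"no cell found in frame {frame_index}")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] > 0.5 * sizes[order[0]]:
        raise SegmentationError(
            f"frame {frame_index}: multiple comparably sized components "
            f"({int(sizes[order[0]])} and {int(sizes[order[1]])} px); expected one cell"
        )
    mask = labels == order[0] + 1
    return CellMask(mask=mask, pixel_size_um=pixel_size_um, frame_index=frame_index)


def _resample_closed(xy: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample a closed polyline to uniform arclength spacing."""
    closed = np.vstack([xy, xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s[-1]
    m = max(64, int(round(perimeter / spacing)))
    s_new = np.arange(m) * perimeter / m
    x = np.interp(s_new, s, closed[:, 0])
    y = np.interp(s_new, s, closed[:, 1])
    return np.column_stack([x, y]), s_new, perimeter


def boundary_from_polyline(
    xy_um: np.ndarray,
    pixel_size_um: float = 0.2,
    frame_index: int = 0,
    spacing_um: Optional[float] = None,
) -> BoundaryFrame:
    """Build a boundary frame from an analytic closed polyline (no mask).

    Normals are oriented away from the vertex centroid, which is correct for
    the star-convex shapes this constructor is meant for (synthetic ground
    truth, geometric test fixtures).
    """
    xy = np.asarray(xy_um, dtype=float)
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    spacing = spacing_um if spacing_um is not None else pixel_size_um / 2
    xy, s, perimeter = _resample_closed(xy, spacing)
    tangent = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    centroid = xy.mean(axis=0)
    outwardness = np.einsum("ij,ij->i", normals, xy - centroid)
    if np.median(outwardness) < 0:
        normals = -normals
    ang = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    start = int(np.argmin(np.abs(ang)))
    xy = np.roll(xy, -start, axis=0)
    normals = np.roll(normals, -start, axis=0)
    return BoundaryFrame(
        xy_um=xy,
        normals=normals,
        arclength_um=s,
        perimeter_um=perimeter,
        pixel_size_um=pixel_size_um,
        frame_index=frame_index,
    )


def extract_boundary(cell: CellMask) -> BoundaryFrame:
    """Sub-pixel closed boundary with uniform arclength and outward normals."""
    mask = cell.mask
    if mask.sum() == 0 or measure.perimeter(mask) < 16:
        raise SegmentationError(
            f"frame {cell.frame_index}: mask too small for boundary extraction"
        )
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError(f"frame {cell.frame_index}: no contour found")
    contour = max(contours, key=len)  # (row, col)
    xy = contour[:, ::-1] * cell.pixel_size_um  # -> (x, y) um
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]

    # marching squares yields a staircase that overestimates arclength by
    # ~5% and wobbles normals; smooth along the curve over ~3 px before
    # measuring geometry
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    mean_spacing = seg.mean()
    sigma = 3.0 * cell.pixel_size_um / mean_spacing
    xy = np.column_stack([
        ndimage.gaussian_filter1d(xy[:, 0], sigma, mode="wrap"),
        ndimage.gaussian_filter1d(xy[:, 1], sigma, mode="wrap"),
    ])

    xy, s, perimeter = _resample_closed(xy, spacing=cell.pixel_size_um / 2)

    # tangent by central difference on the closed curve
    tangent = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])

    # orient normals outward: the vertex plus a half-pixel step along the
    # normal should leave the mask more often than not
    probe = xy + normals * cell.pixel_size_um
    rows = np.clip(np.round(probe[:, 1] / cell.pixel_size_um).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(probe[:, 0] / cell.pixel_size_um).astype(int), 0, mask.shape[1] - 1)
    if mask[rows, cols].mean() > 0.5:
        normals = -normals

    # anchor vertex 0 at the +x ray from the centroid
    centroid = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    start = int(np.argmin(np.abs(ang)))
    xy = np.roll(xy, -start, axis=0)
    normals = np.roll(normals, -start, axis=0)

    return BoundaryFrame(
        xy_um=xy,
        normals=normals,
        arclength_um=s,
        perimeter_um=perimeter,
        pixel_size_um=cell.pixel_size_um,
        frame_index=cell.frame_index,
    )


def discretize_sectors(
    boundary: BoundaryFrame,
    sector_length_um: float = 10.0,
    n_sectors: Optional[int] = None,
) -> BoundaryFrame:
    """Assign each vertex to one of N contiguous equal-arclength sectors.

    N defaults to round(perimeter / sector_length_um); pass ``n_sectors`` to
    force the count chosen on a reference frame so heatmap rows align across
    a movie.
    """
    p = boundary.perimeter_um
    if n_sectors is None:
        if p < 2 * sector_length_um:
            raise SegmentationError(
                f"perimeter {p:.1f} um shorter than two sectors of {sector_length_um} um"
            )
        n_sectors = max(4, round(p / sector_length_um))
    length = p / n_sectors
    sector_id = np.minimum((boundary.arclength_um // length).astype(int), n_sectors - 1)
    boundary.sector_id = sector_id
    boundary.n_sectors = n_sectors
    return boundary


def track_sectors(
    boundary_t: BoundaryFrame,
    boundary_t1: BoundaryFrame,
    max_motion_um: float = 5.0,
) -> SectorDisplacement:
    """Displacement of each sector midpoint from frame t to frame t+1.

    Correspondence casts a ray along the sector's outward normal (both
    directions, window ``max_motion_um``) and takes the intersection with
    the t+1 boundary closest to the midpoint; if the ray misses, the nearest
    Euclidean boundary point is used, and sectors with no boundary within
    the window are flagged invalid rather than zeroed.
    """
    if boundary_t.n_sectors != boundary_t1.n_sectors or boundary_t.n_sectors == 0:
        raise ValueError("both frames must be sectorized with equal sector counts")
    mids, norms = boundary_t.sector_midpoints()
    target = LineString(np.vstack([boundary_t1.xy_um, boundary_t1.xy_um[:1]]))

    n_sec = boundary_t.n_sectors
    d = np.zeros((n_sec, 2))
    valid = np.ones(n_sec, dtype=bool)
    for i in range(n_sec):
        m, n = mids[i], norms[i]
        ray = LineString([m - max_motion_um * n, m + max_motion_um * n])
        inter = ray.intersection(target)
        best = None
        if not inter.is_empty:
            pts = []
            if inter.geom_type == "Point":
                pts = [inter]
            elif hasattr(inter, "geoms"):
                for g in inter.geoms:
                    if g.geom_type == "Point":
                        pts.append(g)
                    else:  # collinear overlap: use its nearest coordinate
                        pts.append(Point(g.coords[0]))
            if pts:
                pm = Point(m)
                best = min(pts, key=lambda pt: pt.distance(pm))
        if best is None:
            nearest = target.interpolate(target.project(Point(m)))
            if nearest.distance(Point(m)) <= max_motion_um:
                best = nearest
        if best is None:
            valid[i] = False
            continue
        d[i] = [best.x - m[0], best.y - m[1]]
    return SectorDisplacement(d_um=d, normals=norms, valid=valid)
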