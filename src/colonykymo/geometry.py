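"""Colony segmentation and the center-to-rim radial sampling line.

The colony footprint is segmented from the live channel with a Triangle
histogram threshold; per-frame centroid and Feret (maximum caliper) angle are
measured, and a fixed sampling ray — anchored at the centroid of the first
analyzed frame, pointing along its Feret angle — is intersected with each
frame's colony boundary to give the calibrated radial axis used by the
kymograph.

Coordinate convention: (row, col), 0-based pixel centers; angles in degrees,
measured counterclockwise from the +col axis (so +row is at -90).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "triangle_threshold",
    "segment_colony",
    "centroid",
    "feret",
    "radial_line",
    "RadialLine",
    "ColonyGeometry",
    "compute_geometry",
    "geometry_to_csv",
]


def triangle_threshold(frame: np.ndarray | None = None, *,
                       histogram: tuple[np.ndarray, np.ndarray] | None = None,
                       nbins: int = 256) -> float:
    """Automatic threshold by the Triangle construction.

    A line is drawn from the histogram peak to the farthest nonempty bin;
    the threshold is the bin (strictly between the two) maximizing the
    perpendicular distance between the histogram curve and that line, with
    bin index and count axes normalized to the peak-to-tail span. Ties break
    to the lower bin.

    Pass either a 2-D ``frame`` (histogrammed with ``nbins`` bins over its
    observed range, the 8-bit-style convention) or a precomputed
    ``histogram = (counts, bin_centers)``.
    """
    if histogram is None:
        if frame is None:
            raise ValueError("provide a frame or a histogram")
        frame = np.asarray(frame)
        lo, hi = float(frame.min()), float(frame.max())
        if lo == hi:
            raise ValueError("single-bin histogram: no separation possible")
        counts, edges = np.histogram(frame, bins=nbins, range=(lo, hi))
        centers = (edges[:-1] + edges[1:]) / 2
    else:
        counts, centers = histogram
        counts = np.asarray(counts, dtype=float)
        centers = np.asarray(centers, dtype=float)
    nonzero = np.flatnonzero(counts)
    if len(nonzero) < 2:
        raise ValueError("histogram must have at least two nonempty bins")

    peak = int(np.argmax(counts))  # ties: lower bin
    dist = np.abs(nonzero - peak)
    far = int(nonzero[np.argmax(dist)])  # ties: lower bin (nonzero is sorted
    # ascending, argmax returns the first, i.e. the lower-index side)
    if far == peak:
        raise ValueError("histogram peak is the only nonempty bin")

    lo_i, hi_i = sorted((peak, far))
    inner = np.arange(lo_i + 1, hi_i)
    if len(inner) == 0:
        return float((centers[lo_i] + centers[hi_i]) / 2)
    # normalized coordinates: peak -> (0, 1), far tail -> (1, y_far)
    x = (inner - peak) / (far - peak)
    y = counts[inner] / counts[peak]
    y_far = counts[far] / counts[peak]
    # perpendicular distance from (x, y) to the line (0,1)-(1,y_far)
    d = np.abs((y_far - 1.0) * x - y + 1.0) / np.hypot(y_far - 1.0, 1.0)
    best = inner[int(np.argmax(d))]  # ties: lower bin
    return float(centers[best])


def segment_colony(live_frame: np.ndarray,
                   threshold: float | None = None) -> np.ndarray:
    """Colony mask: largest connected component above threshold, holes filled.

    The threshold defaults to :func:`triangle_threshold` of the frame.
    """
    live_frame = np.asarray(live_frame)
    if threshold is None:
        threshold = triangle_threshold(live_frame)
    fg = live_frame > threshold
    if not fg.any():
        raise ValueError("no colony detected")
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(mask)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixel coordinates."""
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("empty mask")
    r, c = pts.mean(axis=0)
    return float(r), float(c)


def feret(mask: np.ndarray) -> tuple[float, float]:
    """Maximum caliper (Feret) diameter in px and its angle in degrees.

    The diameter is the largest distance between foreground pixel centers,
    found by a pair scan over convex-hull vertices; the angle is measured
    counterclockwise from the +col axis, reported in [0, 180) with ties
    broken toward the smaller angle.
    """
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        raise ValueError("empty mask")
    if len(pts) == 1:
        return 0.0, 0.0
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear points: scan all of them
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    dmax = d.max()
    best_angle = None
    ii, jj = np.where(d >= dmax - 1e-9)
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        drow, dcol = pts[j] - pts[i]
        ang = np.rad2deg(np.arctan2(-drow, dcol)) % 180.0
        if best_angle is None or ang < best_angle:
            best_angle = ang
    return float(dmax), float(best_angle)


@dataclass
class RadialLine:
    """Unit-spaced samples from the ray origin to the colony boundary."""

    path: np.ndarray       # [N, 2] (row, col) float coordinates
    length_mm: float
    origin: tuple[float, float]
    angle_deg: float


def radial_line(origin: tuple[float, float], angle_deg: float,
                mask: np.ndarray, pixel_size: float = 1.0) -> RadialLine:
    """Discrete ray from ``origin`` along ``angle_deg`` to its first exit
    from the mask; samples are one pixel apart and the endpoint is the last
    sample inside the mask (a boundary pixel)."""
    r0, c0 = origin
    ir, ic = int(round(r0)), int(round(c0))
    h, w = mask.shape
    if not (0 <= ir < h and 0 <= ic < w) or not mask[ir, ic]:
        raise ValueError("ray origin lies outside the mask")
    a = np.deg2rad(angle_deg)
    step = np.array([-np.sin(a), np.cos(a)])
    max_steps = int(np.ceil(np.hypot(h, w)))
    pts = np.array([r0, c0]) + np.arange(max_steps)[:, None] * step
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= h - 1)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1)
    )
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    inside &= mask[rows, cols]
    # first exit truncates the ray
    n = int(np.argmin(inside)) if not inside.all() else len(pts)
    if n == 0:
        raise ValueError("ray origin lies outside the mask")
    path = pts[:n]
    length_mm = float((n - 1) * pixel_size)
    return RadialLine(path=path, length_mm=length_mm,
                      origin=(float(r0), float(c0)),
                      angle_deg=float(angle_deg))


@dataclass
class ColonyGeometry:
    """Per-frame colony geometry plus the frozen sampling ray."""

    masks: np.ndarray              # [T, H, W] bool
    centroids: np.ndarray          # [T, 2] (row, col)
    feret_angles: np.ndarray       # [T] degrees
    feret_diameters: np.ndarray    # [T] px
    boundary_radius_mm: np.ndarray  # [T] along the frozen ray
    ray_origin: tuple[float, float]
    ray_angle_deg: float
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def _angle_in_wedge(angle: float, wedge: tuple[float, float]) -> bool:
    center, width = wedge
    d = (angle - center + 180.0) % 360.0 - 180.0
    return abs(d) <= width / 2


def compute_geometry(live_frames: np.ndarray, pixel_size: float,
                     angle_deg: float | None = None, freeze_frame: int = 0,
                     excluded_wedges: list[tuple[float, float]] | None = None
                     ) -> ColonyGeometry:
    """Segment every frame and construct the frozen sampling ray.

    The ray origin and angle are taken from ``freeze_frame`` (centroid and
    Feret angle, or the explicit ``angle_deg`` override) so the kymograph
    tracks one fixed ray while its endpoint follows colony growth.
    ``excluded_wedges`` — (center deg, width deg) angular sectors to avoid,
    the reproducible surrogate for manually steering the line away from
    sector outgrowths — rotate the ray to the nearest allowed angle.
    """
    live_frames = np.asarray(live_frames)
    if live_frames.ndim != 3:
        raise ValueError("live_frames must be [T, H, W]")
    n = live_frames.shape[0]
    masks = np.zeros(live_frames.shape, dtype=bool)
    cents = np.full((n, 2), np.nan)
    angles = np.full(n, np.nan)
    diams = np.full(n, np.nan)
    thresholds = np.full(n, np.nan)
    for t in range(n):
        thresholds[t] = triangle_threshold(live_frames[t])
        masks[t] = segment_colony(live_frames[t], thresholds[t])
        cents[t] = centroid(masks[t])
        diams[t], angles[t] = feret(masks[t])

    origin = (float(cents[freeze_frame, 0]), float(cents[freeze_frame, 1]))
    ray_angle = float(angles[freeze_frame]) if angle_deg is None else float(angle_deg)
    if excluded_wedges:
        candidates = (ray_angle + np.arange(0, 360, 5.0)) % 360.0
        for cand in candidates:
            if not any(_angle_in_wedge(cand, w) for w in excluded_wedges):
                ray_angle = float(cand)
                break
        else:
            raise ValueError("excluded wedges leave no admissible ray angle")

    radius_mm = np.full(n, np.nan)
    a = np.deg2rad(ray_angle)
    step = np.array([-np.sin(a), np.cos(a)])
    for t in range(n):
        try:
            line = radial_line(origin, ray_angle, masks[t], pixel_size)
        except ValueError:
            warnings.warn(f"ray origin outside colony mask at frame {t}")
            continue
        radius_mm[t] = line.length_mm
        # sub-pixel refinement: the boundary is where the live intensity
        # falls to the mid-edge level (halfway between the interior plateau
        # and the outside level), sampled along the ray around the mask
        # endpoint — the mask endpoint itself sits at the segmentation-
        # threshold crossing, which is biased toward the outer edge foot
        k = len(line.path) - 1
        offs = np.arange(max(0, k - 3), k + 4, dtype=float)
        pts = np.asarray(origin)[None, :] + offs[:, None] * step[None, :]
        h, w = masks[t].shape
        ok = ((pts[:, 0] >= 0) & (pts[:, 0] <= h - 1)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1))
        offs, pts = offs[ok], pts[ok]
        if len(offs) >= 3:
            vals = ndi.map_coordinates(live_frames[t], pts.T, order=1)
            level = 0.5 * (vals[0] + vals[-1])
            for j in range(len(vals) - 1):
                if vals[j] >= level > vals[j + 1]:
                    frac = (vals[j] - level) / (vals[j] - vals[j + 1])
                    radius_mm[t] = (offs[j] + frac) * pixel_size
                    break
    return ColonyGeometry(masks=masks, centroids=cents, feret_angles=angles,
                          feret_diameters=diams, boundary_radius_mm=radius_mm,
                          ray_origin=origin, ray_angle_deg=ray_angle,
                          pixel_size=pixel_size)


def geometry_to_csv(geom: ColonyGeometry, times: np.ndarray,
                    path: str | Path) -> None:
    """Export per-frame geometry (t, centroid, Feret angle, radius in mm)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "centroid_row", "centroid_col",
                         "feret_angle_deg", "radius_mm"])
        for t in range(geom.n_frames):
            writer.writerow([float(times[t]), geom.centroids[t, 0],
                             geom.centroids[t, 1], geom.feret_angles[t],
                             geom.boundary_radius_mm[t]])
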