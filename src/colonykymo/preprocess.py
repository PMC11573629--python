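"""Image conditioning applied before geometry extraction.

Stages, in acquisition-processing order: maximum-intensity z-projection,
linear-blend tile stitching, rolling-ball background subtraction, and rigid
(translation + rotation) time-series registration estimated on the live
channel and applied identically to both channels.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import block_reduce
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .simulate import TileSet

__all__ = [
    "RigidTransform",
    "apply_rigid",
    "max_projection",
    "stitch_tiles",
    "rolling_ball_background",
    "register_series",
    "RegistrationResult",
    "apply_transforms",
    "transforms_to_csv",
    "transforms_from_csv",
]


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rigid correction (rotate by ``theta`` about the image center, then
    translate by ``(dy, dx)`` pixels) that aligns a frame to its reference."""

    dy: float = 0.0
    dx: float = 0.0
    theta: float = 0.0  # degrees, counterclockwise
    reference_frame_index: int = 0
    degenerate: bool = False

    @property
    def is_identity(self) -> bool:
        return self.dy == 0.0 and self.dx == 0.0 and self.theta == 0.0


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def _inverse_map(dy: float, dx: float, theta_deg: float,
                 center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(M, off) such that output(x) = input(M @ x + off) realizes the
    rotate-about-center-then-translate forward transform."""
    m = _rotation_matrix(-theta_deg)
    t = np.array([dy, dx], dtype=float)
    off = center - m @ (center + t)
    return m, off


def _params_from_inverse_map(m: np.ndarray, off: np.ndarray,
                             center: np.ndarray) -> tuple[float, float, float]:
    theta = -np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    t = np.linalg.solve(m, center - off) - center
    return float(t[0]), float(t[1]), float(theta)


def compose(first: RigidTransform, second: RigidTransform,
            shape: tuple[int, int]) -> RigidTransform:
    """Rigid transform equivalent to applying ``first`` then ``second``."""
    center = (np.asarray(shape, dtype=float) - 1) / 2
    m1, o1 = _inverse_map(first.dy, first.dx, first.theta, center)
    m2, o2 = _inverse_map(second.dy, second.dx, second.theta, center)
    # inverse maps compose in reverse order
    m, off = m1 @ m2, m1 @ o2 + o1
    dy, dx, theta = _params_from_inverse_map(m, off, center)
    return RigidTransform(dy=dy, dx=dx, theta=theta,
                          reference_frame_index=second.reference_frame_index,
                          degenerate=first.degenerate or second.degenerate)


def apply_rigid(frame: np.ndarray, dy: float = 0.0, dx: float = 0.0,
                theta_deg: float = 0.0, order: int = 1,
                cval: float = 0.0) -> np.ndarray:
    """Rotate a frame by ``theta_deg`` about its center then shift by
    ``(dy, dx)`` px, bilinear by default. Exact (no interpolation) when the
    transform is the identity."""
    if dy == 0.0 and dx == 0.0 and theta_deg == 0.0:
        return frame.copy()
    center = (np.asarray(frame.shape, dtype=float) - 1) / 2
    m, off = _inverse_map(dy, dx, theta_deg, center)
    return ndi.affine_transform(frame, m, offset=off, order=order,
                                mode="constant", cval=cval,
                                output=np.float32 if frame.dtype == np.float32
                                else float)


# ---------------------------------------------------------------------------
# z-projection and stitching
# ---------------------------------------------------------------------------

def max_projection(zstack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over the leading (slice) axis."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("zstack must be a non-empty [Z, H, W] array")
    return zstack.max(axis=0)


def stitch_tiles(tileset: TileSet) -> np.ndarray:
    """Reassemble tiles into one frame with a linear-blend cross-fade.

    Each tile contributes a separable weight that falls off linearly toward
    its edges; weights are normalized to sum to one, so regions covered by a
    single tile are copied verbatim and two-tile overlaps are a linear
    cross-fade.
    """
    if not tileset.tiles:
        raise ValueError("tileset has no tiles")
    if len(tileset.tiles) != len(tileset.positions):
        raise ValueError("every tile needs a grid position")
    shape0 = tileset.tiles[0].shape
    if any(t.shape != shape0 for t in tileset.tiles):
        raise ValueError("inconsistent tile sizes")
    h, w = tileset.frame_shape
    th, tw = shape0
    ramp_r = np.minimum(np.arange(th) + 1, th - np.arange(th)).astype(float)
    ramp_c = np.minimum(np.arange(tw) + 1, tw - np.arange(tw)).astype(float)
    weight = ramp_r[:, None] * ramp_c[None, :]
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for tile, (r0, c0) in zip(tileset.tiles, tileset.positions):
        if r0 < 0 or c0 < 0 or r0 + th > h or c0 + tw > w:
            raise ValueError("tile position outside the frame")
        num[r0:r0 + th, c0:c0 + tw] += weight * tile
        den[r0:r0 + th, c0:c0 + tw] += weight
    if np.any(den == 0):
        raise ValueError("tiles do not cover the frame")
    return num / den


# ---------------------------------------------------------------------------
# rolling-ball background subtraction
# ---------------------------------------------------------------------------

def _ball_structure(radius: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-radius, radius + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    footprint = d2 <= radius * radius
    structure = np.sqrt(np.maximum(radius * radius - d2, 0.0))
    return footprint, structure


def _rolling_ball_exact(frame: np.ndarray, radius: int) -> np.ndarray:
    """Background as the envelope traced by a ball of the given radius rolled
    under the intensity surface: grey erosion then dilation with the ball's
    height profile as a non-flat structuring element."""
    footprint, structure = _ball_structure(radius)
    eroded = ndi.grey_erosion(frame, footprint=footprint,
                              structure=structure, mode="nearest")
    return ndi.grey_dilation(eroded, footprint=footprint,
                             structure=structure, mode="nearest")


def rolling_ball_background(frame: np.ndarray, radius_px: int = 1000,
                            exact: bool | None = None,
                            shrink_target: int = 25
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-ball background estimation and subtraction.

    Returns ``(background, residual)`` with ``residual = frame - background``
    clipped at zero, so ``residual + background`` reproduces the frame
    wherever no clipping occurred.

    Parameters
    ----------
    frame : ndarray
        2-D intensity image.
    radius_px : int
        Ball radius in pixels (default 1000, suited to removing slowly
        varying illumination from stitched colony montages).
    exact : bool, optional
        Force the exact ball computation (quadratic in the radius). By
        default the exact path is used for radii <= 20 px and larger radii
        use the standard shrink-estimate-upsample approximation, which is
        accurate because a large-radius background varies slowly. Shrinking
        uses the block minimum so that bright compact structures (a colony,
        a death ring) cannot leak into the background estimate.
    shrink_target : int
        Approximate ball radius, in downsampled pixels, used by the
        approximation.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if exact is None:
        exact = radius_px <= 20
    factor = max(1, int(round(radius_px / shrink_target)))
    if exact or factor == 1:
        background = _rolling_ball_exact(frame, radius_px)
    else:
        small = block_reduce(frame, (factor, factor), np.min, cval=np.inf)
        small_radius = max(1, int(round(radius_px / factor)))
        small_bg = _rolling_ball_exact(small, small_radius)
        background = resize(small_bg, frame.shape, order=1,
                            preserve_range=True)
        # the upsampled estimate may locally overshoot the surface
        background = np.minimum(background, frame)
    background = np.clip(background, 0.0, None)
    residual = np.clip(frame - background, 0.0, None)
    return background, residual


# ---------------------------------------------------------------------------
# rigid time-series registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    aligned: np.ndarray            # [T, H, W]
    transforms: list[RigidTransform]
    valid: np.ndarray              # [T, H, W] bool; False where fill was used


def _estimate_single_pass(ref: np.ndarray, mov: np.ndarray,
                          max_rotation: float, rotation_step: float,
                          upsample_factor: int) -> tuple[float, float, float]:
    """One pass of the rigid estimate: a 1-D angular search wrapped around
    translation phase correlation."""
    center = (np.asarray(mov.shape, dtype=float) - 1) / 2
    crop = max(8, mov.shape[0] // 8)
    sl = (slice(crop, -crop), slice(crop, -crop))

    def at(theta: float) -> tuple[float, np.ndarray]:
        # every candidate (theta = 0 included) passes through the same
        # interpolation, otherwise the un-interpolated candidate is
        # systematically sharper and wins regardless of alignment; the
        # objective is the interior residual RMS after shift alignment,
        # cropped so edge fill cannot dominate
        m, off = _inverse_map(0.0, 0.0, theta, center)
        unrot = ndi.affine_transform(mov, m, offset=off, order=3,
                                     mode="nearest")
        shift, _, _ = phase_cross_correlation(
            ref, unrot, upsample_factor=upsample_factor, normalization=None)
        aligned = ndi.shift(unrot, shift, order=3, mode="nearest")
        rms = float(np.sqrt(np.mean((aligned[sl] - ref[sl]) ** 2)))
        return rms, shift

    if max_rotation <= 0:
        _, shift = at(0.0)
        return float(shift[0]), float(shift[1]), 0.0

    thetas = np.arange(-max_rotation, max_rotation + 1e-9, rotation_step)
    errors = np.array([at(t)[0] for t in thetas])
    i = int(np.argmin(errors))
    theta = float(thetas[i])
    if 0 < i < len(thetas) - 1:
        a, b, c = errors[i - 1], errors[i], errors[i + 1]
        denom = a - 2 * b + c
        if abs(denom) > 1e-12:
            theta += float(np.clip(0.5 * (a - c) / denom, -1, 1)) * rotation_step
    _, shift = at(theta)
    return float(shift[0]), float(shift[1]), theta


def _estimate_pair(ref: np.ndarray, mov: np.ndarray, max_rotation: float,
                   rotation_step: float, upsample_factor: int,
                   max_iter: int = 3) -> tuple[float, float, float]:
    """Rigid correction aligning ``mov`` to ``ref``.

    Subpixel phase-correlation estimates on interpolated images are shrunk
    toward zero, so the estimate is refined iteratively: apply the current
    correction, re-estimate the residual, compose."""
    if np.array_equal(ref, mov):
        return 0.0, 0.0, 0.0
    shape = mov.shape
    total = RigidTransform()
    cur = mov
    for it in range(max_iter):
        rot_range = max_rotation if it == 0 else min(max_rotation, 0.75)
        step = rotation_step if it == 0 else min(rotation_step, 0.25)
        dy, dx, theta = _estimate_single_pass(ref, cur, rot_range, step,
                                              upsample_factor)
        total = compose(total, RigidTransform(dy=dy, dx=dx, theta=theta),
                        shape)
        if abs(dy) < 0.1 and abs(dx) < 0.1 and abs(theta) < 0.05:
            break
        cur = apply_rigid(mov, dy=total.dy, dx=total.dx,
                          theta_deg=total.theta,
                          cval=float(np.median(mov)))
    return total.dy, total.dx, total.theta


def register_series(frames: np.ndarray, reference_policy: str = "previous",
                    max_rotation: float = 2.0, rotation_step: float = 0.5,
                    upsample_factor: int = 20,
                    edge_sigma: float | None = 3.0) -> RegistrationResult:
    """Rigid-body registration of a frame series.

    Transforms are estimated on the given (registration) channel; apply them
    to other channels with :func:`apply_transforms`. ``reference_policy``
    is ``"previous"`` (sequential: each frame is registered to the already-
    aligned previous frame, so inter-frame content change stays small and
    the estimate is directly the cumulative correction) or ``"first"``
    (every frame registered directly to frame 0). Blank frames are flagged
    and left untransformed with a warning.

    Estimation runs on a gradient-magnitude (edge) map of the frames
    (``edge_sigma``; ``None`` uses raw intensity): a growing flat object
    gives the raw-intensity correlation a plateau of near-equal optima as
    wide as the per-frame growth, which any residual illumination tilt tips
    sideways, whereas edge maps of concentric boundaries have a unique
    optimum. Transforms are applied to the original frames.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty [T, H, W] array")
    if reference_policy not in ("previous", "first"):
        raise ValueError("reference_policy must be 'previous' or 'first'")
    n = frames.shape[0]
    if edge_sigma is not None:
        est_frames = np.stack([
            ndi.gaussian_gradient_magnitude(frames[t].astype(float),
                                            edge_sigma)
            for t in range(n)])
    else:
        est_frames = frames
    transforms: list[RigidTransform] = [RigidTransform(reference_frame_index=0)]
    aligned_prev = est_frames[0]
    for t in range(1, n):
        mov = est_frames[t]
        if float(np.std(frames[t])) < 1e-9:
            warnings.warn(f"frame {t} is blank; identity transform used")
            transforms.append(RigidTransform(reference_frame_index=0,
                                             degenerate=True))
            continue
        ref = aligned_prev if reference_policy == "previous" else est_frames[0]
        dy, dx, theta = _estimate_pair(ref, mov, max_rotation,
                                       rotation_step, upsample_factor)
        transforms.append(RigidTransform(dy=dy, dx=dx, theta=theta,
                                         reference_frame_index=0))
        if reference_policy == "previous":
            aligned_prev = apply_rigid(mov, dy=dy, dx=dx, theta_deg=theta,
                                       cval=float(np.median(mov)))
    aligned, valid = apply_transforms(frames, transforms, with_valid=True)
    return RegistrationResult(aligned=aligned, transforms=transforms,
                              valid=valid)


def apply_transforms(frames: np.ndarray, transforms: list[RigidTransform],
                     cval: float | None = None, with_valid: bool = False):
    """Apply per-frame rigid corrections (e.g. to the other channel).

    Out-of-frame pixels are filled with the frame's median (or ``cval``) and
    flagged False in the validity mask.
    """
    frames = np.asarray(frames)
    if frames.shape[0] != len(transforms):
        raise ValueError("one transform per frame required")
    aligned = np.empty_like(frames, dtype=np.float32)
    valid = np.ones(frames.shape, dtype=bool)
    ones = np.ones(frames.shape[1:], dtype=np.float32)
    for t, tr in enumerate(transforms):
        fill = float(np.median(frames[t])) if cval is None else cval
        if tr.is_identity or tr.degenerate:
            aligned[t] = frames[t]
            continue
        aligned[t] = apply_rigid(frames[t].astype(np.float32, copy=False),
                                 dy=tr.dy, dx=tr.dx, theta_deg=tr.theta,
                                 cval=fill)
        cov = apply_rigid(ones, dy=tr.dy, dx=tr.dx, theta_deg=tr.theta,
                          cval=0.0)
        valid[t] = cov > 0.99
    if with_valid:
        return aligned, valid
    return aligned


def transforms_to_csv(transforms: list[RigidTransform],
                      path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "dx", "dy", "theta",
                         "reference_frame_index", "degenerate"])
        for i, tr in enumerate(transforms):
            writer.writerow([i, tr.dx, tr.dy, tr.theta,
                             tr.reference_frame_index, int(tr.degenerate)])


def transforms_from_csv(path: str | Path) -> list[RigidTransform]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(RigidTransform(
                dy=float(row["dy"]), dx=float(row["dx"]),
                theta=float(row["theta"]),
                reference_frame_index=int(row["reference_frame_index"]),
                degenerate=bool(int(row["degenerate"]))))
    return out
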