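"""Synthetic colony time-lapse generator.

Produces two-channel (live / dead) fluorescence image series of a radially
expanding bacterial colony undergoing a programmed spatiotemporal cell-death
schedule: a rim-band death episode (phase 1) active over a fixed time window,
and an interior ring (phase 2) that nucleates at a configurable radius and
propagates inward and outward at constant front speed for a fixed duration.
Imaging artifacts (background offset and gradient, shot or Gaussian camera
noise, per-frame rigid stage drift) are applied last, so the generator also
returns the clean ground-truth fields needed for parameter-recovery tests.

The death fields are phenomenological schedules, not a mechanistic model of
interbacterial killing: the generator exists to exercise the downstream
quantification pipeline against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "FrameStack",
    "GroundTruth",
    "TileSet",
    "simulate_colony",
    "emit_tiles",
    "emit_zstack",
    "simulate_reporter_table",
    "save_stack",
    "load_stack",
    "save_ground_truth",
    "load_ground_truth",
]


class ConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic colony time-lapse.

    Defaults describe a wild-type-like colony: a 1 uL spot growing linearly
    to a 3 mm final radius by 48 h, rim-band death between 8 and 40 h at a
    10:1 dead/live intensity ratio, and an interior death ring nucleating at
    1 mm at 44 h whose fronts propagate for 6 h.

    Attributes
    ----------
    image_size : int
        Pixels per side of the (square) field of view.
    pixel_size : float
        Physical calibration, mm per pixel.
    frame_interval : float
        Acquisition cadence in hours.
    t_start, t_end : float
        Observation window in hours; frames at ``t_start, t_start +
        frame_interval, ...`` up to and including ``t_end``.
    spot_radius : float
        Initial colony (spot) radius in mm at ``t=0``.
    colony_radius_final : float
        Final colony radius in mm.
    growth_law : str
        ``"linear"`` (radius reaches the final value at ``growth_end``) or
        ``"logistic"`` (rate ``growth_rate`` per hour).
    p1_window : tuple[float, float] | None
        (on, off) hours of the rim-band death episode; ``None`` disables it.
    p1_band_width : float
        Width in mm of the death annulus at the instantaneous rim.
    p1_intensity_ratio : float
        Dead/live intensity ratio inside the rim band.
    p1_attenuation : float
        Divisor applied to the rim-band ratio for mutant-like strains
        (>= 1; 1 means no attenuation).
    p2_onset : float | None
        Hour at which the interior ring nucleates; ``None`` disables it.
    p2_origin_radius : float
        Radius in mm at which the ring nucleates.
    p2_initial_width : float
        Initial ring width in mm.
    p2_duration : float
        Hours over which the two fronts keep moving.
    p2_speed : float
        Front speed in mm/h (both inward and outward).
    p2_intensity_ratio : float
        Dead/live ratio inside the ring (lower than the rim band: rim death
        is the higher-amplitude episode).
    live_intensity_mean : float
        Live-channel signal amplitude inside the colony, arbitrary units on
        a 16-bit scale.
    background_level : float
        Additive camera background, a.u., both channels.
    background_gradient : float
        Linear background slope, a.u. per pixel along the column axis.
    noise_model : str
        ``"shot"`` (variance = scale x mean), ``"gaussian"`` (additive,
        SD = scale) or ``"none"``.
    noise_scale : float
        Scale of the chosen noise model.
    drift_max_translation : float
        Per-frame random-walk increment bound, px (cumulative rigid drift).
    drift_max_rotation : float
        Per-frame rotation increment bound, degrees.
    n_z_slices : int
        Slices written by :func:`emit_zstack` helpers (1 = no z dimension).
    tile_grid : tuple[int, int, float] | None
        (rows, cols, overlap fraction) for tiled output, or ``None``.
    seed : int
        Seed for all randomness; identical config + seed gives bit-identical
        output stacks.
    """

    image_size: int = 512
    pixel_size: float = 0.015
    frame_interval: float = 1.0
    t_start: float = 0.0
    t_end: float = 54.0
    spot_radius: float = 0.75
    colony_radius_final: float = 3.0
    growth_law: str = "linear"
    growth_end: float = 48.0
    growth_rate: float = 0.15
    p1_window: tuple[float, float] | None = (8.0, 40.0)
    p1_band_width: float = 0.25
    p1_intensity_ratio: float = 10.0
    p1_attenuation: float = 1.0
    p2_onset: float | None = 44.0
    p2_origin_radius: float = 1.0
    p2_initial_width: float = 0.12
    p2_duration: float = 6.0
    p2_speed: float = 0.1
    p2_intensity_ratio: float = 3.0
    live_intensity_mean: float = 3000.0
    background_level: float = 100.0
    background_gradient: float = 0.1
    noise_model: str = "shot"
    noise_scale: float = 1.0
    drift_max_translation: float = 2.0
    drift_max_rotation: float = 0.5
    n_z_slices: int = 1
    tile_grid: tuple[int, int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first violated invariant."""
        if self.t_end <= self.t_start:
            raise ConfigError("t_end must exceed t_start")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.p1_window is not None:
            t_on, t_off = self.p1_window
            if not (self.t_start < t_on < t_off):
                raise ConfigError(
                    "p1_window must satisfy t_start < t_on < t_off"
                )
            if self.p2_onset is not None and t_off > self.p2_onset:
                raise ConfigError("p1_window.t_off must not exceed p2_onset")
            if self.p1_intensity_ratio <= 0:
                raise ConfigError("p1_intensity_ratio must be positive")
            if self.p1_attenuation < 1:
                raise ConfigError("p1_attenuation must be >= 1")
        if self.colony_radius_final / self.pixel_size >= self.image_size / 2:
            raise ConfigError(
                "colony does not fit in frame: colony_radius_final/pixel_size"
                " must be < image_size/2"
            )
        if self.spot_radius <= 0 or self.spot_radius > self.colony_radius_final:
            raise ConfigError(
                "spot_radius must be in (0, colony_radius_final]"
            )
        if self.growth_law not in ("linear", "logistic"):
            raise ConfigError("growth_law must be 'linear' or 'logistic'")
        if self.noise_model not in ("shot", "gaussian", "none"):
            raise ConfigError("noise_model must be 'shot', 'gaussian' or 'none'")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        if self.p2_onset is not None:
            if self.p2_origin_radius <= 0:
                raise ConfigError("p2_origin_radius must be positive")
            if self.p2_duration <= 0 or self.p2_speed < 0:
                raise ConfigError("p2_duration must be > 0 and p2_speed >= 0")
        if self.n_z_slices < 1:
            raise ConfigError("n_z_slices must be >= 1")
        if self.tile_grid is not None:
            rows, cols, overlap = self.tile_grid
            if rows < 1 or cols < 1:
                raise ConfigError("tile_grid rows/cols must be >= 1")
            if not (0 < overlap < 0.5) and (rows > 1 or cols > 1):
                raise ConfigError("tile overlap fraction must be in (0, 0.5)")

    def radius_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Colony radius in mm at time ``t`` (hours) under the growth law."""
        t = np.asarray(t, dtype=float)
        r0, rf = self.spot_radius, self.colony_radius_final
        if self.growth_law == "linear":
            frac = np.clip(t / self.growth_end, 0.0, 1.0)
            r = r0 + (rf - r0) * frac
        else:  # logistic
            r = rf / (1.0 + ((rf - r0) / r0) * np.exp(-self.growth_rate * t))
        return r if r.ndim else float(r)

    def times(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.frame_interval + 1e-9))
        return self.t_start + self.frame_interval * np.arange(n + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["p1_window"] is not None:
            d["p1_window"] = list(d["p1_window"])
        if d["tile_grid"] is not None:
            d["tile_grid"] = list(d["tile_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("p1_window") is not None:
            d["p1_window"] = tuple(d["p1_window"])
        if d.get("tile_grid") is not None:
            d["tile_grid"] = tuple(d["tile_grid"])
        return cls(**d)


@dataclass
class FrameStack:
    """Time-indexed two-channel image series with physical calibration.

    ``live`` and ``dead`` are ``[T, H, W]`` float32 intensity arrays in
    arbitrary units; ``times`` is hours per frame; ``pixel_size`` mm/px.
    """

    live: np.ndarray
    dead: np.ndarray
    times: np.ndarray
    pixel_size: float

    def validate(self) -> None:
        if self.live.shape != self.dead.shape:
            raise ValueError("live and dead channels must share a shape")
        if self.live.ndim != 3:
            raise ValueError("channel arrays must be [T, H, W]")
        if len(self.times) != self.live.shape[0]:
            raise ValueError("times length must match the frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.nanmin(self.live) < 0 or np.nanmin(self.dead) < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.live.shape[0]


@dataclass
class GroundTruth:
    """Clean (un-noised, un-drifted) fields recorded by the generator.

    Used by parameter-recovery tests; ``drift`` holds the cumulative rigid
    offsets (dy px, dx px, theta deg) actually applied to each camera frame.
    """

    times: np.ndarray
    colony_radius_mm: np.ndarray
    p1_active: np.ndarray  # [T, H, W] bool
    p2_active: np.ndarray  # [T, H, W] bool
    true_ratio: np.ndarray  # [T, H, W] float32, dead/live inside the colony
    drift: np.ndarray  # [T, 3] (dy, dx, theta_deg)


def simulate_colony(config: SimulationConfig) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic colony time-lapse and its ground truth.

    The colony is a disk centered in the field whose radius follows the
    configured growth law. The live channel is ``live_intensity_mean`` inside
    the disk (1-px antialiased edge). The dead channel carries signal only
    inside the scheduled death regions, at the configured multiple of the
    local live signal. Background and camera noise are applied last; rigid
    stage drift (a cumulative random walk) is rendered exactly by evaluating
    the colony fields at drifted coordinates — no resampling, as with a real
    moving stage. Because the colony is isotropic about its own center and
    the drift rotation pivots on the image center where the colony sits,
    the rotational component leaves the scene unchanged; it is recorded in
    the ground truth regardless. The returned :class:`GroundTruth` records
    the clean, drift-free (canonical) fields plus the applied drift.
    """
    config.validate()

    n = config.image_size
    px = config.pixel_size
    times = config.times()
    n_frames = len(times)
    c0 = (n - 1) / 2.0
    rows = np.arange(n, dtype=float)[:, None]
    cols = np.arange(n, dtype=float)[None, :]

    rng = np.random.default_rng(config.seed)

    live = np.empty((n_frames, n, n), dtype=np.float32)
    dead = np.empty_like(live)
    p1_active = np.zeros((n_frames, n, n), dtype=bool)
    p2_active = np.zeros_like(p1_active)
    true_ratio = np.zeros((n_frames, n, n), dtype=np.float32)
    radii = np.asarray(config.radius_at(times), dtype=float)

    # cumulative rigid drift random walk; frame 0 is the undrifted reference
    drift = np.zeros((n_frames, 3))
    if config.drift_max_translation > 0 or config.drift_max_rotation > 0:
        steps = np.column_stack([
            rng.uniform(-config.drift_max_translation,
                        config.drift_max_translation, size=(n_frames, 2)),
            rng.uniform(-config.drift_max_rotation,
                        config.drift_max_rotation, size=n_frames),
        ])
        steps[0] = 0.0
        drift = np.cumsum(steps, axis=0)

    background = (config.background_level
                  + config.background_gradient * cols).astype(np.float32)
    background = np.broadcast_to(background, (n, n))

    def render(t: float, r: float, center_row: float, center_col: float):
        """Colony fields with the colony centered at the given position."""
        rr = np.hypot(rows - center_row, cols - center_col) * px
        # subpixel edge coverage: 1 inside, linear ramp over one pixel
        coverage = np.clip((r - rr) / px + 0.5, 0.0, 1.0).astype(np.float32)
        live_sig = config.live_intensity_mean * coverage
        ratio = np.zeros((n, n), dtype=np.float32)
        band = np.zeros((n, n), dtype=bool)
        ring = np.zeros((n, n), dtype=bool)
        if config.p1_window is not None:
            t_on, t_off = config.p1_window
            if t_on <= t <= t_off:
                band = (rr >= r - config.p1_band_width) & (coverage > 0)
                ratio[band] += config.p1_intensity_ratio / config.p1_attenuation
        if config.p2_onset is not None and t >= config.p2_onset:
            elapsed = min(t - config.p2_onset, config.p2_duration)
            half = config.p2_initial_width / 2 + config.p2_speed * elapsed
            inner = max(config.p2_origin_radius - half, 0.0)
            outer = config.p2_origin_radius + half
            ring = (rr >= inner) & (rr <= outer) & (coverage > 0)
            ratio[ring] += config.p2_intensity_ratio
        return live_sig, ratio * live_sig, band, ring, ratio, coverage

    for i, t in enumerate(times):
        r = radii[i]
        dy, dx, _theta = drift[i]
        live_sig, dead_sig, band, ring, ratio, coverage = render(
            t, r, c0 + dy, c0 + dx)
        if dy or dx:
            # ground truth stays in canonical (drift-free) coordinates
            _, _, band, ring, ratio, coverage = render(t, r, c0, c0)
        p1_active[i] = band
        p2_active[i] = ring
        true_ratio[i] = ratio * (coverage > 0)

        live[i] = live_sig + background
        dead[i] = dead_sig + background

    if config.noise_model == "shot" and config.noise_scale > 0:
        s = config.noise_scale
        live = (rng.poisson(live / s) * s).astype(np.float32)
        dead = (rng.poisson(dead / s) * s).astype(np.float32)
    elif config.noise_model == "gaussian" and config.noise_scale > 0:
        live = live + rng.normal(0, config.noise_scale,
                                 live.shape).astype(np.float32)
        dead = dead + rng.normal(0, config.noise_scale,
                                 dead.shape).astype(np.float32)
    live = np.clip(live, 0.0, 65535.0)
    dead = np.clip(dead, 0.0, 65535.0)

    stack = FrameStack(live=live, dead=dead, times=times, pixel_size=px)
    stack.validate()
    truth = GroundTruth(times=times, colony_radius_mm=radii,
                        p1_active=p1_active, p2_active=p2_active,
                        true_ratio=true_ratio, drift=drift)
    return stack, truth


# ---------------------------------------------------------------------------
# tiled / z-stacked acquisition emulation
# ---------------------------------------------------------------------------

@dataclass
class TileSet:
    """Tiles cut from one frame plus the metadata needed to re-stitch them.

    ``positions[i]`` is the (row, col) of each tile's upper-left corner in
    the source frame; all tiles share ``tile_shape``.
    """

    tiles: list[np.ndarray]
    positions: list[tuple[int, int]]
    grid: tuple[int, int]
    overlap: float
    frame_shape: tuple[int, int]


def _tile_starts(extent: int, n_tiles: int, overlap: float) -> tuple[int, list[int]]:
    """Tile size and start offsets covering ``extent`` with ~overlap fraction."""
    if n_tiles == 1:
        return extent, [0]
    size = int(np.ceil(extent / (n_tiles - (n_tiles - 1) * overlap)))
    step = (extent - size) / (n_tiles - 1)
    starts = [int(round(k * step)) for k in range(n_tiles)]
    starts[-1] = extent - size
    return size, starts


def emit_tiles(frame: np.ndarray, grid: tuple[int, int],
               overlap: float = 0.1) -> TileSet:
    """Cut a frame into an overlapping tile grid (montage acquisition).

    Adjacent tiles share approximately ``overlap`` of their extent; tiles
    jointly cover the frame exactly.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one row and column")
    if (rows > 1 or cols > 1) and not (0 < overlap < 0.5):
        raise ValueError("overlap fraction must be in (0, 0.5)")
    h, w = frame.shape
    th, row_starts = _tile_starts(h, rows, overlap)
    tw, col_starts = _tile_starts(w, cols, overlap)
    tiles, positions = [], []
    for r0 in row_starts:
        for c0 in col_starts:
            tiles.append(frame[r0:r0 + th, c0:c0 + tw].copy())
            positions.append((r0, c0))
    return TileSet(tiles=tiles, positions=positions, grid=(rows, cols),
                   overlap=overlap, frame_shape=(h, w))


def emit_zstack(frame: np.ndarray, n_slices: int,
                depth_um: float = 350.0, attenuation: float = 0.6,
                focus_index: int | None = None) -> np.ndarray:
    """Expand one frame into a defocus z-stack ``[Z, H, W]``.

    The in-focus slice equals the frame; slices ``k`` steps away are
    attenuated by ``attenuation**k``, so a pixelwise maximum projection
    recovers the source frame exactly. ``depth_um`` is carried as sectioning
    metadata only.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not (0 < attenuation < 1):
        raise ValueError("attenuation must be in (0, 1)")
    if focus_index is None:
        focus_index = n_slices // 2
    if not (0 <= focus_index < n_slices):
        raise ValueError("focus_index out of range")
    frame = np.asarray(frame)
    out = np.empty((n_slices,) + frame.shape, dtype=frame.dtype)
    for k in range(n_slices):
        out[k] = frame * attenuation ** abs(k - focus_index)
    return out


# ---------------------------------------------------------------------------
# reporter assay tables
# ---------------------------------------------------------------------------

def simulate_reporter_table(true_ratio: float, n_replicates: int = 3,
                            noise_cv: float = 0.1, seed: int = 0,
                            strain_a: str = "WT", strain_b: str = "mutant",
                            rlu_reference: float = 1000.0) -> pd.DataFrame:
    """Simulate a plate-reader luminescence + OD600 replicate table.

    Strain ``strain_a`` has expected RLU (luminescence / OD600) equal to
    ``true_ratio`` times that of ``strain_b``. Noise is multiplicative with
    the given coefficient of variation and unit mean (mean-one lognormal),
    so the expected fold change equals ``true_ratio`` exactly.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for strain, rlu_mean in ((strain_a, rlu_reference * true_ratio),
                             (strain_b, rlu_reference)):
        for rep in range(1, n_replicates + 1):
            od = rng.uniform(0.8, 1.2)
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv ** 2))
                factor = rng.lognormal(-sigma ** 2 / 2, sigma)
            else:
                factor = 1.0
            rows.append({
                "strain": strain,
                "replicate": rep,
                "luminescence": rlu_mean * factor * od,
                "od600": od,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_stack(stack: FrameStack, out_dir: str | Path,
               config: SimulationConfig | None = None) -> Path:
    """Write a stack as two multi-page TIFFs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "live.tif", stack.live)
    tifffile.imwrite(out / "dead.tif", stack.dead)
    sidecar = {
        "times_h": [float(t) for t in stack.times],
        "pixel_size_mm": stack.pixel_size,
    }
    if config is not None:
        sidecar["config"] = config.to_dict()
    (out / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_stack(in_dir: str | Path) -> FrameStack:
    """Read a stack written by :func:`save_stack`."""
    d = Path(in_dir)
    meta = json.loads((d / "stack.json").read_text())
    stack = FrameStack(
        live=tifffile.imread(d / "live.tif").astype(np.float32),
        dead=tifffile.imread(d / "dead.tif").astype(np.float32),
        times=np.asarray(meta["times_h"], dtype=float),
        pixel_size=float(meta["pixel_size_mm"]),
    )
    stack.validate()
    return stack


def save_ground_truth(truth: GroundTruth, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "ground_truth.npz",
        times=truth.times, colony_radius_mm=truth.colony_radius_mm,
        p1_active=truth.p1_active, p2_active=truth.p2_active,
        true_ratio=truth.true_ratio, drift=truth.drift,
    )
    return out


def load_ground_truth(in_dir: str | Path) -> GroundTruth:
    with np.load(Path(in_dir) / "ground_truth.npz") as z:
        return GroundTruth(**{k: z[k] for k in z.files})
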