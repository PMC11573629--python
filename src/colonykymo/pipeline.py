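"""End-to-end analysis orchestration used by the CLI and by scripts.

Stage order follows the acquisition-processing chain: rolling-ball
background subtraction on both channels, rigid registration estimated on the
live channel and applied to both, colony geometry from the live channel,
radial profile extraction, kymograph construction, and phase detection.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from . import kymograph as km
from . import preprocess as pp
from .simulate import FrameStack

__all__ = ["AnalysisParams", "AnalysisResult", "run_analysis"]


@dataclass
class AnalysisParams:
    """All tunable analysis-stage parameters (see docs/methods.md)."""

    rolling_ball_radius: int = 1000
    register: bool = True
    reference_policy: str = "previous"
    max_rotation: float = 2.0
    upsample_factor: int = 20
    edge_sigma: float | None = 3.0
    freeze_frame: int = 0
    ray_angle_deg: float | None = None
    excluded_wedges: list[tuple[float, float]] | None = None
    radial_step_mm: float = km.DEFAULT_RADIAL_STEP_MM
    pseudocount: float = km.DEFAULT_PSEUDOCOUNT
    log_base: float = km.DEFAULT_LOG_BASE
    rim_band_width_mm: float = km.DEFAULT_RIM_BAND_MM
    rim_exclusion_mm: float = 0.4
    activity_k: float = km.DEFAULT_ACTIVITY_K
    min_activity: float = km.DEFAULT_MIN_ACTIVITY
    baseline_frames: int = km.DEFAULT_BASELINE_FRAMES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["excluded_wedges"] is not None:
            d["excluded_wedges"] = [list(w) for w in d["excluded_wedges"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis parameter keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("excluded_wedges") is not None:
            d["excluded_wedges"] = [tuple(w) for w in d["excluded_wedges"]]
        return cls(**d)


@dataclass
class AnalysisResult:
    geometry: geo.ColonyGeometry
    kymograph: km.Kymograph
    phase1: km.Phase1Result
    phase2: km.Phase2Result
    metrics: km.PhaseMetrics
    transforms: list[pp.RigidTransform] | None
    stage_seconds: dict = field(default_factory=dict)


def run_analysis(stack: FrameStack,
                 params: AnalysisParams | None = None) -> AnalysisResult:
    """Run the full quantification pipeline on a two-channel stack."""
    if params is None:
        params = AnalysisParams()
    stack.validate()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    live = np.empty_like(stack.live, dtype=np.float32)
    dead = np.empty_like(live)
    for t in range(stack.n_frames):
        _, live[t] = pp.rolling_ball_background(
            stack.live[t], params.rolling_ball_radius)
        _, dead[t] = pp.rolling_ball_background(
            stack.dead[t], params.rolling_ball_radius)
    timings["background_subtraction"] = time.perf_counter() - t0

    transforms = None
    if params.register:
        t0 = time.perf_counter()
        reg = pp.register_series(live,
                                 reference_policy=params.reference_policy,
                                 max_rotation=params.max_rotation,
                                 upsample_factor=params.upsample_factor,
                                 edge_sigma=params.edge_sigma)
        live = np.clip(reg.aligned, 0.0, None)
        dead = np.clip(pp.apply_transforms(dead, reg.transforms, cval=0.0),
                       0.0, None)
        transforms = reg.transforms
        timings["registration"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    geometry = geo.compute_geometry(
        live, stack.pixel_size, angle_deg=params.ray_angle_deg,
        freeze_frame=params.freeze_frame,
        excluded_wedges=params.excluded_wedges)
    timings["geometry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    live_prof, dead_prof, radii = km.extract_profiles(
        live, dead, geometry, radial_step_mm=params.radial_step_mm)
    kymo = km.build_kymograph(live_prof, dead_prof,
                              pseudocount=params.pseudocount,
                              log_base=params.log_base,
                              times=stack.times, radial_positions=radii,
                              boundary_radius_mm=geometry.boundary_radius_mm)
    timings["kymograph"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    phase1 = km.detect_phase1(kymo,
                              rim_band_width_mm=params.rim_band_width_mm,
                              k=params.activity_k,
                              baseline_frames=params.baseline_frames,
                              min_activity=params.min_activity)
    phase2 = km.detect_phase2(kymo,
                              rim_exclusion_mm=params.rim_exclusion_mm,
                              k=params.activity_k,
                              baseline_frames=params.baseline_frames,
                              min_activity=params.min_activity)
    timings["phase_detection"] = time.perf_counter() - t0

    final_radius = float(geometry.boundary_radius_mm[-1])
    metrics = km.PhaseMetrics.from_results(phase1, phase2,
                                           final_radius_mm=final_radius)
    return AnalysisResult(geometry=geometry, kymograph=kymo, phase1=phase1,
                          phase2=phase2, metrics=metrics,
                          transforms=transforms, stage_seconds=timings)
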