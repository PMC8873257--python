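"""End-to-end measurement pipeline: scene -> holograms -> reconstruction ->
tracks -> volume trajectories -> volatility results -> summary.

Detection always runs on the plain back-propagated reconstruction, whose
twin-image ripple is part of the statistics the adaptive threshold adapts
to.  When iterative refinement is requested, the detected ROIs provide the
object support, every frame is re-reconstructed under that support
constraint, and volumetry is performed on the refined frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.morphology import dilation as sk_dilation, disk

from .config import ScenarioConfig
from .holography import (
    ComplexFrame,
    HologramStack,
    reconstruct_frame,
    reconstruct_stack,
    render_hologram_stack,
)
from .scene import ParticleTruth, sample_particle_population
from .stats import MeasurementSummary, measurement_summary
from .tracking import ParticleROI, ParticleTrack, detect_particles, track_particles
from .volatility import ClassThresholds, VolatilityResult, analyze_trajectory
from .volumetry import VolumeTrajectory, volume_time_series

__all__ = [
    "MeasurementAnalysis",
    "simulate_measurement",
    "analyze_frames",
    "process_measurement",
]


@dataclass
class MeasurementAnalysis:
    """All intermediate and final products of one analyzed measurement."""

    frames: List[ComplexFrame]
    tracks: List[ParticleTrack]
    trajectories: List[VolumeTrajectory]
    results: List[VolatilityResult]
    summary: MeasurementSummary


def simulate_measurement(
    config: ScenarioConfig,
    n_particles: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    noise: bool = True,
) -> Tuple[List[ParticleTruth], HologramStack]:
    """Draw a ground-truth population and render its hologram stack."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_particles_per_measurement if n_particles is None else n_particles
    particles = sample_particle_population(config, n, rng)
    stack = render_hologram_stack(particles, config, rng if noise else None)
    return particles, stack


def _support_from_detections(dets: Sequence[ParticleROI], shape,
                             extra_dilation_px: int = 2) -> np.ndarray:
    support = np.zeros(shape, dtype=bool)
    for roi in dets:
        support[roi.pixels[:, 0], roi.pixels[:, 1]] = True
    if support.any() and extra_dilation_px > 0:
        support = sk_dilation(support, disk(extra_dilation_px))
    return support


def analyze_frames(
    frames: Sequence[ComplexFrame],
    config: ScenarioConfig,
    *,
    thresholds: Optional[ClassThresholds] = None,
    min_area_px: int = 4,
    association_radius_px: float = 5.0,
    min_track_frames: int = 3,
    measure_frames: Optional[Sequence[ComplexFrame]] = None,
) -> MeasurementAnalysis:
    """Run detection, tracking, volumetry and classification.

    Detection and tracking use ``frames``; volumes are measured on
    ``measure_frames`` when given (e.g. twin-suppressed reconstructions of
    the same stack), otherwise on ``frames``.
    """
    detections = [
        detect_particles(f, min_area_px, pixel_pitch_um=config.pixel_pitch_um)
        for f in frames
    ]
    tracks = track_particles(detections, association_radius_px)
    target = list(measure_frames) if measure_frames is not None else list(frames)
    trajectories = [
        volume_time_series(t, target, config)
        for t in tracks
        if len(t.rois) >= min_track_frames
    ]
    results = [analyze_trajectory(traj, thresholds) for traj in trajectories]
    summary = measurement_summary(results, config)
    return MeasurementAnalysis(
        frames=target,
        tracks=tracks,
        trajectories=trajectories,
        results=results,
        summary=summary,
    )


def process_measurement(
    stack: HologramStack,
    config: ScenarioConfig,
    *,
    refine: bool = False,
    z_um: Optional[float] = None,
    thresholds: Optional[ClassThresholds] = None,
    min_area_px: int = 4,
    association_radius_px: float = 5.0,
) -> MeasurementAnalysis:
    """Reconstruct a hologram stack and analyze it end to end."""
    z = stack.z_um if z_um is None else z_um
    frames = reconstruct_stack(stack, config, z_um=z, refine=False)
    measure: Optional[List[ComplexFrame]] = None
    if refine:
        # Support per frame, from that frame's own detections.  Keeping the
        # support tight matters: in-line intensity is nearly blind to
        # smooth phase across wide regions (the phase transfer function
        # vanishes at low spatial frequency), so an oversized support
        # leaves room for unconstrained phase offsets to settle.
        measure = []
        for raw, frame in zip(stack.frames, frames):
            dets = detect_particles(
                frame, min_area_px, pixel_pitch_um=config.pixel_pitch_um
            )
            support = _support_from_detections(dets, frame.field.shape,
                                               extra_dilation_px=0)
            measure.append(
                reconstruct_frame(raw, z, config, refine=True, support=support)
            )
    return analyze_frames(
        frames,
        config,
        thresholds=thresholds,
        min_area_px=min_area_px,
        association_radius_px=association_radius_px,
        measure_frames=measure,
    )
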