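"""Phase-integrated droplet volumetry.

The volume of a droplet at time t is obtained from the unwrapped phase of
its reconstructed complex image,

    V(t) = lambda / (2 pi delta_n) * A_px * sum_{(i,j) in mask} phi(i, j; t),

where ``A_px`` is the reconstruction pixel area.  The sum runs over an
*inner mask*: the ROI pixels at least one standard deviation above the mean
of all pixels in the ROI patch, which separates the droplet body from the
ROI's background fringe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_FULL_EVAPORATION_VOLUME_UM3, ScenarioConfig
from .holography import ComplexFrame, unwrap_phase_roi
from .tracking import ParticleTrack

__all__ = [
    "VolumeTrajectory",
    "inner_mask",
    "particle_volume",
    "volume_time_series",
    "trajectory_to_frame",
]


@dataclass
class VolumeTrajectory:
    """One particle's measured volume time series.

    ``times_s`` are seconds since the track's landing frame; ``below_floor``
    flags every frame from the first volume below the detection floor
    onward (such frames are recorded but excluded from decay fitting).
    ``usable`` is False for tracks too short to fit (< 3 frames).
    """

    track_id: int
    times_s: np.ndarray
    volumes_um3: np.ndarray
    active_pixel_counts: np.ndarray
    below_floor: np.ndarray
    usable: bool = True

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.volumes_um3 = np.asarray(self.volumes_um3, dtype=float)
        self.active_pixel_counts = np.asarray(self.active_pixel_counts, dtype=int)
        self.below_floor = np.asarray(self.below_floor, dtype=bool)
        n = len(self.times_s)
        if not (len(self.volumes_um3) == len(self.below_floor)
                == len(self.active_pixel_counts) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n and self.times_s[0] != 0.0:
            raise ValueError("times must start at 0 (landing frame)")
        if np.any(self.volumes_um3 < 0):
            raise ValueError("volumes must be non-negative")


def inner_mask(roi_values: np.ndarray) -> np.ndarray:
    """Pixels at least one (population) standard deviation above the mean.

    Computed over all supplied ROI values.  A constant ROI yields an empty
    mask; the selection is invariant to affine rescaling of the values.
    """
    vals = np.asarray(roi_values, dtype=float)
    if vals.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    std = vals.std()
    if std == 0:
        return np.zeros_like(vals, dtype=bool)
    return vals >= vals.mean() + std


def particle_volume(phase_values: np.ndarray, mask: np.ndarray,
                    wavelength_um: float, delta_n: float,
                    pixel_area_um2: float) -> float:
    """Phase-integrated volume over the masked pixels (um^3).

    Negative unwrapped-phase pixels are clipped to zero before summation;
    an empty mask gives zero volume.
    """
    if pixel_area_um2 <= 0:
        raise ValueError("pixel_area must be positive")
    phase = np.asarray(phase_values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    phi_sum = np.clip(phase[m], 0.0, None).sum()
    return wavelength_um / (2.0 * math.pi * delta_n) * pixel_area_um2 * phi_sum


def volume_time_series(
    track: ParticleTrack,
    frames: Sequence[ComplexFrame],
    config: ScenarioConfig,
    *,
    floor_um3: float = DEFAULT_FULL_EVAPORATION_VOLUME_UM3,
    patch_margin_px: int = 8,
) -> VolumeTrajectory:
    """Measure one track's volume in every frame it was detected in.

    Per frame: the wrapped phase is unwrapped within the ROI, the inner
    mask is computed on the unwrapped-phase magnitude over the ROI's
    bounding-box patch (padded by ``patch_margin_px``), and the volume
    follows from the phase integral.  The time origin is the landing frame.

    The patch margin is chosen so the statistics patch is dominated by
    background pixels: the one-standard-deviation cut then separates the
    droplet from the background instead of trimming the droplet's own rim.

    Droplets are pinned to the substrate, so the measurement does not stop
    when the particle drops below the detection threshold: frames without a
    fresh ROI reuse the most recent one.  This records the full evaporation
    tail (flagged ``below_floor`` once under the detection floor).
    """
    roi_by_frame = {roi.frame_index: roi for roi in track.rois}
    times, volumes, counts = [], [], []
    roi = None
    for frame_index in range(track.landing_frame, len(frames)):
        roi = roi_by_frame.get(frame_index, roi)
        frame = frames[frame_index]
        h, w = frame.field.shape
        r0, c0, r1, c1 = roi.bbox
        pr0, pc0 = max(r0 - patch_margin_px, 0), max(c0 - patch_margin_px, 0)
        pr1, pc1 = min(r1 + patch_margin_px, h), min(c1 + patch_margin_px, w)
        patch_mask = np.zeros((pr1 - pr0, pc1 - pc0), dtype=bool)
        patch_mask[roi.pixels[:, 0] - pr0, roi.pixels[:, 1] - pc0] = True
        phase_patch = frame.phase[pr0:pr1, pc0:pc1]
        unwrapped = unwrap_phase_roi(phase_patch, patch_mask)
        im = inner_mask(np.abs(unwrapped))
        v = particle_volume(
            unwrapped, im, config.wavelength_um, config.delta_n,
            config.pixel_area_um2,
        )
        times.append((frame_index - track.landing_frame) / config.frame_rate_fps)
        volumes.append(v)
        counts.append(roi.active_pixel_count if frame_index in roi_by_frame else 0)
    volumes_arr = np.asarray(volumes)
    below = np.zeros(len(volumes), dtype=bool)
    under = np.nonzero(volumes_arr < floor_um3)[0]
    if under.size:
        below[under[0]:] = True
    return VolumeTrajectory(
        track_id=track.track_id,
        times_s=np.asarray(times),
        volumes_um3=volumes_arr,
        active_pixel_counts=np.asarray(counts),
        below_floor=below,
        usable=len(volumes) >= 3,
    )


def trajectory_from_volumes(
    track_id: int,
    times_s: np.ndarray,
    volumes_um3: np.ndarray,
    *,
    floor_um3: float = DEFAULT_FULL_EVAPORATION_VOLUME_UM3,
) -> VolumeTrajectory:
    """Wrap a raw volume series in a trajectory with standard flagging.

    Applies the same below-floor flagging as the imaging pipeline; used for
    truth-based simulations and for feeding externally measured series into
    the decay fit.
    """
    volumes = np.asarray(volumes_um3, dtype=float)
    below = np.zeros(len(volumes), dtype=bool)
    under = np.nonzero(volumes < floor_um3)[0]
    if under.size:
        below[under[0]:] = True
    return VolumeTrajectory(
        track_id=track_id,
        times_s=np.asarray(times_s, dtype=float),
        volumes_um3=volumes,
        active_pixel_counts=np.zeros(len(volumes), dtype=int),
        below_floor=below,
        usable=len(volumes) >= 3,
    )


def trajectory_to_frame(trajectories: Sequence[VolumeTrajectory]) -> pd.DataFrame:
    """Flat table: track_id, t_s, volume_um3, active_px, below_floor."""
    records: List[dict] = []
    for traj in trajectories:
        for t, v, a, bf in zip(traj.times_s, traj.volumes_um3,
                               traj.active_pixel_counts, traj.below_floor):
            records.append(
                {"track_id": traj.track_id, "t_s": t, "volume_um3": v,
                 "active_px": int(a), "below_floor": bool(bf)}
            )
    return pd.DataFrame.from_records(
        records, columns=["track_id", "t_s", "volume_um3", "active_px", "below_floor"]
    )
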