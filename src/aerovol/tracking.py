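"""Per-frame particle detection and cross-frame track linking.

Detection follows the adaptive-threshold rule: a pixel is active when it
exceeds the frame mean by ``k_sigma`` standard deviations, applied to both
the amplitude channel (as deviation from the unity background) and the
phase channel; the union of the two masks yields per-particle ROIs.

Because the droplets are immobilized on the substrate after impaction,
tracking needs no motion model: detections are greedily associated to the
nearest existing track centroid within a fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import dilation as sk_dilation, disk

from .holography import ComplexFrame

__all__ = [
    "ParticleROI",
    "ParticleTrack",
    "adaptive_threshold_mask",
    "detect_particles",
    "track_particles",
    "tracks_to_frame",
]


@dataclass
class ParticleROI:
    """One detected particle region in one frame.

    ``pixels`` is the (n, 2) array of (row, col) member pixels of the
    dilated ROI; ``active_pixel_count`` the area of the underlying
    thresholded component before dilation.
    """

    frame_index: int
    bbox: Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    pixels: np.ndarray
    centroid_px: Tuple[float, float]  # (row, col)
    centroid_um: Tuple[float, float]  # (x, y)
    active_pixel_count: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.size == 0:
            raise ValueError("ROI pixel set must be non-empty")
        r0, c0, r1, c1 = self.bbox
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        if rows.min() < r0 or rows.max() >= r1 or cols.min() < c0 or cols.max() >= c1:
            raise ValueError("bounding box does not contain the pixel set")

    def mask_in_bbox(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        m[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        return m


@dataclass
class ParticleTrack:
    """One physical particle's ROIs linked across frames."""

    track_id: int
    rois: List[ParticleROI]

    @property
    def landing_frame(self) -> int:
        return self.rois[0].frame_index

    @property
    def reference_centroid_px(self) -> Tuple[float, float]:
        return self.rois[0].centroid_px

    def __post_init__(self):
        frames = [r.frame_index for r in self.rois]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("ROI frame indices must be strictly increasing")


def adaptive_threshold_mask(image: np.ndarray, k_sigma: float = 5.0) -> np.ndarray:
    """Pixels strictly greater than mean + k_sigma * std of the whole frame.

    A constant image yields an empty mask (std is zero and no pixel exceeds
    the mean strictly).  The mask is invariant to adding a constant to
    every pixel.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    return img > img.mean() + k_sigma * img.std()


def detect_particles(
    frame: ComplexFrame,
    min_area_px: int = 4,
    *,
    k_sigma: float = 5.0,
    dilation_px: int = 2,
    pixel_pitch_um: float = 1.12,
    satellite_radius_px: float = 12.0,
) -> List[ParticleROI]:
    """Detect particle ROIs in one reconstructed frame.

    The amplitude channel is thresholded on its deviation from the unity
    background ``|1 - A|`` (droplets are predominantly phase objects), the
    phase channel on its magnitude; the union of the two masks is labelled
    with 8-connectivity, components smaller than ``min_area_px`` are
    dropped, and each surviving component is dilated by ``dilation_px`` to
    form its ROI.

    Strong scatterers shed twin-image ring fragments that can cross the
    threshold a few pixels away from the droplet core; a component whose
    centroid lies within ``satellite_radius_px`` of a larger component's
    centroid is therefore discarded as a satellite of that detection.
    """
    amp_dev = np.abs(1.0 - frame.amplitude)
    phase_mag = np.abs(frame.phase)
    union = adaptive_threshold_mask(amp_dev, k_sigma) | adaptive_threshold_mask(
        phase_mag, k_sigma
    )
    if not union.any():
        return []
    labels = sk_label(union, connectivity=2)
    shape = union.shape
    selem = disk(dilation_px)
    regions = [r for r in regionprops(labels) if r.area >= min_area_px]
    regions.sort(key=lambda r: (-r.area, r.centroid))
    kept = []
    for region in regions:
        rc = np.asarray(region.centroid)
        if any(
            np.hypot(*(rc - np.asarray(k.centroid))) <= satellite_radius_px
            for k in kept
        ):
            continue  # twin-image satellite of a larger detection
        kept.append(region)
    kept.sort(key=lambda r: r.centroid)
    rois: List[ParticleROI] = []
    for region in kept:
        r0, c0, r1, c1 = region.bbox
        pr0, pc0 = max(r0 - dilation_px, 0), max(c0 - dilation_px, 0)
        pr1, pc1 = min(r1 + dilation_px, shape[0]), min(c1 + dilation_px, shape[1])
        comp = np.zeros((pr1 - pr0, pc1 - pc0), dtype=bool)
        comp[r0 - pr0:r1 - pr0, c0 - pc0:c1 - pc0] = region.image
        dil = sk_dilation(comp, selem) if dilation_px > 0 else comp
        rows, cols = np.nonzero(dil)
        pixels = np.column_stack([rows + pr0, cols + pc0])
        crow, ccol = region.centroid
        rois.append(
            ParticleROI(
                frame_index=-1,  # filled by the caller / pipeline
                bbox=(int(pixels[:, 0].min()), int(pixels[:, 1].min()),
                      int(pixels[:, 0].max()) + 1, int(pixels[:, 1].max()) + 1),
                pixels=pixels,
                centroid_px=(float(crow), float(ccol)),
                centroid_um=(float(ccol * pixel_pitch_um), float(crow * pixel_pitch_um)),
                active_pixel_count=int(region.area),
            )
        )
    return rois


def track_particles(
    detections_by_frame: Sequence[Sequence[ParticleROI]],
    association_radius_px: float = 5.0,
) -> List[ParticleTrack]:
    """Greedy nearest-centroid association of detections into tracks.

    Detections are matched to the nearest existing track reference centroid
    within ``association_radius_px`` (each track takes at most one detection
    per frame, nearest pair first, ties broken by lower pixel row then
    column of the detection centroid).  Unmatched detections start new
    tracks — new landing events.  Tracks are never merged; a track whose
    particle fully evaporates simply stops accruing ROIs.
    """
    if association_radius_px <= 0:
        raise ValueError("association radius must be positive")
    tracks: List[ParticleTrack] = []
    for frame_index, dets in enumerate(detections_by_frame):
        dets = list(dets)
        for d in dets:
            d.frame_index = frame_index
        if not dets:
            continue
        pairs = []
        for ti, track in enumerate(tracks):
            tr, tc = track.reference_centroid_px
            for di, det in enumerate(dets):
                dr, dc = det.centroid_px
                dist = float(np.hypot(dr - tr, dc - tc))
                if dist <= association_radius_px:
                    pairs.append((dist, det.centroid_px[0], det.centroid_px[1], ti, di))
        pairs.sort()
        used_tracks, used_dets = set(), set()
        for dist, _, _, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            tracks[ti].rois.append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        leftovers = sorted(
            (di for di in range(len(dets)) if di not in used_dets),
            key=lambda di: dets[di].centroid_px,
        )
        for di in leftovers:
            tracks.append(ParticleTrack(track_id=len(tracks), rois=[dets[di]]))
    return tracks


def tracks_to_frame(tracks: Sequence[ParticleTrack],
                    pixel_pitch_um: float = 1.12) -> pd.DataFrame:
    """Flat table of per-frame track detections for CSV export."""
    records = []
    for t in tracks:
        for roi in t.rois:
            records.append(
                {
                    "frame": roi.frame_index,
                    "track_id": t.track_id,
                    "x_px": roi.centroid_px[1],
                    "y_px": roi.centroid_px[0],
                    "x_um": roi.centroid_px[1] * pixel_pitch_um,
                    "y_um": roi.centroid_px[0] * pixel_pitch_um,
                    "area_px": roi.active_pixel_count,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["frame", "track_id", "x_px", "y_px", "x_um", "y_um", "area_px"]
    )
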