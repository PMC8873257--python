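"""Scenario configuration for simulated aerosol volatility measurements.

A *measurement* is one run of the portable lens-free holographic air sampler:
droplets are deposited on a sticky substrate by an impactor during a sampling
window while time-lapse in-line holograms of the substrate are recorded, and
recording continues for a short while after the pump stops.  The default
values here reproduce the acquisition protocol of that instrument class:
60 s of sampling plus 30 s of post-sampling imaging at 2 frames/s
(180 frames total), 13 L/min flow, 850 nm illumination, 1.12 um sensor
pixel pitch, and a refractive-index contrast of 0.4 between the droplet
liquid (propylene glycol / vegetable glycerin, n ~ 1.4) and air.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

import yaml

#: Canonical volatility class labels, in fixed order.
CLASSES: Tuple[str, str, str] = ("volatile", "semi_volatile", "non_volatile")

#: Volume below which a droplet counts as fully evaporated (um^3).  Also used
#: as the volumetry detection floor.
DEFAULT_FULL_EVAPORATION_VOLUME_UM3: float = 0.1

#: Volume decay rate below which a particle counts as non-volatile (um^3/s).
DEFAULT_NONVOLATILE_RATE_UM3_S: float = 0.05

#: Minimum R^2 of the exponential fit for a decay to count as "smooth".
DEFAULT_SMOOTHNESS_R2: float = 0.9

Range = Tuple[float, float]


def _default_kappa_ranges() -> dict:
    # Decay constants (1/s).  Volatile droplets must vanish within the 30 s
    # guaranteed post-sampling window; non-volatile ones barely decay.
    return {
        "volatile": (0.2, 0.6),
        "semi_volatile": (0.1, 0.5),
        "non_volatile": (0.0, 0.005),
    }


def _default_alpha_ranges() -> dict:
    # Decaying volume component alpha (um^3).
    return {
        "volatile": (1.0, 20.0),
        "semi_volatile": (1.0, 10.0),
        "non_volatile": (0.0, 0.5),
    }


def _default_b_ranges() -> dict:
    # Persistent volume component b (um^3).  Volatile droplets leave
    # essentially no residue; semi-volatile ones plateau above the
    # full-evaporation threshold.
    return {
        "volatile": (0.0, 0.02),
        "semi_volatile": (0.3, 3.0),
        "non_volatile": (0.5, 5.0),
    }


@dataclass
class ScenarioConfig:
    """Parameters of one simulated measurement scenario.

    Attributes
    ----------
    field_width_px, field_height_px:
        Sensor frame size in pixels.
    pixel_pitch_um:
        Sensor (and reconstruction) pixel pitch in micrometres.
    wavelength_um:
        Illumination wavelength in micrometres.
    delta_n:
        Refractive-index contrast between droplet liquid and air.
    z_distance_um:
        Substrate-to-sensor distance in micrometres.
    frame_rate_fps:
        Hologram frame rate in frames per second.
    n_sampling_frames:
        Frames recorded while the pump runs (droplets may land).
    n_total_frames:
        Total frames recorded per measurement.
    flow_rate_lpm:
        Pump flow rate in litres per minute.
    class_mixture:
        Probabilities of (volatile, semi_volatile, non_volatile) draws.
    kappa_range, alpha_range, b_range:
        Per-class uniform sampling ranges for the decay model
        ``V(t) = alpha * exp(-kappa * t) + b``.
    contact_angle_deg:
        Contact angle of the sessile spherical-cap droplets.
    min_separation_um:
        Minimum centre-to-centre distance between droplets on the substrate.
    mean_counts, shot_noise, read_noise_counts, bit_depth:
        Sensor model: mean counts of the unobstructed illumination, Poisson
        shot noise toggle, Gaussian read noise (counts RMS), quantization depth.
    n_particles_per_measurement:
        Default droplet count per simulated measurement (desk-scale stand-in
        for the "hundreds to thousands" collected in the field).
    gap_range_min:
        Range of the gap between consecutive measurements, minutes.
    rng_seed:
        Seed for all randomness derived from this scenario.
    """

    field_width_px: int = 256
    field_height_px: int = 256
    pixel_pitch_um: float = 1.12
    wavelength_um: float = 0.85
    delta_n: float = 0.4
    z_distance_um: float = 200.0
    frame_rate_fps: float = 2.0
    n_sampling_frames: int = 120
    n_total_frames: int = 180
    flow_rate_lpm: float = 13.0
    class_mixture: Tuple[float, float, float] = (0.35, 0.25, 0.40)
    kappa_range: Mapping[str, Range] = field(default_factory=_default_kappa_ranges)
    alpha_range: Mapping[str, Range] = field(default_factory=_default_alpha_ranges)
    b_range: Mapping[str, Range] = field(default_factory=_default_b_ranges)
    contact_angle_deg: float = 60.0
    min_separation_um: float = 25.0
    mean_counts: float = 10000.0
    shot_noise: bool = True
    read_noise_counts: float = 10.0
    bit_depth: int = 16
    n_particles_per_measurement: int = 150
    gap_range_min: Range = (5.0, 27.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sampling_frames < 1 or self.n_total_frames < self.n_sampling_frames:
            raise ValueError(
                "need n_total_frames >= n_sampling_frames >= 1, got "
                f"{self.n_total_frames} / {self.n_sampling_frames}"
            )
        for name in ("pixel_pitch_um", "wavelength_um", "delta_n", "z_distance_um",
                     "frame_rate_fps", "flow_rate_lpm", "mean_counts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.field_width_px < 1 or self.field_height_px < 1:
            raise ValueError("field size must be at least 1 px")
        if len(self.class_mixture) != 3 or any(p < 0 for p in self.class_mixture):
            raise ValueError("class_mixture must be 3 non-negative probabilities")
        if abs(sum(self.class_mixture) - 1.0) > 1e-12:
            raise ValueError("class_mixture must sum to 1 within 1e-12")
        if not (0.0 < self.contact_angle_deg < 180.0):
            raise ValueError("contact_angle_deg must lie in (0, 180)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo, hi = self.gap_range_min
        if not (5.0 <= lo <= hi <= 30.0):
            raise ValueError("gap_range_min must lie within [5, 30] minutes")
        for ranges in (self.kappa_range, self.alpha_range, self.b_range):
            for cls in CLASSES:
                rlo, rhi = ranges[cls]
                if rlo < 0 or rhi < rlo:
                    raise ValueError(f"invalid range {ranges[cls]!r} for {cls}")

    # -- derived quantities ------------------------------------------------

    @property
    def sampling_duration_s(self) -> float:
        """Length of the sampling (pump-on) window in seconds."""
        return self.n_sampling_frames / self.frame_rate_fps

    @property
    def total_duration_s(self) -> float:
        """Total imaging time per measurement in seconds."""
        return self.n_total_frames / self.frame_rate_fps

    @property
    def post_sampling_duration_s(self) -> float:
        """Guaranteed observation time after the last possible landing."""
        return (self.n_total_frames - self.n_sampling_frames) / self.frame_rate_fps

    @property
    def sampled_air_volume_l(self) -> float:
        """Air volume drawn through the impactor per measurement, litres."""
        return self.flow_rate_lpm * self.sampling_duration_s / 60.0

    @property
    def frame_times_s(self):
        import numpy as np

        return np.arange(self.n_total_frames) / self.frame_rate_fps

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um ** 2

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["class_mixture"] = list(self.class_mixture)
        data["gap_range_min"] = list(self.gap_range_min)
        for key in ("kappa_range", "alpha_range", "b_range"):
            data[key] = {cls: list(rng) for cls, rng in data[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["class_mixture"] = tuple(data["class_mixture"])
        data["gap_range_min"] = tuple(data["gap_range_min"])
        for key in ("kappa_range", "alpha_range", "b_range"):
            data[key] = {c: tuple(r) for c, r in data[key].items()}
        return cls(**data)
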