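"""Ground-truth particle populations and multi-measurement study designs.

The generator emulates the statistical structure of an indoor vaping field
study: droplets land on the substrate during the sampling window, each
droplet's true volume follows ``V(t) = alpha * exp(-kappa * t) + b``, and a
"day" of measurements mixes pre-vaping (background) and post-vaping
(elevated-volatility) measurements spaced 5-30 minutes apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    CLASSES,
    DEFAULT_FULL_EVAPORATION_VOLUME_UM3,
    DEFAULT_NONVOLATILE_RATE_UM3_S,
    ScenarioConfig,
)

# Guard band keeping sampled particles away from the classification
# thresholds, so that class labels are unambiguous on noiseless data.
_THRESHOLD_GUARD = 1.2
_MAX_REJECTION_TRIES = 1000


@dataclass(frozen=True)
class ParticleTruth:
    """Ground truth for one simulated droplet.

    ``x``/``y`` are substrate coordinates in micrometres, ``landing_frame``
    the frame index at which the droplet appears (within the sampling
    window), and ``(alpha, kappa, b_offset)`` the parameters of the decay
    model ``V(t) = alpha * exp(-kappa * t) + b`` with t in seconds since
    landing.
    """

    particle_id: int
    x: float
    y: float
    landing_frame: int
    alpha: float
    kappa: float
    b_offset: float
    true_class: str
    contact_angle: float = 60.0

    def __post_init__(self):
        if self.alpha < 0 or self.kappa < 0 or self.b_offset < 0:
            raise ValueError("alpha, kappa and b_offset must be non-negative")
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")

    @property
    def initial_volume(self) -> float:
        """Volume at landing, alpha + b (um^3)."""
        return self.alpha + self.b_offset

    @property
    def true_decay_rate(self) -> float:
        """Volume decay rate V(t0) * kappa (um^3/s)."""
        return self.initial_volume * self.kappa


@dataclass
class MeasurementTruth:
    """One measurement of a study: timing, condition and its particles."""

    measurement_id: int
    start_min: float
    vaping_flag: bool
    gap_min: float
    particles: List[ParticleTruth]
    class_mixture: Tuple[float, float, float]


@dataclass
class StudyTruth:
    """A day of measurements with pre-/post-vaping structure."""

    measurements: List[MeasurementTruth]

    @property
    def n_pre(self) -> int:
        return sum(not m.vaping_flag for m in self.measurements)

    @property
    def n_post(self) -> int:
        return sum(m.vaping_flag for m in self.measurements)


# ---------------------------------------------------------------------------
# Spherical-cap geometry
# ---------------------------------------------------------------------------

def cap_footprint_radius(volume_um3: float, contact_angle_deg: float) -> float:
    """Footprint (contact-line) radius of a spherical cap of given volume.

    For contact angle theta the cap volume is
    ``V = (pi a^3 / 3) * (2 - 3 cos th + cos^3 th) / sin^3 th``.
    """
    if volume_um3 < 0:
        raise ValueError("volume must be non-negative")
    if volume_um3 == 0:
        return 0.0
    th = math.radians(contact_angle_deg)
    k = (2.0 - 3.0 * math.cos(th) + math.cos(th) ** 3) / math.sin(th) ** 3
    return (3.0 * volume_um3 / (math.pi * k)) ** (1.0 / 3.0)


def cap_height_profile(r: np.ndarray, footprint_radius_um: float,
                       contact_angle_deg: float) -> np.ndarray:
    """Height h(r) of a spherical cap above the substrate, zero outside."""
    r = np.asarray(r, dtype=float)
    if footprint_radius_um <= 0:
        return np.zeros_like(r)
    th = math.radians(contact_angle_deg)
    big_r = footprint_radius_um / math.sin(th)
    inside = r < footprint_radius_um
    h = np.zeros_like(r)
    h[inside] = np.sqrt(big_r ** 2 - r[inside] ** 2) - big_r * math.cos(th)
    return np.clip(h, 0.0, None)


# ---------------------------------------------------------------------------
# Particle sampling
# ---------------------------------------------------------------------------

def _class_invariants_ok(cls: str, alpha: float, kappa: float, b: float,
                         post_window_s: float) -> bool:
    evap = DEFAULT_FULL_EVAPORATION_VOLUME_UM3
    rate = DEFAULT_NONVOLATILE_RATE_UM3_S
    dv = (alpha + b) * kappa
    if cls == "volatile":
        # Must fully evaporate within the guaranteed post-sampling window
        # and decay clearly faster than the non-volatile cut.
        end_volume = alpha * math.exp(-kappa * post_window_s) + b
        return (b < evap / _THRESHOLD_GUARD
                and end_volume < evap / _THRESHOLD_GUARD
                and dv > rate * _THRESHOLD_GUARD)
    if cls == "semi_volatile":
        return (b > evap * _THRESHOLD_GUARD
                and dv > rate * _THRESHOLD_GUARD)
    # non_volatile
    return dv < rate / _THRESHOLD_GUARD


def _sample_class_params(cls: str, config: ScenarioConfig,
                         rng: np.random.Generator,
                         kappa_scale: float = 1.0) -> Tuple[float, float, float]:
    klo, khi = config.kappa_range[cls]
    alo, ahi = config.alpha_range[cls]
    blo, bhi = config.b_range[cls]
    post_window = config.post_sampling_duration_s
    for _ in range(_MAX_REJECTION_TRIES):
        kappa = rng.uniform(klo, khi) * kappa_scale
        alpha = rng.uniform(alo, ahi)
        b = rng.uniform(blo, bhi)
        if _class_invariants_ok(cls, alpha, kappa, b, post_window):
            return alpha, kappa, b
    raise ValueError(
        f"parameter ranges for class {cls!r} cannot satisfy its invariants"
    )


def _sample_positions(n: int, config: ScenarioConfig,
                      rng: np.random.Generator,
                      margin_um: float) -> np.ndarray:
    width = config.field_width_px * config.pixel_pitch_um
    height = config.field_height_px * config.pixel_pitch_um
    if n > 0 and (width <= 2 * margin_um or height <= 2 * margin_um):
        raise ValueError("field too small for the droplet footprints")
    pts: List[Tuple[float, float]] = []
    min_d2 = config.min_separation_um ** 2
    tries = 0
    while len(pts) < n:
        x = rng.uniform(margin_um, width - margin_um)
        y = rng.uniform(margin_um, height - margin_um)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_d2 for px, py in pts):
            pts.append((x, y))
            tries = 0
        else:
            tries += 1
            if tries > _MAX_REJECTION_TRIES:
                raise ValueError(
                    f"cannot place {n} particles with min separation "
                    f"{config.min_separation_um} um in this field"
                )
    return np.array(pts, dtype=float).reshape(n, 2)


def sample_particle_population(
    config: ScenarioConfig,
    n_particles: int,
    rng: Optional[np.random.Generator] = None,
    *,
    class_mixture: Optional[Sequence[float]] = None,
    kappa_scale: float = 1.0,
) -> List[ParticleTruth]:
    """Draw a ground-truth droplet population for one measurement.

    Classes are drawn from ``class_mixture`` (defaulting to the scenario's
    background mixture), per-class decay parameters from the configured
    uniform ranges with rejection so every particle respects its class
    invariants, positions uniformly with a minimum pairwise separation, and
    landing frames uniformly over the sampling window.  Deterministic for a
    given generator state.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    mixture = np.asarray(
        config.class_mixture if class_mixture is None else class_mixture,
        dtype=float,
    )
    if mixture.shape != (3,) or np.any(mixture < 0) or abs(mixture.sum() - 1) > 1e-12:
        raise ValueError("class mixture must be 3 probabilities summing to 1")
    if n_particles == 0:
        return []

    labels = rng.choice(3, size=n_particles, p=mixture)
    params = [
        _sample_class_params(CLASSES[lab], config, rng, kappa_scale)
        for lab in labels
    ]
    max_v0 = max(a + b for a, _, b in params)
    # keep droplets clear of the frame border: their twin-image rings
    # must not collide with the propagation crop boundary
    margin = cap_footprint_radius(max_v0, config.contact_angle_deg) + 10 * config.pixel_pitch_um
    positions = _sample_positions(n_particles, config, rng, margin)
    landing = rng.integers(0, config.n_sampling_frames, size=n_particles)

    return [
        ParticleTruth(
            particle_id=i,
            x=float(positions[i, 0]),
            y=float(positions[i, 1]),
            landing_frame=int(landing[i]),
            alpha=params[i][0],
            kappa=params[i][1],
            b_offset=params[i][2],
            true_class=CLASSES[labels[i]],
            contact_angle=config.contact_angle_deg,
        )
        for i in range(n_particles)
    ]


def truth_volume_trajectory(particle: ParticleTruth,
                            times_s: np.ndarray) -> np.ndarray:
    """Evaluate the true decay model V(t) = alpha e^{-kappa t} + b.

    ``times_s`` are seconds since landing, non-negative and increasing.
    """
    t = np.asarray(times_s, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("times must be non-negative and strictly increasing")
    return particle.alpha * np.exp(-particle.kappa * t) + particle.b_offset


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

def _post_vaping_mixture(mixture: Sequence[float],
                         effect_size: float) -> Tuple[float, float, float]:
    w = np.asarray(mixture, dtype=float) * np.array(
        [1.0 + effect_size, 1.0 + 0.5 * effect_size, 1.0]
    )
    w = w / w.sum()
    return (float(w[0]), float(w[1]), float(w[2]))


def generate_study(
    config: ScenarioConfig,
    n_measurements: int,
    vaping_schedule: Sequence[bool],
    *,
    effect_size: float = 0.5,
    n_particles_per_measurement: Optional[int] = None,
) -> StudyTruth:
    """Generate ground truth for a day of measurements.

    ``vaping_schedule[k]`` marks measurement ``k`` as post-vaping (True) or
    pre-vaping background (False).  Post-vaping measurements use a class
    mixture shifted toward volatile particles and decay constants of the
    volatile and semi-volatile classes scaled by ``1 + effect_size``;
    ``effect_size = 0`` makes both conditions identically distributed.  Gaps
    between consecutive measurements are drawn from ``config.gap_range_min``.

    Each measurement consumes an independent child stream of the scenario
    seed, so any single measurement can be regenerated in isolation.
    """
    if n_measurements < 1:
        raise ValueError("need at least one measurement")
    if len(vaping_schedule) != n_measurements:
        raise ValueError("vaping_schedule length must equal n_measurements")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    n_part = (config.n_particles_per_measurement
              if n_particles_per_measurement is None
              else n_particles_per_measurement)

    root = np.random.SeedSequence(config.rng_seed)
    gap_stream, *measurement_streams = root.spawn(n_measurements + 1)
    gap_rng = np.random.default_rng(gap_stream)
    gaps = gap_rng.uniform(*config.gap_range_min, size=n_measurements)

    post_mixture = _post_vaping_mixture(config.class_mixture, effect_size)
    measurements = []
    start = 0.0
    for k in range(n_measurements):
        vaping = bool(vaping_schedule[k])
        mixture = post_mixture if vaping else tuple(config.class_mixture)
        kappa_scale = 1.0 + effect_size if vaping else 1.0
        rng = np.random.default_rng(measurement_streams[k])
        particles = sample_particle_population(
            config, n_part, rng, class_mixture=mixture, kappa_scale=kappa_scale
        )
        if k > 0:
            start += gaps[k]
        measurements.append(
            MeasurementTruth(
                measurement_id=k,
                start_min=start,
                vaping_flag=vaping,
                gap_min=float(gaps[k]),
                particles=particles,
                class_mixture=mixture,
            )
        )
    return StudyTruth(measurements=measurements)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def particles_to_frame(particles: Sequence[ParticleTruth]) -> pd.DataFrame:
    """One row per particle: id, position, landing frame, decay parameters."""
    return pd.DataFrame(
        {
            "id": [p.particle_id for p in particles],
            "x_um": [p.x for p in particles],
            "y_um": [p.y for p in particles],
            "landing_frame": [p.landing_frame for p in particles],
            "alpha_um3": [p.alpha for p in particles],
            "kappa_per_s": [p.kappa for p in particles],
            "b_um3": [p.b_offset for p in particles],
            "class": [p.true_class for p in particles],
        }
    )


def study_to_frame(study: StudyTruth) -> pd.DataFrame:
    """One row per measurement: id, start time, condition, particle count."""
    return pd.DataFrame(
        {
            "measurement_id": [m.measurement_id for m in study.measurements],
            "start_min": [m.start_min for m in study.measurements],
            "vaping_flag": [m.vaping_flag for m in study.measurements],
            "n_particles": [len(m.particles) for m in study.measurements],
        }
    )
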