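"""Forward hologram rendering and classical holographic reconstruction.

The forward model treats each sessile droplet as a pure phase object: a
spherical-cap height map ``h`` imposes a phase delay
``phi = (2 pi / lambda) * delta_n * h`` on a unit plane wave, which is then
propagated to the sensor plane with the angular-spectrum method and recorded
as intensity (with optional shot and read noise and quantization).

Reconstruction is deterministic: back-propagation of the normalized
hologram amplitude, with optional support-constrained iterative phase
retrieval to suppress the twin image, plus entropy-based autofocus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy import ndimage
from skimage.measure import block_reduce, label as sk_label
from skimage.morphology import dilation as sk_dilation, disk, erosion as sk_erosion
from skimage.restoration import unwrap_phase as sk_unwrap_phase
from skimage.transform import resize

from .config import ScenarioConfig
from .scene import ParticleTruth, cap_footprint_radius, cap_height_profile, truth_volume_trajectory

__all__ = [
    "ComplexFrame",
    "HologramStack",
    "AutofocusResult",
    "droplet_phase_map",
    "propagate_angular_spectrum",
    "propagate_with_unit_background",
    "render_hologram_frame",
    "render_hologram_stack",
    "autofocus",
    "reconstruct_frame",
    "reconstruct_stack",
    "unwrap_phase_roi",
    "estimate_background",
]


@dataclass
class ComplexFrame:
    """One reconstructed complex image with amplitude and phase channels."""

    field: np.ndarray
    z_um: float

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.ndim != 2:
            raise ValueError("field must be 2-D")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]."""
        return np.angle(self.field)


@dataclass
class HologramStack:
    """Time-ordered intensity frames plus acquisition metadata."""

    frames: np.ndarray
    frame_times_s: np.ndarray
    wavelength_um: float
    pixel_pitch_um: float
    z_um: float
    frame_rate_fps: float
    bit_depth: int = 16

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.frame_times_s) != len(self.frames):
            raise ValueError("one frame time per frame required")
        dt = np.diff(self.frame_times_s)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.frame_rate_fps)):
            raise ValueError("frame times must increase at 1/frame_rate spacing")
        if self.frames.min() < 0 or self.frames.max() > 2 ** self.bit_depth - 1:
            raise ValueError("intensities must lie within the bit depth range")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AutofocusResult:
    """Outcome of the autofocus search."""

    z_um: float
    focusable: bool
    z_grid_um: np.ndarray = field(repr=False)
    criterion: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def droplet_phase_map(particle: ParticleTruth, current_volume_um3: float,
                      config: ScenarioConfig) -> np.ndarray:
    """Phase delay map of one droplet at its current volume.

    The footprint radius is fixed by the droplet's *initial* volume (pinned
    contact line); evaporation scales the cap height profile uniformly.  The
    discretized heights are renormalized so the pixel sum times pixel area
    equals ``current_volume_um3`` exactly.
    """
    if current_volume_um3 < 0:
        raise ValueError("current_volume must be non-negative")
    shape = (config.field_height_px, config.field_width_px)
    phi = np.zeros(shape, dtype=float)
    if current_volume_um3 == 0:
        return phi

    pitch = config.pixel_pitch_um
    a = cap_footprint_radius(particle.initial_volume, particle.contact_angle)
    if (particle.x - a < 0 or particle.y - a < 0
            or particle.x + a > config.field_width_px * pitch
            or particle.y + a > config.field_height_px * pitch):
        raise ValueError("droplet footprint exceeds the field of view")

    r0 = max(int(math.floor((particle.y - a) / pitch)) - 1, 0)
    r1 = min(int(math.ceil((particle.y + a) / pitch)) + 2, shape[0])
    c0 = max(int(math.floor((particle.x - a) / pitch)) - 1, 0)
    c1 = min(int(math.ceil((particle.x + a) / pitch)) + 2, shape[1])
    yy = (np.arange(r0, r1) + 0.5) * pitch
    xx = (np.arange(c0, c1) + 0.5) * pitch
    rr = np.hypot(xx[None, :] - particle.x, yy[:, None] - particle.y)
    h = cap_height_profile(rr, a, particle.contact_angle)
    total = h.sum() * config.pixel_area_um2
    if total <= 0:
        # Sub-pixel footprint: deposit the whole volume on the nearest pixel.
        i = min(max(int(particle.y / pitch), 0), shape[0] - 1)
        j = min(max(int(particle.x / pitch), 0), shape[1] - 1)
        height = current_volume_um3 / config.pixel_area_um2
        phi[i, j] = 2.0 * math.pi / config.wavelength_um * config.delta_n * height
        return phi
    h *= current_volume_um3 / total
    phi[r0:r1, c0:c1] = 2.0 * math.pi / config.wavelength_um * config.delta_n * h
    return phi


def propagate_angular_spectrum(field_in: np.ndarray, distance_um: float,
                               wavelength_um: float, pixel_pitch_um: float,
                               *, pad: bool = True) -> np.ndarray:
    """Free-space propagation by the angular-spectrum transfer function.

    Applies ``exp(i 2 pi d sqrt(1/lambda^2 - fx^2 - fy^2))`` in the spatial
    frequency domain; evanescent components are set to zero.  With ``pad``
    the field is zero-padded by 50% per side and cropped back, which
    suppresses wrap-around artifacts of the circular convolution.
    """
    u = np.asarray(field_in, dtype=complex)
    if u.ndim != 2:
        raise ValueError("field must be 2-D")
    if not np.all(np.isfinite(u)):
        raise ValueError("field contains non-finite values")
    n0, n1 = u.shape
    if pad:
        p0, p1 = n0 // 2, n1 // 2
        u = np.pad(u, ((p0, p0), (p1, p1)))
    fy = fftfreq(u.shape[0], d=pixel_pitch_um)
    fx = fftfreq(u.shape[1], d=pixel_pitch_um)
    arg = 1.0 / wavelength_um ** 2 - fx[None, :] ** 2 - fy[:, None] ** 2
    kz = np.sqrt(np.clip(arg, 0.0, None))
    transfer = np.exp(2j * math.pi * distance_um * kz)
    transfer[arg < 0] = 0.0
    out = ifft2(fft2(u) * transfer)
    if pad:
        out = out[p0:p0 + n0, p1:p1 + n1]
    return out


def propagate_with_unit_background(field_in: np.ndarray, distance_um: float,
                                   wavelength_um: float,
                                   pixel_pitch_um: float) -> np.ndarray:
    """Propagate a field whose background is a unit plane wave.

    Zero-padding a field with unity background would turn the frame edge
    into a hard aperture and flood the result with edge diffraction.  The
    compactly supported scattered component ``field - 1`` is propagated
    instead and the analytically propagated plane wave
    ``exp(i 2 pi d / lambda)`` added back.
    """
    scattered = np.asarray(field_in, dtype=complex) - 1.0
    out = propagate_angular_spectrum(
        scattered, distance_um, wavelength_um, pixel_pitch_um
    )
    return out + np.exp(2j * math.pi * distance_um / wavelength_um)


def render_hologram_frame(
    particles_and_volumes: Sequence[Tuple[ParticleTruth, float]],
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one intensity frame of the landed droplets.

    A unit plane wave is modulated by the summed droplet phase at the
    substrate, propagated to the sensor, recorded as intensity scaled to the
    configured mean counts, degraded by shot and read noise (when an ``rng``
    is supplied and the scenario enables them) and quantized to the
    configured bit depth.
    """
    phi = np.zeros((config.field_height_px, config.field_width_px))
    for particle, volume in particles_and_volumes:
        phi += droplet_phase_map(particle, volume, config)
    u = np.exp(1j * phi)
    u_sensor = propagate_with_unit_background(
        u, config.z_distance_um, config.wavelength_um, config.pixel_pitch_um
    )
    intensity = np.abs(u_sensor) ** 2 * config.mean_counts
    if rng is not None:
        if config.shot_noise:
            intensity = rng.poisson(intensity).astype(float)
        if config.read_noise_counts > 0:
            intensity = intensity + rng.normal(
                0.0, config.read_noise_counts, size=intensity.shape
            )
    full_scale = 2 ** config.bit_depth - 1
    intensity = np.clip(np.round(intensity), 0, full_scale)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return intensity.astype(dtype)


def render_hologram_stack(
    particles: Sequence[ParticleTruth],
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
) -> HologramStack:
    """Render the full time-lapse hologram stack of one measurement."""
    frames = []
    for i in range(config.n_total_frames):
        landed = []
        for p in particles:
            if p.landing_frame <= i:
                t = (i - p.landing_frame) / config.frame_rate_fps
                v = float(truth_volume_trajectory(p, np.array([t]))[0])
                landed.append((p, v))
        frames.append(render_hologram_frame(landed, config, rng))
    return HologramStack(
        frames=np.stack(frames),
        frame_times_s=config.frame_times_s,
        wavelength_um=config.wavelength_um,
        pixel_pitch_um=config.pixel_pitch_um,
        z_um=config.z_distance_um,
        frame_rate_fps=config.frame_rate_fps,
        bit_depth=config.bit_depth,
    )


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def estimate_background(intensity: np.ndarray, *, downsample: int = 4,
                        median_size: int = 31) -> np.ndarray:
    """Smooth illumination-profile estimate via a coarse median filter.

    The frame is block-averaged (suppressing fine interference fringes),
    median filtered over a window much wider than any fringe period
    (robust against the broad central lobes of particle holograms), and
    resampled to full resolution.
    """
    img = np.asarray(intensity, dtype=float)
    small = block_reduce(img, (downsample, downsample), np.mean)
    med = ndimage.median_filter(small, size=median_size, mode="nearest")
    bg = resize(med, img.shape, order=1, mode="edge", anti_aliasing=False)
    return bg


def _zero_background_phase(field_in: np.ndarray) -> np.ndarray:
    """Rotate out the global phase so the field mean is real positive.

    Back-propagation of a real sensor amplitude carries an arbitrary
    overall phase ``exp(-i 2 pi z / lambda)``; the physically meaningful
    phase is relative to the unscattered background.
    """
    mean = field_in.mean()
    if mean == 0:
        return field_in
    return field_in * np.exp(-1j * np.angle(mean))


def _amplitude_entropy(amplitude: np.ndarray) -> float:
    p = amplitude / amplitude.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def autofocus(
    hologram_frame: np.ndarray,
    z_search_range_um: Tuple[float, float],
    z_step_um: float,
    config: ScenarioConfig,
    *,
    flat_tol: float = 1e-8,
) -> AutofocusResult:
    """Grid-plus-golden-section search for the sharpest focus distance.

    For phase objects the back-propagated amplitude is flattest at focus, so
    the criterion maximized here is the Shannon entropy of the normalized
    amplitude channel (maximal for a uniform image).  The criterion is
    invariant to global intensity scaling.  If it is flat over the whole
    search grid (no signal), the frame is flagged unfocusable.
    """
    z_lo, z_hi = z_search_range_um
    if z_step_um <= 0:
        raise ValueError("z_step must be positive")
    if z_hi <= z_lo:
        raise ValueError("empty z search range")
    img = np.asarray(hologram_frame, dtype=float)
    amp = np.sqrt(img / img.mean())

    def criterion(z: float) -> float:
        u = propagate_with_unit_background(
            amp, -z, config.wavelength_um, config.pixel_pitch_um
        )
        return _amplitude_entropy(np.abs(u))

    z_grid = np.arange(z_lo, z_hi + 0.5 * z_step_um, z_step_um)
    values = np.array([criterion(z) for z in z_grid])
    spread = float(values.max() - values.min())
    if spread < flat_tol:
        return AutofocusResult(float(np.nan), False, z_grid, values)

    i_best = int(np.argmax(values))
    lo = z_grid[max(i_best - 1, 0)]
    hi = z_grid[min(i_best + 1, len(z_grid) - 1)]
    # Golden-section refinement to 1 um.
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = criterion(c), criterion(d)
    while b - a > 1.0:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = criterion(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = criterion(d)
    return AutofocusResult(float(0.5 * (a + b)), True, z_grid, values)


def _detection_support(frame: ComplexFrame, k_sigma: float = 5.0,
                       dilation_px: int = 4) -> np.ndarray:
    """Union of amplitude-deviation and phase threshold masks, dilated."""
    def mask(img: np.ndarray) -> np.ndarray:
        return img > img.mean() + k_sigma * img.std()

    m = mask(np.abs(1.0 - frame.amplitude)) | mask(np.abs(frame.phase))
    if dilation_px > 0 and m.any():
        m = sk_dilation(m, disk(dilation_px))
    return m


def _nonnegative_phase_projection(obj: np.ndarray,
                                  support: np.ndarray) -> np.ndarray:
    """Project onto the droplet object set: non-negative phase delay
    inside the support, zero outside, unit transmission everywhere.

    The non-negativity is imposed on the *unwrapped* phase: droplets can
    delay the wave by more than pi, so clipping the wrapped angle would
    destroy their cores.  Intensity is almost blind to smooth phase
    offsets within the support, and without this pin the retrieval can
    park an arbitrary low-frequency phase ramp there.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        unwrapped = unwrap_phase_roi(np.angle(obj), support)
    return np.where(support, np.clip(unwrapped, 0.0, None), 0.0)


def reconstruct_frame(
    hologram_frame: np.ndarray,
    z_um: float,
    config: ScenarioConfig,
    *,
    refine: bool = False,
    n_refine: int = 20,
    support: Optional[np.ndarray] = None,
    constraint: str = "phase_object",
) -> ComplexFrame:
    """Back-propagate one hologram to the substrate plane.

    The measured intensity is normalized by a median-filtered background
    estimate, its square root taken as the sensor-plane amplitude (zero
    phase), and the field propagated by ``-z``.  With ``refine`` a fixed
    number of support-constrained phase-retrieval rounds is run: outside
    the object support the transmission is reset to unity, and at the
    sensor the amplitude is reset to the measurement.  This suppresses the
    twin image for sparse scenes.  The default ``phase_object`` constraint
    additionally imposes what is known about sessile droplets — they are
    transparent (unit amplitude) with non-negative phase delay — which is
    considerably stronger than the loose ``support`` constraint (arbitrary
    complex transmission inside the support).
    """
    if constraint not in ("phase_object", "support"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if z_um <= 0:
        raise ValueError("z must be positive")
    img = np.asarray(hologram_frame, dtype=float)
    bg = estimate_background(img)
    if np.any(bg <= 0):
        raise ValueError("zero-valued background estimate")
    amp = np.sqrt(img / bg)
    obj = _zero_background_phase(propagate_with_unit_background(
        amp, -z_um, config.wavelength_um, config.pixel_pitch_um
    ))
    if refine:
        if support is None:
            support = _detection_support(ComplexFrame(obj, z_um))
        if support.any():
            for _ in range(n_refine):
                if constraint == "phase_object":
                    constrained = np.exp(
                        1j * _nonnegative_phase_projection(obj, support)
                    )
                else:
                    constrained = np.where(support, obj, 1.0 + 0.0j)
                sensor = propagate_with_unit_background(
                    constrained, z_um, config.wavelength_um, config.pixel_pitch_um
                )
                sensor = amp * np.exp(1j * np.angle(sensor))
                obj = _zero_background_phase(propagate_with_unit_background(
                    sensor, -z_um, config.wavelength_um, config.pixel_pitch_um
                ))
            # Return the object-constrained estimate: the residual twin
            # ripple lives outside the support and would otherwise leak
            # into downstream phase integrals.
            obj = np.where(support, obj, 1.0 + 0.0j)
    return ComplexFrame(obj, z_um)


def reconstruct_stack(
    stack: HologramStack,
    config: ScenarioConfig,
    *,
    z_um: Optional[float] = None,
    refine: bool = False,
    n_refine: int = 20,
) -> List[ComplexFrame]:
    """Reconstruct every frame of a stack at a common focus distance."""
    z = stack.z_um if z_um is None else z_um
    return [
        reconstruct_frame(f, z, config, refine=refine, n_refine=n_refine)
        for f in stack.frames
    ]


# ---------------------------------------------------------------------------
# Phase unwrapping
# ---------------------------------------------------------------------------

def _anchor_shift(boundary_median: float) -> float:
    """2*pi multiple bringing the boundary median into (-pi, pi]."""
    k = round(boundary_median / (2.0 * math.pi))
    while boundary_median - 2.0 * math.pi * k > math.pi:
        k += 1
    while boundary_median - 2.0 * math.pi * k <= -math.pi:
        k -= 1
    return 2.0 * math.pi * k


def unwrap_phase_roi(phase: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Unwrap the phase inside an ROI, anchored at its boundary.

    Returns a copy of ``phase`` whose in-ROI values are replaced by a
    2-pi-discontinuity-free unwrapping (reliability-guided), shifted by a
    multiple of 2*pi so the median phase on the ROI boundary lies in
    (-pi, pi].  A disconnected ROI is processed per connected component with
    a warning.
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if phase.shape != mask.shape:
        raise ValueError("phase and mask shapes differ")
    out = phase.copy()
    if not mask.any():
        return out
    labels = sk_label(mask, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1:
        warnings.warn(
            f"ROI has {n_comp} connected components; unwrapping each separately",
            stacklevel=2,
        )
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        sub = comp[r0:r1, c0:c1]
        patch = np.ma.array(phase[r0:r1, c0:c1], mask=~sub)
        if sub.sum() == 1:
            unwrapped = patch.data
        else:
            unwrapped = np.ma.filled(sk_unwrap_phase(patch), 0.0)
        boundary = sub & ~sk_erosion(
            sub, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        )
        if not boundary.any():
            boundary = sub
        shift = _anchor_shift(float(np.median(unwrapped[boundary])))
        out_patch = out[r0:r1, c0:c1]
        out_patch[sub] = unwrapped[sub] - shift
    return out
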