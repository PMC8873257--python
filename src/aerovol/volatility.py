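"""Exponential decay fitting and volatility classification.

Each particle's volume time series is fitted with

    V(t) = alpha * exp(-kappa * t) + b,

the lifetime is ``tau = 1 / kappa`` and the volume decay rate
``dV_tau = V(t0) / tau = V(t0) * kappa`` (um^3/s), a size-normalized figure
of merit for volatility.  Particles are then classified:

* **non-volatile** — decay rate below 0.05 um^3/s;
* **volatile** — the last observed volume is below the full-evaporation
  threshold of 0.1 um^3 *and* the decay is smooth (fit R^2 >= 0.9);
* **semi-volatile** — everything else (initial decay to a residue that
  stays above 0.1 um^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import (
    DEFAULT_FULL_EVAPORATION_VOLUME_UM3,
    DEFAULT_NONVOLATILE_RATE_UM3_S,
    DEFAULT_SMOOTHNESS_R2,
    ScenarioConfig,
)
from .scene import ParticleTruth
from .volumetry import VolumeTrajectory

__all__ = [
    "ClassThresholds",
    "VolatilityResult",
    "fit_exponential_decay",
    "lifetime",
    "volume_decay_rate",
    "classify_particle",
    "analyze_trajectory",
    "truth_result",
    "semi_volatile_band_screen",
    "results_to_frame",
]

#: kappa below this is treated as zero (infinite lifetime).
KAPPA_ZERO_TOL = 1e-8

#: Upper bound on kappa (1/s): a particle with tau = 0.1 s would evaporate
#: between consecutive frames at 2 fps, so faster decays are unobservable.
KAPPA_MAX = 10.0


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds of the three-way volatility classification."""

    full_evaporation_volume: float = DEFAULT_FULL_EVAPORATION_VOLUME_UM3
    nonvolatile_rate: float = DEFAULT_NONVOLATILE_RATE_UM3_S
    smoothness_r2: float = DEFAULT_SMOOTHNESS_R2

    def __post_init__(self):
        if self.full_evaporation_volume <= 0 or self.nonvolatile_rate <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0.0 < self.smoothness_r2 <= 1.0):
            raise ValueError("smoothness_r2 must lie in (0, 1]")


@dataclass
class FitResult:
    alpha: float
    kappa: float
    b: float
    r_squared: float
    converged: bool


@dataclass
class VolatilityResult:
    """Fitted decay model, derived volatility metrics and class label."""

    track_id: int
    alpha_um3: float
    kappa_per_s: float
    b_um3: float
    tau_s: float
    v0_um3: float
    dv_tau_um3_per_s: float
    r_squared: float
    assigned_class: str
    fit_converged: bool
    warning: bool = False


def _decay_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    alpha, kappa, b = params
    return alpha * np.exp(-kappa * t) + b


def fit_exponential_decay(trajectory: VolumeTrajectory) -> FitResult:
    """Bounded nonlinear least squares of V(t) = alpha e^{-kappa t} + b.

    Only frames above the volume floor are fitted.  Initialization:
    ``b0 = min(V)``, ``alpha0 = V(t0) - b0`` and ``kappa0`` from the slope
    of a log-linear regression of ``max(V - b0, eps)`` against time.
    Bounds: alpha >= 0, kappa in [0, 10 /s], b >= 0.  R^2 is computed on
    the fitted frames.
    """
    sel = ~trajectory.below_floor
    t = trajectory.times_s[sel]
    v = trajectory.volumes_um3[sel]
    if len(t) < 3 or not trajectory.usable:
        return FitResult(math.nan, math.nan, math.nan, math.nan, False)

    b0 = float(v.min())
    alpha0 = max(float(v[0] - b0), 1e-6)
    eps = max(1e-9, 1e-6 * float(v.max()))
    decay_part = np.clip(v - b0, eps, None)
    slope = np.polyfit(t, np.log(decay_part), 1)[0]
    kappa0 = float(np.clip(-slope, 1e-6, KAPPA_MAX))

    res = least_squares(
        lambda p: _decay_model(p, t) - v,
        x0=np.array([alpha0, kappa0, b0]),
        bounds=(np.zeros(3), np.array([np.inf, KAPPA_MAX, np.inf])),
        xtol=1e-8,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=500 * 4,
    )
    alpha, kappa, b = (float(x) for x in res.x)
    if alpha < 1e-10:
        # No decaying component: kappa is unidentifiable, report zero.
        kappa = 0.0
    ss_res = float(np.sum((v - _decay_model(res.x, t)) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return FitResult(alpha, kappa, b, r2, bool(res.success))


def lifetime(kappa_per_s: float) -> float:
    """tau = 1 / kappa; +inf for kappa at or below the zero tolerance."""
    if kappa_per_s < 0:
        raise ValueError("kappa must be non-negative")
    if kappa_per_s <= KAPPA_ZERO_TOL:
        return math.inf
    return 1.0 / kappa_per_s


def volume_decay_rate(v0_um3: float, tau_s: float) -> float:
    """dV_tau = V(t0) / tau (um^3/s); zero for infinite lifetime."""
    if v0_um3 < 0 or tau_s <= 0:
        raise ValueError("v0 must be >= 0 and tau > 0")
    if math.isinf(tau_s):
        return 0.0
    return v0_um3 / tau_s


def classify_particle(
    trajectory: VolumeTrajectory,
    result: VolatilityResult,
    thresholds: Optional[ClassThresholds] = None,
) -> str:
    """Assign exactly one volatility class.

    Rule order: (1) non-volatile if the decay rate is below the
    non-volatile cut; (2) volatile if the last observed volume is below the
    full-evaporation threshold and the fit is smooth (R^2 at or above the
    smoothness cut); (3) semi-volatile otherwise.  Trajectories without a
    converged fit fall back to the raw-trajectory empirical rate and can
    only be non- or semi-volatile (smoothness cannot be established).
    """
    thr = thresholds or ClassThresholds()
    n = len(trajectory.volumes_um3)
    if result.fit_converged:
        if result.dv_tau_um3_per_s < thr.nonvolatile_rate:
            return "non_volatile"
        if (n and trajectory.volumes_um3[-1] < thr.full_evaporation_volume
                and result.r_squared >= thr.smoothness_r2):
            return "volatile"
        return "semi_volatile"
    if n >= 2 and trajectory.times_s[-1] > trajectory.times_s[0]:
        rate = (trajectory.volumes_um3[0] - trajectory.volumes_um3[-1]) / (
            trajectory.times_s[-1] - trajectory.times_s[0]
        )
        if rate < thr.nonvolatile_rate:
            return "non_volatile"
    return "semi_volatile"


def analyze_trajectory(
    trajectory: VolumeTrajectory,
    thresholds: Optional[ClassThresholds] = None,
) -> VolatilityResult:
    """Fit, derive tau and dV_tau, and classify one trajectory.

    ``V(t0)`` is the first above-floor measured volume.  The identity
    ``dV_tau = v0 * kappa = v0 / tau`` holds exactly for finite results.
    """
    fit = fit_exponential_decay(trajectory)
    above = trajectory.volumes_um3[~trajectory.below_floor]
    v0 = float(above[0]) if above.size else (
        float(trajectory.volumes_um3[0]) if len(trajectory.volumes_um3) else math.nan
    )
    if fit.converged:
        tau = lifetime(fit.kappa)
        kappa = 0.0 if math.isinf(tau) else fit.kappa
        dv = volume_decay_rate(v0, tau)
    else:
        tau, kappa, dv = math.nan, math.nan, math.nan
    result = VolatilityResult(
        track_id=trajectory.track_id,
        alpha_um3=fit.alpha,
        kappa_per_s=kappa,
        b_um3=fit.b,
        tau_s=tau,
        v0_um3=v0,
        dv_tau_um3_per_s=dv,
        r_squared=fit.r_squared,
        assigned_class="semi_volatile",
        fit_converged=fit.converged,
        warning=not fit.converged,
    )
    result.assigned_class = classify_particle(trajectory, result,
                                              thresholds=thresholds)
    return result


def truth_result(
    particle: ParticleTruth,
    config: ScenarioConfig,
    thresholds: Optional[ClassThresholds] = None,
) -> VolatilityResult:
    """Volatility metrics a noiseless, exact measurement would yield.

    Used by study-level simulations: the decay parameters are known, so the
    fit is exact (R^2 = 1) and the metrics follow in closed form, observed
    over the particle's actual time in view.
    """
    thr = thresholds or ClassThresholds()
    observed_s = (config.n_total_frames - 1 - particle.landing_frame) / config.frame_rate_fps
    v0 = particle.initial_volume
    last = particle.alpha * math.exp(-particle.kappa * observed_s) + particle.b_offset
    tau = lifetime(particle.kappa)
    dv = volume_decay_rate(v0, tau)
    if dv < thr.nonvolatile_rate:
        cls = "non_volatile"
    elif last < thr.full_evaporation_volume:
        cls = "volatile"
    else:
        cls = "semi_volatile"
    return VolatilityResult(
        track_id=particle.particle_id,
        alpha_um3=particle.alpha,
        kappa_per_s=particle.kappa,
        b_um3=particle.b_offset,
        tau_s=tau,
        v0_um3=v0,
        dv_tau_um3_per_s=dv,
        r_squared=1.0,
        assigned_class=cls,
        fit_converged=True,
    )


def semi_volatile_band_screen(
    results: Sequence[VolatilityResult],
    n_sigma: float = 2.0,
) -> np.ndarray:
    """Optional alternative semi-volatile screen.

    Flags a particle as semi-volatile when its decay rate lies within
    ``mean +- n_sigma * std`` of the volatile population's decay rates but
    it did not fully evaporate.  Returns a boolean array aligned with
    ``results``.
    """
    vol_rates = np.array([
        r.dv_tau_um3_per_s for r in results if r.assigned_class == "volatile"
    ])
    flags = np.zeros(len(results), dtype=bool)
    if vol_rates.size == 0:
        return flags
    lo = vol_rates.mean() - n_sigma * vol_rates.std()
    hi = vol_rates.mean() + n_sigma * vol_rates.std()
    for i, r in enumerate(results):
        if r.assigned_class != "volatile" and lo <= r.dv_tau_um3_per_s <= hi:
            flags[i] = True
    return flags


def results_to_frame(results: Sequence[VolatilityResult]) -> pd.DataFrame:
    """One row per particle: fitted parameters, metrics and class."""
    return pd.DataFrame(
        {
            "track_id": [r.track_id for r in results],
            "alpha": [r.alpha_um3 for r in results],
            "kappa": [r.kappa_per_s for r in results],
            "b": [r.b_um3 for r in results],
            "tau_s": [r.tau_s for r in results],
            "v0_um3": [r.v0_um3 for r in results],
            "dv_tau_um3_per_s": [r.dv_tau_um3_per_s for r in results],
            "r2": [r.r_squared for r in results],
            "class": [r.assigned_class for r in results],
            "converged": [r.fit_converged for r in results],
        }
    )
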