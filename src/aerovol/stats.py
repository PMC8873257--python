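"""Study-level statistics: per-measurement summaries, pre/post-vaping
comparison, and PM10 mass concentration from a size distribution.

The pre/post comparison uses a two-sided Wilcoxon rank-sum test on the
pooled per-particle volume decay rates (or on per-measurement means),
testing the null that the two conditions' decay rates come from continuous
distributions with equal medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import ScenarioConfig
from .volatility import VolatilityResult, truth_result
from .scene import StudyTruth

__all__ = [
    "MeasurementSummary",
    "SizeDistribution",
    "ComparisonReport",
    "measurement_summary",
    "wilcoxon_rank_sum",
    "compare_pre_post",
    "pm10_mass_concentration",
    "study_truth_decay_rates",
    "summaries_to_frame",
    "plot_study",
]

#: Largest pooled sample size for which the exact null distribution is
#: enumerated by default (C(12, 6) = 924 assignments at most).
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class MeasurementSummary:
    """Aggregates of one measurement's classified particles."""

    measurement_id: int
    start_min: float
    vaping_flag: bool
    n_particles: int
    mean_dv_tau: float
    pct_volatile: float
    pct_semi_volatile: float
    pct_non_volatile: float
    pct_volatile_plus_semi: float
    sampled_air_volume_l: float


@dataclass
class SizeDistribution:
    """Particle counts per aerodynamic-diameter bin.

    ``bin_edges_um`` must be increasing and lie within the sizing
    instrument's range [0.5, 19.8] um; ``counts`` are particles per bin in
    the sampled air volume (m^3).
    """

    bin_edges_um: np.ndarray
    counts: np.ndarray
    air_volume_m3: float

    def __post_init__(self):
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges_um) != len(self.counts) + 1:
            raise ValueError("need one more edge than bins")
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if (len(self.bin_edges_um)
                and (self.bin_edges_um[0] < 0.5 or self.bin_edges_um[-1] > 19.8)):
            raise ValueError("bin edges must lie within [0.5, 19.8] um")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class ComparisonReport:
    """Pre- vs post-vaping decay-rate comparison."""

    n_pre: int
    n_post: int
    median_pre: float
    median_post: float
    rank_sum_post: float
    p_value: float
    post_higher: bool


def measurement_summary(
    results: Sequence[VolatilityResult],
    config: ScenarioConfig,
    *,
    measurement_id: int = 0,
    start_min: float = 0.0,
    vaping_flag: bool = False,
) -> MeasurementSummary:
    """Aggregate one measurement's results.

    ``mean_dv_tau`` is the arithmetic mean of the finite decay rates; the
    class percentages cover all classified particles and sum to 100.  With
    zero particles the aggregates are NaN-marked.
    """
    n = len(results)
    if n == 0:
        nan = math.nan
        return MeasurementSummary(measurement_id, start_min, vaping_flag, 0,
                                  nan, nan, nan, nan, nan,
                                  config.sampled_air_volume_l)
    rates = np.array([r.dv_tau_um3_per_s for r in results])
    finite = rates[np.isfinite(rates)]
    classes = [r.assigned_class for r in results]
    pct = {c: 100.0 * classes.count(c) / n
           for c in ("volatile", "semi_volatile", "non_volatile")}
    return MeasurementSummary(
        measurement_id=measurement_id,
        start_min=start_min,
        vaping_flag=vaping_flag,
        n_particles=n,
        mean_dv_tau=float(finite.mean()) if finite.size else math.nan,
        pct_volatile=pct["volatile"],
        pct_semi_volatile=pct["semi_volatile"],
        pct_non_volatile=pct["non_volatile"],
        pct_volatile_plus_semi=pct["volatile"] + pct["semi_volatile"],
        sampled_air_volume_l=config.sampled_air_volume_l,
    )


def _exact_two_sided_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments of ranks to x."""
    n_le = n_ge = total = 0
    tol = 1e-9
    for idx in combinations(range(len(ranks)), n_x):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + tol:
            n_le += 1
        if w >= w_obs - tol:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(
    sample_x: Sequence[float],
    sample_y: Sequence[float],
    mode: str = "auto",
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Ties receive midranks.  In ``exact`` mode (default for pooled sizes up
    to 12) the two-sided p is obtained by full enumeration of the rank
    assignments; otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.  Returns
    ``(rank sum of sample_x, p)``.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    w = float(ranks[:n_x].sum())

    if mode == "exact" or (mode == "auto" and n <= EXACT_ENUMERATION_LIMIT):
        return w, _exact_two_sided_p(ranks, n_x, w)

    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    d = w - mu
    z = (d - 0.5 * np.sign(d)) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def compare_pre_post(
    vaping_flags: Sequence[bool],
    dv_per_measurement: Sequence[Sequence[float]],
    *,
    level: str = "particle",
    mode: str = "auto",
) -> ComparisonReport:
    """Compare post- against pre-vaping volume decay rates.

    ``level='particle'`` pools every particle's decay rate by condition;
    ``level='measurement'`` compares the per-measurement mean decay rates
    (one value per measurement).  Raises if either condition is absent.
    """
    if level not in ("particle", "measurement"):
        raise ValueError(f"unknown level {level!r}")
    if len(vaping_flags) != len(dv_per_measurement):
        raise ValueError("one decay-rate set per measurement required")
    pre: List[float] = []
    post: List[float] = []
    for flag, values in zip(vaping_flags, dv_per_measurement):
        vals = [v for v in values if math.isfinite(v)]
        if level == "measurement":
            if not vals:
                continue
            vals = [float(np.mean(vals))]
        (post if flag else pre).extend(vals)
    if not pre or not post:
        raise ValueError("need at least one pre- and one post-vaping measurement")
    w_post, p = wilcoxon_rank_sum(post, pre, mode=mode)
    med_pre, med_post = float(np.median(pre)), float(np.median(post))
    return ComparisonReport(
        n_pre=len(pre),
        n_post=len(post),
        median_pre=med_pre,
        median_post=med_post,
        rank_sum_post=w_post,
        p_value=p,
        post_higher=med_post > med_pre,
    )


def pm10_mass_concentration(dist: SizeDistribution,
                            density_g_cm3: float = 1.1) -> float:
    """PM10 mass concentration (ug/m^3) from a size distribution.

    Bins whose geometric-mean midpoint exceeds 10 um are excluded; each
    remaining bin contributes ``count * (pi/6) d_mid^3 * density`` assuming
    spherical particles, normalized by the sampled air volume.
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    if dist.air_volume_m3 <= 0:
        raise ValueError("sampled air volume must be positive")
    mids = np.sqrt(dist.bin_edges_um[:-1] * dist.bin_edges_um[1:])
    sel = mids <= 10.0
    # mass per particle in ug: (pi/6) d^3 [um^3 = 1e-12 cm^3] * rho [g/cm^3]
    # = (pi/6) d^3 rho * 1e-12 g = (pi/6) d^3 rho * 1e-6 ug
    mass_ug = np.sum(dist.counts[sel] * (math.pi / 6.0) * mids[sel] ** 3
                     * density_g_cm3 * 1e-6)
    return float(mass_ug / dist.air_volume_m3)


def study_truth_decay_rates(
    study: StudyTruth, config: ScenarioConfig
) -> Tuple[List[bool], List[np.ndarray]]:
    """Per-measurement decay rates a noiseless measurement would report.

    Convenience for study-level power and calibration simulations: each
    ground-truth particle is converted to its closed-form volatility result
    without rendering holograms.
    """
    flags, rates = [], []
    for m in study.measurements:
        flags.append(m.vaping_flag)
        rates.append(np.array([
            truth_result(p, config).dv_tau_um3_per_s for p in m.particles
        ]))
    return flags, rates


def summaries_to_frame(summaries: Sequence[MeasurementSummary]) -> pd.DataFrame:
    """One row per measurement with all summary fields."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def plot_study(summaries: Sequence[MeasurementSummary], path=None):
    """Time series of mean decay rate, color-coded by volatile fraction.

    Pre-vaping measurements are drawn as filled markers, post-vaping ones
    as open markers.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = [s.start_min for s in summaries]
    dv = [s.mean_dv_tau for s in summaries]
    pct = [s.pct_volatile_plus_semi for s in summaries]
    pre = [not s.vaping_flag for s in summaries]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(t, dv, ":", color="0.6", zorder=1)
    sc = ax.scatter(t, dv, c=pct, cmap="viridis", vmin=0, vmax=100, zorder=2)
    for ti, di, is_pre in zip(t, dv, pre):
        if is_pre:
            ax.scatter([ti], [di], facecolors="none", edgecolors="k",
                       s=110, zorder=3)
    fig.colorbar(sc, ax=ax, label="% volatile + semi-volatile")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(r"mean $\Delta V_\tau$ ($\mu m^3$/s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
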