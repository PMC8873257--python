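# Methods

This note documents the models, numerical choices and limitations behind
`aerovol`.  The package re-creates, at desk scale, the analysis chain of a
portable lens-free holographic air sampler used to quantify the
volatility of indoor (e.g. exhaled e-cigarette) aerosols: droplets are
deposited on a sticky substrate by an impactor while time-lapse in-line
holograms are recorded, each droplet's volume decay is measured from the
reconstructed phase, an exponential model is fitted, and particles are
classified by volatility.  Because no raw field data are available, a
synthetic-scene generator stands in for the instrument, and every claim
the test suite makes is a claim about this synthetic world.

## Acquisition model and study conditions

One *measurement* records `n_total_frames = 180` frames at 2 fps: a 60 s
sampling window (120 frames) during which droplets may land, plus 30 s of
continued imaging.  The pump draws 13 L/min, so one measurement samples
13 L of air.  Illumination is a 850 nm plane wave; the sensor has a
1.12 µm pixel pitch and 8- or 16-bit quantization with Poisson shot noise
and Gaussian read noise (10 counts RMS at a mean level of 10⁴ counts by
default).  The droplet liquid is modelled with a refractive-index
contrast Δn = 0.4 against air, the typical value for propylene glycol
and vegetable glycerin.

The substrate-to-sensor distance defaults to z = 200 µm.  This is a
desk-scale choice: at 256×256 px the hologram fringes of a droplet must
stay inside the field of view, otherwise the cropped fringe energy is
irrecoverable and iterative phase retrieval saturates well below full
recovery (observed directly when prototyping at z = 400 µm: ~70% of the
phase volume at 400 µm versus ~97% at 200 µm).  The distance is a config
field, not a physical constant of the method.

## Droplet model

Each droplet is a sessile spherical cap with contact angle θ (default
60°) pinned at its initial footprint radius; evaporation scales the cap
height profile uniformly at fixed footprint, which reproduces the
observation that the lateral extent of a drying droplet shrinks much more
slowly than its volume.  The discretized height map is renormalized so
that the pixel sum times pixel area equals the requested volume exactly;
the phase delay is φ = (2π/λ)·Δn·h.

True volumes follow `V(t) = α·e^(−κt) + b` (t in seconds since landing).
Per-class default parameter ranges, chosen once as plausible study
conditions and held fixed:

| class | κ (1/s) | α (µm³) | b (µm³) |
|---|---|---|---|
| volatile | 0.2–0.6 | 1–20 | 0–0.02 |
| semi-volatile | 0.1–0.5 | 1–10 | 0.3–3 |
| non-volatile | 0–0.005 | 0–0.5 | 0.5–5 |

Draws are rejected until the class invariants hold with a 20% guard band
(volatile: residue and end-of-window volume below the 0.1 µm³
full-evaporation threshold, decay rate clearly above the 0.05 µm³/s
non-volatile cut; semi-volatile: plateau above threshold and decay rate
above the cut; non-volatile: decay rate below the cut).  The guard band
keeps generated particles away from the classification boundaries, so
class-recovery statements are about the method, not about coin flips at a
threshold.  Landing times are uniform over the sampling window; positions
are uniform with a minimum pairwise separation (25 µm) and a border
margin of the footprint radius plus 10 px, because droplets too close to
the frame border interact with the propagation crop and shed spurious
detections.

A *study* is a sequence of measurements with gaps drawn uniformly from
5–27 min (mean ~16 min, within the 5–30 min protocol bounds).
Post-vaping measurements shift the class mixture toward volatile
particles (weights `(1+e, 1+e/2, 1)` renormalized) and scale volatile and
semi-volatile κ by `1+e`, where `e` is the effect size; `e = 0` makes
both conditions identically distributed.  Each measurement consumes an
independent child stream of the scenario seed (`numpy` `SeedSequence`
spawning), so any measurement can be regenerated in isolation.

## Optics

Forward rendering and reconstruction use the angular-spectrum method with
the transfer function `exp(i·2π·d·sqrt(1/λ² − f²))`, evanescent
components zeroed, and 50% zero-padding per side against wrap-around.
Fields whose background is a unit plane wave are handled by propagating
the compactly supported *scattered* component (field − 1) and adding the
analytically propagated plane wave: zero-padding the background itself
would turn the frame edge into a hard aperture.

Reconstruction normalizes the measured intensity by a median-filtered
background estimate (block-average ×4, median window 31 on the reduced
grid — wide compared with any fringe period), takes the square root as
the sensor amplitude, back-propagates, and removes the global phase so
the background phase is zero.  Plain back-propagation of an intensity
hologram splits a weak phase object evenly between the in-focus image and
the defocused twin, so measured phase volumes come out at ~50% — a purely
multiplicative bias that cancels in κ.  Optional refinement runs 20
alternating projections between (a) the sensor constraint (measured
amplitude, retrieved phase) and (b) the object constraint: unit
transmission outside the detected support, unit amplitude with
*non-negative unwrapped phase* inside it.  Two properties of this
constraint matter:

* the non-negativity must be imposed on the unwrapped phase — clipping
  the wrapped angle destroys droplets whose delay exceeds π;
* without the non-negativity pin, smooth phase offsets accumulate inside
  wide supports, because the phase transfer function of in-line intensity
  (∝ sin(πλz f²)) vanishes at low spatial frequency; for the same reason
  supports are kept per frame and tight.  The returned refined frame is
  the object-constrained estimate, so residual twin ripple outside the
  support cannot leak into downstream phase integrals.

Autofocus maximizes the Shannon entropy of the normalized amplitude of
the back-propagated field over a z grid, followed by golden-section
refinement to 1 µm.  For phase objects the amplitude is *flattest* — i.e.
its entropy is maximal — at focus; a flat criterion (spread < 10⁻⁸ nats)
flags the frame as unfocusable.  The criterion is scale-invariant by
construction.

Phase unwrapping inside ROIs uses reliability-guided unwrapping
(scikit-image), per connected component, anchored so the median phase on
the ROI boundary lies in (−π, π].

## Detection, tracking, volumetry

Detection thresholds both channels at 5σ above the frame mean (amplitude
as deviation from unity background, phase as magnitude), unions the
masks, labels 8-connected components, drops components under 4 px,
dilates survivors by 2 px into ROIs, and discards *satellites* —
components whose centroid lies within 12 px of a larger component's
centroid, which in practice are twin-image ring fragments of strong
scatterers.  Tracking is greedy nearest-centroid association within 5 px,
ties broken deterministically; tracks never merge.

Volumetry unwraps the phase inside each ROI, computes the inner mask
(values ≥ mean + 1 population σ) over the ROI's bounding-box patch padded
by 8 px, clips negative phase to zero and integrates.  The 8 px pad is
load-bearing: the statistics patch must be background-dominated so the
one-σ cut separates droplet from background; with a thin pad the cut
lands inside the droplet's own flank and trims up to ~35% of a spherical
cap's volume (area-weighted height distribution of the cap profile),
which was confirmed numerically before fixing the default.  Because
droplets are substrate-pinned, measurement continues through the end of
the record using the last known ROI even after the droplet falls below
the detection threshold; this records the full evaporation tail, without
which volatile particles could never be observed below the 0.1 µm³
full-evaporation threshold.  Frames from the first sub-threshold volume
onward are flagged `below_floor` and excluded from fitting.

## Decay fitting and classification

`V(t) = α·e^(−κt) + b` is fitted by bounded trust-region least squares
(α ≥ 0, κ ∈ [0, 10] s⁻¹ — a droplet with τ = 0.1 s evaporates between
frames at 2 fps and is unobservable — b ≥ 0), initialized with
b₀ = min V, α₀ = V(t₀) − b₀ and κ₀ from a log-linear slope; parameter
tolerance 10⁻⁸, at most 500 iterations' worth of evaluations.  If the
fitted α is numerically zero the trajectory carries no decay information
and κ is reported as 0.  R² is computed on the fitted frames; a constant
trajectory with zero residual reports R² = 1.

Classification applies, in order: non-volatile if ΔV_τ = V(t₀)·κ <
0.05 µm³/s; volatile if the last observed volume is below 0.1 µm³ *and*
R² ≥ 0.9 ("smooth exponential decay" operationalized as a fit-quality
threshold, since no formula exists for it); semi-volatile otherwise.
Unconverged fits fall back to the raw empirical rate and can only be non-
or semi-volatile, since smoothness cannot be established.  An optional
screen flags as semi-volatile any particle whose decay rate lies within
mean ± 2σ of the volatile population's rates but which did not fully
evaporate; it is exposed as a utility, not wired into the default rule.

## Study statistics

Per-measurement summaries report the arithmetic mean of finite decay
rates, the three class percentages (always summing to 100) and the
sampled air volume.  The pre/post comparison pools decay rates by
condition — at the particle level by default, with a per-measurement-mean
alternative, since the original unit of analysis is ambiguous — and runs
a two-sided Wilcoxon rank-sum test: midranks for ties; exact p by full
enumeration of rank assignments when the pooled size is ≤ 12; otherwise a
normal approximation with tie-corrected variance and continuity
correction.  PM10 mass concentration sums, over bins whose
geometric-mean midpoint is ≤ 10 µm, count × (π/6)·d³·ρ with ρ =
1.1 g/cm³, normalized by the sampled air volume.

## What the synthetic world does and does not show

The generator reproduces the *structure* of the field experiment — the
acquisition protocol, droplet decay law, class mixture, measurement
timing, pre/post contrast — with sizes chosen for a single CPU: 256² px
fields with tens of droplets for imaging runs (against the real sensor's
multi-megapixel field with hundreds to thousands of particles), and
wide-field, non-rendered ground-truth populations for study-level
statistics.  It does not model substrate deformation, droplet
coagulation, humidity/temperature coupling, illumination aberrations or
partial coherence, and its droplets are ideal phase objects.  Passing
tests therefore demonstrate that the *algorithms* recover known truth
under the stated physics, not that the instrument performs identically on
real vape-shop air.

Two quantitative regimes must be kept apart:

* **Resolvable regime** — peak phase delay below ~π on the reconstruction
  grid.  Here forward/inverse volumetry is validated end to end: 50
  random weak-phase droplets (peak φ ≤ π/2, realised with a
  reduced-contrast Δn = 0.1 scenario so the droplets span several
  pixels) reconstruct within 10% of truth, and full scenes classify
  correctly.
* **Aliased regime** — at the native 1.12 µm pitch and Δn = 0.4, droplets
  above ~6 µm³ have phase gradients beyond π per pixel; no unwrapping can
  recover them, volumes are distorted, and only κ-level statements
  survive.  The field instrument used pixel super-resolution (a finer
  reconstruction grid) for exactly this reason; users can emulate that by
  lowering `pixel_pitch_um`.

Study-level calibration and power results (type-I error of the rank-sum
test within its binomial interval; ≥95% detection of a 50% post-vaping κ
shift with 200 particles per stratum) are computed on closed-form truth
volatility results, which is what they are claims about: the statistical
machinery, not the imaging chain.
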