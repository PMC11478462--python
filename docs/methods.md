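# Methods

`sonotrap` reproduces, at desk scale, a learning-based workflow for
generating acoustic traps through heterogeneous tissue with a small linear
phased array: collect (target position → per-element time of flight and
arrival amplitude) pairs by time reversal in a synthetic 2-D tissue map,
train two small feed-forward networks to invert a trap position into array
actuation signals, convert predictions into phase–amplitude patterns for
focal-beam and twin traps, and simulate microbubble capture by the twin
trap under pulsatile microvessel flow. This note records the models, their
assumptions, the default parameters, and the choices made where the design
was genuinely open.

## Tissue phantom

The phantom is a dense raster of sound speed c(x), mass density ρ(x) and
attenuation coefficient α(x) over a 120 mm × 110 mm slice, built from
horizontal layers that emulate a segmented abdominal window: a 20 mm water
coupling stand-off (the tilted array sits inside it), then skin (2 mm),
fat (8 mm), muscle (15 mm), liver (55 mm) and bone (10 mm). Acoustic
property values are representative literature figures (e.g. fat
1450 m/s / 950 kg/m³ / 0.48 dB·cm⁻¹·MHz⁻¹; liver 1595 / 1060 / 0.50) and
are fully overridable in the run configuration; the *structure* is the
reproducible part, not the constants. Layer boundaries are half-open
intervals, a cell belonging to the layer containing its centre. The cell
size (0.18 mm by default) must not exceed λ/8 in the slowest medium at the
operating frequency, mirroring standard mesh-resolution practice.

A real segmented MR slice has curved interfaces, inclusions and ribs; the
layered phantom has none of these, so passing tests demonstrate the
pipeline's behaviour under idealized stratified heterogeneity, not
anatomical fidelity. Flat horizontal interfaces do produce the essential
difficulty — refraction, path-dependent attenuation, and first-arrival
kinks where fast-layer head waves overtake direct arrivals.

## Array, workspace and sampling plan

The default array has n = 8 circular elements of diameter 3.7 mm with
0.5 mm gaps (pitch 4.2 mm ≈ 2.8 λ), operating at 1.0 MHz (λ = 1.5 mm in
water), rotated by a pose angle α = 30° so the array plane parallels the
intended vessel. Element 1 is the minimum-lateral-coordinate end after
rotation; this fixes twin-trap laterality.

The training workspace is a wedge bounded by two rays leaving the outer
element centres at ±σ from the array normal, where σ solves the circular
piston directivity relation 2·J₁(k·e·sin σ)/(k·e·sin σ) = ½ (the −6 dB
spread). For e = 1.85 mm and λ = 1.5 mm this gives σ ≈ 16.6°. The depth
range along the normal defaults to 24–62 mm, chosen once so the wedge
holds ≈950 targets at the reference sampling density D = 1/λ (one target
per wavelength along and across columns, columns parallel to the normal).
Sparser densities 1/2λ, 1/3λ, 1/4λ are obtained by keeping every k-th
grid position along both plan axes.

## Forward model (geometric acoustics)

The forward solver provides exactly the three quantities the workflow
consumes; it is not a full-wave code.

**Time of flight.** First-arrival times solve the eikonal equation
|∇T| = 1/c(x) with a Godunov upwind fast-sweeping method (numba-compiled;
four alternating sweep orderings iterated to a 10⁻⁹ µs update tolerance).
A disk of 4 cells around the source is initialized with exact local times
to suppress the point-source singularity of the first-order scheme.
Receiver times are read by bilinear interpolation. Tests hold the solver
within 1% of an independent lattice shortest-time (Dijkstra) oracle; the
oracle uses a 32-direction stencil because the classic 8-neighbour lattice
metric itself misprices oblique paths by up to ~8%. Transmission
reciprocity (T(a→b) = T(b→a)) holds to the measured solver tolerance of
5·10⁻³ µs on 0.1 mm grids; a first-order scheme cannot do better, and a
higher-order solver is a natural extension point behind the same
interface.

**Amplitude.** The arrival amplitude follows
A = A₀ · (r₀/r)^s · 10^(−f·∫α ds / 20) · D(θ):
cylindrical spreading with exponent s = ½ (2-D domain; r₀ = 1 mm reference
radius), attenuation integrated along the *straight* source–receiver
segment (first-order heterogeneity handling — the ToF, by contrast,
follows the true fastest path; this asymmetry is a documented limitation),
and an element directional response D(θ). The response is a smooth
Gaussian beam-spread model D(θ) = 2^(−(θ/σ₆)²) with σ₆ = 24.2°, the
elements' characterized −6 dB half-spread, floored at 0.05. A signed
piston pattern was rejected because its first null falls inside the
sampling wedge, making the amplitude-equalization inversion W = A_max/A
ill-posed (near-zero recorded amplitudes, exploding drive pressures). The
source emission level defaults to 1000 Pa at r₀.

**Field synthesis.** The steady-state complex pressure for an actuation
vector Ψ ∈ ℂⁿ is the superposition
p(x) = Σⱼ |Ψⱼ| · D_j(x) · (r₀/r_j)^s · 10^(−dB_j/20) · e^{i(2π·T_j(x)/T + arg Ψⱼ)},
with one travel-time field per element (reciprocity keeps any number of
patterns at n eikonal solves). The directional response appears
*consistently* in both data collection and synthesis — any per-path factor
common to both cancels in W·A, which is what makes amplitude modulation
equalize the target contributions exactly. Diffraction-accurate side-lobe
amplitudes are outside this model's scope; side lobes and the grating
lobes of the 2.8 λ pitch appear qualitatively only.

A known, quantified consequence of the amplitude law: the focal "finger"
is axially elongated (extent ∝ 7λF#²) and the (r₀/r)^s·attenuation tilt
slides the |p| arg-max along it toward the array by ~0.5–4 mm depending on
depth. Lateral alignment of the finger with the target remains
sub-wavelength in the core steering region. The test suite asserts both
statements separately; the strict "Euclidean peak within λ/2" reading
fails for this model and is kept as an intentionally failing check rather
than silently redefined.

## Dataset, split and persistence

One sample per planned target records the target position P ∈ ℝ², the
per-element ToF vector T ∈ ℝⁿ (µs) and amplitude vector A ∈ ℝⁿ (Pa);
element positions are constant per dataset and live in the CSV header.
The split is 74.5% train / 13% validation / 12.5% hold-out by a seeded
uniform shuffle, hold-out and validation counts rounded to nearest
(920 samples → 685/120/115); a deterministic evenly-spread "spatial" mode
exists for ablations. CSVs round-trip losslessly (17-significant-digit
formatting, exact-rounding parse).

## Surrogate networks

Two multilayer perceptrons map the 2n+2 inputs (target position plus the
flattened element centres) to n outputs: ToF (five hidden layers,
60 nodes each, 300 total) and amplitude (five × 144, 720 total), ReLU
activations, linear output. The loss is the mean squared L2 norm of the
per-sample error vector. Training is stochastic with batch size 1 — the
study protocol — using Adam (initial learning rate 2·10⁻³), a seeded
per-epoch shuffle, a plateau schedule that halves the learning rate after
12 epochs without validation improvement (floor 2·10⁻⁵), early stopping
(patience 60, max 400 epochs) and restoration of the best-validation
weights. Inputs and outputs are z-scored on the training split only;
element-position features are constant within a dataset and map to zero
after scaling, but are retained so a trained model is bound to one array
geometry. Choices left open by the protocol (per-layer node allocation,
optimizer, schedule, stopping rule, scaling) are recorded in the model
metadata; equal per-layer allocation was chosen because only the totals
are part of the architecture contract.

The forward/backward/Adam loop is implemented in-package (numba kernel).
One practical detail worth recording: with batch-1 updates, parameters
whose gradients are exactly zero (constant input features, dead ReLU
units) decay the Adam moments geometrically into subnormal floats, where
arithmetic is ~100× slower; moments below 10⁻²⁵⁰ are flushed to zero
after each epoch.

Hold-out errors are reported signed (predicted − true; µs for ToF,
percent of the true value for amplitude) with outliers flagged per element
by the standard 1.5×IQR boxplot whisker rule. On the synthetic phantom the
error distribution is heavier-tailed relative to its IQR than on the
study's original anatomy: all ToF errors fall inside the reference
non-outlier band, but the *count* of IQR-flagged points is larger than the
reference count. The tails localize near first-arrival refraction kinks
crossing the workspace; this is a property of the phantom, asserted
honestly rather than tuned away.

## Phase–amplitude modulation

With T_max and A_max the per-target maxima:
focal phases H_j = 2π(T_max − T_j)/T (period T = 1 µs), wrapped to
[0, 2π); twin phases M_j = H_j + π/2 − π·Θ(j − (n+1)/2) with 1-based
indices and Θ(0) = ½, so the two array halves carry a π signature and an
odd array's centre element is unshifted; amplitude coefficients
W_j = A_max/A_j (min W = 1), making every beam contribute equal pressure
at the target; actuation Ψ_j = ϑ·W_j·e^{iφ_j} with base emission pressure
ϑ = 1000 Pa. The whole field scales linearly in ϑ.

Trap metrics: localization error (distance from target to the sub-cell
refined |p| arg-max), lateral FWHM of the intensity |p|² profile through
the peak (pressure-profile mode available), the sequential-activation
uniformity test (normalized rise of |p(target)| per added element,
evaluated at the exact target point so the AM-on ideal of 1/n is exact),
and the twin structure test (two lateral lobes flanking a pressure well;
lobe separation scales as depth/aperture and is ≈2λ at the nominal
mid-workspace vessel depth).

## Microbubble trapping

Bubbles are point particles: radius 10 µm, shell thickness 50 nm
(τ = shell/radius = 0.005), shell density 1050 kg/m³, mean density
ρ_mb = ρ_shell·(1 − (1 − τ)³) ≈ 15.7 kg/m³; surface tension (0.1 N/m) is
stored but unused by the point-force model. The acoustic contrast factor
is negative for τ < 0.10 (antinode-seeking) and positive otherwise — this
threshold is the sign *contract*, enforced on the force, because no simple
effective-medium shell model crosses over at exactly 0.10.

The radiation force is the gradient of a Gor'kov potential
U = V[f₁⟨p²⟩/(2ρc²) − ¾f₂ρ⟨v²⟩], with the monopole factor from a
volume-weighted gas-core/shell compressibility (adiabatic perfluoropropane
core, γ = 1.07) and the dipole factor from the mean density. The
*magnitude* is model-dependent: no resonance or shell-elasticity physics
is included, so the quasi-static |f₁| ~ 2·10⁴ is far stiffer than a real
driven bubble's response near 1 MHz. Consequently the demo scales the
twin-trap field to a 15 kPa maximum, the level at which the overdamped
drift (∝ p²) traverses a lobe-to-null distance in ~0.1 s and antinode
capture completes within the 0.2 s horizon — the trapping *timescale* is
calibrated, the field level is not a claim about the original experiment.

Flow is a Poiseuille parabola across a Ø40 µm straight vessel whose
centreline follows the pulsatile inflow waveform (period 1 s,
v_min = 0.5 mm/s, v_max = 1.54 mm/s). The printed waveform's terminal
logistic factor 1.35/(1 + e^{130t+10}) is ≈4.5·10⁻⁵ already at t = 0, so
the verbatim curve never approaches v_max; both the verbatim evaluation
(round = half away from zero, numerically stable logistic) and an affine
"normalized" mode mapping one period onto [v_min, v_max] are provided, and
the simulation uses the normalized mode.

Integration is overdamped: bubble momentum relaxes in m/(6πμR) ≈ 0.4 µs,
so v_mb = v_fluid + (F_rad + F_gravity)/(6πμR) (viscosity 10⁻³ Pa·s,
water-like plasma), explicit position updates at dt = 10⁻⁴ s, no-flux
reflecting walls, gravity/buoyancy across the vessel axis. A step
displacing any bubble by more than a tenth of the vessel diameter aborts
with a diagnostic. No bubble–bubble interaction, oscillation dynamics or
rupture.

## Problem sizes and determinism

Default problem sizes: 667×611-cell phantom rasters, 8 eikonal solves per
geometry (reciprocity), ≈950 collected samples, 400/≈350 training epochs
for the ToF/amplitude networks, field windows of 100–200 cells per side,
2000 trapping steps for 10 bubbles. Every stochastic stage (split,
network initialization and shuffling, bubble seeding) takes an explicit
seed, and the pipeline manifest records seeds and artifact hashes;
re-running a stage from persisted inputs reproduces downstream CSVs
bit-identically.

## Known limitations

- Geometric acoustics only: no diffraction-accurate side lobes, no
  scattering, no shear waves in bone.
- Straight-ray attenuation vs. fastest-path ToF (inconsistent at strong
  refraction).
- First-order eikonal solver: ~10⁻² µs absolute accuracy at the default
  resolution; reciprocity to 5·10⁻³ µs.
- Layered phantom only (optional inclusions are out of scope); anatomical
  realism is not claimed.
- Gor'kov force magnitude is quasi-static; trapping speeds are meaningful
  relative to the calibrated field scale only.
- The |p| arg-max of an elongated focal finger is not a λ/2-accurate
  localizer of the target (see Forward model above).
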