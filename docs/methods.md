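# Methods

Units throughout: lengths in Å, times in ns, rates in ns⁻¹, rotational
diffusion in rad²/ns. The experiment schedule alone (bursts per second,
total duration) is in seconds.

## Model chain

### Linker mechanics

A dye tether of N C–C links is treated as N identical springs in series,
k_eff = k/N, and each C–C–C unit contributes a projected length
L = (l/2)√(2 − 2cos θ) with l = 1.54 Å and θ = 109.5°, giving L ≈ 1.26 Å and
a contour reach of ≈ 18.9 Å for the default N = 15. The single-bond spring
constant is kept as a configuration value (default 1010, in the caller's
units); all downstream dynamics are parameterized by relaxation *rates*, so
no absolute stiffness unit is consumed anywhere.

### Translational dye models

*Springs.* The dye position follows an Ornstein–Uhlenbeck process
dX = −K(X − X_eq)dt + σ dB with diagonal K. Because the noise coefficient is
constant, the Stratonovich and Itô readings coincide and the process is
propagated with its exact Gaussian transition kernel (mean decay e^(−k·dt),
variance (σ²/2k)(1 − e^(−2k·dt))) — no time-discretization error for any
step length. The stationary per-axis variance is σ²/(2k).

The isotropic default uses a per-axis stationary sd of 4.7 Å (3σ ≈ 14 Å,
slightly inside the 19 Å contour reach), an accessible volume of the size
molecular-dynamics accessible-volume calculations produce. The literal
linker-chemistry stiffness would give a sub-Ångström cloud in which every
translational effect collapses to shot noise; the volatility is therefore an
accessible-volume-matched default, not a chemistry-derived one.

The anisotropic configuration keeps the accessible *volume* of the isotropic
cloud (determinant of the stationary covariance preserved) while making the
soft/stiff variance ratio 1/p (default p = 0.1) with the stiff axis along
the inter-dye axis for both dyes. This isolates the lateral accessible
volume: motion along the detection axis is suppressed, and the measured
shift collapses toward the shot-noise floor. (With soft planes placed
mutually orthogonal, one dye is soft along the detection axis and the
anisotropic shift can never fall below the isotropic one — that geometry
contradicts the reported ordering of the configurations, which is why this
package's default is the volume-preserving, stiff-axial one.)

*Elastic pendulum.* In spherical coordinates (r, θ, φ) about the attachment
point,

    dr = [−k_r(r − r_eq) + c_r/r] dt + σ_r ∘dB,
    dθ = [−k_θ sin θ + σ_θ²/(2r² tan θ)] dt + (σ_θ/r) ∘dB,
    dφ = (σ_φ/(r sin θ)) ∘dB.

The radial line is integrated with a Stratonovich–Heun predictor–corrector;
a step that would drive r ≤ 0 is re-taken as two half steps. The angular
pair is advanced coordinate-free: a tangent-plane diffusion step (per-axis
volatilities σ_θ/r and σ_φ/r) composed, by Strang splitting, with the exact
flow of the restoring ODE θ' = −k_θ sin θ (tan(θ/2) → tan(θ/2)e^(−k_θ t)).
The geodesic step generates the metric (cot θ) drift exactly and has no pole
singularity; for σ_θ = σ_φ it is the same diffusion as the coordinate form.
Direct Heun integration of the θ-equation is unstable near the pole (the
cot θ drift evaluated at an overshooting predictor ejects trajectories) and
visibly corrupts the stationary law at usable step sizes, which is why the
split integrator is the production path. The simulated θ-marginal matches
the analytic stationary density sin θ^(σ_φ²/σ_θ²) · e^(β cos θ),
β = 2k_θ r²/σ_θ², to KS precision at the default step (0.1 ns).

The c_r/r radial term is kept with a configurable coefficient c_r
(default 1, the literal reading; c_r = σ_r² is the noise-induced-drift
alternative). Its rest radius is the positive root of
k_r r² − k_r r_eq r − c_r = 0.

Pendulum defaults: k_r = 0.2, r_eq = 18 (≈ contour reach), σ_r = 0.6,
k_θ = 0.02, σ_θ = 0.6, σ_φ = 16. The angular anisotropy encodes the
chemistry of the tether: dihedral (azimuthal) rotation about single bonds is
nearly free while bond-angle (polar) bending is stiff. The swing then lives
on a narrow ring nearly perpendicular to the arm, and the *relative azimuth*
of the two dyes — arms on the same side vs. opposite sides of the inter-dye
axis — makes the inter-dye distance distribution bimodal (dip test
significant). That bimodality is the two-state-like mixing that gives the
pendulum its translational dynamic shift; with isotropic angular
volatilities no parameter setting we scanned produces it.

### Orientational dynamics

Each transition dipole performs spherical Brownian motion with diffusion
coefficient D (optionally derived as kT/(8πνR_h³)). Production propagation
uses geodesic tangent-plane steps with sub-stepping capped at angular
variance 0.02 rad² per step, an exact uniform draw once 2·D·t ≥ 15 (the ℓ=1
relaxation factor e^(−2Dt) < 3·10⁻⁷), and renormalization after every step;
the angle-coordinate form (drift (σ²/2)cot θ, noise σ, azimuthal σ/sin θ)
is also implemented and both leave the uniform law invariant in tests.

Rotational regimes are declared relative to the translational diffusion
scale of the default pendulum dye, σ_r²/2 = 0.0018 nm²/ns: "slow" is one
order of magnitude above it (0.018 rad²/ns) and "fast" three (1.8 rad²/ns).
The dynamic-κ configuration uses slow–slow: dipole reorientation
(τ ≈ 28 ns) is slow on the excited-state dwell (≈ 2–4 ns), the regime in
which path-to-path κ² heterogeneity is maximal.

### Photophysics

An excitation event is the four-state chain {D, A, FD, FA}: D exits to FD
(rate k_D) or to A (rate k_ET(t)); A exits to FA (rate k_A); FD/FA absorb.
With dipoles rotating during the dwell the exit hazard is time-dependent and
events are sampled by Lewis–Shedler thinning with the rigorous bound
k_D(1 + 4C/r⁶) from κ² ≤ 4 — exact, with no path-grid bias; an
integrated-hazard inversion sampler on a fine grid is kept purely as the
test oracle. The inter-dye distance is frozen over one dwell (translational
relaxation ≥ 5 ns vs. dwell ≈ 2–4 ns, and the error vanishes with the
separation of those scales); dipoles are drawn from their uniform
equilibrium at each excitation and evolve during the dwell. r = 0 collapses
the chain to A → FA with rate k_A.

Defaults: k_D = 0.25 (τ_D(0) = 4 ns), k_A = 0.5, reference Förster radius
R0 = (2C/3)^(1/6) = 40 Å. R0 = 40 Å is a standard mid-range value for
organic dye pairs; relative to the chemistry-fixed 18–19 Å linker reach it
places the dye cloud's distance spread in the regime where translational
mixing is visible on the efficiency scale, which is the regime the
four-configuration comparison describes.

### Experiment

Pulsed excitation every 50 ns, 1-ms bursts (20 000 pulses), one burst per
second for 7 h in the scheduled experiment (25 200 bursts). Detection is a
per-channel Bernoulli thinning, default efficiency 0.005 (≈ 100 detected
photons per burst, a typical smFRET burst size). For equal channel
efficiencies detection is independent of photon color, so pulses are thinned
*before* their outcome is simulated; unequal efficiencies are rejected
rather than silently approximated. Bursts with fewer than 10 photons or no
donor photon are flagged unusable. Each burst is a fresh molecule
(translational state redrawn from the stationary law); within a burst the
state persists between events. Because gaps between detected events are
always ≥ one pulse period, and the period (50 ns) covers ≥ 10 relaxation
times of every pendulum coordinate, pendulum states at successive detected
events are stationary-decorrelated; the engine then draws them from a
pre-equilibrated stationary pool (a documented fast path, checked against
explicit gap propagation by KS on the resulting burst coordinates). Spring
models always use the exact OU transition over the true gap.

### Shift statistics

Two variants of the signed distance to ℰ + τ = 1 are computed: the printed
form with denominator √(ℰ² + τ²) (default, undefined at the origin) and the
geometric perpendicular distance with denominator √2. Both are zero exactly
on the line and positive above it; they are reported side by side because
the printed form's corner values (±1/√2 at (1,1)) differ from the ±1/2
sometimes quoted for it, and no reading reproduces both.

The moment-difference view projects (ℰ_I, ℰ_τ(1 − ℰ_τ)) onto the parabola
y = x(1 − x) by bounded 1-D minimization of the squared distance along the
curve parameter (tolerance 1e−10), signed negative below the curve.

The two-state reference simulates a symmetric telegraph process between two
efficiencies at exchange rate λ, resolved exactly at pulse times. Its mixing
arc has the closed form ℰ(τ) = 1 − τ₁τ₂/(τ₁ + τ₂ − τ), τᵢ = 1 − ℰᵢ, which
is *exact* for any within-burst occupancy f: with u = fτ₁ + (1−f)τ₂ = 1 − ℰ
and v = fτ₁² + (1−f)τ₂² = τu, the identity u(τ₁+τ₂) − v = τ₁τ₂ holds
algebraically. The simulation is still used as the ground-truth check.

A useful identity behind all of this (used to choose operating points, and
a good sanity check on any implementation): for a burst mixing independent
events with per-event transfer probability E, the expected burst coordinate
satisfies τ̄ = (1 − Ē) + Var(E)/(1 − Ē), so the structural shift numerator
is exactly Var(E)/(1 − Ē) — the dynamic shift *is* the variance of the
per-event efficiency, made visible by the lifetime channel.

### Dip statistic

Bimodality is assessed with a from-scratch Hartigan-style dip statistic: the
smallest sup-norm distance between the sample ECDF and any *atomless*
unimodal CDF, computed by bisection on the band half-width with an exact
convex/concave feasibility sweep (a forward and a backward pass propagate
the convex piecewise-linear "minimal arrival slope" function through the
ECDF band; unimodal feasibility holds iff the convex-side and concave-side
feasible value intervals overlap at some node). The implementation is
validated against a brute-force linear-programming oracle over all mode
positions (agreement to 5e−5 across uniform, normal, bimodal and tied
samples). Because the class excludes atoms the statistic can exceed the
classical dip by O(1/n) for continuous data; p-values are calibrated by
Monte Carlo against the *same* statistic under the uniform null, so the
test is exact as a test. Frozen null tables (999 draws each, seeds recorded
in the module) are shipped for subsample sizes 200, 500 and 1000; larger
samples are subsampled reproducibly.

## Default study conditions (frozen)

| parameter | value | why |
|---|---|---|
| k_D, k_A | 0.25, 0.5 ns⁻¹ | typical donor/acceptor lifetimes (4 ns, 2 ns) |
| R0 | 40 Å | mid-range organic-dye pair; sets linker-reach/R0 ≈ 0.47 |
| spring sd | 4.7 Å/axis | MD-like accessible volume, 3σ ≲ contour reach |
| spring rate | 0.2 ns⁻¹ | diffusive linker relaxation ≈ 5 ns |
| anisotropy p | 0.1 | strong stiff-axial anisotropy at equal volume |
| pendulum | k_r=0.2, r_eq=18, σ_r=0.6, k_θ=0.02, σ_θ=0.6, σ_φ=16 | ring-swing regime; bimodal inter-dye distance |
| rotation (dynamic κ) | 0.018 rad²/ns per dye | slow regime, 10× translational scale |
| attachment separation | calibrated | mean per-event transfer probability = 0.5 |
| pulse period / burst | 50 ns / 1 ms | time-resolved lifetime readout |
| detection | 0.005/channel | ≈ 100 photons/burst |

The separation calibration draws one stationary ensemble (fixed internal
seed 20240612) and bisects the attachment separation until the ensemble-mean
transfer probability — with a frozen orientational draw per member for
dynamic-κ models — equals 0.5, the mid-range operating point at which an
experimenter would run such a construct and at which the shift statistics
are most visible. For static-κ models this essentially coincides with
"static efficiency 0.5 at the mean distance".

Simulation sizes: the four-configuration comparison uses 2000 bursts per
configuration (the scheduled experiment would give 25 200); at ≈ 100
photons/burst the standard error of a mean shift is ≈ 0.003, an order of
magnitude below the differences of interest.

## What the generator does and does not emulate

Emulated: pulsed excitation with exponential(-mixture) delays, photon-color
competition, per-burst estimator noise at realistic photon counts, dye
translational and orientational stochasticity with their timescale
separation, scheduled 1-ms bursts.

Not emulated: diffusion through the confocal volume (burst durations and
sizes are fixed, not distributed), background photons, detector artifacts
(dead time, afterpulsing, IRF), photobleaching/triplet states, spectral
crosstalk, direct acceptor excitation, and any biomolecule conformational
dynamics. Passing tests therefore demonstrate properties of the dye-motion
mechanism in isolation, not of a complete instrument model; in particular
per-burst shift *spreads* are shot-noise dominated here, whereas real burst
ensembles add burst-size and background variability.

## Known limitations

* The per-burst shift spread of the dynamic-κ configuration (≈ 0.12) is
  essentially the same as the static configurations' at equal photon
  counts: with detected events ≈ 2.5 µs apart and every model correlation
  time ≤ 30 ns, events within a burst are independent, so κ² heterogeneity
  averages out of the burst variance. A strong spread *contrast* between
  static and dynamic rows would require κ² correlations on the millisecond
  burst scale, which ns-scale rotational diffusion with per-excitation
  equilibrium initialization cannot produce.
* Per-path mean-κ² distributions are right-skewed and unimodal in every
  rotation regime we scanned (dip test); their principal mode sits below
  2/3 while the mean is 2/3.
* Translational–orientational coupling (a full rigid-body state on SE(3))
  and non-spherical inertia tensors are out of scope; the overdamped
  spherical reduction is used throughout.
* The exact-thinning path freezes r during a dwell; for constructs whose
  translational relaxation approaches the excited-state lifetime this
  approximation would need revisiting.
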