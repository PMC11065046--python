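# fretshift

Stochastic simulation of time-resolved confocal single-molecule FRET
(smFRET) experiments in which the motion of the fluorescent dyes themselves
— not the labeled biomolecule — generates a *dynamic shift* of the joint
FRET-efficiency / fluorescence-lifetime distribution, together with the
signed-distance statistics that quantify it.

## The problem

In smFRET, a donor and an acceptor dye report the distance r between two
attachment points through the energy-transfer rate

    k_ET(t) = k_D · (R0(t) / r)^6,        R0^6(t) = C · κ²(t),

where k_D is the donor de-excitation rate and κ² ∈ [0, 4] is the mutual
orientation factor of the two transition dipoles,

    κ = μ̂_D·μ̂_A − 3 (r̂·μ̂_D)(r̂·μ̂_A).

A static system obeys ℰ = 1 − τ in the plane of intensity-based efficiency
ℰ_I = I_A/(I_A+I_D) and normalized donor lifetime τ = τ_D(A)/τ_D(0); any
mixing of transfer rates *within* a burst lifts the burst's coordinate above
that line (Jensen's inequality: the mean of 1/K exceeds 1/mean K). The
per-burst signed distance to the line,

    Δ(ℰ, τ) = (ℰ + τ − 1) / √(ℰ² + τ²),

is the dynamic shift. Experimentally dye motion alone contributes μ(Δ) ≈ 0.2,
and attributing it correctly matters whenever the shift is used to infer
biomolecular conformational dynamics.

The package simulates the full chain from first-principles dye models to
burst statistics:

* **Linker chemistry** — N C–C links as springs in series (k_eff = k/N) with
  the tetrahedral link length from the law of cosines.
* **Translational dynamics** — isotropic/anisotropic Ornstein–Uhlenbeck
  springs (exact Gaussian transitions) or an elastic pendulum in spherical
  coordinates (Stratonovich–Heun radial step, coordinate-free angular step).
* **Orientational dynamics** — spherical Brownian motion of each dipole,
  D = kT/(8πνR_h³), uniform stationary law.
* **Photophysics** — the four-state chain {D, A, FD, FA}; with rotating
  dipoles the donor-exit hazard k_D + k_ET(t) is time-inhomogeneous and
  excitation events are sampled by exact Lewis–Shedler thinning (κ² ≤ 4
  bound), never by grid discretization.
* **Experiment** — pulsed excitation (50 ns), 1-ms bursts, per-channel
  detection thinning, per-burst (ℰ_I, τ) coordinates.
* **Analysis** — dynamic-shift distributions, the moment-difference shift
  against the parabola y = x(1−x), Jensen lifetime bounds, a two-state
  mixing reference with its closed-form arc, κ²-path statistics, and a
  from-scratch Hartigan-style dip test for bimodality.

## Worked example

```python
from fretshift import BurstConfig, PhotophysicsParams, run_experiment, table1_model
from fretshift.shift import ShiftConfig, shift_distribution

model = table1_model("pendulum-dynamic")   # elastic pendulum, dynamic kappa
photo = PhotophysicsParams()               # k_D=0.25/ns, k_A=0.5/ns, R0=40 A
result = run_experiment(model, photo, BurstConfig(), n_bursts=2000, seed=1)
shift = shift_distribution(result, ShiftConfig("printed"))
print(f"mu(Delta) = {shift.mean:.3f}, sigma(Delta) = {shift.std:.3f}, "
      f"n = {shift.n_bursts}")
```

prints

```
mu(Delta) = 0.165, sigma(Delta) = 0.117, n = 2000
```

i.e. 2000 one-millisecond bursts of the dynamic-κ elastic-pendulum dye pair
carry a mean dynamic shift of 0.16 with a per-burst spread of 0.12 — the
dye-motion signature, with no biomolecule dynamics in the model at all.

The same comparison across all four dye configurations:

```
$ fretshift reproduce-table1 --bursts 2000 --seed 1
           model variant    mu sigma  n_bursts   mean_E  mean_tau
       isotropic printed 0.100 0.124      2000 0.499736  0.587427
     anisotropic printed 0.033 0.125      2000 0.498219  0.534519
 pendulum-static printed 0.096 0.124      2000 0.497654  0.585859
pendulum-dynamic printed 0.162 0.116      2000 0.550920  0.588899
```

The anisotropic spring (stiff along the inter-dye axis) produces almost no
shift, the isotropic spring and the static-κ pendulum produce comparable
intermediate shifts, and only the pendulum with time-varying κ² approaches
the experimentally observed 0.2.

Other entry points: `fretshift simulate` (burst tables + summary JSON,
optional Photon-HDF5-style per-photon export), `fretshift analyze` (shift
summary of a stored table), `fretshift fixtures` (small deterministic runs
with SHA-256 digests).

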