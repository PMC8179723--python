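# nifs — nanowaveguide-illuminated fluorescence correlation spectroscopy, in silico

Fluorescence correlation spectroscopy (FCS) infers concentrations and
diffusion constants from the fluctuating photon stream emitted by molecules
crossing a small illuminated volume. The diffraction-limited confocal volume
(~1 fL) restricts conventional FCS to nanomolar samples; studying densely
packed membrane proteins at micromolar densities needs an illumination spot
thousands of times smaller and confined to within nanometers of the
membrane. Light squeezed through a metal-clad dielectric nanowire waveguide
provides exactly that: a near field ~50 nm wide that decays exponentially
within ~10–20 nm of the waveguide exit surface, giving zeptoliter-scale
observation volumes on a flat substrate.

This package is the computational side of that technique (NIFS,
nanowaveguide-illuminated FCS), for physicists and method developers who
want to simulate such experiments and validate the analytic correlation
models used to fit them. It provides:

* **`nifs.illumination`** — analytic excitation profiles, peak-normalized:
  the Gaussian-ellipsoid confocal focus
  `W = exp(−2(x²+y²)/r0²) exp(−2z²/z0²)`; the nanowaveguide near field
  `W = exp(−2(x²+y²)/r0²) exp(−z/z0)` for z > 0 (zero inside the waveguide);
  the annular edge field `W = exp(−(r−a0)²/b0²)` produced by the
  lightning-rod enhancement at the waveguide rim; plus a grid-sampled
  profile loader for field maps from electromagnetic solvers.
* **`nifs.simulate`** — a three-stage Brownian-dynamics Monte Carlo:
  uniform initial positions, Gaussian displacement steps of variance 2·D·Δt
  per axis (Δt = 100 ns), periodic lateral boundaries with a specularly
  reflecting wall at the waveguide exit surface, and per-step Bernoulli
  photon emission with probability `brightness · W(r)`. The inner loop is
  JIT-compiled (numba); a numpy engine replays the identical random stream.
* **`nifs.correlate`** — the normalized fluctuation autocorrelation
  `G(τ) = ⟨δF(t) δF(t+τ)⟩ / ⟨F⟩²` on a quasi-logarithmic lag grid, run
  averaging with per-lag standard deviations, and normalized residuals.
* **`nifs.models`** — the closed-form ACFs:

  conventional FCS (free 3D diffusion, Gaussian ellipsoid, κ = z0/r0):

      G(τ) = G0 (1 + τ/τD)⁻¹ (1 + τ/(κ²τD))^(−1/2),      τD = r0²/4D

  3D NIFS (half-space diffusion, exponential axial illumination — the
  axial part familiar from TIR-FCS):

      G(τ) = G0 (1 + τ/τD)⁻¹ [ √(τ/πτz) + (1 − τ/2τz) erfcx(√(τ/4τz)) ],
      τz = z0²/4D,  G0 = 1/(2 Veff⟨C⟩),  Veff = π r0² z0

  2D NIFS (in-plane diffusion through the annular edge field), a piecewise
  two-timescale model with shared amplitude G0 switching at the branch
  intersection τ_crit (≈ 8 τC for the nominal geometry):

      τ ≤ τ_crit:  G0 (1 + τ/τD)^(−1/2),                τD = b0²/2D
      τ > τ_crit:  G0 √(4π τC τD)/τ · [1 + (τC/τ)² + ¼(τC/τ)⁴] e^(−2τC/τ),
                   τC = a0²/4D

  plus a brute-force quadrature oracle for the underlying correlation
  integral (free-space and method-of-images propagators) used to verify all
  three closed forms independently.
* **`nifs.fit`** — weighted trust-region least squares on log-transformed
  parameters with guess heuristics, restarts, and derived quantities
  (Veff = 1/(G0·C), Aeff = 1/(G0·C), N = Veff·C).
* **`nifs.experiments`** — config-driven reproduction of the three
  simulated studies (conventional FCS in 1000 fL, 3D NIFS in 2 fL, 2D NIFS
  on a 4 µm² membrane) at a chosen scale, emitting input-vs-fitted
  comparison tables.

## Worked example

Simulate a conventional FCS measurement (300 fluorophores at 1/fL in a
300-fL box, D = 3×10⁻¹¹ m²/s), estimate the averaged autocorrelation, fit
the closed-form model, and derive the focal volume:

```python
from nifs import (SimulationConfig, GaussianEllipsoidProfile, calibrate_brightness,
                  run_simulation, correlate_runs, fit_curve, derive_quantities)
from dataclasses import replace

L = (300e-18) ** (1 / 3)
cfg = SimulationConfig(box=(L, L, L), n_particles=300, D=3e-11,
                       profile=GaussianEllipsoidProfile(r0=0.708e-6, z0=2.124e-6),
                       mode="FCS3D", n_steps=4_000_000, n_runs=6, seed=0)
cfg = replace(cfg, brightness=calibrate_brightness(cfg, 2.9e5))
curve = correlate_runs(run_simulation(cfg))          # ~5 min on one CPU
fit = fit_curve(curve, "FCS3D", weights="sd", fit_offset=True, fixed={"kappa": 3.0})
d = derive_quantities(fit, cfg.concentration)
print(f"tau_D = {fit.params.tau_d*1e3:.2f} ms   Veff = {d.veff*1e18:.2f} fL")
```

which prints (seed 0):

```
tau_D = 4.62 ms   Veff = 6.11 fL
```

The analytic inputs for this geometry are τD = r0²/4D = 4.2 ms and
Veff = π^{3/2} r0² z0 = 5.93 fL: at this reduced scale the pipeline recovers
the diffusion time within ~10% and the focal volume within ~3% (a full-scale
run, 10⁷ steps × 20 runs × 1000 particles, tightens both to a few percent).

The same flow drives the other two scenarios; `nifs.experiments` wraps
them:

```sh
nifs reproduce --experiment table1 --scale 0.1 --seed 0 --out out/
```

writes per-D averaged curves, fit reports, and a comparison table of
analytic inputs against fitted values.

## Grid-sampled profiles

`GridProfile.from_csv` reads a plain-text field map: one header line per
axis, `axis,<name>,v1,v2,...` (x, y[, z] order, meters), followed by the
intensity values row-major over the leading axes with one line per
row containing `len(last axis)` comma-separated values. Values are
peak-normalized, non-negative; positions outside the grid evaluate to 0.

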