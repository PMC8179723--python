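# Methods

This note documents the models, the Monte Carlo engine, the estimator and
fitting choices, and the limits of what the synthetic studies demonstrate.

## Models

All three autocorrelation models derive from the general relation between
the measured intensity correlation, the illumination profile W(r), and the
concentration-fluctuation propagator P:

    G(τ) = ∬ W(r) W(r′) ⟨δC(r,0) δC(r′,τ)⟩ dV dV′ / (⟨C⟩ [∫W dV]²),
    ⟨δC(r,0) δC(r′,τ)⟩ = ⟨C⟩ P(r, r′, τ)   (ideal, non-interacting particles).

* **Conventional FCS**: free 3D diffusion through a Gaussian ellipsoid.
  G(τ) = G0 (1+τ/τD)⁻¹ (1+τ/κ²τD)^(−1/2) with τD = r0²/4D, κ = z0/r0,
  G0 = 1/(Veff⟨C⟩), Veff = π^{3/2} r0² z0.
* **3D NIFS**: the nanowire near field is laterally Gaussian with an
  exponential axial decay, zero for z < 0 (molecules cannot enter the
  waveguide), and the wall at z = 0 reflects. The axial factor is the
  evanescent-illumination result known from TIR-FCS, written with the scaled
  complementary error function erfcx (evaluated by the numerically stable
  library routine — the naive exp(x²)·erfc(x) overflows beyond x ≈ 26):

      G(τ) = (1/2Veff⟨C⟩) (1+τ/τD)⁻¹ [√(τ/πτz) + (1 − τ/2τz) erfcx(√(τ/4τz))],

  τz = z0²/4D, Veff = π r0² z0. Both closed forms are verified against the
  quadrature oracle (below) to better than 10⁻⁴ relative.
* **2D NIFS**: in-plane diffusion through the annular edge field
  W = exp(−(r−a0)²/b0²) has no closed-form ACF; a two-timescale piecewise
  approximation is used. At short delays only radial motion across the
  ring's Gaussian cross-section decorrelates the signal — a one-dimensional
  Gaussian profile — giving G0 (1+τ/τD)^(−1/2) with τD = b0²/2D. At long
  delays molecules sample the whole ring; treating the annulus as a thin
  ring of radius a0 gives

      G(τ) = G0 √(4π τC τD)/τ · e^(−2τC/τ) I0(2τC/τ),   τC = a0²/4D,

  of which the implemented polynomial 1 + (τC/τ)² + ¼(τC/τ)⁴ is the Bessel
  series truncated after three terms (error < 0.1% for τ > 1.1 τC). The two
  branches share one amplitude G0 = true G(0); the switch time τ_crit is the
  τ > τC intersection found by bracketed root-finding, ≈ 8.29 τC for the
  nominal geometry τD/τC = 2b0²/a0² = 0.32. Consistency checks built into
  the form: the long-time tail reduces to the universal 2D result
  1/(4πDτ⟨C⟩), and G0 = 1/(Aeff⟨C⟩) with Aeff = 2√2 π^{3/2} a0 b0 — the
  amplitude-consistent effective area. A simpler closed form for the
  effective area, 2π^{3/2} a0 b0, is also in circulation; it is smaller by
  exactly √2 and does not equal the profile's (∫W)²/∫W². The package
  exposes both (`effective_volume("NIFS2D", ...)` returns the simple form,
  `effective_area_consistent` the √2-larger one) and reports never
  silently substitute one for the other.

### The quadrature oracle

`numeric_acf_oracle` evaluates the defining double integral directly:
tensor-product Gauss–Legendre in the profile coordinates with the free
Gaussian propagator (conventional, lateral factors), the method-of-images
reflected propagator for the half-space (reduced exactly to a 1D integral
in sum/difference coordinates and integrated adaptively), and the polar
Bessel kernel e^{−(r−r′)²/4Dτ} I0e(rr′/2Dτ)/(π·4Dτ) for the 2D annulus.
Node counts adapt to the propagator width (target relative accuracy 10⁻⁴,
verified by node-count refinement; non-convergence raises). The oracle
shares no algebra with the closed forms and is the package's independent
referee: agreement is asserted at <1% (conventional), <2% (3D NIFS) over
four decades of τ, and <3% against the small-time 2D branch.

For the nominal 2D geometry the ring is not thin (b0/a0 = 0.4) and the
piecewise form carries a real approximation error: fitting it to the exact
oracle curve recovers τD +17% and τC −28%. This intrinsic bias, not
estimator noise, dominates 2D parameter recovery — matching the level of
deviation the piecewise model shows against full-scale simulated data.

## Monte Carlo engine

* **Dynamics**: overdamped positional Langevin — independent Gaussian
  displacements of variance 2DΔt per axis per step, Δt = 100 ns. At these
  timescales solvent momentum relaxation (~ns for nm-scale particles) is
  long over, so a velocity-resolved scheme would be statistically identical;
  the positional update is exactly diffusive at every step.
* **Boundaries**: lateral faces wrap periodically. In the 3D NIFS geometry
  the exit surface (z = 0) reflects specularly (z → −z). The top face also
  reflects: wrapping the top onto the bottom while reflecting at the bottom
  would create a one-way circulation (particles teleport downward but can
  never wrap upward), whose steady state piles density onto the exit
  surface — a ~2× count-rate excess in trials. Two reflecting z-faces
  preserve the uniform equilibrium exactly. A step that moves a particle
  more than one box length raises an error (inconsistent D/Δt/box).
* **Emission**: per step, each particle emits a photon with Bernoulli
  probability brightness·W(r); brightness ≤ 0.1 so the per-step Bernoulli
  approximates the underlying Poisson intensity. Counts are binned at Δt.
* **Brightness calibration** targets a mean count rate (100 kHz at full
  scale). The pilot samples the stationary state directly: uniform
  positions are the exact equilibrium of this dynamics, so
  E[counts/step] = brightness·n·E_uniform[W], estimated from ~4×10⁶ static
  uniform draws. A short dynamical pilot would need to outlast the slowest
  diffusion time to see the same average. Where the full-scale 3D NIFS
  concentration cannot reach the target under the Bernoulli cap, the
  brightness clips at 0.1 and the achieved rate is recorded. For
  reduced-scale runs the rate target grows as 1/√(total steps) so the
  shot-noise contribution per lag stays comparable to full scale.
* **Randomness and determinism**: one SFC64 generator per run, seeded
  seed + run index; displacement and uniform streams are drawn in bulk
  (float32 — quantization ~10⁻⁷ relative, far below any physical scale) and
  consumed by the JIT-compiled kernel. The pure-numpy engine replays the
  identical stream and must produce bit-identical photon counts (tested).
  Everything downstream is deterministic, so traces, curves and fit reports
  regenerate bit-for-bit from a seed.

## Correlation estimator

Direct summation of G(τ) = ⟨δF δF⟩/⟨F⟩² on a quasi-logarithmic grid of bin
multiples (τ = 0 excluded; maximum lag one tenth of the trace). A multi-tau
cascade would be faster at full scale but the direct sum is exact and fast
enough at the sizes used here. Per-lag standard deviations across runs use
the n−1 sample convention.

Finite traces bias the estimator: subtracting a mean estimated from the
same trace removes ≈ (2/T)∫G dτ from every lag, which matters when G(0) is
large and the trace covers few correlation times (the reduced-scale 3D NIFS
runs: G(0) ≈ 7 at mean occupancy 0.03). Two mitigations are used: the
reference mean is pooled across all runs of an experiment
(`correlate_runs`), dividing the bias by the run count; and conventional-FCS
fits include a bounded additive offset that absorbs the flat remainder.

## Fitting

Trust-region least squares (scipy) on log-transformed positive parameters
with generous box bounds, a half-decay-based initial guess, and up to five
restarts from deterministically jittered starts. For the piecewise 2D model
τ_crit is not free: an outer fixed-point loop (≤10 iterations, 1%
tolerance) re-solves the branch intersection at the current parameters.
Parameter uncertainties come from the weighted Jacobian at the optimum and
are approximate.

Weighting: 1/sd is the default, but a sample sd from ≤6 runs is itself so
noisy that raw inverse-variance weights systematically over-trust
downward-fluctuated points; the weights therefore use a geometric moving
average of sd over ±2 neighboring lags. For the reduced-scale 3D NIFS
recovery, uniform weights are used outright — at 6 runs even smoothed sd
weighting measurably degraded the τD estimate, and the source studies do
not specify a weighting. κ is pinned at its known value 3 in reduced-scale
conventional-FCS fits: it is a calibrated instrument property, and at desk
statistics it is nearly unidentifiable, dragging τD with it when left free.

## Study conditions and scale

Full-scale experiment configs mirror the reference study conditions: 10⁷ steps of
100 ns × 20 runs; 1000 fluorophores in 1000 fL (conventional), 1000 in 2 fL
(3D NIFS), 400 on 4 µm² at z = 2.3 nm (2D NIFS); D spanning 3×10⁻¹¹ to
3×10⁻¹⁰ m²/s (conventional) and 10⁻¹³ to 10⁻¹² m²/s (NIFS). The `scale`
factor shrinks steps and runs proportionally (floors 10⁵ steps / 4 runs).

The desk-scale validation runs (`desk_recovery`, minutes on one CPU) keep
the reference concentrations where the statistics allow and deviate only
where they would not:

* conventional: 300 particles in a 300-fL cube at the reference 1/fL
  (lateral edge ≥ 10 r0), 4×10⁶ steps × 6 runs;
* 3D NIFS: 250 particles over 0.18 fL (≈2.3 µM — inside the technique's
  target range; at the reference 0.8 µM the mean occupancy of 0.03
  molecules makes τD scatter ~30% at any affordable length) and
  D = 3×10⁻¹² m²/s so the lag window spans 13 τD (at 10⁻¹² it spans only
  4, leaving τD barely identifiable);
* 2D NIFS: 250 fluorophores/µm² (a density the technique explicitly
  targets) on 1 µm², 8 runs.

What passing these runs shows: the engine's diffusion, boundary and
emission statistics are correct; the closed-form models describe the
simulated fluctuations; and the fitting stack recovers generating
parameters at the stated tolerances. What they do not show: anything about
detector artifacts, photophysics (triplet blinking, bleaching,
saturation), background, or the true electromagnetic field of a real
waveguide — the 3D simulations use the analytic profile, so the systematic
fit offsets seen with finite-element field maps (edge effects near the
waveguide rim) are out of scope by design.

## Known limitations

* The piecewise 2D model's thin-ring assumption is marginal at b0/a0 = 0.4;
  τC estimates inherit a ≈ −30% bias (see above). Treat fitted τC as
  order-of-magnitude unless the geometry is thinner.
* Bernoulli emission caps the count rate at 0.1 photons/particle/step;
  very dilute, very bright regimes need either finer binning or an
  exponential waiting-time scheme.
* Reflection is specular and instantaneous; near-wall discretization error
  is O(√(2DΔt)/z0), ~4% of the axial decay length at the default settings.
* Uncertainties from the Jacobian underestimate errors when residuals are
  correlated across lags, as they are at large τ.
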