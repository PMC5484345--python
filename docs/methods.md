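# Methods

## The model

The compartmental tissue uptake (CTU) model describes contrast-agent
kinetics in a tissue whose extravascular space acts as a sink on the
time scale of the acquisition: plasma (volume fraction `vp`) is fed by
arterial blood at flow `Fp` (min⁻¹) and leaks irreversibly into the
extravascular space at permeability–surface-area product `PS` (min⁻¹).
It is the limit of the two-compartment exchange model for negligible
back-flux, and it nests the one-compartment model (`PS = 0`) and the
Patlak model (fast vascular equilibration). The measured concentration
is

    C(t) = ca(t) ⊗ h(t),   h(t) = Fp·e^(−t/Tp) + Ktrans·(1 − e^(−t/Tp)),

with `Tp = vp/(Fp+PS)`, `E = PS/(PS+Fp)`, `Ktrans = E·Fp`. The model is
valid for `Fp > 0`, `vp > 0`, `PS ≥ 0`, i.e. `0 ≤ E ≤ 1`.

Double time-integration of the governing equations gives the linear
form

    C(t) = −α·C̄(t) + β·c̄a(t) + γ·c̄̄a(t),

with `α = (Fp+PS)/vp`, `β = Fp`, `γ = Fp·PS/vp`, estimated by ordinary
least squares over the sampled time points and mapped back
algebraically (`vp = β²/(αβ−γ)`, `Fp = β`, `PS = γβ/(αβ−γ)`,
`Tp = 1/α`, `E = γ/(αβ)`). `γ ≈ 0` indicates a one-compartment state.

## Numerical choices

- **Convolution.** `ca ⊗ e^(−t/τ)` is computed exactly under a
  piecewise-linear interpolation of `ca` between samples, by a
  per-interval closed-form recursion (all exponents negative, hence
  unconditionally stable; series expansions below `τ⁻¹Δt = 0.01` avoid
  cancellation). This, not FFT or Riemann sums, is what keeps the
  forward model usable on coarse clinical grids; a brute-force 1-ms
  Riemann oracle lives in the test suite only. The constant (leakage)
  term of the impulse response reduces to the running integral of
  `ca`, computed with the same trapezoidal rule as the linear fitter
  for consistency.
- **Linear solve.** Running integrals use cumulative trapezoids
  anchored at the first sample of the fitted window; baseline samples
  are included as acquired. The 3×3 normal matrix is inverted
  analytically; a Gram determinant below 1e−12 of its Hadamard bound
  flags the solution as `degenerate` (NaN parameters) instead of
  returning garbage. No row weighting, no clipping: negative `vp` or
  `E` outside [0, 1] are returned as-is and classified, because those
  categories are diagnostically meaningful.
- **Nonlinear solve.** `scipy.optimize.least_squares` (trust-region
  reflective) over `(Fp, vp, PS)` with positivity bounds and no upper
  bound by default; tolerances 1e−8, at most 200 iterations. The
  forward model handles the boundary by its limits (`vp → 0` drops the
  vascular pass; `Fp+PS → 0` gives a zero curve) so the optimiser can
  probe the bounds safely. On data the initial guess is the linear
  estimate projected into the bounds (non-positive components floored
  at 1e−3, fixed mid-range fallback if the linear system is
  degenerate); in simulation the fit is initialised at the generating
  values, giving the nonlinear method its best case.

## Simulation conventions

The simulator emulates a bolus-tracking acquisition:

- Parker population AIF (two Gaussians plus sigmoid-gated exponential;
  published population constants, first-pass FWHM 8.43 s on a 10-ms
  grid) with onset at the end of a 20-s baseline; 260-s total
  duration; noiseless curves generated on a 10-ms master grid.
- Per replicate, both curves are point-sampled at `t₀ + kΔt` with a
  shared uniform jitter `t₀ ~ U[0, Δt)` (nearest master-grid sample),
  then i.i.d. Gaussian noise is added to tissue and arterial curves
  independently.
- Noise SD is set by the contrast-to-noise ratio, CNR = (max
  concentration difference of the noiseless tissue curve)/(baseline
  noise SD), so sigma is deterministic per condition. The arterial
  noise level is not separately specified by the CNR definition; the
  default applies the same absolute sigma to both curves
  (`aif_noise_scale` exposes this choice — scaling the arterial noise
  by the arterial amplitude instead inflates all precision figures
  several-fold and is clearly not the reference convention).
- Default study conditions: the three literature tissue parameter
  sets (brain tumour 0.23/0.05/0.02; cervix tumour 0.57/0.28/0.2 and
  0.65/0.22/0.14), Δt = 2 s, CNR = 10, 1000 replicates, seeded and
  bit-reproducible. Degenerate linear solves are counted and excluded
  from the summary statistics, never silently dropped.

Percentage error is `100·(mean − truth)/truth` (the typeset reference
formula is ambiguous between `mean(x) − truth` and per-replicate
values; the mean reading is the one consistent with "systematic
variation") and precision is `100·sd/truth` with the sample SD.

What the simulation does *not* emulate: signal-to-concentration
conversion and T1-mapping errors, patient-specific AIF measurement,
motion, and spatial correlation of noise. Passing the Monte Carlo
checks therefore validates the estimators against sampling and
thermal-type noise, not against every clinical error source.

## Voxel QC

Clinical maps are screened in a fixed ladder: (1) negative
distribution volume `vd = ∫C/∫ca`; (2) fitted curve completely inside
the 95% baseline-noise band (mean ± 1.96·SD of the first `n_baseline`
samples — the plain reading of "contained within the 95% confidence
interval of the baseline noise"); then model validity of the linear
solution: (3) `vp ≤ 0`, (4) `E < 0`, (5) `E > 1`; otherwise included.
The flatness test uses the fitted curve of whichever fit is being
QC'd (for the linear fit, the linear-model reconstruction `A·b`). The
number of baseline samples is inferred from the arterial curve when
not given (first sample above 5% of the arterial maximum).

## Design notes and known limitations

- Internal time unit is minutes everywhere; readers convert declared
  seconds on ingest. The curve-table format requires an explicit time
  unit (`time_s`/`time_min` column or a `unit` argument).
- The simulated voxel-population fixture draws per-voxel `(Fp, vp,
  PS)` from the ranges reported for valid tumour voxels in clinical
  cervix data, so that across-voxel method agreement is dominated by
  true heterogeneity as it is clinically; agreement is assessed after
  discarding voxels whose unconstrained linear solution is physically
  undefined, mirroring the clinical comparison.
- Upper parameter bounds for the nonlinear fit default to +∞ and are
  configurable; clinical workflows sometimes cap `vp`.
- The two fitters respond differently to temporal downsampling: with
  exact-convolution forward modelling the nonlinear fit overestimates
  `Fp` slightly on coarse grids (the piecewise-linear arterial
  interpolation clips the first-pass peak), while the linear fit is
  less affected. The sign and size of this discretisation bias at
  Δt ≳ 2 s depend on the convolution discretisation and differ between
  otherwise-equivalent implementations; comparisons of absolute bias
  across software should keep that in mind.
- Weighted linear least squares (to correct the noise-model distortion
  introduced by integrating the data) is out of scope.
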