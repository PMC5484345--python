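# ctufit

Compartmental tissue uptake (CTU) tracer-kinetic modelling for
DCE-MRI, with both the conventional nonlinear fit and a closed-form
linear least-squares fit.

## What problem this solves

Dynamic contrast-enhanced MRI records the passage of a gadolinium
bolus through tissue at high temporal resolution. Fitting a tracer
kinetic model to each voxel's concentration-time curve yields
hemodynamic parameters — but nonlinear fitting of tens of thousands of
voxels is slow and needs good starting guesses. The CTU model is a
three-parameter special case of the two-compartment exchange model,
valid when back-flux of contrast agent from the extravascular space is
negligible (acquisitions shorter than the extravascular transit time,
e.g. tumours with trapped contrast agent). Its parameters are:

- `Fp` — plasma flow per unit tissue volume (min⁻¹)
- `vp` — fractional plasma volume (dimensionless)
- `PS` — permeability–surface-area product (min⁻¹)

with derived quantities `Tp = vp/(Fp+PS)` (plasma transit time),
`E = PS/(PS+Fp)` (extraction fraction) and `Ktrans = E·Fp`.

The analytical (nonlinear) form convolves the arterial input `ca(t)`
with the impulse response:

    C(t) = ca(t) ⊗ [ Fp·e^(−t/Tp) + Ktrans·(1 − e^(−t/Tp)) ]

Integrating the underlying differential system twice over time turns
the same model into a relation that is *linear* in three coefficients,

    C = −α·C̄ + β·c̄a + γ·c̄̄a,   α = (Fp+PS)/vp,  β = Fp,  γ = Fp·PS/vp

(overbars are running time-integrals), so a single analytic 3×3
normal-equation solve replaces iterative optimisation — orders of
magnitude faster per voxel — and the coefficients map back exactly:
`vp = β²/(αβ−γ)`, `Fp = β`, `PS = γβ/(αβ−γ)`.

The package provides:

- `ctufit.model` — analytical forward model with exact exponential
  convolution (piecewise-linear input, per-interval closed form)
- `ctufit.linear` — closed-form linear least-squares fit and validity
  classification of its unconstrained solutions
- `ctufit.nonlinear` — bounded trust-region nonlinear fit (optionally
  seeded by the linear estimate)
- `ctufit.aif` — Parker population arterial input function
- `ctufit.simulate` — simulated acquisitions (CNR-controlled noise,
  jittered temporal downsampling) and Monte Carlo error/precision
  evaluation
- `ctufit.qc` — voxel-level exclusion/classification rules for
  clinical parameter maps
- `ctu` command-line interface (`simulate`, `fit`, `montecarlo`, `qc`,
  `make-fixtures`) reading delimited curve tables and NIfTI volumes

## Worked example

Simulate a brain-tumour acquisition (Parker AIF, 20-s baseline, 260-s
duration, 2-s sampling) and fit it:

```python
from ctufit import (SimConfig, TABLE_TISSUES, generate_noiseless,
                    downsample_jitter, solve_lls, run_monte_carlo)

cfg = SimConfig(tissue=TABLE_TISSUES["brain"], dt_s=2.0, cnr=10.0,
                n_reps=1000, seed=1)
ca_master, C_master = generate_noiseless(cfg)
ca = downsample_jitter(ca_master, 2.0, t0_s=0.0)
C = downsample_jitter(C_master, 2.0, t0_s=0.0)

lls = solve_lls(C, ca)
print(f"LLS:  Fp={lls.params.Fp:.4f}  vp={lls.params.vp:.4f}  "
      f"PS={lls.params.PS:.4f}  E={lls.derived.E:.4f}  category={lls.category}")

summary = run_monte_carlo(cfg)
print(summary.to_frame().to_string(index=False))
```

prints

```
LLS:  Fp=0.2301  vp=0.0499  PS=0.0200  E=0.0800  category=valid
method parameter  error_pct  precision_pct  mean_l2  n_degenerate
   lls        Fp  -3.387956      10.572480 0.156104             0
   lls        vp   1.732112       5.267944 0.156104             0
   lls        PS  -0.728469       4.999896 0.156104             0
  nlls        Fp   1.097451       7.794736 0.144986             0
  nlls        vp   0.030752       4.596174 0.144986             0
  nlls        PS  -0.285195       4.451423 0.144986             0
```

The noiseless 2-s fit recovers the generating parameters
(Fp = 0.23 min⁻¹, vp = 0.05, PS = 0.02 min⁻¹) to better than 0.5%.
The Monte Carlo table summarises 1000 noisy replicates at
contrast-to-noise ratio 10: `error_pct` is the systematic deviation of
the mean estimate from the truth, `precision_pct` the replicate
standard deviation, both as percentages of the true value. At this
noise level the closed-form linear fit is nearly as accurate and
precise as the nonlinear fit initialised at the truth.

The same thing from a shell:

```sh
ctu montecarlo --tissue brain --dt 2 --cnr 10 --reps 1000 --seed 1 --out mc.csv
ctu simulate --tissue brain --cnr inf --out curves.csv
ctu fit --curves curves.csv --method both --out params.csv
```

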