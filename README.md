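# dcsflow

Diffuse correlation spectroscopy (DCS) analysis for longitudinal blood-flow
monitoring, built around a preclinical bone-graft study design: forward-model
intensity autocorrelation curves for a semi-infinite tissue, invert them for
the blood flow index (BFI), and run the relative-blood-flow cohort statistics
(rBF, ΔrBF, group means ± SEM, weekly t-tests, elevation durations) — with a
synthetic-cohort generator standing in for animal data so the whole pipeline
is testable offline.

## Who this is for

DCS measures the temporal autocorrelation of multiply scattered coherent
near-infrared light; moving red blood cells decorrelate the speckle field, so
the decay rate of the measured intensity autocorrelation g₂(τ) encodes
microvascular blood flow. This package targets researchers analysing
longitudinal small-animal DCS measurements (e.g. weekly monitoring of bone
graft healing in mice) who need a reproducible path from raw g₂(τ) curves to
group-level statistics.

## The model

For a point source on a semi-infinite homogeneous turbid medium with Brownian
scatterer dynamics, the normalized field autocorrelation is

    g₁(τ) = G₁(τ) / G₁(0),
    G₁(τ) = exp(−K(τ)·r₁)/r₁ − exp(−K(τ)·r₂)/r₂,
    K(τ)  = √(3·μa·μs′ + 6·μs′²·k₀²·BFI·τ),      k₀ = 2π·n/λ,

with r₁, r₂ the distances from the detector to the isotropic source at depth
z₀ = 1/(μa + μs′) and to its negative image at z₀ + 2·z_b, where
z_b = (2/3μs′)·(1+R_eff)/(1−R_eff) is the extrapolated-boundary offset. The
measured intensity autocorrelation follows from the Siegert relation
g₂(τ) = 1 + β·g₁(τ)². BFI = αD_B (fraction of moving scatterers × their
effective Brownian diffusion coefficient, cm²/s) and the coherence factor β
are extracted per curve by Nelder-Mead least squares in (ln BFI, β).

Longitudinal statistics normalize each site to its pre-surgery baseline,

    rBF(r, tᵢ) = BFI(r, tᵢ) / BFI(r, t₀),
    ΔrBF(t)    = rBF_graft(t) − rBF_contralateral(t),

and compare groups week by week with a two-sided pooled-variance Student's
t-test (p < 0.05).

## Worked example

```bash
python examples/02_fit_single_curve.py
```

```
true BFI   = 2.0000e-08 cm^2/s   true beta = 0.5
fitted BFI = 2.0138e-08 cm^2/s   fitted beta = 0.5004
relative BFI error = +0.69 %
converged = True, sse = 2.355e-03, lags used = 89
```

A single noisy curve (additive g₂ noise σ = 0.005) is inverted to better
than 1 % here; averaging the 30 repeats acquired per site pushes the
measurement error well below week-to-week physiology. The other examples
forward-model curves (`01`), propagate a ±10 % absorption-coefficient bias
into BFI (`03`; ∓1.8 % at 5 mm separation), and run a scaled-down cohort
end-to-end (`04`), printing the group-mean rBF table and elevation durations.

The same pipeline is scriptable from the shell:

```bash
dcsflow simulate --config config.yaml --out simdir
dcsflow fit --manifest simdir/manifest.csv --out estimates.csv
dcsflow analyze --estimates estimates.csv --out analysis/
dcsflow report --analysis analysis/ --out report/
```

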