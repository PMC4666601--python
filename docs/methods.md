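# Methods

## Forward model

The field autocorrelation of multiply scattered light on a semi-infinite
homogeneous medium is modelled with the extrapolated-boundary Green's
function solution of the correlation diffusion equation under Brownian
scatterer dynamics:

g₁(τ) = [exp(−K(τ)r₁)/r₁ − exp(−K(τ)r₂)/r₂] / G₁(0), with
K(τ)² = 3 μa μs′ + 6 μs′² k₀² · BFI · τ and k₀ = 2π n_tissue/λ.

Assumptions: photon transport in the diffusion regime (μs′ ≫ μa, detector
several transport lengths from the source), homogeneous optical properties,
an index-mismatched planar boundary handled by a single negative image
source, and purely Brownian dynamics of the moving scatterers so that only
the product BFI = αD_B is identifiable. The measured intensity
autocorrelation is linked by the Siegert relation g₂ = 1 + β g₁², valid for
Gaussian field statistics; β is a detection-optics constant (≈ 0.5 for
single-mode fiber collection) and is always co-estimated rather than assumed.

Unit system: lengths cm, μa/μs′ 1/cm, τ s, BFI cm²/s; wavelength entered in
nm and converted internally. The source depth is z₀ = 1/(μa+μs′) (exact
transport definition — numerically indistinguishable from 1/μs′ but fixed for
reproducibility), and the boundary offset z_b = (2/3μs′)(1+R_eff)/(1−R_eff)
uses the standard polynomial R_eff(n_rel) = −1.440 n_rel⁻² + 0.710 n_rel⁻¹ +
0.668 + 0.0636 n_rel, clipped to [0, 0.999].

Default optics are canonical near-infrared soft-tissue values — μa = 0.10
/cm, μs′ = 10 /cm at 785 nm, n_tissue = 1.37 against air — kept in one
configurable dataclass. Absolute BFI depends strongly on these assumptions;
baseline-normalized rBF largely cancels them, which is why the longitudinal
statistics work on ratios.

## Inversion

Each curve is fit by unweighted least squares on g₂ over lags ≤ 10 ms
(the default cutoff keeps ~89 of the 96 multi-tau channels). The objective
is minimized with a Nelder-Mead simplex in (ln BFI, β): the log
parametrization enforces positivity without a constrained solver; β is
clipped to (0, 1] inside the objective with a quadratic penalty outside.
Initialization: β₀ = mean(g₂ − 1) over the three smallest lags clipped to
(0.05, 1], BFI₀ = 10⁻⁸ cm²/s, with one restart from 5·BFI₀ if the simplex
fails to collapse; the best of all starts is returned. Tolerances are 10⁻¹⁰
(objective) and 10⁻⁸ (parameters) with at most 2000 iterations — generous
for a 2-parameter problem.

The simplex itself is compiled with numba (standard reflection/expansion/
contraction/shrink coefficients 1, 2, ½, ½ and a scipy-style 5 % initial
perturbation) so a full cohort (~143k fits) runs in under a minute on one
core; the test suite verifies it against scipy's independent Nelder-Mead on
the same objective, and against an optimizer-free brute-force grid search.

Degenerate inputs are contracts, not crashes: fewer than 10 usable lags
raises an error; a curve that never rises above the noise floor
(max g₂ − 1 ≤ 0.05 by default) returns a non-converged estimate at the BFI
lower bound (10⁻¹² cm²/s) with a warning. Repeat-averaging takes the plain
arithmetic mean of converged BFIs; non-converged repeats are excluded and
counted, and a site-visit with zero converged repeats propagates as missing,
never as zero. An optional flag drops repeats with sse > 5× the median (off
by default: plain averaging is the stated protocol).

### Absorption-bias propagation

`mua_sensitivity` quantifies how an error in the assumed μa propagates into
BFI within the homogeneous model: generate a noiseless curve with true
optics, refit with μa scaled by (1 + bias), report the relative BFI error.
At the default optics and ρ = 5 mm a −10 % μa bias gives a −1.8 % BFI error,
symmetric within a percentage point for +10 %. The naive slope-matching
argument (decay rate ∝ BFI/√μa, hence an error of 1 − √0.9 ≈ 5 %)
overstates the effect: lowering μa also lowers the static attenuation
K(0) = √(3 μa μs′), which lengthens the effective source–image pathlength
and cancels most of the slope change at small separations. The residual
error grows with ρ (≈ −3.9 % at 3 cm) and with μa, and depends mildly on the
fitted lag range. Because the error enters all weeks multiplicatively, rBF
is insensitive to it as long as the optics are stable over time.

## Synthetic cohort generator

The generator emulates a two-group longitudinal graft study: autograft n = 7
and allograft n = 10 mice; visits at week 0 (pre-surgery baseline) through
week 9; positions P1–P6 spaced 1.5 mm along the grafted femur plus a
contralateral control P7; separations 2.9/3.6/4.3/5.0 mm; 30 repeat curves
of 2 s integration per site.

The site-level model is multiplicative-lognormal around deterministic
trajectories:

BFI(m, w, p, ρ) = B(m, p) · rBF_true(g, p, w, ρ) · exp(ε_week),
with B(m, p) lognormal (median 10⁻⁸ cm²/s, geometric SD 1.3),
ε_week ~ N(0, 0.06²) per visit, a per-repeat factor exp(N(0, 0.03²)), and
additive Gaussian g₂ noise of amplitude σ₀ = 0.003 decaying as √(τ₁/τ_k)
across lags (the long-lag channels of a multi-tau correlator average more
samples; a constant profile is also available). These variance components
put the group-mean SEM at roughly 0.03–0.06, the scale typical of such
cohorts, and are design choices — real per-animal variance decompositions
are study-specific.

The default trajectory table encodes the study conditions at the 5.0 mm
reference separation: an early surge to ~1.95 in the autograft group at all
graft positions that returns below the 1.25 elevation threshold by week 3; a
later, spatially graded allograft response peaking at 1.99 (week 2, central
P4) and remaining above 1.25 for 2/4/6 consecutive weeks at the
proximal/central/distal positions; a systemic contralateral echo in the
allograft group (1.61 and 1.47 at weeks 1–2) and a flat autograft
contralateral leg. Unreported intermediate positions are interpolated
(P1 = P2, P3 = mean(P2, P4), P5 = mean(P4, P6)). Values between the anchor
weeks keep ≥ 0.10 margin from the 1.25 threshold so the integer durations
are stable under the default noise. Depth scaling across separations is
linear for the allograft group, v(ρ) = 1 + s(ρ)(v(5.0) − 1) with
s(2.9) = 0.465, so the shallow central peak is 1.46; the autograft response
is depth-uniform (s ≡ 1).

Reproducibility: every random stream is opened from a `SeedSequence` keyed
by (master seed, stream tag, CRC32 of mouse id, week, position, separation,
repeat). Two runs with one seed are byte-identical, and adding or renaming
one mouse perturbs only that mouse's data.

What the generator does not emulate: layered bone/muscle geometry and
depth-dependent partial volume (the separation scaling is a phenomenological
stand-in), correlator dead-time/afterpulsing, motion artifacts, animal
dropout, and any coupling between graft and contralateral legs beyond the
deterministic trajectories. Passing end-to-end tests therefore demonstrates
that the pipeline recovers the statistics its own generative model encodes
under realistic noise — not that the physiological trajectories themselves
are predictive of real healing.

## Longitudinal statistics

rBF divides each site's BFI by that site's week-0 baseline (missing or
non-positive baselines propagate as missing/errors, never imputed); ΔrBF
subtracts the same-week, same-separation contralateral (P7) rBF per mouse.
Group summaries report mean and SEM (sd with n−1 denominator; SEM missing
for n = 1). Weekly comparisons use the classic pooled-variance two-sided
Student's t-test at p < 0.05 with no multiple-testing correction, per cell
(week × separation): graft P4 vs contralateral P7 within each group, and
autograft vs allograft for rBF (each position) and ΔrBF (graft positions).
The within-group comparison is unpaired by default ("two sample" semantics)
with a paired-test switch, since pairing by mouse is plausible but not
stated. Zero-pooled-variance cells resolve explicitly (equal means → t = 0,
p = 1; unequal → p = 0 with a warning). The elevation duration counts
consecutive weeks from week 1 with group-mean rBF strictly above 1.25; the
strict inequality and the week-1 start make it a deterministic integer.

## Numerical choices and problem sizes

The multi-tau lag grid uses 16 linear 1 μs channels then groups of 8 with
dwell doubling per group, ending at 16.4 ms (96 channels). Grid-oracle
tests use a 200-point log grid over 10⁻¹⁰–10⁻⁶ cm²/s with a 199-point β
grid; ties break toward smaller BFI then smaller β. Monte-Carlo test sizes
— 100–200 noisy curves for recovery/bias, 1000 curves for the noise-profile
check, 500 mice for generator-consistency, 900 null cells for t-test
calibration — were chosen so each check resolves its tolerance with
comfortable statistical margin while the whole suite stays quick; the full
default cohort (≈143k curve fits) runs end to end in about a minute.

## Known limitations

Single-separation, homogeneous, semi-infinite analysis only: no layered or
tomographic models, no simultaneous multi-separation fitting, no flow models
beyond Brownian diffusion. Absolute BFI inherits the assumed optics;
comparisons across cohorts fitted with different assumptions are only
meaningful through rBF. The t-tests are per-cell with no correction for the
many cells examined, mirroring the simple protocol the pipeline implements.
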