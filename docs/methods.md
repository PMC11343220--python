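# Methods

## Signal model

A voxel's normalized trace-weighted DWI signal is a mixture of
stretched-exponential components, `S(b) = Σ fᵢ exp(−(b·Dᵢ)^γᵢ)`, with the
stretch applied to the dimensionless product `b·D`. This choice (rather
than `exp(−b·D^γ)`) keeps the exponent unit-free, makes γ=1 collapse
exactly onto the Gaussian mixture, and is algebraically identical to the
expansion `exp(−b · D^γ · b^(γ−1))` used for the Gaussian approximation:
near a working b-value `b_ref` the component behaves like a Gaussian
component with apparent coefficient `D^γ·b_ref^(γ−1)`. Regime-center
b-values are 500 (tissue), 100 (tubule) and 10 (vascular) s/mm².

Units are strictly mm²/s and s/mm² internally; every exported table and
map converts D and fD to the conventional 10⁻³ mm²/s display scale. This
avoids the 1000× unit mistakes that plague IVIM code.

Consequences of the stretch worth knowing when interpreting results:

* sub-diffusion (γ≈0.85, tissue) spreads a component's Gaussian-equivalent
  representation toward *slower* coefficients — part of its spectrum
  amplitude falls below the 0.8×10⁻³ mm²/s exclusion bound and its
  recovered `fD` is biased low;
* super-diffusion (γ≈1.75, vascular) *deflates* the apparent coefficient at
  the b-values where vascular signal survives: a component drawn at
  D=70×10⁻³ is seen by any Gaussian-basis fit near
  `(b·D)^(γ−1)·D ≈ 53×10⁻³` — directly on the tubule/vascular division
  (see "Known limitations").

## The flow proxy

The sphere-escape derivation: the probability that a molecule of an
isotropic Gaussian with per-axis spread σ remains within radius R is the
Maxwell radial CDF `erf(u/√2) − √(2/π)·u·exp(−u²/2)`, `u = R/σ`. Solving
for 50% at R = 0.5 mm gives 2σ² = 0.2113 mm² (σ = 0.3251 mm); Brent's
method on the closed form, with 3-D quadrature kept as the test oracle.
With σ² = 2Dt the half-residence time is `t = σ²/2D` and volume flow per
gram is `f·f_w/(ρ·t) ∝ f·D`. Water content f_w and density ρ default to 1
(kidney ≈ unit density; f_w is not separately identifiable from DWI and is
exposed as a constant). The unrounded σ is used throughout; the rounded
0.32 mm changes downstream numbers by <2% and can be forced via
`FlowConstants(sigma=0.32)`.

## Cohort simulator

Defaults are the study conditions and are not tuning knobs:

| parameter | tissue | tubule | vascular |
|---|---|---|---|
| f (before normalization) | 0.60±0.10 | 0.30±0.015 | 0.10±0.05 |
| D_mean (mm²/s) | 0.0015±0.00075 | 0.010±0.0025 | 0.070±0.009 |
| FA | 0.18±0.02 | 0.12±0.03 | 0.09±0.04 |
| γ | 0.85±0.051 | 1.0±0.10 | 1.75±0.2 |

b = [0, 10, 30, 50, 80, 120, 200, 400, 800] s/mm²; 1000 sets; Rician noise
σ = 0.02 (SNR 50 at b=0).

Per set: draws are rejected-and-redrawn when out of range (no clipping
mass at zero); fractions are normalized to sum to one over the active
components. Tensors are built by drawing 500 candidate eigenvalue triples
i.i.d. uniform on (0,1], keeping the one whose FA is closest to the target
(hits within 0.02 of the target in ≥99% of draws), and rescaling the
eigenvalues so their mean equals the drawn mean diffusivity exactly.
Rotations are uniform over SO(3) via normalized random quaternions.

The acquisition is modelled as a three-direction trace measurement: each
global axis sees the decay of the corresponding diagonal tensor entry,
Rician noise (Gaussian with mean √(I²+σ²), sd σ, constant across b) is
applied to each directional measurement, and the three noisy signals are
averaged into the voxel's curve. The recorded truth coefficient D_approx
is the diagonal mean, which equals the drawn mean diffusivity exactly for
every rotation — the designed insensitivity of trace-weighted DWI to
anisotropy, asserted at machine precision in the tests. Averaging three
noisy measurements means the trace curve's effective noise is σ/√3; the
two parametric reference fitters reproduce their expected cohort behavior
only under this reading, which is why it was adopted over adding a single
noise draw to the averaged curve.

Not modelled: motion, distortion, cardiac pulsatility, b-value
discrepancy, T1/T2 effects, medullary compartments, diffusion kurtosis.
Passing cohort tests therefore says nothing about robustness to those
effects in vivo.

## Spectral diffusion

Per voxel, minimize `‖A·s − y‖² + λ‖L·s‖²` s.t. `s ≥ 0`, where column m of
A is `exp(−b·D_m)` on M=300 log-spaced coefficients and L is the
second-difference operator on interior grid points; solved as one NNLS on
the augmented system `[A; √λ·L]`. λ = 0.1. Grid bounds: D_min = 1×10⁻⁴
mm²/s (well below the 0.8×10⁻³ exclusion bound, so too-slow and
sub-diffusive content can be represented and then excluded) and D_max =
0.3 mm²/s. The ceiling matters: a coefficient ≥0.3 decays to nothing by
b=10, so such amplitude is constrained only by the noisy b=0 sample while
contributing enormously to the vascular first moment; an open-ended grid
converts b=0 noise directly into spurious vascular fD.

Peaks are maximal contiguous supra-floor runs (floor 10⁻⁶ of the maximum —
NNLS off-support values are exact zeros, the floor only guards
regularization ripple), additionally split where a run crosses a regime
division: a smoothed lobe spanning a division carries signal from two
regimes. Per peak, `f = Σsₖ/Σs_all` and `D = Σ sₖDₖ/Σsₖ`. Peaks with
D < 0.8×10⁻³ are excluded; multiple peaks within one regime merge
(area-weighted); fractions keep the whole-spectrum denominator, so after
an exclusion the retained regimes sum to slightly under one — the excluded
signal is real but unassignable, and silently re-inflating the other
regimes was found to distort the fraction agreement. An empty regime is
reported as (0, 0, 0); a voxel with no retained peak at all is flagged
`no_peaks` and treated like a fit failure downstream.

## Parametric reference fitters

**Bayesian biexponential.** `S = f·e^(−bD*) + (1−f)·e^(−bD)`; Gaussian
priors on ln D (−6.2±1) and ln D* (−3.5±1) — i.e. centered on 2.0×10⁻³ and
3.0×10⁻² mm²/s — flat prior on f. The noise scale is marginalized under a
Jeffreys prior, leaving a marginal likelihood ∝ RSS^(−N/2), evaluated on a
deterministic grid (f in steps of 0.01; 121 points over ±3 sd in each
log-coefficient). The point estimate is the posterior mean; if it inverts
D* > D the pools are swapped (post-hoc regime sorting). A grid posterior
is exactly reproducible — no sampler state — and one cached model matrix
makes a voxel fit a single matrix–vector product. Being a posterior mean
over bounded parameters it shrinks: fractions regress toward the interior
(visible as pooled regression slopes ≈0.8), and f is unidentifiable on
noiseless data when D*=D. Mapping: fast pool → vascular, slow pool →
tissue, tubule ≡ 0.

**Triexponential.** Trust-region bounded least squares from the single
published start (f = 0.7/0.2/0.1; D = 0.001/0.01/0.1 with bounds up to
0.01/0.1/0.5), tolerances 10⁻¹⁰, ≤1000 evaluations, fractions normalized
post-fit, components labeled by sorting coefficients. Deliberately
single-start: multi-starting would mask the documented failure mode on
two-component data (two fitted coefficients collapsing onto one
component), which is part of what the evaluation measures. A component
with equal lower and upper bounds is held fixed, which yields the nested
biexponential as a special case.

**Fixed-γ stretched fit** (demonstration only): least squares over (f_A,
D_A) with γ frozen at 0.85/1/2 per regime.

## Evaluation

Agreement of fitted (f, D, fD) against the generated truth uses: pooled
OLS regression across all components and sets (D, fD in 10⁻³ mm²/s),
Bland–Altman mean difference ±1.96 sd, and the symmetric median percent
difference `200·|in−out|/(in+out)` per component — bounded by 200%, with
both-zero pairs scoring 0 (correctly absent component) and excluded from
regressions. R² < 0.70 excludes a voxel from map statistics; 0.70 itself
is retained. Group-comparison wrappers (Mann–Whitney U with signed normal
z, one-way ANOVA, Spearman) delegate to scipy.stats.

## Imaging pipeline

NIfTI in, NIfTI out (nibabel); b-values from a text file or JSON sidecar;
per-voxel normalization by b=0. Fits run voxel-wise inside a mask; the
exclusion map distinguishes low-R², no-component and outside-mask voxels,
because with a data-driven component count a legitimate zero is otherwise
indistinguishable from a failed fit. ROI summaries are voxel-weighted
(pooled across ROIs), with per-ROI rows retained. The synthetic phantom
builds labelled regions from the same signal models with the same
three-measurement noise averaging, and is the stand-in for clinical
volumes in all end-to-end tests.

## Numerical choices

* NNLS: SciPy's active-set solver on the augmented system; maxiter 50·M.
* Escape-sphere root: Brent on the closed-form CDF, |Δ| < 10⁻¹².
* Posterior grid in float32 after the float64 RSS reduction — ample for a
  posterior mean, halves memory and time.
* RSS floored at 10⁻³⁰ before the log (noiseless curves can reach exact
  zero residual on grid points).
* Ties at regime divisions: a grid point exactly at a division belongs to
  the upper regime (bounds are `lo ≤ D < hi`); the R² exclusion boundary
  keeps 0.70.

## Known limitations

* **The tubule/vascular division is the binding constraint on
  three-component recovery.** The super-diffusive vascular component's
  Gaussian-equivalent coefficient (~53×10⁻³ mm²/s at the drawn means)
  sits essentially on the 50×10⁻³ division, so under noise its spectral
  amplitude straddles the boundary and the vascular fraction/moment split
  with the tubule regime is unstable. Pooled spectral fD correlation on
  the three-component cohort plateaus near R² ≈ 0.33 (two-component:
  ≈ 0.6) for this reason; sensitivity analysis shows the recovery improves
  sharply if the division is lowered toward the geometric midpoint between
  the tubule and deflated-vascular positions (~25–35×10⁻³). The published
  division is kept; users separating super-diffusive compartments should
  be aware the boundary placement, not the solver, limits accuracy.
* Spectral fraction errors grow whenever sub-diffusive tissue content
  leaks below the 0.8×10⁻³ exclusion bound (the leak varies voxel to
  voxel), and the biexponential posterior mean is shrunk by construction.
* The simulator draws γ independently per component with no
  inter-component correlation, and its anomalous values extrapolate from
  brain literature; the phantom inherits all simulator idealizations.
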