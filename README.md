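# spectraldwi

Multi-component flow estimation in the kidney from multi-b-value
diffusion-weighted MRI (DWI), built around **spectral diffusion**:
regularized non-negative least-squares (NNLS) decomposition of a decay
curve into a continuous spectrum of diffusion coefficients, without fixing
the number of components in advance.

## Who this is for

Researchers analyzing renal IVIM-style DWI (9 b-values, 0–800 s/mm²,
trace-weighted) who want to separate the cortical signal into **tissue
parenchyma** (restricted diffusion), **tubular flow** (moderate
pseudo-diffusion) and **vascular perfusion** (fast pseudo-diffusion), and
to summarize each component by the flow proxy `fD` — the product of its
signal fraction and diffusion coefficient.

## The model

A voxel's normalized decay is a mixture of stretched-exponential
components,

    S(b)/S0 = Σᵢ fᵢ · exp(−(b·Dᵢ)^γᵢ),

with γ<1 sub-diffusion (tissue), γ=1 Brownian (tubular flow) and γ→2
ballistic (capillary blood). Around each regime's working b-value the
stretch is well approximated by a Gaussian component, so the Gaussian
product `f·D` approximates the anomalous `f_A·D_A`.

`fD` is proportional to volume flow: integrating an isotropic Gaussian
over a sphere of 1 mm diameter and solving for the spread at 50% escape
probability gives 2σ² ≈ 0.21 mm² (σ ≈ 0.32 mm); with σ² = 2Dt the
half-residence time of water in a cubic millimeter is t = σ²/2D, and the
cleared volume per time per gram is ∝ f·D — no capillary-geometry
assumptions required.

Three estimators are provided and compared:

1. **Spectral diffusion** — NNLS over 300 log-spaced coefficients with a
   second-difference curvature penalty (λ=0.1); spectrum peaks are
   segmented, assigned to the physiologic regimes
   0.8 < tissue < 5 ≤ tubule < 50 ≤ vascular (D in 10⁻³ mm²/s), and peaks
   below 0.8×10⁻³ are excluded as too slow to capture at b ≤ 800 s/mm².
2. **Bayesian biexponential IVIM** — grid posterior with kidney log-priors
   ln D = −6.2±1, ln D* = −3.5±1 and flat f; posterior-mean estimate.
3. **Bounded least-squares triexponential** — the published single
   start/bound set, fractions normalized post-fit.

A cohort simulator generates the study conditions: 1000 voxels, each with
up to three anisotropic diffusion tensors built to drawn (FA, mean-D)
targets, randomly rotated, measured along three orthogonal directions, with
Rician noise (σ=0.02, SNR 50) per directional measurement.

## Worked example

```python
import spectraldwi as sd

# the escape-sphere constants behind the flow proxy
print(round(sd.solve_sigma_sq(radius=0.5, target_prob=0.5), 2))  # 0.21
print(round(sd.FlowConstants().sigma, 2))                        # 0.33 -> ~0.32 mm

# a noiseless cortical voxel at the cohort's mean parameters
curve = sd.gaussian_signal(
    [sd.ComponentParams(0.6, 0.0015),   # tissue
     sd.ComponentParams(0.3, 0.010),    # tubule
     sd.ComponentParams(0.1, 0.070)],   # vascular
    sd.DEFAULT_BVALUES)
fit = sd.spectral_fit_voxel(curve)
for name in sd.REGIMES:
    r = fit.regime(name)
    print(f"{name:9s} f={r.f:.3f}  D={r.D*1e3:.2f}e-3  fD={r.fD*1e3:.2f}e-3")
```

prints

```
0.21
0.33
tissue    f=0.610  D=1.57e-3  fD=0.96e-3
tubule    f=0.293  D=10.47e-3  fD=3.07e-3
vascular  f=0.096  D=72.16e-3  fD=6.96e-3
```

— the three regimes are recovered within a few percent of the generating
values (f = 0.6/0.3/0.1, D = 1.5/10/70 ×10⁻³ mm²/s) without telling the
fitter how many components exist.

The same machinery runs from the shell:

```bash
spectraldwi simulate --n-sets 1000 --components 3 --seed 7 --out cohort
spectraldwi fit --curves cohort_curves.csv --method spectral --out fits.csv
spectraldwi evaluate --truth cohort_truth.csv --fits fits.csv --method spectral
spectraldwi phantom --seed 1 --out-dir phantom/
spectraldwi map --dwi phantom/phantom_dwi.nii.gz --bvals phantom/phantom_bvals.txt \
    --method spectral --out-dir maps/
```

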