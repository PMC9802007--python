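# Methods

## The model

At very high diffusion weighting (b ≳ 6 ms/μm²) the extra-axonal water
signal in white matter is assumed fully attenuated, so the remaining
diffusion signal comes from the intra-axonal space alone.  `noddax`
models that signal as a stick response (Gaussian diffusion `d∥` along
the axon, none across it) convolved with a Watson orientation
distribution of concentration κ about the fibre axis μ:

    S(b, g) = F · ₁F₁(½; 3/2; κμμᵀ − b d∥ ggᵀ) / ₁F₁(½; 3/2; κμμᵀ),

where F = f_in·S0 is the non-attenuated intra-axonal signal and
₁F₁(½;3/2;·) is the confluent hypergeometric function of a symmetric
3×3 matrix argument.  Dispersion is reported as the orientation
dispersion index ODI = (2/π)·arctan(1/κ) ∈ [0, 1] (0 = parallel fibres,
1 = isotropic).

The spherical mean (powder average) of a stick response is independent
of the orientation distribution,

    S̄_b = F · √π · erf(√(b d∥)) / (2 √(b d∥)),

so dividing the directional model by the per-shell spherical mean of the
data eliminates F and S0, leaving two free shape parameters (ODI, d∥).

Low SNR makes two further signal components non-negligible:

* a signal offset `c` (background signal independent of diffusion
  weighting, sometimes called a dot compartment): Y = S + c;
* for magnitude-reconstructed data, the rectified Rician noise floor
  with scale ε (the std of the complex Gaussian noise):
  Y = √((S + c)² + ε²).

Both are estimated (or deliberately pinned) inside the fit.  Before
spherical means are formed the data are inverted back to signal,
S = Re√(Y² − ε²) − c (the real part clamps Y < ε to zero), per
measurement and then averaged within each shell; this order matters and
is the default (`correct_then_mean`).

## Fitting

The fit (class `WatsonStickMH`) holds the fibre orientation fixed at a
supplied axis — normally V1, the primary eigenvector of a diffusion
tensor fitted to the low-b portion of the acquisition — and samples the
remaining parameters with component-wise Metropolis–Hastings:

* parameters and bounds: ODI ∈ [0, 1], d∥ ∈ [0, 4] μm²/ms (free water
  at body temperature is ≈ 3–3.1 μm²/ms); a single free noise
  parameter is bounded to [0, 0.5·S0]; when both c and ε are free they
  are instead constrained to 50–150% of prior estimates from a Rician
  fit to pure-noise samples (ventricle-like voxels), because the two
  are strongly degenerate (posterior correlation ≈ −0.99 in the
  packaged experiments);
* likelihood: independent Gaussian residuals between the data and the
  forward-mapped model with the residual variance profiled out
  analytically (log L = −(n/2)·log SSR).  The spherical means are
  recomputed from the noise-corrected data at the *proposal's* (c, ε)
  on every step, so the noise parameters genuinely shape the objective;
* initialisation: exhaustive grid search (default 32 points per
  parameter; Watson-stick kernels cached per (ODI, d∥) node, noise axes
  vectorised), ties broken toward smaller d∥ then smaller ODI;
* sampling: Gaussian proposals on one coordinate at a time with hard
  bound rejection; proposal scales adapted toward 20–50% acceptance
  during burn-in only, so the recorded chain has a fixed kernel.
  Defaults are 20 000 recorded sweeps after 5 000 burn-in; the packaged
  experiment drivers and the acceptance script use 6 000/2 000, which
  reproduces posterior means to well within their Monte-Carlo error at
  a fraction of the cost.  Everything is seeded and re-runs are bitwise
  identical.

The assumed measurement model ("offset" = Gaussian noise, Eq. Y = S+c;
"rician" = floor) is selected independently of what the data actually
are, which is how the misspecification experiments express fitting
magnitude data under a naive Gaussian assumption or real-valued data
under a Rician one.

## Numerics of the matrix-argument ₁F₁

The function is evaluated in the eigenbasis of its argument; only the
eigenvalues matter, so the evaluator is exactly rotation invariant.
With sorted eigenvalues a ≥ c ≥ b, the azimuthal part of the sphere
integral has the closed form 2π·exp(...)·I₀((a−b)(1−u²)/2), leaving a
single Gauss–Legendre quadrature over the polar coordinate u ∈ [0, 1].
The integrand is written with the exponentially scaled Bessel function
`i0e` so that it is bounded by 1 and the log of the result never
overflows at any concentration.  The quadrature order escalates as
⌈2.2√spread⌉ + 8 with the eigenvalue spread (measured accuracy ~1e-11
against order 512); the default order 64 (32 in the fitting hot loop)
is exact to ~1e-13 for the κ ≤ 300 regime the fits inhabit.  Above
κ = 1e5 the Watson distribution is numerically a delta function and the
stick closed form exp(−b d∥ (gᵀμ)²) is used instead.  For the
rank-deficient argument κμμᵀ − b d∥ ggᵀ that the signal model needs,
the eigenvalues are computed analytically from the 2×2 restriction to
span{μ, g} (λ± = ((κ−t) ± √((κ−t)² + 4κt sin²α))/2, third eigenvalue
0), avoiding per-call matrix diagonalisation.

Other numerical choices: the powder average uses the series
1 − bd/3 + O((bd)²) below bd = 1e-12 (the erf form is 0/0 there); ODI = 0
is represented by κ = ∞ and handled by the stick branch; shells are
inferred by grouping b-values within 0.1 ms/μm².

## The synthetic-data generator

`SimulationConfig` encodes the study conditions: three shells at
b = 6.75, 9.85, 13.5 ms/μm² with 64 directions each (spherical-Fibonacci
lattices, independently rotated per shell by a seeded random rotation)
plus 6 b=0 volumes; ground truth d∥ = 2.2 μm²/ms, ODI = 0.03,
f_in = 0.6, offset c = 10; per-voxel SNR S0/σ = 16.5.  S0 is fixed at
100 signal units — only S0/σ matters, and c = 10 is then 10% of S0.
The b=0 count is a package choice (the protocol being emulated
intersperses them); it only affects bookkeeping, not the high-b fit.

Noise enters the complex signal: both quadratures receive independent
Gaussian noise of std σ.  The magnitude channel |z| is Rician; the
real channel assumes perfect background-phase removal and is Gaussian.
Both are extracted from the same complex draws, so real/magnitude
comparisons are noise-matched.  Voxels sharing a fixed, known fibre
orientation are averaged without interpolation (SNR grows as √N), or
concatenated after rotating each voxel's gradient table so its fibre
axis maps onto a common axis with a random azimuthal roll — the signal
values themselves are never resampled.

What the generator does *not* emulate: spatially correlated noise,
eddy/susceptibility/motion artefacts, gradient nonlinearity, imperfect
phase removal, across-voxel variation in (d∥, ODI, S0), diffusion-time
dependence and finite axon radius.  Passing tests therefore demonstrate
correctness of the estimator under the stated noise model, not
robustness to everything real data contain.

## Standard NODDI with settable d∥

For the sensitivity analysis, the classic three-compartment model is
implemented with S/S0 = f_iso·e^(−3b) + (1−f_iso)·[f_in·A_stick +
(1−f_in)·A_zeppelin], the zeppelin obeying the tortuosity constraint
d⊥ = d∥(1−f_in), d_iso = 3 μm²/ms, and both anisotropic kernels
convolved with the same Watson ODF through the same hypergeometric
machinery (a Watson-convolved zeppelin is e^(−b d⊥) times a stick
kernel of diffusivity d∥ − d⊥; no separate closed form is assumed).
The five free parameters [f_in, f_iso, θ, φ, ODI] are sampled by the
same MH machinery with d∥ held at a user-chosen value (1.7 by
tradition; the sensitivity experiment refits at 1.7 and 3.0).  The fit
uses the same profiled-Gaussian likelihood as the high-b model; no
Rician likelihood is used anywhere in the package.

On noiseless synthetic voxels the direction of change when raising the
assumed d∥ from 1.7 to 3.0 — f_iso toward zero, intra-axonal fraction
and ODI up — is reproduced robustly.  The sign of the *extra-axonal*
fraction change depends on the voxel's composition: it decreases for
coherent, high-f_in white-matter-like voxels (the regime the model is
intended for, and the regime the packaged test uses) but can increase
for low-f_in/high-dispersion compositions.

## Misspecification behaviour worth knowing

* The c–ε degeneracy is real and strong: with both free and
  unconstrained, offset and floor trade off almost perfectly (a floor
  can absorb a missing offset and vice versa).  Hence the 50–150% band.
* Correcting magnitude data with the *true* complex-noise std ε = σ is
  not neutral: where the per-volume non-centrality is below ≈ 2σ
  (high-b signal without offset), the positivity clamp biases the
  spherical mean upward and d∥/ODI with it.  The floor value that best
  recovers the ground truth is above σ.  With the default offset c = 10
  the per-volume non-centrality stays above ≈ 3σ and correcting with
  ε = σ is near-unbiased.
* Fitting magnitude data while assuming Gaussian noise (ε pinned at 0
  with the offset pinned at truth) overestimates both d∥ and ODI and
  inflates their posterior spread; letting c float instead lets the
  offset absorb most of the floor (the same degeneracy, working in the
  analyst's favour).
* Fitting real-valued (floorless) data with a free Rician floor drives
  ε to zero, as it should.

## Problem sizes

The packaged experiments default to desk scale: 100-voxel averages,
6 000 recorded sweeps after 2 000 burn-in, 10 seeds for the recovery
study, 5 repeats per condition for the SNR sweep over
N ∈ {1, 25, 100, 400, 1000} (the acceptance checks use {1, 25, 100,
1000}).  A `full=True` / `--full` switch selects 20 repeats and
20 000/5 000 chains.  Posterior *means* are stable across these chain
lengths; posterior tail quantiles benefit from the long chains.

## Known limitations

Single fibre population with symmetric (Watson) dispersion only; no
Bingham asymmetry; orientation is normally held fixed at the supplied
V1 (a `free_orientation` flag exists for very high SNR data); no
diffusion-time or axon-diameter dependence (pulse timings are carried
as metadata only); no full Rician likelihood — the Gaussian-residual
likelihood with explicit floor/offset forward modelling is used
instead, which is exactly the regime the misspecification experiments
probe.
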