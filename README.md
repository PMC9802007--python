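# noddax

Estimating intra-axonal axial diffusivity and orientation dispersion
from high b-value diffusion MRI.

The NODDI family of biophysical models normally *assumes* the
intra-axonal axial diffusivity (classically d∥ = 1.7 μm²/ms), although
most modern measurements put it at 2–2.5 μm²/ms; whatever value is
assumed propagates into every other fitted parameter.  `noddax` is for
researchers who want to (a) quantify how sensitive standard NODDI
outputs are to that assumption, and (b) *estimate* d∥ instead, by
fitting an intra-axonal-only model to ultra-high b-value data
(b ≈ 7–14 ms/μm²), where extra-axonal water is fully attenuated.

The core model is a Watson-dispersed stick.  The directional signal

S(b,g) = F · ₁F₁(½; 3⁄2; κμμᵀ − b d∥ ggᵀ) / ₁F₁(½; 3⁄2; κμμᵀ),  F = f_in S0,

is divided by the per-shell spherical mean
S̄_b = F·√π·erf(√(b d∥))/(2√(b d∥)) (exact for sticks under any
orientation distribution), leaving two shape parameters: d∥ and the
orientation dispersion index ODI = (2/π)arctan(1/κ).  Because high-b
data are low-SNR, the measurement model additionally carries a signal
offset c (Y = S + c for real-valued data) and, for magnitude data, a
rectified Rician noise floor ε (Y = √((S+c)² + ε²)); both are estimated
inside the fit.  Posteriors come from grid-search-initialised
Metropolis–Hastings sampling.  A standard three-compartment NODDI
forward model with user-settable d∥, a synthetic-data simulator, a
diffusion-tensor utility (for the fixed fibre orientation V1) and
reproducible experiment drivers round out the package.  See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate 100 voxels at the default study conditions (3 shells at
b = 6.75/9.85/13.5 ms/μm², 64 directions each, per-voxel SNR 16.5,
ground truth d∥ = 2.2 μm²/ms, ODI = 0.03, offset c = 10), average them,
and fit the real-valued variant:

```python
from noddax import (SimulationConfig, simulate_voxels, average_voxels,
                    FitConfig, mh_fit)

cfg = SimulationConfig(n_voxels=100, seed=7)
real, magnitude = simulate_voxels(cfg)          # paired noise draws
est = mh_fit(average_voxels(real), FitConfig(n_samples=6000, burn_in=2000, seed=1))
print(est.summary_.round(4))
```

```
              mean     std     q05   median      q95
parameter
odi         0.0299  0.0012  0.0279   0.0300   0.0319
d_par       2.1526  0.0819  2.0117   2.1532   2.2853
c          10.0403  0.0520  9.9536  10.0397  10.1259
```

The posterior means sit on the generating values: d∥ = 2.15 ± 0.08
μm²/ms against a ground truth of 2.2 (single noise realisations scatter
by about ±0.15), ODI = 0.030 against 0.030, and the offset c = 10.04
against 10.  `est` is a scikit-learn-style estimator: `est.predict()`
returns the fitted signal, `est.samples_.draws` the full MH chain.

The same machinery drives the packaged experiments (posterior shape for
real vs magnitude data, precision vs number of averaged voxels,
noise-model misspecification) from the command line:

```bash
noddax simulate --n-voxels 100 --seed 7 --average --out-prefix out/sim
noddax fit --data-prefix out/sim_real --seed 1 --out out/fit.json
noddax exp-snr --seed 0 --out out/snr.csv
noddax exp-misspec --seed 0 --out-dir out/misspec
```

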