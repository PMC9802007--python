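"""Noise forward models, noise-corrected powder averaging and pure-noise
characterisation.

Two measurement models link the noiseless diffusion signal S to the data Y:

* real-valued data (background phase removed, Gaussian noise):
      Y = S + c
* magnitude data (Rician, rectified noise floor):
      Y = sqrt((S + c)^2 + eps^2)

c is a diffusion-weighting-independent signal offset (sometimes called a
dot compartment); eps is the Rician scale, i.e. the standard deviation of
the Gaussian noise in each complex channel.  Before computing spherical
means the data are inverted back to S (Koay-style inversion for
magnitude), because the floor and offset would otherwise bias the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .scheme import AcquisitionScheme

__all__ = [
    "NoiseParams",
    "VoxelDataset",
    "apply_offset",
    "apply_rician_floor",
    "correct_signal",
    "corrected_powder_average",
    "fit_pure_noise",
    "snr_of_average",
]


@dataclass(frozen=True)
class NoiseParams:
    """Offset c, Rician scale eps and complex-channel std sigma, all in
    signal units.  For magnitude data eps plays the role of the complex
    Gaussian noise std."""

    c: float = 0.0
    epsilon: float = 0.0
    sigma: float | None = None

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("offset c must be non-negative")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive where used")


@dataclass
class VoxelDataset:
    """Per-voxel diffusion-weighted measurements.

    Y has shape (n_voxels, n_volumes); ``kind`` is "real" or "magnitude"
    (magnitude data must be non-negative); S0 is the non-diffusion-weighted
    signal per voxel.  ``orientation`` optionally records the fibre axis
    (shared (3,) vector or per-voxel (n_voxels, 3)).
    """

    Y: np.ndarray
    kind: str
    S0: np.ndarray
    scheme: AcquisitionScheme
    orientation: np.ndarray | None = None

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.S0 = np.atleast_1d(np.asarray(self.S0, dtype=float))
        if self.kind not in ("real", "magnitude"):
            raise ValueError("kind must be 'real' or 'magnitude'")
        if self.kind == "magnitude" and np.any(self.Y < 0):
            raise ValueError("magnitude data must be non-negative")
        if np.any(self.S0 <= 0):
            raise ValueError("S0 must be positive")
        if self.Y.shape[1] != len(self.scheme):
            raise ValueError("Y must have one column per scheme volume")
        if self.Y.shape[0] != len(self.S0):
            raise ValueError("S0 must have one entry per voxel")

    @property
    def n_voxels(self):
        return self.Y.shape[0]


def apply_offset(S, c: float):
    """Forward model for real-valued data: Y = S + c."""
    if c < 0:
        raise ValueError("offset c must be non-negative")
    return np.asarray(S, dtype=float) + c


def apply_rician_floor(S, c: float, epsilon: float):
    """Forward model for magnitude data: Y = sqrt((S + c)^2 + eps^2).

    Reduces to the plain offset model at eps = 0.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return np.sqrt(apply_offset(S, c) ** 2 + epsilon**2)


def correct_signal(Y, kind: str, noise: NoiseParams):
    """Invert the measurement model, converting data Y back to signal S.

    magnitude: S = Re(sqrt(Y^2 - eps^2)) - c  (values with Y < eps clamp
    the root to zero before the offset subtraction); real: S = Y - c.
    """
    Y = np.asarray(Y, dtype=float)
    if kind == "magnitude":
        return np.sqrt(np.maximum(Y**2 - noise.epsilon**2, 0.0)) - noise.c
    if kind == "real":
        return Y - noise.c
    raise ValueError("kind must be 'real' or 'magnitude'")


def corrected_powder_average(dataset: VoxelDataset, noise: NoiseParams, order="correct_then_mean"):
    """Noise-corrected spherical mean per b > 0 shell.

    Each measurement is first converted from Y to S with
    :func:`correct_signal` and then averaged within its shell (over all
    voxels and directions).  ``order="mean_then_correct"`` averages first
    and corrects the shell mean instead; off by default.

    Returns
    -------
    dict mapping shell id -> spherical mean, for shells with b > 0.
    """
    if order not in ("correct_then_mean", "mean_then_correct"):
        raise ValueError(f"unknown order {order!r}")
    out = {}
    for s in dataset.scheme.shells:
        mask = dataset.scheme.shell_mask(s)
        if dataset.scheme.b[mask][0] <= 0:
            continue
        block = dataset.Y[:, mask]
        if block.size == 0:
            raise ValueError(f"shell {int(s)} has no measurements")
        if order == "correct_then_mean":
            out[int(s)] = float(np.mean(correct_signal(block, dataset.kind, noise)))
        else:
            out[int(s)] = float(correct_signal(np.mean(block), dataset.kind, noise))
    if not out:
        raise ValueError("no b > 0 shells in dataset")
    return out


def _rician_loglik(params, x):
    nu, sigma = params
    return np.sum(stats.rice.logpdf(x, b=nu / sigma, scale=sigma))


def fit_pure_noise(samples, family: str):
    """Maximum-likelihood noise characterisation of pure-noise samples
    (e.g. ventricle voxels at very high b).

    family="rician" fits (non-centrality nu, scale sigma) — nu estimates
    the signal offset c and sigma the floor parameter eps.  family=
    "gaussian" fits (mean, std).  Standard errors come from the observed
    information (numerical Hessian of the log-likelihood at the MLE).

    Returns
    -------
    dict with keys c, epsilon (or mean/std aliases), and their standard
    errors; plus a NoiseParams under "params".
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 pure-noise samples")
    if family == "gaussian":
        mean, std = float(np.mean(x)), float(np.std(x, ddof=1))
        n = len(x)
        return {
            "family": "gaussian",
            "c": mean,
            "epsilon": 0.0,
            "sigma": std,
            "se_c": std / np.sqrt(n),
            "se_sigma": std / np.sqrt(2.0 * (n - 1)),
            "params": NoiseParams(c=max(mean, 0.0), epsilon=0.0, sigma=std),
        }
    if family != "rician":
        raise ValueError("family must be 'rician' or 'gaussian'")
    if np.any(x <= 0):
        raise ValueError("rician samples must be positive")
    # method-of-moments start: E[Y^2] = nu^2 + 2 sigma^2, Var approx sigma^2
    m2 = np.mean(x**2)
    var = np.var(x)
    sigma0 = np.sqrt(max(var, 1e-12))
    nu0 = np.sqrt(max(m2 - 2.0 * sigma0**2, 1e-12))
    res = optimize.minimize(
        lambda p: -_rician_loglik(p, x),
        x0=[nu0, sigma0],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    nu, sigma = res.x
    # observed information via central differences
    h = np.maximum(np.abs(res.x), 1e-3) * 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = res.x.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = res.x.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = res.x.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = res.x.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = (
                _rician_loglik(pp, x)
                - _rician_loglik(pm, x)
                - _rician_loglik(mp, x)
                + _rician_loglik(mm, x)
            ) / (4.0 * h[i] * h[j])
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return {
        "family": "rician",
        "c": float(nu),
        "epsilon": float(sigma),
        "se_c": float(se[0]),
        "se_epsilon": float(se[1]),
        "converged": bool(res.success),
        "params": NoiseParams(c=max(float(nu), 0.0), epsilon=float(sigma), sigma=float(sigma)),
    }


def snr_of_average(snr_vox: float, n: int):
    """SNR of the signal averaged over n voxels: SNR_vox * sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(snr_vox) * np.sqrt(n)
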