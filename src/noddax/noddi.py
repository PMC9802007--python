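"""Three-compartment NODDI forward model with a user-settable axial
diffusivity, and its MH fit.

The normalised signal is

    S/S0 = f_iso exp(-b d_iso)
         + (1 - f_iso) [ f_in A_stick + (1 - f_in) A_zeppelin ],

where both anisotropic kernels are convolved with the same Watson
orientation distribution.  The stick has diffusivity d_par along the
fibre and zero across it; the zeppelin (extra-axonal tensor) has the same
axial diffusivity with the tortuosity constraint d_perp = d_par (1 -
f_in); the isotropic ball has d_iso = 3 um^2/ms (free water).  d_par is a
fixed, assumed value (classically 1.7 um^2/ms) — the point of the
sensitivity analysis is how strongly the five fitted parameters
[f_in, f_iso, theta, phi, ODI] depend on that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mh import metropolis_hastings
from .noise import VoxelDataset
from .scheme import AcquisitionScheme
from .signal import DispersionIndex, FibreOrientation, watson_stick_log_kernel
from .simulate import fibonacci_directions

__all__ = [
    "NoddiParams",
    "noddi_forward",
    "NoddiWatsonMH",
    "noddi_fit_fixed_dpar",
    "sensitivity_report",
    "hcp_style_scheme",
]

D_ISO = 3.0  # um^2/ms, free water


@dataclass(frozen=True)
class NoddiParams:
    """NODDI parameter set; d_par_fixed is assumed, not fitted."""

    f_in: float
    f_iso: float
    orientation: FibreOrientation
    dispersion: DispersionIndex
    d_par_fixed: float

    def __post_init__(self):
        if not 0.0 <= self.f_in <= 1.0 or not 0.0 <= self.f_iso <= 1.0:
            raise ValueError("signal fractions must lie in [0, 1]")
        if self.d_par_fixed < 0:
            raise ValueError("d_par_fixed must be non-negative")

    @property
    def d_perp(self):
        """Tortuosity model: d_perp = d_par (1 - f_in)."""
        return self.d_par_fixed * (1.0 - self.f_in)

    @property
    def f_aniso(self):
        return 1.0 - self.f_iso


def hcp_style_scheme(n_b0: int = 18, n_dirs: int = 90, seed: int = 0) -> AcquisitionScheme:
    """Low-b multi-shell scheme (b = 1, 2, 3 ms/um^2, 90 directions each,
    18 b0 volumes) of the kind used for standard NODDI fitting."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4C9]))
    b = [np.zeros(n_b0)]
    g = [np.tile([0.0, 0.0, 1.0], (n_b0, 1))]
    for bval in (1.0, 2.0, 3.0):
        b.append(np.full(n_dirs, bval))
        g.append(fibonacci_directions(n_dirs, rng))
    return AcquisitionScheme(b=np.concatenate(b), g=np.vstack(g))


def noddi_forward(params: NoddiParams, scheme: AcquisitionScheme, order: int = 48):
    """Normalised NODDI signal S/S0 per volume (equals 1 at b = 0).

    Both the stick and the zeppelin are convolved with the Watson ODF via
    the same matrix-argument hypergeometric kernel as the high-b model:
    a zeppelin exp(-b d_perp - b (d_par - d_perp) (g.x)^2) convolved with
    the Watson ODF is exp(-b d_perp) times a stick kernel of diffusivity
    d_par - d_perp.
    """
    mu = params.orientation.mu
    cos_alpha = scheme.g @ mu
    kappa = params.dispersion.kappa
    b = scheme.b
    a_stick = np.exp(
        watson_stick_log_kernel(kappa, b * params.d_par_fixed, cos_alpha, order=order)
    )
    a_zepp = np.exp(-b * params.d_perp) * np.exp(
        watson_stick_log_kernel(
            kappa, b * (params.d_par_fixed - params.d_perp), cos_alpha, order=order
        )
    )
    a_iso = np.exp(-b * D_ISO)
    return params.f_iso * a_iso + (1.0 - params.f_iso) * (
        params.f_in * a_stick + (1.0 - params.f_in) * a_zepp
    )


class NoddiWatsonMH(BaseEstimator):
    """Standard NODDI fit with fixed axial diffusivity by MH sampling.

    fit(X, y): X is the scheme (or (n, 4) design), y the *normalised*
    signal (Y/S0).  Samples [f_in, f_iso, theta, phi, odi] under the
    profiled-Gaussian likelihood; d_par is the assumed constant.

    Attributes: f_in_, f_iso_, odi_, theta_, phi_ (posterior means),
    samples_, summary_, acceptance_rate_.
    """

    def __init__(
        self,
        d_par_fixed: float = 1.7,
        n_samples: int = 4000,
        burn_in: int = 1500,
        quadrature_order: int = 32,
        random_state: int | None = None,
    ):
        self.d_par_fixed = d_par_fixed
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.quadrature_order = quadrature_order
        self.random_state = random_state

    def _predict_vec(self, x, cos_cache):
        f_in, f_iso, theta, phi, odi = x
        scheme, = cos_cache
        p = NoddiParams(
            f_in=f_in,
            f_iso=f_iso,
            orientation=FibreOrientation(theta, phi),
            dispersion=DispersionIndex.from_odi(odi) if odi > 0 else DispersionIndex.from_kappa(np.inf),
            d_par_fixed=self.d_par_fixed,
        )
        return noddi_forward(p, scheme, order=self.quadrature_order)

    def fit(self, X, y, mu0=None):
        scheme = X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n != len(scheme):
            raise ValueError("y must have one value per volume")
        cache = (scheme,)

        def log_post(x):
            yhat = self._predict_vec(x, cache)
            ssr = float(np.sum((y - yhat) ** 2))
            return -0.5 * n * np.log(max(ssr, 1e-300))

        if mu0 is None:
            mu0 = np.array([0.0, 0.0, 1.0])
        mu0 = np.asarray(mu0, dtype=float)
        theta0 = float(np.arccos(np.clip(abs(mu0[2]), -1, 1)))
        phi0 = float(np.mod(np.arctan2(mu0[1], mu0[0]), 2 * np.pi))
        # coarse grid on (f_in, f_iso, odi) at the supplied orientation
        best, x0 = np.inf, None
        for f_in in np.linspace(0.05, 0.95, 7):
            for f_iso in np.linspace(0.0, 0.6, 7):
                for odi in (0.01, 0.05, 0.15, 0.3, 0.6):
                    x = np.array([f_in, f_iso, theta0, phi0, odi])
                    val = -log_post(x)
                    if val < best:
                        best, x0 = val, x
        bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, np.pi), (0.0, 2 * np.pi), (1e-4, 1.0)]
        rng = np.random.default_rng(self.random_state)
        self.samples_ = metropolis_hastings(
            log_post,
            x0,
            bounds,
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            rng=rng,
            param_names=["f_in", "f_iso", "theta", "phi", "odi"],
            seed=self.random_state,
        )
        m = self.samples_.mean()
        self.f_in_ = float(m["f_in"])
        self.f_iso_ = float(m["f_iso"])
        self.theta_ = float(m["theta"])
        self.phi_ = float(m["phi"])
        self.odi_ = float(m["odi"])
        self.summary_ = self.samples_.summary()
        self.acceptance_rate_ = self.samples_.acceptance_rate
        self._scheme = scheme
        return self

    def predict(self, X=None):
        scheme = self._scheme if X is None else (
            X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        )
        return self._predict_vec(
            np.array([self.f_in_, self.f_iso_, self.theta_, self.phi_, self.odi_]),
            (scheme,),
        )


def noddi_fit_fixed_dpar(
    dataset: VoxelDataset,
    d_par_fixed: float,
    n_samples: int = 4000,
    burn_in: int = 1500,
    seed: int = 0,
    mu0=None,
):
    """Fit standard NODDI (fractions, orientation, ODI) per voxel with the
    supplied assumed axial diffusivity.  Returns a list of fitted
    :class:`NoddiWatsonMH`, one per voxel."""
    out = []
    for v in range(dataset.n_voxels):
        est = NoddiWatsonMH(
            d_par_fixed=d_par_fixed,
            n_samples=n_samples,
            burn_in=burn_in,
            random_state=seed + v,
        )
        est.fit(dataset.scheme, dataset.Y[v] / dataset.S0[v], mu0=mu0)
        out.append(est)
    return out


def sensitivity_report(posteriors: dict) -> pd.DataFrame:
    """Percentage change of NODDI parameters across assumed diffusivities.

    ``posteriors`` maps an assumed d_par value to a list of fitted
    estimators (matched voxel sets).  The report gives, per parameter,
    the per-voxel ratio (highest vs lowest assumed d_par) in percent with
    across-voxel summaries.  Ratios with near-zero denominators are
    flagged undefined (NaN) rather than infinite.
    """
    keys = sorted(posteriors)
    if len(keys) < 2:
        raise ValueError("need posteriors for at least two assumed d_par values")
    lo, hi = keys[0], keys[-1]
    if len(posteriors[lo]) != len(posteriors[hi]):
        raise ValueError("voxel sets must be matched across assumed d_par values")
    def _row(name, num, den):
        ok = np.abs(den) > 1e-6
        ratio = np.where(ok, 100.0 * num / np.where(ok, den, 1.0), np.nan)
        valid = ratio[ok]
        return {
            "parameter": name,
            "ratio_pct_mean": float(np.mean(valid)) if valid.size else np.nan,
            "ratio_pct_median": float(np.median(valid)) if valid.size else np.nan,
            "n_undefined": int((~ok).sum()),
            "d_par_hi": hi,
            "d_par_lo": lo,
        }

    rows = []
    for name in ("f_in", "f_iso", "odi"):
        num = np.array([getattr(e, f"{name}_") for e in posteriors[hi]])
        den = np.array([getattr(e, f"{name}_") for e in posteriors[lo]])
        rows.append(_row(name, num, den))
    # derived gross fractions
    for label, f in (
        ("f_in_x_faniso", lambda e: e.f_in_ * (1.0 - e.f_iso_)),
        ("f_ex_x_faniso", lambda e: (1.0 - e.f_in_) * (1.0 - e.f_iso_)),
    ):
        num = np.array([f(e) for e in posteriors[hi]])
        den = np.array([f(e) for e in posteriors[lo]])
        rows.append(_row(label, num, den))
    return pd.DataFrame(rows)
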