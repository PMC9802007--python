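"""Grid-search-initialised Metropolis-Hastings estimation of the
dispersed-stick model with explicit noise parameters.

The model fitted to the high-b shells of one (possibly averaged or
concatenated) voxel is the spherical-mean-normalised dispersed-stick
signal combined with a measurement model:

    real data       Y = Sbar_b * K(b, g; ODI, d_par) / P(b d_par) + c
    magnitude data  Y = sqrt((... + c)^2 + eps^2)

where K is the Watson-stick attenuation kernel and P the stick powder
average.  Sbar_b is not a parameter: it is recomputed per shell from the
noise-corrected data at the *current* (c, eps) on every proposal, so the
noise parameters shape the objective.  The fibre orientation is held
fixed (normally the diffusion-tensor V1).

The likelihood is an independent-Gaussian residual model with the
residual variance profiled out analytically, log L = -(n/2) log SSR.
Parameters are bounded (ODI in [0,1], d_par in [0,4] um^2/ms; a single
free noise parameter in [0, 0.5 S0], or a joint (c, eps) band at 50-150%
of prior pure-noise estimates) and sampled with component-wise MH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mh import PosteriorSamples, metropolis_hastings
from .noise import VoxelDataset
from .scheme import AcquisitionScheme
from .signal import powder_average_model, watson_stick_log_kernel
from .watson import odi_to_kappa

__all__ = ["FitConfig", "WatsonStickMH", "grid_search_init", "mh_fit", "fixed_noise_sweep"]


@dataclass(frozen=True)
class FitConfig:
    """Sampler and grid settings for the dispersed-stick fit."""

    odi_bounds: tuple = (0.0, 1.0)
    d_par_bounds: tuple = (0.0, 4.0)
    grid_points: int = 32
    n_samples: int = 20_000
    burn_in: int = 5_000
    min_b: float = 2.0
    quadrature_order: int = 32
    sbar_policy: str = "correct_then_mean"
    seed: int = 0
    proposal_scales: dict = field(default_factory=dict)


class _RatioObjective:
    """Cached evaluation of the profiled-Gaussian log posterior.

    ``model`` is the *assumed* measurement model ("offset" or "rician"),
    which governs both the data-to-signal correction used for the
    spherical means and the forward noise map — deliberately independent
    of what the data actually are, so that misspecified fits (e.g. a
    Gaussian assumption on magnitude data) can be expressed.
    """

    def __init__(self, y, scheme, mu, model, order):
        mask = scheme.weighted
        self.b = scheme.b[mask]
        self.y = np.asarray(y, dtype=float)[mask]
        if model not in ("offset", "rician"):
            raise ValueError("model must be 'offset' or 'rician'")
        self.model = model
        self.floor = model == "rician"
        self.order = order
        self.n = int(mask.sum())
        g = scheme.g[mask]
        mu = np.asarray(mu, dtype=float)
        self.cos_alpha = g @ (mu / np.linalg.norm(mu))
        sid = scheme.shell_id[mask]
        self.shell_ids = np.unique(sid)
        self.shell_slices = [sid == s for s in self.shell_ids]
        self.vol_shell = np.searchsorted(self.shell_ids, sid)
        self.shell_y = [self.y[sl] for sl in self.shell_slices]
        self._kernel_key = None
        self._kernel_val = None

    def sbar(self, c, eps):
        """Per-shell spherical mean of the noise-corrected data."""
        if self.floor and eps > 0:
            means = np.array(
                [np.mean(np.sqrt(np.maximum(ys**2 - eps**2, 0.0))) for ys in self.shell_y]
            )
        else:
            means = np.array([np.mean(ys) for ys in self.shell_y])
        return means - c

    def model_over_sbar(self, odi, d_par):
        """exp(kernel)/powder per volume, cached on (odi, d_par)."""
        key = (odi, d_par)
        if key != self._kernel_key:
            kappa = np.inf if odi == 0 else odi_to_kappa(odi)
            logk = watson_stick_log_kernel(
                kappa, self.b * d_par, self.cos_alpha, order=self.order
            )
            self._kernel_val = np.exp(logk) / powder_average_model(self.b, d_par)
            self._kernel_key = key
        return self._kernel_val

    def predict(self, odi, d_par, c, eps):
        sbar = self.sbar(c, eps)
        if np.any(sbar <= 0):
            return None
        S = sbar[self.vol_shell] * self.model_over_sbar(odi, d_par)
        if self.floor:
            return np.sqrt((S + c) ** 2 + eps**2)
        return S + c

    def log_post(self, odi, d_par, c, eps):
        yhat = self.predict(odi, d_par, c, eps)
        if yhat is None:
            return -np.inf
        ssr = float(np.sum((self.y - yhat) ** 2))
        if ssr <= 0:
            ssr = 1e-300
        return -0.5 * self.n * np.log(ssr)


class WatsonStickMH(BaseEstimator):
    """Dispersed-stick model fitted by grid-search-initialised MH.

    Parameters
    ----------
    data_kind : {"real", "magnitude"}
        Noise character of the data; selects the default measurement model
        (offset-only for real, offset + Rician floor for magnitude).
    noise_model : {"offset", "rician"} or None
        Override the measurement model, e.g. to deliberately fit magnitude
        data under a Gaussian assumption ("offset") or real data with a
        floor ("rician").
    fix_c, fix_epsilon : float or None
        Pin a noise parameter instead of sampling it.
    noise_prior : (c0, eps0) or None
        Prior pure-noise estimates; when both c and eps are free they are
        constrained to 50-150% of these.
    free_orientation : bool
        Also sample (theta, phi); for very high SNR use only.
    n_samples, burn_in : int
        Recorded / adaptation MH sweeps.
    min_b : float
        Shells with b below this (ms/um^2) are excluded from the fit.
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    odi_, d_par_, c_, epsilon_ : posterior means
    samples_ : PosteriorSamples
    summary_ : DataFrame of posterior summaries
    grid_init_ : dict, grid-search starting point
    acceptance_rate_ : dict per sampled parameter
    sbar_ : dict, shell b-value -> corrected spherical mean at the
        posterior-mean noise parameters
    """

    def __init__(
        self,
        data_kind: str = "real",
        noise_model: str | None = None,
        fix_c: float | None = None,
        fix_epsilon: float | None = None,
        noise_prior: tuple | None = None,
        free_orientation: bool = False,
        odi_bounds: tuple = (0.0, 1.0),
        d_par_bounds: tuple = (0.0, 4.0),
        grid_points: int = 32,
        n_samples: int = 20_000,
        burn_in: int = 5_000,
        min_b: float = 2.0,
        quadrature_order: int = 32,
        sbar_policy: str = "correct_then_mean",
        random_state: int | None = None,
    ):
        self.data_kind = data_kind
        self.noise_model = noise_model
        self.fix_c = fix_c
        self.fix_epsilon = fix_epsilon
        self.noise_prior = noise_prior
        self.free_orientation = free_orientation
        self.odi_bounds = odi_bounds
        self.d_par_bounds = d_par_bounds
        self.grid_points = grid_points
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.min_b = min_b
        self.quadrature_order = quadrature_order
        self.sbar_policy = sbar_policy
        self.random_state = random_state

    # -- layout -----------------------------------------------------------
    def _noise_model(self):
        if self.noise_model is not None:
            return self.noise_model
        return "rician" if self.data_kind == "magnitude" else "offset"

    def _free_params(self):
        free = ["odi", "d_par"]
        if self.fix_c is None:
            free.append("c")
        if self._noise_model() == "rician" and self.fix_epsilon is None:
            free.append("epsilon")
        if self.free_orientation:
            free += ["theta", "phi"]
        return free

    def _noise_bounds(self, s0):
        free = self._free_params()
        both = "c" in free and "epsilon" in free
        if both and self.noise_prior is not None:
            c0, e0 = self.noise_prior
            return {"c": (0.5 * c0, 1.5 * c0), "epsilon": (0.5 * e0, 1.5 * e0)}
        hi = 0.5 * s0
        return {"c": (0.0, hi), "epsilon": (0.0, hi)}

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, mu=None, s0=None):
        scheme = X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(scheme):
            raise ValueError("y must have one value per scheme volume")
        if mu is None:
            raise ValueError("a fixed fibre orientation mu (e.g. DTI V1) is required")
        mu = np.asarray(mu, dtype=float)
        if s0 is None:
            b0 = scheme.b < 1e-9
            s0 = float(np.mean(y[b0])) if b0.any() else float(np.max(y))
        high = scheme.b >= self.min_b
        if len(np.unique(scheme.shell_id[high])) < 2:
            raise ValueError("need at least 2 shells above min_b")
        scheme_high = scheme.subset(high)
        obj = _RatioObjective(
            y[high], scheme_high, mu, self._noise_model(), self.quadrature_order
        )
        if self.sbar_policy != "correct_then_mean":
            raise NotImplementedError("only correct_then_mean sbar policy is sampled")

        free = self._free_params()
        nb = self._noise_bounds(s0)
        bounds_map = {
            "odi": tuple(self.odi_bounds),
            "d_par": tuple(self.d_par_bounds),
            "c": nb["c"],
            "epsilon": nb["epsilon"],
            "theta": (0.0, np.pi),
            "phi": (0.0, 2.0 * np.pi),
        }
        fixed = {
            "c": 0.0 if self.fix_c is None else float(self.fix_c),
            "epsilon": 0.0 if self.fix_epsilon is None else float(self.fix_epsilon),
        }
        if self._noise_model() == "offset":
            fixed["epsilon"] = 0.0 if self.fix_epsilon is None else float(self.fix_epsilon)

        if self.free_orientation:

            def log_post_vec(x):
                d = dict(zip(free, x))
                o = _RatioObjective(
                    y[high],
                    scheme_high,
                    _angles_to_vec(d["theta"], d["phi"]),
                    self._noise_model(),
                    self.quadrature_order,
                )
                return o.log_post(
                    d["odi"], d["d_par"], d.get("c", fixed["c"]), d.get("epsilon", fixed["epsilon"])
                )

        else:

            def log_post_vec(x):
                d = dict(zip(free, x))
                return obj.log_post(
                    d["odi"], d["d_par"], d.get("c", fixed["c"]), d.get("epsilon", fixed["epsilon"])
                )

        init = grid_search_init(
            obj,
            free,
            bounds_map,
            fixed,
            grid_points=self.grid_points,
        )
        if self.free_orientation:
            m = mu / np.linalg.norm(mu)
            init["theta"] = float(np.arccos(np.clip(m[2], -1, 1)))
            init["phi"] = float(np.mod(np.arctan2(m[1], m[0]), 2.0 * np.pi))
        x0 = np.array([init[p] for p in free])
        rng = np.random.default_rng(self.random_state)
        self.samples_ = metropolis_hastings(
            log_post_vec,
            x0,
            [bounds_map[p] for p in free],
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            rng=rng,
            param_names=free,
            seed=self.random_state,
        )
        means = self.samples_.mean()
        self.grid_init_ = init
        self.odi_ = float(means["odi"])
        self.d_par_ = float(means["d_par"])
        self.c_ = float(means["c"]) if "c" in free else fixed["c"]
        self.epsilon_ = float(means["epsilon"]) if "epsilon" in free else fixed["epsilon"]
        self.acceptance_rate_ = self.samples_.acceptance_rate
        self.summary_ = self.samples_.summary()
        self.mu_ = mu / np.linalg.norm(mu)
        self.s0_ = s0
        self._objective = obj
        sb = obj.sbar(self.c_, self.epsilon_)
        self.sbar_ = {
            float(obj.b[sl][0]): float(v) for sl, v in zip(obj.shell_slices, sb)
        }
        return self

    def predict(self, X=None):
        """Model data Yhat at the posterior-mean parameters (training
        shells; X defaults to the fitted high-b scheme)."""
        obj = self._objective
        if X is None:
            return obj.predict(self.odi_, self.d_par_, self.c_, self.epsilon_)
        scheme = X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        o = _RatioObjective(
            np.zeros(len(scheme)), scheme, self.mu_, self._noise_model(), self.quadrature_order
        )
        # carry over the fitted spherical means, matched by shell b-value
        sbar = np.array([self.sbar_[min(self.sbar_, key=lambda k: abs(k - b))] for b in o.b])
        S = sbar * o.model_over_sbar(self.odi_, self.d_par_)
        if self.data_kind == "magnitude":
            return np.sqrt((S + self.c_) ** 2 + self.epsilon_**2)
        return S + self.c_


def _angles_to_vec(theta, phi):
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def grid_search_init(obj, free, bounds_map, fixed, grid_points: int = 32):
    """Exhaustive grid minimisation of the fit objective.

    Evaluates the sum of squared residuals on a regular grid of
    ``grid_points`` per free parameter (kernels cached per (odi, d_par)
    pair, noise axes vectorised) and returns the argmin as a dict.  Ties
    are broken toward smaller d_par, then smaller ODI, then smaller noise
    values.
    """
    if any(p in free for p in ("theta", "phi")):
        free = [p for p in free if p not in ("theta", "phi")]
    grids = {p: np.linspace(*bounds_map[p], grid_points) for p in free}
    c_vals = grids.get("c", np.array([fixed["c"]]))
    e_vals = grids.get("epsilon", np.array([fixed["epsilon"]]))

    # corrected per-shell means for every epsilon value: (n_eps, n_shells)
    if obj.floor:
        shell_means = np.stack(
            [
                np.array(
                    [np.mean(np.sqrt(np.maximum(ys**2 - e**2, 0.0))) for ys in obj.shell_y]
                )
                for e in e_vals
            ]
        )
    else:
        base = np.array([np.mean(ys) for ys in obj.shell_y])
        shell_means = np.tile(base, (len(e_vals), 1))
    # sbar per (eps, c, shell)
    sbar = shell_means[:, None, :] - c_vals[None, :, None]
    valid = np.all(sbar > 0, axis=2)  # (n_eps, n_c)

    best = (np.inf, None)
    records = []
    for odi in grids["odi"]:
        kappa = np.inf if odi == 0 else odi_to_kappa(odi)
        for d in grids["d_par"]:
            ratio = np.exp(
                watson_stick_log_kernel(kappa, obj.b * d, obj.cos_alpha, order=obj.order)
            ) / powder_average_model(obj.b, d)
            S = sbar[:, :, obj.vol_shell] * ratio[None, None, :]
            if obj.floor:
                yhat = np.sqrt((S + c_vals[None, :, None]) ** 2 + e_vals[:, None, None] ** 2)
            else:
                yhat = S + c_vals[None, :, None]
            ssr = np.sum((obj.y[None, None, :] - yhat) ** 2, axis=2)
            ssr = np.where(valid, ssr, np.inf)
            idx = np.unravel_index(np.argmin(ssr), ssr.shape)
            records.append((float(ssr[idx]), d, odi, c_vals[idx[1]], e_vals[idx[0]]))
    arr = np.array([r[0] for r in records])
    mn = arr.min()
    if not np.isfinite(mn):
        raise ValueError("grid search found no valid point (sbar <= 0 everywhere)")
    ties = [records[i] for i in np.flatnonzero(arr == mn)]
    ties.sort(key=lambda r: (r[1], r[2], r[3], r[4]))
    _, d, odi, c, e = ties[0]
    out = {"odi": float(odi), "d_par": float(d)}
    if "c" in grids:
        out["c"] = float(c)
    if "epsilon" in grids:
        out["epsilon"] = float(e)
    return out


def mh_fit(
    dataset: VoxelDataset,
    config: FitConfig = FitConfig(),
    mu=None,
    **estimator_kwargs,
):
    """Fit the dispersed-stick model to a (single-voxel) dataset.

    Thin wrapper over :class:`WatsonStickMH`; returns the fitted
    estimator (posterior draws under ``.samples_``).
    """
    if dataset.n_voxels != 1:
        raise ValueError("fit expects a single (averaged or concatenated) voxel")
    if mu is None:
        mu = dataset.orientation
    if mu is None:
        raise ValueError("dataset carries no orientation; pass mu explicitly")
    est = WatsonStickMH(
        data_kind=dataset.kind,
        odi_bounds=config.odi_bounds,
        d_par_bounds=config.d_par_bounds,
        grid_points=config.grid_points,
        n_samples=config.n_samples,
        burn_in=config.burn_in,
        min_b=config.min_b,
        quadrature_order=config.quadrature_order,
        sbar_policy=config.sbar_policy,
        random_state=config.seed,
        **estimator_kwargs,
    )
    return est.fit(dataset.scheme, dataset.Y[0], mu=np.asarray(mu, dtype=float), s0=float(dataset.S0[0]))


def fixed_noise_sweep(
    dataset: VoxelDataset,
    fixed: str,
    values,
    config: FitConfig = FitConfig(),
    mu=None,
    **estimator_kwargs,
):
    """Refit with one noise parameter pinned to each of ``values``.

    Returns a DataFrame with one row per fixed value: posterior mean/std
    of ODI, d_par and the remaining free noise parameter, plus the
    posterior ODI-d_par correlation (degeneracy indicator).
    """
    if fixed not in ("c", "epsilon"):
        raise ValueError("fixed must be 'c' or 'epsilon'")
    rows = []
    for i, v in enumerate(values):
        kw = dict(estimator_kwargs)
        if fixed == "c":
            kw["fix_c"] = float(v)
        else:
            kw["fix_epsilon"] = float(v)
            kw.setdefault("noise_model", "rician")
        cfg = FitConfig(
            odi_bounds=config.odi_bounds,
            d_par_bounds=config.d_par_bounds,
            grid_points=config.grid_points,
            n_samples=config.n_samples,
            burn_in=config.burn_in,
            min_b=config.min_b,
            quadrature_order=config.quadrature_order,
            sbar_policy=config.sbar_policy,
            seed=config.seed + i,
        )
        est = mh_fit(dataset, cfg, mu=mu, **kw)
        row = {f"fixed_{fixed}": float(v)}
        for p in est.samples_.draws.columns:
            row[f"{p}_mean"] = float(est.samples_.mean()[p])
            row[f"{p}_std"] = float(est.samples_.std()[p])
        row["corr_odi_dpar"] = float(est.samples_.corr().loc["odi", "d_par"])
        rows.append(row)
    return pd.DataFrame(rows)
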