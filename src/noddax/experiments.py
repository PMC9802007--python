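"""Reproducible simulation experiments: posterior shape, precision vs
SNR, and noise-model misspecification.

Each driver simulates its own data from a :class:`SimulationConfig`, runs
the MH fits and returns plain DataFrames/dicts; every random element is
derived from the single ``seed`` argument, so re-runs are bitwise
identical.  Default problem sizes (chain lengths, repeat counts) are
desk-scale; pass ``full=True`` for the heavier settings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .fitting import FitConfig, mh_fit
from .noise import fit_pure_noise
from .simulate import (
    SimulationConfig,
    average_voxels,
    simulate_pure_noise,
    simulate_voxels,
)

__all__ = [
    "run_posterior_experiment",
    "run_snr_sweep",
    "run_misspecification_sweep",
]


def _fit_config(seed, full, base=None):
    if base is not None:
        return replace(base, seed=seed)
    if full:
        return FitConfig(n_samples=20_000, burn_in=5_000, seed=seed)
    return FitConfig(n_samples=6_000, burn_in=2_000, seed=seed)


def _noise_prior(config: SimulationConfig, n_samples: int = 5_000):
    """Pure-noise Rician characterisation, mimicking a ventricle fit."""
    samples = simulate_pure_noise(config, n_samples, kind="magnitude")
    res = fit_pure_noise(samples, "rician")
    return res["c"], res["epsilon"]


def _summarise(est, extra=None):
    row = {}
    for p in est.samples_.draws.columns:
        row[f"{p}_mean"] = float(est.samples_.mean()[p])
        row[f"{p}_std"] = float(est.samples_.std()[p])
    row["corr_odi_dpar"] = float(est.samples_.corr().loc["odi", "d_par"])
    if extra:
        row.update(extra)
    return row


def run_posterior_experiment(
    seed: int = 0,
    n_voxels: int = 100,
    include_c0_magnitude: bool = False,
    full: bool = False,
    thin: int = 10,
    fit_config: FitConfig | None = None,
):
    """Posterior shape at high SNR (N-voxel average, SNR ~ SNR_vox sqrt(N)).

    Fits the real-valued variant (offset model) and the magnitude variant
    (offset + floor, jointly constrained to 50-150% of a pure-noise Rician
    characterisation) of one simulated dataset; optionally also a
    magnitude dataset generated without offset.

    Returns a dict: per variant, the posterior summary, thinned draws (for
    pair plots) and model-fit residual summaries; plus the configuration
    and all seeds used.
    """
    sim = SimulationConfig(n_voxels=n_voxels, seed=seed)
    real, mag = simulate_voxels(sim)
    out = {"config": sim.to_json(), "seed": seed}

    est_r = mh_fit(average_voxels(real), _fit_config(seed + 1, full, fit_config))
    est_m = mh_fit(
        average_voxels(mag),
        _fit_config(seed + 2, full, fit_config),
        noise_prior=_noise_prior(sim),
    )
    variants = {"real": est_r, "magnitude": est_m}
    if include_c0_magnitude:
        sim0 = replace(sim, c=0.0)
        _, mag0 = simulate_voxels(sim0)
        variants["magnitude_c0"] = mh_fit(
            average_voxels(mag0), _fit_config(seed + 3, full, fit_config), fix_c=0.0
        )
    for name, est in variants.items():
        resid = est._objective.y - est.predict()
        out[name] = {
            "summary": est.summary_,
            "draws": est.samples_.draws.iloc[::thin].reset_index(drop=True),
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "residual_max_abs": float(np.max(np.abs(resid))),
            "acceptance": est.acceptance_rate_,
            "row": _summarise(est),
        }
    return out


def run_snr_sweep(
    seed: int = 0,
    n_list=(1, 25, 100, 400, 1000),
    repeats: int = 5,
    kinds=("real", "magnitude"),
    full: bool = False,
    fit_config: FitConfig | None = None,
):
    """Precision/accuracy of (ODI, d_par) vs number of averaged voxels.

    For each repeat a fresh pool of max(n_list) voxels is simulated (new
    noise, same protocol); fits run on the first-N average for each N.
    Per-voxel SNR stays at the configured 16.5, so N maps to an effective
    SNR of 16.5 sqrt(N).

    Returns a tidy DataFrame: one row per (kind, N, repeat).
    """
    if full:
        repeats = max(repeats, 20)
    rows = []
    for r in range(repeats):
        sim = SimulationConfig(n_voxels=max(n_list), seed=seed + 1000 * r)
        real, mag = simulate_voxels(sim)
        prior = _noise_prior(sim) if "magnitude" in kinds else None
        for n in n_list:
            for kind in kinds:
                ds = average_voxels(real if kind == "real" else mag, n)
                kw = {}
                if kind == "magnitude":
                    kw["noise_prior"] = prior
                est = mh_fit(ds, _fit_config(seed + 1000 * r + n, full, fit_config), **kw)
                rows.append(
                    _summarise(
                        est,
                        extra={
                            "kind": kind,
                            "n_voxels": n,
                            "snr": sim.snr_vox * np.sqrt(n),
                            "repeat": r,
                            "seed": seed + 1000 * r + n,
                        },
                    )
                )
    return pd.DataFrame(rows)


def run_misspecification_sweep(
    seed: int = 0,
    n_voxels: int = 100,
    offset_values=(0.0, 5.0, 10.0, 15.0, 20.0),
    floor_factors=(0.0, 0.5, 1.0, 1.5, 2.0),
    full: bool = False,
    fit_config: FitConfig | None = None,
):
    """Bias from assuming wrong noise parameters (high-SNR N-voxel average).

    Three panels:

    * ``offset_sweep``: real-valued data generated with c = 10, fitted
      with the offset pinned to each of ``offset_values`` (truth = 10).
    * ``floor_sweep``: magnitude data generated *without* offset, fitted
      with the Rician floor pinned to ``floor_factors`` x the true complex
      noise std (0 = naive Gaussian assumption).
    * ``real_rician``: real-valued data fitted with a free floor — the
      posterior of eps should collapse toward zero.

    Returns a dict of DataFrames.
    """
    from .fitting import fixed_noise_sweep

    cfg = _fit_config(seed, full, fit_config)

    sim = SimulationConfig(n_voxels=n_voxels, seed=seed)
    real, _ = simulate_voxels(sim)
    avg_real = average_voxels(real)
    offset_df = fixed_noise_sweep(avg_real, "c", offset_values, cfg)
    offset_df["true_c"] = sim.c

    sim0 = replace(sim, c=0.0, seed=seed + 17)
    _, mag0 = simulate_voxels(sim0)
    avg_mag0 = average_voxels(mag0)
    eps_values = [f * sim0.sigma for f in floor_factors]
    floor_df = fixed_noise_sweep(avg_mag0, "epsilon", eps_values, cfg, fix_c=0.0)
    floor_df["true_sigma"] = sim0.sigma
    floor_df["floor_factor"] = list(floor_factors)

    est = mh_fit(
        avg_real,
        replace(cfg, seed=cfg.seed + 29),
        noise_model="rician",
    )
    real_rician = pd.DataFrame([_summarise(est, extra={"kind": "real", "model": "rician"})])

    return {
        "offset_sweep": offset_df,
        "floor_sweep": floor_df,
        "real_rician": real_rician,
        "seed": seed,
        "config": sim.to_json(),
    }
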