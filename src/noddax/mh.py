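"""Component-wise Metropolis-Hastings sampling with burn-in adaptation.

A deliberately small sampler: Gaussian proposals on one coordinate at a
time, hard-bound rejection, and per-component proposal-scale adaptation
restricted to the burn-in phase (so the recorded chain is a valid,
fixed-kernel Markov chain).  Given a seed the chain is bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorSamples", "metropolis_hastings"]


@dataclass
class PosteriorSamples:
    """MH draws with summary statistics.

    ``draws`` is a DataFrame with one column per parameter; acceptance
    rates are per component, measured after burn-in.
    """

    draws: pd.DataFrame
    acceptance_rate: dict
    seed: int | None = None
    scales: dict = field(default_factory=dict)

    def mean(self):
        return self.draws.mean()

    def std(self):
        return self.draws.std(ddof=1)

    def quantile(self, q):
        return self.draws.quantile(q)

    def corr(self):
        return self.draws.corr()

    def summary(self) -> pd.DataFrame:
        s = pd.DataFrame(
            {
                "mean": self.mean(),
                "std": self.std(),
                "q05": self.quantile(0.05),
                "median": self.quantile(0.5),
                "q95": self.quantile(0.95),
            }
        )
        s.index.name = "parameter"
        return s


def metropolis_hastings(
    log_post,
    x0,
    bounds,
    n_samples: int,
    burn_in: int,
    rng,
    param_names=None,
    scales=None,
    adapt_interval: int = 100,
    target_acceptance=(0.2, 0.5),
    seed=None,
) -> PosteriorSamples:
    """Sample from ``log_post`` with component-wise Gaussian proposals.

    Parameters
    ----------
    log_post : callable
        Maps a parameter vector to the (unnormalised) log posterior;
        may return -inf.
    x0 : array
        Start point (must have finite log posterior).
    bounds : list of (lo, hi)
        Hard box constraints enforced by proposal rejection.
    n_samples, burn_in : int
        Recorded sweeps after / discarded sweeps of adaptation.
    scales : array, optional
        Initial proposal stds; default 5% of each bound range.
    """
    x = np.asarray(x0, dtype=float).copy()
    ndim = len(x)
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if param_names is None:
        param_names = [f"p{i}" for i in range(ndim)]
    if scales is None:
        scales = np.array([0.05 * (hi - lo) for lo, hi in bounds])
    else:
        scales = np.asarray(scales, dtype=float).copy()
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")
    draws = np.empty((n_samples, ndim))
    accepted = np.zeros(ndim, dtype=int)
    proposed = np.zeros(ndim, dtype=int)
    adapt_acc = np.zeros(ndim, dtype=int)
    adapt_try = np.zeros(ndim, dtype=int)
    lo_t, hi_t = target_acceptance
    total = burn_in + n_samples
    for it in range(total):
        in_burn = it < burn_in
        for j in range(ndim):
            prop = x.copy()
            prop[j] = x[j] + scales[j] * rng.standard_normal()
            if in_burn:
                adapt_try[j] += 1
            else:
                proposed[j] += 1
            if not bounds[j][0] <= prop[j] <= bounds[j][1]:
                continue
            lp_prop = float(log_post(prop))
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                if in_burn:
                    adapt_acc[j] += 1
                else:
                    accepted[j] += 1
        if in_burn and (it + 1) % adapt_interval == 0:
            rate = adapt_acc / np.maximum(adapt_try, 1)
            # gentle steps near the target band, aggressive when far off
            scales[rate > hi_t] *= 1.6
            scales[rate > 0.8] *= 2.5
            scales[rate < lo_t] /= 1.6
            scales[rate < 0.05] /= 2.5
            for j in range(ndim):
                width = bounds[j][1] - bounds[j][0]
                scales[j] = min(scales[j], width)
            adapt_acc[:] = 0
            adapt_try[:] = 0
        if not in_burn:
            draws[it - burn_in] = x
    rates = {
        name: float(a) / max(int(p), 1)
        for name, a, p in zip(param_names, accepted, proposed)
    }
    if all(r == 0.0 for r in rates.values()) and n_samples > 100:
        raise RuntimeError(
            "zero acceptance after burn-in: proposal scales are misconfigured"
        )
    return PosteriorSamples(
        draws=pd.DataFrame(draws, columns=param_names),
        acceptance_rate=rates,
        seed=seed,
        scales={n: float(s) for n, s in zip(param_names, scales)},
    )
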