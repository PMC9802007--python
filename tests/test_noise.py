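"""Noise forward models, corrected spherical means and pure-noise fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noddax.noise import (
    NoiseParams,
    VoxelDataset,
    apply_offset,
    apply_rician_floor,
    corrected_powder_average,
    fit_pure_noise,
    snr_of_average,
)
from noddax.scheme import AcquisitionScheme
from noddax.signal import powder_average_model
from noddax.simulate import fibonacci_directions


def _shell_dataset(Y, kind="magnitude", b=9.85):
    n = Y.shape[-1]
    scheme = AcquisitionScheme(b=np.full(n, b), g=fibonacci_directions(n))
    return VoxelDataset(Y=Y, kind=kind, S0=np.full(np.atleast_2d(Y).shape[0], 100.0), scheme=scheme)


class TestForwardModels:
    def test_offset_examples(self):
        assert apply_offset(0.0, 10.0) == 10.0
        x = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(apply_offset(x, 0.0), x)
        assert apply_offset(x, 2.0).shape == x.shape

    def test_rician_floor_345(self):
        assert apply_rician_floor(3.0, 0.0, 4.0) == pytest.approx(5.0)
        assert apply_rician_floor(-1.0, 1.0, 7.0) == pytest.approx(7.0)  # S+c = 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0, 200), st.floats(0, 30))
    def test_floor_reduces_to_offset_at_zero_epsilon(self, s, c):
        # identity holds on the physical domain S, c >= 0 (at eps = 0 the
        # magnitude of a negative S + c would rectify instead)
        assert apply_rician_floor(s, c, 0.0) == pytest.approx(apply_offset(s, c), rel=1e-12)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            apply_offset(1.0, -1.0)
        with pytest.raises(ValueError):
            apply_rician_floor(1.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            NoiseParams(c=-1.0)


class TestCorrectedPowderAverage:
    def test_exact_inversion_noiseless(self):
        noise = NoiseParams(c=10.0, epsilon=6.0)
        S = np.linspace(2.0, 20.0, 64)[None, :]
        Y = apply_rician_floor(S, noise.c, noise.epsilon)
        ds = _shell_dataset(Y, kind="magnitude")
        sbar = corrected_powder_average(ds, noise)
        assert sbar[0] == pytest.approx(S.mean(), rel=1e-12)

    def test_real_kind_subtracts_offset(self):
        S = np.linspace(2.0, 20.0, 64)[None, :]
        ds = _shell_dataset(S + 7.0, kind="real")
        sbar = corrected_powder_average(ds, NoiseParams(c=7.0))
        assert sbar[0] == pytest.approx(S.mean(), rel=1e-12)

    def test_all_below_floor_gives_minus_c(self):
        Y = np.full((1, 64), 3.0)
        ds = _shell_dataset(Y, kind="magnitude")
        sbar = corrected_powder_average(ds, NoiseParams(c=2.0, epsilon=5.0))
        assert sbar[0] == pytest.approx(-2.0)

    def test_rician_noise_biases_sbar_upward(self):
        # positivity of the magnitude-correction clamps Y^2 - eps^2 at 0;
        # where the per-volume non-centrality falls below ~2 eps (true of
        # the high-b dispersed-stick signal without an offset) the
        # corrected spherical mean overshoots the ground truth
        from noddax.simulate import SimulationConfig, simulate_voxels

        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(n_voxels=1, c=0.0, seed=900 + seed)
            _, mag = simulate_voxels(cfg)
            sbar = corrected_powder_average(mag, NoiseParams(c=0.0, epsilon=cfg.sigma))
            sid = [s for s, b in mag.scheme.shell_b.items() if b == 13.5][0]
            truth = cfg.f_in * cfg.s0 * powder_average_model(13.5, cfg.d_par)
            wins += sbar[sid] > truth
        assert wins >= 15  # one-sided sign test, p < 0.025 under no bias

    def test_mean_then_correct_option(self):
        S = np.linspace(2.0, 20.0, 64)[None, :]
        ds = _shell_dataset(S + 7.0, kind="real")
        a = corrected_powder_average(ds, NoiseParams(c=7.0), order="mean_then_correct")
        b = corrected_powder_average(ds, NoiseParams(c=7.0))
        assert a[0] == pytest.approx(b[0])  # linear for real data
        with pytest.raises(ValueError):
            corrected_powder_average(ds, NoiseParams(), order="whatever")


class TestPureNoiseFit:
    def test_gaussian_recovery(self, rng):
        # generator settings mirror a real-channel ventricle histogram
        mu, sigma = 10.4, 9.2
        x = mu + sigma * rng.standard_normal(5000)
        res = fit_pure_noise(x, "gaussian")
        assert abs(res["c"] - mu) < 3.0 * res["se_c"] + 1e-9
        assert abs(res["sigma"] - sigma) < 3.0 * res["se_sigma"] + 1e-9

    def test_rician_recovery(self, rng):
        nu, sigma = 13.7, 8.4
        re = nu + sigma * rng.standard_normal(5000)
        im = sigma * rng.standard_normal(5000)
        res = fit_pure_noise(np.hypot(re, im), "rician")
        assert abs(res["c"] - nu) < 3.0 * res["se_c"]
        assert abs(res["epsilon"] - sigma) < 3.0 * res["se_epsilon"]

    def test_vanishing_noise_collapses(self, rng):
        x = 10.0 + 1e-6 * rng.standard_normal(500)
        res = fit_pure_noise(x, "gaussian")
        assert res["c"] == pytest.approx(10.0, abs=1e-6)
        assert res["sigma"] < 1e-5

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            fit_pure_noise(np.ones(10), "gaussian")
        with pytest.raises(ValueError):
            fit_pure_noise(np.linspace(-1, 1, 200), "rician")
        with pytest.raises(ValueError):
            fit_pure_noise(np.ones(200), "lognormal")


class TestSnrBookkeeping:
    def test_values(self):
        assert snr_of_average(16.5, 1) == pytest.approx(16.5)
        assert snr_of_average(16.5, 100) == pytest.approx(165.0)
        assert snr_of_average(7.3, 1) == pytest.approx(7.3)

    def test_n_floor(self):
        with pytest.raises(ValueError):
            snr_of_average(16.5, 0)


def test_dataset_validation(high_b_scheme):
    with pytest.raises(ValueError, match="non-negative"):
        VoxelDataset(
            Y=-np.ones((1, len(high_b_scheme))),
            kind="magnitude",
            S0=np.array([100.0]),
            scheme=high_b_scheme,
        )
    with pytest.raises(ValueError):
        VoxelDataset(
            Y=np.ones((1, 5)), kind="real", S0=np.array([100.0]), scheme=high_b_scheme
        )
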