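"""Synthetic-data generator: scheme structure, noise law, averaging and
rotation-based concatenation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from noddax.noise import fit_pure_noise
from noddax.simulate import (
    SimulationConfig,
    average_voxels,
    concatenate_with_rotation,
    make_scheme,
    simulate_pure_noise,
    simulate_voxels,
)


class TestMakeScheme:
    def test_volume_counts(self, default_config, high_b_scheme):
        assert len(high_b_scheme) == default_config.n_b0 + 3 * 64
        assert int(high_b_scheme.weighted.sum()) == 192
        assert sorted(high_b_scheme.shell_b.values())[1:] == [6.75, 9.85, 13.5]

    def test_deterministic(self, default_config):
        a, b = make_scheme(default_config), make_scheme(default_config)
        assert np.array_equal(a.b, b.b) and np.array_equal(a.g, b.g)

    def test_per_shell_uniformity(self, high_b_scheme):
        for s in high_b_scheme.shells:
            mask = high_b_scheme.shell_mask(s) & high_b_scheme.weighted
            if not mask.any():
                continue
            g = high_b_scheme.g[mask]
            assert np.linalg.norm(g.sum(axis=0)) / len(g) < 0.1

    def test_antipodal_duplication_preserves_predictions(self, default_config):
        from noddax.scheme import AcquisitionScheme
        from noddax.signal import predict_signal_full

        sch = make_scheme(default_config)
        dup = AcquisitionScheme(
            b=np.concatenate([sch.b, sch.b]),
            g=np.vstack([sch.g, -sch.g]),
            shell_id=np.concatenate([sch.shell_id, sch.shell_id]),
        )
        p = default_config.ground_truth
        s = predict_signal_full(p, dup)
        assert np.allclose(s[: len(sch)], s[len(sch):], rtol=1e-12)


class TestSimulateVoxels:
    def test_bitwise_reproducible(self, default_config):
        r1, m1 = simulate_voxels(default_config)
        r2, m2 = simulate_voxels(default_config)
        assert np.array_equal(r1.Y, r2.Y) and np.array_equal(m1.Y, m2.Y)

    def test_shared_complex_draws(self, default_config):
        real, mag = simulate_voxels(default_config)
        # |z| >= |Re z| measurement-wise only if they share draws
        assert np.all(mag.Y >= np.abs(real.Y) - 1e-12)

    def test_noise_free_limit(self, default_config):
        cfg = replace(default_config, snr_vox=1e9)
        real, mag = simulate_voxels(cfg)
        assert np.allclose(real.Y, mag.Y, rtol=1e-6)
        assert np.allclose(real.Y[0, :6], cfg.s0 + cfg.c, rtol=1e-6)

    def test_rayleigh_mean_for_pure_noise(self, default_config):
        cfg = replace(default_config, f_in=0.0, c=0.0, n_voxels=400)
        _, mag = simulate_voxels(cfg)
        weighted = mag.scheme.weighted
        samples = mag.Y[:, weighted].ravel()
        expected = cfg.sigma * np.sqrt(np.pi / 2.0)
        se = cfg.sigma * np.sqrt((4.0 - np.pi) / 2.0) / np.sqrt(samples.size)
        assert abs(samples.mean() - expected) < 4.0 * se

    def test_configured_voxel_snr(self, default_config):
        cfg = replace(default_config, n_voxels=500)
        real, _ = simulate_voxels(cfg)
        b0 = ~real.scheme.weighted
        sigma_hat = real.Y[:, b0].std(ddof=1)
        assert cfg.s0 / sigma_hat == pytest.approx(16.5, rel=0.1)

    def test_magnitude_pure_noise_is_rician(self, default_config):
        x = simulate_pure_noise(replace(default_config, n_voxels=1), 10_000)
        fitres = fit_pure_noise(x, "rician")
        nu, sig = fitres["c"], fitres["epsilon"]
        _, p = stats.kstest(x, stats.rice(b=nu / sig, scale=sig).cdf)
        assert p > 0.01


class TestAverageVoxels:
    def test_identity_for_single_voxel(self, default_config):
        real, _ = simulate_voxels(default_config)
        avg = average_voxels(real, 1)
        assert np.array_equal(avg.Y, real.Y[:1])

    def test_snr_gain(self, default_config):
        cfg = replace(default_config, n_voxels=100)
        real, _ = simulate_voxels(cfg)
        avg = average_voxels(real)
        b0 = ~avg.scheme.weighted
        # pool b0 deviations around the known clean level to estimate noise
        resid = avg.Y[0, b0] - (cfg.s0 + cfg.c)
        # also use weighted volumes around their across-voxel clean value
        clean_w = real.Y[:, avg.scheme.weighted].mean(axis=0)
        sigma_eff = np.sqrt(np.mean(resid**2))
        snr = cfg.s0 / sigma_eff
        assert 90 < snr  # ~165 expected; crude bound given only 6 b0 draws
        del clean_w

    def test_magnitude_average_keeps_noise_floor(self, default_config):
        # Jensen: averaging magnitudes is not the magnitude of the average
        cfg = replace(default_config, f_in=0.0, c=0.0, n_voxels=200)
        _, mag = simulate_voxels(cfg)
        avg = average_voxels(mag)
        floor = avg.Y[0, avg.scheme.weighted].mean()
        assert floor == pytest.approx(cfg.sigma * np.sqrt(np.pi / 2), rel=0.1)
        assert floor > 5 * cfg.sigma / np.sqrt(cfg.n_voxels)


class TestConcatenateWithRotation:
    def test_geometry_preserved(self, default_config):
        cfg = replace(default_config, n_voxels=2, theta=0.6, phi=0.3)
        real, _ = simulate_voxels(cfg)
        mu = cfg.ground_truth.orientation.mu
        parts = [average_voxels(real, 1)]
        cc = concatenate_with_rotation(parts, [mu], seed=5)
        # rotated directions stay unit norm and keep their angle to the fibre
        gw = cc.scheme.g[cc.scheme.weighted]
        assert np.allclose(np.linalg.norm(gw, axis=1), 1.0, atol=1e-9)
        orig = np.abs(real.scheme.g[real.scheme.weighted] @ mu)
        new = np.abs(gw @ np.array([0.0, 0.0, 1.0]))
        assert np.allclose(np.sort(orig), np.sort(new), atol=1e-9)
        # signals are untouched
        assert np.array_equal(cc.Y[0], real.Y[0])

    def test_rejects_non_unit_orientation(self, default_config):
        real, _ = simulate_voxels(default_config)
        with pytest.raises(ValueError):
            concatenate_with_rotation([real], [np.array([0.0, 0.0, 2.0])], seed=0)

    def test_fit_consistency_across_pool_size(self):
        # concatenating more voxels must give a d_par estimate consistent
        # with the smaller pool (within combined posterior spread)
        from noddax.fitting import FitConfig, mh_fit

        cfg = SimulationConfig(n_voxels=32, n_directions=16, seed=21)
        real, _ = simulate_voxels(cfg)
        mu = cfg.ground_truth.orientation.mu
        singles = [
            average_voxels(
                type(real)(
                    Y=real.Y[i : i + 1],
                    kind=real.kind,
                    S0=real.S0[i : i + 1],
                    scheme=real.scheme,
                    orientation=mu,
                ),
                1,
            )
            for i in range(32)
        ]
        small = concatenate_with_rotation(singles[:16], [mu] * 16, seed=1)
        large = concatenate_with_rotation(singles, [mu] * 32, seed=2)
        fc = FitConfig(n_samples=1500, burn_in=800, seed=3)
        est_s = mh_fit(small, fc)
        est_l = mh_fit(large, fc)
        spread = np.hypot(est_s.samples_.std()["d_par"], est_l.samples_.std()["d_par"])
        assert abs(est_s.d_par_ - est_l.d_par_) < 4.0 * spread
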