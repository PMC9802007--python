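"""Forward-model tests: dispersed-stick signal, powder average, ratio model."""

import numpy as np
import pytest
from scipy.special import erf

from noddax.scheme import AcquisitionScheme
from noddax.signal import (
    DispersionIndex,
    FibreOrientation,
    WatsonStickParams,
    numeric_convolution_oracle,
    powder_average_model,
    predict_signal_full,
    predict_signal_ratio,
)
from noddax.simulate import fibonacci_directions


def _params(odi=0.03, d_par=2.2, theta=0.3, phi=1.1, F=60.0):
    return WatsonStickParams(
        dispersion=DispersionIndex.from_odi(odi),
        d_par=d_par,
        orientation=FibreOrientation(theta, phi),
        F=F,
    )


class TestPredictSignalFull:
    def test_b0_returns_F(self, high_b_scheme):
        s = predict_signal_full(_params(), high_b_scheme)
        assert np.allclose(s[~high_b_scheme.weighted], 60.0, rtol=1e-10)

    def test_stick_limit(self):
        # infinite concentration, gradient along the fibre: F exp(-b d)
        b = np.array([0.0, 6.75, 13.5])
        g = np.tile([0.0, 0.0, 1.0], (3, 1))
        scheme = AcquisitionScheme(b=b, g=g)
        p = WatsonStickParams(
            dispersion=DispersionIndex.from_kappa(np.inf),
            d_par=2.2,
            orientation=FibreOrientation(0.0, 0.0),
            F=60.0,
        )
        s = predict_signal_full(p, scheme)
        assert np.allclose(s, 60.0 * np.exp(-b * 2.2), rtol=1e-10)

    def test_antipodal_symmetry(self, tiny_scheme):
        p = _params()
        s = predict_signal_full(p, tiny_scheme)
        flipped = tiny_scheme.with_directions(-tiny_scheme.g)
        assert np.allclose(predict_signal_full(p, flipped), s, rtol=1e-12)
        p_flip = WatsonStickParams(
            dispersion=p.dispersion,
            d_par=p.d_par,
            orientation=FibreOrientation(np.pi - 0.3, 1.1 + np.pi),
            F=p.F,
        )
        assert np.allclose(predict_signal_full(p_flip, tiny_scheme), s, rtol=1e-9)

    def test_bounded_and_decreasing_in_b(self):
        p = _params()
        g = np.tile([0.3, 0.5, np.sqrt(1 - 0.09 - 0.25)], (6, 1))
        b = np.array([1.0, 3.0, 6.75, 9.85, 13.5, 20.0])
        s = predict_signal_full(p, AcquisitionScheme(b=b, g=g, shell_id=np.arange(6)))
        assert np.all(s <= p.F + 1e-12)
        assert np.all(s > 0)
        assert np.all(np.diff(s) < 0)

    def test_matches_monte_carlo_oracle(self, tiny_scheme, rng):
        # the analytic evaluator must agree with the sampled convolution
        # integral within 3 Monte-Carlo standard errors, over random params
        z_all = []
        for i in range(20):
            p = _params(
                odi=float(rng.uniform(0.02, 0.9)),
                d_par=float(rng.uniform(0.3, 3.5)),
                theta=float(rng.uniform(0, np.pi)),
                phi=float(rng.uniform(0, 2 * np.pi)),
                F=float(rng.uniform(10, 100)),
            )
            s = predict_signal_full(p, tiny_scheme)
            mc, se = numeric_convolution_oracle(p, tiny_scheme, n_samples=40_000, seed=i)
            z_all.append(np.abs(s - mc) / np.maximum(se, 1e-9))
        z = np.concatenate(z_all)
        # 20 sets x 9 volumes: a stray 3-sigma excursion is expected, a
        # systematic discrepancy is not
        assert np.mean(z <= 3.0) > 0.97
        assert z.max() < 5.0
        assert np.median(z) < 1.5


class TestPowderAverage:
    def test_small_bd_limit(self):
        assert powder_average_model(0.0, 2.2) == pytest.approx(1.0, abs=1e-12)
        assert powder_average_model(1e-14, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        bd = 13.5 * 2.2
        expected = np.sqrt(np.pi) * erf(np.sqrt(bd)) / (2.0 * np.sqrt(bd))
        assert powder_average_model(13.5, 2.2) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        assert powder_average_model(9.85, 2.2) > powder_average_model(13.5, 2.2)
        bd = np.linspace(0.01, 40, 100)
        vals = powder_average_model(bd, 1.0)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("odi", [0.03, 0.3, 1.0])
    def test_odf_independence(self, odi):
        # the spherical mean of the full model over a dense uniform set
        # equals the stick powder average whatever the dispersion
        g = fibonacci_directions(10_000)
        b = 13.5
        scheme = AcquisitionScheme(b=np.full(len(g), b), g=g)
        p = _params(odi=odi, F=1.0)
        mean = predict_signal_full(p, scheme).mean()
        assert mean == pytest.approx(powder_average_model(b, p.d_par), rel=2e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            powder_average_model(-1.0, 2.0)


class TestPredictSignalRatio:
    def test_isotropic_dispersion_is_flat(self, rng):
        g = fibonacci_directions(32, rng)
        scheme = AcquisitionScheme(b=np.full(32, 9.85), g=g)
        s = predict_signal_ratio(
            {0: 5.0}, DispersionIndex.from_kappa(0.0), 2.2, FibreOrientation(0.4, 0.2), scheme
        )
        assert np.allclose(s, 5.0, rtol=1e-10)

    def test_stick_limit_closed_form(self):
        bd = 9.85 * 2.2
        scheme = AcquisitionScheme(b=np.array([9.85]), g=np.array([[0.0, 0.0, 1.0]]))
        s = predict_signal_ratio(
            {0: 1.0},
            DispersionIndex.from_kappa(np.inf),
            2.2,
            FibreOrientation(0.0, 0.0),
            scheme,
        )
        expected = 2.0 * np.sqrt(bd) * np.exp(-bd) / (np.sqrt(np.pi) * erf(np.sqrt(bd)))
        assert s[0] == pytest.approx(expected, rel=1e-10)

    def test_consistent_with_full_model(self, rng):
        # ratio prediction == full model divided by its own sphere mean
        g = fibonacci_directions(64, rng)
        b = 9.85
        scheme = AcquisitionScheme(b=np.full(64, b), g=g)
        p = _params(odi=0.03, d_par=2.2, F=60.0)
        full = predict_signal_full(p, scheme)
        sbar_true = p.F * powder_average_model(b, p.d_par)
        ratio = predict_signal_ratio(
            {0: float(sbar_true)}, p.dispersion, p.d_par, p.orientation, scheme
        )
        assert np.allclose(ratio, full, rtol=1e-9)

    def test_sphere_mean_self_consistency(self):
        # averaging the ratio prediction over a dense uniform direction
        # set must give back the supplied sbar (1e-4)
        g = fibonacci_directions(10_000)
        for b, sbar in ((6.75, 2.0), (13.5, 0.7)):
            scheme = AcquisitionScheme(b=np.full(len(g), b), g=g)
            pred = predict_signal_ratio(
                {0: sbar}, DispersionIndex.from_odi(0.03), 2.2, FibreOrientation(0.7, 0.1), scheme
            )
            assert pred.mean() == pytest.approx(sbar, rel=1e-4)

    def test_missing_shell_rejected(self, high_b_scheme):
        weighted = high_b_scheme.subset(high_b_scheme.weighted)
        with pytest.raises(ValueError, match="missing"):
            predict_signal_ratio(
                {0: 1.0}, DispersionIndex.from_odi(0.1), 2.0, FibreOrientation(0, 0), weighted
            )

    def test_b0_rejected(self, high_b_scheme):
        with pytest.raises(ValueError, match="b > 0"):
            predict_signal_ratio(
                {int(s): 1.0 for s in high_b_scheme.shells},
                DispersionIndex.from_odi(0.1),
                2.0,
                FibreOrientation(0, 0),
                high_b_scheme,
            )


class TestConvolutionOracle:
    def test_uniform_odf_equals_powder(self, rng):
        g = fibonacci_directions(8, rng)
        scheme = AcquisitionScheme(b=np.full(8, 6.75), g=g)
        p = WatsonStickParams(
            dispersion=DispersionIndex.from_kappa(0.0),
            d_par=2.2,
            orientation=FibreOrientation(0.2, 0.9),
            F=60.0,
        )
        mc, se = numeric_convolution_oracle(p, scheme, n_samples=100_000, seed=3)
        expected = 60.0 * powder_average_model(6.75, 2.2)
        assert np.all(np.abs(mc - expected) <= 3.0 * se)

    def test_b0_exact(self):
        scheme = AcquisitionScheme(b=np.array([0.0]), g=np.array([[0, 0, 1.0]]))
        mc, se = numeric_convolution_oracle(_params(), scheme, n_samples=10_000, seed=0)
        assert mc[0] == pytest.approx(60.0, abs=1e-9)
        assert se[0] == pytest.approx(0.0, abs=1e-12)

    def test_sample_size_floor(self, tiny_scheme):
        with pytest.raises(ValueError):
            numeric_convolution_oracle(_params(), tiny_scheme, n_samples=100, seed=0)
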