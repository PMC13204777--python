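"""Kernel construction and convolution engines against independent oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from msod import kernels as K


def direct_spatial_oracle(arr, weights):
    """O(N^2 k^2) nested-loop 'same' convolution with replicate padding."""
    r = weights.shape[0] // 2
    padded = np.pad(arr, r, mode="edge")
    out = np.zeros_like(arr, dtype=float)
    H, W = arr.shape
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += weights[r + dy, r + dx] * padded[y + r - dy, x + r - dx]
            out[y, x] = acc
    return out


class TestGaussian:
    def test_unit_sum_and_symmetry(self):
        g = K.make_gaussian2d(1.0, radius=3)
        assert abs(g.weights.sum() - 1.0) < 1e-9
        assert np.allclose(g.weights, g.weights[::-1, :])
        assert np.allclose(g.weights, g.weights[:, ::-1])
        assert np.allclose(g.weights, g.weights.T)

    def test_continuous_center_value(self):
        # 1/(2*pi*sigma^2) at the origin for sigma = 1
        assert K.gaussian2d_continuous(0.0, 0.0, 1.0) == pytest.approx(1.0 / (2 * math.pi))

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            K.make_gaussian2d(0.0)
        with pytest.raises(ValueError):
            K.make_gaussian2d(-1.0)


class TestDog:
    def test_zero_sum_and_rectified_halves(self):
        dog, w_sp, w_sn = K.make_dog(1.5, 2.0)
        assert abs(dog.weights.sum()) < 1e-9
        assert np.all(w_sp.weights >= 0)
        assert np.all(w_sn.weights <= 0)
        assert np.allclose(dog.weights, w_sp.weights + w_sn.weights)

    def test_center_positive(self):
        # narrow Gaussian dominates at the origin: 1/(2 pi s2^2) > 1/(2 pi s3^2)
        dog, _, _ = K.make_dog(1.5, 2.0)
        r = dog.radius
        assert dog.weights[r, r] > 0

    def test_rejects_bad_sigmas(self):
        with pytest.raises(ValueError):
            K.make_dog(2.0, 1.5)


class TestBandpass:
    def test_zero_at_origin_and_zero_sum(self):
        h = K.make_bandpass(1, 6, length=31)
        assert h.taps[0] == 0.0
        assert abs(h.taps.sum()) < 1e-9

    def test_continuous_integral_vanishes(self):
        total, _ = integrate.quad(lambda t: K.bandpass_continuous(t, 1, 6), 0, np.inf)
        assert abs(total) < 1e-9

    def test_sign_change_location(self):
        # dense evaluation brackets the single sign change at 720^(1/5)
        t = np.linspace(0.5, 10, 20001)
        v = K.bandpass_continuous(t, 1, 6)
        i = int(np.nonzero(np.diff(np.sign(v)))[0][0])
        root = optimize.brentq(lambda s: K.bandpass_continuous(s, 1, 6), t[i], t[i + 1])
        assert root == pytest.approx(720 ** 0.2, abs=1e-6)

    def test_rejects_bad_orders(self):
        with pytest.raises(ValueError):
            K.make_bandpass(6, 1)


class TestExpLowpass:
    def test_unit_sum_and_monotone(self):
        e = K.make_exp_lowpass(3.0)
        assert abs(e.taps.sum() - 1.0) < 1e-9
        assert np.all(np.diff(e.taps) < 0)

    def test_lag0_ordering(self):
        # pre-normalization values at t=0 are 1/lambda: 1/3 > 1/9
        assert K.exp_lowpass_continuous(0.0, 3.0) > K.exp_lowpass_continuous(0.0, 9.0)

    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            K.make_exp_lowpass(0.0)


class TestGamma:
    def test_unit_sum(self):
        g = K.make_gamma(5, 25.0)
        assert abs(g.taps.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("n,tau", [(5, 25.0), (10, 25.0), (2, 4.0)])
    def test_continuous_unit_integral_and_mode(self, n, tau):
        total, _ = integrate.quad(lambda t: K.gamma_continuous(t, n, tau), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)
        res = optimize.minimize_scalar(
            lambda t: -K.gamma_continuous(t, n, tau), bounds=(0.1, 10 * tau), method="bounded"
        )
        assert res.x == pytest.approx(tau, rel=1e-5)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            K.make_gamma(0, 25.0)
        with pytest.raises(ValueError):
            K.make_gamma(5, -1.0)


class TestTruncation:
    @pytest.mark.parametrize(
        "f,kern",
        [
            (lambda t: abs(K.bandpass_continuous(t, 1, 6)), K.make_bandpass(1, 6)),
            (lambda t: K.gamma_continuous(t, 5, 25.0), K.make_gamma(5, 25.0)),
            (lambda t: K.gamma_continuous(t, 10, 25.0), K.make_gamma(10, 25.0)),
            (lambda t: K.exp_lowpass_continuous(t, 9.0), K.make_exp_lowpass(9.0)),
        ],
    )
    def test_mass_loss_below_point1_percent(self, f, kern):
        total, _ = integrate.quad(f, 0, np.inf, limit=200)
        covered, _ = integrate.quad(f, 0, len(kern) * kern.dt, limit=200)
        assert 1.0 - covered / total < 1e-3


class TestSpatialConvolve:
    def test_constant_map_unit_sum_kernel(self):
        g = K.make_gaussian2d(1.0)
        out = K.convolve_spatial(np.full((16, 16), 7.0), g)
        assert np.allclose(out, 7.0, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        g = K.make_gaussian2d(1.0, radius=3)
        arr = np.zeros((9, 9))
        arr[4, 4] = 1.0
        out = K.convolve_spatial(arr, g)
        assert np.allclose(out[1:8, 1:8], g.weights, atol=1e-12)

    def test_matches_direct_oracle(self):
        g = K.make_gaussian2d(1.0, radius=3)
        rng = np.random.default_rng(0)
        for _ in range(20):
            arr = rng.uniform(size=(16, 16))
            assert np.max(np.abs(K.convolve_spatial(arr, g) - direct_spatial_oracle(arr, g.weights))) < 1e-9

    def test_kernel_larger_than_map(self):
        g = K.make_gaussian2d(2.0)  # 13x13
        with pytest.raises(ValueError):
            K.convolve_spatial(np.zeros((5, 5)), g)


class TestTemporalConvolve:
    def test_zero_history(self):
        e = K.make_exp_lowpass(3.0)
        out = K.convolve_temporal_causal(np.zeros((40, 4, 4)), e)
        assert np.all(out == 0)

    def test_constant_history_unit_sum(self):
        e = K.make_exp_lowpass(3.0)
        hist = np.full((len(e) + 10, 3, 3), 5.0)
        out = K.convolve_temporal_causal(hist, e)
        # once the kernel has filled, a unit-sum kernel reproduces the constant
        assert np.allclose(out[len(e):], 5.0, atol=1e-9)

    def test_impulse_sifting(self):
        taps = np.array([0.5, 0.3, 0.2])
        kern = K.DiscreteKernel1D(taps)
        hist = np.zeros((10, 1, 1))
        hist[4] = 1.0
        out = K.convolve_temporal_causal(hist, kern)[:, 0, 0]
        expect = np.zeros(10)
        expect[4:7] = taps
        assert np.allclose(out, expect, atol=1e-12)

    def test_strict_causality(self):
        # truncating the future must not change the past
        e = K.make_exp_lowpass(2.0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2, 2))
        full = K.convolve_temporal_causal(x, e)
        cut = K.convolve_temporal_causal(x[:20], e)
        assert np.array_equal(full[:20], cut)


class TestKernelTypes:
    def test_unit_sum_policy_enforced(self):
        with pytest.raises(ValueError):
            K.DiscreteKernel1D(np.array([0.5, 0.4]), norm_policy="unit_sum")

    def test_dump_roundtrip_text(self):
        g = K.make_gaussian2d(1.0)
        text = g.dump()
        assert "radius=3" in text and len(text.splitlines()) == 8
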