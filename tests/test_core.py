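"""Subunit and divisive-normalization forward passes against brute-force
loop oracles, plus the structural invariants of the core."""

import numpy as np
import pytest

from dnv1.autodiff import Tensor
from dnv1.core import (DNParams, ExtendedDNParams, SubunitParams, POW_EPS,
                       dn_forward, extended_dn_forward, make_nonspecific,
                       nonspecific_project, subunit_forward, subunit_variant)
from dnv1.core import InvalidParameterError


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def conv_valid_loop(img, kernel):
    kh, kw = kernel.shape
    h = img.shape[0] - kh + 1
    w = img.shape[1] - kw + 1
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (img[i:i + kh, j:j + kw] * kernel).sum()
    return out


def avg_pool_loop(a, size):
    half = size // 2
    H, W = a.shape
    out = np.zeros_like(a)
    for i in range(H):
        for j in range(W):
            s = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    if 0 <= i + di < H and 0 <= j + dj < W:
                        s += a[i + di, j + dj]
            out[i, j] = s / size ** 2
    return out


def dn_loop(y, n, sigma, p, pool):
    B, C, H, W = y.shape
    yn = (y + POW_EPS) ** n[None, :, None, None]
    z = np.zeros_like(y)
    for b in range(B):
        pooled = np.array([avg_pool_loop(yn[b, k], pool) for k in range(C)])
        for l in range(C):
            den = (sigma[l] + POW_EPS) ** n[l]
            for k in range(C):
                den = den + p[k, l] * pooled[k]
            z[b, l] = yn[b, l] / den
    return z


def extended_dn_loop(y, n, sigma, c, d, k_size, dil, pool):
    B, C, H, W = y.shape
    yn = (y + POW_EPS) ** n[None, :, None, None]
    pk = np.einsum("luvm,klm->lkuv", c, d)
    h = H - dil * (k_size - 1)
    w = W - dil * (k_size - 1)
    s = np.zeros((B, C, h, w))
    for b in range(B):
        pooled = np.array([avg_pool_loop(yn[b, kk], pool) for kk in range(C)])
        for l in range(C):
            for u in range(h):
                for v in range(w):
                    acc = 0.0
                    for kk in range(C):
                        for i in range(k_size):
                            for j in range(k_size):
                                acc += pk[l, kk, i, j] * pooled[kk, u + i * dil,
                                                                v + j * dil]
                    s[b, l, u, v] = acc
    off_r = (H - h) // 2
    off_c = (W - w) // 2
    num = yn[:, :, off_r:off_r + h, off_c:off_c + w]
    return num / ((sigma + POW_EPS)[None, :, None, None]
                  ** n[None, :, None, None] + s)


# ---------------------------------------------------------------------------
# subunit stage
# ---------------------------------------------------------------------------

class TestSubunitForward:
    def test_output_shape_40_to_28(self, rng):
        params = SubunitParams(rng.normal(size=(3, 13, 13)), np.zeros(3),
                               use_bn=False)
        y = subunit_forward(rng.normal(size=(2, 40, 40)), params)
        assert y.data.shape == (2, 3, 28, 28)

    def test_zero_image_zero_bias_gives_zero_maps(self, rng):
        params = SubunitParams(rng.normal(size=(2, 3, 3)), np.zeros(2),
                               use_bn=False)
        y = subunit_forward(np.zeros((1, 5, 5)), params)
        assert np.all(y.data == 0)

    def test_matches_loop_convolution_without_bn(self):
        img = np.arange(25, dtype=float).reshape(5, 5) / 10.0
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        params = SubunitParams(delta[None], np.zeros(1), use_bn=False)
        y = subunit_forward(img[None], params).data[0, 0]
        expected = np.maximum(conv_valid_loop(img, delta), 0.0)
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_rectification_nonnegative(self, rng):
        params = SubunitParams(rng.normal(size=(4, 5, 5)),
                               rng.normal(size=4), use_bn=False)
        y = subunit_forward(rng.normal(size=(3, 12, 12)), params)
        assert np.all(y.data >= 0)

    def test_train_mode_standardizes_with_batch_statistics(self, rng):
        params = SubunitParams(rng.normal(size=(2, 5, 5)), np.zeros(2))
        x = rng.normal(size=(16, 12, 12)) * 3.0 + 1.0
        subunit_forward(x, params, mode="train")
        assert params.bn_mean is not None and np.all(params.bn_var > 0)
        # eval now works and scale-standardizes
        y = subunit_forward(x, params, mode="eval")
        assert np.all(np.isfinite(y.data))

    def test_eval_without_bn_state_rejected(self, rng):
        params = SubunitParams(rng.normal(size=(2, 5, 5)), np.zeros(2))
        with pytest.raises(ValueError, match="bn"):
            subunit_forward(rng.normal(size=(2, 12, 12)), params, mode="eval")

    def test_nonfinite_stimuli_rejected(self, rng):
        params = SubunitParams(rng.normal(size=(2, 5, 5)), np.zeros(2),
                               use_bn=False)
        bad = np.full((1, 12, 12), np.nan)
        with pytest.raises(ValueError, match="finite"):
            subunit_forward(bad, params)


# ---------------------------------------------------------------------------
# divisive normalization
# ---------------------------------------------------------------------------

class TestDNForward:
    def test_identity_when_unnormalized(self, rng):
        C = 3
        y = rng.uniform(0, 2, size=(2, C, 8, 8))
        params = DNParams(np.ones(C), np.ones(C), np.zeros((C, C)))
        z = dn_forward(y, params).data
        # p = 0, sigma = 1, n = 1: denominator collapses to 1 (up to eps)
        np.testing.assert_allclose(z, (y + POW_EPS) / (1 + POW_EPS), rtol=1e-6)

    def test_uniform_field_hand_value(self):
        # single channel, y = 2 everywhere, n = 2, sigma = 1, self-weight 1:
        # interior pooled <y^2> = 4, z = 4 / (1 + 4) = 0.8
        y = np.full((1, 1, 9, 9), 2.0)
        params = DNParams(np.array([2.0]), np.array([1.0]), np.array([[1.0]]),
                          pool_size=3)
        z = dn_forward(y, params).data[0, 0]
        np.testing.assert_allclose(z[2:-2, 2:-2], 0.8, rtol=1e-5)

    def test_matches_loop_oracle(self, rng):
        C = 8
        y = rng.uniform(0, 2, size=(2, C, 12, 12))
        n = rng.uniform(0.5, 2.5, C)
        sigma = rng.uniform(0.5, 2.0, C)
        p = rng.uniform(0, 1, (C, C))
        z = dn_forward(y, DNParams(n, sigma, p, pool_size=5)).data
        zo = dn_loop(y, n, sigma, p, 5)
        assert np.abs(z - zo).max() < 1e-6

    def test_nonnegative_output(self, rng):
        C = 4
        y = rng.uniform(0, 3, size=(2, C, 10, 10))
        params = DNParams(rng.uniform(0.5, 2, C), rng.uniform(0.1, 1, C),
                          rng.uniform(0, 1, (C, C)))
        assert np.all(dn_forward(y, params).data >= 0)

    def test_scale_equivalence_linear_exponent(self, rng):
        # n = 1: scaling drives and semi-saturation by beta leaves z fixed
        C = 3
        y = rng.uniform(0.1, 2, size=(1, C, 10, 10))
        n = np.ones(C)
        sigma = rng.uniform(0.5, 1.5, C)
        p = rng.uniform(0, 1, (C, C))
        beta = 1.9
        za = dn_forward(y, DNParams(n, sigma, p)).data
        zb = dn_forward(y * beta, DNParams(n, sigma * beta, p)).data
        assert np.abs(za - zb).max() < 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            DNParams(np.array([-0.1]), np.array([1.0]), np.array([[0.0]]))
        with pytest.raises(InvalidParameterError):
            DNParams(np.array([1.0]), np.array([1.0]), np.array([[-0.5]]))


class TestExtendedDN:
    def test_kernel1_reduces_to_center_model(self, rng):
        C = 4
        y = rng.uniform(0, 2, size=(2, C, 12, 12))
        n = rng.uniform(0.5, 2, C)
        sigma = rng.uniform(0.5, 1.5, C)
        c = rng.uniform(0, 1, (C, 1, 1, 2))
        d = rng.uniform(0, 1, (C, C, 2))
        ext = ExtendedDNParams(n, sigma, c, d, kernel_size=1, pool_size=3)
        p = np.einsum("lm,klm->kl", c[:, 0, 0, :], d)
        z_ext = extended_dn_forward(y, ext).data
        z_dn = dn_forward(y, DNParams(n, sigma, p, pool_size=3)).data
        assert np.abs(z_ext - z_dn).max() < 1e-10

    def test_matches_nested_loop_oracle(self, rng):
        C = 4
        y = rng.uniform(0, 2, size=(2, C, 12, 12))
        n = rng.uniform(0.5, 2, C)
        sigma = rng.uniform(0.5, 1.5, C)
        c = rng.uniform(0, 1, (C, 3, 3, 2))
        d = rng.uniform(0, 1, (C, C, 2))
        ext = ExtendedDNParams(n, sigma, c, d, kernel_size=3, dilation=2,
                               pool_size=3)
        z = extended_dn_forward(y, ext).data
        zo = extended_dn_loop(y, n, sigma, c, d, 3, 2, 3)
        assert np.abs(z - zo).max() < 1e-6

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            ExtendedDNParams(np.ones(2), np.ones(2),
                             np.zeros((2, 2, 2, 2)), np.zeros((2, 2, 2)),
                             kernel_size=2)


class TestVariants:
    def test_subunit_variant_is_identity_with_identity_jacobian(self, rng):
        y = Tensor(rng.uniform(0, 2, size=(2, 3, 6, 6)), requires_grad=True)
        z = subunit_variant(y)
        assert z is y
        z.sum().backward()
        np.testing.assert_allclose(y.grad, 1.0)

    def test_make_nonspecific_projects_columns_constant(self, rng):
        C = 5
        params = DNParams(np.ones(C), np.ones(C), np.eye(C))
        ns = make_nonspecific(params)
        assert np.allclose(ns.norm_weights, ns.norm_weights[0:1, :])
        # the projection preserves each column's mean
        np.testing.assert_allclose(ns.norm_weights.mean(axis=0),
                                   params.norm_weights.mean(axis=0))

    def test_nonspecific_has_c_free_weights(self):
        # C free normalization weights (one per target) instead of C^2
        C = 32
        p = nonspecific_project(np.random.default_rng(0).uniform(size=(C, C)))
        assert np.unique(p, axis=0).shape[0] == 1
        assert np.unique(p).size == C
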