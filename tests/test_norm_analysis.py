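"""Normalization-input matrix, orientation/cosine splits, binned profiles
and the readout-contribution control."""

import numpy as np
import pytest

from dnv1.core import DNParams, SubunitParams
from dnv1.model import Architecture, EncodingModel
from dnv1.norm_analysis import (NormInputMatrix, bin_by_orientation_difference,
                                cosine_similarity_split, exponent_summary,
                                normalization_input_matrix, readout_contribution,
                                split_similar_dissimilar)
from dnv1.orientation import OrientationEstimate, estimate_orientation
from dnv1.readout import ReadoutParams, TentGrid
from dnv1.synth import SyntheticConfig, make_ground_truth, generate_images


def oriented_estimates(thetas):
    return [OrientationEstimate(1.0 + 0j, 0.5, t, True) for t in thetas]


def _model(filters, n, sigma, p, pool=3):
    C = filters.shape[0]
    fs = 12 - filters.shape[1] + 1
    subunit = SubunitParams(filters, np.zeros(C), use_bn=False)
    dn = DNParams(n, sigma, p, pool_size=pool)
    readout = ReadoutParams(np.zeros((1, fs, fs)), np.zeros((1, C)),
                            np.zeros(1), np.zeros((1, len(TentGrid()))))
    arch = Architecture(channels=C, kernel_size=filters.shape[1], pool_size=pool,
                        variant="dn", use_bn=False, n_neurons=1)
    return EncodingModel(arch, subunit, dn, readout)


class TestNormalizationInputMatrix:
    def test_zero_weights_zero_matrix(self, rng):
        C = 3
        m = _model(rng.normal(size=(C, 5, 5)), np.ones(C), np.ones(C),
                   np.zeros((C, C)))
        res = normalization_input_matrix(m, rng.normal(size=(4, 12, 12)))
        np.testing.assert_allclose(res.matrix, 0.0)

    def test_uniform_drive_hand_value(self):
        """One channel driven at y = 2 everywhere, n = 1, p = 0.5: the
        interior pooled drive is 2, so the entry is 1.0."""
        filt = np.zeros((1, 5, 5))
        filt[0, 2, 2] = 1.0                       # delta filter: y = image
        m = _model(filt, np.ones(1), np.ones(1), np.array([[0.5]]))
        imgs = np.full((1, 16, 16), 2.0)
        res = normalization_input_matrix(m, imgs)
        # border under-pooling dilutes the average slightly below 1.0
        assert 0.8 < res.matrix[0, 0] < 1.0
        # the unpooled variant has no border effect: exactly 1.0 (up to eps)
        res_u = normalization_input_matrix(m, imgs, pooled=False)
        assert res_u.matrix[0, 0] == pytest.approx(1.0, rel=1e-5)

    def test_invariant_to_image_order(self, rng):
        C = 4
        m = _model(rng.normal(size=(C, 5, 5)), np.ones(C), np.ones(C),
                   rng.uniform(0, 1, (C, C)))
        imgs = rng.normal(size=(6, 12, 12))
        a = normalization_input_matrix(m, imgs).matrix
        b = normalization_input_matrix(m, imgs[::-1].copy()).matrix
        np.testing.assert_allclose(a, b, rtol=1e-10)


class TestSplits:
    def test_similar_only_mass_capped_ratio(self):
        est = oriented_estimates([0.0, 0.1, np.pi / 2])
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 1.0        # pairs within 45 degrees
        res = NormInputMatrix(M, est)
        s = split_similar_dissimilar(res)
        assert s.capped and np.isinf(s.fold_ratio)

    def test_uniform_matrix_uniform_orientations_ratio_near_one(self, rng):
        # for orientations drawn uniformly, an acute difference is below
        # 45 degrees with probability 1/2, so uniform input splits evenly
        thetas = rng.uniform(0, np.pi, 400)
        res = NormInputMatrix(np.ones((400, 400)),
                              oriented_estimates(thetas))
        s = split_similar_dissimilar(res)
        assert s.fold_ratio == pytest.approx(1.0, abs=0.15)

    def test_planted_von_mises_profile_ratio_matches_direct_sum(self):
        thetas = np.pi * np.arange(8) / 8
        d = thetas[:, None] - thetas[None, :]
        M = np.exp(np.cos(2 * d))      # kappa = 1
        res = NormInputMatrix(M, oriented_estimates(thetas))
        s = split_similar_dissimilar(res)
        acute = np.minimum(np.abs(d) % np.pi, np.pi - np.abs(d) % np.pi)
        direct = M[acute < np.pi / 4].sum() / M[acute >= np.pi / 4].sum()
        assert s.fold_ratio == pytest.approx(direct)
        assert s.fold_ratio > 1

    def test_too_few_oriented_filters_rejected(self):
        est = [OrientationEstimate(0j, 0.0, 0.0, False)] * 3
        with pytest.raises(ValueError):
            split_similar_dissimilar(NormInputMatrix(np.ones((3, 3)), est))


class TestBinnedProfile:
    def test_mass_at_zero_difference_lands_in_first_bin(self):
        est = oriented_estimates([0.3, 0.3])
        prof = bin_by_orientation_difference(NormInputMatrix(np.ones((2, 2)), est))
        assert prof[0] == pytest.approx(1.0)
        assert np.all(np.isnan(prof[1:]))

    def test_conservation_of_oriented_mass(self, rng):
        thetas = rng.uniform(0, np.pi, 6)
        M = rng.uniform(size=(6, 6))
        res = NormInputMatrix(M, oriented_estimates(thetas))
        prof = bin_by_orientation_difference(res)
        # reconstruct totals: bin mean * bin count sums to the full mass
        counts = np.zeros(9)
        for l in range(6):
            for k in range(6):
                d = abs(thetas[k] - thetas[l]) % np.pi
                d = min(d, np.pi - d)
                counts[min(int(np.rad2deg(d) // 10), 8)] += 1
        total = np.nansum(prof * counts)
        assert total == pytest.approx(M.sum(), rel=1e-9)

    def test_planted_decreasing_profile_recovered_monotone(self):
        from scipy.stats import spearmanr
        thetas = np.pi * np.arange(12) / 12
        d = thetas[:, None] - thetas[None, :]
        M = np.exp(2.0 * np.cos(2 * d))
        prof = bin_by_orientation_difference(
            NormInputMatrix(M, oriented_estimates(thetas)))
        valid = ~np.isnan(prof)
        rho, _ = spearmanr(np.arange(9)[valid], prof[valid])
        assert rho < 0


class TestCosineSplit:
    def test_self_similarity_and_negation(self, rng):
        f = rng.normal(size=(2, 5, 5))
        f[1] = -f[0]
        M = np.ones((2, 2))
        est = oriented_estimates([0.0, 0.0])
        s = cosine_similarity_split(NormInputMatrix(M, est), f)
        # each filter: its own column contributes to similar (cos=1),
        # the negated partner to dissimilar (cos=-1)
        np.testing.assert_allclose(s.similar_per_target, 1.0)
        np.testing.assert_allclose(s.dissimilar_per_target, 1.0)
        assert s.fold_ratio == pytest.approx(1.0)

    def test_matches_pairwise_loop(self, rng):
        C = 5
        f = rng.normal(size=(C, 4, 4))
        M = rng.uniform(size=(C, C))
        s = cosine_similarity_split(
            NormInputMatrix(M, oriented_estimates(np.zeros(C))), f)
        sim = np.zeros(C)
        dis = np.zeros(C)
        for l in range(C):
            for k in range(C):
                c = (f[k].ravel() @ f[l].ravel()
                     / np.linalg.norm(f[k]) / np.linalg.norm(f[l]))
                if c > 0:
                    sim[l] += M[k, l]
                elif c < 0:
                    dis[l] += M[k, l]
        np.testing.assert_allclose(s.similar_per_target, sim)
        np.testing.assert_allclose(s.dissimilar_per_target, dis)


class TestSummaries:
    def test_exponent_summary_pools_models(self, rng):
        cfg = SyntheticConfig(n_images=10, seed=3)
        m1 = make_ground_truth(cfg)
        m2 = make_ground_truth(cfg)
        m1.dn.exponents[:] = 1.0
        m2.dn.exponents[:] = 2.0
        s = exponent_summary([m1, m2])
        assert s["mean"] == pytest.approx(1.5)
        assert s["histogram"].sum() == 32

    def test_readout_contribution_identical_weights(self):
        res = readout_contribution(np.ones((10, 8)))
        assert res["cv"] == pytest.approx(0.0)
        np.testing.assert_allclose(res["mean_per_channel"], 1 / 8)

    def test_readout_contribution_one_hot_closed_form(self):
        C = 16
        b = np.zeros((5, C))
        b[:, 3] = 2.0
        res = readout_contribution(b)
        assert res["cv"] == pytest.approx(np.sqrt(C - 1))

    def test_scaling_degeneracy_removed(self, rng):
        b = rng.uniform(0.1, 1, size=(6, 4))
        scaled = b * rng.uniform(0.5, 5, size=(6, 1))
        a = readout_contribution(b)
        c = readout_contribution(scaled)
        np.testing.assert_allclose(a["mean_per_channel"],
                                   c["mean_per_channel"])

    def test_zero_weight_neuron_excluded_with_warning(self):
        b = np.ones((3, 4))
        b[1] = 0.0
        with pytest.warns(UserWarning, match="zero"):
            res = readout_contribution(b)
        assert res["n_neurons"] == 2
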