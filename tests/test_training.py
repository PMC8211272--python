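"""Optimizer behaviour, constraint projections, the early-stopping
schedule, hyperparameter sampling and model selection."""

import numpy as np
import pytest

from dnv1.core import SubunitParams
from dnv1.init import init_model
from dnv1.losses import LossConfig
from dnv1.model import Architecture
from dnv1.synth import SyntheticConfig, make_dataset
from dnv1.training import (Adam, FitResult, HyperparameterSpace, TrainConfig,
                           sample_hyperparameters, select_top_models, train)


class TestAdam:
    def test_minimizes_quadratic(self):
        params = {"x": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(500):
            opt.step({"x": 2 * params["x"]})
        np.testing.assert_allclose(params["x"], 0.0, atol=1e-3)


class TestSchedule:
    @pytest.fixture(scope="class")
    def small_fit(self):
        cfg = SyntheticConfig(n_images=400, trials=(2, 2), seed=0)
        data, gt = make_dataset(cfg)
        arch = Architecture(channels=16, variant="dn", use_bn=False,
                            n_neurons=cfg.n_neurons)
        sub = SubunitParams(gt.subunit.filters.copy(),
                            gt.subunit.biases.copy(), use_bn=False)
        model = init_model(arch, seed=1, subunit=sub)
        fit = train(data, model, LossConfig(0, 1e-6, 1e-2),
                    TrainConfig(seed=1, max_steps=200, eval_every=50),
                    freeze_filters=True)
        return data, gt, model, fit

    def test_learning_improves_validation_correlation(self, small_fit):
        _, _, _, fit = small_fit
        first = fit.trace[0][3]        # untrained
        assert fit.validation_score > first

    def test_trace_monotone_in_step(self, small_fit):
        _, _, _, fit = small_fit
        steps = [row[0] for row in fit.trace]
        assert steps == sorted(steps)

    def test_constraints_hold_after_training(self, small_fit):
        _, _, model, _ = small_fit
        assert np.all(model.dn.exponents >= 0)
        assert np.all(model.dn.semi_saturation >= 0)
        assert np.all(model.dn.norm_weights >= 0)
        assert np.all(model.readout.spatial >= 0)
        assert np.all(model.readout.feature >= 0)

    def test_nonspecific_constraint_maintained_every_step(self):
        cfg = SyntheticConfig(n_images=300, trials=(2, 2), kappa=0.0, seed=2)
        data, gt = make_dataset(cfg)
        arch = Architecture(channels=16, variant="dn_nonspecific",
                            use_bn=False, n_neurons=cfg.n_neurons)
        sub = SubunitParams(gt.subunit.filters.copy(),
                            gt.subunit.biases.copy(), use_bn=False)
        model = init_model(arch, seed=3, subunit=sub)

        def assert_constant_columns(step, m, vloss, vcorr):
            p = m.dn.norm_weights
            np.testing.assert_array_equal(p, np.broadcast_to(p[0:1], p.shape))

        train(data, model, LossConfig(), TrainConfig(seed=3, max_steps=80,
                                                     eval_every=40),
              freeze_filters=True, eval_callback=assert_constant_columns)
        assert_constant_columns(-1, model, 0, 0)

    def test_missing_partition_rejected(self, small_fit):
        data, gt, _, _ = small_fit
        import copy
        broken = copy.copy(data)
        broken.split = np.full(data.split.shape, "train")
        arch = Architecture(channels=16, variant="dn", use_bn=False,
                            n_neurons=data.responses.shape[2])
        model = init_model(arch, seed=1)
        with pytest.raises(ValueError, match="partition"):
            train(broken, model, LossConfig(), TrainConfig(max_steps=10))


class TestConditionalIdentifiability:
    def test_normalization_weights_recovered_given_rest_of_model(
            self, recovery_population_k1):
        """Conditional maximum likelihood: with the subunit filters,
        exponents, semi-saturation constants and readout held at the
        generating values, the normalization weights alone are strongly
        identifiable from 4000 images x 2 Poisson trials."""
        cfg, data, truth = recovery_population_k1
        arch = Architecture(channels=16, variant="dn", use_bn=False,
                            n_neurons=cfg.n_neurons)
        sub = SubunitParams(truth.subunit.filters.copy(),
                            truth.subunit.biases.copy(), use_bn=False)
        model = init_model(arch, seed=1, subunit=sub)
        for attr in ("spatial", "feature", "bias", "alpha"):
            setattr(model.readout, attr, getattr(truth.readout, attr).copy())
        model.dn.exponents = truth.dn.exponents.copy()
        model.dn.semi_saturation = truth.dn.semi_saturation.copy()
        train(data, model, LossConfig(),
              TrainConfig(seed=1, max_steps=1200), freeze_filters=True,
              trainable={"p"})
        r = np.corrcoef(model.dn.norm_weights.ravel(),
                        truth.dn.norm_weights.ravel())[0, 1]
        assert r >= 0.8


class TestExtendedVariantTraining:
    def test_extended_model_trains_end_to_end(self):
        """Spatially-extended DN: a short fit on 50 px images (needed for
        a 28 px feature space with a 3x3 dilated kernel) runs and
        improves validation correlation."""
        from dnv1.synth import DatasetContainer, generate_images, simulate_population
        arch = Architecture(channels=16, variant="dn_extended",
                            norm_kernel_size=3, use_bn=False, n_neurons=6)
        assert arch.image_side == 50
        truth = init_model(arch, seed=5)
        truth.readout.bias[:] = 1.0        # keep rates away from zero
        imgs = generate_images(300, seed=5, side=50)
        data = simulate_population(truth, imgs, trials=(2, 2), seed=5)
        model = init_model(arch, seed=6)
        fit = train(data, model, LossConfig(),
                    TrainConfig(seed=6, max_steps=60, eval_every=30),
                    freeze_filters=True)
        assert fit.steps_run == 60
        assert np.all(model.dn.spatial_pools >= 0)
        assert np.all(model.dn.feature_weights >= 0)


class TestHyperparameters:
    def test_draws_within_interval(self):
        rng = np.random.default_rng(0)
        space = HyperparameterSpace()
        draws = np.array([sample_hyperparameters(space, rng).lambda_smooth
                          for _ in range(10_000)])
        assert draws.min() >= 10 ** -9 and draws.max() <= 10 ** -3.5

    def test_log_uniformity(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        space = HyperparameterSpace()
        draws = np.log10([sample_hyperparameters(space, rng).lambda_sparse
                          for _ in range(4000)])
        ks = stats.kstest(draws, stats.uniform(loc=-9, scale=4.5).cdf)
        assert ks.statistic < 0.03

    def test_deterministic_under_seed(self):
        space = HyperparameterSpace.for_variant("dn")
        a = [sample_hyperparameters(space, np.random.default_rng(7))
             for _ in range(5)]
        b = [sample_hyperparameters(space, np.random.default_rng(7))
             for _ in range(5)]
        assert [x.lambda_out for x in a] == [x.lambda_out for x in b]

    def test_narrowed_interval_for_constrained_variants(self):
        assert HyperparameterSpace.for_variant("dn").out == (-8.0, 2.0)
        assert HyperparameterSpace.for_variant("dn_nonspecific").out == (-5.0, 0.0)
        assert HyperparameterSpace.for_variant("dn_extended").out == (-5.0, 0.0)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterSpace(smooth=(-3.0, -5.0))


class TestSelection:
    def _fit(self, val, test):
        return FitResult(model=None, validation_score=val, test_score=test)

    def test_selects_top_k_by_validation(self):
        fits = [self._fit(v / 20, v / 20) for v in range(1, 21)]
        s = select_top_models(fits, k=10)
        np.testing.assert_allclose(sorted(s["scores"]),
                                   [v / 20 for v in range(11, 21)])

    def test_identical_fits_zero_ci_width(self):
        fits = [self._fit(0.5, 0.5)] * 10
        s = select_top_models(fits, k=10)
        assert s["ci95"][1] - s["ci95"][0] == pytest.approx(0.0)

    def test_k_one_returns_best(self):
        fits = [self._fit(0.1, 0.2), self._fit(0.9, 0.7)]
        s = select_top_models(fits, k=1)
        assert s["mean"] == pytest.approx(0.7)

    def test_too_few_fits_warns_and_uses_all(self):
        fits = [self._fit(0.1, 0.1), self._fit(0.2, 0.2)]
        with pytest.warns(UserWarning, match="fits"):
            s = select_top_models(fits, k=10)
        assert s["k"] == 2
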