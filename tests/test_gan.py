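"""Architectures, adversarial objectives, the condition-smoothness
regularizer, checkpoint selection, and short-run training contracts."""

import numpy as np
import pytest

from toxgan.data import ScalerState, StudyScalers, TreatmentCondition
from toxgan.fixtures import FixtureConfig, make_fixture
from toxgan.gan import (
    CheckpointRecord,
    Critic,
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
    TrainConfig,
    adversarial_losses,
    build_generator_input,
    generator_regularization,
    select_checkpoint,
    train,
)
from toxgan.nn import Tensor


def _scalers(D):
    n = D + 2
    return StudyScalers(
        condition=ScalerState(np.full(n, -10.0), np.full(n, 10.0)),
        profile=ScalerState(np.full(38, -1.0), np.full(38, 1.0)),
    )


class TestSpecsAndInput:
    def test_full_scale_dimensions(self):
        g = GeneratorSpec(condition_dim=1828)
        assert g.input_dim == 3656
        assert g.noise_dim == 1828
        d = DiscriminatorSpec(profile_dim=38, condition_dim=1828)
        assert d.input_dim == 1866

    @pytest.mark.parametrize("D,total", [(1826, 3656), (10, 24)])
    def test_generator_input_length(self, D, total):
        cond = TreatmentCondition("c", "high", 28, descriptors=np.zeros(D))
        sc = _scalers(D)
        v = build_generator_input(cond, np.zeros(D + 2), sc)
        assert v.shape == (total,)

    def test_generator_input_deterministic_and_ordered(self):
        D = 4
        cond = TreatmentCondition("c", "mid", 7, descriptors=np.arange(D, dtype=float))
        sc = _scalers(D)
        noise = np.arange(D + 2, dtype=float) / 10
        v1 = build_generator_input(cond, noise, sc)
        v2 = build_generator_input(cond, noise, sc)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(v1[D + 2:], noise)  # noise block unscaled

    def test_noise_length_mismatch_raises(self):
        cond = TreatmentCondition("c", "low", 3, descriptors=np.zeros(4))
        with pytest.raises(ValueError, match="noise"):
            build_generator_input(cond, np.zeros(9), _scalers(4))


class TestGeneratorForward:
    def _gen(self, D=4, seed=0):
        spec = GeneratorSpec(condition_dim=D + 2, output_dim=38, hidden=(16, 8))
        return Generator(spec, np.random.default_rng(seed)), spec

    def test_output_shape_and_tanh_range(self):
        G, spec = self._gen()
        X = np.random.default_rng(1).normal(size=(7, spec.input_dim))
        out = G.infer(X)
        assert out.shape == (7, 38)
        assert np.all(np.abs(out) < 1.0)

    def test_batch_permutation_equivariance(self):
        G, spec = self._gen()
        X = np.random.default_rng(2).normal(size=(5, spec.input_dim))
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(G.infer(X)[perm], G.infer(X[perm]), atol=1e-12)

    def test_inference_is_bit_stable(self):
        G, spec = self._gen()
        X = np.random.default_rng(3).normal(size=(4, spec.input_dim))
        np.testing.assert_array_equal(G.infer(X), G.infer(X))

    def test_dimension_mismatch_raises(self):
        G, spec = self._gen()
        with pytest.raises(ValueError):
            G.infer(np.zeros((2, spec.input_dim + 1)))

    def test_weight_snapshot_round_trip(self):
        G, spec = self._gen()
        X = np.random.default_rng(4).normal(size=(3, spec.input_dim))
        before = G.infer(X)
        ws = G.get_weights()
        G2, _ = self._gen(seed=99)
        G2.set_weights(ws)
        np.testing.assert_array_equal(G2.infer(X), before)


class TestAdversarialLosses:
    def test_wgan_separated_scores(self):
        d_loss, g_loss = adversarial_losses(
            "wgan_gp", Tensor(np.array([[1.0], [1.0]])), Tensor(np.array([[0.0], [0.0]]))
        )
        assert d_loss.item() == pytest.approx(-1.0)
        assert g_loss.item() == pytest.approx(0.0)

    def test_wgan_identical_scores_zero(self):
        s = Tensor(np.random.default_rng(0).normal(size=(6, 1)))
        d_loss, _ = adversarial_losses("wgan_gp", s, s)
        assert d_loss.item() == pytest.approx(0.0)

    def test_log_gan_extreme_scores_stay_finite(self):
        # discriminator rejects every fake: the saturating regime, loss -> 0
        d_loss, g_loss = adversarial_losses(
            "log_gan", Tensor(np.full((3, 1), 50.0)), Tensor(np.full((3, 1), -50.0))
        )
        assert np.isfinite(d_loss.item()) and np.isfinite(g_loss.item())
        assert abs(g_loss.item()) < 1e-5
        # discriminator fooled by every fake: log(1 - p) clamps at log(eps)
        _, g_loss2 = adversarial_losses(
            "log_gan", Tensor(np.full((3, 1), 50.0)), Tensor(np.full((3, 1), 50.0))
        )
        assert np.isfinite(g_loss2.item()) and g_loss2.item() < -10

    def test_empty_batches_raise(self):
        with pytest.raises(ValueError):
            adversarial_losses("wgan_gp", Tensor(np.empty((0, 1))), Tensor(np.empty((0, 1))))

    def test_unknown_objective_raises(self):
        s = Tensor(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            adversarial_losses("mystery", s, s)


class _LinearToyGenerator:
    """G(c, z) = slope * c, condition block only."""

    def __init__(self, cdim, slope):
        self.cdim = cdim
        self.slope = slope

    def forward(self, x, train=True):
        return x[:, : self.cdim] * self.slope


class _ConstantGenerator:
    def __init__(self, out):
        self.out = out

    def forward(self, x, train=True):
        return Tensor(np.tile(self.out, (x.data.shape[0], 1)))


class TestGeneratorRegularization:
    def test_condition_independent_generator_gives_zero(self):
        G = _ConstantGenerator(np.zeros(5))
        rng = np.random.default_rng(0)
        term = generator_regularization(
            G, np.zeros((8, 3)), np.zeros((8, 3)), 0.01, 10.0, 1e-8, rng
        )
        assert term.item() == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("slope,tau,expected", [(2.0, 10.0, 2.0), (1e6, 10.0, 10.0)])
    def test_linear_generator_ratio_equals_min_slope_tau(self, slope, tau, expected):
        G = _LinearToyGenerator(cdim=4, slope=slope)
        rng = np.random.default_rng(1)
        term = generator_regularization(
            G, np.zeros((16, 4)), np.zeros((16, 4)), 0.01, tau, 1e-8, rng
        )
        assert term.item() == pytest.approx(expected, rel=1e-6)

    def test_term_bounded_by_tau_and_batch_order_invariant(self):
        rng = np.random.default_rng(2)
        spec = GeneratorSpec(condition_dim=5, output_dim=7, hidden=(8,))
        G = Generator(spec, rng)
        cond = rng.normal(size=(12, 5))
        noise = rng.normal(size=(12, 5))
        tau = 0.5
        t1 = generator_regularization(G, cond, noise, 0.01, tau, 1e-8,
                                      np.random.default_rng(7), train=False)
        assert 0.0 <= t1.item() <= tau + 1e-12

    def test_invalid_sigma_raises(self):
        G = _ConstantGenerator(np.zeros(3))
        with pytest.raises(ValueError):
            generator_regularization(G, np.zeros((2, 3)), np.zeros((2, 3)),
                                     0.0, 10.0, 1e-8, np.random.default_rng(0))


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def tiny_fixture(self):
        return make_fixture(FixtureConfig(n_compounds=2, descriptor_dim=3,
                                          n_animals_per_condition=2,
                                          n_controls_per_time=2, seed=5))

    def test_zero_epochs_is_noop(self, tiny_fixture):
        ds, _, S = tiny_fixture
        cfg = TrainConfig(epochs=0, generator_hidden=(8,), critic_hidden=(8,), seed=0)
        res = train(ds, S, cfg)
        assert res.checkpoints == []
        assert len(res.history) == 0

    def test_same_seed_gives_identical_loss_history(self, tiny_fixture):
        ds, _, S = tiny_fixture
        cfg = TrainConfig(epochs=2, checkpoint_every=2, batch_size=16,
                          generator_hidden=(8,), critic_hidden=(8,), seed=11)
        h1 = train(ds, S, cfg).history
        h2 = train(ds, S, cfg).history
        np.testing.assert_array_equal(h1.to_numpy(), h2.to_numpy())

    def test_checkpoints_carry_metrics(self, tiny_fixture):
        ds, _, S = tiny_fixture
        cfg = TrainConfig(epochs=2, checkpoint_every=1, batch_size=16,
                          generator_hidden=(8,), critic_hidden=(8,), seed=1,
                          n_target_draws=10)
        res = train(ds, S, cfg)
        assert [c.epoch for c in res.checkpoints] == [1, 2]
        for c in res.checkpoints:
            assert 0.0 <= c.validity_rate <= 1.0


class TestSelectCheckpoint:
    def _rec(self, epoch, cos, rm):
        return CheckpointRecord(epoch=epoch, weights=[], mean_cosine=cos, mean_rmse=rm)

    def test_argmax_cosine(self):
        recs = [self._rec(1, 0.90, 5), self._rec(2, 0.99, 5), self._rec(3, 0.95, 5)]
        assert select_checkpoint(recs).epoch == 2

    def test_tie_broken_by_rmse_then_epoch(self):
        recs = [self._rec(1, 0.9, 5.0), self._rec(2, 0.9, 3.0)]
        assert select_checkpoint(recs).epoch == 2
        recs = [self._rec(1, 0.9, 3.0), self._rec(2, 0.9, 3.0)]
        assert select_checkpoint(recs).epoch == 2

    def test_single_and_empty(self):
        only = self._rec(7, 0.5, 1.0)
        assert select_checkpoint([only]) is only
        with pytest.raises(ValueError):
            select_checkpoint([])
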