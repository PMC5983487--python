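import math

import numpy as np
import pytest

from crfalign.factors import init_bank
from crfalign.lattice import Label, LatticeDims, enumerate_alignments, labels_to_positions
from crfalign.synthetic import SyntheticConfig, simulate_dataset
from crfalign.training import (TrainConfig, loss, loss_gradient,
                               sgd_momentum_step, train)
from conftest import zero_bank
from helpers import constant_tracks, random_tracks

M, Iq, It = Label.M, Label.Iq, Label.It


class TestLoss:
    def test_uniform_unit_lattice_loss_is_log3(self):
        bank = zero_bank(1)
        ds = [(constant_tracks(1, 1), labels_to_positions([M], LatticeDims(1, 1)))]
        assert loss(bank, ds, l2=0.0) == pytest.approx(math.log(3), rel=1e-12)

    def test_zero_parameters_make_regularizer_vanish(self):
        bank = zero_bank(1)
        ds = [(constant_tracks(1, 1), labels_to_positions([M], LatticeDims(1, 1)))]
        assert loss(bank, ds, l2=5.0) == loss(bank, ds, l2=0.0)

    def test_matches_enumerated_path_probability(self, order, rng):
        bank = init_bank(order, seed=2)
        tracks = random_tracks(rng, 2, 2)
        ref = list(enumerate_alignments(LatticeDims(2, 2)))[5]
        from crfalign.inference import path_log_probability
        expected = -path_log_probability(ref, bank, tracks)
        assert loss(bank, [(tracks, ref)], l2=0.0) == pytest.approx(expected, rel=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            loss(init_bank(1, seed=0), [], l2=0.0)


class TestLossGradient:
    def test_matches_central_finite_differences(self, order, rng):
        bank = init_bank(order, seed=6)
        ds = [(random_tracks(rng, 2, 2), p)
              for p in list(enumerate_alignments(LatticeDims(2, 2)))[3:5]]
        grad = loss_gradient(bank, ds, l2=0.01)
        theta = bank.flatten()
        h = 1e-5
        stride = 17 if order == 2 else 5  # probe a spread of parameters
        for i in range(0, len(theta), stride):
            t = theta.copy()
            t[i] += h
            bank.unflatten(t)
            up = loss(bank, ds, l2=0.01)
            t[i] -= 2 * h
            bank.unflatten(t)
            down = loss(bank, ds, l2=0.01)
            fd = (up - down) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        bank.unflatten(theta)

    def test_regularizer_gradient_is_scaled_theta(self):
        """The l2 part of the gradient is exactly 2*l2*theta/L_theta."""
        bank = init_bank(1, seed=1)
        ds = [(constant_tracks(2, 2), labels_to_positions([M, M], LatticeDims(2, 2)))]
        g0 = loss_gradient(bank, ds, l2=0.0)
        g1 = loss_gradient(bank, ds, l2=0.5)
        theta = bank.flatten()
        assert np.allclose(g1 - g0, 2 * 0.5 / bank.n_params * theta)


class TestSgdStep:
    def test_plain_descent_when_gamma_zero(self):
        theta, vel = np.array([1.0, -1.0]), np.zeros(2)
        t2, v2 = sgd_momentum_step(theta, np.array([0.5, 0.5]), vel, eta=0.1, gamma=0.0)
        assert np.allclose(t2, [0.95, -1.05])

    def test_momentum_coasting_with_zero_gradient(self):
        theta, vel = np.zeros(2), np.array([0.2, -0.2])
        t2, v2 = sgd_momentum_step(theta, np.zeros(2), vel, eta=0.1, gamma=0.5)
        assert np.allclose(t2, [0.1, -0.1])
        assert np.allclose(v2, [0.1, -0.1])

    def test_worked_example(self):
        t2, v2 = sgd_momentum_step(np.zeros(2), np.array([1.0, -1.0]), np.zeros(2),
                                   eta=0.01, gamma=0.5)
        assert np.allclose(t2, [-0.01, 0.01])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sgd_momentum_step(np.zeros(2), np.zeros(3), np.zeros(2), 0.1, 0.5)


@pytest.fixture(scope="module")
def tiny_splits():
    cfg = SyntheticConfig(n_pairs=12, n_train=8, n_valid=2,
                          length_range=(5, 8), seed=21)
    return simulate_dataset(cfg)


class TestTrainLoop:

    def test_loss_decreases_on_synthetic_data(self, tiny_splits):
        model = train(tiny_splits["train"], tiny_splits["valid"],
                      TrainConfig(order=1, epochs=12, seed=1))
        losses = [r.loss for r in model.history]
        assert losses[-1] < losses[0]
        assert model.selected_epoch == max(
            range(len(model.history)),
            key=lambda i: (model.history[i].valid_accuracy, -i))

    def test_same_config_reproduces_identical_history(self, tiny_splits):
        cfg = TrainConfig(order=1, epochs=4, seed=5)
        m1 = train(tiny_splits["train"], tiny_splits["valid"], cfg)
        m2 = train(tiny_splits["train"], tiny_splits["valid"], cfg)
        assert [r.loss for r in m1.history] == [r.loss for r in m2.history]
        assert np.array_equal(m1.bank.flatten(), m2.bank.flatten())

    def test_zero_epochs_returns_initial_model(self, tiny_splits):
        model = train(tiny_splits["train"], tiny_splits["valid"],
                      TrainConfig(order=1, epochs=0, seed=3))
        assert model.history == []
        assert model.selected_epoch == -1

    def test_single_pair_reference_probability_increases(self, rng):
        """With no regularization, gradient steps raise the probability of
        the single training path (monotone apart from float noise)."""
        from crfalign.inference import path_log_probability
        tracks = random_tracks(rng, 3, 3)
        ref = labels_to_positions([M, Iq, M, It], LatticeDims(3, 3))
        bank = init_bank(1, seed=4)
        probs = []
        theta = bank.flatten()
        vel = np.zeros_like(theta)
        for _ in range(25):
            probs.append(path_log_probability(ref, bank, tracks))
            g = loss_gradient(bank, [(tracks, ref)], l2=0.0)
            theta, vel = sgd_momentum_step(theta, g, vel, eta=0.05, gamma=0.0)
            bank.unflatten(theta)
        assert path_log_probability(ref, bank, tracks) > probs[0]
        assert probs[-1] > probs[0]

    def test_dataset_order_invariance(self, tiny_splits):
        cfg = TrainConfig(order=1, epochs=3, seed=2)
        fwd = train(tiny_splits["train"], tiny_splits["valid"], cfg)
        rev = train(list(reversed(tiny_splits["train"])), tiny_splits["valid"], cfg)
        assert fwd.history[-1].loss == pytest.approx(rev.history[-1].loss, rel=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(eta=0.0)
        with pytest.raises(ValueError):
            TrainConfig(gamma=1.0)
        with pytest.raises(ValueError):
            TrainConfig(order=3)
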