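"""Maximum-likelihood training of the alignment CRF.

The loss is the mean negative log-probability of the reference alignments
plus an L2 penalty scaled by the parameter count:

    l(theta) = -(1/N) sum_n log p(A_n | features_n, theta)
               + (l2 / L_theta) * sum_k theta_k^2

minimized by full-batch gradient descent with momentum (the training set is
not split into batches; one update per epoch).  The data term's gradient is
the difference between expected and observed factor statistics: expected
under the pattern posteriors from forward-backward, observed along the
reference path (with the dummy labels preceding the path weighted by their
posterior share).  This is mathematically the derivative of log Z minus the
derivative of the path's log weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import aggregate_accuracy, reference_dependent_accuracy
from .factors import FactorBank, init_bank, select_constant_patterns
from .features import FeatureTracks, Normalizer, apply_normalizer, fit_normalizer
from .decoding import viterbi_decode
from .inference import (PairCache, forward_backward, path_pattern_weights,
                        pattern_posteriors)
from .lattice import AlignmentPath

Pair = tuple[FeatureTracks, AlignmentPath]


@dataclass
class TrainConfig:
    order: int = 1
    l2: float = 0.001
    eta: float = 0.01
    gamma: float = 0.5
    epochs: int = 100
    seed: int = 0
    constant_threshold: float = 0.002

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate eta must be > 0")
        if not 0 <= self.gamma < 1:
            raise ValueError("momentum gamma must be in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    train_accuracy: float
    valid_accuracy: float


@dataclass
class TrainedModel:
    bank: FactorBank
    normalizer: Normalizer
    config: TrainConfig
    history: list[EpochRecord] = field(default_factory=list)
    selected_epoch: int = -1


def _pair_loss_and_counts(bank, cache, path):
    """Per-pair negative log-likelihood and (posterior - observed) pattern
    occupancy grids, the per-pattern weights of the gradient."""
    tables = forward_backward(bank, None, cache)
    counts = pattern_posteriors(tables)
    lw, occ = path_pattern_weights(path, tables.log_psi, bank.order)
    for fp, entries in occ.items():
        grid = counts[fp]
        for (x, y), w in entries:
            grid[x, y] -= w
    return tables.logZ - lw, counts


def _accumulate_factor_grads(bank, cache, counts, grad, slices):
    """Fold pattern-occupancy weights into per-factor parameter gradients."""
    for sub in bank.patterns:
        k = len(sub)
        w = None
        for fp, grid in counts.items():
            if fp[-k:] == sub:
                w = grid if w is None else w + grid
        grad[slices[sub]] += bank.factors[sub].grad_batch(cache.inputs[sub], w.ravel())


def loss(bank: FactorBank, dataset: list[Pair], l2: float = 0.0,
         caches: list[PairCache] | None = None) -> float:
    """Regularized mean negative log-likelihood of the reference paths."""
    if not dataset:
        raise ValueError("empty dataset")
    caches = caches or [PairCache(t, bank.order) for t, _ in dataset]
    nll = 0.0
    for (tracks, path), cache in zip(dataset, caches):
        if not path.is_global or path.dims != tracks.dims:
            raise ValueError(f"invalid reference path for pair with dims {tracks.dims}")
        tables = forward_backward(bank, tracks, cache)
        lw, _ = path_pattern_weights(path, tables.log_psi, bank.order)
        nll += tables.logZ - lw
    theta = bank.flatten()
    return nll / len(dataset) + l2 / bank.n_params * float(theta @ theta)


def loss_gradient(bank: FactorBank, dataset: list[Pair], l2: float = 0.0,
                  caches: list[PairCache] | None = None) -> np.ndarray:
    """Gradient of :func:`loss` w.r.t. the flattened parameter vector."""
    return _loss_and_gradient(bank, dataset, l2, caches)[1]


def _loss_and_gradient(bank, dataset, l2, caches=None):
    if not dataset:
        raise ValueError("empty dataset")
    caches = caches or [PairCache(t, bank.order) for t, _ in dataset]
    slices = bank.param_slices()
    grad = np.zeros(bank.n_params)
    nll = 0.0
    for (tracks, path), cache in zip(dataset, caches):
        pair_nll, counts = _pair_loss_and_counts(bank, cache, path)
        nll += pair_nll
        _accumulate_factor_grads(bank, cache, counts, grad, slices)
    n = len(dataset)
    theta = bank.flatten()
    grad = grad / n + 2.0 * l2 / bank.n_params * theta
    total = nll / n + l2 / bank.n_params * float(theta @ theta)
    return total, grad


def sgd_momentum_step(theta: np.ndarray, grad: np.ndarray, velocity: np.ndarray,
                      eta: float, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """One momentum update:  v' = gamma*v - eta*g,  theta' = theta + v'."""
    if theta.shape != grad.shape or theta.shape != velocity.shape:
        raise ValueError("theta, grad and velocity shapes must agree")
    velocity = gamma * velocity - eta * grad
    return theta + velocity, velocity


def _decoded_accuracy(bank, pairs, caches) -> float:
    results = []
    for (tracks, ref), cache in zip(pairs, caches):
        pred, _ = viterbi_decode(bank, tracks, cache)
        results.append(reference_dependent_accuracy(pred, ref))
    return aggregate_accuracy(results, "per-pair")


def train(train_set: list[Pair], valid_set: list[Pair], config: TrainConfig,
          bank: FactorBank | None = None, verbose: bool = False) -> TrainedModel:
    """Full-batch training with per-epoch history and validation-based model
    selection (best validation accuracy; ties go to the earliest epoch).

    The feature normalizer is fitted on the training set only; rarely seen
    label patterns (empirical frequency below ``config.constant_threshold``
    among the training paths) get constant factors instead of networks.
    """
    if not train_set or not valid_set:
        raise ValueError("training and validation sets must be non-empty")
    normalizer = fit_normalizer([t for t, _ in train_set])
    train_pairs = [(apply_normalizer(normalizer, t), p) for t, p in train_set]
    valid_pairs = [(apply_normalizer(normalizer, t), p) for t, p in valid_set]
    if bank is None:
        constant = select_constant_patterns([p for _, p in train_set], config.order,
                                            config.constant_threshold)
        bank = init_bank(config.order, constant_patterns=constant, seed=config.seed)
    train_caches = [PairCache(t, config.order) for t, _ in train_pairs]
    valid_caches = [PairCache(t, config.order) for t, _ in valid_pairs]

    model = TrainedModel(bank=bank, normalizer=normalizer, config=config)
    theta = bank.flatten()
    velocity = np.zeros_like(theta)
    best_theta = theta.copy()
    best_acc = -1.0
    for epoch in range(config.epochs):
        value, grad = _loss_and_gradient(bank, train_pairs, config.l2, train_caches)
        if not np.isfinite(value):
            raise FloatingPointError(f"training diverged at epoch {epoch}: loss={value}")
        train_acc = _decoded_accuracy(bank, train_pairs, train_caches)
        valid_acc = _decoded_accuracy(bank, valid_pairs, valid_caches)
        model.history.append(EpochRecord(epoch, value, train_acc, valid_acc))
        if valid_acc > best_acc:
            best_acc = valid_acc
            best_theta = theta.copy()
            model.selected_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  loss {value:.4f}  "
                  f"train {train_acc:5.1f}%  valid {valid_acc:5.1f}%")
        theta, velocity = sgd_momentum_step(theta, grad, velocity, config.eta, config.gamma)
        bank.unflatten(theta)
    if model.history:
        bank.unflatten(best_theta)
    return model
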