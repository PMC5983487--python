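"""Log-factors and the scoring function of the alignment CRF.

The score of a label pattern at a lattice position is

    log Psi = phi^v  (+ phi^{u->v})  (+ chi^{t->u->v})

with a node factor for the last label, an edge factor for the last two and,
at order 2, a triple factor for all three.  Each factor is either a small
neural network (one hidden layer of 12 tanh units, no bias anywhere) fed the
concatenated per-label feature vector of its pattern, or a single trainable
constant for patterns too rare in training to support a network.

Everything is kept in the log domain; the exponential of the score is never
materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_DIMS, FeatureTracks, factor_input, pattern_input_dim
from .lattice import AlignmentPath, Label, label_patterns, pattern_from_name, pattern_name

HIDDEN_UNITS = 12
INIT_SCALE = 0.1

CONSTANT_FREQ_THRESHOLD = 0.002


@dataclass
class NNLogFactor:
    """One-hidden-layer network without bias: ``out = w2 . tanh(x @ W1)``."""

    W1: np.ndarray  # (input_dim, HIDDEN_UNITS)
    w2: np.ndarray  # (HIDDEN_UNITS,)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.w2.size

    def value(self, x: np.ndarray) -> float:
        if x.shape != (self.input_dim,):
            raise ValueError(f"expected input of length {self.input_dim}, got {x.shape}")
        return float(np.tanh(x @ self.W1) @ self.w2)

    def value_batch(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1) @ self.w2

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Scalar output and its gradient w.r.t. the flattened parameters
        (W1 entries row-major, then w2)."""
        h = np.tanh(x @ self.W1)
        gW1 = np.outer(x, self.w2 * (1.0 - h * h))
        return float(h @ self.w2), np.concatenate([gW1.ravel(), h])

    def grad_batch(self, X: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """``sum_i weights[i] * d value(X[i]) / d params``."""
        H = np.tanh(X @ self.W1)
        gw2 = H.T @ weights
        gW1 = X.T @ ((1.0 - H * H) * self.w2[None, :] * weights[:, None])
        return np.concatenate([gW1.ravel(), gw2])

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.w2])

    def set_params(self, v: np.ndarray) -> None:
        n1 = self.W1.size
        self.W1 = v[:n1].reshape(self.W1.shape).copy()
        self.w2 = v[n1:n1 + self.w2.size].copy()


@dataclass
class ConstantLogFactor:
    """A single trainable value that ignores the features."""

    value_param: float = 0.0

    input_dim = None
    n_params = 1

    def value(self, x: np.ndarray) -> float:
        return self.value_param

    def value_batch(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.value_param)

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return self.value_param, np.ones(1)

    def grad_batch(self, X: np.ndarray, weights: np.ndarray) -> np.ndarray:
        return np.array([weights.sum()])

    def get_params(self) -> np.ndarray:
        return np.array([self.value_param])

    def set_params(self, v: np.ndarray) -> None:
        self.value_param = float(v[0])


LogFactor = NNLogFactor | ConstantLogFactor


def select_constant_patterns(training_paths: list[AlignmentPath], order: int,
                             threshold: float = CONSTANT_FREQ_THRESHOLD) -> set[tuple[Label, ...]]:
    """Label patterns whose empirical frequency among all length-(order+1)
    windows of the training paths is strictly below ``threshold`` (patterns
    never seen included).  Those get constant factors instead of networks."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    width = order + 1
    counts: dict[tuple[Label, ...], int] = {p: 0 for p in label_patterns(width)}
    total = 0
    for path in training_paths:
        labs = path.labels
        for i in range(len(labs) - width + 1):
            counts[tuple(labs[i:i + width])] += 1
            total += 1
    if total == 0:
        raise ValueError("training paths contain no label window of the required width")
    return {p for p, c in counts.items() if c / total < threshold}


@dataclass
class FactorBank:
    """All log-factors of a model: 3 node + 9 edge patterns (order 1), plus
    27 triple patterns at order 2; 12 or 39 factors in total."""

    order: int
    factors: dict[tuple[Label, ...], LogFactor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 12 if self.order == 1 else 39
        if len(self.factors) != expected:
            raise ValueError(f"order {self.order} bank needs {expected} factors, "
                             f"got {len(self.factors)}")

    @property
    def patterns(self) -> list[tuple[Label, ...]]:
        """All factor patterns, nodes first, in label order (deterministic)."""
        pats = label_patterns(1) + label_patterns(2)
        if self.order == 2:
            pats += label_patterns(3)
        return pats

    @property
    def full_patterns(self) -> list[tuple[Label, ...]]:
        """The order+1 length patterns the scoring function is defined on."""
        return label_patterns(self.order + 1)

    @property
    def n_params(self) -> int:
        return sum(f.n_params for f in self.factors.values())

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.factors[p].get_params() for p in self.patterns])

    def unflatten(self, v: np.ndarray) -> None:
        if v.shape != (self.n_params,):
            raise ValueError(f"expected parameter vector of length {self.n_params}")
        off = 0
        for p in self.patterns:
            f = self.factors[p]
            f.set_params(v[off:off + f.n_params])
            off += f.n_params

    def param_slices(self) -> dict[tuple[Label, ...], slice]:
        out, off = {}, 0
        for p in self.patterns:
            n = self.factors[p].n_params
            out[p] = slice(off, off + n)
            off += n
        return out

    def scoring_function(self, pattern: tuple[Label, ...], pos: tuple[int, int],
                         tracks: FeatureTracks) -> float:
        """log Psi of a full-order label pattern at a lattice position: the
        node factor on the last label's vector, the edge factor on the last
        two, and (order 2) the triple factor on all three."""
        if len(pattern) != self.order + 1:
            raise ValueError(f"order {self.order} scoring needs a pattern of length "
                             f"{self.order + 1}, got {len(pattern)}")
        total = 0.0
        for k in (1, 2, 3)[:self.order + 1]:
            sub = pattern[-k:]
            total += self.factors[sub].value(factor_input(sub, pos, tracks))
        return total


def init_bank(order: int, constant_patterns: set[tuple[Label, ...]] | None = None,
              seed: int = 0, feature_dims: dict[Label, int] | None = None) -> FactorBank:
    """Fresh bank: network factors get small uniform random weights in
    ``[-0.1, 0.1]`` from the seed, constant factors start at 0."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dims = feature_dims or FEATURE_DIMS
    constant_patterns = constant_patterns or set()
    all_pats = label_patterns(1) + label_patterns(2) + (label_patterns(3) if order == 2 else [])
    for p in constant_patterns:
        if p not in all_pats:
            raise ValueError(f"unknown constant pattern {pattern_name(p)}")
    rng = np.random.default_rng(seed)
    factors: dict[tuple[Label, ...], LogFactor] = {}
    for p in all_pats:
        if p in constant_patterns:
            factors[p] = ConstantLogFactor(0.0)
        else:
            d = sum(dims[lab] for lab in p)
            factors[p] = NNLogFactor(
                W1=rng.uniform(-INIT_SCALE, INIT_SCALE, size=(d, HIDDEN_UNITS)),
                w2=rng.uniform(-INIT_SCALE, INIT_SCALE, size=HIDDEN_UNITS),
            )
    return FactorBank(order=order, factors=factors)


def bank_to_dict(bank: FactorBank) -> dict:
    out = {"order": bank.order, "factors": {}}
    for p, f in bank.factors.items():
        if isinstance(f, NNLogFactor):
            out["factors"][pattern_name(p)] = {
                "kind": "nn", "W1": f.W1.tolist(), "w2": f.w2.tolist()}
        else:
            out["factors"][pattern_name(p)] = {"kind": "constant", "value": f.value_param}
    return out


def bank_from_dict(d: dict) -> FactorBank:
    factors: dict[tuple[Label, ...], LogFactor] = {}
    for name, spec in d["factors"].items():
        p = pattern_from_name(name)
        if spec["kind"] == "nn":
            f = NNLogFactor(W1=np.asarray(spec["W1"], dtype=float),
                            w2=np.asarray(spec["w2"], dtype=float))
            if f.W1.shape != (pattern_input_dim(p), HIDDEN_UNITS) or f.w2.shape != (HIDDEN_UNITS,):
                raise ValueError(f"factor {name}: weight shapes do not match its pattern")
        elif spec["kind"] == "constant":
            f = ConstantLogFactor(float(spec["value"]))
        else:
            raise ValueError(f"factor {name}: unknown kind {spec['kind']!r}")
        factors[p] = f
    return FactorBank(order=int(d["order"]), factors=factors)
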