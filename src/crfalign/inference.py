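"""Exact inference on the alignment lattice: forward-backward tables,
partition function, pattern posteriors and path probabilities.

The forward recursion keeps one term per suffix label pattern (3 at order 1,
9 at order 2) and cell:

    alpha^{u->v}(x, y) = sum_t  Psi^{t->u->v}(x, y) * alpha^{t->u}(x_p, y_p)

where the predecessor cell is fixed by the move of the incoming label ``v``
and the dummy corner is initialized to 1 for every suffix pattern (which
marginalizes the unspecified labels preceding the path).  The backward
recursion mirrors it over prefix patterns; both yield the same partition
function Z.  All quantities live in the log domain (log-sum-exp); ``-inf``
marks unreachable states.

The per-cell score tables log Psi are precomputed for the whole lattice by
evaluating every factor network as one batched matrix product over all
cells (a :class:`PairCache`); the recursions themselves run over plain
Python lists, which for the small per-cell state space is faster than
per-cell numpy calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .factors import FactorBank
from .features import FEATURE_DIMS, FeatureTracks
from .lattice import AlignmentPath, Label, LatticeDims, MOVES, label_patterns, pattern_name

NEG_INF = float("-inf")


@lru_cache(maxsize=None)
def suffix_states(order: int) -> tuple[tuple[Label, ...], ...]:
    """Suffix label patterns tracked per cell: 3 labels or 9 label pairs."""
    return tuple(label_patterns(order))


@lru_cache(maxsize=None)
def transitions(order: int) -> tuple[tuple[tuple[Label, ...], int, int, int, int], ...]:
    """Per full pattern ``fp``: (fp, prev-state index, new-state index, dx, dy)
    where the move (dx, dy) is that of the incoming label ``fp[-1]``."""
    states = suffix_states(order)
    idx = {s: i for i, s in enumerate(states)}
    out = []
    for fp in label_patterns(order + 1):
        dx, dy = MOVES[fp[-1]]
        out.append((fp, idx[fp[:-1]], idx[fp[1:]], dx, dy))
    return tuple(out)


class PairCache:
    """Per-pair precomputation: factor input matrices for every label
    (sub)pattern over all ``(Lq+1) x (Lt+1)`` cells.  Inputs depend only on
    the features, so one cache serves every epoch of training."""

    def __init__(self, tracks: FeatureTracks, order: int):
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.order = order
        self.dims = tracks.dims
        Lq, Lt = self.dims.Lq, self.dims.Lt
        padded = {}
        for lab, d in FEATURE_DIMS.items():
            grid = np.zeros((Lq + 1, Lt + 1, d))
            grid[1:, 1:] = tracks.grid(lab)
            padded[lab] = grid
        self.inputs: dict[tuple[Label, ...], np.ndarray] = {}
        for k in range(1, order + 2):
            for sub in label_patterns(k):
                segs: list[np.ndarray] = []
                dx = dy = 0
                for j in range(k - 1, -1, -1):
                    segs.append(self._shift(padded[sub[j]], dx, dy))
                    mx, my = MOVES[sub[j]]
                    dx, dy = dx + mx, dy + my
                cat = np.concatenate(segs[::-1], axis=-1)
                self.inputs[sub] = cat.reshape(-1, cat.shape[-1])

    @staticmethod
    def _shift(grid: np.ndarray, dx: int, dy: int) -> np.ndarray:
        if dx == 0 and dy == 0:
            return grid
        out = np.zeros_like(grid)
        nx, ny = grid.shape[0] - dx, grid.shape[1] - dy
        out[dx:, dy:] = grid[:nx, :ny]
        return out

    def log_psi_tables(self, bank: FactorBank) -> dict[tuple[Label, ...], np.ndarray]:
        """log Psi per full-order pattern over the whole lattice."""
        if bank.order != self.order:
            raise ValueError("bank order does not match cache order")
        Lq, Lt = self.dims.Lq, self.dims.Lt
        shape = (Lq + 1, Lt + 1)
        values = {sub: bank.factors[sub].value_batch(self.inputs[sub]).reshape(shape)
                  for sub in bank.patterns}
        tables = {}
        for fp in bank.full_patterns:
            t = values[fp[-1:]] + values[fp[-2:]]
            if self.order == 2:
                t = t + values[fp]
            if not np.all(np.isfinite(t)):
                bad = np.argwhere(~np.isfinite(t))[0]
                raise FloatingPointError(
                    f"non-finite score for pattern {pattern_name(fp)} at cell "
                    f"({bad[0]}, {bad[1]})")
            tables[fp] = t
        return tables


@dataclass
class ForwardBackwardTables:
    order: int
    dims: LatticeDims
    alpha: np.ndarray  # (Lq+1, Lt+1, n_states), log domain
    beta: np.ndarray
    logZ: float
    logZ_backward: float
    log_psi: dict[tuple[Label, ...], np.ndarray]


def _logaddexp(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def _forward(log_psi, order: int, dims: LatticeDims) -> np.ndarray:
    Lq, Lt = dims.Lq, dims.Lt
    n_states = len(suffix_states(order))
    trans = [(log_psi[fp].tolist(), ps, ns, dx, dy)
             for fp, ps, ns, dx, dy in transitions(order)]
    alpha = [[[NEG_INF] * n_states for _ in range(Lt + 1)] for _ in range(Lq + 1)]
    alpha[0][0] = [0.0] * n_states
    for x in range(Lq + 1):
        ax = alpha[x]
        for y in range(Lt + 1):
            if x == 0 and y == 0:
                continue
            cell = ax[y]
            for table, ps, ns, dx, dy in trans:
                px, py = x - dx, y - dy
                if px < 0 or py < 0:
                    continue
                a = alpha[px][py][ps]
                if a == NEG_INF:
                    continue
                cell[ns] = _logaddexp(cell[ns], a + table[x][y])
    return np.array(alpha)


def _backward(log_psi, order: int, dims: LatticeDims) -> np.ndarray:
    Lq, Lt = dims.Lq, dims.Lt
    n_states = len(suffix_states(order))
    trans = [(log_psi[fp].tolist(), ps, ns, dx, dy)
             for fp, ps, ns, dx, dy in transitions(order)]
    beta = [[[NEG_INF] * n_states for _ in range(Lt + 1)] for _ in range(Lq + 1)]
    beta[Lq][Lt] = [0.0] * n_states
    for x in range(Lq, -1, -1):
        bx = beta[x]
        for y in range(Lt, -1, -1):
            if x == Lq and y == Lt:
                continue
            cell = bx[y]
            for table, ps, ns, dx, dy in trans:
                nx, ny = x + dx, y + dy
                if nx > Lq or ny > Lt:
                    continue
                b = beta[nx][ny][ns]
                if b == NEG_INF:
                    continue
                cell[ps] = _logaddexp(cell[ps], b + table[nx][ny])
    return np.array(beta)


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if m == NEG_INF:
        return NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


def forward_backward(bank: FactorBank, tracks: FeatureTracks,
                     cache: PairCache | None = None) -> ForwardBackwardTables:
    """Run both passes and return the complete tables with log Z."""
    cache = cache or PairCache(tracks, bank.order)
    log_psi = cache.log_psi_tables(bank)
    dims = cache.dims
    alpha = _forward(log_psi, bank.order, dims)
    beta = _backward(log_psi, bank.order, dims)
    logZ = _logsumexp(alpha[dims.Lq, dims.Lt])
    logZ_b = _logsumexp(beta[0, 0])
    return ForwardBackwardTables(bank.order, dims, alpha, beta, logZ, logZ_b, log_psi)


def pattern_posteriors(tables: ForwardBackwardTables) -> dict[tuple[Label, ...], np.ndarray]:
    """Posterior probability that a path realizes each full-order label
    pattern at each cell:  alpha(prev) * Psi * beta(here) / Z.

    Summed over patterns and cells this equals the expected alignment
    length; per cell it is the probability that any path passes through."""
    Lq, Lt = tables.dims.Lq, tables.dims.Lt
    out = {}
    for fp, ps, ns, dx, dy in transitions(tables.order):
        a_prev = np.full((Lq + 1, Lt + 1), NEG_INF)
        a_prev[dx:, dy:] = tables.alpha[:Lq + 1 - dx, :Lt + 1 - dy, ps]
        logp = a_prev + tables.log_psi[fp] + tables.beta[:, :, ns] - tables.logZ
        post = np.exp(logp, where=logp != NEG_INF, out=np.zeros_like(logp))
        out[fp] = post
    return out


def path_pattern_weights(path: AlignmentPath, log_psi,
                         order: int) -> tuple[float, dict[tuple[Label, ...], list]]:
    """Log weight of a path (its score summed over the dummy labels that
    precede it) and, per full pattern, the (cell, weight) occupancies whose
    weighted sum is the gradient statistic of the log weight.

    At every interior step the pattern is determined by the path; at the
    first step (first two, at order 2) the unspecified dummy labels carry a
    softmax weight proportional to their share of the path weight.
    """
    labs, pos = path.labels, path.positions
    occ: dict[tuple[Label, ...], list] = {}

    def add(fp, cell, w):
        occ.setdefault(fp, []).append((cell, w))

    fixed = 0.0
    start = min(order, len(labs))
    for i in range(start, len(labs)):
        fp = tuple(labs[i - order:i + 1])
        fixed += log_psi[fp][pos[i]]
        add(fp, pos[i], 1.0)

    if order == 1:
        scores = np.array([log_psi[(u, labs[0])][pos[0]] for u in Label])
        lw = _logsumexp(scores) + fixed
        w = np.exp(scores - _logsumexp(scores))
        for u, wu in zip(Label, w):
            add((u, labs[0]), pos[0], float(wu))
    else:
        # joint softmax over the two dummy labels (t, u); u also enters the
        # second step's pattern when the path has length >= 2
        scores = np.empty((3, 3))
        for t in Label:
            for u in Label:
                s = log_psi[(t, u, labs[0])][pos[0]]
                if len(labs) >= 2:
                    s += log_psi[(u, labs[0], labs[1])][pos[1]]
                scores[t, u] = s
        tot = _logsumexp(scores.ravel())
        lw = tot + fixed
        w = np.exp(scores - tot)
        for t in Label:
            for u in Label:
                add((t, u, labs[0]), pos[0], float(w[t, u]))
        if len(labs) >= 2:
            for u in Label:
                add((u, labs[0], labs[1]), pos[1], float(w[:, u].sum()))
    return lw, occ


def path_log_probability(path: AlignmentPath, bank: FactorBank, tracks: FeatureTracks,
                         tables: ForwardBackwardTables | None = None) -> float:
    """log p(path | features, parameters) = log weight - log Z."""
    if not path.is_global:
        raise ValueError("path log-probability is defined for global alignments")
    if path.dims != tracks.dims:
        raise ValueError("path dims do not match feature tracks")
    if tables is None:
        tables = forward_backward(bank, tracks)
    lw, _ = path_pattern_weights(path, tables.log_psi, bank.order)
    return lw - tables.logZ
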