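"""Independent brute-force oracles used by the tests.

These deliberately avoid the batched score cache and the forward-backward
recursions: path weights are rebuilt position by position from
``FactorBank.scoring_function`` (which itself goes through ``factor_input``),
and lattice-level quantities are obtained by exhaustive path enumeration.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from crfalign.factors import FactorBank
from crfalign.features import FeatureTracks
from crfalign.lattice import (AlignmentPath, Label, LatticeDims,
                              enumerate_alignments)


def delannoy(a: int, b: int) -> int:
    """Number of monotone three-move lattice paths, by the independent
    recurrence D(a,b) = D(a-1,b) + D(a,b-1) + D(a-1,b-1)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i < 0 or j < 0:
            return 0
        if i == 0 and j == 0:
            return 1
        return d(i - 1, j) + d(i, j - 1) + d(i - 1, j - 1)

    return d(a, b)


def brute_path_weight(bank: FactorBank, tracks: FeatureTracks, path: AlignmentPath) -> float:
    """Path weight summed over the dummy labels preceding the path."""
    labs, pos = path.labels, path.positions
    if bank.order == 1:
        first = sum(math.exp(bank.scoring_function((u, labs[0]), pos[0], tracks))
                    for u in Label)
        rest = math.prod(
            math.exp(bank.scoring_function((labs[i - 1], labs[i]), pos[i], tracks))
            for i in range(1, len(labs)))
        return first * rest
    first = 0.0
    for t in Label:
        for u in Label:
            w = math.exp(bank.scoring_function((t, u, labs[0]), pos[0], tracks))
            if len(labs) > 1:
                w *= math.exp(bank.scoring_function((u, labs[0], labs[1]), pos[1], tracks))
            first += w
    rest = math.prod(
        math.exp(bank.scoring_function(tuple(labs[i - 2:i + 1]), pos[i], tracks))
        for i in range(2, len(labs)))
    return first * rest


def brute_best_path_score(bank: FactorBank, tracks: FeatureTracks,
                          path: AlignmentPath) -> float:
    """Single-path log score with the best (not summed) dummy prefix."""
    labs, pos = path.labels, path.positions
    if bank.order == 1:
        first = max(bank.scoring_function((u, labs[0]), pos[0], tracks) for u in Label)
        rest = sum(bank.scoring_function((labs[i - 1], labs[i]), pos[i], tracks)
                   for i in range(1, len(labs)))
        return first + rest
    first = max(
        bank.scoring_function((t, u, labs[0]), pos[0], tracks)
        + (bank.scoring_function((u, labs[0], labs[1]), pos[1], tracks)
           if len(labs) > 1 else 0.0)
        for t in Label for u in Label)
    rest = sum(bank.scoring_function(tuple(labs[i - 2:i + 1]), pos[i], tracks)
               for i in range(2, len(labs)))
    return first + rest


def brute_logZ(bank: FactorBank, tracks: FeatureTracks, dims: LatticeDims) -> float:
    return math.log(sum(brute_path_weight(bank, tracks, p)
                        for p in enumerate_alignments(dims)))


def random_tracks(rng: np.random.Generator, Lq: int, Lt: int) -> FeatureTracks:
    return FeatureTracks(None, None,
                         rng.normal(size=(Lq, Lt, 4)),
                         rng.normal(size=(Lq, Lt, 3)),
                         rng.normal(size=(Lq, Lt, 3)))


def constant_tracks(Lq: int, Lt: int, value: float = 0.0) -> FeatureTracks:
    return FeatureTracks(None, None,
                         np.full((Lq, Lt, 4), value),
                         np.full((Lq, Lt, 3), value),
                         np.full((Lq, Lt, 3), value))
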