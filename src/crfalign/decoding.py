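"""Viterbi decoding: the single best global alignment path.

Max-product analogue of the forward recursion: per cell and suffix pattern
keep the best cumulative log score (delta) and the predecessor label that
achieved it (the backpointer records).  At the dummy corner the best single
predecessor replaces the sum over dummy labels, so the returned score is a
pure single-path score (hence always <= log Z).

Ties are broken by the global label order M < Iq < It, both among
predecessors and at the terminal cell, making decoding deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factors import FactorBank
from .features import FeatureTracks
from .inference import NEG_INF, PairCache, suffix_states, transitions
from .lattice import AlignmentPath, LatticeDims, labels_to_positions, previous_position


@dataclass
class ViterbiTables:
    order: int
    dims: LatticeDims
    delta: np.ndarray        # (Lq+1, Lt+1, n_states) best log scores
    backpointers: np.ndarray  # same shape, predecessor state index or -1


def viterbi_tables(bank: FactorBank, tracks: FeatureTracks,
                   cache: PairCache | None = None) -> ViterbiTables:
    cache = cache or PairCache(tracks, bank.order)
    log_psi = cache.log_psi_tables(bank)
    dims = cache.dims
    Lq, Lt = dims.Lq, dims.Lt
    n_states = len(suffix_states(bank.order))
    trans = [(log_psi[fp].tolist(), ps, ns, dx, dy)
             for fp, ps, ns, dx, dy in transitions(bank.order)]
    delta = [[[NEG_INF] * n_states for _ in range(Lt + 1)] for _ in range(Lq + 1)]
    bp = [[[-1] * n_states for _ in range(Lt + 1)] for _ in range(Lq + 1)]
    delta[0][0] = [0.0] * n_states
    for x in range(Lq + 1):
        dxrow, bxrow = delta[x], bp[x]
        for y in range(Lt + 1):
            if x == 0 and y == 0:
                continue
            cell, bcell = dxrow[y], bxrow[y]
            # transitions iterate in lexicographic pattern order, so with a
            # strict comparison ties keep the smallest predecessor label
            for table, ps, ns, dx, dy in trans:
                px, py = x - dx, y - dy
                if px < 0 or py < 0:
                    continue
                d = delta[px][py][ps]
                if d == NEG_INF:
                    continue
                s = d + table[x][y]
                if s > cell[ns]:
                    cell[ns] = s
                    bcell[ns] = ps
    return ViterbiTables(bank.order, dims, np.array(delta), np.array(bp))


def viterbi_decode(bank: FactorBank, tracks: FeatureTracks,
                   cache: PairCache | None = None) -> tuple[AlignmentPath, float]:
    """Best global alignment and its log score."""
    tables = viterbi_tables(bank, tracks, cache)
    dims = tables.dims
    states = suffix_states(tables.order)
    terminal = tables.delta[dims.Lq, dims.Lt]
    if not np.all(np.isfinite(terminal) | (terminal == NEG_INF)) or np.all(terminal == NEG_INF):
        raise FloatingPointError("no finite-score path reaches the terminal corner")
    s_idx = int(np.argmax(terminal))  # argmax keeps the first (smallest) state on ties
    best = float(terminal[s_idx])
    labels_rev = []
    pos = (dims.Lq, dims.Lt)
    while pos != (0, 0):
        state = states[s_idx]
        v = state[-1]
        labels_rev.append(v)
        prev_idx = int(tables.backpointers[pos[0], pos[1], s_idx])
        pos = previous_position(pos, v)
        s_idx = prev_idx
    path = labels_to_positions(labels_rev[::-1], dims)
    return path, best
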