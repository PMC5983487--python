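"""Synthetic query-template pairs with planted alignments and
label-correlated feature grids.

The generator stands in for real feature pipelines so that training,
inference, decoding and evaluation are exercisable end to end with no
external data.  Each pair consists of

* a planted global alignment path sampled from a first-order Markov chain
  over the three labels (gap open / gap extend probabilities), and
* per-label feature grids where cells the path actually uses are drawn from
  normal distributions whose mean is shifted by ``signal_mu`` relative to
  unused cells -- the label-conditional signal the CRF assumes.

With ``second_order_strength > 0`` the third channel of each insertion grid
receives an extra shift only where the path carries three consecutive
insertions of the same kind.  That conjunction lives on triples of labels,
which is precisely the context a second-order model scores directly and a
first-order model can only approximate pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureTracks, INSERT_DIM, MATCH_DIM
from .lattice import AlignmentPath, Label, LatticeDims, labels_to_positions

_MAX_RESAMPLE = 100


@dataclass
class SyntheticConfig:
    n_pairs: int = 45
    n_train: int = 30
    n_valid: int = 5
    length_range: tuple[int, int] = (20, 30)
    gap_open: float = 0.15
    gap_extend: float = 0.6
    second_order_strength: float = 2.0
    signal_mu: float = 1.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_extend"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.second_order_strength < 0 or self.noise_sigma <= 0:
            raise ValueError("second_order_strength must be >= 0 and noise_sigma > 0")


def _sample_labels(config: SyntheticConfig, rng: np.random.Generator) -> list[Label]:
    """Markov label chain until the query budget is consumed; template
    insertions may extend the tail so paths can end in any label."""
    lo, hi = config.length_range
    for _ in range(_MAX_RESAMPLE):
        Lq = int(rng.integers(lo, hi + 1))
        labels: list[Label] = []
        state = Label.M
        x = y = 0
        while x < Lq:
            if state is Label.M:
                r = rng.random()
                if r < config.gap_open:
                    state = Label.Iq
                elif r < 2 * config.gap_open:
                    state = Label.It
            elif rng.random() >= config.gap_extend:
                state = Label.M
            labels.append(state)
            if state is not Label.It:
                x += 1
            if state is not Label.Iq:
                y += 1
        # allow a trailing template-insertion run with the same gap dynamics
        if labels[-1] is not Label.It and rng.random() < config.gap_open:
            labels.append(Label.It)
            y += 1
        while labels[-1] is Label.It and y < hi and rng.random() < config.gap_extend:
            labels.append(Label.It)
            y += 1
        if lo <= y <= hi:
            return labels
    raise RuntimeError("could not sample a label sequence within the length range")


def simulate_pair(config: SyntheticConfig,
                  rng: np.random.Generator) -> tuple[FeatureTracks, AlignmentPath]:
    """One pair: planted path plus label-correlated feature grids."""
    labels = _sample_labels(config, rng)
    Lq = sum(1 for l in labels if l is not Label.It)
    Lt = sum(1 for l in labels if l is not Label.Iq)
    dims = LatticeDims(Lq, Lt)
    path = labels_to_positions(labels, dims)

    match = rng.normal(0.0, config.noise_sigma, size=(Lq, Lt, MATCH_DIM))
    qins = rng.normal(0.0, config.noise_sigma, size=(Lq, Lt, INSERT_DIM))
    tins = rng.normal(0.0, config.noise_sigma, size=(Lq, Lt, INSERT_DIM))
    grids = {Label.M: match, Label.Iq: qins, Label.It: tins}
    for i, (lab, (x, y)) in enumerate(zip(path.labels, path.positions)):
        if x < 1 or y < 1:
            continue  # boundary cells have no grid entry
        grids[lab][x - 1, y - 1, :] += config.signal_mu
        if (config.second_order_strength > 0 and i >= 2 and lab is not Label.M
                and path.labels[i - 1] is lab and path.labels[i - 2] is lab):
            grids[lab][x - 1, y - 1, 2] += config.second_order_strength
    return FeatureTracks(None, None, match, qins, tins), path


def simulate_dataset(config: SyntheticConfig) -> dict[str, list[tuple[FeatureTracks, AlignmentPath]]]:
    """Seed-deterministic dataset split into train / valid / test subsets."""
    if config.n_pairs < 3:
        raise ValueError("need at least 3 pairs for a train/valid/test split")
    if config.n_train + config.n_valid >= config.n_pairs:
        raise ValueError("n_train + n_valid must leave room for a test set")
    rng = np.random.default_rng(config.seed)
    pairs = [simulate_pair(config, rng) for _ in range(config.n_pairs)]
    order = rng.permutation(config.n_pairs)
    train = [pairs[i] for i in order[:config.n_train]]
    valid = [pairs[i] for i in order[config.n_train:config.n_train + config.n_valid]]
    test = [pairs[i] for i in order[config.n_train + config.n_valid:]]
    return {"train": train, "valid": valid, "test": test}
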