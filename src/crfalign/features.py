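"""Per-residue tracks and per-label feature vectors for the alignment CRF.

Each protein comes with five raw tracks: the amino-acid sequence, a 20-column
evolutionary profile (a position-specific frequency matrix for the query, a
position-specific scoring matrix for the template), 3-state secondary
structure (probabilities for the query, an observed class for the template),
solvent accessibility (state probabilities for the query, observed relative
solvent accessibility for the template) and a per-residue disorder flag.

From these the module assembles the label-conditional feature vectors fed to
the log-factors:

* match ``M`` at ``(x, y)`` -- 4 channels: profile inner product,
  BLOSUM50 substitution score, secondary-structure match score and
  solvent-accessibility match score of query residue ``x`` vs template
  residue ``y``;
* query insertion ``Iq`` at ``(x, y)`` -- 3 channels from the template
  residue ``y``: context hydropathy count, RSA, secondary-structure class;
* template insertion ``It`` at ``(x, y)`` -- 3 channels from the query
  residue ``x``: context hydropathy count, estimated RSA, estimated
  secondary-structure class.

Disordered residues have their structural channels zeroed.  All channels are
mean/variance normalized with statistics fitted on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .lattice import MOVES, Label, LatticeDims, previous_position

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

SS3_CLASSES = "HEC"
SA_CLASSES = "BME"

#: RSA thresholds separating buried / medium / exposed states
RSA_CUTOFF_BURIED = 10.0
RSA_CUTOFF_MEDIUM = 42.0

#: residues counted as hydrophilic by the context hydropathy feature
HYDROPHILIC = frozenset("DEGKNPQRS")
HYDROPATHY_WINDOW = 7

MATCH_DIM = 4
INSERT_DIM = 3
#: feature-vector length per label
FEATURE_DIMS: dict[Label, int] = {Label.M: MATCH_DIM, Label.Iq: INSERT_DIM, Label.It: INSERT_DIM}

_BLOSUM50 = substitution_matrices.load("BLOSUM50")


def rsa_estimate(pB: float, pM: float, pE: float) -> float:
    """Expected relative solvent accessibility from buried/medium/exposed
    state probabilities: ``10*pB + 42*pM + 100*pE``.

    The anchors 10 and 42 are the class cutoffs on the 0-100 RSA scale, so
    the estimate lands in [10, 100] on the probability simplex.
    """
    if pB < 0 or pM < 0 or pE < 0 or abs(pB + pM + pE - 1.0) > 1e-6:
        raise ValueError(f"state probabilities must be non-negative and sum to 1, got "
                         f"({pB}, {pM}, {pE})")
    return 10.0 * pB + 42.0 * pM + 100.0 * pE


def profile_similarity(query_profile_row: np.ndarray, template_profile_row: np.ndarray) -> float:
    """Inner product of the query PSFM row with the template PSSM row."""
    q = np.asarray(query_profile_row, dtype=float)
    t = np.asarray(template_profile_row, dtype=float)
    if q.shape != (20,) or t.shape != (20,):
        raise ValueError("profile rows must have exactly 20 entries")
    return float(q @ t)


def sequence_similarity(q_aa: str, t_aa: str) -> float:
    """BLOSUM50 substitution score; the unknown residue X scores 0."""
    if q_aa == "X" or t_aa == "X":
        return 0.0
    if q_aa not in _AA_INDEX or t_aa not in _AA_INDEX:
        raise ValueError(f"unknown amino acid in pair ({q_aa}, {t_aa})")
    return float(_BLOSUM50[q_aa, t_aa])


def ss3_match_score(query_ss3_probs: np.ndarray, template_ss3_class: str) -> float:
    """Query probability assigned to the template's observed secondary-structure class."""
    p = np.asarray(query_ss3_probs, dtype=float)
    if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("query SS3 probabilities must be a 3-vector summing to 1")
    if template_ss3_class not in SS3_CLASSES:
        raise ValueError(f"invalid SS3 class {template_ss3_class!r}")
    return float(p[SS3_CLASSES.index(template_ss3_class)])


def sa_class_from_rsa(rsa: float) -> str:
    if not 0.0 <= rsa <= 100.0:
        raise ValueError(f"RSA must be in [0, 100], got {rsa}")
    if rsa < RSA_CUTOFF_BURIED:
        return "B"
    if rsa < RSA_CUTOFF_MEDIUM:
        return "M"
    return "E"


def sa_match_score(query_sa_probs: np.ndarray, template_rsa: float) -> float:
    """Query probability of the solvent-accessibility class the template
    residue occupies (class from its observed RSA via the 10/42 cutoffs)."""
    p = np.asarray(query_sa_probs, dtype=float)
    if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("query SA probabilities must be a 3-vector summing to 1")
    return float(p[SA_CLASSES.index(sa_class_from_rsa(template_rsa))])


def hydropathy_count(sequence: str, position: int) -> int:
    """Hydrophilic residues in the length-7 window centred at ``position``
    (1-based), truncated at the sequence ends."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    half = HYDROPATHY_WINDOW // 2
    lo = max(0, position - 1 - half)
    hi = min(len(sequence), position + half)
    return sum(1 for aa in sequence[lo:hi] if aa in HYDROPHILIC)


@dataclass
class ResidueTrack:
    """Raw per-residue tracks for one protein.

    ``ss3`` is an ``L x 3`` probability matrix for a query or a string of
    classes in ``HEC`` for a template; ``sa`` is an ``L x 3`` probability
    matrix (query) or a length-``L`` array of observed RSA values in
    ``[0, 100]`` (template).
    """

    sequence: str
    profile: np.ndarray
    ss3: np.ndarray | str
    sa: np.ndarray
    disorder: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.sequence)
        self.profile = np.asarray(self.profile, dtype=float)
        self.sa = np.asarray(self.sa, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=bool)
        if self.profile.shape != (L, 20):
            raise ValueError(f"profile must be {L}x20, got {self.profile.shape}")
        if self.is_template:
            if len(self.ss3) != L:
                raise ValueError("template SS3 class string length mismatch")
            if any(c not in SS3_CLASSES for c in self.ss3):
                raise ValueError("template SS3 classes must be in HEC")
            if self.sa.shape != (L,):
                raise ValueError(f"template RSA must be length {L}")
            if np.any((self.sa < 0) | (self.sa > 100)):
                raise ValueError("template RSA values must be in [0, 100]")
        else:
            self.ss3 = np.asarray(self.ss3, dtype=float)
            if self.ss3.shape != (L, 3):
                raise ValueError(f"query SS3 must be {L}x3, got {self.ss3.shape}")
            if self.sa.shape != (L, 3):
                raise ValueError(f"query SA must be {L}x3, got {self.sa.shape}")
            for name, mat in (("ss3", self.ss3), ("sa", self.sa)):
                if np.any(mat < -1e-12) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-6):
                    raise ValueError(f"query {name} rows must be probabilities summing to 1")
        if self.disorder.shape != (L,):
            raise ValueError(f"disorder flags must be length {L}")

    @property
    def is_template(self) -> bool:
        return isinstance(self.ss3, str)

    def __len__(self) -> int:
        return len(self.sequence)


def _query_channels(q: ResidueTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-query-residue hydropathy, estimated RSA and estimated SS3 class
    index (argmax probability), with disorder zeroing the structural two."""
    L = len(q)
    hyd = np.array([hydropathy_count(q.sequence, x) for x in range(1, L + 1)], dtype=float)
    rsa = np.array([rsa_estimate(*q.sa[x]) for x in range(L)])
    ss = np.argmax(q.ss3, axis=1).astype(float)
    rsa[q.disorder] = 0.0
    ss[q.disorder] = 0.0
    return hyd, rsa, ss


def _template_channels(t: ResidueTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = len(t)
    hyd = np.array([hydropathy_count(t.sequence, y) for y in range(1, L + 1)], dtype=float)
    rsa = t.sa.copy()
    ss = np.array([SS3_CLASSES.index(c) for c in t.ss3], dtype=float)
    rsa[t.disorder] = 0.0
    ss[t.disorder] = 0.0
    return hyd, rsa, ss


@dataclass
class FeatureTracks:
    """Label-conditional feature grids for one query-template pair.

    ``match_features`` has shape ``(Lq, Lt, 4)``; the insertion grids have
    shape ``(Lq, Lt, 3)`` (the ``Iq`` grid is constant in ``x``, the ``It``
    grid constant in ``y``; both are materialized on the full grid so that
    every label reads its vector at the current lattice position).
    """

    query: ResidueTrack | None
    template: ResidueTrack | None
    match_features: np.ndarray
    qins_features: np.ndarray
    tins_features: np.ndarray

    @property
    def dims(self) -> LatticeDims:
        return LatticeDims(self.match_features.shape[0], self.match_features.shape[1])

    def grid(self, label: Label) -> np.ndarray:
        return {Label.M: self.match_features,
                Label.Iq: self.qins_features,
                Label.It: self.tins_features}[label]

    def label_vector(self, label: Label, pos: tuple[int, int]) -> np.ndarray:
        """Feature vector of ``label`` at lattice position ``pos``; the zero
        vector when the position falls outside the residue grid."""
        x, y = pos
        if x < 1 or y < 1 or x > self.dims.Lq or y > self.dims.Lt:
            return np.zeros(FEATURE_DIMS[label])
        return self.grid(label)[x - 1, y - 1]


def build_feature_tracks(query: ResidueTrack, template: ResidueTrack) -> FeatureTracks:
    """Assemble the per-label feature grids from two raw tracks."""
    if query.is_template or not template.is_template:
        raise ValueError("expected a query track (probabilistic) and a template track (observed)")
    Lq, Lt = len(query), len(template)

    prof = query.profile @ template.profile.T  # (Lq, Lt) inner products
    subst = np.array([[sequence_similarity(qa, ta) for ta in template.sequence]
                      for qa in query.sequence])
    ss_idx = np.array([SS3_CLASSES.index(c) for c in template.ss3])
    ssm = query.ss3[:, ss_idx]  # (Lq, Lt) query prob of template class
    sa_idx = np.array([SA_CLASSES.index(sa_class_from_rsa(r)) for r in template.sa])
    sam = query.sa[:, sa_idx]
    # disorder on either side blanks the structural match channels
    dis = query.disorder[:, None] | template.disorder[None, :]
    ssm = np.where(dis, 0.0, ssm)
    sam = np.where(dis, 0.0, sam)
    match = np.stack([prof, subst, ssm, sam], axis=-1)

    t_hyd, t_rsa, t_ss = _template_channels(template)
    qins = np.broadcast_to(np.stack([t_hyd, t_rsa, t_ss], axis=-1)[None, :, :],
                           (Lq, Lt, INSERT_DIM)).copy()
    q_hyd, q_rsa, q_ss = _query_channels(query)
    tins = np.broadcast_to(np.stack([q_hyd, q_rsa, q_ss], axis=-1)[:, None, :],
                           (Lq, Lt, INSERT_DIM)).copy()
    return FeatureTracks(query, template, match, qins, tins)


@dataclass
class Normalizer:
    """Per-channel mean/std statistics, one pair per channel of each label
    type, fitted by pooling every lattice position of the training pairs."""

    mean: dict[Label, np.ndarray] = field(default_factory=dict)
    std: dict[Label, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {lab.name: {"mean": self.mean[lab].tolist(), "std": self.std[lab].tolist()}
                for lab in self.mean}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        n = cls()
        for name, stats in d.items():
            lab = Label[name]
            n.mean[lab] = np.asarray(stats["mean"], dtype=float)
            n.std[lab] = np.asarray(stats["std"], dtype=float)
        return n

    @classmethod
    def identity(cls) -> "Normalizer":
        n = cls()
        for lab, d in FEATURE_DIMS.items():
            n.mean[lab] = np.zeros(d)
            n.std[lab] = np.ones(d)
        return n


def fit_normalizer(training_tracks: list[FeatureTracks]) -> Normalizer:
    """Pool all lattice positions of all training pairs per channel and fit
    mean/std.  Zero-variance channels get std 1 so they normalize to 0."""
    if not training_tracks:
        raise ValueError("cannot fit a normalizer on an empty training set")
    n = Normalizer()
    for lab in FEATURE_DIMS:
        pooled = np.concatenate([t.grid(lab).reshape(-1, FEATURE_DIMS[lab])
                                 for t in training_tracks], axis=0)
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        std[std < 1e-12] = 1.0
        n.mean[lab], n.std[lab] = mean, std
    return n


def apply_normalizer(n: Normalizer, t: FeatureTracks) -> FeatureTracks:
    return FeatureTracks(
        t.query, t.template,
        (t.match_features - n.mean[Label.M]) / n.std[Label.M],
        (t.qins_features - n.mean[Label.Iq]) / n.std[Label.Iq],
        (t.tins_features - n.mean[Label.It]) / n.std[Label.It],
    )


def factor_input(pattern: tuple[Label, ...], pos: tuple[int, int],
                 tracks: FeatureTracks) -> np.ndarray:
    """Concatenated input vector for a log-factor of the given label pattern
    evaluated at lattice position ``pos``.

    The last label reads its feature vector at ``pos``; each earlier label
    reads at the position obtained by stepping back with the move of its
    successor.  Segments whose position falls outside the residue grid are
    zero-filled.
    """
    segments: list[np.ndarray] = []
    p = pos
    for i in range(len(pattern) - 1, -1, -1):
        segments.append(tracks.label_vector(pattern[i], p))
        p = previous_position(p, pattern[i])
    return np.concatenate(segments[::-1])


def pattern_input_dim(pattern: tuple[Label, ...]) -> int:
    return sum(FEATURE_DIMS[lab] for lab in pattern)
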