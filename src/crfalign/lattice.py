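"""Alignment lattice: labels, moves, paths and a brute-force path enumerator.

A global query-template alignment is a monotone path on the
``(Lq+1) x (Lt+1)`` lattice from the dummy corner ``(0, 0)`` to
``(Lq, Lt)``.  Each step carries one of three labels:

* ``M``  -- match: consumes one query and one template residue,
* ``Iq`` -- query insertion: consumes one query residue,
* ``It`` -- template insertion: consumes one template residue.

Positions are 1-based residue indices; position ``(x, y)`` means query
residue ``x`` and template residue ``y`` are the most recently consumed
ones.  Paths may run along row 0 / column 0 (leading insertions).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence


class Label(enum.IntEnum):
    """Alignment state.  The integer order ``M < Iq < It`` is the global
    tie-breaking order used everywhere (Viterbi, enumeration)."""

    M = 0
    Iq = 1
    It = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


LABELS: tuple[Label, Label, Label] = (Label.M, Label.Iq, Label.It)

#: lattice advance of each label: (dx, dy)
MOVES: dict[Label, tuple[int, int]] = {
    Label.M: (1, 1),
    Label.Iq: (1, 0),
    Label.It: (0, 1),
}

_DELTA_TO_LABEL = {v: k for k, v in MOVES.items()}


def label_patterns(length: int) -> list[tuple[Label, ...]]:
    """All label patterns of the given length in lexicographic (M < Iq < It)
    order: 3 node, 9 edge or 27 triple patterns."""
    if length not in (1, 2, 3):
        raise ValueError(f"pattern length must be 1, 2 or 3, got {length}")
    return list(itertools.product(LABELS, repeat=length))


def pattern_name(pattern: Sequence[Label]) -> str:
    return "->".join(l.name for l in pattern)


def pattern_from_name(name: str) -> tuple[Label, ...]:
    return tuple(Label[p] for p in name.split("->"))


@dataclass(frozen=True)
class LatticeDims:
    """Query length and template length (residues)."""

    Lq: int
    Lt: int

    def __post_init__(self) -> None:
        if self.Lq < 1 or self.Lt < 1:
            raise ValueError(f"lattice dims must be >= 1, got ({self.Lq}, {self.Lt})")

    def contains(self, pos: tuple[int, int]) -> bool:
        x, y = pos
        return 0 <= x <= self.Lq and 0 <= y <= self.Lt


def previous_position(pos: tuple[int, int], v: Label) -> tuple[int, int]:
    """Position the path occupied before label ``v`` moved into ``pos``.

    May fall outside the lattice; the caller checks."""
    dx, dy = MOVES[v]
    return (pos[0] - dx, pos[1] - dy)


def next_position(pos: tuple[int, int], v: Label) -> tuple[int, int]:
    """Position reached when label ``v`` moves out of ``pos``."""
    dx, dy = MOVES[v]
    return (pos[0] + dx, pos[1] + dy)


@dataclass(frozen=True)
class AlignmentPath:
    """A global alignment as parallel label and lattice-position sequences."""

    labels: tuple[Label, ...]
    positions: tuple[tuple[int, int], ...]
    dims: LatticeDims

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")
        if len(self.labels) == 0:
            raise ValueError("empty alignment path")
        prev = previous_position(self.positions[0], self.labels[0])
        if prev[0] < 0 or prev[1] < 0:
            raise ValueError(f"path starts outside the lattice (before {self.positions[0]})")
        for i, (lab, pos) in enumerate(zip(self.labels, self.positions)):
            if not self.dims.contains(pos):
                raise ValueError(f"step {i + 1}: position {pos} outside lattice {self.dims}")
            if i > 0 and previous_position(pos, lab) != self.positions[i - 1]:
                raise ValueError(
                    f"step {i + 1}: move {lab.name} from {self.positions[i - 1]} "
                    f"does not reach {pos}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_global(self) -> bool:
        return self.positions[-1] == (self.dims.Lq, self.dims.Lt)

    def match_pairs(self) -> dict[int, int]:
        """Query residue -> template residue for every match step."""
        return {x: y for lab, (x, y) in zip(self.labels, self.positions) if lab is Label.M}


def labels_to_positions(labels: Sequence[Label], dims: LatticeDims) -> AlignmentPath:
    """Cumulate label moves from the dummy corner into a lattice path."""
    if not labels:
        raise ValueError("empty label sequence")
    x, y = 0, 0
    positions: list[tuple[int, int]] = []
    for i, lab in enumerate(labels):
        x, y = next_position((x, y), lab)
        if x > dims.Lq or y > dims.Lt:
            raise ValueError(
                f"step {i + 1} ({lab.name}) leaves the lattice: ({x}, {y}) "
                f"exceeds ({dims.Lq}, {dims.Lt})"
            )
        positions.append((x, y))
    return AlignmentPath(tuple(labels), tuple(positions), dims)


def positions_to_labels(positions: Sequence[tuple[int, int]]) -> list[Label]:
    """Inverse of :func:`labels_to_positions`: read labels off position deltas."""
    if not positions:
        raise ValueError("empty position sequence")
    labels: list[Label] = []
    prev = None
    for i, pos in enumerate(positions):
        if prev is not None:
            delta = (pos[0] - prev[0], pos[1] - prev[1])
            lab = _DELTA_TO_LABEL.get(delta)
            if lab is None:
                raise ValueError(f"step {i + 1}: invalid move {prev} -> {pos}")
            labels.append(lab)
        prev = pos
    # Paths start at the dummy corner, so the first label is the unique move
    # from (0, 0) into the first position.
    first = None
    for lab in LABELS:
        if previous_position(positions[0], lab) == (0, 0):
            first = lab
            break
    if first is None:
        raise ValueError(f"first position {positions[0]} is not reachable from the dummy corner")
    return [first] + labels


def enumerate_alignments(dims: LatticeDims, guard: int = 12) -> Iterator[AlignmentPath]:
    """Yield every global alignment path, exactly once (brute-force oracle).

    Refuses lattices with ``Lq + Lt > guard``; meant for tests only.  The
    number of paths is the Delannoy number D(Lq, Lt).
    """
    if dims.Lq + dims.Lt > guard:
        raise ValueError(f"enumerate_alignments is an oracle for tiny lattices (Lq+Lt <= {guard})")

    def rec(x: int, y: int, acc: list[Label]) -> Iterator[tuple[Label, ...]]:
        if x == dims.Lq and y == dims.Lt:
            yield tuple(acc)
            return
        for lab in LABELS:  # deterministic M < Iq < It order
            dx, dy = MOVES[lab]
            if x + dx <= dims.Lq and y + dy <= dims.Lt:
                acc.append(lab)
                yield from rec(x + dx, y + dy, acc)
                acc.pop()

    for labels in rec(0, 0, []):
        yield labels_to_positions(labels, dims)


def write_alignment_tsv(path: AlignmentPath, fh) -> None:
    """TSV with one row per alignment step: step, label, x, y."""
    fh.write("step\tlabel\tx\ty\n")
    for i, (lab, (x, y)) in enumerate(zip(path.labels, path.positions), start=1):
        fh.write(f"{i}\t{lab.name}\t{x}\t{y}\n")


def read_alignment_tsv(fh) -> AlignmentPath:
    header = fh.readline().rstrip("\n").split("\t")
    if header != ["step", "label", "x", "y"]:
        raise ValueError(f"unexpected alignment header: {header}")
    labels: list[Label] = []
    positions: list[tuple[int, int]] = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        labels.append(Label[parts[1]])
        positions.append((int(parts[2]), int(parts[3])))
    dims = LatticeDims(positions[-1][0], positions[-1][1])
    return AlignmentPath(tuple(labels), tuple(positions), dims)


def write_aligned_fasta(path: AlignmentPath, query_seq: str, template_seq: str, fh,
                        query_id: str = "query", template_id: str = "template") -> None:
    """Two gapped FASTA records derived from the path; '-' marks a gap."""
    q_row, t_row = [], []
    for lab, (x, y) in zip(path.labels, path.positions):
        q_row.append(query_seq[x - 1] if lab in (Label.M, Label.Iq) else "-")
        t_row.append(template_seq[y - 1] if lab in (Label.M, Label.It) else "-")
    fh.write(f">{query_id}\n{''.join(q_row)}\n>{template_id}\n{''.join(t_row)}\n")
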