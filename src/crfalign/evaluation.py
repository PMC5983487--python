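"""Reference-dependent alignment accuracy.

A query residue is correctly aligned when the predicted alignment pairs it
(via a match label) with the same template residue as the reference
alignment does.  The denominator is the number of query residues the
reference matches; insertion placement never enters the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import AlignmentPath


@dataclass(frozen=True)
class EvaluationResult:
    n_reference_matches: int
    n_correct: int

    @property
    def accuracy_pct(self) -> float:
        if self.n_reference_matches == 0:
            return 0.0
        return 100.0 * self.n_correct / self.n_reference_matches


def reference_dependent_accuracy(predicted: AlignmentPath,
                                 reference: AlignmentPath) -> EvaluationResult:
    if predicted.dims != reference.dims:
        raise ValueError(f"dims mismatch: predicted {predicted.dims} vs "
                         f"reference {reference.dims}")
    ref_pairs = reference.match_pairs()
    pred_pairs = predicted.match_pairs()
    correct = sum(1 for x, y in ref_pairs.items() if pred_pairs.get(x) == y)
    return EvaluationResult(n_reference_matches=len(ref_pairs), n_correct=correct)


def aggregate_accuracy(results: list[EvaluationResult],
                       weighting: str = "per-pair") -> float:
    """Aggregate over pairs: ``per-pair`` averages each pair's percentage,
    ``per-residue`` pools correct counts over pooled reference matches."""
    if not results:
        raise ValueError("no results to aggregate")
    if weighting == "per-pair":
        return sum(r.accuracy_pct for r in results) / len(results)
    if weighting == "per-residue":
        total = sum(r.n_reference_matches for r in results)
        if total == 0:
            return 0.0
        return 100.0 * sum(r.n_correct for r in results) / total
    raise ValueError(f"unknown weighting {weighting!r}")
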