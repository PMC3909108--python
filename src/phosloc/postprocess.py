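"""Quality post-processing: dCn gate, redundancy criterion, evaluation.

Abundant peptides are fragmented many times in an LC-MS/MS run.  When the
same peptide with the same assigned site set tops the ranking in many
independent scans, the assignment is very unlikely to be a coincidence: under
a null where each scan independently picks one of ``n`` candidate sites
uniformly at random, the probability that an agreement of ``k`` scans is
wrong is ``(1/n)^k`` — for two candidate sites and 7 scans this leaves
``1 - 0.5^7 = 99.22%`` confidence.  An assignment therefore *passes* when its
redundancy reaches the redundancy threshold (default 7) regardless of dCn;
otherwise it needs dCn strictly above the dCn threshold (default 0.99).
A tie at the top of the ranking can never pass on dCn alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .configurations import PhosphoConfiguration, parse_label
from .io import AssignmentRecord

__all__ = [
    "QualityParameters",
    "RedundancyKey",
    "redundancy_counts",
    "verdict",
    "chance_agreement_probability",
    "EvaluationResult",
    "evaluate",
]


@dataclass(frozen=True)
class QualityParameters:
    """Thresholds for the pass/ambiguous decision."""

    dcn_threshold: float = 0.99
    redundancy_threshold: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.dcn_threshold <= 1:
            raise ValueError("dcn_threshold must lie in [0, 1]")
        if self.redundancy_threshold < 1:
            raise ValueError("redundancy_threshold must be >= 1")


@dataclass(frozen=True)
class RedundancyKey:
    """Identity used to pool scans: peptide sequence plus assigned site set.

    Non-phospho modifications are ignored: oxidized and unoxidized forms of
    the same phosphopeptide corroborate the same site.
    """

    sequence: str
    phospho_positions: tuple[int, ...]

    @classmethod
    def from_configuration(cls, config: PhosphoConfiguration) -> "RedundancyKey":
        return cls(
            sequence=config.base.sequence,
            phospho_positions=tuple(config.phospho_positions),
        )

    @classmethod
    def from_label(cls, label: str) -> "RedundancyKey":
        peptide = parse_label(label)
        return cls(
            sequence=peptide.sequence,
            phospho_positions=tuple(peptide.phospho_positions),
        )


def redundancy_counts(
    top_assignments: Mapping[str, RedundancyKey]
) -> dict[RedundancyKey, int]:
    """Count scans whose top-ranked configuration shares each key.

    ``top_assignments`` maps scan id to the top configuration's key, so each
    scan contributes exactly once.
    """
    return dict(Counter(top_assignments.values()))


def verdict(
    dcn: float,
    redundancy: int,
    params: QualityParameters = QualityParameters(),
    top_tie: bool = False,
) -> str:
    """Pass/ambiguous decision for one assignment.

    Passes when redundancy reaches the redundancy threshold, or when dCn is
    strictly above the dCn threshold and the top of the ranking is not tied.
    """
    if redundancy >= params.redundancy_threshold:
        return "passed"
    if dcn > params.dcn_threshold and not top_tie:
        return "passed"
    return "ambiguous"


def chance_agreement_probability(n_sites: int, n_agreeing_spectra: int) -> float:
    """Model probability that an agreeing assignment is correct.

    Under the uniform-chance null each spectrum independently favors one of
    ``n_sites`` candidate sites with probability ``1/n_sites``; the
    probability that ``k`` agreeing scans are all wrong by chance is
    ``(1/n_sites)^k``, so the assignment is correct with probability
    ``1 - (1/n_sites)^k``.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 candidate sites")
    if n_agreeing_spectra < 1:
        raise ValueError("need at least 1 agreeing spectrum")
    return 1.0 - (1.0 / n_sites) ** n_agreeing_spectra


@dataclass(frozen=True)
class EvaluationResult:
    """Accuracy/sensitivity of a batch against known sites.

    ``accuracy`` is ``None`` (not applicable) when no record passed.
    """

    accuracy: float | None
    sensitivity: float
    n_total: int
    n_passed: int
    n_correct_passed: int


def evaluate(
    records: Sequence[AssignmentRecord],
    truth: Mapping[str, tuple[int, ...]],
) -> EvaluationResult:
    """Score a batch of assignments against ground-truth site placements.

    accuracy    = 100 x (correct among passed) / passed
    sensitivity = 100 x passed / total
    """
    n_total = len(records)
    n_passed = 0
    n_correct = 0
    for r in records:
        if r.scan_id not in truth:
            raise KeyError(f"scan {r.scan_id!r} missing from truth")
        if r.verdict != "passed":
            continue
        n_passed += 1
        assigned = tuple(parse_label(r.assigned_label).phospho_positions)
        if assigned == tuple(sorted(truth[r.scan_id])):
            n_correct += 1
    accuracy = 100.0 * n_correct / n_passed if n_passed else None
    sensitivity = 100.0 * n_passed / n_total if n_total else 0.0
    return EvaluationResult(
        accuracy=accuracy,
        sensitivity=sensitivity,
        n_total=n_total,
        n_passed=n_passed,
        n_correct_passed=n_correct,
    )
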