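"""Diagnostic cut-offs and binary classification performance.

A labelled cohort pairs one quantitative metric per patient with the 0-3
visual cardiac-uptake grade.  A cut-off splits the cohort (test-positive
when value >= cutoff, matching the inclusive convention of the threshold
segmentation); performance is summarized as the confusion counts and
TPR/FPR/PPV/NPV in percent.  An undefined rate (zero denominator) is
reported as ``None`` — missing, not zero.

Cut-off derivation operationalizes "highest true positive rate and lowest
false positive rate" as maximizing the Youden index J = TPR - FPR over the
midpoints between consecutive distinct sorted values; midpoint candidates
avoid tying the cut-off to an observed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["LabelledCohort", "DiagnosticResult", "classify", "derive_cutoff"]


@dataclass
class LabelledCohort:
    """Per-patient metric values with visual grades 0-3."""

    values: Sequence[float]
    grades: Sequence[int]

    def __post_init__(self) -> None:
        self.values = [float(v) for v in self.values]
        self.grades = [int(g) for g in self.grades]
        if len(self.values) != len(self.grades):
            raise ValueError("values and grades differ in length")
        if any(g not in (0, 1, 2, 3) for g in self.grades):
            raise ValueError("grades must be in {0,1,2,3}")
        if not all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class DiagnosticResult:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float | None
    fpr: float | None
    ppv: float | None
    npv: float | None

    @property
    def youden_j(self) -> float | None:
        if self.tpr is None or self.fpr is None:
            return None
        return self.tpr - self.fpr

    def as_dict(self) -> dict:
        return {"cutoff": self.cutoff, "TP": self.tp, "FP": self.fp,
                "TN": self.tn, "FN": self.fn, "TPR": self.tpr,
                "FPR": self.fpr, "PPV": self.ppv, "NPV": self.npv}


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def classify(cohort: LabelledCohort, cutoff: float,
             positive_grades: Iterable[int]) -> DiagnosticResult:
    """Apply a cut-off: test-positive iff value >= cutoff; disease-positive
    iff grade is in ``positive_grades`` (a non-empty proper subset of the
    grades 0-3)."""
    pos = frozenset(int(g) for g in positive_grades)
    if not pos or not pos < {0, 1, 2, 3}:
        raise ValueError("positive_grades must be a non-empty proper subset "
                         "of {0,1,2,3}")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    tp = fp = tn = fn = 0
    for v, g in zip(cohort.values, cohort.grades):
        test_pos = v >= cutoff
        if g in pos:
            tp += test_pos
            fn += not test_pos
        else:
            fp += test_pos
            tn += not test_pos
    return DiagnosticResult(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=_rate(tp, tp + fn), fpr=_rate(fp, fp + tn),
        ppv=_rate(tp, tp + fp), npv=_rate(tn, tn + fn),
    )


def derive_cutoff(cohort: LabelledCohort,
                  positive_grades: Iterable[int]) -> tuple[float, DiagnosticResult]:
    """Best separating cut-off by Youden J over midpoint candidates.

    Candidates are the midpoints between consecutive distinct sorted values.
    Ties on J are broken toward higher TPR, then toward the lower cut-off.
    Requires at least one diseased and one non-diseased patient and at least
    two distinct values.
    """
    pos = frozenset(int(g) for g in positive_grades)
    labels = [g in pos for g in cohort.grades]
    if not any(labels) or all(labels):
        raise ValueError("need at least one positive and one negative patient")
    distinct = sorted(set(cohort.values))
    if len(distinct) < 2:
        raise ValueError("all values identical: no separating candidate")
    candidates = [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]

    best: tuple[float, DiagnosticResult] | None = None
    for c in candidates:
        res = classify(cohort, c, pos)
        j = res.youden_j if res.youden_j is not None else -np.inf
        if best is None:
            best = (c, res)
            continue
        bj = best[1].youden_j if best[1].youden_j is not None else -np.inf
        if (j, res.tpr or 0.0, -c) > (bj, best[1].tpr or 0.0, -best[0]):
            best = (c, res)
    assert best is not None
    return best
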