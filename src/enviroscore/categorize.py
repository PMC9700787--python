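"""Mapping raw single-index values to the 5-level A-E Enviroscore grade.

Default cutoffs (raw dimensionless scale):

    A  very low   index <  4e-4
    B  low        4e-4    <= index < 1.45e-3
    C  medium     1.45e-3 <= index < 2e-3
    D  high       2e-3    <= index < 1e-2
    E  very high  index >= 1e-2

Lower bounds are inclusive.  Negative values (net environmental credit)
grade A with a logged warning rather than erroring.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .single_index import SingleIndexResult

logger = logging.getLogger(__name__)

GRADES = ("A", "B", "C", "D", "E")
IMPACT_LABELS = ("Very low", "Low", "Medium", "High", "Very high")


@dataclass(frozen=True)
class GradeThresholds:
    """Four strictly increasing raw-scale cutoffs separating five grades."""

    cutoffs: tuple[float, float, float, float] = (4.0e-4, 1.45e-3, 2.0e-3, 1.0e-2)
    labels: tuple[str, ...] = GRADES
    impact_labels: tuple[str, ...] = IMPACT_LABELS

    def __post_init__(self):
        if len(self.cutoffs) != len(self.labels) - 1:
            raise ValueError(
                f"{len(self.labels)} grades require {len(self.labels) - 1} cutoffs, "
                f"got {len(self.cutoffs)}"
            )
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError(f"cutoffs must be strictly increasing: {self.cutoffs}")
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))


DEFAULT_THRESHOLDS = GradeThresholds()


@dataclass(frozen=True)
class EnviroscoreGrade:
    """An assigned grade, carrying the value and thresholds for audit."""

    grade: str
    impact_label: str
    efsi_value: float
    thresholds_used: GradeThresholds = field(default=DEFAULT_THRESHOLDS)
    item_id: str = ""


def assign_enviroscore(
    efsi_value: float,
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
    item_id: str = "",
) -> EnviroscoreGrade:
    """Grade a raw-scale index value against the thresholds.

    Each grade's lower bound is inclusive: a value exactly at a cutoff takes
    the higher grade.
    """
    if not math.isfinite(efsi_value):
        raise ValueError(f"cannot grade non-finite index value: {efsi_value}")
    if efsi_value < 0:
        logger.warning(
            "negative index value %g%s graded A (net credit)",
            efsi_value,
            f" for {item_id}" if item_id else "",
        )
    idx = bisect_right(thresholds.cutoffs, efsi_value)
    return EnviroscoreGrade(
        grade=thresholds.labels[idx],
        impact_label=thresholds.impact_labels[idx],
        efsi_value=float(efsi_value),
        thresholds_used=thresholds,
        item_id=item_id,
    )


def grade_batch(
    results: Sequence[SingleIndexResult],
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS,
) -> list[EnviroscoreGrade]:
    """Grade a sequence of single-index results, preserving order."""
    grades = []
    for res in results:
        try:
            grades.append(assign_enviroscore(res.total, thresholds, item_id=res.item_id))
        except ValueError as exc:
            raise ValueError(f"item {res.item_id!r}: {exc}") from exc
    return grades
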