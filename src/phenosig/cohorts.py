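"""Outcome-rate comparison between two patient cohorts.

This is the "virtual perturbation experiment" primitive: given disjoint
exposed/unexposed cohorts, compare the reporting rate of one clinical
outcome with an exact test.  Rates are kept at full precision internally
and rounded to one decimal (percent) only for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .integrate import AnnotatedCase
from .model import OUTCOME_CODES
from .signals import ContingencyTable, fisher_exact

__all__ = ["CohortComparison", "compare_outcome", "compare_counts"]


@dataclass(frozen=True)
class CohortComparison:
    """Exposed-vs-unexposed contrast of one outcome's reporting rate."""

    outcome: str
    table: ContingencyTable  # a = outcome in exposed, rows = exposed/unexposed
    p: float
    sided: str = "two"

    @property
    def n_exposed(self) -> int:
        return self.table.a + self.table.b

    @property
    def n_unexposed(self) -> int:
        return self.table.c + self.table.d

    @property
    def rate_exposed(self) -> float:
        """Outcome rate in the exposed arm, in percent (full precision)."""
        return 100.0 * self.table.a / self.n_exposed

    @property
    def rate_unexposed(self) -> float:
        return 100.0 * self.table.c / self.n_unexposed

    @property
    def risk_ratio(self) -> float:
        if self.rate_unexposed == 0.0:
            return math.inf if self.rate_exposed > 0 else math.nan
        return self.rate_exposed / self.rate_unexposed

    def summary(self) -> str:
        return (
            f"outcome {self.outcome}: exposed {self.table.a}/{self.n_exposed} "
            f"({self.rate_exposed:.1f}%) vs unexposed {self.table.c}/{self.n_unexposed} "
            f"({self.rate_unexposed:.1f}%); risk ratio {self.risk_ratio:.3f}, "
            f"Fisher p = {self.p:.2g} ({self.sided}-sided)"
        )


def compare_counts(
    outcome_exposed: int,
    n_exposed: int,
    outcome_unexposed: int,
    n_unexposed: int,
    outcome: str = "DE",
    sided: str = "two",
) -> CohortComparison:
    """Build a comparison directly from arm counts."""
    if outcome not in OUTCOME_CODES:
        raise ValueError(f"unknown outcome code {outcome!r}")
    if n_exposed <= 0 or n_unexposed <= 0:
        raise ValueError("both cohorts must be non-empty")
    if outcome_exposed > n_exposed or outcome_unexposed > n_unexposed:
        raise ValueError("outcome count exceeds cohort size")
    table = ContingencyTable(
        a=outcome_exposed,
        b=n_exposed - outcome_exposed,
        c=outcome_unexposed,
        d=n_unexposed - outcome_unexposed,
    )
    return CohortComparison(outcome=outcome, table=table, p=fisher_exact(table, sided), sided=sided)


def compare_outcome(
    cohort_exposed: Sequence[AnnotatedCase],
    cohort_unexposed: Sequence[AnnotatedCase],
    outcome: str,
    sided: str = "two",
) -> CohortComparison:
    """Compare one outcome's reporting rate between two disjoint cohorts."""
    if outcome not in OUTCOME_CODES:
        raise ValueError(f"unknown outcome code {outcome!r}")
    if not cohort_exposed or not cohort_unexposed:
        raise ValueError("both cohorts must be non-empty")
    overlap = {c.case_id for c in cohort_exposed} & {c.case_id for c in cohort_unexposed}
    if overlap:
        raise ValueError(f"cohorts overlap on {len(overlap)} case(s), e.g. {sorted(overlap)[:3]}")
    a = sum(outcome in c.outcomes for c in cohort_exposed)
    c_ = sum(outcome in c.outcomes for c in cohort_unexposed)
    return compare_counts(a, len(cohort_exposed), c_, len(cohort_unexposed), outcome, sided)
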