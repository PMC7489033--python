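"""Client records, GDS severity mapping, and analysis-sample selection.

Clients of outpatient dementia services are staged on the Global
Deterioration Scale (GDS), a 7-point clinical scale: stages 1-2 are
pre-dementia, 3-7 full-blown dementia.  The Markov model works on a coarser
three-state severity space:

* mild      - GDS 3 or 4
* moderate  - GDS 5
* severe    - GDS 6 or 7

The analysis sample consists of clients observed twice roughly a year
apart, with a dementia-stage baseline (GDS >= 3).  Each retained client
contributes exactly one (baseline-state, follow-up-state) pair; these
pairs are the sufficient statistic for the annual transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from .errors import DomainError

__all__ = [
    "SeverityState",
    "ClientRecord",
    "SelectionReport",
    "STATES",
    "map_gds_to_state",
    "select_analysis_sample",
]


class SeverityState(IntEnum):
    """Three-state dementia severity space, totally ordered mild < severe."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


STATES: tuple[SeverityState, ...] = (
    SeverityState.MILD,
    SeverityState.MODERATE,
    SeverityState.SEVERE,
)

#: GDS levels belonging to each severity state.
GDS_BY_STATE: dict[SeverityState, tuple[int, ...]] = {
    SeverityState.MILD: (3, 4),
    SeverityState.MODERATE: (5,),
    SeverityState.SEVERE: (6, 7),
}


@dataclass(frozen=True)
class ClientRecord:
    """One client's baseline and (optional) one-year follow-up observation.

    ``gds_followup`` is ``None`` when the client was not re-assessed
    (dropout).  ``benefit_level`` is the ordinal 1-7 long-term care benefit
    tier, if known.
    """

    client_id: str
    gds_baseline: int
    gds_followup: Optional[int] = None
    benefit_level: Optional[int] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        for field in ("gds_baseline", "gds_followup"):
            value = getattr(self, field)
            if value is not None and value not in range(1, 8):
                raise DomainError(f"{field}={value!r} outside GDS range 1..7")


@dataclass(frozen=True)
class SelectionReport:
    """Accounting of the sample-selection flow.

    Exclusions are disjoint and applied in order: missing follow-up first,
    then pre-dementia baseline (GDS 1-2), then follow-up improvement out of
    dementia (GDS 1-2 at follow-up, unrepresentable in the 3-state chain).
    """

    n_input: int
    n_excluded_no_followup: int
    n_excluded_predementia: int
    n_excluded_followup_remission: int
    n_analysis: int

    def __post_init__(self) -> None:
        total = (
            self.n_analysis
            + self.n_excluded_no_followup
            + self.n_excluded_predementia
            + self.n_excluded_followup_remission
        )
        if total != self.n_input:
            raise ValueError("selection counts do not reconcile with n_input")


def map_gds_to_state(gds: int) -> Optional[SeverityState]:
    """Map a GDS level to a severity state.

    Returns ``None`` for GDS 1-2 (pre-dementia, excluded from the chain).

    Raises
    ------
    DomainError
        If ``gds`` is not an integer in 1..7.
    """
    if gds not in range(1, 8):
        raise DomainError(f"GDS value {gds!r} outside 1..7")
    if gds <= 2:
        return None
    if gds <= 4:
        return SeverityState.MILD
    if gds == 5:
        return SeverityState.MODERATE
    return SeverityState.SEVERE


def select_analysis_sample(
    records: Iterable[ClientRecord],
) -> tuple[list[tuple[SeverityState, SeverityState]], SelectionReport]:
    """Select paired state transitions from raw client records.

    Keeps records with both GDS observations present, a dementia-stage
    baseline (GDS >= 3) and a dementia-stage follow-up; emits one
    (from-state, to-state) pair per retained record.  Follow-up improvement
    to GDS 1-2 cannot be represented in the three-state space and is
    excluded and counted separately.

    The operation is idempotent in the sense that a sample that passes all
    filters is returned unchanged by a second pass.
    """
    records = list(records)
    pairs: list[tuple[SeverityState, SeverityState]] = []
    n_no_followup = 0
    n_predementia = 0
    n_remission = 0
    for rec in records:
        if rec.gds_followup is None:
            n_no_followup += 1
            continue
        from_state = map_gds_to_state(rec.gds_baseline)
        if from_state is None:
            n_predementia += 1
            continue
        to_state = map_gds_to_state(rec.gds_followup)
        if to_state is None:
            n_remission += 1
            continue
        pairs.append((from_state, to_state))
    report = SelectionReport(
        n_input=len(records),
        n_excluded_no_followup=n_no_followup,
        n_excluded_predementia=n_predementia,
        n_excluded_followup_remission=n_remission,
        n_analysis=len(pairs),
    )
    return pairs, report


def report_to_rows(report: SelectionReport) -> Sequence[tuple[str, int]]:
    """Flatten a SelectionReport for CSV/stdout emission."""
    return [
        ("n_input", report.n_input),
        ("n_excluded_no_followup", report.n_excluded_no_followup),
        ("n_excluded_predementia", report.n_excluded_predementia),
        ("n_excluded_followup_remission", report.n_excluded_followup_remission),
        ("n_analysis", report.n_analysis),
    ]
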