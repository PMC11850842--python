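"""Prescription-derived drug-exposure phenotype.

Dispensing records are cleaned, merged into active treatment periods by
scanning consecutive dispensations, and each person is classified at blood
draw as EXPOSED, UNEXPOSED, or EXCLUDED:

* EXPOSED — the draw falls at least ``lead_days`` after the start of some
  treatment period and strictly less than ``tail_days`` after its end;
* UNEXPOSED — the person has no dispensing records at all;
* EXCLUDED — records exist but no period satisfies the window rule.

Days are integer offsets from an arbitrary epoch; calendar parsing lives in
:mod:`mwastools.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PrescriptionRecord",
    "TreatmentPeriod",
    "ExposureStatus",
    "ExposureCall",
    "clean_prescriptions",
    "build_treatment_periods",
    "classify_exposure",
    "derive_exposure",
    "mdd_subgroup_mask",
]

#: default BNF paragraph prefix identifying antidepressant dispensations
DEFAULT_CODE_PREFIX = "040303"
DEFAULT_GRACE_DAYS = 30
DEFAULT_LEAD_DAYS = 7
DEFAULT_TAIL_DAYS = 7


@dataclass(frozen=True)
class PrescriptionRecord:
    person_id: str
    dispense_day: int
    drug_code: str
    quantity: float | None = None
    daily_dose: float | None = None

    def __post_init__(self) -> None:
        if not self.drug_code:
            raise ValueError("drug_code must be non-empty")
        if not math.isfinite(self.dispense_day):
            raise ValueError("dispense_day must be finite")

    @property
    def coverage_days(self) -> int:
        """Days of supply: ceil(quantity / daily_dose)."""
        if self.quantity is None or self.daily_dose is None or self.daily_dose <= 0:
            raise ValueError("coverage undefined without positive quantity and dose")
        return int(math.ceil(self.quantity / self.daily_dose))


@dataclass(frozen=True)
class TreatmentPeriod:
    person_id: str
    start_day: int
    end_day: int
    n_prescriptions: int

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError("period end before start")


class ExposureStatus(str, Enum):
    EXPOSED = "EXPOSED"
    UNEXPOSED = "UNEXPOSED"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class ExposureCall:
    person_id: str
    status: ExposureStatus
    time_in_treatment_days: int | None = None
    period_index: int | None = None

    def __post_init__(self) -> None:
        if self.time_in_treatment_days is not None and self.time_in_treatment_days < 0:
            raise ValueError("time in treatment must be non-negative")


@dataclass
class DroppedRecord:
    record: PrescriptionRecord
    reason: str


def clean_prescriptions(
    records: Iterable[PrescriptionRecord],
    code_filter: str = DEFAULT_CODE_PREFIX,
) -> tuple[list[PrescriptionRecord], list[DroppedRecord]]:
    """Split records into usable ones and drops with machine-readable reasons.

    Drop reasons: ``code-mismatch``, ``missing-quantity``,
    ``nonpositive-quantity``, ``missing-dose``, ``nonpositive-dose``.
    """
    kept: list[PrescriptionRecord] = []
    dropped: list[DroppedRecord] = []
    for rec in records:
        if not rec.drug_code.startswith(code_filter):
            dropped.append(DroppedRecord(rec, "code-mismatch"))
        elif rec.quantity is None or (
            isinstance(rec.quantity, float) and math.isnan(rec.quantity)
        ):
            dropped.append(DroppedRecord(rec, "missing-quantity"))
        elif rec.quantity <= 0:
            dropped.append(DroppedRecord(rec, "nonpositive-quantity"))
        elif rec.daily_dose is None or (
            isinstance(rec.daily_dose, float) and math.isnan(rec.daily_dose)
        ):
            dropped.append(DroppedRecord(rec, "missing-dose"))
        elif rec.daily_dose <= 0:
            dropped.append(DroppedRecord(rec, "nonpositive-dose"))
        else:
            kept.append(rec)
    return kept, dropped


def build_treatment_periods(
    records: Sequence[PrescriptionRecord],
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> list[TreatmentPeriod]:
    """Merge one person's cleaned dispensations into active treatment periods.

    Records are scanned in dispensing order.  A record joins the current
    period when its dispense day is no later than the period end plus
    ``grace_days``; the period end is then extended to
    ``max(end, dispense_day + coverage)``.  Otherwise a new period starts.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be non-negative")
    records = sorted(records, key=lambda r: r.dispense_day)
    if not records:
        return []
    person_ids = {r.person_id for r in records}
    if len(person_ids) > 1:
        raise ValueError(f"records from multiple persons: {sorted(person_ids)}")
    person_id = records[0].person_id

    periods: list[TreatmentPeriod] = []
    start = records[0].dispense_day
    end = records[0].dispense_day + records[0].coverage_days
    count = 1
    for rec in records[1:]:
        if rec.dispense_day <= end + grace_days:
            end = max(end, rec.dispense_day + rec.coverage_days)
            count += 1
        else:
            periods.append(TreatmentPeriod(person_id, start, end, count))
            start = rec.dispense_day
            end = rec.dispense_day + rec.coverage_days
            count = 1
    periods.append(TreatmentPeriod(person_id, start, end, count))
    return periods


def _check_disjoint(periods: Sequence[TreatmentPeriod]) -> None:
    for a, b in zip(periods, periods[1:]):
        if b.start_day <= a.end_day:
            raise ValueError(
                f"overlapping treatment periods: [{a.start_day},{a.end_day}] "
                f"and [{b.start_day},{b.end_day}]"
            )


def classify_exposure(
    periods: Sequence[TreatmentPeriod],
    has_any_prescription: bool,
    draw_day: int,
    lead_days: int = DEFAULT_LEAD_DAYS,
    tail_days: int = DEFAULT_TAIL_DAYS,
    person_id: str | None = None,
) -> ExposureCall:
    """Classify one person's exposure state at the blood draw.

    ``time_in_treatment_days`` is defined only when the draw lies inside the
    covering period (``draw_day <= end_day``); draws inside the tail window
    count as exposed but carry no treatment time.
    """
    periods = sorted(periods, key=lambda p: p.start_day)
    _check_disjoint(periods)
    if person_id is None:
        person_id = periods[0].person_id if periods else "?"

    for idx, period in enumerate(periods):
        if draw_day >= period.start_day + lead_days and draw_day < period.end_day + tail_days:
            tit = draw_day - period.start_day if draw_day <= period.end_day else None
            return ExposureCall(person_id, ExposureStatus.EXPOSED, tit, idx)
    if not has_any_prescription:
        return ExposureCall(person_id, ExposureStatus.UNEXPOSED)
    return ExposureCall(person_id, ExposureStatus.EXCLUDED)


def derive_exposure(
    records: Iterable[PrescriptionRecord],
    draw_days: dict[str, int],
    code_filter: str = DEFAULT_CODE_PREFIX,
    grace_days: int = DEFAULT_GRACE_DAYS,
    lead_days: int = DEFAULT_LEAD_DAYS,
    tail_days: int = DEFAULT_TAIL_DAYS,
) -> pd.DataFrame:
    """Full pipeline over a cohort: clean, build periods, classify per person.

    Returns a frame indexed by person id with columns ``status``,
    ``time_in_treatment_days``, ``period_start``, ``period_end``,
    ``n_periods``, ``n_prescriptions``.  Persons present in ``draw_days``
    but without records are UNEXPOSED.
    """
    kept, _ = clean_prescriptions(records, code_filter)
    by_person: dict[str, list[PrescriptionRecord]] = {}
    for rec in kept:
        by_person.setdefault(rec.person_id, []).append(rec)

    rows = []
    for person_id, draw_day in draw_days.items():
        recs = by_person.get(person_id, [])
        periods = build_treatment_periods(recs, grace_days) if recs else []
        call = classify_exposure(
            periods, bool(recs), draw_day, lead_days, tail_days, person_id=person_id
        )
        period = periods[call.period_index] if call.period_index is not None else None
        rows.append(
            {
                "person_id": person_id,
                "status": call.status.value,
                "time_in_treatment_days": call.time_in_treatment_days,
                "period_start": period.start_day if period else None,
                "period_end": period.end_day if period else None,
                "n_periods": len(periods),
                "n_prescriptions": len(recs),
            }
        )
    return pd.DataFrame(rows).set_index("person_id")


def mdd_subgroup_mask(phenotypes: pd.DataFrame) -> pd.Series:
    """Lifetime-MDD subgroup: MDD flag set and bipolar flag unset."""
    return phenotypes["lifetime_MDD"].astype(bool) & ~phenotypes["bipolar"].astype(bool)
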