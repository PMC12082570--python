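"""Hand-built report fixtures for unit tests."""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence, Tuple

from pvkit.faers_ingest import CaseReport, DrugEntry


def make_case(
    primary_id: str = "100",
    case_id: str = "1",
    version: int = 1,
    receipt: Optional[dt.date] = dt.date(2020, 1, 1),
    sex: str = "male",
    age: Optional[float] = 40.0,
    weight: Optional[float] = 70.0,
    drugs: Sequence[Tuple[str, str, Optional[dt.date]]] = (("DRUG_A", "PS", None),),
    reactions: Sequence[str] = (),
    event_date: Optional[dt.date] = None,
    outcomes: Sequence[str] = ("OT",),
) -> CaseReport:
    return CaseReport(
        primary_id=primary_id,
        case_id=case_id,
        case_version=version,
        receipt_date=receipt,
        sex=sex,
        age_years=age,
        weight_kg=weight,
        reporter_type="MD",
        country="US",
        outcomes=frozenset(outcomes),
        drugs=tuple(DrugEntry(name, role, start) for name, role, start in drugs),
        reactions=frozenset(reactions),
        event_date=event_date,
    )
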