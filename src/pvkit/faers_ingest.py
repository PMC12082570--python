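"""Reading, deduplicating, and case-finding over FAERS-dialect report tables.

A FAERS quarterly extract carries several versions of the same case (one per
follow-up submission). Analysis wants exactly one report per case: the winner
is the version with the latest receipt date (``FDA_DT``), ties broken by the
highest ``CASEVERSION``, then the highest ``PRIMARYID``. Target-event cases are
flagged through a configurable SMQ-style preferred-term list with narrow and
broad scopes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .synth_faers import DELIMITER, TABLE_COLUMNS, TABLE_FILENAMES

ROLE_CODES = ("PS", "SS", "C", "I")
DATE_POLICIES = ("strict_day", "impute_first")


class IngestError(ValueError):
    pass


def parse_faers_date(value: str, policy: str = "strict_day") -> Optional[dt.date]:
    """Parse a YYYYMMDD / YYYYMM / YYYY FAERS date string.

    Under ``strict_day`` (the default) partial dates become missing, because
    time-to-onset needs day resolution. ``impute_first`` maps partial dates to
    the first day of the period instead.
    """
    if policy not in DATE_POLICIES:
        raise ValueError(f"unknown date policy {policy!r}")
    value = (value or "").strip()
    if not value.isdigit():
        return None
    try:
        if len(value) == 8:
            return dt.datetime.strptime(value, "%Y%m%d").date()
        if policy == "impute_first":
            if len(value) == 6:
                return dt.datetime.strptime(value + "01", "%Y%m%d").date()
            if len(value) == 4:
                return dt.datetime.strptime(value + "0101", "%Y%m%d").date()
    except ValueError:
        return None
    return None


def _norm(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class DrugEntry:
    name: str
    role: str
    start_date: Optional[dt.date]


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated spontaneous report."""

    primary_id: str
    case_id: str
    case_version: int
    receipt_date: Optional[dt.date]
    sex: str  # male / female / unknown
    age_years: Optional[float]
    weight_kg: Optional[float]
    reporter_type: str
    country: str
    outcomes: frozenset
    drugs: Tuple[DrugEntry, ...]
    reactions: frozenset
    event_date: Optional[dt.date]

    def has_drug_role(self, drug_name: str, role: str) -> bool:
        target = _norm(drug_name)
        return any(d.role == role and _norm(d.name) == target for d in self.drugs)

    def ps_start_date(self, drug_name: str) -> Optional[dt.date]:
        """Earliest therapy start across the named drug's PS entries."""
        target = _norm(drug_name)
        starts = [
            d.start_date
            for d in self.drugs
            if d.role == "PS" and _norm(d.name) == target and d.start_date is not None
        ]
        return min(starts) if starts else None


@dataclass(frozen=True)
class SMQDefinition:
    name: str
    narrow_pts: frozenset
    broad_pts: frozenset = frozenset()

    def __post_init__(self):
        if not self.narrow_pts:
            raise IngestError("SMQ narrow scope must be non-empty")

    def scope_pts(self, scope: str) -> frozenset:
        if scope == "narrow":
            return self.narrow_pts
        if scope == "broad":
            return self.narrow_pts | self.broad_pts
        raise ValueError(f"unknown SMQ scope {scope!r}")


def load_smq(path: Path, name: Optional[str] = None) -> SMQDefinition:
    """Parse an SMQ config: one PT per line under ``[narrow]`` / ``[broad]``."""
    path = Path(path)
    section = None
    pts: Dict[str, set] = {"narrow": set(), "broad": set()}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in pts:
                raise IngestError(f"unknown SMQ section [{section}] in {path}")
            continue
        if section is None:
            raise IngestError(f"PT {line!r} outside any section in {path}")
        pts[section].add(line)
    return SMQDefinition(
        name=name or path.stem,
        narrow_pts=frozenset(pts["narrow"]),
        broad_pts=frozenset(pts["broad"]),
    )


def default_smq() -> SMQDefinition:
    """The packaged acute-pancreatitis PT list (editable ship-with config)."""
    ref = resources.files("pvkit.data") / "acute_pancreatitis_smq.txt"
    with resources.as_file(ref) as path:
        return load_smq(path, name="Acute pancreatitis (SMQ)")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_tables(directory: Path) -> Dict[str, pd.DataFrame]:
    """Read the five "$"-delimited tables as string frames ('' = missing)."""
    directory = Path(directory)
    tables = {}
    for name, filename in TABLE_FILENAMES.items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"missing FAERS table file: {path}")
        frame = pd.read_csv(
            path, sep=DELIMITER, dtype=str, keep_default_na=False, engine="python"
        )
        missing = [c for c in TABLE_COLUMNS[name] if c not in frame.columns]
        if missing:
            raise IngestError(f"{filename}: malformed header, missing columns {missing}")
        tables[name] = frame
    return tables


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _parse_age(age: str, cod: str) -> Optional[float]:
    age = (age or "").strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    cod = (cod or "").strip().upper()
    if cod in ("", "YR"):
        return value
    if cod == "MON":
        return value / 12.0
    if cod == "DY":
        return value / 365.25
    if cod == "WK":
        return value * 7.0 / 365.25
    if cod == "DEC":
        return value * 10.0
    return None


def _parse_weight(wt: str, cod: str) -> Optional[float]:
    wt = (wt or "").strip()
    if not wt:
        return None
    try:
        value = float(wt)
    except ValueError:
        return None
    cod = (cod or "").strip().upper()
    if cod in ("", "KG"):
        return value if value > 0 else None
    if cod == "LBS":
        return value * 0.45359237 if value > 0 else None
    return None


_SEX_MAP = {"M": "male", "F": "female"}


def deduplicate(
    tables: Mapping[str, pd.DataFrame], date_policy: str = "strict_day"
) -> List[CaseReport]:
    """Collapse to one :class:`CaseReport` per case id.

    Winner: latest FDA_DT, then highest CASEVERSION, then highest PRIMARYID.
    Idempotent and insensitive to input row order.
    """
    demo = tables["demo"]
    if demo.empty:
        return []
    work = demo.copy()
    work["_fda"] = pd.to_numeric(work["FDA_DT"], errors="coerce").fillna(-1)
    work["_ver"] = pd.to_numeric(work["CASEVERSION"], errors="coerce").fillna(-1)
    work["_pid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce").fillna(-1)
    work = work.sort_values(["CASEID", "_fda", "_ver", "_pid"], kind="mergesort")
    winners = work.drop_duplicates("CASEID", keep="last")
    winner_pids = set(winners["PRIMARYID"])

    def rows_for(name: str) -> pd.DataFrame:
        frame = tables[name]
        if frame.empty:
            return frame
        return frame[frame["PRIMARYID"].isin(winner_pids)]

    reac_map: Dict[str, set] = {}
    for pid, pt in zip(rows_for("reac")["PRIMARYID"], rows_for("reac")["PT"]):
        reac_map.setdefault(pid, set()).add(pt)

    outc_map: Dict[str, set] = {}
    for pid, code in zip(rows_for("outc")["PRIMARYID"], rows_for("outc")["OUTC_COD"]):
        outc_map.setdefault(pid, set()).add(code)

    ther_map: Dict[Tuple[str, str], Optional[dt.date]] = {}
    ther = rows_for("ther")
    if not ther.empty:
        for pid, seq, start in zip(
            ther["PRIMARYID"], ther["DSG_DRUG_SEQ"], ther["START_DT"]
        ):
            ther_map[(pid, seq)] = parse_faers_date(start, date_policy)

    drug_map: Dict[str, list] = {}
    drug = rows_for("drug")
    if not drug.empty:
        for pid, seq, role, name in zip(
            drug["PRIMARYID"], drug["DRUG_SEQ"], drug["ROLE_COD"], drug["DRUGNAME"]
        ):
            role = role.strip().upper()
            if role not in ROLE_CODES:
                role = "C"
            drug_map.setdefault(pid, []).append(
                DrugEntry(name=name, role=role, start_date=ther_map.get((pid, seq)))
            )

    reports = []
    order = winners.sort_values("_pid", kind="mergesort")
    columns = [
        "PRIMARYID", "CASEID", "_ver", "FDA_DT", "SEX", "AGE", "AGE_COD",
        "WT", "WT_COD", "OCCP_COD", "REPORTER_COUNTRY", "EVENT_DT",
    ]
    for pid, cid, ver, fda, sex, age, age_cod, wt, wt_cod, occp, country, ev in zip(
        *(order[c] for c in columns)
    ):
        reports.append(
            CaseReport(
                primary_id=pid,
                case_id=cid,
                case_version=int(ver),
                receipt_date=parse_faers_date(fda, date_policy),
                sex=_SEX_MAP.get(sex.strip().upper(), "unknown"),
                age_years=_parse_age(age, age_cod),
                weight_kg=_parse_weight(wt, wt_cod),
                reporter_type=occp,
                country=country,
                outcomes=frozenset(outc_map.get(pid, ())),
                drugs=tuple(drug_map.get(pid, ())),
                reactions=frozenset(reac_map.get(pid, ())),
                event_date=parse_faers_date(ev, date_policy),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# selection / flagging
# ---------------------------------------------------------------------------

def select_ps_reports(reports: Sequence[CaseReport], drug_name: str) -> List[CaseReport]:
    """Reports naming ``drug_name`` with role PS (case-insensitive exact match)."""
    return [r for r in reports if r.has_drug_role(drug_name, "PS")]


def flag_event_cases(
    reports: Sequence[CaseReport], smq: SMQDefinition, scope: str = "narrow"
) -> Dict[str, bool]:
    """Per-report boolean keyed by primary id: does the reaction set intersect
    the scope's PT list (case-insensitive exact match)?"""
    pts = {_norm(p) for p in smq.scope_pts(scope)}
    return {
        r.primary_id: any(_norm(pt) in pts for pt in r.reactions) for r in reports
    }


def ingest_log(
    tables: Mapping[str, pd.DataFrame],
    reports: Sequence[CaseReport],
    flags: Optional[Mapping[str, bool]] = None,
    smq: Optional[SMQDefinition] = None,
    scope: str = "narrow",
) -> dict:
    """Per-stage record counts (report-level and PT-occurrence-level tallies
    are both logged because published counts can be either)."""
    log = {
        "demo_rows": int(len(tables["demo"])),
        "unique_cases": int(tables["demo"]["CASEID"].nunique()) if len(tables["demo"]) else 0,
        "reports_after_dedup": len(reports),
    }
    if flags is not None:
        log["event_flagged_reports"] = int(sum(flags.values()))
    if smq is not None:
        pts = {_norm(p) for p in smq.scope_pts(scope)}
        kept = {r.primary_id for r in reports}
        reac = tables["reac"]
        if len(reac):
            in_kept = reac["PRIMARYID"].isin(kept)
            matches = reac.loc[in_kept, "PT"].map(_norm).isin(pts)
            log["event_pt_occurrences"] = int(matches.sum())
        else:
            log["event_pt_occurrences"] = 0
    return log
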