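"""Disproportionality statistics on 2x2 drug-by-event contingency tables.

Four detectors are computed per table: the reporting odds ratio (ROR), the
proportional reporting ratio (PRR) with its Pearson chi-square, the BCPNN
information component E(IC) with its two-standard-deviation lower bound IC025,
and the relative reporting ratio EBGM with its one-sided lower bound EBGM05.
A pair is signal-positive only when all four per-detector criteria hold
simultaneously.

Notes on conventions:

* EBGM here is the plain relative reporting ratio a*N / ((a+c)(a+b)); no
  empirical-Bayes gamma-mixture shrinkage is applied, so values on very sparse
  tables run higher than MGPS-style software would report.
* IC025 is E(IC) minus exactly two standard deviations (not a 97.5% normal
  quantile).
* When a table has a zero cell, the Haldane-Anscombe continuity correction
  (+0.5 on all four cells) is applied to the ROR/PRR/EBGM point estimates and
  intervals, and the result is flagged ``zero_corrected``. The chi-square uses
  the raw cells, degenerating to 0 when a margin is empty.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .faers_ingest import CaseReport, SMQDefinition, flag_event_cases

Z95 = 1.96
Z90_ONE_SIDED = 1.64

ADJUST_METHODS = {"fdr_bh", "bonferroni"}


@dataclass(frozen=True)
class ContingencyTable:
    """a: target drug & target event; b: target drug only; c: target event
    only; d: neither. N = a+b+c+d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def cells(self, corrected: bool = False) -> Tuple[float, float, float, float]:
        if corrected:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


@dataclass(frozen=True)
class BCPNNPriors:
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self):
        for name in ("alpha1", "beta1", "gamma11", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be strictly positive")


@dataclass(frozen=True)
class Thresholds:
    """Joint signal criteria; defaults follow the standard four-detector rule."""

    ror_min_a: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_a: int = 3
    bcpnn_min_a: int = 3
    ic025_min: float = 0.0
    ebgm_min_a: int = 1
    ebgm05_min: float = 2.0

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path) -> "Thresholds":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class StatInterval:
    point: float
    ci95: Tuple[float, float]
    zero_corrected: bool = False


@dataclass(frozen=True)
class PRRResult:
    point: float
    ci95: Tuple[float, float]
    chi2: float
    zero_corrected: bool = False


@dataclass(frozen=True)
class BCPNNResult:
    ic: float
    ic025: float


@dataclass(frozen=True)
class SignalResult:
    drug: str
    event: str
    stratum: str
    table: ContingencyTable
    ror: float
    ror_ci95: Tuple[float, float]
    prr: float
    prr_ci95: Tuple[float, float]
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    p_raw: float
    p_adjusted: Optional[float] = None
    flags: Mapping[str, bool] = field(default_factory=dict)
    signal: bool = False
    zero_corrected: bool = False


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

StratumFilter = Callable[[CaseReport], Optional[bool]]


def build_table(
    reports: Sequence[CaseReport],
    drug: str,
    event_flags: Mapping[str, bool],
    stratum: Optional[StratumFilter] = None,
) -> ContingencyTable:
    """Count the 2x2 cells over (already deduplicated) reports.

    ``stratum`` may return None for a report whose stratifying field is
    missing; such reports are excluded from the table entirely.
    """
    a = b = c = d = 0
    for r in reports:
        if stratum is not None and stratum(r) is not True:
            continue
        exposed = r.has_drug_role(drug, "PS")
        event = bool(event_flags.get(r.primary_id, False))
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# the four detectors
# ---------------------------------------------------------------------------

def ror_stat(t: ContingencyTable) -> StatInterval:
    """ROR = ad/bc with exp(ln ROR +/- 1.96 * sqrt(1/a+1/b+1/c+1/d))."""
    corrected = t.has_zero_cell
    a, b, c, d = t.cells(corrected)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_point = math.log(point)
    ci = (math.exp(log_point - Z95 * se), math.exp(log_point + Z95 * se))
    return StatInterval(point, ci, corrected)


def _chi2(t: ContingencyTable) -> float:
    a, b, c, d = t.cells()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return (a * d - b * c) ** 2 * t.N / denom


def prr_stat(t: ContingencyTable) -> PRRResult:
    """PRR = [a/(a+b)] / [c/(c+d)]; chi-square from the raw cells."""
    corrected = t.has_zero_cell
    a, b, c, d = t.cells(corrected)
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_point = math.log(point)
    ci = (math.exp(log_point - Z95 * se), math.exp(log_point + Z95 * se))
    return PRRResult(point, ci, _chi2(t), corrected)


def bcpnn_stat(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors()) -> BCPNNResult:
    """Shrunken information component E(IC) and IC025 = E(IC) - 2*sd.

    The priors regularize empty tables, so no continuity correction is needed.
    """
    a, b, c, _ = t.cells()
    n = float(t.N)
    a1, b1, g11 = priors.alpha1, priors.beta1, priors.gamma11
    al, be = priors.alpha, priors.beta
    row = a + b + a1   # a+b+alpha1
    col = a + c + b1   # a+c+beta1
    gamma = g11 * (n + al) * (n + be) / (row * col)
    e_ic = math.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * row * col))
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / (row * (1 + n + al))
        + (n - (a + c) + be - b1) / (col * (1 + n + be))
    ) / math.log(2) ** 2
    return BCPNNResult(e_ic, e_ic - 2.0 * math.sqrt(v_ic))


def ebgm_stat(t: ContingencyTable) -> StatInterval:
    """EBGM = a*N / ((a+c)(a+b)) (relative reporting ratio) and
    EBGM05 = exp(ln EBGM - 1.64 * sqrt(1/a+1/b+1/c+1/d))."""
    corrected = t.has_zero_cell
    a, b, c, d = t.cells(corrected)
    n = a + b + c + d
    point = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    low = math.exp(math.log(point) - Z90_ONE_SIDED * se)
    return StatInterval(point, (low, math.inf), corrected)


# ---------------------------------------------------------------------------
# decision and adjustment
# ---------------------------------------------------------------------------

def signal_decision(
    r: SignalResult, thresholds: Thresholds = Thresholds()
) -> Tuple[Dict[str, bool], bool]:
    """Apply the per-detector criteria; the joint signal is their conjunction."""
    a = r.table.a
    flags = {
        "ror": a >= thresholds.ror_min_a and r.ror_ci95[0] > thresholds.ror_ci_low,
        "prr": (
            r.prr >= thresholds.prr_min
            and r.chi2 >= thresholds.chi2_min
            and a >= thresholds.prr_min_a
        ),
        "bcpnn": a >= thresholds.bcpnn_min_a and r.ic025 > thresholds.ic025_min,
        "ebgm": a >= thresholds.ebgm_min_a and r.ebgm05 > thresholds.ebgm05_min,
    }
    return flags, all(flags.values())


def evaluate_pair(
    table: ContingencyTable,
    drug: str,
    event: str,
    stratum: str = "overall",
    priors: BCPNNPriors = BCPNNPriors(),
    thresholds: Thresholds = Thresholds(),
) -> SignalResult:
    """Compute all four detectors plus the raw chi-square p-value (1 df)."""
    ror = ror_stat(table)
    prr = prr_stat(table)
    ic = bcpnn_stat(table, priors)
    ebgm = ebgm_stat(table)
    p_raw = float(stats.chi2.sf(prr.chi2, df=1))
    result = SignalResult(
        drug=drug,
        event=event,
        stratum=stratum,
        table=table,
        ror=ror.point,
        ror_ci95=ror.ci95,
        prr=prr.point,
        prr_ci95=prr.ci95,
        chi2=prr.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=ebgm.point,
        ebgm05=ebgm.ci95[0],
        p_raw=p_raw,
        zero_corrected=ror.zero_corrected or prr.zero_corrected or ebgm.zero_corrected,
    )
    flags, signal = signal_decision(result, thresholds)
    return dataclasses.replace(result, flags=flags, signal=signal)


def adjust_pvalues(
    results: Sequence[SignalResult], method: str = "fdr_bh"
) -> List[SignalResult]:
    """Multiplicity adjustment across all results in a run (default BH)."""
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}; use one of {sorted(ADJUST_METHODS)}")
    if not results:
        return []
    p_raw = [r.p_raw for r in results]
    adjusted = multipletests(p_raw, method=method)[1]
    return [dataclasses.replace(r, p_adjusted=float(p)) for r, p in zip(results, adjusted)]


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

class OverlappingBinsError(ValueError):
    pass


NumericBins = Sequence[Tuple[str, float, float]]  # (label, low, high], half-open


def _numeric_strata(variable: str, spec: Union[float, NumericBins]) -> List[Tuple[str, NumericBins]]:
    if isinstance(spec, (int, float)):
        cut = float(spec)
        bins: NumericBins = [
            (f"{variable}<={cut:g}", -math.inf, cut),
            (f"{variable}>{cut:g}", cut, math.inf),
        ]
    else:
        bins = [(label, float(lo), float(hi)) for label, lo, hi in spec]
        ordered = sorted(bins, key=lambda x: x[1])
        for (_, _, hi_prev), (_, lo_next, _) in zip(ordered, ordered[1:]):
            if lo_next < hi_prev:
                raise OverlappingBinsError(f"overlapping bins for {variable!r}")
    return [(label, (lo, hi)) for label, lo, hi in bins]


def make_strata(strata_spec: Mapping[str, object]) -> List[Tuple[str, StratumFilter]]:
    """Turn a spec like ``{"sex": None, "age": 65, "weight": 80}`` into labelled
    report filters. Filters return None when the stratifying field is missing,
    which excludes the report from that stratification only."""
    strata: List[Tuple[str, StratumFilter]] = []
    for variable, spec in strata_spec.items():
        if variable == "sex":
            for level in ("male", "female"):
                def sex_filter(r: CaseReport, level=level) -> Optional[bool]:
                    if r.sex == "unknown":
                        return None
                    return r.sex == level
                strata.append((f"sex={level}", sex_filter))
        elif variable in ("age", "weight"):
            attr = "age_years" if variable == "age" else "weight_kg"
            for label, (lo, hi) in _numeric_strata(variable, spec):
                def num_filter(r: CaseReport, attr=attr, lo=lo, hi=hi) -> Optional[bool]:
                    value = getattr(r, attr)
                    if value is None:
                        return None
                    return lo < value <= hi
                strata.append((label, num_filter))
        else:
            raise ValueError(f"unknown stratification variable {variable!r}")
    return strata


def stratified_scan(
    reports: Sequence[CaseReport],
    drug: str,
    smq: SMQDefinition,
    strata_spec: Mapping[str, object],
    scope: str = "narrow",
    priors: BCPNNPriors = BCPNNPriors(),
    thresholds: Thresholds = Thresholds(),
    include_overall: bool = True,
) -> List[SignalResult]:
    """One SignalResult per stratum (plus the overall table first, by default).

    p_adjusted is left unset; multiplicity adjustment belongs at the run
    level, across every pair in the scan (see :func:`adjust_pvalues`).
    """
    flags = flag_event_cases(reports, smq, scope)
    results = []
    if include_overall:
        table = build_table(reports, drug, flags)
        results.append(evaluate_pair(table, drug, smq.name, "overall", priors, thresholds))
    for label, stratum_filter in make_strata(strata_spec):
        table = build_table(reports, drug, flags, stratum_filter)
        results.append(evaluate_pair(table, drug, smq.name, label, priors, thresholds))
    return results


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "event": r.event,
                "stratum": r.stratum,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror,
                "ror_lo": r.ror_ci95[0],
                "ror_hi": r.ror_ci95[1],
                "prr": r.prr,
                "prr_lo": r.prr_ci95[0],
                "prr_hi": r.prr_ci95[1],
                "chi2": r.chi2,
                "ic": r.ic,
                "ic025": r.ic025,
                "ebgm": r.ebgm,
                "ebgm05": r.ebgm05,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "flag_ror": r.flags.get("ror"),
                "flag_prr": r.flags.get("prr"),
                "flag_bcpnn": r.flags.get("bcpnn"),
                "flag_ebgm": r.flags.get("ebgm"),
                "signal": r.signal,
                "zero_corrected": r.zero_corrected,
            }
        )
    return pd.DataFrame(rows)
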