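"""Synthetic spontaneous-report generator in the FAERS quarterly ASCII dialect.

The generator plants a fully known ground truth — per drug–event reporting-rate
ratios, Weibull onset latencies, demographic risk effects, and literal duplicate
report versions — so that every downstream stage (deduplication, case finding,
disproportionality, time-to-onset, logistic modelling) can be tested against an
exact oracle without any external data.

Rate ratios and risk effects are both planted on the log-odds scale: for a
report whose primary-suspect drug is ``d``, the probability that event ``e`` is
mentioned satisfies

    logit P(e) = logit(background_rate) + log(rate_ratio[d, e]) + x' * effects

so the population reporting odds ratio of a planted pair equals the configured
rate ratio exactly, which is what the downstream estimators target.

Draw order (part of the reproducibility contract; a single seeded
``numpy.random.Generator`` is threaded through all stages in this sequence):

1. demographics — sex, age, weight category draws, then missingness masks
2. primary-suspect drug index per case
3. concomitant drug presence and identity
4. reporter occupation and country
5. event occurrence matrix (cases x events)
6. onset latencies (one Weibull draw per case)
7. therapy start dates, then receipt-date offsets
8. outcome codes
9. duplicate flags and extra version counts
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

DELIMITER = "$"

DEMO_COLUMNS = [
    "PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "EVENT_DT", "SEX",
    "AGE", "AGE_COD", "WT", "WT_COD", "OCCP_COD", "REPORTER_COUNTRY",
]
DRUG_COLUMNS = ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"]
REAC_COLUMNS = ["PRIMARYID", "CASEID", "PT"]
THER_COLUMNS = ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"]
OUTC_COLUMNS = ["PRIMARYID", "CASEID", "OUTC_COD"]

TABLE_COLUMNS: Dict[str, list] = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "ther": THER_COLUMNS,
    "outc": OUTC_COLUMNS,
}
TABLE_FILENAMES: Dict[str, str] = {
    "demo": "DEMO.txt",
    "drug": "DRUG.txt",
    "reac": "REAC.txt",
    "ther": "THER.txt",
    "outc": "OUTC.txt",
}

OUTCOME_CODES = ["OT", "HO", "DE", "LT", "DS", "RI"]
OUTCOME_PROBS = [0.45, 0.30, 0.08, 0.07, 0.05, 0.05]
OCCP_CODES = ["MD", "PH", "OT", "CN", "LW"]
OCCP_PROBS = [0.30, 0.10, 0.20, 0.30, 0.10]
COUNTRIES = ["US", "CA", "GB", "FR", "DE"]
COUNTRY_PROBS = [0.80, 0.05, 0.05, 0.05, 0.05]

DEFAULT_TARGET_PT = "Pancreatitis acute"
DEFAULT_LATENCY = (365.0, 1.0)  # (scale_days, shape) when a pair has no entry

RISK_COVARIATES = ("female", "age_le65", "weight_gt80")  # plus "conmed:<NAME>"


class ConfigError(ValueError):
    """Invalid simulation configuration; ``.field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class CategoricalMix:
    """A categorical distribution over observed values plus a missingness mass."""

    categories: Mapping[Any, float]
    missing: float = 0.0

    def validate(self, name: str) -> None:
        if not self.categories:
            raise ConfigError(name, "needs at least one category")
        if not 0.0 <= self.missing <= 1.0:
            raise ConfigError(name, "missing probability must be in [0, 1]")
        probs = list(self.categories.values())
        if any(p < 0 for p in probs):
            raise ConfigError(name, "category probabilities must be non-negative")
        total = sum(probs) + self.missing
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(name, f"probabilities must sum to 1 (got {total})")

    def draw(self, rng: np.random.Generator, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Return (values, missing_mask); values are drawn pre-missingness.

        Categories are sorted before drawing so the draw order (part of the
        reproducibility contract) does not depend on dict insertion order.
        """
        values = sorted(self.categories, key=lambda v: (type(v).__name__, v))
        probs = np.array([self.categories[v] for v in values], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(values), size=n, p=probs)
        drawn = np.array(values, dtype=object)[idx]
        miss = rng.random(n) < self.missing
        return drawn, miss


def _default_mix() -> Dict[str, CategoricalMix]:
    return {
        "sex": CategoricalMix({"M": 0.43, "F": 0.47}, missing=0.10),
        "age": CategoricalMix(
            {32.0: 0.25, 45.0: 0.25, 58.0: 0.20, 70.0: 0.15, 80.0: 0.05},
            missing=0.10,
        ),
        "weight": CategoricalMix(
            {55.0: 0.20, 70.0: 0.30, 85.0: 0.25, 110.0: 0.10}, missing=0.15
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of one synthetic reporting universe."""

    n_cases: int
    n_drugs: int = 10
    n_events: int = 10
    background_rate: float = 0.01
    signal_matrix: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    demographic_mix: Mapping[str, CategoricalMix] = field(default_factory=_default_mix)
    tto_params: Mapping[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    risk_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    concomitant_rate: float = 0.3
    target_event_pt: str = DEFAULT_TARGET_PT

    # -- vocabulary -------------------------------------------------------
    def drug_names(self) -> list:
        return [f"DRUG_{i + 1:03d}" for i in range(self.n_drugs)]

    def event_names(self) -> list:
        names = [f"EVENT_PT_{i + 1:03d}" for i in range(self.n_events)]
        if self.target_event_pt:
            names[0] = self.target_event_pt
        return names

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.n_cases, (int, np.integer)) or self.n_cases <= 0:
            raise ConfigError("n_cases", "must be a positive integer")
        for name in ("n_drugs", "n_events"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(name, "must be a positive integer")
        if not 0.0 <= self.background_rate < 1.0:
            raise ConfigError("background_rate", "must be in [0, 1)")
        for name in ("duplicate_rate", "concomitant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must be in [0, 1]")
        drugs, events = set(self.drug_names()), set(self.event_names())
        for (d, e), rr in self.signal_matrix.items():
            if d not in drugs:
                raise ConfigError("signal_matrix", f"unknown drug {d!r}")
            if e not in events:
                raise ConfigError("signal_matrix", f"unknown event {e!r}")
            if rr < 0:
                raise ConfigError("signal_matrix", f"rate ratio for {(d, e)} must be >= 0")
        for (d, e), (scale, shape) in self.tto_params.items():
            if d not in drugs or e not in events:
                raise ConfigError("tto_params", f"unknown pair {(d, e)}")
            if scale <= 0 or shape <= 0:
                raise ConfigError("tto_params", f"Weibull parameters for {(d, e)} must be > 0")
        for name in ("sex", "age", "weight"):
            if name not in self.demographic_mix:
                raise ConfigError("demographic_mix", f"missing field {name!r}")
            self.demographic_mix[name].validate(f"demographic_mix.{name}")
        for key in self.risk_effects:
            if key not in RISK_COVARIATES and not key.startswith("conmed:"):
                raise ConfigError("risk_effects", f"unknown covariate {key!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed", "must be an integer")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_matrix"] = {f"{k[0]}|{k[1]}": v for k, v in self.signal_matrix.items()}
        d["tto_params"] = {f"{k[0]}|{k[1]}": list(v) for k, v in self.tto_params.items()}
        d["demographic_mix"] = {
            name: {"categories": {str(k): p for k, p in mix.categories.items()},
                   "missing": mix.missing}
            for name, mix in self.demographic_mix.items()
        }
        d["risk_effects"] = dict(self.risk_effects)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "signal_matrix" in d:
            d["signal_matrix"] = {
                tuple(k.split("|", 1)): float(v) for k, v in d["signal_matrix"].items()
            }
        if "tto_params" in d:
            d["tto_params"] = {
                tuple(k.split("|", 1)): tuple(map(float, v))
                for k, v in d["tto_params"].items()
            }
        if "demographic_mix" in d:
            mixes = {}
            for name, spec in d["demographic_mix"].items():
                cats = {
                    (k if name == "sex" else float(k)): float(p)
                    for k, p in spec["categories"].items()
                }
                mixes[name] = CategoricalMix(cats, float(spec.get("missing", 0.0)))
            d["demographic_mix"] = mixes
        return cls(**d)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """Generated record tables plus the planted truth that produced them."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    truth: Optional[SimulationConfig] = None
    truth_cases: Optional[pd.DataFrame] = None
    event_matrix: Optional[np.ndarray] = None  # (n_cases, n_events) bool

    @property
    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "demo": self.demo, "drug": self.drug, "reac": self.reac,
            "ther": self.ther, "outc": self.outc,
        }


def empty_dataset() -> SyntheticDataset:
    frames = {
        name: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for name, cols in TABLE_COLUMNS.items()
    }
    return SyntheticDataset(**frames)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _fmt_dates(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD strings."""
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")


def _covariate_vector(
    key: str,
    sex: np.ndarray,
    age: np.ndarray,
    weight: np.ndarray,
    con_name: np.ndarray,
) -> np.ndarray:
    if key == "female":
        return (sex == "F").astype(float)
    if key == "age_le65":
        return (age.astype(float) <= 65.0).astype(float)
    if key == "weight_gt80":
        return (weight.astype(float) > 80.0).astype(float)
    if key.startswith("conmed:"):
        return (con_name == key[len("conmed:"):]).astype(float)
    raise ConfigError("risk_effects", f"unknown covariate {key!r}")


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset under ``config``. Identical seeds give identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = np.array(config.drug_names(), dtype=object)
    event_names = np.array(config.event_names(), dtype=object)

    # 1. demographics (values, then missingness)
    sex_true, sex_miss = config.demographic_mix["sex"].draw(rng, n)
    age_true, age_miss = config.demographic_mix["age"].draw(rng, n)
    wt_true, wt_miss = config.demographic_mix["weight"].draw(rng, n)

    # 2. primary-suspect drug
    ps_idx = rng.integers(0, config.n_drugs, size=n)

    # 3. concomitant drug (at most one, never the PS drug)
    has_con = rng.random(n) < config.concomitant_rate
    if config.n_drugs > 1:
        raw = rng.integers(0, config.n_drugs - 1, size=n)
        con_idx = np.where(raw >= ps_idx, raw + 1, raw)
    else:
        con_idx = np.zeros(n, dtype=int)
        has_con[:] = False
    con_name = np.where(has_con, drug_names[con_idx], "")

    # 4. reporter occupation and country
    occp = rng.choice(OCCP_CODES, size=n, p=OCCP_PROBS)
    country = rng.choice(COUNTRIES, size=n, p=COUNTRY_PROBS)

    # 5. event occurrences
    rr = np.ones((config.n_drugs, config.n_events))
    drug_pos = {d: i for i, d in enumerate(drug_names)}
    event_pos = {e: j for j, e in enumerate(event_names)}
    for (d, e), ratio in config.signal_matrix.items():
        rr[drug_pos[d], event_pos[e]] = ratio
    if config.background_rate == 0.0:
        occur = np.zeros((n, config.n_events), dtype=bool)
        _ = rng.random((n, config.n_events))  # keep the draw-order contract
    else:
        with np.errstate(divide="ignore"):
            base = logit(config.background_rate) + np.log(rr)
        lp = np.zeros(n)
        for key, eff in config.risk_effects.items():
            lp += eff * _covariate_vector(key, sex_true, age_true, wt_true, con_name)
        probs = expit(base[ps_idx] + lp[:, None])
        occur = rng.random((n, config.n_events)) < probs
    any_event = occur.any(axis=1)
    first_ev = np.where(any_event, occur.argmax(axis=1), -1)

    # 6. onset latencies (days, >= 1); one draw per case to keep draw order fixed
    scale_c = np.full(n, DEFAULT_LATENCY[0])
    shape_c = np.full(n, DEFAULT_LATENCY[1])
    for (d, e), (scale, shape) in config.tto_params.items():
        m = any_event & (ps_idx == drug_pos[d]) & (first_ev == event_pos[e])
        scale_c[m] = scale
        shape_c[m] = shape
    w = rng.weibull(shape_c)
    latency = np.maximum(np.ceil(scale_c * w), 1.0).astype(int)
    latency = np.where(any_event, latency, -1)

    # 7. dates
    start = np.datetime64("2005-01-01") + rng.integers(0, 5478, size=n).astype(
        "timedelta64[D]"
    )
    event_dt = start + np.where(any_event, latency, 0).astype("timedelta64[D]")
    anchor = np.where(any_event, event_dt, start)
    fda_base = anchor + rng.integers(30, 400, size=n).astype("timedelta64[D]")

    # 8. outcomes
    outc = rng.choice(OUTCOME_CODES, size=n, p=OUTCOME_PROBS)

    # 9. duplicate versions (literal re-emissions with new PRIMARYID, higher
    #    CASEVERSION, later FDA_DT)
    dup = rng.random(n) < config.duplicate_rate
    extra = rng.integers(1, 3, size=n)  # 1 or 2 extra versions when duplicated
    n_ver = np.where(dup, 1 + extra, 1)

    case_ids = 10_000_000 + np.arange(n)
    total = int(n_ver.sum())
    case_rep = np.repeat(np.arange(n), n_ver)
    offsets = np.cumsum(n_ver) - n_ver
    version = np.arange(total) - offsets[case_rep] + 1
    caseid_rep = case_ids[case_rep]
    primaryid = caseid_rep * 100 + version
    # earlier versions are spaced 37 days apart before the final receipt date
    fda_dt = fda_base[case_rep] - ((n_ver[case_rep] - version) * 37).astype(
        "timedelta64[D]"
    )

    sex_obs = np.where(sex_miss, "", sex_true.astype(str))
    age_obs = np.where(age_miss, "", np.char.mod("%d", age_true.astype(float).astype(int)))
    wt_obs = np.where(wt_miss, "", np.char.mod("%d", wt_true.astype(float).astype(int)))

    def rep(arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr)[case_rep]

    pid_s = primaryid.astype(str)
    cid_s = caseid_rep.astype(str)

    demo = pd.DataFrame(
        {
            "PRIMARYID": pid_s,
            "CASEID": cid_s,
            "CASEVERSION": version.astype(str),
            "FDA_DT": _fmt_dates(fda_dt),
            "EVENT_DT": np.where(rep(any_event), _fmt_dates(event_dt)[case_rep], ""),
            "SEX": rep(sex_obs),
            "AGE": rep(age_obs),
            "AGE_COD": np.where(rep(age_obs) == "", "", "YR"),
            "WT": rep(wt_obs),
            "WT_COD": np.where(rep(wt_obs) == "", "", "KG"),
            "OCCP_COD": rep(occp),
            "REPORTER_COUNTRY": rep(country),
        },
        dtype=object,
    )

    # DRUG: PS row (seq 1) for every version, concomitant row (seq 2) when present
    con_rep = rep(has_con)
    drug = pd.DataFrame(
        {
            "PRIMARYID": np.concatenate([pid_s, pid_s[con_rep]]),
            "CASEID": np.concatenate([cid_s, cid_s[con_rep]]),
            "DRUG_SEQ": np.concatenate(
                [np.full(total, "1", dtype=object), np.full(con_rep.sum(), "2", dtype=object)]
            ),
            "ROLE_COD": np.concatenate(
                [np.full(total, "PS", dtype=object), np.full(con_rep.sum(), "C", dtype=object)]
            ),
            "DRUGNAME": np.concatenate(
                [drug_names[rep(ps_idx)], rep(con_name)[con_rep]]
            ),
        },
        dtype=object,
    )
    drug = drug.sort_values(
        ["PRIMARYID", "DRUG_SEQ"], kind="mergesort", key=lambda s: s.astype(int) if s.name != "ROLE_COD" else s
    ).reset_index(drop=True)

    # REAC: one row per (version, occurred event)
    counts = occur.sum(axis=1)
    ev_case, ev_idx = np.nonzero(occur)
    events_by_case = np.split(ev_idx, np.cumsum(counts)[:-1])
    rows_per_version = counts[case_rep]
    reac_pid = np.repeat(pid_s, rows_per_version)
    reac_cid = np.repeat(cid_s, rows_per_version)
    if total:
        reac_pt = np.concatenate(
            [events_by_case[c] for c in case_rep]
        ) if rows_per_version.sum() else np.array([], dtype=int)
    else:
        reac_pt = np.array([], dtype=int)
    reac = pd.DataFrame(
        {
            "PRIMARYID": reac_pid,
            "CASEID": reac_cid,
            "PT": event_names[reac_pt] if len(reac_pt) else np.array([], dtype=object),
        },
        dtype=object,
    )

    ther = pd.DataFrame(
        {
            "PRIMARYID": pid_s,
            "CASEID": cid_s,
            "DSG_DRUG_SEQ": np.full(total, "1", dtype=object),
            "START_DT": _fmt_dates(start)[case_rep],
        },
        dtype=object,
    )

    outc_df = pd.DataFrame(
        {"PRIMARYID": pid_s, "CASEID": cid_s, "OUTC_COD": rep(outc)}, dtype=object
    )

    truth_cases = pd.DataFrame(
        {
            "case_id": case_ids,
            "current_primaryid": case_ids * 100 + n_ver,
            "n_versions": n_ver,
            "ps_drug": drug_names[ps_idx],
            "concomitant": con_name,
            "sex_true": sex_true,
            "age_true": age_true.astype(float),
            "weight_true": wt_true.astype(float),
            "sex_missing": sex_miss,
            "age_missing": age_miss,
            "weight_missing": wt_miss,
            "start_date": start,
            "event_any": any_event,
            "first_event": np.where(any_event, event_names[first_ev], ""),
            "latency_days": latency,
        }
    )

    return SyntheticDataset(
        demo=demo, drug=drug, reac=reac, ther=ther, outc=outc_df,
        truth=config, truth_cases=truth_cases, event_matrix=occur,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_faers_tables(ds: SyntheticDataset, directory: Path) -> Dict[str, Path]:
    """Write the five "$"-delimited tables; the dialect has no escaping, so any
    field containing the delimiter is rejected."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in ds.tables.items():
        for col in frame.columns:
            values = frame[col].astype(str)
            if values.str.contains(DELIMITER, regex=False).any():
                raise ValueError(
                    f"table {name!r} column {col!r} contains the {DELIMITER!r} delimiter"
                )
        path = directory / TABLE_FILENAMES[name]
        frame.to_csv(path, sep=DELIMITER, index=False)
        paths[name] = path
    return paths
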