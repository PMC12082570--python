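"""Logistic risk modelling of event occurrence, nomogram scaling, and ROC/AUC.

The outcome is the target-event flag among one drug's primary-suspect reports.
Covariates are binary indicators (age <=65 vs >65 reference, weight >80 vs <=80
reference, female vs male reference, one indicator per concomitant drug). Rows
with a missing modelled covariate are dropped and counted. Univariable mode
fits one model per covariate; multivariable mode fits them jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .faers_ingest import CaseReport

Z95 = 1.959963984540054

BUILTIN_COVARIATES = ("age_le65", "weight_gt80", "female")


class SeparationError(RuntimeError):
    def __init__(self, covariate: str, detail: str = "complete separation"):
        self.covariate = covariate
        super().__init__(f"covariate {covariate!r}: {detail}")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: Optional[dict] = None):
        self.trace = trace or {}
        super().__init__(message)


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str = "binary"           # binary | categorical
    reference: str = "0"
    levels: Tuple[str, ...] = ("0", "1")


@dataclass(frozen=True)
class LogisticRiskModel:
    mode: str
    outcome: str
    covariates: Tuple[str, ...]
    params: Mapping[str, float]           # includes "const"
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    odds_ratios: Mapping[str, Tuple[float, float, float]]  # (OR, lo, hi)
    fitted: np.ndarray
    n_obs: int
    n_dropped: int
    converged: bool

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(df), self.params["const"], dtype=float)
        for cov in self.covariates:
            lp += self.params[cov] * df[cov].to_numpy(dtype=float)
        return lp

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(df))


# ---------------------------------------------------------------------------
# model frame construction
# ---------------------------------------------------------------------------

def build_model_frame(
    reports: Sequence[CaseReport],
    drug: str,
    event_flags: Mapping[str, bool],
    conmeds: Sequence[str] = (),
) -> pd.DataFrame:
    """Outcome + covariates for the drug's PS reports.

    Demographic covariates are NaN when the underlying field is unknown;
    concomitant-drug indicators come from the report's non-PS drug entries and
    are never missing.
    """
    rows = []
    con_norm = [(c, c.strip().casefold()) for c in conmeds]
    for r in reports:
        if not r.has_drug_role(drug, "PS"):
            continue
        other = {
            d.name.strip().casefold() for d in r.drugs if d.role != "PS"
        }
        row = {
            "primary_id": r.primary_id,
            "event": int(bool(event_flags.get(r.primary_id, False))),
            "age_le65": (
                np.nan if r.age_years is None else float(r.age_years <= 65.0)
            ),
            "weight_gt80": (
                np.nan if r.weight_kg is None else float(r.weight_kg > 80.0)
            ),
            "female": (
                np.nan if r.sex == "unknown" else float(r.sex == "female")
            ),
        }
        for label, norm in con_norm:
            row[f"conmed:{label}"] = float(norm in other)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_separation(sub: pd.DataFrame, covariates: Sequence[str], outcome: str) -> None:
    y = sub[outcome]
    for cov in covariates:
        x = sub[cov]
        if x.nunique() < 2:
            raise SeparationError(cov, "constant across rows")
        values = set(x.unique())
        if values <= {0.0, 1.0} and len(covariates) == 1:
            # univariable binary: any empty 2x2 cell makes the MLE diverge
            counts = pd.crosstab(x, y)
            if counts.shape != (2, 2) or (counts.to_numpy() == 0).any():
                raise SeparationError(cov)


def _fit_one(
    df: pd.DataFrame, covariates: Sequence[str], outcome: str, mode: str
) -> LogisticRiskModel:
    cols = [outcome, *covariates]
    sub = df[cols].dropna()
    n_dropped = len(df) - len(sub)
    if sub.empty:
        raise ValueError("no complete rows left after missing-covariate drop")
    _check_separation(sub, covariates, outcome)
    y = sub[outcome].to_numpy(dtype=float)
    X = sm.add_constant(sub[list(covariates)].to_numpy(dtype=float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    except PerfectSeparationError as exc:
        raise SeparationError(",".join(covariates), str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(",".join(covariates), f"singular design: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge", fit.mle_retvals)
    if np.abs(fit.params[1:]).max(initial=0.0) > 30:
        worst = covariates[int(np.argmax(np.abs(fit.params[1:])))]
        raise SeparationError(worst, "divergent coefficient")
    names = ["const", *covariates]
    params = dict(zip(names, map(float, fit.params)))
    bse = dict(zip(names, map(float, fit.bse)))
    pvalues = dict(zip(names, map(float, fit.pvalues)))
    odds = {
        cov: (
            math.exp(params[cov]),
            math.exp(params[cov] - Z95 * bse[cov]),
            math.exp(params[cov] + Z95 * bse[cov]),
        )
        for cov in covariates
    }
    return LogisticRiskModel(
        mode=mode,
        outcome=outcome,
        covariates=tuple(covariates),
        params=params,
        bse=bse,
        pvalues=pvalues,
        odds_ratios=odds,
        fitted=np.asarray(fit.predict(X)),
        n_obs=len(sub),
        n_dropped=n_dropped,
        converged=True,
    )


def fit_logistic(
    df: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "event",
    mode: str = "multivariable",
) -> Union[LogisticRiskModel, Dict[str, LogisticRiskModel]]:
    """Maximum-likelihood logistic fit(s) with Wald p-values and CIs.

    ``mode="univariable"`` returns ``{covariate: model}`` with one single-
    covariate model each; ``mode="multivariable"`` returns one joint model.
    """
    if mode == "univariable":
        return {cov: _fit_one(df, [cov], outcome, mode) for cov in covariates}
    if mode == "multivariable":
        return _fit_one(df, list(covariates), outcome, mode)
    raise ValueError(f"unknown mode {mode!r}")


def select_covariates(
    univariable: Mapping[str, LogisticRiskModel], p_threshold: float = 0.05
) -> List[str]:
    """Default screening rule: carry forward covariates with univariable
    p < threshold (configurable; pass inf to keep all)."""
    return [
        cov for cov, model in univariable.items() if model.pvalues[cov] < p_threshold
    ]


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NomogramSpec:
    """Point-scale rendering of a logistic model.

    The covariate with the largest absolute coefficient contribution spans
    exactly 100 points; total points map back to probability through the
    model's own inverse logit, so nomogram probabilities reproduce fitted
    probabilities exactly.
    """

    points: Mapping[str, Mapping[float, float]]  # covariate -> {level: points}
    unit: float        # log-odds per point
    base_lp: float     # intercept plus the per-covariate minimum contributions

    def total_points(self, row: Mapping[str, float]) -> float:
        return sum(levels[float(row[cov])] for cov, levels in self.points.items())

    def probability(self, total_points: float) -> float:
        return float(expit(self.base_lp + self.unit * total_points))

    def to_dict(self) -> dict:
        return {
            "points": {
                cov: {str(level): pts for level, pts in levels.items()}
                for cov, levels in self.points.items()
            },
            "unit": self.unit,
            "base_lp": self.base_lp,
        }


def build_nomogram(model: LogisticRiskModel) -> NomogramSpec:
    """Linear rescaling of coefficient contributions to a 0-100 point scale.

    Binary covariates only (levels 0/1), which is what the pipeline fits.
    The rescaling is scale-free: multiplying every coefficient by a constant
    leaves the point assignments unchanged.
    """
    spans = {cov: abs(model.params[cov]) for cov in model.covariates}
    max_span = max(spans.values(), default=0.0)
    if max_span == 0.0:
        raise ValueError("all coefficients are zero; nomogram scale undefined")
    unit = max_span / 100.0
    points = {}
    base_lp = model.params["const"]
    for cov in model.covariates:
        coef = model.params[cov]
        low = min(0.0, coef)
        base_lp += low
        points[cov] = {0.0: (0.0 - low) / unit, 1.0: (coef - low) / unit}
    return NomogramSpec(points=points, unit=unit, base_lp=base_lp)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based concordance probability; ties get half credit."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both outcome classes")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """(fpr, tpr, threshold) at every distinct score threshold, descending."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    last_of_threshold = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    frame = pd.DataFrame(
        {
            "threshold": s[last_of_threshold],
            "fpr": fp[last_of_threshold] / n_neg,
            "tpr": tp[last_of_threshold] / n_pos,
        }
    )
    start = pd.DataFrame({"threshold": [np.inf], "fpr": [0.0], "tpr": [0.0]})
    return pd.concat([start, frame], ignore_index=True)


def roc_auc(
    model: LogisticRiskModel, df: pd.DataFrame, outcome: str = "event"
) -> Tuple[float, pd.DataFrame]:
    """Apparent (resubstitution) AUC of the model on ``df`` plus curve points."""
    sub = df[[outcome, *model.covariates]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    scores = model.predict(sub)
    return auc_score(y, scores), roc_curve_points(y, scores)
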