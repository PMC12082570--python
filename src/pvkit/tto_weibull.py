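"""Time-to-onset extraction, summaries, and Weibull shape-parameter hazard test.

Latency is the day count from the earliest primary-suspect therapy start to
the event onset date. Only strictly positive, fully dated latencies enter the
analysis; exclusions are counted, never silently dropped. The two-parameter
Weibull is fitted by maximum likelihood (shape profiled, scale in closed
form), with Wald intervals on the log parameters from the observed
information. The fitted shape classifies the hazard: ``wear_out`` when the
shape and its whole 95% CI sit above 1, ``early`` when they sit below 1, and
``random`` otherwise. No censoring model is applied: only observed onsets are
analyzed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .faers_ingest import CaseReport

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class WeibullFitError(RuntimeError):
    """Raised when the likelihood cannot be maximized; carries the trace."""

    def __init__(self, message: str, trace: Optional[list] = None):
        self.trace = trace or []
        super().__init__(message)


@dataclass(frozen=True)
class TTOSample:
    values: Tuple[float, ...]
    n_excluded_missing: int = 0
    n_excluded_nonpositive: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.values):
            raise ValueError("TTO values must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WeibullFit:
    alpha: float          # scale, days
    beta: float           # shape
    alpha_ci95: Tuple[float, float]
    beta_ci95: Tuple[float, float]
    failure_type: str     # early / random / wear_out
    median: float
    iqr: Tuple[float, float]
    n: int
    loglik: float


def compute_tto(reports: Sequence[CaseReport], drug: str) -> TTOSample:
    """Per-report latency in days: event date minus the earliest PS start date.

    Reports missing either date are counted in ``n_excluded_missing``;
    non-positive differences in ``n_excluded_nonpositive``.
    """
    values = []
    n_missing = 0
    n_nonpositive = 0
    for r in reports:
        start = r.ps_start_date(drug)
        if start is None or r.event_date is None:
            n_missing += 1
            continue
        days = (r.event_date - start).days
        if days <= 0:
            n_nonpositive += 1
            continue
        values.append(float(days))
    return TTOSample(tuple(values), n_missing, n_nonpositive)


def summarize_tto(s: TTOSample) -> dict:
    """Median and quartiles (linear interpolation), plus min and max."""
    if s.n == 0:
        raise ValueError("cannot summarize an empty TTO sample")
    x = np.asarray(s.values)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return {
        "n": s.n,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(x.min()),
        "max": float(x.max()),
    }


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def weibull_loglik(x: np.ndarray, alpha: float, beta: float) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    return float(
        n * math.log(beta)
        - n * beta * math.log(alpha)
        + (beta - 1) * np.log(x).sum()
        - ((x / alpha) ** beta).sum()
    )


def _profile_score(beta: float, x: np.ndarray, log_x: np.ndarray) -> float:
    """d/d(beta) of the profile log-likelihood (scale solved in closed form)."""
    xb = x ** beta
    return 1.0 / beta + log_x.mean() - (xb * log_x).sum() / xb.sum()


def _alpha_hat(beta: float, x: np.ndarray) -> float:
    return float(np.mean(x ** beta) ** (1.0 / beta))


def fit_weibull(s: TTOSample, min_n: int = 30) -> WeibullFit:
    """MLE of the uncensored two-parameter Weibull, deterministic per sample.

    Initialization is the moment estimate on the log scale (Gumbel variance
    identity); the shape score equation is then bracketed and solved by Brent's
    method. 95% CIs are Wald intervals on (log alpha, log beta) using a
    finite-difference observed information matrix.
    """
    x = np.asarray(s.values, dtype=float)
    n = len(x)
    if n < 2:
        raise WeibullFitError(f"need at least 2 observations, got {n}")
    if n < min_n:
        warnings.warn(
            f"Weibull fit on n={n} < {min_n} observations; intervals are unreliable",
            UserWarning,
            stacklevel=2,
        )
    log_x = np.log(x)
    sd_log = log_x.std(ddof=1)
    if sd_log == 0:
        raise WeibullFitError("degenerate sample: all values identical")

    beta0 = math.pi / (math.sqrt(6.0) * sd_log)
    trace = [("init", beta0)]
    lo, hi = beta0, beta0
    for _ in range(80):
        if _profile_score(lo, x, log_x) > 0:
            break
        lo /= 2.0
        trace.append(("bracket_lo", lo))
    else:
        raise WeibullFitError("could not bracket the shape score from below", trace)
    for _ in range(80):
        if _profile_score(hi, x, log_x) < 0:
            break
        hi *= 2.0
        trace.append(("bracket_hi", hi))
    else:
        raise WeibullFitError("could not bracket the shape score from above", trace)

    beta = float(optimize.brentq(_profile_score, lo, hi, args=(x, log_x), xtol=1e-12))
    alpha = _alpha_hat(beta, x)
    ll = weibull_loglik(x, alpha, beta)

    # observed information on (u, v) = (log alpha, log beta)
    u, v = math.log(alpha), math.log(beta)

    def nll(theta):
        return -weibull_loglik(x, math.exp(theta[0]), math.exp(theta[1]))

    h = 1e-5
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            t = np.array([u, v])
            tpp = t.copy(); tpp[i] += h; tpp[j] += h
            tpm = t.copy(); tpm[i] += h; tpm[j] -= h
            tmp = t.copy(); tmp[i] -= h; tmp[j] += h
            tmm = t.copy(); tmm[i] -= h; tmm[j] -= h
            hess[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise WeibullFitError(f"singular observed information: {exc}", trace) from exc
    se_u, se_v = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
    alpha_ci = (math.exp(u - Z95 * se_u), math.exp(u + Z95 * se_u))
    beta_ci = (math.exp(v - Z95 * se_v), math.exp(v + Z95 * se_v))

    summary = summarize_tto(s)
    return WeibullFit(
        alpha=alpha,
        beta=beta,
        alpha_ci95=alpha_ci,
        beta_ci95=beta_ci,
        failure_type=classify_shape(beta, beta_ci),
        median=summary["median"],
        iqr=(summary["q1"], summary["q3"]),
        n=n,
        loglik=ll,
    )


def classify_shape(beta: float, beta_ci95: Tuple[float, float]) -> str:
    """Hazard regime from the shape estimate and its 95% CI."""
    lo, hi = beta_ci95
    if beta > 1.0 and lo > 1.0:
        return "wear_out"
    if beta < 1.0 and hi < 1.0:
        return "early"
    return "random"


def classify_failure(fit: WeibullFit) -> str:
    return classify_shape(fit.beta, fit.beta_ci95)
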