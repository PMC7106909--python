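"""Evaluation of burden metrics as predictors of immunotherapy response and survival.

Response is assessed by ROC/AUC (the AUC equals the Mann-Whitney probability
that a responder outranks a non-responder, ties counted half) and by
logistic regression of response on log2 burden (pseudocount 1), optionally
with an aCTLA4-vs-aPD1 therapy indicator; fitted response probabilities are
reported at the cohort's 25th and 75th burden percentiles, marginalized over
the observed therapy mix.  P values across metrics are Benjamini-Hochberg
adjusted.  Survival is assessed by stratifying patients at the
disease-matched 80th percentile (high = strictly exceeds), Cox proportional
hazards (Efron ties), Kaplan-Meier curves with at-risk tables, and sweeps of
the percentile threshold.  Classification concordance quantifies how often
two metrics disagree on a patient's high/low label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy.special import expit
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

HIGH_LOW_PERCENTILE = 80.0
PSEUDOCOUNT = 1.0


@dataclass
class PatientRecord:
    """Clinical/outcome container for one patient."""

    patient_id: str
    cancer_type: str
    therapy: str = "none"  # aPD1 | aCTLA4 | combination | none
    response: bool | None = None
    os_time: float | None = None  # days
    os_event: bool | None = None
    hla_alleles: frozenset = frozenset()
    has_rna: bool = False

    def __post_init__(self) -> None:
        if self.therapy not in {"aPD1", "aCTLA4", "combination", "none"}:
            raise ValueError(f"invalid therapy {self.therapy!r}")
        if self.os_time is not None and self.os_time <= 0:
            raise ValueError("os_time must be > 0 when present")


@dataclass
class RocResult:
    metric: str
    cohort: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class LogisticFit:
    cohort: str
    predictor: str
    intercept: float
    slope: float  # per log2 unit of burden
    therapy_offset: float | None
    p_value: float
    response_prob_q25: float
    response_prob_q75: float
    n: int
    p_adjusted: float | None = None
    separation_flag: bool = False
    slope_se: float = float("nan")

    def slope_ci(self, z: float = 1.959963984540054) -> tuple[float, float]:
        """Wald confidence interval for the burden slope."""
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se

    @property
    def odds_increase_pct(self) -> float:
        """Percent increase in odds of response per log2 fold change in burden."""
        return (np.exp(self.slope) - 1.0) * 100.0


@dataclass
class SurvivalFit:
    cohort: str
    stratifier: str
    percentile: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_high: int
    n_low: int
    km_curves: dict = field(default_factory=dict)
    at_risk: dict = field(default_factory=dict)
    flagged: bool = False


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    metric: str = "",
    cohort: str = "",
) -> RocResult:
    """ROC curve from a threshold sweep; AUC as trapezoidal area under it.

    The trapezoidal AUC is numerically identical to the Mann-Whitney pair
    statistic P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both responder and non-responder labels are required")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(metric=metric, cohort=cohort, auc=auc, fpr=fpr, tpr=tpr)


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the rank-sum identity; used as a cross-check of the curve area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    from scipy.stats import rankdata

    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _log_burden(burden: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    if np.any(burden < 0):
        raise ValueError("burdens must be >= 0")
    return np.log2(burden + pseudocount)


def fit_response_model(
    burden: Sequence[float],
    response: Sequence[int],
    therapy: Sequence[str] | None = None,
    cohort: str = "",
    predictor: str = "",
    pseudocount: float = PSEUDOCOUNT,
) -> LogisticFit:
    """Logistic regression of response on log2(burden + 1).

    When ``therapy`` is supplied, an aCTLA4-vs-aPD1 indicator enters the
    model (combination therapy is excluded upstream).  Fitted response
    probabilities at the cohort's 25th/75th burden percentiles are averaged
    over the observed therapy mix.  Perfect separation is flagged rather than
    left to diverge silently.
    """
    burden = np.asarray(burden, dtype=float)
    response = np.asarray(response, dtype=int)
    if burden.shape != response.shape:
        raise ValueError("burden and response must have equal length")
    n = len(burden)
    if n < 10:
        raise ValueError(f"need n >= 10 patients, got {n}")
    x = _log_burden(burden, pseudocount)
    cols = {"log2_burden": x}
    if therapy is not None:
        th = np.asarray(therapy)
        if not set(np.unique(th)) <= {"aPD1", "aCTLA4"}:
            raise ValueError("therapy must be aPD1 or aCTLA4 (combination excluded)")
        cols["aCTLA4"] = (th == "aCTLA4").astype(float)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(response, X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
            res = sm.Logit(response, X).fit_regularized(alpha=1e-6, disp=0)
    params = np.asarray(res.params, dtype=float)
    intercept, slope = params[0], params[1]
    offset = params[2] if therapy is not None else None
    try:
        p_slope = float(np.asarray(res.pvalues)[1])
        se_slope = float(np.asarray(res.bse)[1])
    except Exception:  # regularized fits lack Wald p values
        p_slope = float("nan")
        se_slope = float("nan")
    q25, q75 = np.percentile(burden, [25, 75])

    def prob_at(b: float) -> float:
        eta = intercept + slope * np.log2(b + pseudocount)
        if therapy is None:
            return float(expit(eta))
        frac_ctla4 = float(cols["aCTLA4"].mean())
        return float(
            (1 - frac_ctla4) * expit(eta) + frac_ctla4 * expit(eta + offset)
        )

    return LogisticFit(
        cohort=cohort,
        predictor=predictor,
        intercept=float(intercept),
        slope=float(slope),
        therapy_offset=None if offset is None else float(offset),
        p_value=p_slope,
        response_prob_q25=prob_at(q25),
        response_prob_q75=prob_at(q75),
        n=n,
        separation_flag=separation,
        slope_se=se_slope,
    )


def wald_ci(fit_result, index: int = 1, alpha: float = 0.05) -> tuple[float, float]:
    """Wald confidence interval for one coefficient of a statsmodels fit."""
    ci = np.asarray(fit_result.conf_int(alpha))
    return float(ci[index, 0]), float(ci[index, 1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_high_low(
    burdens: Sequence[float],
    percentile: float = HIGH_LOW_PERCENTILE,
) -> np.ndarray:
    """High/low labels by strict exceedance of the cohort percentile.

    The percentile uses linear interpolation between order statistics
    (type-7); a patient is "high" iff burden strictly exceeds it, so with all
    burdens equal nobody is high.
    """
    burdens = np.asarray(burdens, dtype=float)
    if burdens.size == 0:
        raise ValueError("empty cohort")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    cut = np.percentile(burdens, percentile)
    return (burdens > cut).astype(int)


def classification_concordance(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    percentile_grid: Sequence[float],
) -> dict[float, float]:
    """Fraction of patients labeled incongruously high/low by two metrics."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metrics must cover the same patients")
    out: dict[float, float] = {}
    for pct in percentile_grid:
        la = classify_high_low(a, pct)
        lb = classify_high_low(b, pct)
        out[float(pct)] = float(np.mean(la != lb))
    return out


def fit_survival(
    records: Sequence[PatientRecord],
    high_low: Sequence[int],
    cohort: str = "",
    stratifier: str = "",
    percentile: float = HIGH_LOW_PERCENTILE,
    horizon_days: float | None = None,
) -> SurvivalFit:
    """Cox PH hazard ratio (high vs low) plus Kaplan-Meier curves.

    Right-censoring is honored; ``horizon_days`` applies additional
    administrative censoring.  Strata without any event yield a flagged fit
    with an undefined hazard ratio.
    """
    high = np.asarray(high_low, dtype=int)
    if len(records) != len(high):
        raise ValueError("records and high_low must have equal length")
    rows = [
        (r.os_time, bool(r.os_event), h)
        for r, h in zip(records, high)
        if r.os_time is not None and r.os_event is not None
    ]
    df = pd.DataFrame(rows, columns=["time", "event", "high"])
    if horizon_days is not None:
        over = df["time"] > horizon_days
        df.loc[over, "time"] = horizon_days
        df.loc[over, "event"] = False
    n_high = int((df["high"] == 1).sum())
    n_low = int((df["high"] == 0).sum())
    events_by = df.groupby("high")["event"].sum() if len(df) else pd.Series(dtype=int)
    km_curves: dict = {}
    at_risk: dict = {}
    for label, sub in df.groupby("high"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label="high" if label else "low")
        name = "high" if label else "low"
        km_curves[name] = kmf.survival_function_
        at_risk[name] = kmf.event_table["at_risk"]
    flagged = (
        n_high == 0
        or n_low == 0
        or 0 not in events_by.index
        or 1 not in events_by.index
        or events_by.min() == 0
    )
    hr = ci_lo = ci_hi = p = float("nan")
    if not flagged:
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            summ = cph.summary.loc["high"]
            hr = float(np.exp(summ["coef"]))
            ci_lo = float(np.exp(summ["coef lower 95%"]))
            ci_hi = float(np.exp(summ["coef upper 95%"]))
            p = float(summ["p"])
        except ConvergenceError:
            flagged = True
    return SurvivalFit(
        cohort=cohort,
        stratifier=stratifier,
        percentile=percentile,
        hazard_ratio=hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_value=p,
        n_high=n_high,
        n_low=n_low,
        km_curves=km_curves,
        at_risk=at_risk,
        flagged=flagged,
    )


def threshold_sweep(
    records: Sequence[PatientRecord],
    burdens: Sequence[float],
    percentile_grid: Sequence[float],
    cohort: str = "",
    stratifier: str = "",
) -> pd.DataFrame:
    """fit_survival at each percentile of the grid; failed points are flagged."""
    burdens = np.asarray(burdens, dtype=float)
    rows = []
    for pct in percentile_grid:
        if not 0 < pct < 100:
            raise ValueError("percentile grid must lie within (0, 100)")
        labels = classify_high_low(burdens, pct)
        fit = fit_survival(
            records, labels, cohort=cohort, stratifier=stratifier, percentile=pct
        )
        rows.append(
            {
                "percentile": float(pct),
                "hazard_ratio": fit.hazard_ratio,
                "p_value": fit.p_value,
                "n_high": fit.n_high,
                "flagged": fit.flagged,
            }
        )
    return pd.DataFrame(rows)
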