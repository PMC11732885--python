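"""Dose-efficacy and dose-toxicity statistics.

Covers the analysis battery applied to the cohort table: objective response
rate with a Wilson score interval, tumor-control / normal-tissue-complication
probability curves as logistic regressions of a binary outcome on absorbed
dose (effects reported per 100 Gy), a Cox proportional-hazards dose effect on
overall survival (Efron tie handling), Kaplan–Meier survival with median and
log-log confidence band, and a two-step multivariable logistic selection that
keeps the dose term fixed and screens then backward-eliminates covariates at
the 10% two-sided level.

Logistic models are fitted with statsmodels; Cox and Kaplan–Meier with
lifelines.  Dose enters every model in Gy; per-100-Gy odds and hazard ratios
are exp(100 * slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "LogisticFit",
    "CoxFit",
    "KMEstimate",
    "SelectionResult",
    "SeparationError",
    "orr_with_ci",
    "fit_dose_response_logistic",
    "fit_cox_tad",
    "km_curve",
    "multivariable_select",
]

_Z95 = norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Raised when a logistic outcome is perfectly separated by the predictor."""


@dataclass
class LogisticFit:
    """Logistic dose-response fit with the per-100-Gy odds ratio."""

    intercept: float
    slope_per_gy: float
    or_per_100gy: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_dropped_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "or_per_100gy": self.or_per_100gy,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "slope_per_gy": self.slope_per_gy,
            "intercept": self.intercept,
            "n": self.n,
        }


@dataclass
class CoxFit:
    """Cox proportional-hazards dose effect with the per-100-Gy hazard ratio."""

    slope_per_gy: float
    hr_per_100gy: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hr_per_100gy": self.hr_per_100gy,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "n": self.n,
            "n_events": self.n_events,
        }


@dataclass
class KMEstimate:
    """Kaplan–Meier product-limit estimate with median survival."""

    times: np.ndarray
    survival: np.ndarray
    median_months: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return self.median_months is not None

    def to_dict(self) -> dict:
        return {
            "median_months": self.median_months,
            "median_ci95": list(self.median_ci),
            "n": self.n,
            "n_events": self.n_events,
        }


def orr_with_ci(responders: int, n: int) -> tuple[float, tuple[float, float]]:
    """Objective response rate in % with its 95% Wilson score interval.

    Returns ``(rate, (low, high))``, each rounded to 0.1 percentage points.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= responders <= n):
        raise ValueError("responders must lie in [0, n]")
    low, high = proportion_confint(responders, n, alpha=0.05, method="wilson")
    rate = 100.0 * responders / n
    return round(rate, 1), (round(100.0 * low, 1), round(100.0 * high, 1))


def _clean(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    clean = sub.dropna()
    return clean, len(sub) - len(clean)


def fit_dose_response_logistic(
    cohort: pd.DataFrame, dose_col: str, outcome_col: str
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on dose (Gy).

    Serves both the TCP curve (response vs tumor dose) and the NTCP curve
    (toxicity vs normal-tissue dose).  Missing rows are dropped listwise and
    counted.  Perfect separation raises :class:`SeparationError` instead of
    returning a silently divergent estimate.
    """
    data, n_dropped = _clean(cohort, [dose_col, outcome_col])
    y = data[outcome_col].to_numpy()
    x = data[dose_col].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct dose values")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, RuntimeWarning) as exc:
        raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        raise SeparationError("separation detected: unbounded slope estimate")

    slope = float(res.params[1])
    se = float(res.bse[1])
    return LogisticFit(
        intercept=float(res.params[0]),
        slope_per_gy=slope,
        or_per_100gy=float(np.exp(100.0 * slope)),
        ci_low=float(np.exp(100.0 * (slope - _Z95 * se))),
        ci_high=float(np.exp(100.0 * (slope + _Z95 * se))),
        p_value=float(res.pvalues[1]),
        n=len(data),
        n_dropped_missing=n_dropped,
    )


def fit_cox_tad(
    cohort: pd.DataFrame,
    dose_col: str,
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> CoxFit:
    """Cox PH regression of overall survival on dose (Gy), Efron ties."""
    data, _ = _clean(cohort, [dose_col, time_col, event_col])
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("Cox regression needs at least one event")
    if data[dose_col].nunique() < 2:
        raise ValueError("dose must vary")

    flags: list[str] = []
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(data, duration_col=time_col, event_col=event_col)
        for w in caught:
            if "convergence" in str(w.message).lower() or "monoton" in str(
                w.message
            ).lower():
                flags.append(str(w.message))

    slope = float(cph.params_[dose_col])
    se = float(cph.standard_errors_[dose_col])
    if not np.isfinite(se) or se > 1e4:
        flags.append("monotone likelihood suspected: unbounded standard error")
    return CoxFit(
        slope_per_gy=slope,
        hr_per_100gy=float(np.exp(100.0 * slope)),
        ci_low=float(np.exp(100.0 * (slope - _Z95 * se))),
        ci_high=float(np.exp(100.0 * (slope + _Z95 * se))),
        p_value=float(cph.summary.loc[dose_col, "p"]),
        n=len(data),
        n_events=n_events,
        flags=flags,
    )


def km_curve(
    cohort: pd.DataFrame, time_col: str = "os_months", event_col: str = "os_event"
) -> KMEstimate:
    """Kaplan–Meier survival curve with median and its 95% CI (log-log).

    The median is the earliest time at which the survival estimate drops to
    0.5 or below; if the curve never reaches 0.5 the median is not reached
    and reported as ``None``.
    """
    data, _ = _clean(cohort, [time_col, event_col])
    if len(data) == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(data[time_col], event_observed=data[event_col])

    def _finite(v: float) -> float | None:
        return float(v) if np.isfinite(v) else None

    med = _finite(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = (_finite(v) for v in np.asarray(ci_df).ravel())
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median_months=med,
        median_ci=(lo, hi),
        n=len(data),
        n_events=int(data[event_col].sum()),
    )


# ---------------------------------------------------------------------------
# Two-step multivariable selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Final multivariable logistic model plus the full audit trail."""

    forced_term: str
    selected: list[str]
    final_params: dict[str, float]
    final_pvalues: dict[str, float]
    trail: list[dict]
    n: int


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
            disp=0, maxiter=200
        )


def multivariable_select(
    cohort: pd.DataFrame,
    outcome: str = "tox_grade3plus",
    forced: str = "ntad_perfused_gy",
    candidates: list[str] | None = None,
    enter_p: float = 0.1,
    stay_p: float = 0.1,
) -> SelectionResult:
    """Two-step covariate selection around a forced dose term.

    Step 1 fits each candidate one at a time alongside the forced term;
    candidates with two-sided p < ``enter_p`` advance.  Step 2 starts from
    all advancing candidates and backward-eliminates the worst remaining
    candidate until every one has p < ``stay_p``.  The forced term is never
    removed.  Candidates whose model cannot be estimated (separation,
    collinearity) are dropped with a logged reason; a rank-deficient step-2
    design drops the offending candidate with a warning.
    """
    candidates = list(candidates or [])
    cols = [outcome, forced] + candidates
    data, n_dropped = _clean(cohort, cols)
    y = data[outcome].to_numpy()
    trail: list[dict] = []
    if n_dropped:
        trail.append({"step": 0, "action": "dropped_missing", "n": n_dropped})

    advancing: list[str] = []
    for cand in candidates:
        try:
            res = _fit_logit(y, data[[forced, cand]])
            p = float(res.pvalues[cand])
        except Exception as exc:  # non-estimable: log and skip
            trail.append(
                {"step": 1, "candidate": cand, "action": "dropped_error", "reason": str(exc)}
            )
            continue
        if np.isfinite(p) and p < enter_p:
            advancing.append(cand)
            trail.append({"step": 1, "candidate": cand, "action": "entered", "p": p})
        else:
            trail.append({"step": 1, "candidate": cand, "action": "screened_out", "p": p})

    # Guard against collinear step-2 designs: keep candidates only while the
    # design matrix stays full rank.
    kept: list[str] = []
    base = np.column_stack([np.ones(len(data)), data[forced].to_numpy(dtype=float)])
    for cand in advancing:
        trial = np.column_stack([base] + [data[c].to_numpy(dtype=float) for c in kept + [cand]])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(
                f"candidate {cand!r} is collinear with the current model; dropped",
                stacklevel=2,
            )
            trail.append({"step": 2, "candidate": cand, "action": "dropped_collinear"})
        else:
            kept.append(cand)

    while True:
        res = _fit_logit(y, data[[forced] + kept])
        if not kept:
            break
        pvals = {c: float(res.pvalues[c]) for c in kept}
        worst = max(pvals, key=lambda c: (not np.isfinite(pvals[c]), pvals[c]))
        worst_p = pvals[worst]
        if not np.isfinite(worst_p) or worst_p >= stay_p:
            kept.remove(worst)
            trail.append({"step": 2, "candidate": worst, "action": "removed", "p": worst_p})
        else:
            break

    res = _fit_logit(y, data[[forced] + kept])
    params = {k: float(v) for k, v in res.params.items()}
    pvalues = {k: float(v) for k, v in res.pvalues.items()}
    trail.append({"step": 2, "action": "final", "terms": [forced] + kept})
    return SelectionResult(
        forced_term=forced,
        selected=kept,
        final_params=params,
        final_pvalues=pvalues,
        trail=trail,
        n=len(data),
    )
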