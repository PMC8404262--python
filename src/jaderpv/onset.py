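"""Time-to-onset profiling of adverse events with the Weibull shape parameter.

For each (report, drug-in-class) combination with a complete start date and
adverse-event onset date, the onset time is ``t = onset − first start`` in
days, restricted to a 0–90-day window after therapy initiation. Onset-day
samples per ATC class and administration route are summarized by median and
interquartile range and fitted with a two-parameter Weibull distribution by
maximum likelihood:

    f(t) = (β/α) (t/α)^{β−1} exp(−(t/α)^β),   α, β > 0

α (scale, days) measures the spread of the distribution; β (shape, the
Weibull shape parameter, WSP) classifies the hazard over time using the 95%
CI of β: upper bound < 1 → decreasing hazard ("initial failure"); lower
bound > 1 → increasing hazard ("wear-out failure"); CI containing 1 →
constant hazard ("random failure").

Same-day onsets (t = 0) are outside the Weibull support; by default half a
day is added to every onset time for fitting only (medians and IQRs use the
raw integer day differences). Alternatives: drop day-0 events, or add a full
day. Only complete, in-window events enter the likelihood — no censoring
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

from .io import CaseDatabase
from .terms import AtcMap, aki_pt_set

__all__ = [
    "HazardClass",
    "OnsetObservation",
    "WeibullFit",
    "extract_onsets",
    "median_iqr",
    "weibull_mle",
    "hazard_class",
    "onset_histogram",
    "onset_profile_table",
]

Z_95 = 1.96
ZERO_POLICIES = ("shift0.5", "exclude", "add1")


class HazardClass(str, Enum):
    initial_failure = "initial_failure"  # beta CI entirely below 1
    random_failure = "random_failure"  # beta CI contains 1
    wearout_failure = "wearout_failure"  # beta CI entirely above 1
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class OnsetObservation:
    case_id: str
    atc_class: str
    route: str
    t: float  # days, raw difference within the analysis window


class WeibullFitError(RuntimeError):
    """Maximum-likelihood fit failed (degenerate data or non-convergence)."""


@dataclass
class WeibullFit:
    """MLE of the Weibull scale/shape with Wald CIs on the log scale."""

    alpha: float
    alpha_ci: tuple[float, float]
    beta: float
    beta_ci: tuple[float, float]
    n: int
    median: float
    q1: float
    q3: float
    hazard: HazardClass
    loglik: float


def _apply_zero_policy(t_raw: np.ndarray, zero_policy: str) -> np.ndarray:
    if zero_policy == "shift0.5":
        return t_raw + 0.5
    if zero_policy == "add1":
        return t_raw + 1.0
    if zero_policy == "exclude":
        return t_raw[t_raw > 0].astype(float)
    raise ValueError(f"unknown zero policy {zero_policy!r}; choose from {ZERO_POLICIES}")


def extract_onsets(
    db: CaseDatabase,
    atc_class: str | None = None,
    route: str | None = None,
    window_days: int = 90,
    atc_map: AtcMap | None = None,
    outcome_pt_codes: frozenset[int] | None = None,
) -> list[OnsetObservation]:
    """Onset-day observations for drugs of one ATC class (or all classes).

    One observation per (report, drug-in-class) pair with both dates
    complete, using the earliest start date per drug on the report and the
    earliest outcome onset date on the report. Differences outside
    ``[0, window_days]`` (including negative differences, i.e. onset before
    start) are excluded.
    """
    atc_map = atc_map or AtcMap.bundled()
    if outcome_pt_codes is None:
        outcome_pt_codes = aki_pt_set().codes
    reac = db.reac
    hit = reac["pt_code"].notna() & reac["pt_code"].astype("Int64").isin(
        list(outcome_pt_codes)
    ) & reac["onset_date"].notna()
    onset_by_case = reac[hit].groupby("case_id")["onset_date"].min()

    drug = atc_map.drug_annotations(db)
    drug = drug[drug["canonical_name"].notna() & drug["start_date"].notna()]
    if atc_class is None:
        # pooled ("Total") extraction covers anti-infectives only
        drug = drug[drug["is_anti_infective"]]
    if atc_class is not None:
        members = {
            name
            for name in drug["canonical_name"].unique()
            if atc_class in atc_map.classes_of(name)
        }
        drug = drug[drug["canonical_name"].isin(members)]
    if route is not None:
        drug = drug[drug["route"] == route]
    if len(drug) == 0:
        return []
    starts = drug.groupby(["case_id", "canonical_name", "route"])["start_date"].min().reset_index()
    starts = starts[starts["case_id"].isin(onset_by_case.index)]
    observations: list[OnsetObservation] = []
    for row in starts.itertuples():
        t = (onset_by_case[row.case_id] - row.start_date).days
        if 0 <= t <= window_days:
            observations.append(
                OnsetObservation(
                    case_id=row.case_id,
                    atc_class=atc_class or "|".join(sorted(atc_map.classes_of(row.canonical_name))),
                    route=row.route,
                    t=float(t),
                )
            )
    return observations


def median_iqr(t_values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quantiles."""
    t = np.asarray(t_values, dtype=float)
    if t.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _neg_loglik(theta: np.ndarray, t: np.ndarray) -> float:
    log_a, log_b = theta
    a, b = math.exp(log_a), math.exp(log_b)
    z = t / a
    return -float(np.sum(np.log(b / a) + (b - 1) * np.log(z) - z**b))


def weibull_mle(
    t_values,
    zero_policy: str = "shift0.5",
    min_n: int = 10,
) -> WeibullFit:
    """Fit Weibull(α, β) to uncensored onset times by maximum likelihood.

    CIs are Wald intervals from the observed information matrix on the
    (log α, log β) scale, exponentiated back. Raises
    :class:`WeibullFitError` below ``min_n`` usable observations or when all
    values are identical (the shape diverges).
    """
    t_raw = np.asarray(t_values, dtype=float)
    if np.any(~np.isfinite(t_raw)) or np.any(t_raw < 0):
        raise ValueError("onset times must be finite and non-negative")
    med, q1, q3 = median_iqr(t_raw) if t_raw.size else (math.nan,) * 3
    t = _apply_zero_policy(t_raw, zero_policy)
    if t.size < min_n:
        raise WeibullFitError(f"need at least {min_n} observations, got {t.size}")
    if np.ptp(t) == 0:
        raise WeibullFitError("all onset times identical; shape parameter diverges")

    theta0 = np.array([math.log(float(np.mean(t))), 0.0])
    res = optimize.minimize(
        _neg_loglik, theta0, args=(t,), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    res = optimize.minimize(
        _neg_loglik, res.x, args=(t,), method="BFGS", options={"gtol": 1e-10}
    )
    if not np.all(np.isfinite(res.x)):
        raise WeibullFitError(f"optimizer failed: {res.message}")
    hess = approx_hess1(res.x, _neg_loglik, args=(t,))
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise WeibullFitError("singular observed information matrix") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    log_a, log_b = res.x
    alpha, beta = math.exp(log_a), math.exp(log_b)
    alpha_ci = (math.exp(log_a - Z_95 * se[0]), math.exp(log_a + Z_95 * se[0]))
    beta_ci = (math.exp(log_b - Z_95 * se[1]), math.exp(log_b + Z_95 * se[1]))
    fit = WeibullFit(
        alpha=alpha,
        alpha_ci=alpha_ci,
        beta=beta,
        beta_ci=beta_ci,
        n=int(t.size),
        median=med,
        q1=q1,
        q3=q3,
        hazard=HazardClass.indeterminate,
        loglik=-res.fun,
    )
    fit.hazard = hazard_class(fit)
    return fit


def hazard_class(fit: WeibullFit) -> HazardClass:
    """Classify the hazard profile from the 95% CI of the shape parameter."""
    lo, hi = fit.beta_ci
    if not (math.isfinite(lo) and math.isfinite(hi)):
        return HazardClass.indeterminate
    if lo > 1.0:
        return HazardClass.wearout_failure
    if hi < 1.0:
        return HazardClass.initial_failure
    return HazardClass.random_failure


def classify_beta_ci(beta_lo: float, beta_hi: float) -> HazardClass:
    """Hazard class straight from a published β confidence interval."""
    if beta_lo > 1.0:
        return HazardClass.wearout_failure
    if beta_hi < 1.0:
        return HazardClass.initial_failure
    return HazardClass.random_failure


def onset_histogram(observations, window_days: int = 90) -> pd.Series:
    """Counts of onsets per integer day 0..window; total equals sample size."""
    days = [int(obs.t) for obs in observations]
    counts = pd.Series(0, index=pd.RangeIndex(0, window_days + 1, name="day"))
    for day in days:
        if 0 <= day <= window_days:
            counts[day] += 1
    return counts


def onset_profile_table(
    db: CaseDatabase,
    atc_classes=None,
    routes=("po", "iv"),
    window_days: int = 90,
    zero_policy: str = "shift0.5",
    min_n: int = 10,
    atc_map: AtcMap | None = None,
) -> pd.DataFrame:
    """Median/IQR and Weibull parameters per (ATC class, route).

    Cells below ``min_n`` observations report the median summary only (the
    Weibull columns stay empty) — small samples do not support a stable
    shape estimate.
    """
    atc_map = atc_map or AtcMap.bundled()
    if atc_classes is None:
        atc_classes = atc_map.anti_infective_classes()
    rows = []
    for code in list(atc_classes) + [None]:
        for route in routes:
            obs = extract_onsets(db, code, route, window_days, atc_map)
            label = code or "Total"
            if not obs:
                continue
            t = np.array([o.t for o in obs])
            med, q1, q3 = median_iqr(t)
            row = {
                "atc_class": label,
                "route": route,
                "n": len(t),
                "median": med,
                "q1": q1,
                "q3": q3,
                "alpha": math.nan,
                "alpha_lo": math.nan,
                "alpha_hi": math.nan,
                "beta": math.nan,
                "beta_lo": math.nan,
                "beta_hi": math.nan,
                "hazard": "",
            }
            if len(t) >= min_n and np.ptp(_apply_zero_policy(t, zero_policy)) > 0:
                fit = weibull_mle(t, zero_policy=zero_policy, min_n=min_n)
                row.update(
                    alpha=fit.alpha,
                    alpha_lo=fit.alpha_ci[0],
                    alpha_hi=fit.alpha_ci[1],
                    beta=fit.beta,
                    beta_lo=fit.beta_ci[0],
                    beta_hi=fit.beta_ci[1],
                    hazard=fit.hazard.value,
                )
            rows.append(row)
    return pd.DataFrame(rows)
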