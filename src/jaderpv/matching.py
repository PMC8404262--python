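"""Propensity-score caliper matching of anti-infective mono- vs combination therapy.

The treatment of interest is combination therapy (≥ 2 distinct anti-infectives
on a report) versus monotherapy (exactly 1). A logistic regression of
treatment on age, body weight, height (decade / 10-unit band midpoints used as
continuous covariates) and sepsis yields the propensity score (PS). Treated
reports are then matched 1:1 without replacement to the nearest control on the
logit of the PS, within a caliper of 0.2 × SD of the pooled logit-PS
distribution. Covariate balance is assessed with the standardized mean
difference (SMD); values below 0.1 are conventionally adequate.

Sex is deliberately excluded from the PS model but always reported in the
balance table. Reports with any unknown model covariate are excluded
(complete-case analysis); the exclusion count is recorded on the result.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import CaseDatabase
from .ror import RORResult, ContingencyTable, crude_ror
from .terms import AtcMap, aki_case_ids, anti_infective_counts, sepsis_case_ids

__all__ = [
    "band_midpoint",
    "build_covariates",
    "PSModel",
    "fit_ps_model",
    "MatchResult",
    "greedy_caliper_match",
    "smd",
    "balance_table",
    "adjusted_ror",
    "match_therapy_arms",
]

PS_COVARIATES = ("age", "weight", "height", "sepsis")
BALANCE_COVARIATES = ("age", "weight", "height", "sepsis", "male")

_RANGE = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_GE = re.compile(r"^>=\s*(\d+)$")


def band_midpoint(band: str) -> float:
    """Midpoint of a 10-unit bin label ("0-9" → 5, "150-159" → 155, ">=100" → 105).

    Unknown or malformed labels map to NaN.
    """
    if not isinstance(band, str):
        return math.nan
    band = band.strip()
    m = _RANGE.match(band)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        return (lo + hi + 1) / 2
    m = _GE.match(band)
    if m:
        return int(m.group(1)) + 5.0
    return math.nan


def build_covariates(
    db: CaseDatabase, atc_map: AtcMap | None = None
) -> tuple[pd.DataFrame, int]:
    """Per-report covariate frame for the two therapy arms.

    Returns ``(frame, n_excluded)``. The frame is indexed by case_id and
    restricted to reports with 1 (control) or ≥ 2 (treated) distinct
    anti-infectives and complete age/height/weight bands; columns: treated,
    age, height, weight (band midpoints), sepsis, male, aki.
    """
    counts = anti_infective_counts(db, atc_map)
    arm = counts[counts >= 1]
    demo = db.demo.set_index("case_id").loc[arm.index]
    sepsis = sepsis_case_ids(db)
    aki = aki_case_ids(db)
    frame = pd.DataFrame(
        {
            "treated": (arm >= 2),
            "age": demo["age_band"].map(band_midpoint),
            "height": demo["height_band"].map(band_midpoint),
            "weight": demo["weight_band"].map(band_midpoint),
            "sepsis": demo.index.isin(sepsis).astype(float),
            "male": (demo["sex"] == "male").astype(float),
            "aki": demo.index.isin(aki),
        },
        index=arm.index,
    )
    complete = frame[list(PS_COVARIATES)].notna().all(axis=1)
    return frame[complete], int((~complete).sum())


@dataclass
class PSModel:
    """Fitted treatment-allocation logistic regression.

    ``params`` are maximum-likelihood log-odds coefficients (with intercept);
    ``ps`` the predicted probability of combination therapy per case;
    ``auc`` the area under the ROC curve of treatment prediction.
    """

    params: pd.Series
    bse: pd.Series
    ps: pd.Series
    auc: float
    n_treated: int
    n_control: int
    converged: bool

    def summary_text(self) -> str:
        lines = ["treatment-allocation logistic model (>=2 anti-infectives vs 1)"]
        for name in self.params.index:
            lines.append(f"  {name:>10}: {self.params[name]:+.4f} (SE {self.bse[name]:.4f})")
        lines.append(f"  AUC: {self.auc:.4f}")
        lines.append(f"  n treated: {self.n_treated}, n control: {self.n_control}")
        return "\n".join(lines)


class FittingError(RuntimeError):
    """The PS model failed to converge (e.g. perfect separation)."""


def fit_ps_model(
    covariates: pd.DataFrame, model_covariates: tuple[str, ...] = PS_COVARIATES
) -> PSModel:
    """Fit the PS logistic regression by maximum likelihood."""
    from sklearn.metrics import roc_auc_score

    y = covariates["treated"].astype(float)
    if y.nunique() < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise FittingError("need at least two cases in each therapy arm")
    X = sm.add_constant(covariates[list(model_covariates)].astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels raises various types
        raise FittingError(f"PS model failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FittingError(f"PS model failed to converge: {fit.mle_retvals}")
    ps = pd.Series(np.asarray(fit.predict(X)), index=covariates.index, name="ps")
    auc = float(roc_auc_score(y, ps))
    return PSModel(
        params=fit.params,
        bse=fit.bse,
        ps=ps,
        auc=auc,
        n_treated=int((y == 1).sum()),
        n_control=int((y == 0).sum()),
        converged=True,
    )


@dataclass
class MatchResult:
    """1:1 matched pairs with caliper and balance diagnostics."""

    pairs: pd.DataFrame  # columns: treated_id, control_id, logit_distance
    caliper: float
    n_treated: int
    n_control: int
    n_unmatched_treated: int
    smd_before: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    smd_after: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_excluded_incomplete: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def treated_ids(self) -> list[str]:
        return self.pairs["treated_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        return self.pairs["control_id"].tolist()


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def greedy_caliper_match(
    ps: pd.Series,
    treated: pd.Series,
    caliper_multiplier: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching on logit(PS) within a caliper.

    Treated cases are processed in a seeded random order that is independent
    of input row order (IDs are sorted before permuting), each taking the
    unmatched control with the nearest logit PS, provided the absolute logit
    difference does not exceed ``caliper_multiplier`` × SD of the pooled
    logit-PS values (sample SD, ddof=1). Matching is without replacement;
    treated cases with no admissible control are dropped. Distance ties break
    toward the lower-logit control, then the lexicographically smaller ID.
    """
    ps = ps.astype(float)
    if ((ps <= 0) | (ps >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    treated = treated.reindex(ps.index).astype(bool)
    t_ids = ps.index[treated]
    c_ids = ps.index[~treated]
    if len(t_ids) == 0 or len(c_ids) == 0:
        raise ValueError("both therapy arms must be non-empty")

    logits = pd.Series(_logit(ps.to_numpy()), index=ps.index)
    pooled_sd = float(np.std(logits.to_numpy(), ddof=1)) if len(logits) > 1 else 0.0
    caliper = caliper_multiplier * pooled_sd

    # canonical processing order: sort IDs, then apply a seeded permutation,
    # so the pair multiset does not depend on input row order
    t_sorted = sorted(t_ids, key=str)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t_sorted))

    # controls sorted by (logit, id); "alive" bookkeeping via next/prev links
    c_sorted = sorted(c_ids, key=lambda i: (logits[i], str(i)))
    c_logit = np.array([logits[i] for i in c_sorted])
    m = len(c_sorted)
    nxt = np.arange(1, m + 1)  # skip pointer to the next possibly-alive index
    prv = np.arange(-1, m)
    dead = np.zeros(m, dtype=bool)

    def right_of(i: int) -> int:
        # first alive index >= i (m if none)
        while i < m and dead[i]:
            i = nxt[i]
        return i

    def left_of(i: int) -> int:
        # last alive index <= i (-1 if none)
        while i >= 0 and dead[i]:
            i = prv[i]
        return i

    pairs = []
    for k in order:
        tid = t_sorted[k]
        tl = logits[tid]
        pos = int(np.searchsorted(c_logit, tl))
        ri = right_of(pos)
        li = left_of(pos - 1)
        best = -1
        if li >= 0 and ri < m:
            d_left = abs(tl - c_logit[li])
            d_right = abs(c_logit[ri] - tl)
            best = li if d_left <= d_right else ri  # tie -> lower logit
        elif li >= 0:
            best = li
        elif ri < m:
            best = ri
        if best < 0:
            continue
        dist = abs(tl - c_logit[best])
        if dist > caliper:
            continue
        dead[best] = True
        nxt[best] = right_of(best + 1) if best + 1 < m else m
        prv[best] = left_of(best - 1)
        pairs.append((tid, c_sorted[best], float(dist)))

    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "control_id", "logit_distance"])
    pairs_df = pairs_df.sort_values("treated_id", key=lambda s: s.astype(str)).reset_index(
        drop=True
    )
    return MatchResult(
        pairs=pairs_df,
        caliper=caliper,
        n_treated=len(t_ids),
        n_control=len(c_ids),
        n_unmatched_treated=len(t_ids) - len(pairs_df),
    )


def smd(
    group1,
    group2,
    kind: str = "binned-numeric",
) -> float:
    """Standardized mean difference between two groups.

    ``binary``: inputs are proportions (scalars) or 0/1 vectors;
    ``|p1−p2| / sqrt((p1(1−p1) + p2(1−p2)) / 2)``.
    ``binned-numeric``: inputs are value vectors (bin midpoints);
    ``|m1−m2| / sqrt((s1² + s2²) / 2)`` with sample variances.
    Zero pooled variance with unequal means yields ``inf``.
    """
    if kind == "binary":
        p1 = float(np.mean(group1)) if np.ndim(group1) else float(group1)
        p2 = float(np.mean(group2)) if np.ndim(group2) else float(group2)
        denom = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
        num = abs(p1 - p2)
    elif kind == "binned-numeric":
        x1 = np.asarray(group1, dtype=float)
        x2 = np.asarray(group2, dtype=float)
        if len(x1) == 0 or len(x2) == 0:
            raise ValueError("both groups must be non-empty")
        v1 = float(np.var(x1, ddof=1)) if len(x1) > 1 else 0.0
        v2 = float(np.var(x2, ddof=1)) if len(x2) > 1 else 0.0
        denom = math.sqrt((v1 + v2) / 2)
        num = abs(float(np.mean(x1)) - float(np.mean(x2)))
    else:
        raise ValueError(f"unknown SMD kind {kind!r}")
    if denom == 0:
        return 0.0 if num == 0 else math.inf
    return num / denom


def _smd_series(covariates: pd.DataFrame, treated_ids, control_ids) -> pd.Series:
    g1 = covariates.loc[list(treated_ids)]
    g2 = covariates.loc[list(control_ids)]
    out = {}
    for cov in BALANCE_COVARIATES:
        kind = "binary" if cov in ("sepsis", "male") else "binned-numeric"
        out[cov] = smd(g1[cov].to_numpy(), g2[cov].to_numpy(), kind=kind)
    return pd.Series(out, name="smd")


def balance_table(
    covariates: pd.DataFrame, match: MatchResult
) -> pd.DataFrame:
    """Per-covariate SMD before and after matching."""
    before = _smd_series(
        covariates,
        covariates.index[covariates["treated"]],
        covariates.index[~covariates["treated"]],
    )
    after = _smd_series(covariates, match.treated_ids, match.control_ids)
    return pd.DataFrame({"smd_before": before, "smd_after": after})


def match_therapy_arms(
    db: CaseDatabase,
    atc_map: AtcMap | None = None,
    caliper_multiplier: float = 0.2,
    seed: int = 0,
) -> tuple[PSModel, MatchResult, pd.DataFrame]:
    """Covariates → PS model → caliper matching → balance, in one call."""
    covariates, n_excluded = build_covariates(db, atc_map)
    model = fit_ps_model(covariates)
    match = greedy_caliper_match(
        model.ps, covariates["treated"], caliper_multiplier=caliper_multiplier, seed=seed
    )
    balance = balance_table(covariates, match)
    match.smd_before = balance["smd_before"]
    match.smd_after = balance["smd_after"]
    match.n_excluded_incomplete = n_excluded
    return model, match, balance


def adjusted_ror(
    db: CaseDatabase,
    match: MatchResult,
    outcome_ids: set[str] | None = None,
) -> tuple[RORResult, RORResult]:
    """Post-matching RORs for the monotherapy and combination-therapy arms.

    Each matched arm is treated as the exposed group against the remainder of
    the database; returns ``(monotherapy arm, combination arm)`` results.
    """
    if match.n_matched == 0:
        raise ValueError("matched set is empty")
    if outcome_ids is None:
        outcome_ids = aki_case_ids(db)
    all_ids = db.case_ids
    mono = ContingencyTable.from_case_sets(all_ids, set(match.control_ids), outcome_ids)
    combo = ContingencyTable.from_case_sets(all_ids, set(match.treated_ids), outcome_ids)
    return crude_ror(mono), crude_ror(combo)
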