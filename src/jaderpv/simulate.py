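"""Synthetic JADER-format report generator with known ground truth.

Every pipeline stage is testable without any external download: the
generator emulates the joint structure the analysis assumes — per-report
demographics (decade age bands, sex, height/weight bands conditional on
sex), drug exposures with configurable marginal prevalence and a
polypharmacy mixture, an adverse-event outcome drawn from a logistic model
with per-drug and pairwise-combination log-odds, sepsis flags that can shift
the propensity for combination therapy, and per-drug Weibull-distributed
onset days with a configurable fraction of missing dates.

Generation is a pure function of ``(config, seed)``; independent named
random sub-streams per table keep draws stable when unrelated features are
added. The ``jader-like`` preset is numerically anchored to the marginal
structure of the public JADER 2004–2018 extract (AKI base rate ≈ 4.1% of
reports, ≈ 5.6% of reports with exactly one anti-infective and ≈ 1.8% with
two or more).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CaseDatabase

__all__ = [
    "DrugSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "preset",
    "PRESETS",
]

#: innocuous (non-AKI, non-sepsis) preferred terms used for control reports
DEFAULT_NONAKI_PTS = (
    (10012735, "Diarrhoea"),
    (10037844, "Rash"),
    (10019211, "Hepatic function abnormal"),
    (10028813, "Nausea"),
)

DEFAULT_AGE_BAND_PROBS = {
    "0-9": 0.05,
    "10-19": 0.03,
    "20-29": 0.04,
    "30-39": 0.06,
    "40-49": 0.08,
    "50-59": 0.12,
    "60-69": 0.21,
    "70-79": 0.23,
    "80-89": 0.15,
    "90-99": 0.028,
    ">=100": 0.002,
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class DrugSpec:
    """One drug of the simulated catalog.

    ``aki_log_odds`` is the drug's additive contribution to the logit of the
    adverse-event probability; ``onset_alpha``/``onset_beta`` parameterize
    the Weibull onset-day distribution (days) used when this drug is the
    event's culprit.
    """

    name: str
    atc_class: str
    is_anti_infective: bool = True
    prevalence: float = 0.1
    p_po: float = 0.5
    onset_alpha: float = 8.0
    onset_beta: float = 1.0
    aki_log_odds: float = 0.0


@dataclass
class SimulationConfig:
    n_reports: int = 1000
    seed: int = 0
    drugs: tuple[DrugSpec, ...] = ()
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_aki_log_odds: float = _logit(0.05)
    combination_aki_log_odds: float = 0.0  # extra log-odds when >=2 anti-infectives
    age_aki_log_odds_per_decade: float = 0.0
    sepsis_prevalence: float = 0.0
    sepsis_aki_log_odds: float = 0.0
    # treatment-allocation shifts added to every anti-infective's exposure logit
    allocation: dict[str, float] = field(default_factory=dict)  # keys: sepsis, age, male
    heavy_fraction: float = 0.0  # polypharmacy mixture: fraction of "heavy" reports
    heavy_multiplier: float = 1.0  # anti-infective prevalence multiplier for them
    exclusive_drugs: bool = False  # at most one drug per report (onset-profile demos)
    missing_date_fraction: float = 0.0
    age_band_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_BAND_PROBS))
    p_male: float = 0.55
    nonaki_pts: tuple[tuple[int, str], ...] = DEFAULT_NONAKI_PTS
    base_date: str = "2016-01-01"

    def validate(self) -> "SimulationConfig":
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        probs = [self.sepsis_prevalence, self.heavy_fraction, self.p_male,
                 self.missing_date_fraction] + [d.prevalence for d in self.drugs] + [
                 d.p_po for d in self.drugs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(d.onset_alpha <= 0 or d.onset_beta <= 0 for d in self.drugs):
            raise ValueError("Weibull onset parameters must be positive")
        total_age = sum(self.age_band_probs.values())
        if not math.isclose(total_age, 1.0, abs_tol=1e-6):
            raise ValueError(f"age band probabilities must sum to 1 (got {total_age})")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in catalog")
        for a, b in self.interactions:
            if a not in names or b not in names:
                raise ValueError(f"interaction references unknown drug ({a}, {b})")
        if self.exclusive_drugs and sum(d.prevalence for d in self.drugs) > 1.0:
            raise ValueError("exclusive catalog prevalences must sum to <= 1")
        return self


@dataclass
class GroundTruth:
    """Latent quantities behind one generated database."""

    config: SimulationConfig
    aki_prob: np.ndarray  # per-report latent event probability
    aki: np.ndarray  # realized outcome
    exposure: pd.DataFrame  # report × drug boolean matrix
    anti_infective_count: np.ndarray
    sepsis: np.ndarray
    culprit: np.ndarray  # drug index behind each event's onset time, -1 if none
    true_onset_params: dict[str, tuple[float, float]]
    true_drug_log_odds: dict[str, float]

    def summary(self) -> dict:
        return {
            "n_reports": int(len(self.aki)),
            "n_aki": int(self.aki.sum()),
            "n_sepsis": int(self.sepsis.sum()),
            "n_monotherapy": int((self.anti_infective_count == 1).sum()),
            "n_combination": int((self.anti_infective_count >= 2).sum()),
            "true_drug_log_odds": self.true_drug_log_odds,
            "true_onset_params": {k: list(v) for k, v in self.true_onset_params.items()},
            "seed": self.config.seed,
        }

    def write_sidecar(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def _load_pt_table(filename: str) -> pd.DataFrame:
    with resources.as_file(resources.files("jaderpv.data").joinpath(filename)) as p:
        return pd.read_csv(p)


def generate(config: SimulationConfig) -> tuple[CaseDatabase, GroundTruth]:
    """Generate a validated four-table database plus its ground truth."""
    config.validate()
    n = config.n_reports
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_demo, rng_sepsis, rng_expo, rng_aki, rng_dates, rng_onset, rng_miss, rng_reac = (
        np.random.default_rng(s) for s in streams
    )
    drugs = config.drugs
    n_drugs = len(drugs)
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    # ---- demographics -------------------------------------------------
    bands = list(config.age_band_probs)
    band_p = np.array([config.age_band_probs[b] for b in bands])
    age_band = rng_demo.choice(bands, size=n, p=band_p / band_p.sum())
    age_mid = np.array(
        [105.0 if b == ">=100" else int(b.split("-")[0]) + 5.0 for b in age_band]
    ) if n else np.empty(0)
    male = rng_demo.random(n) < config.p_male
    height = np.where(
        male, rng_demo.normal(166, 9, n), rng_demo.normal(153, 9, n)
    ) if n else np.empty(0)
    weight = np.where(
        male, rng_demo.normal(63, 12, n), rng_demo.normal(52, 10, n)
    ) if n else np.empty(0)
    # children: scale body size roughly with age
    juvenile = age_mid < 20
    height = np.where(juvenile, 60 + age_mid * 5.0, height)
    weight = np.where(juvenile, 5 + age_mid * 2.2, weight)

    def to_band(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
        clipped = np.clip(np.floor(values / 10).astype(int) * 10, lo, hi)
        return np.array([f"{v}-{v + 9}" for v in clipped])

    height_band = to_band(height, 30, 190) if n else np.empty(0, dtype=object)
    weight_band = to_band(weight, 0, 190) if n else np.empty(0, dtype=object)

    sepsis = rng_sepsis.random(n) < config.sepsis_prevalence

    # ---- drug exposure ------------------------------------------------
    alloc = config.allocation
    alloc_shift = np.zeros(n)
    if alloc.get("sepsis"):
        alloc_shift += alloc["sepsis"] * sepsis
    if alloc.get("age"):
        alloc_shift += alloc["age"] * (age_mid - 50.0)
    if alloc.get("male"):
        alloc_shift += alloc["male"] * male
    heavy = rng_expo.random(n) < config.heavy_fraction

    exposure = np.zeros((n, n_drugs), dtype=bool)
    if config.exclusive_drugs and n_drugs:
        p = np.array([d.prevalence for d in drugs])
        cum = np.concatenate([[0.0], np.cumsum(p)])
        u = rng_expo.random(n)
        for j in range(n_drugs):
            exposure[:, j] = (u >= cum[j]) & (u < cum[j + 1])
    else:
        for j, d in enumerate(drugs):
            base = np.full(n, d.prevalence)
            if d.is_anti_infective:
                base = np.where(heavy, np.minimum(base * config.heavy_multiplier, 0.95), base)
            with np.errstate(divide="ignore"):
                logit = np.log(base) - np.log1p(-base)
            if d.is_anti_infective:
                logit = logit + alloc_shift
            prob = np.where(base <= 0, 0.0, _sigmoid(logit))
            exposure[:, j] = rng_expo.random(n) < prob

    ai_mask = np.array([d.is_anti_infective for d in drugs], dtype=bool)
    ai_count = exposure[:, ai_mask].sum(axis=1) if n_drugs else np.zeros(n, dtype=int)

    # ---- adverse-event outcome ----------------------------------------
    logit_aki = np.full(n, config.baseline_aki_log_odds)
    for j, d in enumerate(drugs):
        if d.aki_log_odds:
            logit_aki += d.aki_log_odds * exposure[:, j]
    name_index = {d.name: j for j, d in enumerate(drugs)}
    for (a, b), lo in config.interactions.items():
        logit_aki += lo * (exposure[:, name_index[a]] & exposure[:, name_index[b]])
    if config.combination_aki_log_odds:
        logit_aki += config.combination_aki_log_odds * (ai_count >= 2)
    if config.sepsis_aki_log_odds:
        logit_aki += config.sepsis_aki_log_odds * sepsis
    if config.age_aki_log_odds_per_decade:
        logit_aki += config.age_aki_log_odds_per_decade * (age_mid - 50.0) / 10.0
    aki_prob = _sigmoid(logit_aki)
    aki = rng_aki.random(n) < aki_prob

    # ---- dates ---------------------------------------------------------
    base = np.datetime64(config.base_date)
    report_day = rng_dates.integers(0, 365, size=n) if n else np.empty(0, dtype=int)
    start_date = base + report_day.astype("timedelta64[D]")

    # culprit drug per event: uniformly among its anti-infectives if any,
    # otherwise among all present drugs
    culprit = np.full(n, -1, dtype=int)
    for i in np.flatnonzero(aki):
        present = np.flatnonzero(exposure[i])
        if present.size == 0:
            continue
        ai_present = present[ai_mask[present]]
        pool = ai_present if ai_present.size else present
        culprit[i] = pool[rng_onset.integers(0, pool.size)]

    onset_day = np.full(n, -1, dtype=int)
    for j, d in enumerate(drugs):
        idx = np.flatnonzero(culprit == j)
        if idx.size:
            delay = d.onset_alpha * rng_onset.weibull(d.onset_beta, size=idx.size)
            onset_day[idx] = np.floor(delay).astype(int)

    onset_missing = rng_miss.random(n) < config.missing_date_fraction
    start_missing = rng_miss.random(n) < config.missing_date_fraction

    # ---- assemble tables ----------------------------------------------
    demo = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": np.where(male, "male", "female") if n else np.empty(0, dtype=object),
            "age_band": age_band,
            "height_band": height_band,
            "weight_band": weight_band,
            "report_quarter": (
                lambda idx: idx.year.astype(str) + "Q" + idx.quarter.astype(str)
            )(pd.DatetimeIndex(start_date)),
        }
    )

    case_idx, drug_idx = np.nonzero(exposure)
    n_rows = len(case_idx)
    roles = np.array(["suspected", "concomitant", "interacting"])
    role_draw = rng_reac.choice(3, size=n_rows, p=[0.55, 0.40, 0.05])
    p_po_arr = np.array([d.p_po for d in drugs]) if n_drugs else np.empty(0)
    route_po = rng_reac.random(n_rows) < (p_po_arr[drug_idx] if n_rows else np.empty(0))
    drug_names_arr = np.array([d.name for d in drugs]) if n_drugs else np.empty(0, dtype=object)
    row_start = pd.to_datetime(pd.Series(start_date[case_idx] if n_rows else []))
    row_start[pd.Series(start_missing[case_idx] if n_rows else [], dtype=bool).to_numpy()] = pd.NaT
    drug_table = pd.DataFrame(
        {
            "case_id": case_ids[case_idx] if n_rows else np.empty(0, dtype=object),
            "drug_name": drug_names_arr[drug_idx] if n_rows else np.empty(0, dtype=object),
            "role_code": roles[role_draw] if n_rows else np.empty(0, dtype=object),
            "route": np.where(route_po, "po", "iv") if n_rows else np.empty(0, dtype=object),
            "start_date": row_start.to_numpy() if n_rows else pd.DatetimeIndex([]),
        }
    )
    drug_table = drug_table.sort_values(["case_id", "drug_name"], kind="stable").reset_index(
        drop=True
    )

    aki_pts = _load_pt_table("aki_pt.csv")
    sepsis_pts = _load_pt_table("sepsis_pt.csv")
    nonaki_codes = np.array([c for c, _ in config.nonaki_pts])
    nonaki_names = np.array([s for _, s in config.nonaki_pts])

    # one primary adverse-event row per report
    pt_code = np.zeros(n, dtype=int)
    pt_name = np.empty(n, dtype=object)
    onset = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    aki_idx = np.flatnonzero(aki)
    non_idx = np.flatnonzero(~aki)
    k_aki = rng_reac.integers(0, len(aki_pts), size=aki_idx.size)
    pt_code[aki_idx] = aki_pts["pt_code"].to_numpy()[k_aki]
    pt_name[aki_idx] = aki_pts["pt_name"].to_numpy()[k_aki]
    has_onset = aki_idx[(onset_day[aki_idx] >= 0) & ~onset_missing[aki_idx]]
    onset[has_onset] = start_date[has_onset] + onset_day[has_onset].astype("timedelta64[D]")
    k_non = rng_reac.integers(0, len(nonaki_codes), size=non_idx.size)
    pt_code[non_idx] = nonaki_codes[k_non]
    pt_name[non_idx] = nonaki_names[k_non]
    onset[non_idx] = start_date[non_idx] + rng_reac.integers(
        0, 30, size=non_idx.size
    ).astype("timedelta64[D]")
    # sepsis background lands in REAC or HIST with equal probability
    sep_idx = np.flatnonzero(sepsis)
    k_sep = rng_reac.integers(0, len(sepsis_pts), size=sep_idx.size)
    in_reac = rng_reac.random(sep_idx.size) < 0.5
    sep_codes = sepsis_pts["pt_code"].to_numpy()[k_sep]
    sep_names = sepsis_pts["pt_name"].to_numpy()[k_sep]
    hist_rows = list(zip(case_ids[sep_idx[~in_reac]], sep_codes[~in_reac]))

    n_sep_reac = int(in_reac.sum())
    reac_table = pd.DataFrame(
        {
            "case_id": np.concatenate([case_ids, case_ids[sep_idx[in_reac]]]),
            "pt_code": np.concatenate([pt_code, sep_codes[in_reac]]),
            "pt_name": np.concatenate([pt_name, sep_names[in_reac]]),
            "onset_date": pd.to_datetime(
                np.concatenate(
                    [onset, np.full(n_sep_reac, np.datetime64("NaT"), dtype="datetime64[D]")]
                )
            ),
        }
    )
    reac_table = reac_table.sort_values("case_id", kind="stable").reset_index(drop=True)
    reac_table["pt_code"] = reac_table["pt_code"].astype("Int64")
    hist_table = pd.DataFrame(hist_rows, columns=["case_id", "pt_code"])
    hist_table["pt_code"] = hist_table["pt_code"].astype("Int64")

    db = CaseDatabase(demo=demo, drug=drug_table, reac=reac_table, hist=hist_table).validate()
    truth = GroundTruth(
        config=config,
        aki_prob=aki_prob,
        aki=aki,
        exposure=pd.DataFrame(exposure, index=case_ids, columns=[d.name for d in drugs]),
        anti_infective_count=ai_count,
        sepsis=sepsis,
        culprit=culprit,
        true_onset_params={d.name: (d.onset_alpha, d.onset_beta) for d in drugs},
        true_drug_log_odds={d.name: d.aki_log_odds for d in drugs},
    )
    return db, truth


# ----------------------------------------------------------------------
# presets


def _jader_like() -> SimulationConfig:
    """Marginals anchored to the public JADER 2004–2018 extract.

    Ten anti-infectives at 0.46% prevalence with a 3% "heavy polypharmacy"
    subpopulation (prevalence × 37) put ≈ 5.7% of reports on exactly one
    anti-infective and ≈ 1.8% on two or more; the baseline event logit puts
    the AKI rate near 4–5%.
    """
    ai = [
        # name, class, alpha, beta, log-odds
        ("vancomycin", "J01XA", 8.7, 1.10, math.log(4.0)),
        ("tazobactam/piperacillin", "J01CR", 7.4, 1.04, math.log(3.5)),
        ("meropenem", "J01DH", 8.6, 1.03, math.log(2.2)),
        ("levofloxacin", "J01MA", 7.6, 0.92, math.log(1.35)),
        ("clarithromycin", "J01FA", 9.0, 1.00, 0.0),
        ("fluconazole", "J02AC", 13.1, 0.83, math.log(2.1)),
        ("cefazolin", "J01DB", 7.0, 1.00, math.log(1.15)),
        ("ceftriaxone", "J01DD", 7.2, 1.02, math.log(1.6)),
        ("micafungin", "J02AX", 10.8, 0.96, math.log(2.9)),
        ("minocycline", "J01AA", 8.0, 0.90, math.log(1.3)),
    ]
    drugs = [
        DrugSpec(
            name=n,
            atc_class=c,
            prevalence=0.0046,
            p_po=0.35,
            onset_alpha=a,
            onset_beta=b,
            aki_log_odds=lo,
        )
        for n, c, a, b, lo in ai
    ] + [
        DrugSpec("acetaminophen", "N02BE", is_anti_infective=False, prevalence=0.15, p_po=0.9),
        DrugSpec("furosemide", "C03CA", is_anti_infective=False, prevalence=0.08, p_po=0.8),
        DrugSpec("omeprazole", "A02BC", is_anti_infective=False, prevalence=0.10, p_po=0.9),
    ]
    return SimulationConfig(
        n_reports=50_000,
        drugs=tuple(drugs),
        interactions={("vancomycin", "tazobactam/piperacillin"): 0.35},
        baseline_aki_log_odds=_logit(0.039),
        age_aki_log_odds_per_decade=0.10,
        sepsis_prevalence=0.02,
        sepsis_aki_log_odds=0.3,
        allocation={"sepsis": 1.2, "age": 0.005},
        heavy_fraction=0.03,
        heavy_multiplier=37.0,
        missing_date_fraction=0.3,
    )


def _null() -> SimulationConfig:
    """A single exposure with zero association — for calibration checks."""
    return SimulationConfig(
        n_reports=5_000,
        drugs=(DrugSpec("vancomycin", "J01XA", prevalence=0.3, aki_log_odds=0.0),),
        baseline_aki_log_odds=_logit(0.05),
    )


def _interaction_demo() -> SimulationConfig:
    """Two drugs with a planted positive combination effect."""
    return SimulationConfig(
        n_reports=20_000,
        drugs=(
            DrugSpec("vancomycin", "J01XA", prevalence=0.15, aki_log_odds=math.log(2.0)),
            DrugSpec(
                "tazobactam/piperacillin", "J01CR", prevalence=0.15, aki_log_odds=math.log(2.0)
            ),
        ),
        interactions={("vancomycin", "tazobactam/piperacillin"): 0.7},
        baseline_aki_log_odds=_logit(0.05),
    )


def _ps_demo() -> SimulationConfig:
    """Planted covariate imbalance between mono- and combination therapy.

    Sepsis and age shift the allocation toward combination therapy, and
    combination therapy itself carries a planted event log-odds of 0.4, so
    both the balance-recovery and the adjusted-ROR checks can run on it.
    """
    names = [
        ("vancomycin", "J01XA"),
        ("meropenem", "J01DH"),
        ("levofloxacin", "J01MA"),
        ("ceftriaxone", "J01DD"),
        ("fluconazole", "J02AC"),
        ("cefazolin", "J01DB"),
    ]
    drugs = tuple(
        DrugSpec(n, c, prevalence=0.12, p_po=0.4, aki_log_odds=0.0) for n, c in names
    )
    return SimulationConfig(
        n_reports=10_000,
        drugs=drugs,
        baseline_aki_log_odds=_logit(0.05),
        combination_aki_log_odds=0.4,
        sepsis_prevalence=0.15,
        sepsis_aki_log_odds=0.2,
        allocation={"sepsis": 1.2, "age": 0.02},
    )


def _tto_demo() -> SimulationConfig:
    """Three onset-hazard regimes (decreasing, constant, increasing)."""
    return SimulationConfig(
        n_reports=6_000,
        drugs=(
            DrugSpec("fluconazole", "J02AC", prevalence=0.25, onset_alpha=8.0, onset_beta=0.7),
            DrugSpec("meropenem", "J01DH", prevalence=0.25, onset_alpha=8.0, onset_beta=1.0),
            DrugSpec("amikacin", "J01GB", prevalence=0.25, onset_alpha=8.0, onset_beta=1.4),
        ),
        exclusive_drugs=True,
        baseline_aki_log_odds=_logit(0.5),
        missing_date_fraction=0.0,
    )


PRESETS = {
    "jader-like": _jader_like,
    "null": _null,
    "interaction-demo": _interaction_demo,
    "ps-demo": _ps_demo,
    "tto-demo": _tto_demo,
}


def preset(name: str, n_reports: int | None = None, seed: int | None = None) -> SimulationConfig:
    """A fully populated, documented configuration by name."""
    try:
        config = PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    if n_reports is not None:
        config = dataclasses.replace(config, n_reports=n_reports)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    return config
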