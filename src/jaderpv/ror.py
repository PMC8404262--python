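"""Reporting odds ratio (ROR) disproportionality analysis.

For an exposure E and an outcome O over the reports of a spontaneous
reporting system, the 2×2 contingency table is

===========  ==========  =============
group        outcome     no outcome
===========  ==========  =============
exposed      a           b
non-exposed  c           d
===========  ==========  =============

and the crude ROR is ``(a/b)/(c/d)`` with the Woolf (log-normal) 95%
confidence interval ``exp(ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d))``.
A drug–event combination is a *signal* when the ROR is defined and the lower
CI bound exceeds 1. The ROR is undefined — rendered "–" — when any cell is
empty or there are fewer than two exposed cases with the outcome (a < 2); no
continuity correction is applied, mirroring the reporting convention of
published disproportionality tables.

Exposures are pure predicates over a report's joined record: a single drug,
an ATC class, a co-reported drug pair, an anti-infective count band, or a
demographic stratum. The ROR is a reporting-disproportionality statistic,
not an incidence measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .io import CaseDatabase
from .terms import AtcMap, aki_case_ids, anti_infective_counts, bundled_atc_classes

__all__ = [
    "ContingencyTable",
    "RORResult",
    "ExposureDefinition",
    "drug_exposure",
    "atc_class_exposure",
    "drug_pair_exposure",
    "anti_infective_count_exposure",
    "age_band_exposure",
    "sex_exposure",
    "crude_ror",
    "build_contingency",
    "class_ror_table",
    "combination_ror",
    "stratified_ror",
]

Z_95 = 1.96  # normal quantile used for every 95% interval in this package


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts: a=E∧O, b=E∧¬O, c=¬E∧O, d=¬E∧¬O."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"negative cell {cell} in contingency table {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_outcome(self) -> int:
        return self.a + self.c

    @classmethod
    def from_case_sets(
        cls, all_ids: Iterable[str], exposed: set[str], outcome: set[str]
    ) -> "ContingencyTable":
        all_ids = set(all_ids)
        exposed = exposed & all_ids
        outcome = outcome & all_ids
        a = len(exposed & outcome)
        b = len(exposed) - a
        c = len(outcome) - a
        d = len(all_ids) - a - b - c
        return cls(a, b, c, d)

    @classmethod
    def from_margins(
        cls, n_total: int, n_outcome: int, n_exposed: int, n_exposed_outcome: int
    ) -> "ContingencyTable":
        """Build the table by subtraction from marginal report counts."""
        a = n_exposed_outcome
        b = n_exposed - a
        c = n_outcome - a
        d = n_total - n_exposed - c
        return cls(a, b, c, d)

    def swapped(self) -> "ContingencyTable":
        """Exposed and non-exposed groups interchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RORResult:
    """Point estimate, Woolf 95% CI and signal flag for one 2×2 table.

    ``defined`` is False when any cell is zero or ``a < min_cases`` — such
    rows render as "–". ``signal`` additionally requires a lower CI bound
    above 1.
    """

    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    case_count: int
    defined: bool
    signal: bool

    def rounded(self, digits: int = 2) -> tuple[float, float, float]:
        return (round(self.ror, digits), round(self.ci_low, digits), round(self.ci_high, digits))


def crude_ror(table: ContingencyTable, min_cases: int = 2, z: float = Z_95) -> RORResult:
    """Crude ROR with Woolf interval and the two-criterion signal rule.

    The estimate is suppressed (``defined=False``, NaNs, rendered "–") when
    any cell is zero or fewer than ``min_cases`` exposed cases carry the
    outcome — the reporting convention of published disproportionality
    tables.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0 or a < min_cases:
        return RORResult(
            table=table,
            ror=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            case_count=a,
            defined=False,
            signal=False,
        )
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = ror * math.exp(-z * se)
    ci_high = ror * math.exp(z * se)
    signal = (a >= min_cases) and (ci_low > 1.0)
    return RORResult(
        table=table,
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        case_count=a,
        defined=True,
        signal=signal,
    )


# ----------------------------------------------------------------------
# exposure definitions


@dataclass(frozen=True)
class ExposureDefinition:
    """A labelled pure predicate selecting the exposed case IDs."""

    label: str
    kind: str
    selector: Callable[[CaseDatabase, AtcMap], set[str]]

    def case_ids(self, db: CaseDatabase, atc_map: AtcMap | None = None) -> set[str]:
        return self.selector(db, atc_map or AtcMap.bundled())


def drug_exposure(drug_name: str) -> ExposureDefinition:
    """Reports listing ``drug_name`` (any role code), alias-aware."""

    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        canon = atc_map.canonical_name(drug_name)
        drug = atc_map.drug_annotations(db)
        if canon is None:
            from .terms import normalize_drug_name

            names = drug["drug_name"].map(normalize_drug_name)
            return set(drug.loc[names == normalize_drug_name(drug_name), "case_id"])
        return set(drug.loc[drug["canonical_name"] == canon, "case_id"])

    return ExposureDefinition(drug_name, "drug_name", select)


def atc_class_exposure(atc_code: str) -> ExposureDefinition:
    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        return atc_map.class_exposure_ids(db, atc_code)

    return ExposureDefinition(atc_code, "atc_class", select)


def drug_pair_exposure(drug_a: str, drug_b: str) -> ExposureDefinition:
    """Reports listing BOTH drugs (co-reported combination)."""

    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        return drug_exposure(drug_a).case_ids(db, atc_map) & drug_exposure(drug_b).case_ids(
            db, atc_map
        )

    return ExposureDefinition(f"{drug_a} + {drug_b}", "drug_pair", select)


def anti_infective_count_exposure(band: str) -> ExposureDefinition:
    """Reports whose distinct anti-infective count falls in ``band`` (0, 1, >=2)."""
    if band not in {"0", "1", ">=2"}:
        raise ValueError(f"unknown anti-infective count band {band!r}")

    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        counts = anti_infective_counts(db, atc_map)
        if band == "0":
            mask = counts == 0
        elif band == "1":
            mask = counts == 1
        else:
            mask = counts >= 2
        return set(counts.index[mask])

    label = {"0": "0 drugs", "1": "1 drug", ">=2": ">=2 drugs"}[band]
    return ExposureDefinition(label, "drug_count_band", select)


def age_band_exposure(bands: str | Sequence[str]) -> ExposureDefinition:
    bands = (bands,) if isinstance(bands, str) else tuple(bands)

    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        return set(db.demo.loc[db.demo["age_band"].isin(bands), "case_id"])

    return ExposureDefinition("/".join(bands), "age_band", select)


def sex_exposure(sex: str) -> ExposureDefinition:
    def select(db: CaseDatabase, atc_map: AtcMap) -> set[str]:
        return set(db.demo.loc[db.demo["sex"] == sex, "case_id"])

    return ExposureDefinition(sex, "sex", select)


# ----------------------------------------------------------------------
# table builders


def build_contingency(
    db: CaseDatabase,
    exposure: ExposureDefinition,
    outcome_ids: set[str] | None = None,
    atc_map: AtcMap | None = None,
) -> ContingencyTable:
    """Count each report exactly once into the 2×2 table.

    ``outcome_ids`` defaults to the AKI case set.
    """
    if outcome_ids is None:
        outcome_ids = aki_case_ids(db)
    exposed = exposure.case_ids(db, atc_map)
    return ContingencyTable.from_case_sets(db.case_ids, exposed, outcome_ids)


def _result_row(label: str, table: ContingencyTable, min_cases: int) -> dict:
    res = crude_ror(table, min_cases=min_cases)
    return {
        "label": label,
        "total_n": table.n_exposed,
        "case_n": table.a,
        "ror": res.ror,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "defined": res.defined,
        "signal": res.signal,
    }


def class_ror_table(
    db: CaseDatabase,
    atc_classes: Sequence[str] | None = None,
    outcome_ids: set[str] | None = None,
    atc_map: AtcMap | None = None,
    min_cases: int = 2,
) -> pd.DataFrame:
    """Per-ATC-class crude RORs (one row per class, undefined rows kept).

    A report listing drugs from several classes appears in each of their
    rows; within one row it is counted once.
    """
    atc_map = atc_map or AtcMap.bundled()
    if atc_classes is None:
        atc_classes = bundled_atc_classes()["atc_code"].tolist()
    if outcome_ids is None:
        outcome_ids = aki_case_ids(db)
    labels = dict(
        zip(bundled_atc_classes()["atc_code"], bundled_atc_classes()["class_label"])
    )
    rows = []
    for code in atc_classes:
        table = build_contingency(db, atc_class_exposure(code), outcome_ids, atc_map)
        row = _result_row(code, table, min_cases)
        row["class_label"] = labels.get(code, atc_map.class_label(code))
        rows.append(row)
    return pd.DataFrame(rows)


def combination_ror(
    db: CaseDatabase,
    drug_a: str,
    drug_b: str,
    outcome_ids: set[str] | None = None,
    atc_map: AtcMap | None = None,
    min_cases: int = 2,
) -> RORResult:
    """ROR of reports containing both drugs versus all other reports."""
    table = build_contingency(db, drug_pair_exposure(drug_a, drug_b), outcome_ids, atc_map)
    return crude_ror(table, min_cases=min_cases)


AGE_STRATA = ("<=19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", ">=90")
_AGE_STRATUM_BANDS = {
    "<=19": ("0-9", "10-19"),
    ">=90": ("90-99", ">=100"),
}


def stratified_ror(
    db: CaseDatabase,
    stratifier: str,
    outcome_ids: set[str] | None = None,
    atc_map: AtcMap | None = None,
    min_cases: int = 2,
) -> pd.DataFrame:
    """Stratum-membership RORs for the AKI outcome.

    For each stratum the exposed group is the stratum itself and the
    comparison group is every report outside it. Stratifiers: ``age_band``
    (decade strata, with the youngest and oldest strata pooling two decade
    bands), ``sex`` and ``anti_infective_count`` (0 / 1 / >=2 distinct
    anti-infectives).
    """
    if outcome_ids is None:
        outcome_ids = aki_case_ids(db)
    if stratifier == "sex":
        exposures = [sex_exposure("male"), sex_exposure("female")]
    elif stratifier == "age_band":
        exposures = [
            ExposureDefinition(
                s, "age_band", age_band_exposure(_AGE_STRATUM_BANDS.get(s, (s,))).selector
            )
            for s in AGE_STRATA
        ]
    elif stratifier == "anti_infective_count":
        exposures = [anti_infective_count_exposure(b) for b in ("0", "1", ">=2")]
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    rows = []
    for exp in exposures:
        table = build_contingency(db, exp, outcome_ids, atc_map)
        rows.append(_result_row(exp.label, table, min_cases))
    return pd.DataFrame(rows)
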