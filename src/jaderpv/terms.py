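"""MedDRA preferred-term outcome sets and ATC drug-class mapping.

The acute-kidney-injury (AKI) outcome is defined by a fixed set of 19 MedDRA
preferred terms (PTs) chosen from the 'acute renal failure' standardized
MedDRA query plus closely related renal terms; the sepsis covariate by a set
of 22 sepsis-related PTs. Both sets ship as package data. AKI status is read
from the adverse-event (REAC) table only; sepsis status from either the
adverse-event or the primary-disease (HIST) table.

Drug exposure is mapped through an :class:`AtcMap`: normalized drug name →
ATC code(s), class label and anti-infective status. The bundled map is a
fixture covering common anti-infectives (36 anti-infective ATC classes are
recognized) plus a handful of non-anti-infectives; users supply their own CSV
for fuller coverage. Name matching is exact after normalization and explicit
aliasing — no fuzzy matching, so unmapped names surface as warnings rather
than silent misclassification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import CaseDatabase

__all__ = [
    "PTSet",
    "AtcMap",
    "aki_pt_set",
    "sepsis_pt_set",
    "is_aki_event",
    "is_sepsis_term",
    "aki_case_ids",
    "sepsis_case_ids",
    "case_has_aki",
    "case_has_sepsis",
    "anti_infective_counts",
    "count_anti_infectives",
]


@dataclass(frozen=True)
class PTSet:
    """A named set of MedDRA preferred-term codes."""

    name: str
    codes: frozenset[int]

    def __contains__(self, pt_code: object) -> bool:
        try:
            return int(pt_code) in self.codes  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False

    def __len__(self) -> int:
        return len(self.codes)


def _data_path(filename: str):
    return resources.files("jaderpv.data").joinpath(filename)


def _load_pt_set(filename: str, name: str) -> PTSet:
    with resources.as_file(_data_path(filename)) as path:
        frame = pd.read_csv(path)
    return PTSet(name=name, codes=frozenset(int(c) for c in frame["pt_code"]))


@lru_cache(maxsize=None)
def aki_pt_set() -> PTSet:
    """The 19 preferred terms defining the AKI outcome."""
    return _load_pt_set("aki_pt.csv", "acute kidney injury")


@lru_cache(maxsize=None)
def sepsis_pt_set() -> PTSet:
    """The 22 preferred terms defining the sepsis covariate."""
    return _load_pt_set("sepsis_pt.csv", "sepsis")


def is_aki_event(pt_code: int) -> bool:
    return pt_code in aki_pt_set()


def is_sepsis_term(pt_code: int) -> bool:
    return pt_code in sepsis_pt_set()


def normalize_drug_name(name: str) -> str:
    return " ".join(str(name).casefold().split())


class AtcMap:
    """Drug name → ATC code / class label / anti-infective status.

    A drug may map to several ATC codes (combination products): it then
    contributes to each mapped class in class-level counts but counts once
    toward the per-report anti-infective count. ``alias_of`` rows redirect
    alternative names to a canonical entry, so duplicated spellings of one
    substance are never double-counted.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"drug_name", "atc_code", "class_label", "is_anti_infective"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"ATC map is missing column(s) {sorted(missing)}")
        frame = frame.copy()
        frame["drug_name"] = frame["drug_name"].map(normalize_drug_name)
        if "alias_of" not in frame.columns:
            frame["alias_of"] = ""
        frame["alias_of"] = frame["alias_of"].fillna("").map(
            lambda v: normalize_drug_name(v) if v else ""
        )
        frame["is_anti_infective"] = frame["is_anti_infective"].astype(int).astype(bool)
        self._frame = frame
        self._canonical = {
            row.drug_name: (row.alias_of or row.drug_name)
            for row in frame.itertuples()
        }
        base = frame[frame["alias_of"] == ""]
        self._entries = {
            name: group[["atc_code", "class_label", "is_anti_infective"]].to_records(index=False)
            for name, group in base.groupby("drug_name")
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtcMap":
        return cls(pd.read_csv(path))

    @classmethod
    @lru_cache(maxsize=None)
    def bundled(cls) -> "AtcMap":
        """The fixture map shipped with the package."""
        with resources.as_file(_data_path("atc_map.csv")) as path:
            return cls.from_csv(path)

    def canonical_name(self, drug_name: str) -> str | None:
        name = normalize_drug_name(drug_name)
        canon = self._canonical.get(name)
        if canon is None:
            return None
        return canon

    def lookup(self, drug_name: str) -> list[tuple[str, str, bool]]:
        """All (atc_code, class_label, is_anti_infective) entries for a drug."""
        canon = self.canonical_name(drug_name)
        if canon is None or canon not in self._entries:
            return []
        return [tuple(rec) for rec in self._entries[canon]]

    def is_anti_infective(self, drug_name: str) -> bool:
        return any(ai for _, _, ai in self.lookup(drug_name))

    def classes_of(self, drug_name: str) -> set[str]:
        return {code for code, _, _ in self.lookup(drug_name)}

    def class_label(self, atc_code: str) -> str:
        hits = self._frame.loc[self._frame["atc_code"] == atc_code, "class_label"]
        return hits.iloc[0] if len(hits) else atc_code

    def anti_infective_classes(self) -> list[str]:
        mask = self._frame["is_anti_infective"]
        return sorted(self._frame.loc[mask, "atc_code"].unique())

    # ------------------------------------------------------------------
    # vectorized per-database helpers

    def drug_annotations(self, db: CaseDatabase, warn_unmapped: bool = False) -> pd.DataFrame:
        """DRUG table with canonical name and anti-infective flag columns."""
        drug = db.drug.copy()
        names = drug["drug_name"].map(normalize_drug_name)
        canon = names.map(self._canonical)
        unmapped = canon.isna()
        if warn_unmapped and unmapped.any():
            unknown = sorted(names[unmapped].unique().tolist())
            warnings.warn(f"{len(unknown)} drug name(s) not in ATC map: {unknown[:20]}")
        drug["canonical_name"] = canon
        drug["is_anti_infective"] = canon.map(
            lambda n: any(ai for _, _, ai in self._entries.get(n, []))
            if isinstance(n, str)
            else False
        ).astype(bool)
        return drug

    def class_exposure_ids(self, db: CaseDatabase, atc_code: str) -> set[str]:
        """Case IDs with at least one drug mapping to ``atc_code`` (any role)."""
        members = {
            name
            for name, recs in self._entries.items()
            if any(code == atc_code for code, _, _ in recs)
        }
        drug = self.drug_annotations(db)
        mask = drug["canonical_name"].isin(members)
        return set(drug.loc[mask, "case_id"])


@lru_cache(maxsize=None)
def bundled_atc_classes() -> pd.DataFrame:
    """The 36 anti-infective ATC classes (code, label, group)."""
    with resources.as_file(_data_path("atc_classes.csv")) as path:
        return pd.read_csv(path)


def _pt_case_ids(frame: pd.DataFrame, ptset: PTSet) -> set[str]:
    codes = frame["pt_code"]
    mask = codes.notna() & codes.astype("Int64").isin(list(ptset.codes))
    return set(frame.loc[mask, "case_id"])


def aki_case_ids(db: CaseDatabase) -> set[str]:
    """Case IDs with an AKI preferred term in the adverse-event table."""
    return _pt_case_ids(db.reac, aki_pt_set())


def sepsis_case_ids(db: CaseDatabase) -> set[str]:
    """Case IDs with a sepsis term in the adverse-event OR history table."""
    return _pt_case_ids(db.reac, sepsis_pt_set()) | _pt_case_ids(db.hist, sepsis_pt_set())


def _require_case(db: CaseDatabase, case_id: str) -> None:
    if not (db.demo["case_id"] == case_id).any():
        raise KeyError(f"unknown case_id {case_id!r}")


def case_has_aki(db: CaseDatabase, case_id: str) -> bool:
    _require_case(db, case_id)
    return case_id in aki_case_ids(db)


def case_has_sepsis(db: CaseDatabase, case_id: str) -> bool:
    _require_case(db, case_id)
    return case_id in sepsis_case_ids(db)


def anti_infective_counts(db: CaseDatabase, atc_map: AtcMap | None = None) -> pd.Series:
    """Distinct anti-infective substances per report, indexed by case_id.

    Counts distinct canonical drug names (any role code); duplicated DRUG
    rows and aliases of the same substance count once. Reports with no DRUG
    rows count zero.
    """
    atc_map = atc_map or AtcMap.bundled()
    drug = atc_map.drug_annotations(db)
    ai = drug[drug["is_anti_infective"]]
    counts = ai.groupby("case_id")["canonical_name"].nunique()
    return counts.reindex(db.demo["case_id"], fill_value=0).astype(int)


def count_anti_infectives(db: CaseDatabase, case_id: str, atc_map: AtcMap | None = None) -> int:
    _require_case(db, case_id)
    return int(anti_infective_counts(db, atc_map).loc[case_id])
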