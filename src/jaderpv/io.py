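"""Read, validate, join and write four-table JADER-layout report databases.

A spontaneous-reporting-system extract in the JADER layout consists of four
delimited tables keyed by an opaque case identifier:

* ``DEMO`` — one row per report: sex, age band (decades), height/weight bands
  (10-unit bins), reporting quarter;
* ``DRUG`` — one row per drug per report: drug name, role code (suspected /
  concomitant / interacting), administration route, start date;
* ``REAC`` — one row per adverse event per report: MedDRA preferred-term (PT)
  code and name, onset date;
* ``HIST`` — one row per primary-disease entry per report: PT code.

Every child-table row must reference a DEMO case; the number of reports in a
database equals the number of DEMO rows. Files are mapped onto this canonical
model through a :class:`Dialect` (delimiter, encoding, header map, enum value
map, date format), so the same reader handles both the public JADER CSV layout
and the canonical layout written by :mod:`jaderpv.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Dialect",
    "CaseDatabase",
    "CaseView",
    "ValidationIssue",
    "ValidationReport",
    "JaderIOError",
    "SchemaError",
    "ValidationError",
    "get_dialect",
    "read_tables",
    "write_tables",
    "case_view",
]


class JaderIOError(Exception):
    """Base class for errors raised by this module."""


class SchemaError(JaderIOError):
    """A required column is missing or a dialect is malformed."""


class ValidationError(JaderIOError):
    """The tables violate a key invariant of the four-table model."""


SEX_VALUES = ("male", "female", "unknown")
ROLE_VALUES = ("suspected", "concomitant", "interacting")
ROUTE_VALUES = ("po", "iv", "other", "unknown")

DEMO_COLUMNS = ["case_id", "sex", "age_band", "height_band", "weight_band", "report_quarter"]
DRUG_COLUMNS = ["case_id", "drug_name", "role_code", "route", "start_date"]
REAC_COLUMNS = ["case_id", "pt_code", "pt_name", "onset_date"]
HIST_COLUMNS = ["case_id", "pt_code"]

_DATE_COLUMNS = {"drug": ["start_date"], "reac": ["onset_date"]}
_TABLE_COLUMNS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "hist": HIST_COLUMNS,
}


@dataclass(frozen=True)
class Dialect:
    """How the four files map onto the canonical table model.

    ``columns`` maps, per table, a file header to its canonical column name;
    canonical headers need no entry. ``values`` maps, per canonical enum
    column, raw cell values to canonical enum values (e.g. Japanese role
    codes). Dates are parsed with ``date_format``; cells that do not parse
    (including partial year–month dates) become missing.
    """

    name: str = "canonical"
    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "%Y-%m-%d"
    columns: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    values: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            name=raw.get("name", Path(path).stem),
            delimiter=raw.get("delimiter", ","),
            encoding=raw.get("encoding", "utf-8"),
            date_format=raw.get("date_format", "%Y-%m-%d"),
            columns=raw.get("columns", {}),
            values=raw.get("values", {}),
        )


#: Approximate header map for the public JADER CSV distribution. The PMDA
#: files use Japanese headers and Shift-JIS-family encodings; both are
#: configurable because distributions have varied across years.
JADER_DIALECT = Dialect(
    name="jader",
    encoding="cp932",
    date_format="%Y%m%d",
    columns={
        "demo": {
            "識別番号": "case_id",
            "性別": "sex",
            "年齢": "age_band",
            "身長": "height_band",
            "体重": "weight_band",
            "報告年度・四半期": "report_quarter",
        },
        "drug": {
            "識別番号": "case_id",
            "医薬品（一般名）": "drug_name",
            "医薬品の関与": "role_code",
            "投与経路": "route",
            "投与開始日": "start_date",
        },
        "reac": {
            "識別番号": "case_id",
            "有害事象コード": "pt_code",
            "有害事象": "pt_name",
            "発現日": "onset_date",
        },
        "hist": {"識別番号": "case_id", "原疾患等コード": "pt_code"},
    },
    values={
        "sex": {"男性": "male", "女性": "female", "不明": "unknown"},
        "role_code": {"被疑薬": "suspected", "併用薬": "concomitant", "相互作用": "interacting"},
        "route": {"経口": "po", "静脈内注射": "iv", "不明": "unknown"},
    },
)

_DIALECTS = {"canonical": Dialect(), "jader": JADER_DIALECT}


def get_dialect(name_or_dialect: str | Dialect) -> Dialect:
    if isinstance(name_or_dialect, Dialect):
        return name_or_dialect
    try:
        return _DIALECTS[name_or_dialect]
    except KeyError:
        raise SchemaError(
            f"unknown dialect {name_or_dialect!r}; known: {sorted(_DIALECTS)}"
        ) from None


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    case_id: str
    problem: str


@dataclass
class ValidationReport:
    """Row-level problems found while reading; rejected rows are enumerated."""

    issues: list[ValidationIssue] = field(default_factory=list)
    n_demo_rows_read: int = 0
    n_reports: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.issues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.table, i.case_id, i.problem) for i in self.issues],
            columns=["table", "case_id", "problem"],
        )

    def to_text(self) -> str:
        lines = [
            f"reports read: {self.n_reports} (DEMO rows: {self.n_demo_rows_read})",
            f"rows rejected: {self.n_rejected}",
        ]
        lines += [f"  [{i.table}] case {i.case_id}: {i.problem}" for i in self.issues]
        return "\n".join(lines)


@dataclass
class CaseDatabase:
    """A joined four-table report collection keyed by case ID.

    Invariants: ``case_id`` is unique in ``demo``; every ``case_id`` in
    ``drug``/``reac``/``hist`` exists in ``demo``. ``validate()`` enforces
    them; readers and the simulator only produce validated databases.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def case_ids(self) -> pd.Index:
        return pd.Index(self.demo["case_id"])

    def validate(self) -> "CaseDatabase":
        for name, cols in _TABLE_COLUMNS.items():
            frame = getattr(self, name)
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise SchemaError(f"{name.upper()} table is missing column(s) {missing}")
        dupes = self.demo.loc[self.demo["case_id"].duplicated(), "case_id"]
        if len(dupes):
            raise ValidationError(
                f"duplicate case_id in DEMO: {sorted(dupes.unique().tolist())}"
            )
        if (self.demo["case_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty case_id in DEMO")
        known = set(self.demo["case_id"])
        for name in ("drug", "reac", "hist"):
            ids = getattr(self, name)["case_id"]
            orphans = sorted(set(ids) - known)
            if orphans:
                raise ValidationError(
                    f"{name.upper()} references case_id(s) absent from DEMO: {orphans}"
                )
        return self

    def copy(self) -> "CaseDatabase":
        return CaseDatabase(
            self.demo.copy(), self.drug.copy(), self.reac.copy(), self.hist.copy()
        )


@dataclass
class CaseView:
    """All records for one case, with child rows in input order."""

    case_id: str
    demo: pd.Series
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    history: pd.DataFrame


def case_view(db: CaseDatabase, case_id: str) -> CaseView:
    """Join the four tables for one case.

    Raises ``KeyError`` for a case_id absent from DEMO.
    """
    hits = db.demo.index[db.demo["case_id"] == case_id]
    if len(hits) == 0:
        raise KeyError(f"unknown case_id {case_id!r}")
    return CaseView(
        case_id=case_id,
        demo=db.demo.loc[hits[0]],
        drugs=db.drug[db.drug["case_id"] == case_id].reset_index(drop=True),
        reactions=db.reac[db.reac["case_id"] == case_id].reset_index(drop=True),
        history=db.hist[db.hist["case_id"] == case_id].reset_index(drop=True),
    )


def _read_one(path: str | Path, table: str, dialect: Dialect) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep=dialect.delimiter,
        encoding=dialect.encoding,
        dtype=str,
        keep_default_na=False,
    )
    rename = dict(dialect.columns.get(table, {}))
    frame = frame.rename(columns=rename)
    missing = [c for c in _TABLE_COLUMNS[table] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{table.upper()} file {path} is missing required column(s) {missing}"
        )
    frame = frame[_TABLE_COLUMNS[table]].copy()

    for col, vmap in dialect.values.items():
        if col in frame.columns and vmap:
            frame[col] = frame[col].map(lambda v: vmap.get(v, v))
    for col in _DATE_COLUMNS.get(table, []):
        frame[col] = pd.to_datetime(frame[col], format=dialect.date_format, errors="coerce")
    if "pt_code" in frame.columns:
        frame["pt_code"] = pd.to_numeric(frame["pt_code"], errors="coerce").astype("Int64")
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].str.strip()
    return frame


def read_tables(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
    dialect: str | Dialect = "canonical",
    strict: bool = True,
) -> tuple[CaseDatabase, ValidationReport]:
    """Read and validate a four-table database.

    With ``strict=True`` (default) any orphan child row — a case_id missing
    from DEMO — raises :class:`ValidationError` naming the offending IDs.
    With ``strict=False`` orphan rows are removed and enumerated in the
    returned :class:`ValidationReport` instead. Duplicate DEMO case IDs are
    always an error: the layout gives no safe way to deduplicate reports.
    """
    dialect = get_dialect(dialect)
    demo = _read_one(demo_path, "demo", dialect)
    drug = _read_one(drug_path, "drug", dialect)
    reac = _read_one(reac_path, "reac", dialect)
    hist = _read_one(hist_path, "hist", dialect)

    report = ValidationReport(n_demo_rows_read=len(demo))

    dupes = demo.loc[demo["case_id"].duplicated(), "case_id"]
    if len(dupes):
        raise ValidationError(f"duplicate case_id in DEMO: {sorted(dupes.unique().tolist())}")

    known = set(demo["case_id"])
    tables = {"drug": drug, "reac": reac, "hist": hist}
    for name, frame in tables.items():
        orphan_mask = ~frame["case_id"].isin(known)
        if orphan_mask.any():
            orphans = sorted(frame.loc[orphan_mask, "case_id"].unique().tolist())
            if strict:
                raise ValidationError(
                    f"{name.upper()} references case_id(s) absent from DEMO: {orphans}"
                )
            for cid in frame.loc[orphan_mask, "case_id"]:
                report.issues.append(
                    ValidationIssue(name, str(cid), "case_id absent from DEMO; row dropped")
                )
            tables[name] = frame[~orphan_mask].reset_index(drop=True)

    db = CaseDatabase(demo=demo, drug=tables["drug"], reac=tables["reac"], hist=tables["hist"])
    db.validate()
    report.n_reports = db.n_reports
    return db, report


def write_tables(
    db: CaseDatabase,
    out_dir: str | Path,
    dialect: str | Dialect = "canonical",
) -> dict[str, Path]:
    """Write the four tables; inverse of :func:`read_tables` (round-trip safe)."""
    dialect = get_dialect(dialect)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inverse_values = {
        col: {v: k for k, v in vmap.items()} for col, vmap in dialect.values.items()
    }
    paths: dict[str, Path] = {}
    for name in ("demo", "drug", "reac", "hist"):
        frame = getattr(db, name).copy()
        for col in _DATE_COLUMNS.get(name, []):
            frame[col] = frame[col].dt.strftime(dialect.date_format)
        for col, vmap in inverse_values.items():
            if col in frame.columns:
                frame[col] = frame[col].map(lambda v: vmap.get(v, v))
        rename = {v: k for k, v in dialect.columns.get(name, {}).items()}
        frame = frame.rename(columns=rename)
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)
        paths[name] = path
    return paths


def empty_database() -> CaseDatabase:
    """A validated database with zero reports (all four tables empty)."""
    frames = {}
    for name, cols in _TABLE_COLUMNS.items():
        frame = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for col in _DATE_COLUMNS.get(name, []):
            frame[col] = pd.Series(dtype="datetime64[ns]")
        if "pt_code" in cols:
            frame["pt_code"] = pd.Series(dtype="Int64")
        frames[name] = frame
    return CaseDatabase(**frames)


def concat_issues(reports: Iterable[ValidationReport]) -> ValidationReport:
    merged = ValidationReport()
    for rep in reports:
        merged.issues.extend(rep.issues)
        merged.n_demo_rows_read += rep.n_demo_rows_read
        merged.n_reports += rep.n_reports
    return merged
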