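"""Shared fixtures: tiny hand-built databases and small synthetic ones."""

from __future__ import annotations

import pandas as pd
import pytest

from jaderpv.io import CaseDatabase


def make_db(demo_rows, drug_rows=(), reac_rows=(), hist_rows=()) -> CaseDatabase:
    """Build a validated CaseDatabase from lists of dicts (dates as ISO strings)."""
    demo = pd.DataFrame(
        list(demo_rows),
        columns=["case_id", "sex", "age_band", "height_band", "weight_band", "report_quarter"],
    )
    drug = pd.DataFrame(
        list(drug_rows), columns=["case_id", "drug_name", "role_code", "route", "start_date"]
    )
    drug["start_date"] = pd.to_datetime(drug["start_date"], errors="coerce")
    reac = pd.DataFrame(list(reac_rows), columns=["case_id", "pt_code", "pt_name", "onset_date"])
    reac["onset_date"] = pd.to_datetime(reac["onset_date"], errors="coerce")
    reac["pt_code"] = pd.array(reac["pt_code"], dtype="Int64")
    hist = pd.DataFrame(list(hist_rows), columns=["case_id", "pt_code"])
    hist["pt_code"] = pd.array(hist["pt_code"], dtype="Int64")
    return CaseDatabase(demo=demo, drug=drug, reac=reac, hist=hist).validate()


def demo_row(case_id, sex="female", age="60-69", height="150-159", weight="50-59", q="2016Q1"):
    return {
        "case_id": case_id,
        "sex": sex,
        "age_band": age,
        "height_band": height,
        "weight_band": weight,
        "report_quarter": q,
    }


def drug_row(case_id, name, role="suspected", route="iv", start=None):
    return {
        "case_id": case_id,
        "drug_name": name,
        "role_code": role,
        "route": route,
        "start_date": start,
    }


def reac_row(case_id, pt_code, pt_name="", onset=None):
    return {"case_id": case_id, "pt_code": pt_code, "pt_name": pt_name, "onset_date": onset}


AKI_PT = 10069339  # "Acute kidney injury"
CREATININE_PT = 10005483  # "Blood creatinine increased"
SEPSIS_PT = 10040047  # "Sepsis"
SEPTIC_SHOCK_PT = 10040070
OTHER_PT = 10012735  # "Diarrhoea" — neither AKI nor sepsis


@pytest.fixture(scope="session")
def three_case_db() -> CaseDatabase:
    """3 DEMO rows, 5 DRUG rows, 4 REAC rows — counts checked by construction."""
    return make_db(
        demo_rows=[demo_row("A"), demo_row("B", sex="male"), demo_row("C")],
        drug_rows=[
            drug_row("A", "vancomycin", start="2016-01-01"),
            drug_row("A", "tazobactam/piperacillin", start="2016-01-02"),
            drug_row("A", "acetaminophen", role="concomitant", route="po"),
            drug_row("B", "levofloxacin", route="po", start="2016-02-01"),
            drug_row("C", "meropenem", start="2016-03-05"),
        ],
        reac_rows=[
            reac_row("A", AKI_PT, "Acute kidney injury", onset="2016-01-06"),
            reac_row("A", SEPSIS_PT, "Sepsis"),
            reac_row("B", OTHER_PT, "Diarrhoea", onset="2016-02-10"),
            reac_row("C", CREATININE_PT, "Blood creatinine increased", onset="2016-03-12"),
        ],
        hist_rows=[{"case_id": "B", "pt_code": SEPSIS_PT}],
    )
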