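"""Published reference values from the JADER 2004–2018 anti-infective AKI analysis.

The package bundles the publicly reported summary numbers of that analysis —
per-exposure report counts with crude RORs (ATC classes, vancomycin
combinations, demographic and drug-count strata), pre/post-matching group
proportions for selected covariates, and per-class Weibull onset parameters —
as plain CSV/constant data. They serve two purposes: 2×2 tables can be
rebuilt by subtraction from the printed margins (N = 534,688 reports,
21,727 AKI events) to exercise the ROR machinery against published values,
and the β confidence intervals drive the hazard-classification check.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "TOTAL_REPORTS",
    "TOTAL_AKI",
    "ror_reference_rows",
    "onset_reference_rows",
    "BALANCE_PROPORTIONS",
]

#: margins of the published analysis (reports, AKI events)
TOTAL_REPORTS = 534_688
TOTAL_AKI = 21_727


def _read(filename: str) -> pd.DataFrame:
    with resources.as_file(resources.files("jaderpv.data").joinpath(filename)) as path:
        return pd.read_csv(path)


@lru_cache(maxsize=None)
def ror_reference_rows() -> pd.DataFrame:
    """Published exposure rows: label, total_n, case_n and printed ROR/CI.

    ``ror``/``ci_low``/``ci_high`` are NaN for rows published as "–"
    (fewer than two cases).
    """
    return _read("reference_ror_rows.csv")


@lru_cache(maxsize=None)
def onset_reference_rows() -> pd.DataFrame:
    """Published per-(class, route) onset summaries and Weibull parameters."""
    return _read("reference_onset.csv")


#: published group proportions for covariate balance, before and after
#: propensity-score matching (treated = combination therapy, >= 2
#: anti-infectives; control = monotherapy), with the published SMDs
BALANCE_PROPORTIONS = {
    "sepsis": {
        "before": (0.0823, 0.0318, 0.2190),  # (p_treated, p_control, published SMD)
        "after": (0.0791, 0.0778, 0.0048),
    },
    "male": {
        "before": (0.5861, 0.5373, 0.0985),
        "after": (0.5892, 0.5941, 0.0100),
    },
}
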