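"""Descriptive cohort summary: sex, country, reporting year, age, outcome.

Each report contributes exactly one label per section, so counts within
a section always sum to the cohort total.  Outcome codes are collapsed
to the single most severe per report (Death > Life-threatening >
Hospitalization > Disability > Other serious > Unknown), which is what
makes the outcome section an exact partition of the cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from faersig.faers_io import CaseReport

#: FAERS outcome codes mapped to summary labels; CA (congenital anomaly),
#: RI (required intervention) and OT fold into "Other serious events"
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
    "DS": "Disability",
    "CA": "Other serious events",
    "RI": "Other serious events",
    "OT": "Other serious events",
}

DEFAULT_OUTCOME_PRECEDENCE = (
    "Death",
    "Life-threatening",
    "Hospitalization",
    "Disability",
    "Other serious events",
)

#: half-open [low, high) age bins in years with their printed labels
DEFAULT_AGE_BINS = (
    (0.0, 18.0, "< 18 years"),
    (18.0, 45.0, "18 ~ 44 years"),
    (45.0, 60.0, "45 ~ 59 years"),
    (60.0, float("inf"), ">= 60 years"),
)

_USA_ALIASES = {"US", "USA", "UNITED STATES", "UNITED STATES OF AMERICA"}

SECTIONS = ("Sex", "Country", "Year", "Age", "Outcome")


@dataclass
class DemographicsSummary:
    total: int
    rows: pd.DataFrame  # columns: section, label, n, pct

    def section(self, name: str) -> pd.DataFrame:
        return self.rows[self.rows["section"] == name].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def _sex_label(report: CaseReport) -> str:
    if report.sex == "F":
        return "Female"
    if report.sex == "M":
        return "Male"
    return "Unknown"


def _country_label(report: CaseReport) -> str:
    country = (report.reporter_country or "").strip()
    if not country or country.lower() == "unknown":
        return "Unknown"
    return "USA" if country.upper() in _USA_ALIASES else "Rest of the world"


def _age_label(report: CaseReport, bins) -> str:
    age = report.age_years
    if age is None:
        return "Unknown"
    for low, high, label in bins:
        if low <= age < high:
            return label
    return "Unknown"


def _outcome_label(report: CaseReport, precedence: Sequence[str]) -> str:
    labels = {OUTCOME_LABELS[c] for c in report.outcomes if c in OUTCOME_LABELS}
    for label in precedence:
        if label in labels:
            return label
    return "Unknown"


def summarize(
    cohort: Sequence[CaseReport],
    age_bins=DEFAULT_AGE_BINS,
    outcome_precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
) -> DemographicsSummary:
    """Table-1-style summary of a deduplicated cohort.

    Percentages are ``round(100·n/total, 1)``.  An empty cohort yields
    total 0 and no rows.
    """
    total = len(cohort)
    if total == 0:
        return DemographicsSummary(total=0, rows=pd.DataFrame(columns=["section", "label", "n", "pct"]))

    counters: dict[str, Counter] = {s: Counter() for s in SECTIONS}
    for report in cohort:
        counters["Sex"][_sex_label(report)] += 1
        counters["Country"][_country_label(report)] += 1
        counters["Year"][str(report.fda_year) if report.fda_year is not None else "Unknown"] += 1
        counters["Age"][_age_label(report, age_bins)] += 1
        counters["Outcome"][_outcome_label(report, outcome_precedence)] += 1

    section_orders = {
        "Sex": ["Female", "Male", "Unknown"],
        "Country": ["USA", "Rest of the world", "Unknown"],
        "Year": sorted(counters["Year"], key=lambda y: (y == "Unknown", y), reverse=True),
        "Age": [label for _, _, label in age_bins] + ["Unknown"],
        "Outcome": list(outcome_precedence) + ["Unknown"],
    }
    # years descend, Unknown last
    years = sorted((y for y in counters["Year"] if y != "Unknown"), reverse=True)
    section_orders["Year"] = years + (["Unknown"] if "Unknown" in counters["Year"] else [])

    records = []
    for section in SECTIONS:
        for label in section_orders[section]:
            n = counters[section].get(label, 0)
            if n == 0 and label not in counters[section]:
                continue
            records.append(
                {"section": section, "label": label, "n": n, "pct": round(100.0 * n / total, 1)}
            )
    return DemographicsSummary(total=total, rows=pd.DataFrame(records))
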