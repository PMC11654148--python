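"""Shared fixtures: synthetic databases and hand-built reports."""

from __future__ import annotations

import pytest

from faersig.faers_io import CaseReport, cohort_primary_suspect, deduplicate
from faersig.synthetic import SyntheticConfig, simulate_quarters

TARGET = "DRUG_TARGET"


def make_report(
    caseid: str = "1",
    sex: str | None = None,
    age_years: float | None = None,
    country: str = "Unknown",
    fda_year: int | None = None,
    outcomes: set[str] | None = None,
    drugs: tuple[tuple[str, str], ...] = ((TARGET, "PS"),),
    pts: set[str] = frozenset({"PYREXIA"}),
) -> CaseReport:
    return CaseReport(
        caseid=caseid,
        primaryid=caseid + "1",
        sex=sex,
        age_years=age_years,
        reporter_country=country,
        fda_year=fda_year,
        outcomes=frozenset(outcomes or set()),
        drugs=drugs,
        pts=frozenset(pts),
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_reports=4000,
        target_drug_prob=0.05,
        planted={"PT_0001": 8.0, "PT_0002": 8.0},
        duplication_rate=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_quarters(small_config)


@pytest.fixture(scope="session")
def small_reports(small_sim):
    reports, audit = deduplicate(small_sim.quarters)
    return reports, audit


@pytest.fixture(scope="session")
def small_cohort(small_reports):
    reports, _ = small_reports
    return cohort_primary_suspect(reports, [TARGET])
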