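"""Descriptive summary of the target cohort (sex, country, year, age, outcome)."""

from __future__ import annotations

from common import DB_CONFIG, RESULTS, ensure_database

from faersig.demographics import summarize
from faersig.faers_io import cohort_primary_suspect, deduplicate, read_quarter
from faersig.pipeline import discover_quarters

db = ensure_database()
quarters = [read_quarter(q["demo"], q["drug"], q["reac"], q["outc"]) for q in discover_quarters(db)]
reports, _ = deduplicate(quarters)
target, _ = cohort_primary_suspect(reports, [DB_CONFIG.target_drug_name])

summary = summarize(target)
print(f"target cohort: {summary.total} deduplicated reports")
print(summary.to_frame().to_string(index=False))
summary.to_frame().to_csv(RESULTS / "demographics.tsv", sep="\t", index=False)
print(f"wrote {RESULTS / 'demographics.tsv'}")
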