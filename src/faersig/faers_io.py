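"""Reading, writing and assembling FAERS-style quarterly extracts.

FAERS publishes each quarter as a set of "$"-delimited ASCII tables
(DEMO, DRUG, REAC, OUTC, ...) keyed by ``primaryid``.  A single patient
case (``caseid``) may appear as several follow-up versions
(``caseversion``) across quarters; every analysis here first reduces the
database to one report per case by keeping the most recent version.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column sets per table; mandatory columns must be present in the
#: file header, optional ones are filled with NA when absent (pre-2012 LAERS
#: quarters carry a column subset).
MANDATORY_COLUMNS = {
    "demo": ("primaryid", "caseid", "caseversion"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
}
OPTIONAL_COLUMNS = {
    "demo": ("fda_dt", "sex", "age", "age_cod", "reporter_country"),
    "drug": ("drug_seq", "prod_ai"),
    "reac": (),
    "outc": (),
}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: divisors/multipliers converting FAERS age units to years
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1429,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WS = re.compile(r"\s+")


def normalize_drug_name(name: str | None) -> str:
    """Trim, collapse internal whitespace and uppercase a drug name."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return _WS.sub(" ", str(name).strip()).upper()


@dataclass
class Dialect:
    """Parameters of the FAERS quarterly ASCII layout."""

    delimiter: str = "$"
    encoding: str = "utf-8"


@dataclass
class RawQuarter:
    """Parsed rows of one quarterly extract, one DataFrame per table.

    Column names are canonicalized to lowercase; values are kept verbatim
    (ages are not yet converted to years, dates stay as yyyymmdd strings).
    ``malformed`` counts rows per table that lacked a usable primary key
    and were set aside rather than silently dropped.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    malformed: dict[str, int] = field(default_factory=dict)

    def n_reports(self) -> int:
        return len(self.demo)


@dataclass
class CaseReport:
    """One deduplicated individual case safety report (ICSR)."""

    caseid: str
    primaryid: str
    sex: str | None
    age_years: float | None
    reporter_country: str
    fda_year: int | None
    outcomes: frozenset[str]
    drugs: tuple[tuple[str, str], ...]  # (normalized name, role code)
    pts: frozenset[str]

    def has_drug(self, names: set[str], roles: Sequence[str] | None = None) -> bool:
        """True if any drug entry matches ``names`` (already normalized),
        optionally restricted to the given role codes."""
        for name, role in self.drugs:
            if name in names and (roles is None or role in roles):
                return True
        return False


@dataclass
class DedupAudit:
    """Bookkeeping from one deduplication pass."""

    rows_in: int
    cases_out: int
    duplicates_removed: int
    version_ties: int
    zero_reaction_reports: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "rows_in",
                    "cases_out",
                    "duplicates_removed",
                    "version_ties",
                    "zero_reaction_reports",
                ],
                "value": [
                    self.rows_in,
                    self.cases_out,
                    self.duplicates_removed,
                    self.version_ties,
                    self.zero_reaction_reports,
                ],
            }
        )


def _read_table(path: Path, table: str, dialect: Dialect) -> tuple[pd.DataFrame, int]:
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        encoding=dialect.encoding,
        keep_default_na=False,
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MANDATORY_COLUMNS[table]:
        if col not in df.columns:
            raise ValueError(f"{path}: mandatory column {col!r} missing from {table.upper()} table")
    for col in OPTIONAL_COLUMNS[table]:
        if col not in df.columns:
            df[col] = ""
    df = df[list(MANDATORY_COLUMNS[table]) + list(OPTIONAL_COLUMNS[table])]
    df = df.replace("", pd.NA)
    bad = df["primaryid"].isna()
    if table == "demo":
        bad |= df["caseid"].isna() | ~df["caseversion"].astype("string").str.fullmatch(r"\d+").fillna(False)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: %d malformed row(s) in %s table set aside", path, n_bad, table.upper())
    return df.loc[~bad].reset_index(drop=True), n_bad


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    dialect: Dialect | None = None,
) -> RawQuarter:
    """Parse one quarter's DEMO/DRUG/REAC/OUTC files.

    Field names are matched case-insensitively; absent optional columns
    (the pre-2012 LAERS subset) are treated as missing.  A missing
    mandatory column raises :class:`ValueError` naming file and column.
    """
    dialect = dialect or Dialect()
    frames: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for table, path in (
        ("demo", demo_path),
        ("drug", drug_path),
        ("reac", reac_path),
        ("outc", outc_path),
    ):
        frames[table], malformed[table] = _read_table(Path(path), table, dialect)
    return RawQuarter(
        demo=frames["demo"],
        drug=frames["drug"],
        reac=frames["reac"],
        outc=frames["outc"],
        malformed=malformed,
    )


def write_quarter(
    quarter: RawQuarter,
    out_dir: str | Path,
    suffix: str,
    dialect: Dialect | None = None,
) -> dict[str, Path]:
    """Write a quarter back to the FAERS ASCII dialect.

    Files are named ``DEMO<suffix>.txt`` etc. (e.g. suffix ``23Q1``).
    Returns the table → path mapping.
    """
    dialect = dialect or Dialect()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table in ("demo", "drug", "reac", "outc"):
        df: pd.DataFrame = getattr(quarter, table)
        path = out_dir / f"{table.upper()}{suffix}.txt"
        df.to_csv(path, sep=dialect.delimiter, index=False, na_rep="", encoding=dialect.encoding)
        paths[table] = path
    return paths


def convert_age(age: float | str | None, age_cod: str | None) -> float | None:
    """Convert a FAERS (age, unit-code) pair to years.

    Unit codes: DEC decades, YR years, MON months, WK weeks, DY days,
    HR hours.  A missing code with a non-missing age is read as years.
    Results outside [0, 150] years are treated as unusable and returned
    as ``None``.  Total function: never raises.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)) or age is pd.NA:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    code = None
    if age_cod is not None and age_cod is not pd.NA and not (isinstance(age_cod, float) and np.isnan(age_cod)):
        code = str(age_cod).strip().upper() or None
    factor = _AGE_FACTORS.get(code, 1.0) if code is not None else 1.0
    if code is not None and code not in _AGE_FACTORS:
        return None
    years = value * factor
    if not (0.0 <= years <= 150.0):
        logger.debug("age %r %r -> %.3f years out of range; set missing", age, age_cod, years)
        return None
    return years


def _fda_year(fda_dt: object) -> int | None:
    if fda_dt is None or fda_dt is pd.NA:
        return None
    s = str(fda_dt).strip()
    if len(s) >= 4 and s[:4].isdigit():
        year = int(s[:4])
        if 1900 <= year <= 2100:
            return year
    return None


def deduplicate(quarters: Iterable[RawQuarter]) -> tuple[list[CaseReport], DedupAudit]:
    """Collapse multi-version cases to one :class:`CaseReport` per caseid.

    The retained version is the maximum ``caseversion`` across all
    quarters; drugs, reactions and outcomes are attached from the
    retained ``primaryid`` only.  Ties on (caseid, caseversion) are
    broken by latest ``fda_dt``, then lexicographically largest
    ``primaryid`` — deterministic and aligned with the most-recent-version
    intent.
    """
    quarters = list(quarters)
    if not quarters:
        raise ValueError("deduplicate requires at least one quarter")

    demo = pd.concat([q.demo for q in quarters], ignore_index=True)
    drug = pd.concat([q.drug for q in quarters], ignore_index=True)
    reac = pd.concat([q.reac for q in quarters], ignore_index=True)
    outc = pd.concat([q.outc for q in quarters], ignore_index=True)

    rows_in = len(demo)
    demo = demo.assign(
        _version=pd.to_numeric(demo["caseversion"], errors="coerce").fillna(0).astype(int),
        _fda=demo["fda_dt"].fillna("0").astype(str),
    )
    # stable lexicographic sort: last row per caseid is the retained version
    demo = demo.sort_values(["caseid", "_version", "_fda", "primaryid"], kind="mergesort")
    ties = int(demo.duplicated(subset=["caseid", "_version"], keep=False).sum()) - int(
        demo.duplicated(subset=["caseid", "_version", "primaryid"], keep=False).sum()
    )
    if ties:
        logger.info("deduplicate: %d rows involved in same-version ties", ties)
    retained = demo.drop_duplicates(subset=["caseid"], keep="last")

    keep_ids = set(retained["primaryid"])
    drug = drug[drug["primaryid"].isin(keep_ids)]
    reac = reac[reac["primaryid"].isin(keep_ids)]
    outc = outc[outc["primaryid"].isin(keep_ids)]

    drugs_by_id: dict[str, list[tuple[str, str]]] = {}
    for pid, name, prod_ai, role in drug[["primaryid", "drugname", "prod_ai", "role_cod"]].itertuples(index=False):
        norm = normalize_drug_name(name if name is not pd.NA else None)
        ai = normalize_drug_name(prod_ai if prod_ai is not pd.NA else None)
        role = str(role).strip().upper() if role is not pd.NA else ""
        entry = drugs_by_id.setdefault(pid, [])
        entry.append((norm, role))
        if ai and ai != norm:
            entry.append((ai, role))

    pts_by_id: dict[str, set[str]] = {}
    for pid, pt in reac[["primaryid", "pt"]].itertuples(index=False):
        if pt is pd.NA:
            continue
        pts_by_id.setdefault(pid, set()).add(str(pt).strip().upper())

    outc_by_id: dict[str, set[str]] = {}
    for pid, code in outc[["primaryid", "outc_cod"]].itertuples(index=False):
        if code is pd.NA:
            continue
        outc_by_id.setdefault(pid, set()).add(str(code).strip().upper())

    reports: list[CaseReport] = []
    zero_reaction = 0
    for row in retained.itertuples(index=False):
        pid = row.primaryid
        pts = frozenset(pts_by_id.get(pid, set()))
        if not pts:
            zero_reaction += 1
        sex = None
        if row.sex is not pd.NA and str(row.sex).strip():
            sex = str(row.sex).strip().upper()
        country = "Unknown"
        if row.reporter_country is not pd.NA and str(row.reporter_country).strip():
            country = str(row.reporter_country).strip()
        reports.append(
            CaseReport(
                caseid=str(row.caseid),
                primaryid=str(pid),
                sex=sex,
                age_years=convert_age(
                    row.age if row.age is not pd.NA else None,
                    row.age_cod if row.age_cod is not pd.NA else None,
                ),
                reporter_country=country,
                fda_year=_fda_year(row.fda_dt if row.fda_dt is not pd.NA else None),
                outcomes=frozenset(outc_by_id.get(pid, set())),
                drugs=tuple(drugs_by_id.get(pid, [])),
                pts=pts,
            )
        )
    audit = DedupAudit(
        rows_in=rows_in,
        cases_out=len(reports),
        duplicates_removed=rows_in - len(reports),
        version_ties=ties,
        zero_reaction_reports=zero_reaction,
    )
    return reports, audit


def cohort_primary_suspect(
    reports: Sequence[CaseReport], target_names: Iterable[str]
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition reports into target cohort (target drug as primary
    suspect) and background (everything else).

    Matching is exact after name normalization (trim / collapse
    whitespace / uppercase) against both ``drugname`` and ``prod_ai``
    entries; the partition is exhaustive and disjoint.
    """
    names = {normalize_drug_name(n) for n in target_names}
    names.discard("")
    if not names:
        raise ValueError("target_names must contain at least one non-empty name")
    target: list[CaseReport] = []
    background: list[CaseReport] = []
    for report in reports:
        (target if report.has_drug(names, roles=("PS",)) else background).append(report)
    if not target:
        logger.warning("cohort_primary_suspect: no report matched the target drug names")
    return target, background
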