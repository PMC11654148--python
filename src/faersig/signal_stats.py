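"""Disproportionality statistics: 2×2 tables, ROR and BCPNN IC.

For one drug–event pair the report-level 2×2 table is

    a = reports with the drug AND the event
    b = reports with the drug, without the event
    c = comparator reports with the event
    d = comparator reports without the event

The reporting odds ratio is ROR = ad/bc with 95% CI
ROR·exp(±z·sqrt(1/a + 1/b + 1/c + 1/d)), z = 1.96.

The information component compares observed to expected pair counts on
a log2 scale with +0.5 shrinkage:

    IC    = log2((N_obs + 0.5) / (N_exp + 0.5)),
    N_exp = N_drug · N_effect / N_total,
    IC025 = IC − 3.3·(N_obs + 0.5)^(−1/2) − 2·(N_obs + 0.5)^(−3/2),
    IC975 = IC + 2.4·(N_obs + 0.5)^(−1/2) − 0.5·(N_obs + 0.5)^(−3/2).

A pair is a signal when ROR025 > 1, IC025 > 0 and a ≥ 4.  No
multiple-testing adjustment is applied (the signal criteria are the
only filter); treat flagged pairs as hypotheses, not causal claims.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from faersig.faers_io import CaseReport, normalize_drug_name
from faersig.meddra import PtSocMap, rollup_to_soc

logger = logging.getLogger(__name__)

DEFAULT_Z = 1.96
DEFAULT_MIN_A = 4


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts plus the IC marginals for one drug–event pair."""

    term: str
    level: str  # "pt" or "soc"
    a: int
    b: int
    c: int
    d: int
    n_drug: int
    n_effect: int
    n_total: int
    soc: str | None = None

    @property
    def n_observed(self) -> int:
        return self.a

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a > self.n_drug or self.a > self.n_effect:
            raise ValueError("a cannot exceed the drug or effect marginal")
        if max(self.n_drug, self.n_effect) > self.n_total:
            raise ValueError("marginals cannot exceed n_total")


@dataclass(frozen=True)
class SignalResult:
    """ROR + IC result for one term at one analysis level."""

    level: str
    term: str
    n: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    ic: float
    ic025: float
    ic975: float
    is_signal: bool
    soc: str | None = None
    zero_cell_corrected: bool = False


def ror_with_ci(t: ContingencyTable, z: float = DEFAULT_Z) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with its two-sided CI on the given z.

    When any cell is zero the Haldane–Anscombe correction (+0.5 to every
    cell) is applied and flagged via the returned boolean; an all-zero
    table is undefined and raises.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if a == b == c == d == 0.0:
        raise ValueError(f"{t.term}: all-zero contingency table has no defined ROR")
    corrected = min(a, b, c, d) == 0.0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    half_width = z * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return ror, ror * math.exp(-half_width), ror * math.exp(half_width), corrected


def ic_with_bounds(t: ContingencyTable) -> tuple[float, float, float]:
    """Information component with closed-form 95% credibility bounds."""
    if t.n_total <= 0:
        raise ValueError("n_total must be positive for the IC")
    n_obs = float(t.n_observed)
    n_exp = float(t.n_drug) * float(t.n_effect) / float(t.n_total)
    shrunk = n_obs + 0.5
    ic = math.log2(shrunk / (n_exp + 0.5))
    ic025 = ic - 3.3 * shrunk**-0.5 - 2.0 * shrunk**-1.5
    ic975 = ic + 2.4 * shrunk**-0.5 - 0.5 * shrunk**-1.5
    return ic, ic025, ic975


def flag_signal(n: int, ror025: float, ic025: float, min_a: int = DEFAULT_MIN_A) -> bool:
    """Signal rule: ROR lower bound above 1, IC lower bound above 0, and
    at least ``min_a`` observed cases — all three jointly."""
    return ror025 > 1.0 and ic025 > 0.0 and n >= min_a


def _report_terms(report: CaseReport, level: str, mapping: PtSocMap | None) -> frozenset[str]:
    if level == "pt":
        return report.pts
    if level == "soc":
        if mapping is None:
            raise ValueError("SOC-level analysis needs a PT→SOC map")
        return frozenset(rollup_to_soc(report.pts, mapping))
    raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")


def build_tables(
    target_reports: Sequence[CaseReport],
    background_reports: Sequence[CaseReport],
    level: str = "pt",
    mapping: PtSocMap | None = None,
    counting: str = "report",
) -> list[ContingencyTable]:
    """One 2×2 table per term observed in the target cohort.

    Under report-level counting (the dominant FAERS convention, default)
    the counting unit is the report: a = target reports containing the
    term, b = remaining target reports, c/d likewise over background, so
    a+b+c+d equals the database size.  ``counting="pair"`` switches to
    (report, term)-pair units, where b and d count the cohorts' other
    term occurrences.  Terms with a = 0 are never emitted.
    """
    if counting not in ("report", "pair"):
        raise ValueError(f"counting must be 'report' or 'pair', got {counting!r}")
    # reports with no reaction terms carry no information here; they are
    # excluded from the denominators (tallied by the dedup audit)
    target = [r for r in target_reports if r.pts]
    background = [r for r in background_reports if r.pts]
    target_terms = [_report_terms(r, level, mapping) for r in target]
    background_terms = [_report_terms(r, level, mapping) for r in background]

    a_counts: Counter = Counter()
    for terms in target_terms:
        a_counts.update(terms)
    c_counts: Counter = Counter()
    for terms in background_terms:
        c_counts.update(terms)

    n_target = len(target)
    n_background = len(background)
    n_total = n_target + n_background
    if counting == "pair":
        target_pairs = sum(len(t) for t in target_terms)
        background_pairs = sum(len(t) for t in background_terms)

    soc_of: dict[str, str | None] = {}
    if level == "pt" and mapping is not None:
        for term in a_counts:
            soc_of[term] = mapping.get(term)

    tables: list[ContingencyTable] = []
    for term in sorted(a_counts):
        a = a_counts[term]
        c = c_counts.get(term, 0)
        if counting == "report":
            b = n_target - a
            d = n_background - c
        else:
            b = target_pairs - a
            d = background_pairs - c
        tables.append(
            ContingencyTable(
                term=term,
                level=level,
                a=a,
                b=b,
                c=c,
                d=d,
                n_drug=n_target,
                n_effect=a + c,
                n_total=n_total,
                soc=soc_of.get(term),
            )
        )
    return tables


def evaluate_table(
    t: ContingencyTable, z: float = DEFAULT_Z, min_a: int = DEFAULT_MIN_A
) -> SignalResult:
    """Full ROR + IC evaluation and signal flag for one table."""
    ror, lo, hi, corrected = ror_with_ci(t, z=z)
    ic, ic025, ic975 = ic_with_bounds(t)
    return SignalResult(
        level=t.level,
        term=t.term,
        n=t.n_observed,
        ror=ror,
        ror_ci_low=lo,
        ror_ci_high=hi,
        ic=ic,
        ic025=ic025,
        ic975=ic975,
        is_signal=flag_signal(t.n_observed, lo, ic025, min_a=min_a),
        soc=t.soc,
        zero_cell_corrected=corrected,
    )


def results_to_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "soc": r.soc if r.soc is not None else "",
                "n": r.n,
                "ror": r.ror,
                "ror025": r.ror_ci_low,
                "ror975": r.ror_ci_high,
                "ic": r.ic,
                "ic025": r.ic025,
                "ic975": r.ic975,
                "signal": r.is_signal,
                "zero_cell_corrected": r.zero_cell_corrected,
            }
            for r in results
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=[
                "term", "soc", "n", "ror", "ror025", "ror975",
                "ic", "ic025", "ic975", "signal", "zero_cell_corrected",
            ]
        )
    # SOC alphabetically, then descending case count within SOC
    return df.sort_values(["soc", "n", "term"], ascending=[True, False, True]).reset_index(drop=True)


def compute_signals(
    target_reports: Sequence[CaseReport],
    background_reports: Sequence[CaseReport],
    level: str = "pt",
    mapping: PtSocMap | None = None,
    min_a: int = DEFAULT_MIN_A,
    z: float = DEFAULT_Z,
    counting: str = "report",
) -> pd.DataFrame:
    """ROR + IC signal table for every term observed in the target cohort."""
    tables = build_tables(target_reports, background_reports, level=level, mapping=mapping, counting=counting)
    return results_to_frame(evaluate_table(t, z=z, min_a=min_a) for t in tables)


def combo_analysis(
    reports: Sequence[CaseReport],
    target_names: Iterable[str],
    ici_name_sets: Mapping[str, Iterable[str]],
    comparator_mode: str = "other-target-regimens",
    min_a: int = DEFAULT_MIN_A,
    z: float = DEFAULT_Z,
) -> pd.DataFrame:
    """Combination-therapy comparator analysis (ROR only).

    For each immune checkpoint inhibitor (ICI) the exposure group is the
    reports carrying the target drug as primary suspect together with
    that ICI in any role.  The comparator depends on ``comparator_mode``:

    - ``"other-target-regimens"`` (default): target-drug reports lacking
      that ICI, i.e. the combination versus the target drug in other
      regimens including monotherapy;
    - ``"other-ici-regimens"``: reports containing that ICI but not the
      target drug.

    The combo flag uses ROR025 > 1 and a ≥ ``min_a`` only (no IC).
    ICIs with zero co-exposed reports are skipped with a warning.
    """
    if comparator_mode not in ("other-target-regimens", "other-ici-regimens"):
        raise ValueError(f"unknown comparator_mode {comparator_mode!r}")
    targets = {normalize_drug_name(n) for n in target_names} - {""}
    rows: list[dict] = []
    for ici, names in ici_name_sets.items():
        ici_names = {normalize_drug_name(n) for n in names} - {""}
        exposure: list[CaseReport] = []
        comparator: list[CaseReport] = []
        for r in reports:
            if not r.pts:
                continue
            has_target = r.has_drug(targets, roles=("PS",))
            has_ici = r.has_drug(ici_names)
            if has_target and has_ici:
                exposure.append(r)
            elif comparator_mode == "other-target-regimens" and has_target:
                comparator.append(r)
            elif comparator_mode == "other-ici-regimens" and has_ici and not r.has_drug(targets):
                comparator.append(r)
        if not exposure:
            logger.warning("combo_analysis: no reports co-expose the target drug and %s; skipped", ici)
            continue
        for t in build_tables(exposure, comparator, level="pt"):
            ror, lo, hi, corrected = ror_with_ci(t, z=z)
            rows.append(
                {
                    "ici": ici,
                    "term": t.term,
                    "n": t.a,
                    "ror": ror,
                    "ror025": lo,
                    "ror975": hi,
                    "signal": lo > 1.0 and t.a >= min_a,
                    "zero_cell_corrected": corrected,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["ici", "term", "n", "ror", "ror025", "ror975", "signal", "zero_cell_corrected"],
    )
    if df.empty:
        return df
    return df.sort_values(["ici", "n", "term"], ascending=[True, False, True]).reset_index(drop=True)
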