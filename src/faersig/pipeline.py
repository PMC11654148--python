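"""End-to-end orchestration: parse → dedup → cohort → signals → combo → demographics.

``run_full_analysis`` drives the whole workflow over a directory of
quarterly files and writes one delimited table per analysis plus a run
manifest echoing the resolved configuration and per-stage counts, so a
run is reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from faersig.demographics import summarize
from faersig.faers_io import Dialect, cohort_primary_suspect, deduplicate, read_quarter
from faersig.meddra import load_pt_soc_map
from faersig.signal_stats import combo_analysis, compute_signals

logger = logging.getLogger(__name__)

_QUARTER_RE = re.compile(r"^DEMO(?P<suffix>.+)\.(txt|TXT)$")


class RunConfig(BaseModel):
    """Resolved configuration of one analysis run."""

    input_dir: str
    output_dir: str
    target_drug_names: list[str]
    ici_groups: dict[str, list[str]] = Field(default_factory=dict)
    pt_soc_map_path: str
    exclusion_terms_path: Optional[str] = None
    min_a: int = 4
    z: float = 1.96
    comparator_mode: str = "other-target-regimens"
    counting: str = "report"


def discover_quarters(input_dir: str | Path) -> list[dict[str, Path]]:
    """Find quarter file sets by the DEMO<suffix>.txt naming convention."""
    input_dir = Path(input_dir)
    sets = []
    for demo in sorted(input_dir.glob("DEMO*.txt")):
        m = _QUARTER_RE.match(demo.name)
        if not m:
            continue
        suffix = m.group("suffix")
        paths = {"demo": demo}
        ok = True
        for table in ("drug", "reac", "outc"):
            p = input_dir / f"{table.upper()}{suffix}.txt"
            if not p.exists():
                logger.warning("quarter %s missing %s table; skipped", suffix, table.upper())
                ok = False
                break
            paths[table] = p
        if ok:
            sets.append(paths)
    if not sets:
        raise FileNotFoundError(f"no complete quarter file sets under {input_dir}")
    return sets


def load_exclusion_terms(path: str | Path | None) -> set[str]:
    """One term per line, case-insensitive; '#' comments allowed."""
    if path is None:
        return set()
    terms = set()
    for line in Path(path).read_text().splitlines():
        term = line.split("#", 1)[0].strip().upper()
        if term:
            terms.add(term)
    return terms


def run_full_analysis(config: RunConfig) -> dict[str, object]:
    """Run every stage and write the result bundle to ``output_dir``.

    Outputs: ``soc_signals.tsv``, ``pt_signals.tsv`` (exclusion-filtered),
    ``pt_signals_unfiltered.tsv`` (audit copy), ``combo_signals.tsv``,
    ``demographics.tsv``, ``dedup_audit.tsv`` and ``run_manifest.json``.
    Any stage failure raises with the stage name prefixed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("parse")
        quarter_sets = discover_quarters(config.input_dir)
        quarters = [
            read_quarter(qs["demo"], qs["drug"], qs["reac"], qs["outc"], Dialect())
            for qs in quarter_sets
        ]
        counts["quarters_read"] = len(quarters)
        counts["demo_rows_read"] = int(sum(len(q.demo) for q in quarters))
        counts["malformed_rows"] = {
            t: int(sum(q.malformed.get(t, 0) for q in quarters)) for t in ("demo", "drug", "reac", "outc")
        }

        name = stage("map")
        mapping = load_pt_soc_map(config.pt_soc_map_path)
        counts["pt_soc_entries"] = len(mapping)

        name = stage("dedup")
        reports, audit = deduplicate(quarters)
        counts["cases_out"] = audit.cases_out
        counts["duplicates_removed"] = audit.duplicates_removed
        audit.to_frame().to_csv(out_dir / "dedup_audit.tsv", sep="\t", index=False)

        name = stage("cohort")
        target, background = cohort_primary_suspect(reports, config.target_drug_names)
        counts["target_reports"] = len(target)
        counts["background_reports"] = len(background)

        name = stage("soc_signals")
        soc_df = compute_signals(
            target, background, level="soc", mapping=mapping,
            min_a=config.min_a, z=config.z, counting=config.counting,
        )
        soc_df.to_csv(out_dir / "soc_signals.tsv", sep="\t", index=False)
        counts["soc_terms_tested"] = int(len(soc_df))
        counts["soc_signals"] = int(soc_df["signal"].sum()) if len(soc_df) else 0

        name = stage("pt_signals")
        pt_df = compute_signals(
            target, background, level="pt", mapping=mapping,
            min_a=config.min_a, z=config.z, counting=config.counting,
        )
        pt_df.to_csv(out_dir / "pt_signals_unfiltered.tsv", sep="\t", index=False)
        exclusions = load_exclusion_terms(config.exclusion_terms_path)
        filtered = pt_df[~pt_df["term"].str.upper().isin(exclusions)].reset_index(drop=True)
        filtered.to_csv(out_dir / "pt_signals.tsv", sep="\t", index=False)
        counts["pt_terms_tested"] = int(len(pt_df))
        counts["pt_terms_excluded"] = int(len(pt_df) - len(filtered))
        counts["pt_signals"] = int(filtered["signal"].sum()) if len(filtered) else 0

        name = stage("combo")
        combo_df = combo_analysis(
            reports, config.target_drug_names, config.ici_groups,
            comparator_mode=config.comparator_mode, min_a=config.min_a, z=config.z,
        )
        combo_df.to_csv(out_dir / "combo_signals.tsv", sep="\t", index=False)
        counts["combo_rows"] = int(len(combo_df))

        name = stage("demographics")
        demo_summary = summarize(target)
        demo_summary.to_frame().to_csv(out_dir / "demographics.tsv", sep="\t", index=False)
        counts["demographics_total"] = demo_summary.total
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest = {
        "config": config.model_dump(),
        "counts": counts,
        "limitations": "no multiple-testing adjustment; signal criteria only",
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "soc": soc_df,
        "pt": filtered,
        "pt_unfiltered": pt_df,
        "combo": combo_df,
        "demographics": demo_summary,
        "dedup_audit": audit,
        "manifest": manifest,
    }
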