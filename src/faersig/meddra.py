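"""Preferred-term → system-organ-class rollup.

MedDRA itself is licensed and not distributable, so the mapping is a
user-supplied two-column table following the primary-SOC convention
(each PT belongs to exactly one SOC).  Unmapped PTs are routed to the
sentinel SOC ``"UNMAPPED"`` so that SOC-level tallies never silently
lose reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

UNMAPPED_SOC = "UNMAPPED"


@dataclass
class PtSocMap:
    """Case-insensitive PT → SOC lookup (primary SOC convention)."""

    entries: dict[str, str]
    version_label: str = ""
    unmapped_seen: Counter = field(default_factory=Counter, repr=False)

    def __post_init__(self) -> None:
        self.entries = {pt.strip().upper(): soc for pt, soc in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return pt.strip().upper() in self.entries

    def get(self, pt: str) -> str | None:
        return self.entries.get(pt.strip().upper())


def load_pt_soc_map(path: str | Path, delimiter: str | None = None, version_label: str = "") -> PtSocMap:
    """Load a delimited two-column (pt, soc) file with a header row.

    Duplicate PT rows with the same SOC collapse to one entry; a PT
    appearing with conflicting SOCs is a hard error listing every
    conflict.  The delimiter is sniffed when not given.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("pt", "soc"):
        if col not in df.columns:
            raise ValueError(f"{path}: PT→SOC map must have columns 'pt' and 'soc'")
    if df.empty:
        raise ValueError(f"{path}: PT→SOC map is empty")
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    for pt, soc in df[["pt", "soc"]].itertuples(index=False):
        key = str(pt).strip().upper()
        soc = str(soc).strip()
        if key in entries and entries[key] != soc:
            conflicts.append(f"{key}: {entries[key]!r} vs {soc!r}")
        else:
            entries[key] = soc
    if conflicts:
        raise ValueError(f"{path}: conflicting SOC assignments: " + "; ".join(sorted(set(conflicts))))
    return PtSocMap(entries=entries, version_label=version_label)


def rollup_to_soc(report_pts: Iterable[str], mapping: PtSocMap) -> set[str]:
    """Distinct SOCs covering a report's PTs (set semantics: a report
    contributes once per SOC no matter how many of its PTs land there).

    Unmapped PTs map to ``UNMAPPED`` and are tallied on
    ``mapping.unmapped_seen``.
    """
    socs: set[str] = set()
    for pt in report_pts:
        soc = mapping.get(pt)
        if soc is None:
            mapping.unmapped_seen[pt.strip().upper()] += 1
            soc = UNMAPPED_SOC
        socs.add(soc)
    return socs
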