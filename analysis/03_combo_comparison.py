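"""Combination-therapy comparator analysis under both comparator choices.

For each ICI co-reported with the target drug, computes the ROR of the
combination's adverse events against (a) the target drug in other
regimens and (b) other ICI-containing regimens, and writes both tables.
Since the generator plants no combination-specific effect, flags here
reflect the null behaviour of the combo rule (ROR025 > 1, n ≥ 4).
"""

from __future__ import annotations

from common import DB_CONFIG, RESULTS, ensure_database

from faersig.faers_io import deduplicate, read_quarter
from faersig.pipeline import discover_quarters
from faersig.signal_stats import combo_analysis

db = ensure_database()
quarters = [read_quarter(q["demo"], q["drug"], q["reac"], q["outc"]) for q in discover_quarters(db)]
reports, _ = deduplicate(quarters)

for mode in ("other-target-regimens", "other-ici-regimens"):
    df = combo_analysis(
        reports, [DB_CONFIG.target_drug_name],
        {ici: [ici] for ici in DB_CONFIG.ici_probs}, comparator_mode=mode,
    )
    out = RESULTS / f"combo_{mode.replace('-', '_')}.tsv"
    df.to_csv(out, sep="\t", index=False)
    n_flagged = int(df["signal"].sum()) if len(df) else 0
    print(f"{mode}: {len(df)} (ICI, PT) pairs tested, {n_flagged} flagged -> {out}")
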