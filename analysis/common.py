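"""Shared setup for the analysis drivers: one reference synthetic database.

The database is generated once under ``scratch/synthetic_db`` (large,
regenerable, not part of the deliverable) using the generator defaults:
100,000 reports, 1% target-drug exposure, one preferred term planted at
reporting odds ratio 5 over a 2% baseline, 20% duplicated cases.
"""

from __future__ import annotations

from pathlib import Path

from faersig.synthetic import SyntheticConfig, generate

ROOT = Path(__file__).resolve().parent.parent
DB_DIR = ROOT / "scratch" / "synthetic_db"
RESULTS = ROOT / "results"

DB_CONFIG = SyntheticConfig(seed=20260927)


def ensure_database() -> Path:
    """Generate the reference database if it is not already on disk."""
    if not (DB_DIR / "truth.tsv").exists():
        print(f"generating reference database under {DB_DIR} ...")
        generate(DB_CONFIG, DB_DIR)
    return DB_DIR
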