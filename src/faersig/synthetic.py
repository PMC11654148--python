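"""Seeded generator of FAERS-shaped databases with planted signals.

The generator emulates the structural features of a spontaneous
reporting database that the pipeline must survive: the multi-table
quarterly layout, cases re-submitted in several versions (with earlier
versions carrying a perturbed reaction list, so using anything but the
latest version is detectably wrong), multi-drug and multi-reaction
reports, role codes, outcome codes, and per-field missingness.  It does
NOT model reporting trends over time, drug interactions or a realistic
MedDRA vocabulary — the ontology is a toy PT/SOC grid.

Signals are planted multiplicatively on the odds scale: a planted
preferred term's baseline reporting odds p/(1−p) are multiplied by λ
within target-drug reports, so λ IS the design reporting odds ratio of
the planted pair (and ≈ the rate ratio for rare terms), giving
closed-form expectations for tests.

Fixed config + seed ⇒ byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from faersig.faers_io import Dialect, RawQuarter, write_quarter
from faersig.meddra import PtSocMap

_COUNTRIES = ("JP", "DE", "FR", "GB", "CA", "AU")
_OUTCOME_CODES = ("DE", "LT", "HO", "DS", "OT", "CA", "RI")


class SyntheticConfig(BaseModel):
    """Generator parameters.  Defaults are the reference study
    conditions used throughout the test suite."""

    n_reports: int = Field(default=100_000, ge=1)
    n_background_drugs: int = Field(default=20, ge=1)
    n_pts: int = Field(default=50, ge=1)
    n_socs: int = Field(default=20, ge=1)
    n_quarters: int = Field(default=4, ge=1)
    start_year: int = 2020
    target_drug_name: str = "DRUG_TARGET"
    target_drug_prob: float = Field(default=0.01, ge=0.0, le=1.0)
    baseline_pt_prob: float = Field(default=0.02, ge=0.0, le=1.0)
    background_pt_probs: Optional[list[float]] = None  # per-PT override
    planted: dict[str, float] = Field(default_factory=lambda: {"PT_0001": 5.0})
    ici_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "PEMBROLIZUMAB": 0.05,
            "NIVOLUMAB": 0.04,
            "IPILIMUMAB": 0.03,
            "ATEZOLIZUMAB": 0.02,
        }
    )
    duplication_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    missing_rates: dict[str, float] = Field(
        default_factory=lambda: {"sex": 0.32, "age": 0.46, "country": 0.001, "fda_dt": 0.0}
    )
    # loosely shaped like the outcome mix of a real oncology cohort
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {"DE": 0.10, "LT": 0.02, "HO": 0.21, "DS": 0.01, "OT": 0.38, "none": 0.28}
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for pt, lam in self.planted.items():
            if lam <= 0:
                raise ValueError(f"planted λ must be > 0 (got {lam} for {pt})")
        for name, p in {**self.ici_probs, **self.missing_rates}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {name}={p}")
        if self.background_pt_probs is not None and len(self.background_pt_probs) != self.n_pts:
            raise ValueError("background_pt_probs must have length n_pts")
        return self

    def pt_names(self) -> list[str]:
        return [f"PT_{i + 1:04d}" for i in range(self.n_pts)]

    def soc_names(self) -> list[str]:
        return [f"SOC_{i + 1:02d}" for i in range(self.n_socs)]

    def pt_soc_frame(self) -> pd.DataFrame:
        socs = self.soc_names()
        return pd.DataFrame(
            {"pt": self.pt_names(), "soc": [socs[i % self.n_socs] for i in range(self.n_pts)]}
        )

    def pt_soc_map(self) -> PtSocMap:
        df = self.pt_soc_frame()
        return PtSocMap(entries=dict(zip(df["pt"], df["soc"])), version_label="synthetic-toy")


@dataclass
class SimulationResult:
    """In-memory output of one simulation: quarter tables plus ground truth."""

    quarters: list[RawQuarter]
    truth: pd.DataFrame  # per PT: planted_lambda and realized a/b/c/d + marginals
    pt_soc: PtSocMap
    config: SyntheticConfig


def _quarter_suffix(config: SyntheticConfig, q: int) -> str:
    year = config.start_year + q // 4
    return f"{year % 100:02d}Q{q % 4 + 1}"


def _fda_dates(rng: np.random.Generator, config: SyntheticConfig, quarter: np.ndarray) -> np.ndarray:
    year = config.start_year + quarter // 4
    month = 3 * (quarter % 4) + rng.integers(1, 4, size=len(quarter))
    day = rng.integers(1, 29, size=len(quarter))
    return np.char.add(
        np.char.add(year.astype(str), np.char.zfill(month.astype(str), 2)),
        np.char.zfill(day.astype(str), 2),
    )


def simulate_quarters(config: SyntheticConfig) -> SimulationResult:
    """Draw one synthetic database under ``config``.

    Every report gets at least one reaction (empty draws are resampled).
    Duplicated cases are emitted in 2–4 versions whose earlier versions
    drop one reaction; the final version is the ground truth, and the
    truth table records the realized 2×2 counts of every PT computed
    from final versions only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pts = config.pt_names()

    target = rng.random(n) < config.target_drug_prob
    if target.sum() < 5:
        import warnings

        warnings.warn(
            f"only {int(target.sum())} target-drug reports realized; disproportionality will be unstable",
            stacklevel=2,
        )

    p = (
        np.asarray(config.background_pt_probs, dtype=float)
        if config.background_pt_probs is not None
        else np.full(config.n_pts, config.baseline_pt_prob)
    )
    probs = np.broadcast_to(p, (n, config.n_pts)).copy()
    pt_index = {name: i for i, name in enumerate(pts)}
    lam = np.ones(config.n_pts)
    for pt, l in config.planted.items():
        if pt not in pt_index:
            raise ValueError(f"planted PT {pt!r} not in the generated vocabulary")
        j = pt_index[pt]
        lam[j] = l
        odds = l * p[j] / (1.0 - p[j])  # λ multiplies the reporting odds
        probs[target, j] = odds / (1.0 + odds)

    mat = rng.random((n, config.n_pts)) < probs
    empty = ~mat.any(axis=1)
    while empty.any():  # resample until every report has >= 1 reaction
        idx = np.flatnonzero(empty)
        mat[idx] = rng.random((len(idx), config.n_pts)) < probs[idx]
        empty[idx] = ~mat[idx].any(axis=1)

    # ground truth 2x2 from final versions (report-level counting)
    a = mat[target].sum(axis=0).astype(int)
    c = mat[~target].sum(axis=0).astype(int)
    n_target = int(target.sum())
    truth = pd.DataFrame(
        {
            "term": pts,
            "planted_lambda": lam,
            "a": a,
            "b": n_target - a,
            "c": c,
            "d": (n - n_target) - c,
            "n_drug": n_target,
            "n_effect": a + c,
            "n_total": n,
        }
    )

    # --- demographics -------------------------------------------------
    caseid = np.array([f"{10_000_000 + i}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.48, "F", "M").astype(object)
    sex[rng.random(n) < config.missing_rates.get("sex", 0.0)] = None

    age_years = np.clip(rng.normal(61.0, 16.0, size=n), 0.2, 99.0)
    unit_pick = rng.random(n)
    age_cod = np.where(unit_pick < 0.90, "YR", np.where(unit_pick < 0.95, "DEC", "MON")).astype(object)
    age_val = np.round(
        np.where(age_cod == "YR", age_years, np.where(age_cod == "DEC", age_years / 10.0, age_years * 12.0)),
        2,
    ).astype(object)
    age_missing = rng.random(n) < config.missing_rates.get("age", 0.0)
    age_val[age_missing] = None
    age_cod[age_missing] = None

    country = np.where(
        rng.random(n) < 0.78, "US", rng.choice(_COUNTRIES, size=n)
    ).astype(object)
    country[rng.random(n) < config.missing_rates.get("country", 0.0)] = None

    # --- outcomes -----------------------------------------------------
    oc_labels = list(config.outcome_probs)
    oc_p = np.array([config.outcome_probs[k] for k in oc_labels], dtype=float)
    oc_p = oc_p / oc_p.sum()
    primary_outcome = rng.choice(oc_labels, size=n, p=oc_p).astype(object)
    extra_mask = rng.random(n) < 0.10
    extra_outcome = rng.choice(_OUTCOME_CODES, size=n).astype(object)

    # --- versions & quarters -----------------------------------------
    dup = rng.random(n) < config.duplication_rate
    n_versions = np.where(dup, rng.integers(2, 5, size=n), 1)
    base_quarter = rng.integers(0, config.n_quarters, size=n)

    rep_idx = np.repeat(np.arange(n), n_versions)  # one row per emitted version
    version = np.concatenate([np.arange(1, k + 1) for k in n_versions])
    is_final = version == n_versions[rep_idx]
    quarter = np.clip(base_quarter[rep_idx] - (n_versions[rep_idx] - version), 0, config.n_quarters - 1)
    primaryid = np.array([f"{cid}{v}" for cid, v in zip(caseid[rep_idx], version)])

    fda_dt = _fda_dates(rng, config, quarter).astype(object)
    fda_dt[rng.random(len(fda_dt)) < config.missing_rates.get("fda_dt", 0.0)] = None

    demo_all = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid[rep_idx],
            "caseversion": version.astype(str),
            "fda_dt": fda_dt,
            "sex": sex[rep_idx],
            "age": [None if v is None else str(v) for v in age_val[rep_idx]],
            "age_cod": age_cod[rep_idx],
            "reporter_country": country[rep_idx],
            "_q": quarter,
        }
    )

    # --- drug rows (per report, replicated per version) ---------------
    bg_names = np.array([f"DRUG_BG_{i + 1:02d}" for i in range(config.n_background_drugs)])
    drug_rows: list[pd.DataFrame] = []

    t_idx = np.flatnonzero(target)
    drug_rows.append(
        pd.DataFrame(
            {
                "report": t_idx,
                "drugname": config.target_drug_name,
                "prod_ai": config.target_drug_name,
                "role_cod": "PS",
            }
        )
    )
    b_idx = np.flatnonzero(~target)
    drug_rows.append(
        pd.DataFrame(
            {
                "report": b_idx,
                "drugname": bg_names[rng.integers(0, len(bg_names), size=len(b_idx))],
                "prod_ai": None,
                "role_cod": "PS",
            }
        )
    )
    for ici, prob in config.ici_probs.items():
        co = t_idx[rng.random(len(t_idx)) < prob]
        if len(co):
            drug_rows.append(
                pd.DataFrame({"report": co, "drugname": ici, "prod_ai": None, "role_cod": "C"})
            )
        # ICIs also circulate in the background (non-target regimens)
        bg_co = b_idx[rng.random(len(b_idx)) < prob]
        if len(bg_co):
            drug_rows.append(
                pd.DataFrame({"report": bg_co, "drugname": ici, "prod_ai": None, "role_cod": "C"})
            )
    n_extra = rng.integers(0, 3, size=n)
    extra_rep = np.repeat(np.arange(n), n_extra)
    if len(extra_rep):
        drug_rows.append(
            pd.DataFrame(
                {
                    "report": extra_rep,
                    "drugname": bg_names[rng.integers(0, len(bg_names), size=len(extra_rep))],
                    "prod_ai": None,
                    "role_cod": rng.choice(["C", "SS", "I"], size=len(extra_rep), p=[0.8, 0.15, 0.05]),
                }
            )
        )
    # target drug as a concomitant on a few background reports: these must
    # stay in the background cohort (primary-suspect rule)
    conc = b_idx[rng.random(len(b_idx)) < 0.002]
    if len(conc):
        drug_rows.append(
            pd.DataFrame(
                {"report": conc, "drugname": config.target_drug_name, "prod_ai": None, "role_cod": "C"}
            )
        )
    drug_per_report = pd.concat(drug_rows, ignore_index=True).sort_values(
        ["report", "role_cod", "drugname"], kind="mergesort"
    )
    drug_per_report["drug_seq"] = drug_per_report.groupby("report").cumcount() + 1

    # --- reaction rows -------------------------------------------------
    rrow, rcol = np.nonzero(mat)
    pt_count = mat.sum(axis=1)
    # last (highest-index) PT per report; dropped from non-final versions
    last_pt = np.full(n, -1)
    np.maximum.at(last_pt, rrow, rcol)

    reac_per_report = pd.DataFrame({"report": rrow, "pt_idx": rcol})

    # --- outcome rows --------------------------------------------------
    oc_rows = [pd.DataFrame({"report": np.flatnonzero(primary_outcome != "none"),
                             "outc_cod": primary_outcome[primary_outcome != "none"]})]
    oc_rows.append(pd.DataFrame({"report": np.flatnonzero(extra_mask), "outc_cod": extra_outcome[extra_mask]}))
    outc_per_report = pd.concat(oc_rows, ignore_index=True).drop_duplicates().sort_values(
        ["report", "outc_cod"], kind="mergesort"
    )

    # --- expand per version and split into quarters --------------------
    pts_arr = np.array(pts)
    version_meta = pd.DataFrame(
        {"report": rep_idx, "primaryid": primaryid, "_q": quarter, "_final": is_final}
    )

    def _attach(per_report: pd.DataFrame) -> pd.DataFrame:
        return version_meta.merge(per_report, on="report", how="inner")

    drug_v = _attach(drug_per_report)
    outc_v = _attach(outc_per_report)
    reac_v = _attach(reac_per_report)
    # non-final versions drop the highest-index PT when the report has >1
    droppable = (~reac_v["_final"].to_numpy()) & (
        reac_v["pt_idx"].to_numpy() == last_pt[reac_v["report"].to_numpy()]
    ) & (pt_count[reac_v["report"].to_numpy()] > 1)
    reac_v = reac_v.loc[~droppable]
    reac_v = reac_v.assign(pt=pts_arr[reac_v["pt_idx"].to_numpy()])

    quarters: list[RawQuarter] = []
    for q in range(config.n_quarters):
        demo_q = demo_all[demo_all["_q"] == q].drop(columns="_q").reset_index(drop=True)
        drug_q = drug_v[drug_v["_q"] == q]
        reac_q = reac_v[reac_v["_q"] == q]
        outc_q = outc_v[outc_v["_q"] == q]
        quarters.append(
            RawQuarter(
                demo=demo_q.astype(object).where(pd.notna(demo_q), pd.NA),
                drug=drug_q[["primaryid", "drugname", "role_cod", "drug_seq"]]
                .assign(drug_seq=lambda d: d["drug_seq"].astype(str), prod_ai=drug_q["prod_ai"])
                [["primaryid", "drugname", "role_cod", "drug_seq", "prod_ai"]]
                .astype(object)
                .where(pd.notna, pd.NA)
                .reset_index(drop=True),
                reac=reac_q[["primaryid", "pt"]].astype(object).reset_index(drop=True),
                outc=outc_q[["primaryid", "outc_cod"]].astype(object).reset_index(drop=True),
            )
        )

    return SimulationResult(quarters=quarters, truth=truth, pt_soc=config.pt_soc_map(), config=config)


def generate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, object]:
    """Simulate and write a database in the FAERS ASCII dialect.

    Writes DEMO/DRUG/REAC/OUTC files per quarter, the toy PT→SOC map
    (``pt_soc_map.tsv``) and the ground-truth table (``truth.tsv``).
    Returns a manifest of written paths plus the in-memory result.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_quarters(config)
    paths: dict[str, object] = {"quarters": []}
    for q, quarter in enumerate(sim.quarters):
        suffix = _quarter_suffix(config, q)
        paths["quarters"].append(write_quarter(quarter, out_dir, suffix, Dialect()))
    map_path = out_dir / "pt_soc_map.tsv"
    config.pt_soc_frame().to_csv(map_path, sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    paths["pt_soc_map"] = map_path
    paths["truth"] = truth_path
    paths["result"] = sim
    return paths
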