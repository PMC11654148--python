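# faersig

Disproportionality signal detection on FAERS-style spontaneous report
databases.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect individual case safety reports (ICSRs): one
patient case with its drugs (each tagged with a role code — PS primary
suspect, SS secondary suspect, C concomitant, I interacting), its
adverse events coded as MedDRA preferred terms (PTs), demographics and
outcome codes. Cases arrive as multiple follow-up versions across
quarterly extracts, so any analysis must first reduce the database to
one report per case. `faersig` implements that workflow end to end for
pharmacoepidemiologists who want a reproducible, testable pipeline:

1. **Parse** the quarterly `$`-delimited DEMO/DRUG/REAC/OUTC tables
   (tolerating the older LAERS column subset).
2. **Deduplicate** by retaining the highest `caseversion` per `caseid`
   (ties: latest `fda_dt`, then largest `primaryid`).
3. **Cohort** the reports naming a target drug as primary suspect.
4. **Detect signals** at PT and system-organ-class (SOC) level with two
   standard disproportionality statistics on the report-level 2×2 table
   (a = target reports with the event, b = without, c/d = the same over
   the background):

   - reporting odds ratio, ROR = ad/bc, with 95% CI
     ROR·exp(±1.96·√(1/a + 1/b + 1/c + 1/d));
   - BCPNN information component,
     IC = log₂((N_obs + 0.5)/(N_exp + 0.5)) with
     N_exp = N_drug·N_effect/N_total and closed-form credibility bounds
     IC025 = IC − 3.3(N_obs+0.5)^−1/2 − 2(N_obs+0.5)^−3/2,
     IC975 = IC + 2.4(N_obs+0.5)^−1/2 − 0.5(N_obs+0.5)^−3/2.

   A pair is flagged as a signal when ROR025 > 1, IC025 > 0 and a ≥ 4.
5. **Combination analysis**: for each immune checkpoint inhibitor (ICI)
   co-reported with the target drug, the ROR of the combination against
   a configurable comparator (flag: ROR025 > 1 and a ≥ 4).
6. **Demographics**: a descriptive cohort table (sex, country,
   reporting year, age bins, most-severe outcome).

A seeded synthetic-data module generates FAERS-shaped multi-quarter
databases with associations planted at a known reporting odds ratio, so
every stage is testable offline; MedDRA is licensed and not bundled —
PT→SOC mapping is a user-supplied two-column table (the generator
fabricates a toy one). Flagged pairs are reporting disproportionalities,
i.e. hypotheses — not causal claims.

## Worked example

```bash
faersig simulate --out db --seed 5
cat > run.yaml <<EOF
input_dir: db
output_dir: out
target_drug_names: [DRUG_TARGET]
ici_groups:
  NIVOLUMAB: [NIVOLUMAB]
pt_soc_map_path: db/pt_soc_map.tsv
EOF
faersig analyze --config run.yaml
```

prints

```
reports after dedup: 100000 (removed 40285 duplicate versions)
target cohort: 1038  background: 98962
SOC signals: 1 of 20 terms
PT signals: 1 of 50 terms
outputs in out
```

The simulated database contains 100,000 cases (20% submitted in 2–4
versions; the stale versions are removed by deduplication), 1% of which
list the target drug as primary suspect, and one preferred term
(`PT_0001`) planted at a design reporting odds ratio of 5 over its 2%
baseline. The analysis recovers exactly that one planted term — at seed
20260927, ROR 5.52 [4.64, 6.58] and IC 2.20 [1.93, 2.39] on n = 154
cases — and its SOC, with every other term correctly left unflagged.
Full result tables (`pt_signals.tsv`, `soc_signals.tsv`,
`combo_signals.tsv`, `demographics.tsv`, dedup audit and run manifest)
land in the output directory.

The same steps are available as a narrated sequence under `analysis/`
(`01_simulate.py` … `05_parameter_recovery.py`), writing small summary
tables to `results/`.

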