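# Methods

## The statistical model

`faersig` performs frequentist and Bayesian disproportionality analysis
on a spontaneous reporting database. After deduplication the database
is a set of N_total reports; for a drug–event pair the report-level
2×2 table is

|              | event | no event |
|--------------|-------|----------|
| target drug  | a     | b        |
| background   | c     | d        |

with marginals N_drug = a+b (reports naming the target drug as primary
suspect), N_effect = a+c, and a+b+c+d = N_total. Two statistics are
computed per term:

- **ROR** = ad/bc with 95% CI = ROR·exp(±z·√(1/a+1/b+1/c+1/d)),
  z = 1.96 by default (configurable for sensitivity analysis). Being an
  odds ratio, it is unaffected by non-selective under-reporting of the
  drug or of the event.
- **Information component** (the closed-form BCPNN approximation):
  IC = log₂((N_obs+0.5)/(N_exp+0.5)) with N_obs = a and
  N_exp = N_drug·N_effect/N_total, and credibility bounds
  IC025 = IC − 3.3(N_obs+0.5)^−1/2 − 2(N_obs+0.5)^−3/2,
  IC975 = IC + 2.4(N_obs+0.5)^−1/2 − 0.5(N_obs+0.5)^−3/2.
  The +0.5 shrinkage is part of the estimator; no further continuity
  handling is needed even at N_obs = 0.

A term is a **signal** when ROR025 > 1, IC025 > 0 and a ≥ 4 (all
inequalities strict; `min_a` configurable). The combination-therapy
analysis uses ROR only, flagging on ROR025 > 1 and a ≥ 4. No
multiple-testing adjustment is applied — the joint ROR+IC+count rule is
the only filter, and this is recorded in every run manifest as a known
limitation. Signals are reporting disproportionalities and generate
hypotheses only.

## Counting conventions and design choices

- **Counting unit is the report.** A report with three PTs in one SOC
  contributes 1 to that SOC's a (set semantics), and b = N_drug − a, so
  a+b+c+d = N_total. This is the dominant FAERS-ROR convention; a
  (report, term)-pair counting mode is available via
  `counting="pair"` for comparison.
- **Deduplication** keeps the maximum `caseversion` per `caseid` across
  all quarters. Ties on (caseid, caseversion) are broken by the latest
  `fda_dt`, then the lexicographically largest `primaryid` —
  deterministic and aligned with the most-recent-version intent. The
  rule is applied uniformly to all quarters, including pre-2012
  LAERS-format ones. Reports with zero reactions after deduplication
  are excluded from disproportionality denominators but counted in the
  audit.
- **Cohorting** requires the target drug with role code PS (primary
  suspect). Matching is exact after normalization (trim, collapse
  whitespace, uppercase) against `drugname` and `prod_ai`, driven by a
  user-supplied synonym list; no fuzzy matching, by design —
  reproducibility over recall.
- **Zero cells** in the ROR get the Haldane–Anscombe +0.5 correction on
  all four cells, with a `zero_cell_corrected` flag in the output. An
  all-zero table is a hard error. The IC needs no correction.
- **Combination comparator.** Two defensible comparators exist for the
  target+ICI exposure group: the target drug in other regimens
  (including monotherapy), and other ICI-containing regimens. The
  default `comparator_mode="other-target-regimens"` asks whether the
  combination changes the target drug's profile;
  `"other-ici-regimens"` asks whether the combination stands out among
  ICI regimens. Both are implemented; neither is asserted as canonical.
- **PT→SOC rollup** follows the primary-SOC convention (one SOC per
  PT), case-insensitive, with conflicting map rows a hard error and
  unmapped PTs routed to the sentinel SOC `UNMAPPED` and audited. No
  LLT handling, SMQs or multi-axial secondary SOCs.
- **Demographics.** Outcome codes are collapsed per report to the most
  severe (Death > Life-threatening > Hospitalization > Disability >
  Other serious; CA/RI/OT fold into "Other serious events") so that
  each section of the summary partitions the cohort exactly. Age bins
  are half-open ([45, 60) is "45 ~ 59 years"). Reporting year comes
  from the FDA receipt date of the retained version; country is
  collapsed to USA / Rest of the world / Unknown. Percentages are
  rounded to one decimal of the section total.
- **Exclusion lists.** Screening out event terms that reflect the
  disease rather than the drug (e.g. progression terms) is inherently a
  judgment call; the pipeline takes it only as a user-editable term
  list applied to the final PT table, with the unfiltered table always
  written alongside for audit.

## The synthetic-data generator

The generator emulates the features of FAERS that the pipeline must
survive: the multi-table `$`-delimited quarterly layout, multi-version
cases (duplication rate 0.2 by default, 2–4 versions, with earlier
versions dropping one reaction so that failing to deduplicate — or
keeping the wrong version — is detectable), multi-drug reports with
role codes, multi-PT reports, outcome codes, and per-field missingness.

Reference defaults (one set of study conditions, fixed): 100,000
reports; target-drug exposure probability 0.01 (primary suspect); 50
PTs over 20 toy SOCs, each PT at baseline reporting probability 0.02;
one PT planted at λ = 5; ICI co-exposure probabilities 2–5%; outcome
mix 10% death / 2% life-threatening / 21% hospitalization / 1%
disability / 38% other / 28% none; missingness 32% sex, 46% age, 0.1%
country, echoing the unknown-fractions of published FAERS oncology
cohorts.

**Planting is multiplicative on the odds scale**: a planted term's
baseline reporting odds p/(1−p) are multiplied by λ within target-drug
reports. This makes λ exactly the design reporting odds ratio of the
planted pair — the estimand the ROR estimates — rather than a rate
ratio that only approximates it for rare terms; at p = 0.02 the
distinction is a ~9% bias that matters when checking estimator
concentration. Every report is guaranteed at least one reaction by
resampling empty draws, which inflates all reporting probabilities by
the same conditioning factor and leaves odds ratios essentially
untouched (verified empirically by the null-generator test).

What the generator does **not** model: reporting trends over time, drug
interactions, correlated events, realistic MedDRA vocabulary, free-text
drug-name noise, or probabilistic duplicates across caseids. Passing
tests therefore demonstrate correctness of the accounting and the
statistics under a clean generative model — not robustness to the
messiness of real FAERS text fields, which the normalization and
synonym-list design deliberately pushes to the user.

## Numerical and degenerate-input behaviour

- All formulas are evaluated in double precision as closed forms; the
  test suite checks agreement with an independently coded direct
  evaluator to 1e-12 relative error on random tables.
- `convert_age` is total: unparseable values, unknown unit codes and
  results outside [0, 150] years become missing (a missing unit code
  with a present age is read as years).
- Empty cohorts, empty exclusion lists, terms absent from the map, and
  ICIs with no co-exposed reports all degrade gracefully (empty
  outputs, sentinel SOC, skip-with-warning respectively); missing
  mandatory columns and conflicting map rows fail hard with the file
  and column named.
- Result tables are sorted by SOC then descending case count;
  re-running the pipeline on the same inputs is byte-identical.

## Problem sizes used in the checks

The recovery study runs the full in-memory pipeline on 20 seeded
databases of 100,000 reports each (≈ 4 s per seed), checking that the
planted term's ROR falls in [4, 6] and is flagged in ≥ 95% of seeds and
that null terms are flagged at ≤ 5% (empirically well under 1%, since
the joint ROR+IC+count rule is conservative). Structural and oracle
tests use 2,000–20,000-report databases, which are ample for exact
count accounting.
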