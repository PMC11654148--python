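"""ROR/IC formulas, 2×2 construction, signal rule, combo comparator."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from faersig.faers_io import CaseReport
from faersig.meddra import PtSocMap
from faersig.signal_stats import (
    ContingencyTable,
    build_tables,
    combo_analysis,
    compute_signals,
    evaluate_table,
    flag_signal,
    ic_with_bounds,
    ror_with_ci,
)

from conftest import TARGET, make_report


def table(a, b, c, d, term="X", level="pt"):
    return ContingencyTable(
        term=term, level=level, a=a, b=b, c=c, d=d,
        n_drug=a + b, n_effect=a + c, n_total=a + b + c + d,
    )


# ---------------------------------------------------------------- oracles
def oracle_ror(a, b, c, d, z=1.96):
    """Independent direct evaluation of the printed ROR formulas."""
    est = (a * d) / (b * c)
    width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.e ** (-width), est * math.e ** width


def oracle_ic(n_obs, n_drug, n_effect, n_total):
    """Independent direct evaluation of the printed IC formulas."""
    n_exp = (n_drug * n_effect) / n_total
    ic = math.log((n_obs + 0.5) / (n_exp + 0.5), 2)
    s = n_obs + 0.5
    ic025 = ic - 3.3 * s ** (-1 / 2) - 2 * s ** (-3 / 2)
    ic975 = ic + 2.4 * s ** (-1 / 2) - 0.5 * s ** (-3 / 2)
    return ic, ic025, ic975


class TestRorFormula:
    def test_worked_example(self):
        ror, lo, hi, corrected = ror_with_ci(table(10, 20, 30, 240))
        assert ror == pytest.approx(4.0)
        assert lo == pytest.approx(1.712, abs=1e-3)
        assert hi == pytest.approx(9.347, abs=1e-3)
        assert not corrected
        # the CI half-width comes from SE = sqrt(1/10+1/20+1/30+1/240)
        assert math.sqrt(0.1875) == pytest.approx(math.log(hi / ror) / 1.96)

    def test_balanced_table_gives_unity(self):
        ror, lo, hi, _ = ror_with_ci(table(5, 10, 10, 20))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_scaling_preserves_ror_and_narrows_ci(self):
        r1 = ror_with_ci(table(10, 20, 30, 240))
        r10 = ror_with_ci(table(100, 200, 300, 2400))
        assert r10[0] == pytest.approx(r1[0])
        assert (r10[2] - r10[1]) < (r1[2] - r1[1])

    def test_zero_cell_haldane_anscombe(self):
        ror, lo, hi, corrected = ror_with_ci(table(10, 0, 5, 85))
        assert corrected
        exp = oracle_ror(10.5, 0.5, 5.5, 85.5)
        assert (ror, lo, hi) == pytest.approx(exp)

    def test_all_zero_is_hard_error(self):
        with pytest.raises(ValueError):
            ror_with_ci(table(0, 0, 0, 0))

    def test_ci_ordering_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, size=4)
            ror, lo, hi, _ = ror_with_ci(table(int(a), int(b), int(c), int(d)))
            assert lo <= ror <= hi


class TestIcFormula:
    def test_worked_example(self):
        t = ContingencyTable(term="X", level="pt", a=10, b=90, c=990, d=98910,
                             n_drug=100, n_effect=1000, n_total=100_000)
        ic, ic025, ic975 = ic_with_bounds(t)
        assert ic == pytest.approx(math.log2(7.0))
        assert ic == pytest.approx(2.807, abs=1e-3)
        assert ic025 == pytest.approx(1.730, abs=1e-3)
        assert ic975 == pytest.approx(3.533, abs=1e-3)

    def test_observed_equals_expected_gives_zero(self):
        # n_exp = 100*1000/10000 = 10 = n_obs
        t = ContingencyTable(term="X", level="pt", a=10, b=90, c=990, d=8910,
                             n_drug=100, n_effect=1000, n_total=10_000)
        ic, ic025, ic975 = ic_with_bounds(t)
        assert ic == 0.0
        assert ic025 < 0.0 < ic975

    def test_zero_observed_zero_expected(self):
        t = ContingencyTable(term="X", level="pt", a=0, b=10, c=0, d=90,
                             n_drug=10, n_effect=0, n_total=100)
        ic, ic025, ic975 = ic_with_bounds(t)
        assert ic == 0.0
        assert ic025 == pytest.approx(-3.3 * 0.5**-0.5 - 2 * 0.5**-1.5)
        assert ic975 == pytest.approx(2.4 * 0.5**-0.5 - 0.5 * 0.5**-1.5)

    def test_zero_database_is_hard_error(self):
        with pytest.raises(ValueError):
            ic_with_bounds(ContingencyTable(term="X", level="pt", a=0, b=0, c=0, d=0,
                                            n_drug=0, n_effect=0, n_total=0))


class TestOracleEquivalence:
    def test_thousand_random_tables_match_to_1e12(self):
        """Implementation vs independently coded direct-formula oracle."""
        rng = np.random.default_rng(12345)
        worst = 0.0
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 501, size=4))
            t = table(a, b, c, d)
            got = (*ror_with_ci(t)[:3], *ic_with_bounds(t))
            want = (*oracle_ror(a, b, c, d), *oracle_ic(a, a + b, a + c, a + b + c + d))
            for g, w in zip(got, want):
                rel = abs(g - w) / max(abs(w), 1e-300)
                worst = max(worst, rel)
        assert worst < 1e-12


class TestMonotonicityAndLimits:
    def test_ror_and_ic_increase_with_a_at_fixed_marginals(self):
        """For fixed n_drug, n_effect, n_total, both statistics grow
        strictly with the observed pair count (enumeration)."""
        n_drug, n_effect, n_total = 30, 40, 200
        prev_ror, prev_ic = -math.inf, -math.inf
        for a in range(1, min(n_drug, n_effect)):
            b, c = n_drug - a, n_effect - a
            d = n_total - a - b - c
            t = ContingencyTable(term="X", level="pt", a=a, b=b, c=c, d=d,
                                 n_drug=n_drug, n_effect=n_effect, n_total=n_total)
            ror = ror_with_ci(t)[0]
            ic = ic_with_bounds(t)[0]
            assert ror > prev_ror and ic > prev_ic
            prev_ror, prev_ic = ror, ic

    def test_large_count_limit(self):
        """Scaling a disproportionate table: IC → log2(a·N/(n_drug·n_effect)),
        credibility interval shrinks to zero width."""
        a, b, c, d = 10, 20, 30, 240
        widths = []
        for k in (1, 100, 10_000):
            t = table(a * k, b * k, c * k, d * k)
            ic, lo, hi = ic_with_bounds(t)
            widths.append(hi - lo)
            limit = math.log2(t.a * t.n_total / (t.n_drug * t.n_effect))
            if k == 10_000:
                assert ic == pytest.approx(limit, abs=1e-3)
        assert widths[0] > widths[1] > widths[2]


class TestSignalRule:
    @pytest.mark.parametrize(
        "n,ror025,ic025,expected",
        [
            (3, 5.0, 2.0, False),     # too few cases, however strong
            (4, 1.01, 0.01, True),    # just above every threshold
            (100, 0.99, 3.0, False),  # ROR bound fails
            (100, 3.0, -0.01, False), # IC bound fails
            (4, 1.0, 0.5, False),     # boundary is strict: > 1, not >= 1
            (4, 1.5, 0.0, False),     # strict: > 0
        ],
    )
    def test_threshold_conjunction(self, n, ror025, ic025, expected):
        assert flag_signal(n, ror025, ic025) is expected

    def test_min_a_boundary_flips_the_flag(self):
        assert flag_signal(4, 2.0, 1.0) and not flag_signal(3, 2.0, 1.0)
        assert flag_signal(3, 2.0, 1.0, min_a=3)


class TestBuildTables:
    def test_degenerate_all_target(self):
        target = [make_report(str(i), pts={"X"}) for i in range(10)]
        background = [make_report(str(i + 10), pts={"Y"}, drugs=(("OTHER", "PS"),)) for i in range(90)]
        (t,) = [x for x in build_tables(target, background) if x.term == "X"]
        assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 90)
        assert (t.n_drug, t.n_effect, t.n_total) == (10, 10, 100)

    def test_duplicate_pt_in_report_counts_once(self):
        # pts is a set by construction; a report can never double-count
        r = make_report("1", pts={"X"})
        t = build_tables([r], [make_report("2", pts={"Y"}, drugs=(("O", "PS"),))])[0]
        assert t.a == 1

    def test_matches_naive_double_loop_oracle(self, small_cohort, small_sim):
        target, background = small_cohort
        for level in ("pt", "soc"):
            tables = build_tables(target, background, level=level, mapping=small_sim.pt_soc)
            # brute-force oracle: per-term membership count over every report
            def terms_of(r):
                if level == "pt":
                    return set(r.pts)
                return {small_sim.pt_soc.get(p) or "UNMAPPED" for p in r.pts}

            a_oracle, c_oracle = Counter(), Counter()
            for r in target:
                for term in terms_of(r):
                    a_oracle[term] += 1
            for r in background:
                for term in terms_of(r):
                    c_oracle[term] += 1
            assert {t.term for t in tables} == set(a_oracle)
            for t in tables:
                assert (t.a, t.c) == (a_oracle[t.term], c_oracle[t.term])
                assert t.a + t.b + t.c + t.d == t.n_total
                assert t.n_effect == t.a + t.c

    def test_zero_a_terms_never_emitted(self, small_cohort):
        target, background = small_cohort
        assert all(t.a > 0 for t in build_tables(target, background))

    def test_pair_level_counting_switch(self):
        target = [make_report("1", pts={"X", "Y"}), make_report("2", pts={"X"})]
        background = [make_report("3", pts={"Y"}, drugs=(("O", "PS"),))]
        (tx,) = [t for t in build_tables(target, background, counting="pair") if t.term == "X"]
        # 3 target pairs total, 2 are X; 1 background pair, 0 are X
        assert (tx.a, tx.b, tx.c, tx.d) == (2, 1, 0, 1)


class TestComboAnalysis:
    @staticmethod
    def _cohort():
        reports = []
        # 20 target+ICI co-exposed, 4 with SEPSIS
        for i in range(20):
            reports.append(make_report(
                f"e{i}", pts={"SEPSIS"} if i < 4 else {"OTHER PT"},
                drugs=((TARGET, "PS"), ("NIVOLUMAB", "C")),
            ))
        # 980 target-without-ICI, 20 with SEPSIS
        for i in range(980):
            reports.append(make_report(
                f"c{i}", pts={"SEPSIS"} if i < 20 else {"OTHER PT"},
                drugs=((TARGET, "PS"),),
            ))
        return reports

    def test_hand_arithmetic_2x2(self):
        df = combo_analysis(self._cohort(), [TARGET], {"NIVOLUMAB": ["NIVOLUMAB"]})
        row = df[df.term == "SEPSIS"].iloc[0]
        # a=4, b=16, c=20, d=960 -> ROR = (4*960)/(16*20) = 12
        assert row.n == 4
        assert row.ror == pytest.approx(12.0)
        assert bool(row.signal)

    def test_three_cases_never_flagged(self):
        reports = self._cohort()[1:]  # drop one SEPSIS exposure case -> a=3
        df = combo_analysis(reports, [TARGET], {"NIVOLUMAB": ["NIVOLUMAB"]})
        row = df[df.term == "SEPSIS"].iloc[0]
        assert row.n == 3 and row.ror > 5 and not bool(row.signal)

    def test_ici_without_coexposure_skipped(self):
        df = combo_analysis(self._cohort(), [TARGET], {"IPILIMUMAB": ["IPILIMUMAB"]})
        assert df.empty

    def test_other_ici_regimens_comparator(self):
        reports = self._cohort()
        # ICI-only background: 100 reports, 10 with SEPSIS
        for i in range(100):
            reports.append(make_report(
                f"i{i}", pts={"SEPSIS"} if i < 10 else {"OTHER PT"},
                drugs=(("NIVOLUMAB", "PS"),),
            ))
        df = combo_analysis(reports, [TARGET], {"NIVOLUMAB": ["NIVOLUMAB"]},
                            comparator_mode="other-ici-regimens")
        row = df[df.term == "SEPSIS"].iloc[0]
        # a=4,b=16 vs c=10,d=90 -> ROR = (4*90)/(16*10)
        assert row.ror == pytest.approx((4 * 90) / (16 * 10))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            combo_analysis([], [TARGET], {}, comparator_mode="bogus")


class TestComputeSignals:
    def test_sorted_by_soc_then_descending_n(self, small_cohort, small_sim):
        target, background = small_cohort
        df = compute_signals(target, background, level="pt", mapping=small_sim.pt_soc)
        for _, grp in df.groupby("soc", sort=False):
            assert list(grp["n"]) == sorted(grp["n"], reverse=True)
        assert list(df["soc"]) == sorted(df["soc"])

    def test_result_invariants(self, small_cohort, small_sim):
        target, background = small_cohort
        tables = build_tables(target, background, level="pt", mapping=small_sim.pt_soc)
        for t in tables:
            r = evaluate_table(t)
            if min(t.a, t.b, t.c, t.d) > 0:
                assert r.ror_ci_low <= r.ror <= r.ror_ci_high
            assert r.ic025 < r.ic < r.ic975
            assert r.is_signal == (r.ror_ci_low > 1.0 and r.ic025 > 0.0 and r.n >= 4)
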