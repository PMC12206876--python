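"""Contingency tables and the four disproportionality statistics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import ingest, signal_engine as se
from pvsignal.errors import DegenerateSampleError


def make_report(pid, events, index=False):
    drug = ingest.DrugEntry("CARBOPLATIN" if index else "OTHERDRUG", "PS", None)
    return ingest.SafetyReport(
        primaryid=str(pid), caseid=str(pid), fda_dt="20200101", event_dt="",
        sex=None, age_years=None, age_group=None, reporter_class=None,
        country=None, report_year=2020, drugs=[drug], events=frozenset(events))


cells = st.integers(min_value=0, max_value=2000)
pos_cells = st.integers(min_value=1, max_value=2000)


def table(a, b, c, d):
    return se.ContingencyTable("T", "PT", a, b, c, d)


class TestBuildTables:
    def test_hand_counted_pair_example(self):
        index = [make_report(1, {"e1", "e2"}, True), make_report(2, {"e1"}, True)]
        background = [make_report(3, {"e1"}), make_report(4, {"e2", "e3"})]
        tables = {t.term: t for t in se.build_tables(index, background)}
        t = tables["E1"] if "E1" in tables else tables["e1"]
        assert (t.a, t.b, t.c, t.d, t.n) == (2, 1, 1, 2, 6)

    def test_boundary_single_report_empty_background(self):
        tables = se.build_tables([make_report(1, {"e1"}, True)], [])
        t = tables[0]
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_pair_conservation_and_constant_index_margin(self, corpus):
        tables = corpus["tables"]
        n_index_pairs = sum(len(r.events) for r in corpus["index"])
        assert sum(t.a for t in tables) == n_index_pairs
        assert len({t.a + t.b for t in tables}) == 1
        assert next(iter({t.a + t.b for t in tables})) == n_index_pairs

    def test_soc_level_counts_one_pair_per_soc(self):
        hier = ingest.EventHierarchy({"E1": "S1", "E2": "S1", "E3": "S2"})
        index = [make_report(1, {"E1", "E2", "E3"}, True)]
        tables = {t.term: t for t in se.build_tables(index, [], hier, "SOC")}
        assert tables["S1"].a == 1  # two PTs, one SOC pair
        assert tables["S2"].a == 1
        assert sum(t.a for t in tables.values()) == 2


class TestRorStat:
    def test_symmetric_table_is_null(self):
        ror, lo, hi, corrected = se.ror_stat(table(5, 5, 5, 5))
        assert ror == 1.0 and lo < 1.0 < hi and not corrected

    def test_wald_interval_arithmetic(self):
        ror, lo, hi, _ = se.ror_stat(table(10, 20, 30, 40))
        assert ror == pytest.approx(2 / 3)
        assert lo == pytest.approx(0.2725, abs=1e-4)
        assert hi == pytest.approx(1.6309, abs=1e-4)

    def test_zero_cell_continuity_correction_flagged(self):
        ror, lo, hi, corrected = se.ror_stat(table(3, 7, 0, 10))
        assert corrected and math.isfinite(ror) and lo > 0


class TestPrrStat:
    def test_null_table(self):
        prr, chi2 = se.prr_stat(table(5, 5, 5, 5))
        assert prr == 1.0 and chi2 == 0.0

    def test_direct_arithmetic(self):
        prr, chi2 = se.prr_stat(table(10, 20, 30, 40))
        assert prr == pytest.approx(0.77778, abs=1e-4)
        assert chi2 == pytest.approx(0.79365, abs=1e-4)

    def test_zero_background_count_gives_flagged_infinity(self):
        prr, chi2 = se.prr_stat(table(5, 5, 0, 10))
        assert math.isinf(prr) and chi2 > 0

    def test_empty_margin_raises(self):
        with pytest.raises(DegenerateSampleError):
            se.prr_stat(table(0, 0, 3, 4))

    def test_yates_correction_shrinks_chi2(self):
        assert se.prr_stat(table(10, 20, 30, 40), yates=True)[1] < \
            se.prr_stat(table(10, 20, 30, 40))[1]


class TestIcStat:
    def test_observed_equals_expected_is_zero_bits(self):
        # E = (a+b)(a+c)/N = a exactly for a fully proportional table
        ic, _ = se.ic_stat(table(10, 10, 10, 10))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        ic, ic025 = se.ic_stat(table(10, 20, 30, 40))
        assert ic == pytest.approx(math.log2(10.5 / 12.5), abs=1e-12)
        assert ic025 < ic

    def test_lower_bound_formula(self):
        assert se.ic025_from_ic(2.56, 68) == pytest.approx(2.1578, abs=1e-4)


class TestAlgebraicProperties:
    @settings(max_examples=300, deadline=None)
    @given(a=pos_cells, b=pos_cells, c=pos_cells, d=pos_cells)
    def test_ror_vs_prr_ordering_identity(self, a, b, c, d):
        # ROR > PRR iff ROR > 1 iff ad > bc (equality throughout at ad = bc)
        t = table(a, b, c, d)
        ror = se.ror_stat(t)[0]
        prr = se.prr_stat(t)[0]
        if a * d > b * c:
            assert ror > prr and ror > 1
        elif a * d < b * c:
            assert ror < prr and ror < 1
        else:
            assert ror == pytest.approx(prr) and ror == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(a=pos_cells, b=pos_cells, c=pos_cells, d=pos_cells)
    def test_chi2_invariant_under_double_swap(self, a, b, c, d):
        chi_1 = se.prr_stat(table(a, b, c, d))[1]
        chi_2 = se.prr_stat(table(d, c, b, a))[1]
        assert chi_1 == pytest.approx(chi_2, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(a=pos_cells, b=pos_cells, c=pos_cells, d=pos_cells)
    def test_ror_and_prr_increase_with_a(self, a, b, c, d):
        t0, t1 = table(a, b, c, d), table(a + 1, b, c, d)
        assert se.ror_stat(t1)[0] > se.ror_stat(t0)[0]
        assert se.prr_stat(t1)[0] > se.prr_stat(t0)[0]

    @settings(max_examples=100, deadline=None)
    @given(a=pos_cells, b=cells, c=cells, d=cells)
    def test_ic025_strictly_below_ic(self, a, b, c, d):
        ic, ic025 = se.ic_stat(table(a, b, c, d))
        assert ic025 < ic


class TestGate:
    def row(self, **kw):
        base = dict(term="T", level="PT", a=100, ror=1.0, ror_low=0.8,
                    ror_high=1.2, prr=1.0, chi2=0.0, ic=0.0, ic025=-0.3,
                    ebgm=1.0, ebgm05=0.8)
        base.update(kw)
        return se.SignalRow(**base)

    def test_support_floor_blocks_all_flags(self):
        out = se.gate_signals([self.row(a=2, ror_low=5.0, prr=10, chi2=100,
                                        ic025=2.0, ebgm05=5.0)])
        assert not out[0].positive and not any(out[0].flags.values())

    def test_any_single_method_suffices(self):
        out = se.gate_signals([self.row(ror_low=2.15)])
        assert out[0].flags["ror"] and out[0].positive

    def test_all_below_threshold_is_negative(self):
        out = se.gate_signals([self.row(ror_low=0.9, prr=1.1, chi2=3.0,
                                        ic025=-0.2, ebgm05=1.0)])
        assert not out[0].positive

    def test_rows_sorted_by_frequency(self):
        out = se.gate_signals([self.row(term="X", a=5), self.row(term="Y", a=50)])
        assert [r.term for r in out] == ["Y", "X"]

    def test_combination_all_requires_every_method(self):
        policy = se.ThresholdPolicy(combination="all")
        out = se.gate_signals([self.row(ror_low=2.0, prr=3.0, chi2=50,
                                        ic025=0.5, ebgm05=1.5)], policy)
        assert not out[0].positive  # ebgm05 <= 2 fails the conjunction


def test_simplified_ebgm_mode_is_two_to_the_ic():
    tables = [table(30, 70, 50, 850), table(5, 95, 60, 840)]
    rows = se.compute_signals(tables, ebgm_mode="ic")
    for r in rows:
        assert r.ebgm == pytest.approx(2.0 ** r.ic, rel=1e-12)
        assert r.ebgm05 == pytest.approx(2.0 ** r.ic025, rel=1e-12)
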