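"""IME filtering, Fisher exact subgroup contrasts, time-to-onset, and
case-by-case extraction."""

import datetime as dt
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignals import (
    IMETermList,
    ReportSet,
    SignalScores,
    extract_cases_by_indication,
    filter_ime,
    fisher_exact_two_sided,
    split_100,
    subgroup_compare,
    tto_bin,
    tto_extract,
)
from pvsignals.screening import _or_with_interval
from pvsignals.disproportionality import ContingencyTable
from pvsignals.errors import ConfigurationError, DegenerateInputError
from pvsignals.simulate import generate_reports

from conftest import make_report, small_synthetic_config


def _sig(pt, positive=True):
    return SignalScores(drug="dantrolene", pt=pt, positive_combined=positive)


class TestIme:
    def test_from_file_with_comments(self, tmp_path):
        p = tmp_path / "ime.txt"
        p.write_text("# header comment\nHepatic failure\nRespiratory failure # inline\n\n")
        ime = IMETermList.from_file(p)
        assert ime.terms == {"hepatic failure", "respiratory failure"}

    def test_case_insensitive_match(self):
        ime = IMETermList.from_terms(["hepatic failure"])
        out = filter_ime([_sig("Hepatic failure")], ime)
        assert [s.pt for s in out] == ["Hepatic failure"]

    def test_intersection_preserves_order(self):
        ime = IMETermList.from_terms(["pt2", "pt5", "pt7", "pt9"])
        signals = [_sig(f"pt{i}") for i in range(10)]
        out = filter_ime(signals, ime)
        assert [s.pt for s in out] == ["pt2", "pt5", "pt7", "pt9"]

    def test_non_positive_signals_excluded(self):
        ime = IMETermList.from_terms(["pt1"])
        assert filter_ime([_sig("pt1", positive=False)], ime) == []

    def test_disjoint_lists_give_empty(self):
        assert filter_ime([_sig("ptA")], IMETermList.from_terms(["ptB"])) == []

    def test_empty_list_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_ime([_sig("pt")], IMETermList(terms=set()))


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 0, 0, 5), 2 / 252),              # 0.0079365
            ((3, 7, 1, 9), 0.5820433436532507),
            ((10, 10, 10, 10), 1.0),
            ((0, 5, 5, 0), 2 / 252),
        ],
    )
    def test_frozen_enumeration_values(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-12)

    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    def test_matches_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        from scipy.stats import fisher_exact

        p_ref = fisher_exact([[a, b], [c, d]]).pvalue
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(p_ref, abs=1e-9)

    @given(a=st.integers(0, 15), b=st.integers(0, 15),
           c=st.integers(0, 15), d=st.integers(0, 15))
    def test_row_swap_symmetry(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_exact_two_sided(c, d, a, b), rel=1e-12
        )

    def test_row_swap_inverts_odds_ratio(self):
        t = ContingencyTable(3, 7, 1, 9)
        orv, _, _ = _or_with_interval(t)
        orv_sw, _, _ = _or_with_interval(ContingencyTable(1, 9, 3, 7))
        assert orv == pytest.approx(27 / 7)
        assert orv * orv_sw == pytest.approx(1.0)


def _aged_reports(n1_event, n1_other, n2_event, n2_other):
    """Reports realizing the subgroup table (rows = age groups)."""
    reports = []
    i = 0
    for age, with_ev, without in ((30, n1_event, n1_other), (60, n2_event, n2_other)):
        for _ in range(with_ev):
            reports.append(make_report(f"r{i}", drug="dantrolene",
                                       events=["Muscular weakness"], age_years=age)); i += 1
        for _ in range(without):
            reports.append(make_report(f"r{i}", drug="dantrolene",
                                       events=["Nausea"], age_years=age)); i += 1
    return ReportSet(reports=reports)


class TestSubgroupCompare:
    def test_identical_proportions(self):
        rs = _aged_reports(3, 7, 3, 7)
        res = subgroup_compare(rs, "age", "muscular weakness")
        assert res.or_point == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_extreme_table_haldane_and_exact_p(self):
        rs = _aged_reports(5, 0, 0, 5)
        res = subgroup_compare(rs, "age", "muscular weakness")
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (5, 0, 0, 5)
        assert res.or_point == pytest.approx(121.0)
        assert res.fisher_p == pytest.approx(2 / 252, rel=1e-12)

    def test_hand_checked_table(self):
        rs = _aged_reports(3, 7, 1, 9)
        res = subgroup_compare(rs, "age", "muscular weakness")
        assert res.or_point == pytest.approx(27 / 7, rel=1e-9)
        assert res.fisher_p == pytest.approx(0.5820433436532507, rel=1e-9)

    def test_under_18_and_missing_age_excluded(self):
        rs = _aged_reports(3, 7, 1, 9)
        rs.reports.append(make_report("kid", drug="dantrolene",
                                      events=["Muscular weakness"], age_years=10))
        rs.reports.append(make_report("na", drug="dantrolene",
                                      events=["Muscular weakness"], age_years=None))
        res = subgroup_compare(rs, "age", "muscular weakness")
        assert (res.table.a, res.table.b) == (3, 7)

    def test_duration_grouping_boundary(self):
        start = dt.date(2020, 1, 1)
        reports = [
            make_report("short", drug="dantrolene", events=["Nausea"],
                        therapy_start=start, therapy_end=start + dt.timedelta(days=180)),
            make_report("long", drug="dantrolene", events=["Muscular weakness"],
                        therapy_start=start, therapy_end=start + dt.timedelta(days=181)),
        ]
        res = subgroup_compare(ReportSet(reports=reports), "duration", "muscular weakness")
        # 180 days inclusive -> short group; 181 -> long group
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (0, 1, 1, 0)

    def test_indication_grouping(self):
        reports = [
            make_report("mh1", drug="dantrolene", events=["Muscular weakness"],
                        indication="malignant hyperthermia"),
            make_report("sp1", drug="dantrolene", events=["Nausea"],
                        indication="muscle spasticity"),
        ]
        res = subgroup_compare(ReportSet(reports=reports), "indication", "muscular weakness")
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (1, 0, 0, 1)

    def test_empty_group_raises_named_error(self):
        rs = _aged_reports(3, 7, 0, 0)
        with pytest.raises(DegenerateInputError, match=">=45"):
            subgroup_compare(rs, "age", "muscular weakness")


class TestTto:
    def test_hand_computed_latencies(self):
        start = dt.date(2020, 1, 1)
        lats = (0, 30, 31, 180, 181, 700)
        reports = [
            make_report(
                f"r{i}", drug="dantrolene", therapy_start=start,
                events=[("Dyspnoea", start + dt.timedelta(days=k))],
            )
            for i, k in enumerate(lats)
        ]
        out = tto_extract(ReportSet(reports=reports), "dantrolene")
        assert sorted(out.all_latencies()) == list(lats)
        assert out.n_missing == 0 and out.n_negative == 0

    def test_missing_and_negative_accounting(self):
        start = dt.date(2020, 6, 1)
        reports = [
            make_report("r0", drug="dantrolene", therapy_start=start,
                        events=[("Nausea", start)]),                      # latency 0
            make_report("r1", drug="dantrolene", therapy_start=start,
                        events=[("Nausea", None)]),                       # missing onset
            make_report("r2", drug="dantrolene", therapy_start=None,
                        events=[("Nausea", start)]),                      # missing start
            make_report("r3", drug="dantrolene", therapy_start=start,
                        events=[("Nausea", start - dt.timedelta(days=3))]),  # negative
        ]
        out = tto_extract(ReportSet(reports=reports), "dantrolene")
        assert out.all_latencies() == [0]
        assert out.n_missing == 2
        assert out.n_negative == 1

    def test_conservation_on_synthetic_set(self):
        rs = generate_reports(small_synthetic_config(n_reports=500, seed=13))
        out = tto_extract(rs, "dantrolene")
        total_mentions = sum(
            len(r.events)
            for r in rs.reports
            if any(m.role == "primary-suspect" and m.drug_name_norm == "dantrolene"
                   for m in r.drugs)
        )
        assert out.n_latencies + out.n_missing + out.n_negative == total_mentions

    def test_default_binning(self):
        bins = tto_bin([0, 30, 31, 180, 181, 700])
        assert list(bins.values()) == [2, 1, 0, 0, 1, 2]
        assert list(bins.keys()) == ["0-30", "31-60", "61-90", "91-120", "121-180", ">180"]

    def test_empty_latencies(self):
        assert all(v == 0 for v in tto_bin([]).values())

    def test_boundary_convention(self):
        assert tto_bin([30])["0-30"] == 1
        assert tto_bin([31])["31-60"] == 1

    def test_split_100(self):
        bins = split_100([0, 99, 100, 101, 500])
        assert bins == {"0-100": 3, ">100": 2}

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            tto_bin([1], edges=(0, 50, 40))


class TestCaseExtraction:
    def _reports(self):
        return ReportSet(
            reports=[
                make_report("mh1", drug="dantrolene", events=["Muscular weakness"],
                            indication="malignant hyperthermia", sex="female",
                            age_years=35.0, outcomes=frozenset({"hospitalization"})),
                make_report("mh2", drug="dantrolene", events=["Pyrexia", "Nausea"],
                            indication="Malignant Hyperthermia", sex="male"),
                make_report("sp1", drug="dantrolene", events=["Nausea"],
                            indication="muscle spasticity"),
                make_report("no1", drug="dantrolene", events=["Rash"]),
                make_report("ot1", drug="baclofen", events=["Nausea"]),
            ]
        )

    def test_hand_extraction(self):
        df = extract_cases_by_indication(self._reports(), {"Malignant hyperthermia"})
        assert list(df["report_id"]) == ["mh1", "mh2"]
        row = df.iloc[0]
        assert row["sex"] == "female"
        assert row["age_years"] == 35.0
        assert row["outcomes"] == "hospitalization"
        assert row["events"] == "muscular weakness"
        assert df.iloc[1]["events"] == "nausea;pyrexia"

    def test_no_match_gives_empty_frame(self):
        df = extract_cases_by_indication(self._reports(), {"neuroleptic malignant syndrome"})
        assert len(df) == 0
        assert "report_id" in df.columns
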