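"""Index formulas, the full gamma-Poisson shrinker, classification, and
algebraic invariants of the 2x2 statistics.

Frozen expected values were computed with an independent high-precision
evaluation of the closed-form formulas (log-normal ROR interval, Pearson
chi-square from margins, Bate closed-form IC moments, digamma/gamma-quantile
posterior summaries)."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignals import (
    ContingencyTable,
    MgpsPrior,
    SignalScores,
    Thresholds,
    bcpnn_ic,
    build_contingency,
    classify_signal,
    ebgm_full,
    ebgm_simple,
    fit_mgps_prior,
    prr_score,
    ror_score,
    score_all_pairs,
)
from pvsignals.disproportionality import _posterior_mixture
from pvsignals.errors import (
    DegenerateInputError,
    UndefinedEstimateError,
)
from pvsignals.reports import ROLE_PRIMARY
from pvsignals.simulate import generate_reports

from conftest import make_report, small_synthetic_config

T_REF = ContingencyTable(25, 75, 900, 9000)

cells = st.integers(min_value=1, max_value=500)


class TestBuildContingency:
    def test_direct_count(self, counts_5_5_10_80):
        t = build_contingency(counts_5_5_10_80, "dantrolene", "respiratory failure")
        assert (t.a, t.b, t.c, t.d) == (5, 5, 10, 80)

    def test_absent_event(self, counts_5_5_10_80):
        t = build_contingency(counts_5_5_10_80, "dantrolene", "unheard of event")
        assert (t.a, t.c) == (0, 0)

    def test_repeated_pt_counts_once(self):
        from pvsignals import ReportSet

        r = make_report("r1", drug="dantrolene", events=["Nausea", "nausea"])
        other = make_report("r2", drug="ibuprofen", events=["Rash"])
        t = build_contingency(ReportSet(reports=[r, other]), "dantrolene", "nausea")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_matches_brute_force_recount(self):
        rs = generate_reports(small_synthetic_config(n_reports=1000, seed=1))
        t = build_contingency(rs, "dantrolene", "respiratory failure")
        a = b = c = d = 0
        for r in rs.reports:
            has_drug = any(
                m.role == ROLE_PRIMARY and m.drug_name_norm == "dantrolene" for m in r.drugs
            )
            has_ev = "respiratory failure" in {e.pt.lower() for e in r.events}
            if has_drug and has_ev:
                a += 1
            elif has_drug:
                b += 1
            elif has_ev:
                c += 1
            else:
                d += 1
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_empty_set_rejected(self):
        from pvsignals import ReportSet

        with pytest.raises(DegenerateInputError):
            build_contingency(ReportSet(reports=[]), "x", "y")


class TestRor:
    def test_reference_table(self):
        ror, lo, hi = ror_score(T_REF)
        assert ror == pytest.approx(3.333333, rel=1e-5)
        assert lo == pytest.approx(2.108932, rel=1e-5)
        assert hi == pytest.approx(5.268597, rel=1e-5)

    def test_symmetric_table_straddles_one(self):
        ror, lo, hi = ror_score(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0
        assert lo < 1.0 < hi

    def test_haldane_on_zero_cell(self):
        ror, _, _ = ror_score(ContingencyTable(5, 0, 10, 80), continuity="haldane")
        assert ror == pytest.approx((5.5 * 80.5) / (0.5 * 10.5))

    def test_zero_cell_error_names_cell(self):
        with pytest.raises(UndefinedEstimateError) as exc:
            ror_score(ContingencyTable(5, 0, 10, 80))
        assert exc.value.cell == "b"


class TestPrr:
    def test_reference_table(self):
        prr, chi2 = prr_score(T_REF)
        assert prr == pytest.approx(2.75, rel=1e-9)
        assert chi2 == pytest.approx(29.84953, rel=1e-5)

    @pytest.mark.parametrize("t", [ContingencyTable(20, 80, 180, 720),
                                   ContingencyTable(10, 10, 10, 10)])
    def test_proportional_margins(self, t):
        prr, chi2 = prr_score(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_c_gives_infinite_prr_finite_chi2(self):
        prr, chi2 = prr_score(ContingencyTable(5, 5, 0, 90))
        assert math.isinf(prr)
        assert chi2 > 0


class TestBcpnn:
    def test_reference_table_plugin_and_posterior(self):
        ic, ic025 = bcpnn_ic(T_REF)
        assert ic == pytest.approx(1.434403, rel=1e-5)
        assert ic025 == pytest.approx(0.689370, rel=1e-4)
        e_ic, _ = bcpnn_ic(T_REF, variant="posterior")
        assert e_ic == pytest.approx(1.329040, rel=1e-5)

    def test_independence_limit(self):
        # margins exactly proportional at N = 1e6
        t = ContingencyTable(1000, 99_000, 9_000, 891_000)
        ic, _ = bcpnn_ic(t)
        assert abs(ic) < 0.1

    def test_zero_a_shrinks_negative_but_finite(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(0, 100, 100, 9800))
        assert math.isfinite(ic025) and ic025 < 0
        assert ic == pytest.approx(-1.014135, rel=1e-5)  # posterior expectation


class TestEbgmSimple:
    def test_reference_table(self):
        ebgm, eb05 = ebgm_simple(T_REF)
        assert ebgm == pytest.approx(2.702703, rel=1e-5)
        assert eb05 == pytest.approx(1.840482, rel=1e-5)

    def test_independence(self):
        ebgm, _ = ebgm_simple(ContingencyTable(20, 80, 180, 720))
        assert ebgm == pytest.approx(1.0)


class TestEbgmFull:
    def test_identical_components_reduce_to_single_gamma(self):
        # both components Gamma(2, rate 2): a=5, E=1 -> posterior Gamma(7, rate 3)
        prior = MgpsPrior(2.0, 2.0, 2.0, 2.0, 0.5)
        t = ContingencyTable(5, 5, 495, 4495)  # E = (10)(500)/5000 = 1
        assert t.expected == pytest.approx(1.0)
        ebgm, eb05 = ebgm_full(t, prior)
        assert ebgm == pytest.approx(2.168796, rel=1e-4)
        assert eb05 == pytest.approx(1.095105, rel=1e-4)

    def test_posterior_weights_normalized(self):
        prior = MgpsPrior()
        (w1, w2), _, _ = _posterior_mixture(3, 0.5, prior)
        assert 0.0 <= w1 <= 1.0
        assert w1 + w2 == pytest.approx(1.0)

    def test_shrinks_small_count_toward_one(self):
        # raw relative reporting ratio 10 from a single case
        t = ContingencyTable(1, 9, 99, 9891)
        assert t.expected == pytest.approx(0.1)
        ebgm, _ = ebgm_full(t, MgpsPrior())
        assert ebgm < 10.0

    def test_agrees_with_simple_variant_for_large_counts(self):
        t = ContingencyTable(25_000, 75_000, 900_000, 9_000_000)
        full, _ = ebgm_full(t, MgpsPrior())
        simple, _ = ebgm_simple(t)
        assert full == pytest.approx(simple, rel=0.05)


class TestMgpsFit:
    def test_objective_improves_on_small_simulation(self):
        rng = np.random.default_rng(5)
        n = 2000
        e = np.exp(rng.uniform(np.log(0.1), np.log(50), n))
        lam = np.where(rng.random(n) < 0.5,
                       rng.gamma(0.5, 1 / 0.5, n), rng.gamma(3.0, 1 / 3.0, n))
        a = rng.poisson(lam * e)
        prior, info = fit_mgps_prior(a, e)
        assert info["loglik_final"] >= info["loglik_start"]
        assert 0 < prior.p_mix < 1

    def test_too_few_cells_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_mgps_prior([1] * 50, [1.0] * 50)


class TestClassify:
    @pytest.mark.parametrize("combo", range(16))
    def test_combined_requires_all_four(self, combo):
        """Exhaustive enumeration: the combined flag is the conjunction of
        the four per-index flags."""
        want = [(combo >> k) & 1 == 1 for k in range(4)]  # ror, prr, bcpnn, mgps
        th = Thresholds()
        s = SignalScores(
            a=5,
            ror_lo=1.5 if want[0] else 0.9,
            prr=3.0 if want[1] else 1.0,
            chi2=10.0 if want[1] else 1.0,
            ic025=0.5 if want[2] else -0.5,
            eb05=3.0 if want[3] else 1.0,
        )
        out = classify_signal(s, th)
        got = (out.positive_ror, out.positive_prr, out.positive_bcpnn, out.positive_mgps)
        assert got == tuple(want)
        assert out.positive_combined == all(want)

    def test_min_case_count_gates_ror_and_prr(self):
        s = SignalScores(a=2, ror_lo=2.0, prr=5.0, chi2=50.0, ic025=1.0, eb05=4.0)
        out = classify_signal(s, Thresholds())
        assert not out.positive_ror and not out.positive_prr
        assert not out.positive_combined

    def test_nan_scores_never_positive(self):
        out = classify_signal(SignalScores(a=10), Thresholds())
        assert not any([out.positive_ror, out.positive_prr,
                        out.positive_bcpnn, out.positive_mgps, out.positive_combined])


# --------------------------------------------------------------------------
# algebraic invariants

@given(a=cells, b=cells, c=cells, d=cells)
def test_transpose_invariance_of_ror_and_ebgm(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    tt = t.transpose()
    assert ror_score(t)[0] == pytest.approx(ror_score(tt)[0])
    assert ebgm_simple(t)[0] == pytest.approx(ebgm_simple(tt)[0])


def test_prr_is_not_transpose_invariant():
    # pinned asymmetric example: PRR changes under b <-> c
    t = ContingencyTable(5, 5, 10, 80)
    prr, _ = prr_score(t)
    prr_t, _ = prr_score(t.transpose())
    assert prr == pytest.approx((5 / 10) / (10 / 90))
    assert prr_t == pytest.approx((5 / 15) / (5 / 85))
    assert prr != pytest.approx(prr_t)


@given(a=cells, b=cells, c=cells, d=cells)
def test_interval_ordering(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    ror, lo, hi = ror_score(t)
    assert lo < ror < hi
    ebgm, eb05 = ebgm_simple(t)
    assert eb05 < ebgm
    ic, ic025 = bcpnn_ic(t)
    assert ic025 < bcpnn_ic(t, variant="posterior")[0]


@given(a=cells, b=st.integers(min_value=2, max_value=500), c=cells, d=cells)
def test_monotone_in_case_shift(a, b, c, d):
    """Moving one report from cell b to cell a (drug margin fixed) never
    decreases ROR, PRR or the plug-in IC."""
    t1 = ContingencyTable(a, b, c, d)
    t2 = ContingencyTable(a + 1, b - 1, c, d)
    assert ror_score(t2)[0] >= ror_score(t1)[0]
    assert prr_score(t2)[0] >= prr_score(t1)[0]
    assert bcpnn_ic(t2)[0] >= bcpnn_ic(t1)[0]


@given(a=cells, b=cells, c=cells, d=cells)
def test_chi2_zero_iff_margins_proportional(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    _, chi2 = prr_score(t)
    if a * d == b * c:
        assert chi2 == pytest.approx(0.0, abs=1e-9)
    else:
        assert chi2 > 0


def test_score_all_pairs_recovers_strong_planted_pair():
    from pvsignals import deduplicate

    rs = deduplicate(generate_reports(small_synthetic_config(n_reports=4000, rr=10, seed=2)))
    df = score_all_pairs(rs)
    row = df[(df.drug == "dantrolene") & (df.pt == "respiratory failure")].iloc[0]
    assert row.positive_combined
    # independence background: no other dantrolene pair should fire
    others = df[(df.drug == "dantrolene") & (df.pt != "respiratory failure")]
    assert not others.positive_combined.any()
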