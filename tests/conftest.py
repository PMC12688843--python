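import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from pvsignals import (
    AEReport,
    DrugMention,
    EventMention,
    ReportSet,
    SyntheticConfig,
    normalize_name,
)
from pvsignals.simulate import DrugSpec, EventSpec, PlantedSignal

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_report(
    report_id,
    case_id=None,
    drug=None,
    role="primary-suspect",
    events=(),
    version_date=None,
    therapy_start=None,
    therapy_end=None,
    indication=None,
    **kw,
):
    """Compact report builder: ``drug`` is a raw name (or None for a
    drug-less report), ``events`` is an iterable of PT strings or
    (pt, onset_date) tuples."""
    drugs = []
    if drug is not None:
        drugs = [
            DrugMention(
                drug_name_raw=drug,
                drug_name_norm=normalize_name(drug),
                role=role,
                therapy_start=therapy_start,
                therapy_end=therapy_end,
                indication_pt=indication,
            )
        ]
    evs = []
    for e in events:
        if isinstance(e, tuple):
            evs.append(EventMention(pt=e[0], onset_date=e[1]))
        else:
            evs.append(EventMention(pt=e))
    return AEReport(
        report_id=report_id,
        case_id=case_id or report_id,
        version_date=version_date,
        drugs=drugs,
        events=evs,
        **kw,
    )


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def counts_5_5_10_80():
    """100 reports realizing the 2x2 table (5, 5, 10, 80) for
    (dantrolene primary suspect, respiratory failure)."""
    reports = []
    i = 0
    for _ in range(5):
        reports.append(make_report(f"r{i}", drug="dantrolene", events=["Respiratory failure"])); i += 1
    for _ in range(5):
        reports.append(make_report(f"r{i}", drug="dantrolene", events=["Nausea"])); i += 1
    for _ in range(10):
        reports.append(make_report(f"r{i}", drug="ibuprofen", events=["Respiratory failure"])); i += 1
    for _ in range(80):
        reports.append(make_report(f"r{i}", drug="ibuprofen", events=["Nausea"])); i += 1
    return ReportSet(reports=reports, meta={"dedup_removed": 0})


def small_synthetic_config(n_reports=2000, rr=10.0, seed=0, duplicate_rate=0.1):
    """Desk-scale generator configuration: a target drug used in 5% of
    reports with one planted pair, three background drugs and six events."""
    return SyntheticConfig(
        n_reports=n_reports,
        drug_vocab=[
            DrugSpec(name="dantrolene", marginal=0.05),
            DrugSpec(name="baclofen", marginal=0.10),
            DrugSpec(name="ibuprofen", marginal=0.15),
            DrugSpec(name="diazepam", marginal=0.10),
        ],
        event_vocab=[
            EventSpec(pt="respiratory failure", baseline=0.05),
            EventSpec(pt="nausea", baseline=0.30),
            EventSpec(pt="headache", baseline=0.25),
            EventSpec(pt="rash", baseline=0.15),
            EventSpec(pt="dizziness", baseline=0.20),
            EventSpec(pt="pyrexia", baseline=0.10),
        ],
        planted_signals=(
            [PlantedSignal(drug="dantrolene", event="respiratory failure", rr=rr)]
            if rr != 1.0
            else []
        ),
        duplicate_rate=duplicate_rate,
        seed=seed,
    )


@pytest.fixture
def small_config():
    return small_synthetic_config()


FAERS_DEMO = """\
primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occr_country$occp_cod
1001$901$20200115$20200110$F$34$YR$60$KG$US$MD
1002$902$20210301$20210227$M$720$MON$154$LBS$JP$PH
1003$903$20190620$20XX0101$$$$$$FR$CN
"""
FAERS_DRUG = """\
primaryid$drug_seq$role_cod$drugname
1001$1$PS$DANTRIUM
1002$1$PS$Dantrolene Sodium
1003$1$C$dantrolene
"""
FAERS_REAC = """\
primaryid$pt
1001$Respiratory failure
1002$Hepatic failure
1003$Nausea
"""
FAERS_OUTC = """\
primaryid$outc_cod
1001$DE
"""
FAERS_THER = """\
primaryid$dsg_drug_seq$start_dt$end_dt
1001$1$20200101$20200131
"""
FAERS_INDI = """\
primaryid$indi_drug_seq$indi_pt
1001$1$Malignant hyperthermia
"""


@pytest.fixture
def faers_fixture_dir(tmp_path):
    """Three-report FAERS-ASCII fixture whose hand parse the reader tests
    assert against."""
    d = tmp_path / "faers"
    d.mkdir()
    for name, text in [
        ("DEMO24Q1.txt", FAERS_DEMO),
        ("DRUG24Q1.txt", FAERS_DRUG),
        ("REAC24Q1.txt", FAERS_REAC),
        ("OUTC24Q1.txt", FAERS_OUTC),
        ("THER24Q1.txt", FAERS_THER),
        ("INDI24Q1.txt", FAERS_INDI),
    ]:
        (d / name).write_text(text)
    return d
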