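"""Readers and writers for spontaneous-report extracts.

Two input dialects are supported:

* ``faers-ascii`` — quarterly "$"-delimited table files in the FAERS style:
  one file per table (DEMO, DRUG, REAC and optionally OUTC, THER, INDI),
  first line a header, rows joined on the primary report identifier and,
  for therapy/indication rows, the drug sequence number.
* ``csv-generic`` — a flat RFC-4180 CSV with one row per
  report-drug-event triple, column roles supplied by a mapping.  This is
  also the package's lossless interchange format (``write_interchange``
  emits it with canonical column names, so a written set re-reads
  identically).

Parsing never raises on malformed field values: unparseable dates, ages or
codes become missing and are counted in the parse log attached to the
returned :class:`~pvsignals.reports.ReportSet` (``meta["parse_log"]``).
"""

from __future__ import annotations

import datetime as dt
import logging
import os
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .errors import ConfigurationError, InputError
from .reports import (
    MISSING,
    AEReport,
    DrugMention,
    EventMention,
    ReportSet,
    ROLE_CONCOMITANT,
    ROLE_INTERACTING,
    ROLE_PRIMARY,
    ROLE_SECONDARY,
    normalize_name,
    normalize_pt,
)

logger = logging.getLogger(__name__)


@dataclass
class ParseLog:
    """Accumulates per-row parse problems without interrupting ingestion."""

    entries: list[str] = field(default_factory=list)
    dropped_rows: int = 0

    def note(self, message: str) -> None:
        self.entries.append(message)

    def drop(self, message: str) -> None:
        self.dropped_rows += 1
        self.entries.append(message)

    def __len__(self) -> int:
        return len(self.entries)


# --------------------------------------------------------------------------
# date handling
#
# Dates arrive as YYYYMMDD; YYYYMM and YYYY are accepted at month/year
# precision.  Arithmetic that needs day precision (therapy dates, onset
# dates) treats lower-precision values as missing; version ordering accepts
# any precision coerced to the start of its period.

def parse_partial_date(s: str | None) -> tuple[dt.date | None, str | None]:
    """Parse a possibly partial date, returning ``(date, precision)`` where
    precision is "day", "month" or "year"; malformed input -> (None, None)."""
    if s is None:
        return None, None
    t = str(s).strip().replace("-", "")
    if not t:
        return None, None
    if not t.isdigit():
        return None, None
    try:
        if len(t) == 8:
            return dt.date(int(t[:4]), int(t[4:6]), int(t[6:8])), "day"
        if len(t) == 6:
            return dt.date(int(t[:4]), int(t[4:6]), 1), "month"
        if len(t) == 4:
            return dt.date(int(t), 1, 1), "year"
    except ValueError:
        return None, None
    return None, None


def _day_date(s: str | None, log: ParseLog, ctx: str) -> dt.date | None:
    """Day-precision date or None; logs malformed or low-precision input."""
    if s is None or str(s).strip() == "":
        return None
    d, prec = parse_partial_date(s)
    if d is None:
        log.note(f"{ctx}: unparseable date {s!r} set to missing")
        return None
    if prec != "day":
        log.note(f"{ctx}: {prec}-precision date {s!r} set to missing for day arithmetic")
        return None
    return d


def _any_date(s: str | None, log: ParseLog, ctx: str) -> dt.date | None:
    if s is None or str(s).strip() == "":
        return None
    d, _prec = parse_partial_date(s)
    if d is None:
        log.note(f"{ctx}: unparseable date {s!r} set to missing")
    return d


# --------------------------------------------------------------------------
# FAERS-ASCII dialect

@dataclass
class FaersColumns:
    """Column names of the FAERS-style tables; defaults match the public
    quarterly ASCII extracts."""

    primaryid: str = "primaryid"
    caseid: str = "caseid"
    fda_dt: str = "fda_dt"
    event_dt: str = "event_dt"
    sex: str = "sex"
    age: str = "age"
    age_cod: str = "age_cod"
    wt: str = "wt"
    wt_cod: str = "wt_cod"
    country: str = "occr_country"
    occp_cod: str = "occp_cod"
    drug_seq: str = "drug_seq"
    role_cod: str = "role_cod"
    drugname: str = "drugname"
    pt: str = "pt"
    outc_cod: str = "outc_cod"
    start_dt: str = "start_dt"
    end_dt: str = "end_dt"
    dsg_drug_seq: str = "dsg_drug_seq"
    indi_drug_seq: str = "indi_drug_seq"
    indi_pt: str = "indi_pt"


_ROLE_CODES = {
    "PS": ROLE_PRIMARY,
    "SS": ROLE_SECONDARY,
    "C": ROLE_CONCOMITANT,
    "I": ROLE_INTERACTING,
}
_OCCP_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "CN": "consumer",
    "HP": "health-professional",
    "LW": "other",
    "OT": "other",
}
_OUTC_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital-anomaly",
    "RI": "other-serious",
    "OT": "other-serious",
}
# per-unit factor converting the coded age to years
_AGE_UNITS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
_WEIGHT_UNITS = {"KG": 1.0, "LBS": 0.45359237, "GMS": 0.001}

_TABLE_TOKENS = ("demo", "drug", "reac", "outc", "ther", "indi")


def _classify_faers_files(paths) -> dict[str, str]:
    tables: dict[str, str] = {}
    for p in paths:
        if not os.path.exists(p):
            raise InputError(f"input file not found: {p}")
        base = os.path.basename(p).lower()
        for tok in _TABLE_TOKENS:
            if tok in base:
                tables[tok] = p
                break
        else:
            raise ConfigurationError(
                f"cannot classify FAERS table file {p!r}; expected one of "
                f"{_TABLE_TOKENS} in the file name"
            )
    if "demo" not in tables:
        raise ConfigurationError("FAERS input requires a DEMO table file")
    return tables


def _read_dollar(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")


def _age_years(age: str, cod: str, log: ParseLog, ctx: str) -> float | None:
    if age.strip() == "":
        return None
    try:
        v = float(age)
    except ValueError:
        log.note(f"{ctx}: unparseable age {age!r}")
        return None
    cod = cod.strip().upper()
    if cod == "":
        factor = 1.0  # blank unit code conventionally means years
    elif cod in _AGE_UNITS:
        factor = _AGE_UNITS[cod]
    else:
        log.note(f"{ctx}: unknown age unit {cod!r}, age set to missing")
        return None
    v *= factor
    if not (0 <= v < 150):
        log.note(f"{ctx}: implausible age {v:.1f} set to missing")
        return None
    return v


def _weight_kg(wt: str, cod: str, log: ParseLog, ctx: str) -> float | None:
    if wt.strip() == "":
        return None
    try:
        v = float(wt)
    except ValueError:
        log.note(f"{ctx}: unparseable weight {wt!r}")
        return None
    factor = _WEIGHT_UNITS.get(cod.strip().upper(), 1.0 if cod.strip() == "" else None)
    if factor is None:
        log.note(f"{ctx}: unknown weight unit {cod!r}, weight set to missing")
        return None
    v *= factor
    if not (0 < v < 700):
        log.note(f"{ctx}: implausible weight {v:.1f} set to missing")
        return None
    return v


def _read_faers(paths, cols: FaersColumns, source_db: str, log: ParseLog) -> list[AEReport]:
    tables = _classify_faers_files(paths)
    demo = _read_dollar(tables["demo"])

    def rows_by_key(tok: str) -> dict[str, list[dict]]:
        out: dict[str, list[dict]] = {}
        if tok not in tables:
            return out
        for row in _read_dollar(tables[tok]).to_dict("records"):
            out.setdefault(str(row.get(cols.primaryid, "")).strip(), []).append(row)
        return out

    drug_rows = rows_by_key("drug")
    reac_rows = rows_by_key("reac")
    outc_rows = rows_by_key("outc")
    ther_rows = rows_by_key("ther")
    indi_rows = rows_by_key("indi")

    def seq_map(rows: dict[str, list[dict]], seq_col: str) -> dict[tuple[str, str], dict]:
        out = {}
        for pid, rr in rows.items():
            for row in rr:
                out[(pid, str(row.get(seq_col, "")).strip())] = row
        return out

    ther_by_seq = seq_map(ther_rows, cols.dsg_drug_seq)
    indi_by_seq = seq_map(indi_rows, cols.indi_drug_seq)

    # last occurrence of a duplicated primaryid within the DEMO file wins
    demo_by_id: dict[str, dict] = {}
    for row in demo.to_dict("records"):
        pid = str(row.get(cols.primaryid, "")).strip()
        if not pid:
            log.drop("DEMO row with empty primary id dropped")
            continue
        if pid in demo_by_id:
            logger.warning("duplicate report id %s in DEMO; last occurrence wins", pid)
            log.note(f"DEMO: duplicate report id {pid}, last occurrence wins")
        demo_by_id[pid] = row

    reports: list[AEReport] = []
    for pid, row in demo_by_id.items():
        ctx = f"report {pid}"
        onset = _day_date(row.get(cols.event_dt, ""), log, ctx + " event_dt")
        sex_raw = str(row.get(cols.sex, "")).strip().upper()
        sex = {"F": "female", "M": "male"}.get(sex_raw)
        occp = str(row.get(cols.occp_cod, "")).strip().upper()
        reporter = _OCCP_CODES.get(occp) if occp else None
        if occp and reporter is None:
            log.note(f"{ctx}: unknown reporter code {occp!r}")
            reporter = "other"
        fda_raw = str(row.get(cols.fda_dt, "")).strip()
        version_date = _any_date(fda_raw, log, ctx + " fda_dt")
        receipt_year = version_date.year if version_date is not None else None

        drugs: list[DrugMention] = []
        for drow in drug_rows.get(pid, []):
            raw = str(drow.get(cols.drugname, "")).strip()
            if not raw:
                log.drop(f"{ctx}: DRUG row with empty name dropped")
                continue
            seq = str(drow.get(cols.drug_seq, "")).strip()
            ther = ther_by_seq.get((pid, seq), {})
            start = _day_date(ther.get(cols.start_dt, ""), log, ctx + " start_dt")
            end = _day_date(ther.get(cols.end_dt, ""), log, ctx + " end_dt")
            if start is not None and end is not None and end < start:
                log.note(f"{ctx}: therapy_end precedes therapy_start; end set to missing")
                end = None
            indi = indi_by_seq.get((pid, seq), {})
            indication = str(indi.get(cols.indi_pt, "")).strip() or None
            role = _ROLE_CODES.get(str(drow.get(cols.role_cod, "")).strip().upper())
            drugs.append(
                DrugMention(
                    drug_name_raw=raw,
                    drug_name_norm=normalize_name(raw),
                    role=role,
                    therapy_start=start,
                    therapy_end=end,
                    indication_pt=normalize_pt(indication) if indication else None,
                )
            )

        events: list[EventMention] = []
        for rrow in reac_rows.get(pid, []):
            pt = str(rrow.get(cols.pt, "")).strip()
            if not pt:
                log.drop(f"{ctx}: REAC row with empty PT dropped")
                continue
            events.append(EventMention(pt=pt, onset_date=onset))

        outcomes = set()
        for orow in outc_rows.get(pid, []):
            code = str(orow.get(cols.outc_cod, "")).strip().upper()
            if not code:
                continue
            mapped = _OUTC_CODES.get(code)
            if mapped is None:
                log.note(f"{ctx}: unknown outcome code {code!r} ignored")
                continue
            outcomes.add(mapped)

        caseid = str(row.get(cols.caseid, "")).strip() or pid
        reports.append(
            AEReport(
                report_id=pid,
                case_id=caseid,
                version_date=version_date,
                source_db=source_db,
                receipt_year=receipt_year,
                sex=sex,
                age_years=_age_years(
                    str(row.get(cols.age, "")), str(row.get(cols.age_cod, "")), log, ctx
                ),
                weight_kg=_weight_kg(
                    str(row.get(cols.wt, "")), str(row.get(cols.wt_cod, "")), log, ctx
                ),
                country=str(row.get(cols.country, "")).strip() or None,
                reporter=reporter,
                outcomes=frozenset(outcomes),
                drugs=drugs,
                events=events,
            )
        )
    return reports


# --------------------------------------------------------------------------
# generic CSV dialect / interchange format

#: canonical interchange columns, one row per report-drug-event triple
INTERCHANGE_COLUMNS = (
    "report_id",
    "case_id",
    "version_date",
    "source_db",
    "receipt_year",
    "sex",
    "age_years",
    "weight_kg",
    "country",
    "reporter",
    "outcomes",
    "drug_name",
    "drug_role",
    "therapy_start",
    "therapy_end",
    "indication_pt",
    "event_pt",
    "onset_date",
)

#: identity mapping for files already in interchange layout
DEFAULT_GENERIC_MAPPING = {c: c for c in INTERCHANGE_COLUMNS}

_GENERIC_REQUIRED = ("report_id", "drug_name", "event_pt")

_ROLE_ALIASES = {
    "ps": ROLE_PRIMARY,
    "primary suspect": ROLE_PRIMARY,
    "primary-suspect": ROLE_PRIMARY,
    "ss": ROLE_SECONDARY,
    "secondary suspect": ROLE_SECONDARY,
    "secondary-suspect": ROLE_SECONDARY,
    "c": ROLE_CONCOMITANT,
    "concomitant": ROLE_CONCOMITANT,
    "i": ROLE_INTERACTING,
    "interacting": ROLE_INTERACTING,
}
_REPORTER_ALIASES = {
    "consumer": "consumer",
    "health professional": "health-professional",
    "health-professional": "health-professional",
    "hp": "health-professional",
    "physician": "physician",
    "medical doctor": "physician",
    "md": "physician",
    "pharmacist": "pharmacist",
    "ph": "pharmacist",
    "other": "other",
}
_OUTCOME_ALIASES = {
    "death": "death",
    "life-threatening": "life-threatening",
    "hospitalization": "hospitalization",
    "disability": "disability",
    "congenital-anomaly": "congenital-anomaly",
    "other-serious": "other-serious",
    "not-serious": "not-serious",
}


def _get(row: dict, mapping: dict, role: str) -> str:
    col = mapping.get(role)
    if col is None:
        return ""
    v = row.get(col, "")
    return "" if v is None else str(v).strip()


def _read_generic(paths, mapping: dict, source_db: str, log: ParseLog) -> list[AEReport]:
    for role in _GENERIC_REQUIRED:
        if role not in mapping:
            raise ConfigurationError(f"generic-CSV mapping missing required column role {role!r}")
    frames = []
    for p in paths:
        if not os.path.exists(p):
            raise InputError(f"input file not found: {p}")
        frames.append(pd.read_csv(p, dtype=str, keep_default_na=False))
    rows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    grouped: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows.to_dict("records"):
        rid = _get(row, mapping, "report_id")
        if not rid:
            log.drop("row with empty report_id dropped")
            continue
        if rid not in grouped:
            grouped[rid] = []
            order.append(rid)
        grouped[rid].append(row)

    reports: list[AEReport] = []
    for rid in order:
        rrows = grouped[rid]
        head = rrows[0]
        ctx = f"report {rid}"

        sex_raw = _get(head, mapping, "sex").lower()
        sex = {"f": "female", "female": "female", "m": "male", "male": "male"}.get(sex_raw)
        if sex_raw and sex is None and sex_raw not in ("missing", "unk", "unknown"):
            log.note(f"{ctx}: unknown sex value {sex_raw!r}")

        def num(role: str, lo: float, hi: float) -> float | None:
            v = _get(head, mapping, role)
            if not v:
                return None
            try:
                x = float(v)
            except ValueError:
                log.note(f"{ctx}: unparseable {role} {v!r}")
                return None
            if not lo <= x < hi:
                log.note(f"{ctx}: implausible {role} {x}")
                return None
            return x

        rep_raw = _get(head, mapping, "reporter").lower()
        reporter = _REPORTER_ALIASES.get(rep_raw)
        outcomes = set()
        for tok in _get(head, mapping, "outcomes").split(";"):
            tok = tok.strip().lower()
            if not tok or tok == MISSING:
                continue
            mapped = _OUTCOME_ALIASES.get(tok)
            if mapped is None:
                log.note(f"{ctx}: unknown outcome {tok!r} ignored")
            else:
                outcomes.add(mapped)

        version_date = _any_date(_get(head, mapping, "version_date"), log, ctx + " version_date")
        year_raw = _get(head, mapping, "receipt_year")
        if year_raw:
            try:
                receipt_year = int(float(year_raw))
            except ValueError:
                log.note(f"{ctx}: unparseable receipt year {year_raw!r}")
                receipt_year = None
        elif version_date is not None:
            receipt_year = version_date.year
        else:
            receipt_year = None

        drugs: list[DrugMention] = []
        seen_drugs = set()
        events: list[EventMention] = []
        seen_events = set()
        for row in rrows:
            name = _get(row, mapping, "drug_name")
            if name:
                role_raw = _get(row, mapping, "drug_role").lower()
                role = _ROLE_ALIASES.get(role_raw)
                if role_raw and role is None and role_raw != MISSING:
                    log.note(f"{ctx}: unknown drug role {role_raw!r}")
                start = _day_date(_get(row, mapping, "therapy_start"), log, ctx + " therapy_start")
                end = _day_date(_get(row, mapping, "therapy_end"), log, ctx + " therapy_end")
                if start is not None and end is not None and end < start:
                    log.note(f"{ctx}: therapy_end precedes therapy_start; end set to missing")
                    end = None
                indication = _get(row, mapping, "indication_pt") or None
                key = (name, role, start, end, indication)
                if key not in seen_drugs:
                    seen_drugs.add(key)
                    drugs.append(
                        DrugMention(
                            drug_name_raw=name,
                            drug_name_norm=normalize_name(name),
                            role=role,
                            therapy_start=start,
                            therapy_end=end,
                            indication_pt=normalize_pt(indication) if indication else None,
                        )
                    )
            pt = _get(row, mapping, "event_pt")
            if pt:
                onset = _day_date(_get(row, mapping, "onset_date"), log, ctx + " onset_date")
                key = (normalize_pt(pt), onset)
                if key not in seen_events:
                    seen_events.add(key)
                    events.append(EventMention(pt=pt, onset_date=onset))

        case_id = _get(head, mapping, "case_id") or rid
        src = _get(head, mapping, "source_db") or source_db
        reports.append(
            AEReport(
                report_id=rid,
                case_id=case_id,
                version_date=version_date,
                source_db=src,
                receipt_year=receipt_year,
                sex=sex,
                age_years=num("age_years", 0, 150),
                weight_kg=num("weight_kg", 1e-6, 700),
                country=_get(head, mapping, "country") or None,
                reporter=reporter,
                outcomes=frozenset(outcomes),
                drugs=drugs,
                events=events,
            )
        )
    return reports


def read_reports(
    paths,
    dialect: str,
    mapping=None,
    source_db: str | None = None,
) -> ReportSet:
    """Read one or more report files into a :class:`ReportSet`.

    ``dialect`` is ``"faers-ascii"`` or ``"csv-generic"``; ``mapping`` is a
    :class:`FaersColumns` instance (FAERS) or a role -> column-name dict
    (generic CSV; defaults to the interchange layout).  Parse problems land
    in ``result.meta["parse_log"]``.
    """
    paths = list(paths)
    log = ParseLog()
    if dialect == "faers-ascii":
        cols = mapping or FaersColumns()
        reports = _read_faers(paths, cols, source_db or "FAERS-like", log)
    elif dialect == "csv-generic":
        m = dict(DEFAULT_GENERIC_MAPPING if mapping is None else mapping)
        reports = _read_generic(paths, m, source_db or "synthetic", log)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    if len(log):
        logger.info("read_reports: %d parse-log entries (%d rows dropped)",
                    len(log), log.dropped_rows)
    return ReportSet(
        reports=reports,
        provenance=f"read {len(paths)} file(s), dialect={dialect}",
        meta={"parse_log": log},
    )


def _iso(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def write_interchange(rs: ReportSet, path) -> None:
    """Write the report set as the flat interchange CSV (one row per
    report-drug-event triple; reports without drugs or events emit rows
    with the corresponding columns empty)."""
    records = []
    for r in rs.reports:
        drugs = r.drugs or [None]
        events = r.events or [None]
        for m, e in product(drugs, events):
            records.append(
                {
                    "report_id": r.report_id,
                    "case_id": r.case_id,
                    "version_date": _iso(r.version_date),
                    "source_db": r.source_db,
                    "receipt_year": "" if r.receipt_year is None else r.receipt_year,
                    "sex": r.sex or "",
                    "age_years": "" if r.age_years is None else r.age_years,
                    "weight_kg": "" if r.weight_kg is None else r.weight_kg,
                    "country": r.country or "",
                    "reporter": r.reporter or "",
                    "outcomes": ";".join(sorted(r.outcomes)),
                    "drug_name": m.drug_name_raw if m else "",
                    "drug_role": (m.role or "") if m else "",
                    "therapy_start": _iso(m.therapy_start) if m else "",
                    "therapy_end": _iso(m.therapy_end) if m else "",
                    "indication_pt": (m.indication_pt or "") if m else "",
                    "event_pt": e.pt if e else "",
                    "onset_date": _iso(e.onset_date) if e else "",
                }
            )
    df = pd.DataFrame.from_records(records, columns=list(INTERCHANGE_COLUMNS))
    df.to_csv(path, index=False)
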