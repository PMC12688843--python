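"""Core domain model for spontaneous adverse-event reports.

A spontaneous reporting system (SRS) such as FAERS, JADER or the Canadian
vigilance database collects case safety reports: one report describes one
patient, the drugs involved (each with a reporter-assigned role such as
"primary suspect"), and the adverse events coded as MedDRA Preferred Terms
(PTs).  The same clinical case may be submitted several times as updated
versions, so analysis starts by collapsing every case to its latest version.

This module holds the in-memory report objects plus the report-level
operations the downstream analyses depend on: deduplication, restriction to
reports where the drug of interest is the primary suspect, Table-1-style
demographic summaries (person-times counting: every report is an
independent instance, even if one patient appears repeatedly), and yearly
report counts.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
import re
from dataclasses import dataclass, field

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

# drug role codes (MedDRA/E2B vocabulary, lower-cased)
ROLE_PRIMARY = "primary-suspect"
ROLE_SECONDARY = "secondary-suspect"
ROLE_CONCOMITANT = "concomitant"
ROLE_INTERACTING = "interacting"
ROLES = (ROLE_PRIMARY, ROLE_SECONDARY, ROLE_CONCOMITANT, ROLE_INTERACTING)

SEXES = ("female", "male")
REPORTERS = ("consumer", "health-professional", "physician", "pharmacist", "other")

# Seriousness outcomes ordered from most to least severe; the demographic
# summary assigns each report its single most severe outcome so that the
# outcome column partitions the report set.
OUTCOME_SEVERITY = (
    "death",
    "life-threatening",
    "hospitalization",
    "disability",
    "congenital-anomaly",
    "other-serious",
    "not-serious",
)

#: trailing salt/ester words stripped during drug-name normalization
DEFAULT_SALT_SUFFIXES = (
    "sodium",
    "hydrochloride",
    "hcl",
    "sulfate",
    "sulphate",
    "mesylate",
    "maleate",
    "tartrate",
    "besylate",
)

MISSING = "missing"

_WS = re.compile(r"\s+")


def normalize_name(name: str, strip_suffixes: tuple[str, ...] = DEFAULT_SALT_SUFFIXES) -> str:
    """Normalize a drug name: lower-case, trim, collapse internal whitespace
    and strip trailing salt words ("Dantrolene  Sodium" -> "dantrolene")."""
    s = _WS.sub(" ", name.strip().lower())
    tokens = s.split(" ")
    while len(tokens) > 1 and tokens[-1] in strip_suffixes:
        tokens.pop()
    return " ".join(tokens)


def normalize_pt(pt: str) -> str:
    """Normalize a MedDRA Preferred Term for matching (lower-case, collapsed
    whitespace).  PT matching throughout the package is case-insensitive."""
    return _WS.sub(" ", pt.strip().lower())


@dataclass(slots=True)
class DrugMention:
    """One drug row of a report."""

    drug_name_raw: str
    drug_name_norm: str
    role: str | None = None
    therapy_start: dt.date | None = None
    therapy_end: dt.date | None = None
    indication_pt: str | None = None

    def __post_init__(self):
        if (
            self.therapy_start is not None
            and self.therapy_end is not None
            and self.therapy_end < self.therapy_start
        ):
            raise ValueError(
                f"therapy_end {self.therapy_end} precedes therapy_start {self.therapy_start}"
            )

    @property
    def duration_days(self) -> int | None:
        """Treatment duration in whole days, or None when either date is missing."""
        if self.therapy_start is None or self.therapy_end is None:
            return None
        return (self.therapy_end - self.therapy_start).days


@dataclass(slots=True)
class EventMention:
    """One adverse-event row of a report (MedDRA PT plus optional onset date)."""

    pt: str
    onset_date: dt.date | None = None

    def __post_init__(self):
        if not normalize_pt(self.pt):
            raise ValueError("event PT empty after normalization")


@dataclass(slots=True)
class AEReport:
    """One safety report.  ``case_id`` is stable across versions of the same
    clinical case; ``report_id`` identifies the submission."""

    report_id: str
    case_id: str
    version_date: dt.date | None = None
    source_db: str = "synthetic"
    receipt_year: int | None = None
    sex: str | None = None
    age_years: float | None = None
    weight_kg: float | None = None
    country: str | None = None
    reporter: str | None = None
    outcomes: frozenset[str] = frozenset()
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)

    def __post_init__(self):
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.age_years is not None and not (
            math.isfinite(self.age_years) and self.age_years >= 0
        ):
            raise ValueError(f"age_years invalid: {self.age_years}")
        if self.weight_kg is not None and not (
            math.isfinite(self.weight_kg) and self.weight_kg > 0
        ):
            raise ValueError(f"weight_kg invalid: {self.weight_kg}")

    def has_primary_suspect(self, names_norm: set[str]) -> bool:
        return any(
            m.role == ROLE_PRIMARY and m.drug_name_norm in names_norm for m in self.drugs
        )

    def event_pts_norm(self) -> set[str]:
        return {normalize_pt(e.pt) for e in self.events}


@dataclass
class ReportSet:
    """A collection of reports plus free-text provenance and a metadata dict
    (parse logs, generator truth, stage counters)."""

    reports: list[AEReport]
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


def _version_key(r: AEReport) -> tuple:
    # Latest version wins; same-date ties go to the lexicographically
    # greatest report_id (deterministic "latest report" reading).
    return (r.version_date or dt.date.min, r.report_id)


def deduplicate(rs: ReportSet) -> ReportSet:
    """Collapse every case to its single latest version.

    Keeps, per ``case_id``, the report with the greatest ``version_date``
    (missing dates sort first); ties break on ``report_id``.  Idempotent.
    """
    best: dict[str, AEReport] = {}
    order: list[str] = []
    for r in rs.reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            order.append(r.case_id)
        elif _version_key(r) > _version_key(cur):
            best[r.case_id] = r
    kept = [best[k] for k in order]
    removed = len(rs.reports) - len(kept)
    logger.info("deduplicate: removed %d of %d records", removed, len(rs.reports))
    meta = dict(rs.meta)
    meta["dedup_removed"] = removed
    return ReportSet(
        reports=kept,
        provenance=(rs.provenance + f"; deduplicated ({removed} removed)").lstrip("; "),
        meta=meta,
    )


def filter_primary_suspect(rs: ReportSet, drug_synonyms: set[str] | list[str]) -> ReportSet:
    """Keep only reports in which some drug mention whose normalized name is
    in ``drug_synonyms`` carries the primary-suspect role."""
    if not drug_synonyms:
        raise ConfigurationError("drug synonym set must be non-empty")
    syn = {normalize_name(s) for s in drug_synonyms}
    kept = [r for r in rs.reports if r.has_primary_suspect(syn)]
    logger.info("filter_primary_suspect: kept %d of %d reports", len(kept), len(rs.reports))
    meta = dict(rs.meta)
    meta["ps_filter_removed"] = len(rs.reports) - len(kept)
    return ReportSet(
        reports=kept,
        provenance=(rs.provenance + f"; primary-suspect filter {sorted(syn)}").lstrip("; "),
        meta=meta,
    )


# Default bands reproduce the conventional SRS baseline table:
# age <18 / 18-64 / 65-85 / >85 years, weight <50 / 50-100 / >100 kg.
DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = ((0, 18), (18, 65), (65, 86), (86, math.inf))
DEFAULT_WEIGHT_BANDS: tuple[tuple[float, float], ...] = ((0, 50), (50, 101), (101, math.inf))


def _check_bands(bands) -> list[tuple[float, float]]:
    out = [(float(lo), float(hi)) for lo, hi in bands]
    for lo, hi in out:
        if not lo < hi:
            raise ConfigurationError(f"band ({lo}, {hi}) is empty")
    for (lo1, hi1), (lo2, hi2) in zip(out, out[1:]):
        if hi1 > lo2:
            raise ConfigurationError(f"bands ({lo1},{hi1}) and ({lo2},{hi2}) overlap")
    return out


def _band_label(lo: float, hi: float, first: bool) -> str:
    if math.isinf(hi):
        return f">{lo - 1:g}"
    if first and lo <= 0:
        return f"<{hi:g}"
    return f"{lo:g}-{hi - 1:g}"


def _band_of(value: float | None, bands, labels: list[str]) -> str:
    if value is None:
        return MISSING
    for (lo, hi), lab in zip(bands, labels):
        if lo <= value < hi:
            return lab
    return MISSING  # outside every band


@dataclass
class DemographicSummary:
    """Counts (and derived percentages) per category over a report set.

    ``counts`` maps category name (sex, age, weight, country, reporter,
    outcome) to an ordered label -> count mapping whose values, including the
    ``missing`` bucket, sum to ``total``.
    """

    total: int
    counts: dict[str, dict[str, int]]

    def percentages(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for cat, labs in self.counts.items():
            out[cat] = {
                lab: (round(100.0 * n / self.total, 1) if self.total else 0.0)
                for lab, n in labs.items()
            }
        return out

    def as_rows(self) -> list[tuple[str, str, int, float]]:
        pct = self.percentages()
        return [
            (cat, lab, n, pct[cat][lab])
            for cat, labs in self.counts.items()
            for lab, n in labs.items()
        ]


def _most_severe_outcome(outcomes: frozenset[str]) -> str:
    for o in OUTCOME_SEVERITY:
        if o in outcomes:
            return o
    return MISSING


def summarize_demographics(
    rs: ReportSet,
    age_bands=DEFAULT_AGE_BANDS,
    weight_bands=DEFAULT_WEIGHT_BANDS,
) -> DemographicSummary:
    """Tabulate sex, banded age/weight, country, reporter and (most severe)
    outcome over the report set, counting person-times: every report is one
    instance regardless of patient identity."""
    age_bands = _check_bands(age_bands)
    weight_bands = _check_bands(weight_bands)
    age_labels = [_band_label(lo, hi, i == 0) for i, (lo, hi) in enumerate(age_bands)]
    weight_labels = [_band_label(lo, hi, i == 0) for i, (lo, hi) in enumerate(weight_bands)]

    total = len(rs.reports)
    sex_c = {s: 0 for s in SEXES} | {MISSING: 0}
    age_c = {lab: 0 for lab in age_labels} | {MISSING: 0}
    wt_c = {lab: 0 for lab in weight_labels} | {MISSING: 0}
    country_c: dict[str, int] = {}
    rep_c = {r: 0 for r in REPORTERS} | {MISSING: 0}
    out_c = {o: 0 for o in OUTCOME_SEVERITY} | {MISSING: 0}

    for r in rs.reports:
        sex_c[r.sex if r.sex in SEXES else MISSING] += 1
        age_c[_band_of(r.age_years, age_bands, age_labels)] += 1
        wt_c[_band_of(r.weight_kg, weight_bands, weight_labels)] += 1
        country_c[r.country or MISSING] = country_c.get(r.country or MISSING, 0) + 1
        rep_c[r.reporter if r.reporter in REPORTERS else MISSING] += 1
        out_c[_most_severe_outcome(r.outcomes)] += 1

    # countries ordered by descending count then name, missing bucket last
    ordered_countries = {
        k: country_c[k]
        for k in sorted((k for k in country_c if k != MISSING), key=lambda k: (-country_c[k], k))
    }
    ordered_countries[MISSING] = country_c.get(MISSING, 0)

    return DemographicSummary(
        total=total,
        counts={
            "sex": sex_c,
            "age": age_c,
            "weight": wt_c,
            "country": ordered_countries,
            "reporter": rep_c,
            "outcome": out_c,
        },
    )


def yearly_counts(rs: ReportSet) -> dict[int, int]:
    """Report counts keyed by receipt year; interior years with no reports
    are emitted with 0.  Reports with an unknown year are skipped."""
    raw: dict[int, int] = {}
    skipped = 0
    for r in rs.reports:
        if r.receipt_year is None:
            skipped += 1
            continue
        raw[r.receipt_year] = raw.get(r.receipt_year, 0) + 1
    if skipped:
        logger.info("yearly_counts: %d reports with missing receipt year skipped", skipped)
    if not raw:
        return {}
    return {y: raw.get(y, 0) for y in range(min(raw), max(raw) + 1)}
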