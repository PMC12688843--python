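"""Signal screening and stratified follow-up analyses.

After the disproportionality step flags combined-positive drug-event
pairs, three follow-ups narrow and characterize them:

* **IME filtering** keeps only signals whose PT appears on a user-supplied
  Important Medical Event term list (the MedDRA IME list is licensed and
  must be provided by the user as plain text, one PT per line);
* **subgroup contrasts** compare event reporting between two strata of the
  target-drug reports — age 18-44 vs >= 45 years, treatment duration
  <= 180 vs > 180 days, and indication (e.g. malignant hyperthermia vs
  other uses) — with a between-group reporting odds ratio and a two-sided
  Fisher exact p-value computed by exact hypergeometric enumeration;
* **time-to-onset** extracts per-PT latencies (event onset minus therapy
  start, whole days) and bins them into the conventional windows
  0-30 / 31-60 / 61-90 / 91-120 / 121-180 / >180 days, plus a two-bin
  <= 100 / > 100 day split; and a case-by-case listing extracts the full
  records of reports with a given indication.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .disproportionality import ContingencyTable
from .errors import ConfigurationError, DegenerateInputError
from .reports import ROLE_PRIMARY, AEReport, ReportSet, normalize_name, normalize_pt

logger = logging.getLogger(__name__)

GROUPINGS = ("age", "duration", "indication")

#: default day-window edges; the terminal bin is open-ended (">180")
DEFAULT_TTO_EDGES = (0, 31, 61, 91, 121, 181)
#: two-bin split used for short- vs long-latency contrasts
SPLIT_100_EDGES = (0, 101)


# --------------------------------------------------------------------------
# IME term list

@dataclass
class IMETermList:
    """Normalized set of Important-Medical-Event preferred terms."""

    terms: set[str]

    @classmethod
    def from_terms(cls, terms) -> "IMETermList":
        return cls(terms={normalize_pt(t) for t in terms if normalize_pt(t)})

    @classmethod
    def from_file(cls, path) -> "IMETermList":
        """Read a plain-text list: one PT per line, ``#`` starts a comment."""
        terms = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.append(line)
        return cls.from_terms(terms)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def filter_ime(signals, ime: IMETermList):
    """Keep the combined-positive signals whose PT is on the IME list
    (case-insensitive on the normalized term); input order is preserved."""
    if len(ime) == 0:
        raise ConfigurationError("IME term list is empty but IME filtering was requested")
    return [s for s in signals if s.positive_combined and s.pt in ime]


# --------------------------------------------------------------------------
# Fisher exact test by hypergeometric enumeration

@lru_cache(maxsize=200_000)
def _hypergeom_numerators(n: int, r1: int, c1: int) -> tuple[int, tuple[int, ...], int]:
    """Exact hypergeometric weights for 2x2 tables with row margin ``r1``
    and column margin ``c1`` out of ``n``: returns (a_min, numerators,
    common denominator C(n, r1))."""
    a_lo = max(0, r1 + c1 - n)
    a_hi = min(r1, c1)
    nums = tuple(math.comb(c1, a) * math.comb(n - c1, r1 - a) for a in range(a_lo, a_hi + 1))
    return a_lo, nums, math.comb(n, r1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value: the sum of the probabilities of all
    tables (with the observed margins) whose point probability does not
    exceed that of the observed table.  Ties are compared exactly in
    integer arithmetic, so no floating-point tie tolerance is needed."""
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ConfigurationError("Fisher exact requires non-negative integer cells")
    n = a + b + c + d
    if n == 0:
        raise DegenerateInputError("Fisher exact test on an empty table")
    a_lo, nums, denom = _hypergeom_numerators(n, a + b, a + c)
    obs = nums[a - a_lo]
    return min(1.0, sum(x for x in nums if x <= obs) / denom)


def _or_with_interval(t: ContingencyTable, ci_level: float = 0.95):
    """Odds ratio with log-normal interval; Haldane 0.5 correction applied
    when any cell is zero (otherwise uncorrected)."""
    from scipy.stats import norm

    if 0 in (t.a, t.b, t.c, t.d):
        a, b, c, d = t.haldane()
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    orv = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(0.5 + ci_level / 2.0))
    return orv, orv * math.exp(-z * se), orv * math.exp(z * se)


# --------------------------------------------------------------------------
# subgroup contrasts

@dataclass
class SubgroupResult:
    """One PT x grouping contrast: 2x2 table (rows = the two subgroups,
    columns = event vs all other events), between-group odds ratio with 95%
    interval, and the two-sided Fisher exact p-value."""

    pt: str
    grouping: str
    group_labels: tuple[str, str]
    table: ContingencyTable
    or_point: float
    or_lo: float
    or_hi: float
    fisher_p: float


def _assign_group(
    r: AEReport,
    grouping: str,
    age_bounds: tuple[float, float],
    duration_split: float,
    indication_terms: set[str],
) -> int | None:
    """0 = first group, 1 = second group, None = excluded (missing or out
    of range)."""
    if grouping == "age":
        lo, split = age_bounds
        if r.age_years is None or r.age_years < lo:
            return None
        return 0 if r.age_years < split else 1
    if grouping == "duration":
        ps = [m for m in r.drugs if m.role == ROLE_PRIMARY and m.duration_days is not None]
        if not ps:
            return None
        dur = ps[0].duration_days
        return 0 if dur <= duration_split else 1
    if grouping == "indication":
        inds = {m.indication_pt for m in r.drugs if m.role == ROLE_PRIMARY and m.indication_pt}
        if not inds:
            return None
        return 0 if inds & indication_terms else 1
    raise ConfigurationError(f"unknown grouping {grouping!r}")


def _group_labels(grouping, age_bounds, duration_split, indication_terms):
    if grouping == "age":
        lo, split = age_bounds
        return (f"{lo:g}-{split - 1:g}", f">={split:g}")
    if grouping == "duration":
        return (f"<={duration_split:g}d", f">{duration_split:g}d")
    return ("indication-match", "indication-other")


def subgroup_compare(
    rs: ReportSet,
    grouping: str,
    pt: str,
    age_bounds: tuple[float, float] = (18.0, 45.0),
    duration_split: float = 180.0,
    indication_terms=("malignant hyperthermia",),
) -> SubgroupResult:
    """Contrast the reporting of ``pt`` between two subgroups of a report
    set already restricted to the target drug as primary suspect.

    Age uses half-open bands [18, 45) vs [45, inf) with under-18 reports
    excluded; duration uses [0, 180] vs (180, inf) days on the
    primary-suspect mention; indication matches the (normalized) term set.
    Reports missing the grouping variable are excluded.
    """
    if grouping not in GROUPINGS:
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    ind = {normalize_pt(t) for t in indication_terms}
    enorm = normalize_pt(pt)
    counts = [[0, 0], [0, 0]]  # [group][has_event]
    for r in rs.reports:
        g = _assign_group(r, grouping, age_bounds, duration_split, ind)
        if g is None:
            continue
        counts[g][0 if enorm in r.event_pts_norm() else 1] += 1
    labels = _group_labels(grouping, age_bounds, duration_split, ind)
    for g in (0, 1):
        if counts[g][0] + counts[g][1] == 0:
            raise DegenerateInputError(
                f"subgroup {labels[g]!r} contains no reports for grouping {grouping!r}"
            )
    t = ContingencyTable(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    orv, lo, hi = _or_with_interval(t)
    p = fisher_exact_two_sided(t.a, t.b, t.c, t.d)
    return SubgroupResult(
        pt=pt, grouping=grouping, group_labels=labels, table=t,
        or_point=orv, or_lo=lo, or_hi=hi, fisher_p=p,
    )


# --------------------------------------------------------------------------
# time-to-onset

@dataclass
class TTOSummary:
    """Per-PT onset latencies (days from therapy start to event onset) for
    one drug, plus bookkeeping for mentions that could not contribute."""

    latencies_by_pt: dict[str, list[int]] = field(default_factory=dict)
    n_missing: int = 0
    n_negative: int = 0

    def all_latencies(self) -> list[int]:
        out: list[int] = []
        for v in self.latencies_by_pt.values():
            out.extend(v)
        return out

    @property
    def n_latencies(self) -> int:
        return sum(len(v) for v in self.latencies_by_pt.values())


def tto_extract(rs: ReportSet, drug: str) -> TTOSummary:
    """Latency extraction over every event mention of reports where ``drug``
    is the primary suspect: latency = onset date - therapy start of the
    primary-suspect mention, in whole days.  Mentions missing either date
    count as missing; negative latencies are dropped (and counted)."""
    dnorm = normalize_name(drug)
    out = TTOSummary()
    for r in rs.reports:
        ps = [m for m in r.drugs if m.role == ROLE_PRIMARY and m.drug_name_norm == dnorm]
        if not ps:
            continue
        start = next((m.therapy_start for m in ps if m.therapy_start is not None), None)
        for e in r.events:
            if start is None or e.onset_date is None:
                out.n_missing += 1
                continue
            lat = (e.onset_date - start).days
            if lat < 0:
                out.n_negative += 1
                logger.info("tto_extract: negative latency %d d dropped (report %s, %s)",
                            lat, r.report_id, e.pt)
                continue
            out.latencies_by_pt.setdefault(normalize_pt(e.pt), []).append(lat)
    return out


def tto_bin_labels(edges) -> list[str]:
    labels = [f"{int(lo)}-{int(hi) - 1}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{int(edges[-1]) - 1}")
    return labels


def tto_bin(latencies, edges=DEFAULT_TTO_EDGES) -> dict[str, int]:
    """Bin latencies into closed-open windows [lo, hi) with an open-ended
    terminal bin.  The default edges give 0-30 / 31-60 / 61-90 / 91-120 /
    121-180 / >180 days."""
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigurationError("TTO bin edges must be strictly increasing")
    arr = np.asarray(list(latencies), dtype=float)
    labels = tto_bin_labels(edges)
    if arr.size == 0:
        return {lab: 0 for lab in labels}
    counts, _ = np.histogram(arr, bins=edges + [np.inf])
    return {lab: int(c) for lab, c in zip(labels, counts)}


def split_100(latencies) -> dict[str, int]:
    """Convenience two-bin split at 100 days (0-100 vs >100)."""
    return tto_bin(latencies, SPLIT_100_EDGES)


# --------------------------------------------------------------------------
# case-by-case extraction

def extract_cases_by_indication(rs: ReportSet, indication_terms) -> pd.DataFrame:
    """Full listing of reports whose target-drug mention carries one of the
    given indications (case-insensitive), one row per report with
    demographics, outcomes and every event PT."""
    terms = {normalize_pt(t) for t in indication_terms}
    rows = []
    for r in rs.reports:
        match = [
            m for m in r.drugs
            if m.indication_pt is not None and normalize_pt(m.indication_pt) in terms
        ]
        if not match:
            continue
        m = match[0]
        rows.append(
            {
                "report_id": r.report_id,
                "case_id": r.case_id,
                "source_db": r.source_db,
                "receipt_year": r.receipt_year,
                "sex": r.sex or "",
                "age_years": r.age_years,
                "weight_kg": r.weight_kg,
                "country": r.country or "",
                "reporter": r.reporter or "",
                "outcomes": ";".join(sorted(r.outcomes)),
                "drug": m.drug_name_norm,
                "indication_pt": m.indication_pt,
                "therapy_start": m.therapy_start.isoformat() if m.therapy_start else "",
                "events": ";".join(sorted(normalize_pt(e.pt) for e in r.events)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "report_id", "case_id", "source_db", "receipt_year", "sex", "age_years",
            "weight_kg", "country", "reporter", "outcomes", "drug", "indication_pt",
            "therapy_start", "events",
        ],
    )
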