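"""Synthetic spontaneous-reporting-system generator with known ground truth.

The generator emulates the structure of a FAERS/JADER-style database at the
level the signal-detection pipeline consumes: reports carry zero or more
drug mentions (with role codes, therapy dates and an indication), one or
more MedDRA-PT event mentions with onset dates, demographics with realistic
missingness, receipt dates, and duplicate case versions.  Drug-event
dependence is planted explicitly: every (drug, event) pair has a known true
relative risk over an independence background, so recovery, false-positive
rate and interval coverage of the disproportionality indices can all be
measured against truth.

Generative model, per base report:

* each drug ``d`` is present independently with its marginal probability;
* each event ``e`` is included with probability
  ``min(1, baseline_e * max_d RR(d, e))``, the maximum running over the
  report's drugs (unplanted pairs have RR 1);
* a report must carry at least one event: empty reports are redrawn;
* onset = therapy start + a log-normal latency (the default, median 20 d
  with log-sd 1.5, puts mass both in the first month and beyond 180 days,
  the bimodal pattern typical of acute-use drugs with delayed sequelae);
* a configurable fraction of reports is re-emitted as a duplicate case
  version with a later version date, exercising deduplication.

All randomness flows from one seeded :class:`numpy.random.Generator`;
identical configuration and seed reproduce the report set exactly.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .reports import (
    AEReport,
    DrugMention,
    EventMention,
    ReportSet,
    ROLE_CONCOMITANT,
    ROLE_PRIMARY,
    normalize_name,
    normalize_pt,
)

logger = logging.getLogger(__name__)

MISSING = "missing"


class DrugSpec(BaseModel):
    name: str
    marginal: float = Field(ge=0.0, le=1.0)


class EventSpec(BaseModel):
    pt: str
    baseline: float = Field(ge=0.0, le=1.0)


class PlantedSignal(BaseModel):
    drug: str
    event: str
    rr: float = Field(ge=0.0, allow_inf_nan=False)


class OnsetModel(BaseModel):
    """Log-normal days from therapy start to event onset."""

    family: str = "lognormal"
    median_days: float = 20.0
    sigma_log: float = 1.5
    p_missing: float = Field(default=0.3, ge=0.0, le=1.0)

    @field_validator("family")
    @classmethod
    def _family(cls, v):
        if v != "lognormal":
            raise ValueError(f"unsupported onset model family {v!r}")
        return v


class Demographics(BaseModel):
    """Categorical distributions including explicit missingness masses.

    Age and weight are drawn as a band (with probability) then uniformly
    within the band.  Defaults approximate the demographic mix of adult
    spontaneous reports for a hospital-administered muscle relaxant:
    male-predominant, mostly 18-64 years, weight largely unrecorded.
    """

    sex: dict[str, float] = {"female": 0.28, "male": 0.55, MISSING: 0.17}
    age_bands: list[tuple[float, float, float]] = [
        (0.0, 18.0, 0.11),
        (18.0, 65.0, 0.46),
        (65.0, 86.0, 0.14),
        (86.0, 100.0, 0.01),
    ]
    age_missing: float = 0.28
    weight_bands: list[tuple[float, float, float]] = [
        (30.0, 50.0, 0.05),
        (50.0, 101.0, 0.10),
        (101.0, 150.0, 0.03),
    ]
    weight_missing: float = 0.82
    country: dict[str, float] = {
        "US": 0.34,
        "JP": 0.19,
        "NL": 0.15,
        "FR": 0.04,
        "GB": 0.04,
        "CA": 0.03,
        "DE": 0.04,
        MISSING: 0.17,
    }
    reporter: dict[str, float] = {
        "consumer": 0.26,
        "health-professional": 0.02,
        "physician": 0.31,
        "pharmacist": 0.20,
        "other": 0.15,
        MISSING: 0.06,
    }
    outcome: dict[str, float] = {
        "death": 0.11,
        "life-threatening": 0.10,
        "hospitalization": 0.27,
        "disability": 0.01,
        "other-serious": 0.39,
        MISSING: 0.12,
    }


class SyntheticConfig(BaseModel):
    """Full generative specification of a synthetic reporting database."""

    n_reports: int = Field(default=200_000, ge=0)
    drug_vocab: list[DrugSpec] = Field(min_length=1)
    event_vocab: list[EventSpec] = Field(min_length=1)
    planted_signals: list[PlantedSignal] = []
    target_drug: str = "dantrolene"
    p_primary_suspect: float = Field(default=0.9, ge=0.0, le=1.0)
    demographics: Demographics = Demographics()
    indications: dict[str, float] = {
        "malignant hyperthermia": 0.30,
        "muscle spasticity": 0.40,
        "neuroleptic malignant syndrome": 0.15,
        MISSING: 0.15,
    }
    date_range: tuple[int, int] = (2004, 2024)
    onset_model: OnsetModel = OnsetModel()
    therapy_duration_median_days: float = 30.0
    therapy_duration_sigma_log: float = 1.2
    p_therapy_start_missing: float = Field(default=0.2, ge=0.0, le=1.0)
    p_therapy_end_missing: float = Field(default=0.3, ge=0.0, le=1.0)
    duplicate_rate: float = Field(default=0.1, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start year exceeds end year")
        names = [d.name for d in self.drug_vocab]
        pts = [e.pt for e in self.event_vocab]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in vocabulary")
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate event PTs in vocabulary")
        for s in self.planted_signals:
            if s.drug not in names:
                raise ValueError(f"planted signal drug {s.drug!r} not in drug vocabulary")
            if s.event not in pts:
                raise ValueError(f"planted signal event {s.event!r} not in event vocabulary")
        return self


_BACKGROUND_DRUGS = (
    "baclofen",
    "diazepam",
    "ibuprofen",
    "metformin",
    "amoxicillin",
    "atorvastatin",
    "omeprazole",
    "sertraline",
    "lisinopril",
)
_BACKGROUND_EVENTS = (
    "nausea",
    "headache",
    "rhabdomyolysis",
    "hepatic failure",
    "dizziness",
    "vomiting",
    "rash",
    "pyrexia",
    "fatigue",
    "dyspnoea",
    "muscular weakness",
    "compartment syndrome",
    "pulmonary oedema",
    "cardiac arrest",
    "hepatotoxicity",
    "diarrhoea",
    "pruritus",
    "insomnia",
    "somnolence",
    "anaemia",
    "hypotension",
    "tachycardia",
    "renal impairment",
    "seizure",
    "confusional state",
    "oedema peripheral",
    "constipation",
    "cough",
    "abdominal pain",
)


def default_config(
    n_reports: int = 200_000,
    planted_rr: float = 30.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Reference configuration: a rare target drug (marginal 1e-3) with one
    planted pair onto a rare event (baseline 2e-3) over a background of 9
    common drugs and 29 background PTs whose baselines span 5e-3 .. 0.3 so
    reports naturally carry one or more events."""
    drug_marginals = np.geomspace(2e-3, 2e-2, len(_BACKGROUND_DRUGS))
    event_baselines = np.geomspace(5e-3, 0.3, len(_BACKGROUND_EVENTS))
    drugs = [DrugSpec(name="dantrolene", marginal=1e-3)] + [
        DrugSpec(name=n, marginal=float(p)) for n, p in zip(_BACKGROUND_DRUGS, drug_marginals)
    ]
    events = [EventSpec(pt="respiratory failure", baseline=2e-3)] + [
        EventSpec(pt=n, baseline=float(p)) for n, p in zip(_BACKGROUND_EVENTS, event_baselines)
    ]
    planted = (
        [PlantedSignal(drug="dantrolene", event="respiratory failure", rr=planted_rr)]
        if planted_rr is not None and planted_rr != 1.0
        else []
    )
    return SyntheticConfig(
        n_reports=n_reports,
        drug_vocab=drugs,
        event_vocab=events,
        planted_signals=planted,
        seed=seed,
    )


@dataclass
class TruthTable:
    """True relative risk for every (drug, event) vocabulary pair."""

    rr: dict[tuple[str, str], float]

    def get(self, drug: str, event: str) -> float:
        return self.rr[(normalize_name(drug), normalize_pt(event))]


def true_association_table(cfg: SyntheticConfig) -> TruthTable:
    rr = {
        (normalize_name(d.name), normalize_pt(e.pt)): 1.0
        for d in cfg.drug_vocab
        for e in cfg.event_vocab
    }
    for s in cfg.planted_signals:
        rr[(normalize_name(s.drug), normalize_pt(s.event))] = s.rr
    return TruthTable(rr=rr)


def _draw_categorical(rng, dist: dict[str, float], n: int) -> list[str | None]:
    labels = list(dist.keys())
    p = np.asarray([dist[k] for k in labels], dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability in categorical distribution")
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return [None if labels[i] == MISSING else labels[i] for i in idx]


def _draw_banded(rng, bands, p_missing: float, n: int) -> np.ndarray:
    """Band-then-uniform draw; NaN marks missing."""
    probs = np.asarray([b[2] for b in bands], dtype=float)
    total = probs.sum() + p_missing
    p = np.concatenate([probs, [p_missing]]) / total
    idx = rng.choice(len(bands) + 1, size=n, p=p)
    u = rng.random(n)
    out = np.full(n, np.nan)
    for i, (lo, hi, _) in enumerate(bands):
        m = idx == i
        out[m] = lo + u[m] * (hi - lo)
    return out


def generate_reports(cfg: SyntheticConfig) -> ReportSet:
    """Generate the synthetic database described by ``cfg``.

    Returns a :class:`ReportSet` of ``cfg.n_reports`` base reports plus
    duplicate case versions; ``meta`` records the duplicate count and any
    probability clipping.  Byte-identical for identical config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drug_names = [d.name for d in cfg.drug_vocab]
    event_pts = [e.pt for e in cfg.event_vocab]
    D, E = len(drug_names), len(event_pts)
    drug_p = np.asarray([d.marginal for d in cfg.drug_vocab])
    base_p = np.asarray([e.baseline for e in cfg.event_vocab])

    if n == 0:
        return ReportSet(reports=[], provenance="synthetic (0 reports)",
                         meta={"n_duplicates": 0, "clipped_probabilities": 0})

    # drug presence, then per-report event probabilities via max-RR scaling
    present = rng.random((n, D)) < drug_p
    mult = np.ones((n, E))
    didx = {d: i for i, d in enumerate(drug_names)}
    eidx = {e: j for j, e in enumerate(event_pts)}
    for s in cfg.planted_signals:
        rows = present[:, didx[s.drug]]
        j = eidx[s.event]
        mult[rows, j] = np.maximum(mult[rows, j], s.rr)
    ev_p = base_p * mult
    clipped = int((ev_p > 1.0).sum())
    if clipped:
        logger.warning("generate_reports: %d event probabilities clipped to 1", clipped)
        ev_p = np.minimum(ev_p, 1.0)

    ev = rng.random((n, E)) < ev_p
    # every report needs at least one event: redraw empty rows
    for _ in range(100):
        empty = ~ev.any(axis=1)
        if not empty.any():
            break
        k = int(empty.sum())
        ev[empty] = rng.random((k, E)) < ev_p[empty]
    else:
        empty = np.flatnonzero(~ev.any(axis=1))
        for i in empty:  # force one event proportional to the row's profile
            p = ev_p[i] / ev_p[i].sum()
            ev[i, rng.choice(E, p=p)] = True

    # demographics
    sex = _draw_categorical(rng, cfg.demographics.sex, n)
    age = _draw_banded(rng, cfg.demographics.age_bands, cfg.demographics.age_missing, n)
    weight = _draw_banded(rng, cfg.demographics.weight_bands, cfg.demographics.weight_missing, n)
    country = _draw_categorical(rng, cfg.demographics.country, n)
    reporter = _draw_categorical(rng, cfg.demographics.reporter, n)
    outcome = _draw_categorical(rng, cfg.demographics.outcome, n)

    # dates: therapy start uniform over the configured range; onset = start
    # + log-normal latency; receipt shortly after onset
    y0, y1 = cfg.date_range
    span_start = dt.date(y0, 1, 1).toordinal()
    span_days = dt.date(y1, 12, 31).toordinal() - span_start + 1
    start_ord = span_start + rng.integers(0, span_days, size=n)
    mu = math.log(cfg.onset_model.median_days)
    latency = np.floor(rng.lognormal(mu, cfg.onset_model.sigma_log, size=n)).astype(int)
    onset_ord = start_ord + latency
    receipt_ord = onset_ord + rng.integers(0, 61, size=n)
    duration = np.floor(
        rng.lognormal(
            math.log(cfg.therapy_duration_median_days),
            cfg.therapy_duration_sigma_log,
            size=n,
        )
    ).astype(int)

    start_missing = rng.random(n) < cfg.p_therapy_start_missing
    end_missing = rng.random(n) < cfg.p_therapy_end_missing
    onset_missing = rng.random(n) < cfg.onset_model.p_missing

    # roles and indications per drug mention
    role_ps = rng.random((n, D)) < cfg.p_primary_suspect
    ind_labels = list(cfg.indications.keys())
    ind_p = np.asarray([cfg.indications[k] for k in ind_labels], dtype=float)
    ind_p = ind_p / ind_p.sum()
    ind_idx = rng.choice(len(ind_labels), size=n, p=ind_p)
    target_idx = didx.get(cfg.target_drug)

    dup_mask = rng.random(n) < cfg.duplicate_rate
    dup_bump = rng.integers(1, 401, size=n)

    drug_rows, drug_cols = np.nonzero(present)
    ev_rows, ev_cols = np.nonzero(ev)
    drug_split = np.searchsorted(drug_rows, np.arange(n + 1))
    ev_split = np.searchsorted(ev_rows, np.arange(n + 1))

    reports: list[AEReport] = []
    duplicates: list[AEReport] = []
    from_ordinal = dt.date.fromordinal
    for i in range(n):
        start = None if start_missing[i] else from_ordinal(int(start_ord[i]))
        end = (
            None
            if (start is None or end_missing[i])
            else from_ordinal(int(start_ord[i] + duration[i]))
        )
        onset = None if onset_missing[i] else from_ordinal(int(onset_ord[i]))
        receipt = from_ordinal(int(receipt_ord[i]))

        mentions = []
        for j in drug_cols[drug_split[i] : drug_split[i + 1]]:
            name = drug_names[j]
            indication = None
            if target_idx is not None and j == target_idx:
                lab = ind_labels[ind_idx[i]]
                indication = None if lab == MISSING else normalize_pt(lab)
            mentions.append(
                DrugMention(
                    drug_name_raw=name,
                    drug_name_norm=normalize_name(name),
                    role=ROLE_PRIMARY if role_ps[i, j] else ROLE_CONCOMITANT,
                    therapy_start=start,
                    therapy_end=end,
                    indication_pt=indication,
                )
            )
        events = [
            EventMention(pt=event_pts[j], onset_date=onset)
            for j in ev_cols[ev_split[i] : ev_split[i + 1]]
        ]
        outs = frozenset() if outcome[i] is None else frozenset([outcome[i]])
        rep = AEReport(
            report_id=f"S{i:08d}",
            case_id=f"C{i:08d}",
            version_date=receipt,
            source_db="synthetic",
            receipt_year=receipt.year,
            sex=sex[i],
            age_years=None if np.isnan(age[i]) else float(age[i]),
            weight_kg=None if np.isnan(weight[i]) else float(weight[i]),
            country=country[i],
            reporter=reporter[i],
            outcomes=outs,
            drugs=mentions,
            events=events,
        )
        reports.append(rep)
        if dup_mask[i]:
            duplicates.append(
                AEReport(
                    report_id=f"S{i:08d}D",
                    case_id=rep.case_id,
                    version_date=receipt + dt.timedelta(days=int(dup_bump[i])),
                    source_db=rep.source_db,
                    receipt_year=rep.receipt_year,
                    sex=rep.sex,
                    age_years=rep.age_years,
                    weight_kg=rep.weight_kg,
                    country=rep.country,
                    reporter=rep.reporter,
                    outcomes=rep.outcomes,
                    drugs=list(rep.drugs),
                    events=list(rep.events),
                )
            )

    logger.info(
        "generate_reports: %d base reports + %d duplicates (seed %d)",
        n, len(duplicates), cfg.seed,
    )
    return ReportSet(
        reports=reports + duplicates,
        provenance=f"synthetic (n={n}, seed={cfg.seed}, duplicates={len(duplicates)})",
        meta={"n_duplicates": len(duplicates), "clipped_probabilities": clipped},
    )
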