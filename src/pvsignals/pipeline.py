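"""End-to-end pipeline: one configuration in, every analysis table out.

Stages: read or generate reports -> deduplicate -> primary-suspect
restriction for the target drug -> demographics and yearly counts ->
all-pair disproportionality scoring and classification -> IME filter ->
subgroup contrasts -> time-to-onset -> case-by-case listing.  Every output
is a CSV with stable column order; a manifest records the configuration
hash, seed and per-stage report counts so that identical configuration and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import reports as rep
from . import screening as scr
from .disproportionality import Thresholds, score_all_pairs
from .errors import ConfigurationError, PipelineError
from .io import FaersColumns, read_reports, write_interchange
from .reports import ReportSet
from .simulate import SyntheticConfig, default_config, generate_reports

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demographics", "yearly", "signals", "signals_ime", "subgroups", "tto", "cases")


class FileInput(BaseModel):
    dialect: str  # "faers-ascii" | "csv-generic"
    paths: list[str]
    mapping: dict[str, str] | None = None
    source_db: str | None = None


class ThresholdConfig(BaseModel):
    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    eb05_min: float = 2.0
    ror_lo_min: float = 1.0
    ci_level: float = 0.95

    def to_thresholds(self) -> Thresholds:
        return Thresholds(**self.model_dump())


class RunConfig(BaseModel):
    """Full run specification (JSON or YAML on disk)."""

    synthetic: SyntheticConfig | None = None
    files: FileInput | None = None
    target_drug: str = "dantrolene"
    drug_synonyms: list[str] = ["dantrolene", "dantrolene sodium", "dantrium",
                                "revonto", "ryanodex"]
    thresholds: ThresholdConfig = ThresholdConfig()
    mgps: str = "simple"  # "simple" | "full"
    score_drugs: str = "target"  # "target" | "all"
    age_bounds: tuple[float, float] = (18.0, 45.0)
    duration_split: float = 180.0
    indication_terms: list[str] = ["malignant hyperthermia"]
    tto_edges: list[float] = [0, 31, 61, 91, 121, 181]
    ime_list: str | None = None
    out_dir: str = "pvsignals_out"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.files is None):
            raise ValueError("exactly one input source (synthetic or files) must be set")
        if not self.target_drug:
            raise ValueError("target_drug must be non-empty")
        if self.mgps not in ("simple", "full"):
            raise ValueError(f"mgps must be 'simple' or 'full', got {self.mgps!r}")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(payload, dict):
            raise ConfigurationError(f"run configuration {path} is not a mapping")
        return cls.model_validate(payload)


@dataclass
class PipelineResult:
    frames: dict[str, pd.DataFrame]
    paths: dict[str, str]
    manifest: dict


def _load_input(cfg: RunConfig) -> ReportSet:
    if cfg.synthetic is not None:
        # the run seed overrides the embedded generator seed so that one
        # --seed flag controls the whole run
        syn = cfg.synthetic.model_copy(update={"seed": cfg.seed})
        return generate_reports(syn)
    fi = cfg.files
    mapping = None
    if fi.dialect == "faers-ascii" and fi.mapping:
        mapping = FaersColumns(**fi.mapping)
    elif fi.mapping:
        mapping = fi.mapping
    return read_reports(fi.paths, fi.dialect, mapping=mapping, source_db=fi.source_db)


# columns whose values are rendered with 2 decimals in the CSVs
_INDEX_COLS = {
    "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "eb05",
    "or_point", "or_lo", "or_hi",
}
_P_COLS = {"fisher_p"}
_PCT_COLS = {"percent"}


def _fmt_value(col: str, v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if col in _INDEX_COLS:
        return "inf" if v == math.inf else f"{v:.2f}"
    if col in _P_COLS:
        return f"{v:.2e}" if v < 0.001 else f"{v:.4f}"
    if col in _PCT_COLS:
        return f"{v:.1f}"
    return v


def write_report_tables(frames: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write every analysis table as CSV with deterministic formatting:
    indices at 2 decimals, p-values scientific below 0.001."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        df = frames.get(name, pd.DataFrame())
        out = df.copy()
        for col in out.columns:
            if col in _INDEX_COLS | _P_COLS | _PCT_COLS:
                out[col] = [_fmt_value(col, v) for v in out[col]]
        path = os.path.join(out_dir, f"{name}.csv")
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``cfg`` and write all tables
    plus ``manifest.json`` into ``cfg.out_dir``.  Any stage failure is
    re-raised as :class:`PipelineError` naming the stage, and files already
    written for this run are removed."""
    written: list[str] = []
    stage = "configure"
    try:
        th = cfg.thresholds.to_thresholds()

        stage = "input"
        rs = _load_input(cfg)
        n_raw = len(rs)

        stage = "deduplicate"
        rs = rep.deduplicate(rs)
        n_dedup = len(rs)

        stage = "primary-suspect-filter"
        rs_drug = rep.filter_primary_suspect(rs, cfg.drug_synonyms)
        n_drug = len(rs_drug)

        stage = "demographics"
        summary = rep.summarize_demographics(rs_drug)
        demo_df = pd.DataFrame(
            summary.as_rows(), columns=["category", "label", "count", "percent"]
        )
        years = rep.yearly_counts(rs_drug)
        yearly_df = pd.DataFrame(
            {"year": list(years.keys()), "count": list(years.values())}
        )

        stage = "scoring"
        drugs = None if cfg.score_drugs == "all" else [cfg.target_drug]
        signals = score_all_pairs(
            rs, drugs=drugs, thresholds=th, min_a=1, mgps=cfg.mgps
        )
        n_scored_from = len(rs)

        stage = "ime-filter"
        if cfg.ime_list is not None:
            ime = scr.IMETermList.from_file(cfg.ime_list)
            keep = signals["positive_combined"] & signals["pt"].isin(ime.terms)
            signals_ime = signals[keep].reset_index(drop=True)
        else:
            signals_ime = signals[signals["positive_combined"]].reset_index(drop=True)

        stage = "subgroups"
        sub_rows = []
        target_pts = signals.loc[
            (signals["drug"] == rep.normalize_name(cfg.target_drug))
            & (signals["a"] >= th.min_a),
            "pt",
        ]
        for pt in target_pts:
            for grouping in scr.GROUPINGS:
                try:
                    res = scr.subgroup_compare(
                        rs_drug, grouping, pt,
                        age_bounds=cfg.age_bounds,
                        duration_split=cfg.duration_split,
                        indication_terms=cfg.indication_terms,
                    )
                except Exception as exc:  # degenerate group: skip, keep going
                    logger.info("subgroup %s/%s skipped: %s", grouping, pt, exc)
                    continue
                sub_rows.append(
                    {
                        "pt": pt,
                        "grouping": grouping,
                        "group1": res.group_labels[0],
                        "group2": res.group_labels[1],
                        "a": res.table.a, "b": res.table.b,
                        "c": res.table.c, "d": res.table.d,
                        "or_point": res.or_point,
                        "or_lo": res.or_lo, "or_hi": res.or_hi,
                        "fisher_p": res.fisher_p,
                        "log2_or": math.log2(res.or_point) if res.or_point > 0 else math.nan,
                        "neg_log10_p": -math.log10(res.fisher_p) if res.fisher_p > 0 else math.nan,
                    }
                )
        sub_cols = ["pt", "grouping", "group1", "group2", "a", "b", "c", "d",
                    "or_point", "or_lo", "or_hi", "fisher_p", "log2_or", "neg_log10_p"]
        subgroups_df = pd.DataFrame(sub_rows, columns=sub_cols)

        stage = "tto"
        tto = scr.tto_extract(rs_drug, cfg.target_drug)
        tto_rows = []
        labels = scr.tto_bin_labels([float(e) for e in cfg.tto_edges])
        overall = scr.tto_bin(tto.all_latencies(), cfg.tto_edges)
        tto_rows.append({"pt": "(all)", "n": tto.n_latencies,
                         "n_missing": tto.n_missing, "n_negative": tto.n_negative,
                         **{f"bin_{lab}": c for lab, c in overall.items()}})
        for pt in sorted(tto.latencies_by_pt):
            bins = scr.tto_bin(tto.latencies_by_pt[pt], cfg.tto_edges)
            tto_rows.append({"pt": pt, "n": len(tto.latencies_by_pt[pt]),
                             "n_missing": "", "n_negative": "",
                             **{f"bin_{lab}": c for lab, c in bins.items()}})
        tto_df = pd.DataFrame(
            tto_rows,
            columns=["pt", "n", "n_missing", "n_negative"] + [f"bin_{lab}" for lab in labels],
        )

        stage = "cases"
        cases_df = scr.extract_cases_by_indication(rs_drug, cfg.indication_terms)

        stage = "write"
        frames = {
            "demographics": demo_df,
            "yearly": yearly_df,
            "signals": signals,
            "signals_ime": signals_ime,
            "subgroups": subgroups_df,
            "tto": tto_df,
            "cases": cases_df,
        }
        paths = write_report_tables(frames, cfg.out_dir)
        written.extend(paths.values())

        # the hash identifies the analysis, not where it was written
        cfg_json = cfg.model_dump_json(exclude={"out_dir"})
        manifest = {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "counts": {
                "raw_reports": n_raw,
                "after_dedup": n_dedup,
                "target_primary_suspect": n_drug,
                "entering_scoring": n_scored_from,
                "scored_pairs": int(len(signals)),
                "combined_positive": int(signals["positive_combined"].sum()),
                "ime_signals": int(len(signals_ime)),
            },
            "tables": {k: os.path.basename(v) for k, v in paths.items()},
        }
        # stage-count conservation: scoring consumes exactly the deduplicated set
        assert n_scored_from == n_dedup, "scoring input must equal deduplicated set"
        mpath = os.path.join(cfg.out_dir, "manifest.json")
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(mpath)
        paths["manifest"] = mpath

        # interchange copy of the deduplicated target-drug reports for
        # stage-wise reruns
        ipath = os.path.join(cfg.out_dir, "reports.csv")
        write_interchange(rs_drug, ipath)
        paths["reports"] = ipath

        return PipelineResult(frames=frames, paths=paths, manifest=manifest)
    except Exception as exc:
        for p in written:
            try:
                os.remove(p)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
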