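"""End-to-end orchestration: generate -> link -> review -> filter -> score ->
release -> denominator flags, with a run manifest and evaluation metrics.

Every stage writes its table to the run directory as documented CSV, so
any stage can also be re-run standalone from files via the CLI.  The run
is fully determined by the configuration (including the seed); the
manifest records a configuration hash and per-stage row counts satisfying
conservation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import date
from pathlib import Path
from typing import Mapping

from . import io
from ._names import IN_AREA_OUTWARDS
from .denominator import cohort_residence_flags, denominator_summary
from .disclosure import build_release, scan_for_leaks
from .deterministic import deterministic_link
from .events import count_records_and_offences, filter_events
from .probabilistic import (
    DEFAULT_SCHEME,
    DEFAULT_THRESHOLD,
    probabilistic_link,
)
from .records import GenParams
from .review import combine_candidates, evaluate_links, flow_report, run_review
from .severity import HarmTable, score_events
from .synthgen import generate_all

DEFAULT_CONFIG: dict = {
    "gen": {},  # GenParams overrides
    "linkage": {
        "threshold": DEFAULT_THRESHOLD,
        "scheme": list(DEFAULT_SCHEME),
    },
    "release": {
        "salt": "release-salt",
        "severity_cutoff": 10.0,
        "offender_count_cutoff": 5,
        "missingness_threshold": 0.90,
    },
}


def merge_config(config: Mapping | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def params_from_config(config: Mapping) -> GenParams:
    overrides = dict(config.get("gen", {}))
    date_fields = {
        f.name for f in dataclasses.fields(GenParams) if f.type in ("date", date)
    } | {"era_boundary", "electronic_start", "court_data_start", "extraction_date",
         "dob_start", "dob_end"}
    for key, value in list(overrides.items()):
        if key in date_fields and isinstance(value, str):
            overrides[key] = date.fromisoformat(value)
    return GenParams(**overrides)


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def in_area_predicate(postcode) -> bool:
    """Default policing-area test against the synthetic gazetteer."""
    return postcode.outward in IN_AREA_OUTWARDS


def run_pipeline(config: Mapping | None, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the whole pipeline into ``out_dir``; returns the manifest dict."""
    cfg = merge_config(config)
    if seed is not None:
        cfg.setdefault("gen", {})["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log = open(log_path, "w")

    def _log(stage: str, **fields) -> None:
        log.write(json.dumps({"stage": stage, **fields}) + "\n")

    params = params_from_config(cfg)

    # --- synth ---------------------------------------------------------
    cohort, subjects, truth, events = generate_all(params)
    io.write_csv(io.cohort_to_frame(cohort), out / "cohort.csv")
    io.write_csv(io.subjects_to_frame(subjects), out / "subjects.csv")
    io.write_csv(io.truth_to_frame(truth), out / "truth.csv")
    io.write_csv(io.events_to_frame(events), out / "events.csv")
    _log("synth", cohort=len(cohort), subjects=len(subjects),
         truth_pairs=len(truth), events=len(events))

    # --- link ----------------------------------------------------------
    linkable = [r for r in cohort if r.linkage_permitted]
    det = deterministic_link(linkable, subjects)
    prob = probabilistic_link(
        linkable,
        subjects,
        threshold=float(cfg["linkage"]["threshold"]),
        scheme=tuple(cfg["linkage"]["scheme"]),
    )
    candidates = combine_candidates(det, prob)
    io.write_csv(io.candidates_to_frame(candidates), out / "candidates.csv")
    _log("link", deterministic=len(det), probabilistic=len(prob),
         candidates=len(candidates))

    # --- review --------------------------------------------------------
    link_table = run_review(candidates, cohort)
    io.write_csv(io.link_table_to_frame(link_table), out / "link_table.csv")
    (out / "ledger.json").write_text(json.dumps(link_table.ledger, indent=2))
    flow = flow_report(candidates, link_table)
    (out / "flow_report.json").write_text(json.dumps(flow, indent=2))
    _log("review", **{k: v for k, v in flow.items() if not isinstance(v, dict)})

    # --- filter + severity --------------------------------------------
    linked = filter_events(events, link_table, era_boundary=params.era_boundary)
    linked = score_events(linked, HarmTable.default())
    io.write_csv(linked, out / "linked_events.csv")
    n_records, n_offences, n_individuals = count_records_and_offences(linked)
    _log("filter", records=n_records, offences=n_offences, individuals=n_individuals)

    # --- release -------------------------------------------------------
    release, drop_report = build_release(linked, cohort, cfg["release"])
    io.write_csv(release, out / "release.csv")
    (out / "drop_report.json").write_text(json.dumps(drop_report, indent=2))
    raw_strings = (
        {r.forename for r in cohort} | {r.surname for r in cohort}
        | {str(p) for r in cohort for p in r.postcodes}
        | {s.forename for s in subjects} | {s.surname for s in subjects}
        | {str(p) for s in subjects for p in s.postcodes}
        | {s.offender_id for s in subjects}
        | {e.occurrence_id for e in events}
        | {e.casefile_id for e in events if e.casefile_id}
        | {e.from_date.isoformat() for e in events}
    )
    leaks = scan_for_leaks(release, raw_strings)
    _log("release", rows=len(release), leaks=len(leaks))

    # --- denominator flags --------------------------------------------
    flags = cohort_residence_flags(cohort, in_area_predicate)
    io.write_csv(flags, out / "flags.csv")
    denom = denominator_summary(flags)

    # --- evaluation ----------------------------------------------------
    evaluation = evaluate_links(link_table, truth, cohort)
    evaluation["leak_hits"] = len(leaks)
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    _log("evaluate", **{k: evaluation[k] for k in ("precision", "recall")})
    log.close()

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": params.seed,
        "stage_counts": {
            "cohort": len(cohort),
            "subjects": len(subjects),
            "truth_pairs": len(truth),
            "events": len(events),
            "candidates": len(candidates),
            "link_rows": len(link_table.rows),
            "removed": sum(link_table.ledger.values()),
            "linked_records": n_records,
            "linked_offences": n_offences,
            "linked_individuals": n_individuals,
            "release_rows": len(release),
        },
        "flow": flow,
        "evaluation": evaluation,
        "denominator": {"every_birthday": denom["every_birthday"]},
        "drop_report": drop_report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
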