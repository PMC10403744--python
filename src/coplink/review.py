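"""Manual-review rules, duplicate resolution and the linkage flow report.

Two review rules guard the probabilistic links: a twin check (twins share
surname, date of birth and usually address, so a sibling's police record
can link to the wrong co-twin) and a low-confidence review of the bottom
decile of match scores.  Duplicate resolution then enforces that each
offender_id belongs to at most one participant, while one participant may
legitimately hold several offender_ids (police-side identity
fragmentation).  Every removal is recorded in a ledger so that the
stage-by-stage flow of candidates is conserved and reportable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .records import CohortRecord, LinkTable, MatchCandidate

REMOVED_TWIN = "removed_twin"
REMOVED_LOW_CONFIDENCE = "removed_low_confidence"
REMOVED_DUPLICATE = "removed_duplicate"


def combine_candidates(
    deterministic: Iterable[MatchCandidate], probabilistic: Iterable[MatchCandidate]
) -> list[MatchCandidate]:
    """Union of both methods' candidates; pairs found both ways keep the
    deterministic record (with its strength tier)."""
    seen: dict[tuple[str, str], MatchCandidate] = {}
    for cand in deterministic:
        seen[(cand.study_id, cand.offender_id)] = cand
    for cand in probabilistic:
        seen.setdefault((cand.study_id, cand.offender_id), cand)
    return list(seen.values())


def twin_check(
    candidates: Sequence[MatchCandidate], cohort: Sequence[CohortRecord]
) -> list[MatchCandidate]:
    """Mark twin-flagged candidates removed unless sex and the first two
    characters of forename both agree with the police identifiers."""
    twins = {r.study_id for r in cohort if r.twin_group}
    for cand in candidates:
        if cand.status != "accepted" or cand.study_id not in twins:
            continue
        ok = cand.agreements.get("sex_exact") and cand.agreements.get("forename_first2")
        if not ok:
            cand.status = REMOVED_TWIN
    return list(candidates)


def _passes_low_confidence_rules(cand: MatchCandidate) -> bool:
    a = cand.agreements
    return bool(
        (a.get("forename_exact") and a.get("dob_exact"))
        or (a.get("surname_exact") and a.get("dob_exact"))
        or a.get("full_postcode")
    )


def low_confidence_review(candidates: Sequence[MatchCandidate]) -> list[MatchCandidate]:
    """Review the lowest-scoring decile of accepted probabilistic links.

    Deterministic matches are exempt: the review targets links the
    probabilistic engine accepted with least confidence.  A reviewed link
    survives only with (forename AND full dob) or (surname AND full dob)
    exact agreement, or a full-postcode match.
    """
    probs = [c for c in candidates if c.method == "probabilistic"]
    if not probs:
        return list(candidates)
    # decile computed over all probabilistic links so the review commutes
    # with the twin check on disjoint candidate subsets
    cutoff = float(np.quantile([c.score for c in probs], 0.10))
    for cand in probs:
        if (
            cand.status == "accepted"
            and cand.score <= cutoff
            and not _passes_low_confidence_rules(cand)
        ):
            cand.status = REMOVED_LOW_CONFIDENCE
    return list(candidates)


def _support_rank(cand: MatchCandidate) -> tuple:
    # deterministic strength tiers sort ahead of probabilistic scores
    if cand.method == "deterministic":
        return (0, cand.strength)
    return (1, -cand.score)


def resolve_duplicates(candidates: Sequence[MatchCandidate]) -> LinkTable:
    """Enforce offender_id uniqueness and prune unsupported one-to-many links.

    (a) If several participants claim one offender_id, only a claim with a
        strong (full-postcode) match survives — the best-supported one if
        several qualify; with no strong claim, all are removed.
    (b) If one participant holds several offender_ids and none of those
        links has date-of-birth or postcode support, names alone are not
        distinguishing enough: all are removed.
    (c) One participant with several well-supported offender_ids keeps all
        of them (police-side identity fragmentation).
    """
    ledger = {REMOVED_TWIN: 0, REMOVED_LOW_CONFIDENCE: 0, REMOVED_DUPLICATE: 0}
    for cand in candidates:
        if cand.status in (REMOVED_TWIN, REMOVED_LOW_CONFIDENCE):
            ledger[cand.status] += 1

    live = [c for c in candidates if c.status == "accepted"]

    by_offender: dict[str, list[MatchCandidate]] = {}
    for cand in live:
        by_offender.setdefault(cand.offender_id, []).append(cand)
    for claims in by_offender.values():
        if len(claims) <= 1:
            continue
        strong = [c for c in claims if c.agreements.get("full_postcode")]
        keep = min(strong, key=_support_rank) if strong else None
        for cand in claims:
            if cand is not keep:
                cand.status = REMOVED_DUPLICATE
                ledger[REMOVED_DUPLICATE] += 1

    live = [c for c in live if c.status == "accepted"]
    by_study: dict[str, list[MatchCandidate]] = {}
    for cand in live:
        by_study.setdefault(cand.study_id, []).append(cand)
    for links in by_study.values():
        if len(links) <= 1:
            continue
        supported = any(
            c.agreements.get("dob_exact") or c.agreements.get("full_postcode") for c in links
        )
        if not supported:
            for cand in links:
                cand.status = REMOVED_DUPLICATE
                ledger[REMOVED_DUPLICATE] += 1

    rows = [c for c in candidates if c.status == "accepted"]
    return LinkTable(rows=rows, ledger=ledger)


def run_review(
    candidates: Sequence[MatchCandidate], cohort: Sequence[CohortRecord]
) -> LinkTable:
    """Twin check, low-confidence review and duplicate resolution in order."""
    twin_check(candidates, cohort)
    low_confidence_review(candidates)
    return resolve_duplicates(candidates)


def flow_report(
    candidates: Sequence[MatchCandidate], link_table: LinkTable
) -> dict:
    """Stage-by-stage counts mirroring a linkage flow chart."""
    det = [c for c in candidates if c.method == "deterministic"]
    strengths = {s: sum(1 for c in det if c.strength == s) for s in (1, 2, 3)}
    n_candidates = len(candidates)
    n_final = len(link_table.rows)
    n_individuals = len(link_table.study_ids())
    n_offender_ids = len(link_table.offender_ids())
    report = {
        "candidates_total": n_candidates,
        "deterministic_total": len(det),
        "deterministic_by_strength": strengths,
        "probabilistic_additions": n_candidates - len(det),
        "removed_twin": link_table.ledger.get(REMOVED_TWIN, 0),
        "removed_low_confidence": link_table.ledger.get(REMOVED_LOW_CONFIDENCE, 0),
        "removed_duplicate": link_table.ledger.get(REMOVED_DUPLICATE, 0),
        "final_pairs": n_final,
        "distinct_individuals": n_individuals,
        "distinct_offender_ids": n_offender_ids,
        "fragmented_surplus": n_offender_ids - n_individuals,
    }
    assert n_candidates == n_final + sum(
        link_table.ledger.values()
    ), "flow conservation violated"
    return report


def evaluate_links(
    link_table: LinkTable,
    truth: Iterable[tuple[str, str]],
    cohort: Sequence[CohortRecord] | None = None,
) -> dict:
    """Precision/recall of the final pairs against ground truth.

    Truth pairs whose participant withheld linkage permission are excluded
    from the denominator: the pipeline never attempts them by design, so
    counting them would measure consent policy rather than linkage
    accuracy.
    """
    predicted = link_table.pairs()
    truth_set = set(truth)
    if cohort is not None:
        permitted = {r.study_id for r in cohort if r.linkage_permitted}
        truth_set = {(s, o) for s, o in truth_set if s in permitted}
    tp = len(predicted & truth_set)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return {
        "true_pairs": len(truth_set),
        "predicted_pairs": len(predicted),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
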