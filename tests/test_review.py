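"""Twin check, low-confidence review, duplicate resolution and flow accounting."""

import copy
from datetime import date

import pytest

from coplink.deterministic import candidate_agreements, deterministic_link
from coplink.probabilistic import probabilistic_link
from coplink.records import MatchCandidate
from coplink.review import (
    REMOVED_DUPLICATE,
    REMOVED_LOW_CONFIDENCE,
    REMOVED_TWIN,
    combine_candidates,
    evaluate_links,
    flow_report,
    low_confidence_review,
    resolve_duplicates,
    run_review,
    twin_check,
)

from conftest import make_person, make_subject


def prob_candidate(person, subject, score=20.0, status="accepted"):
    return MatchCandidate(
        study_id=person.study_id,
        offender_id=subject.offender_id,
        method="probabilistic",
        score=score,
        agreements=candidate_agreements(person, subject),
        status=status,
    )


# --- twin check -------------------------------------------------------------

def test_twin_retained_when_sex_and_forename_prefix_agree():
    """JAMIE vs JAMES shares sex and the first two forename characters."""
    person = make_person(forename="JAMIE", sex="M", twin_group="TW1")
    subject = make_subject(forename="JAMES", sex="M")
    (cand,) = twin_check([prob_candidate(person, subject)], [person])
    assert cand.status == "accepted"


def test_twin_removed_on_sex_mismatch():
    person = make_person(forename="JAMIE", sex="F", twin_group="TW1")
    subject = make_subject(forename="JAMIE", sex="M")
    (cand,) = twin_check([prob_candidate(person, subject)], [person])
    assert cand.status == REMOVED_TWIN


def test_twin_removed_on_forename_prefix_mismatch():
    person = make_person(forename="ROBERT", sex="M", twin_group="TW1")
    subject = make_subject(forename="RICHARD", sex="M")
    (cand,) = twin_check([prob_candidate(person, subject)], [person])
    assert cand.status == REMOVED_TWIN


def test_non_twin_candidate_untouched():
    person = make_person(forename="WENDY", sex="F", twin_group=None)
    subject = make_subject(forename="HOLLY", sex="M")
    (cand,) = twin_check([prob_candidate(person, subject)], [person])
    assert cand.status == "accepted"


# --- low-confidence review --------------------------------------------------

def bottom_decile_set():
    """Nine high-scoring true-ish pairs plus low-scoring review cases."""
    filler_person = make_person(study_id="STF")
    filler = [
        prob_candidate(filler_person, make_subject(offender_id=f"OF{i}"), score=30.0)
        for i in range(27)
    ]
    return filler


def test_low_confidence_rules():
    filler = bottom_decile_set()
    # forename+dob agree, surname differs -> retained
    keep = prob_candidate(
        make_person(study_id="STA"),
        make_subject(offender_id="OFA", surname="BRAXWELL", postcodes=("ZX1 1AA",)),
        score=1.0,
    )
    # only surname agrees -> removed
    drop = prob_candidate(
        make_person(study_id="STB", forename="WENDY"),
        make_subject(
            offender_id="OFB",
            forename="HOLLY",
            dob=date(1991, 2, 3),
            postcodes=("ZX1 1AA",),
        ),
        score=1.0,
    )
    # full postcode agrees alone -> retained
    pc_only = prob_candidate(
        make_person(study_id="STC", forename="WENDY", surname="KERMERE"),
        make_subject(
            offender_id="OFC",
            forename="HOLLY",
            surname="BRAXWELL",
            dob=date(1991, 2, 3),
        ),
        score=1.0,
    )
    cands = filler + [keep, drop, pc_only]
    low_confidence_review(cands)
    assert keep.status == "accepted"
    assert drop.status == REMOVED_LOW_CONFIDENCE
    assert pc_only.status == "accepted"
    assert all(c.status == "accepted" for c in filler)


def test_deterministic_candidates_exempt_from_low_confidence_review():
    person = make_person()
    det = deterministic_link([person], [make_subject()])
    out = low_confidence_review(det)
    assert all(c.status == "accepted" for c in out)


def test_twin_and_low_confidence_commute_on_disjoint_subsets():
    filler = bottom_decile_set()
    twin_person = make_person(study_id="STT", forename="ROBERT", sex="M", twin_group="TW1")
    twin_cand = prob_candidate(twin_person, make_subject(forename="RICHARD", sex="M"), score=30.0)
    weak = prob_candidate(
        make_person(study_id="STW", forename="WENDY"),
        make_subject(offender_id="OFW", forename="HOLLY",
                     dob=date(1991, 2, 3), postcodes=("ZX1 1AA",)),
        score=1.0,
    )
    cohort = [twin_person]
    a = [copy.deepcopy(c) for c in filler + [twin_cand, weak]]
    b = [copy.deepcopy(c) for c in filler + [twin_cand, weak]]
    low_confidence_review(twin_check(a, cohort))
    twin_check(low_confidence_review(b), cohort)
    assert [c.status for c in a] == [c.status for c in b]


# --- duplicate resolution ---------------------------------------------------

def test_offender_claimed_twice_keeps_postcode_supported_claim():
    subject = make_subject()
    strong = prob_candidate(make_person(study_id="ST1"), subject, score=25.0)
    weak_person = make_person(study_id="ST2", postcodes=("ZX1 1AA",))
    weak = prob_candidate(weak_person, subject, score=18.0)
    table = resolve_duplicates([strong, weak])
    assert {(r.study_id, r.offender_id) for r in table.rows} == {("ST1", "OF1")}
    assert weak.status == REMOVED_DUPLICATE
    assert table.ledger[REMOVED_DUPLICATE] == 1


def test_offender_claimed_twice_no_strong_claim_removes_all():
    subject = make_subject(postcodes=("QQ1 9XY",))
    a = prob_candidate(make_person(study_id="ST1"), subject, score=20.0)
    b = prob_candidate(make_person(study_id="ST2"), subject, score=19.0)
    table = resolve_duplicates([a, b])
    assert table.rows == []
    assert table.ledger[REMOVED_DUPLICATE] == 2


def test_fragmented_individual_with_support_keeps_both_ids():
    person = make_person()
    c1 = prob_candidate(person, make_subject(offender_id="OF1"), score=25.0)
    c2 = prob_candidate(person, make_subject(offender_id="OF2", postcodes=("AV2 1AA",)), score=22.0)
    table = resolve_duplicates([c1, c2])
    assert len(table.rows) == 2
    assert table.offender_ids() == {"OF1", "OF2"}


def test_multi_id_individual_without_dob_or_postcode_support_removed():
    person = make_person()
    subjects = [
        make_subject(
            offender_id=f"OF{i}",
            dob=date(1991, 3, 3),
            postcodes=("ZX1 1AA",),
        )
        for i in range(3)
    ]
    cands = [prob_candidate(person, s, score=16.0) for s in subjects]
    table = resolve_duplicates(cands)
    assert table.rows == []
    assert table.ledger[REMOVED_DUPLICATE] == 3


# --- flow report and conservation -------------------------------------------

def test_flow_conservation_on_synthetic_run(small_world):
    cohort, subjects, truth, _ = small_world
    linkable = [r for r in cohort if r.linkage_permitted]
    det = deterministic_link(linkable, subjects)
    prob = probabilistic_link(linkable, subjects)
    candidates = combine_candidates(det, prob)
    table = run_review(candidates, cohort)
    report = flow_report(candidates, table)
    removed = (
        report["removed_twin"]
        + report["removed_low_confidence"]
        + report["removed_duplicate"]
    )
    assert report["candidates_total"] == report["final_pairs"] + removed
    assert (
        report["distinct_individuals"]
        == report["distinct_offender_ids"] - report["fragmented_surplus"]
    )
    assert sum(report["deterministic_by_strength"].values()) == report["deterministic_total"]


def test_uncorrupted_run_removes_nothing_probative(noiseless_world):
    """Noiseless data: no duplicate or low-confidence removals of true links,
    and perfect precision/recall."""
    cohort, subjects, truth, _ = noiseless_world
    linkable = [r for r in cohort if r.linkage_permitted]
    candidates = combine_candidates(
        deterministic_link(linkable, subjects), probabilistic_link(linkable, subjects)
    )
    table = run_review(candidates, cohort)
    metrics = evaluate_links(table, truth, cohort)
    assert metrics["precision"] == 1.0
    assert metrics["recall"] == 1.0


def test_evaluation_restricted_to_permitted_participants(small_world):
    cohort, subjects, truth, _ = small_world
    linkable = [r for r in cohort if r.linkage_permitted]
    candidates = combine_candidates(
        deterministic_link(linkable, subjects), probabilistic_link(linkable, subjects)
    )
    table = run_review(candidates, cohort)
    unrestricted = evaluate_links(table, truth)
    restricted = evaluate_links(table, truth, cohort)
    assert restricted["true_pairs"] <= unrestricted["true_pairs"]
    assert restricted["recall"] >= unrestricted["recall"]
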