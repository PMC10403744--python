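"""Deterministic identifier matching with postcode match-strength tiers.

A deterministic match requires forename, surname and date of birth to be
identical after normalisation (case-folding, accent/punctuation
stripping).  Postcode is deliberately not a mandatory matching variable —
address information held by a study is often stale for exactly the
participants most likely to hold a police record — but it grades each
match into a strength tier:

  1. a full postcode is shared between the two address sets,
  2. only the outward (post-town) part is shared,
  3. no postcode agreement at all.

Current and historical postcodes on both sides participate; the best
strength wins.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .records import CohortRecord, MatchCandidate, PoliceSubject, Postcode
from .similarity import normalise_name


def assign_match_strength(
    cohort_postcodes: Sequence[Postcode], subject_postcodes: Sequence[Postcode]
) -> int:
    """Strength tier for a pair already matched on names and dob."""
    a = {(p.outward, p.inward) for p in cohort_postcodes}
    b = {(p.outward, p.inward) for p in subject_postcodes}
    if a & b:
        return 1
    if {o for o, _ in a} & {o for o, _ in b}:
        return 2
    return 3


def candidate_agreements(person: CohortRecord, subject: PoliceSubject) -> dict:
    """Exact-agreement facts used by the strength tiers and review rules."""
    fore_c = normalise_name(person.forename)
    fore_s = normalise_name(subject.forename)
    pc_c = {(p.outward, p.inward) for p in person.postcodes}
    pc_s = {(p.outward, p.inward) for p in subject.postcodes}
    return {
        "forename_exact": fore_c == fore_s,
        "forename_first2": fore_c[:2] == fore_s[:2] and len(fore_c) >= 2,
        "surname_exact": normalise_name(person.surname) == normalise_name(subject.surname),
        "dob_exact": person.dob == subject.dob,
        "sex_exact": person.sex == subject.sex,
        "full_postcode": bool(pc_c & pc_s),
        "outward_postcode": bool({o for o, _ in pc_c} & {o for o, _ in pc_s}),
    }


def deterministic_link(
    cohort: Iterable[CohortRecord], subjects: Iterable[PoliceSubject]
) -> list[MatchCandidate]:
    """All pairs identical on (forename, surname, dob), graded by strength."""
    index: dict[tuple, list[CohortRecord]] = {}
    for person in cohort:
        key = (normalise_name(person.forename), normalise_name(person.surname), person.dob)
        index.setdefault(key, []).append(person)
    out: list[MatchCandidate] = []
    for subject in subjects:
        key = (normalise_name(subject.forename), normalise_name(subject.surname), subject.dob)
        for person in index.get(key, []):
            out.append(
                MatchCandidate(
                    study_id=person.study_id,
                    offender_id=subject.offender_id,
                    method="deterministic",
                    strength=assign_match_strength(person.postcodes, subject.postcodes),
                    agreements=candidate_agreements(person, subject),
                )
            )
    return out
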