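"""Synthetic cohort, police register and event-table generator.

Emulates the data-generating processes a cohort-to-police linkage has to
survive: nickname/short-form name variants, single-character typos, stale
or changed addresses, occasional wholly fake names given to police,
police-side identity fragmentation (one person under two offender_ids),
twins sharing surname and date of birth, group crimes with per-offender
disposal terms, the pre/post September-2015 change in disposal
terminology, pre-2007 paper-era record loss, and MoPI-style review and
deletion.  A ground-truth link table is produced alongside so precision
and recall of the whole pipeline can be measured.

All randomness flows from ``GenParams.seed`` through a single
``numpy.random.Generator``; identical parameters give identical output.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

import numpy as np

from . import _names
from .records import (
    AddressInterval,
    CohortRecord,
    CrimeEvent,
    GenParams,
    PoliceSubject,
    Postcode,
)

# disposal category -> (single-offender outcome code, modern per-offender terms)
# Categories map onto the Home Office outcome codes the linkage treats as
# eligible (charge, caution, TIC, penalty notice, cannabis warning,
# community resolution) plus an ineligible residue.
DISPOSALS = {
    "charged": ("OC1", ["suspect", "arrested", "charged"]),
    "cautioned": ("OC2", ["suspect", "cautioned"]),
    "adult_conditional_caution": ("OC3", ["suspect", "adult conditional caution"]),
    "tic": ("OC4", ["tic"]),
    "penalty_notice": ("OC6", ["penalty notice for disorder"]),
    "cannabis_warning": ("OC7", ["cannabis warning"]),
    "community_resolution": ("OC8", ["suspect", "community resolution"]),
    "summons": ("OC1", ["reported for summons"]),
    "postal_requisition": ("OC1", ["postal requisition"]),
}
# Disposals folded into the legacy "prosecuted" term before the recording
# system changed (TICs and all out-of-court disposals; charges kept their
# own term throughout).
LEGACY_PROSECUTED = {
    "cautioned",
    "adult_conditional_caution",
    "tic",
    "penalty_notice",
    "cannabis_warning",
    "community_resolution",
}
INELIGIBLE_OUTCOMES = [
    ("OC5", ["suspect", "further investigation"]),
    ("OC10", ["suspect", "formal action not in public interest"]),
    ("OC14", ["suspect", "eliminated"]),
    ("OC15", ["suspect", "named suspect evidential difficulties"]),
    ("OC16", ["suspect", "victim declines prosecution"]),
    ("OC18", ["investigation complete no suspect identified"]),
    ("OC21", ["suspect", "not in public interest police"]),
]

_DISPOSAL_NAMES = list(DISPOSALS)
_DISPOSAL_WEIGHTS = np.array([0.28, 0.16, 0.04, 0.06, 0.08, 0.08, 0.18, 0.06, 0.06])
_DISPOSAL_WEIGHTS = _DISPOSAL_WEIGHTS / _DISPOSAL_WEIGHTS.sum()
ELIGIBLE_EVENT_RATE = 0.55  # share of offender-event rows with an eligible disposal


def _rand_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _rand_postcode(rng: np.random.Generator, in_area: bool) -> Postcode:
    outwards = _names.IN_AREA_OUTWARDS if in_area else _names.OUT_AREA_OUTWARDS
    outward = outwards[int(rng.integers(0, len(outwards)))]
    letters = _names.INWARD_LETTERS
    inward = "%d%s%s" % (
        rng.integers(1, 10),
        letters[int(rng.integers(0, len(letters)))],
        letters[int(rng.integers(0, len(letters)))],
    )
    return Postcode(outward, inward)


def _sample_forename(rng: np.random.Generator, sex: str) -> str:
    pool = _names.MALE_FORENAMES if sex == "M" else _names.FEMALE_FORENAMES
    return pool[int(rng.integers(0, len(pool)))]


def _typo(rng: np.random.Generator, name: str) -> str:
    """Single-character substitution at a random position."""
    if not name:
        return name
    pos = int(rng.integers(0, len(name)))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    repl = alphabet[int(rng.integers(0, 26))]
    while repl == name[pos]:
        repl = alphabet[int(rng.integers(0, 26))]
    return name[:pos] + repl + name[pos + 1 :]


def _address_history(
    rng: np.random.Generator, dob: date, params: GenParams
) -> list[AddressInterval]:
    n_moves = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
    horizon = params.extraction_date
    cuts = sorted(
        _rand_date(rng, dob + timedelta(days=365 * 16), horizon - timedelta(days=30))
        for _ in range(n_moves)
    )
    bounds = [dob] + cuts + [None]
    intervals = []
    for i in range(len(bounds) - 1):
        pc = _rand_postcode(rng, bool(rng.random() < params.in_area_rate))
        intervals.append(AddressInterval(pc, bounds[i], bounds[i + 1]))
    return intervals


def generate_cohort(params: GenParams, rng: Optional[np.random.Generator] = None) -> list[CohortRecord]:
    """Generate the cohort roster, including twin pairs and consent flags."""
    rng = rng or np.random.default_rng(params.seed)
    records: list[CohortRecord] = []
    n_pairs = int(round(params.n_cohort * params.twin_rate / 2.0))
    idx = 0

    def _new_id() -> str:
        nonlocal idx
        idx += 1
        return f"ST{idx:05d}"

    surnames = _names.SURNAMES
    for pair in range(n_pairs):
        dob = _rand_date(rng, params.dob_start, params.dob_end)
        surname = surnames[int(rng.integers(0, len(surnames)))]
        twin_group = f"TW{pair + 1:04d}"
        addresses = None
        first_forename = None
        for _ in range(2):
            sex = "M" if rng.random() < 0.5 else "F"
            forename = _sample_forename(rng, sex)
            # co-twins get forenames with distinct initials so the register
            # can tell them apart by name at all
            while first_forename is not None and forename[0] == first_forename[0]:
                forename = _sample_forename(rng, sex)
            if first_forename is None:
                first_forename = forename
            if addresses is None:
                addresses = _address_history(rng, dob, params)
            records.append(
                CohortRecord(
                    study_id=_new_id(),
                    forename=forename,
                    surname=surname,
                    dob=dob,
                    sex=sex,
                    addresses=[AddressInterval(a.postcode, a.from_date, a.to_date) for a in addresses],
                    twin_group=twin_group,
                    linkage_permitted=bool(rng.random() < params.consent_rate),
                )
            )
    while len(records) < params.n_cohort:
        sex = "M" if rng.random() < 0.5 else "F"
        dob = _rand_date(rng, params.dob_start, params.dob_end)
        records.append(
            CohortRecord(
                study_id=_new_id(),
                forename=_sample_forename(rng, sex),
                surname=surnames[int(rng.integers(0, len(surnames)))],
                dob=dob,
                sex=sex,
                addresses=_address_history(rng, dob, params),
                twin_group=None,
                linkage_permitted=bool(rng.random() < params.consent_rate),
            )
        )
    return records[: params.n_cohort]


def _corrupt_identity(
    rng: np.random.Generator, person: CohortRecord, params: GenParams
) -> tuple[str, str, list[Postcode]]:
    """Apply the register-side error processes to one cohort identity."""
    forename, surname = person.forename, person.surname
    if rng.random() < params.fake_id_rate:
        # a fake name given to police: unrelated name, true dob kept
        sex = person.sex
        forename = _sample_forename(rng, sex)
        surname = _names.SURNAMES[int(rng.integers(0, len(_names.SURNAMES)))]
        postcodes = [_rand_postcode(rng, True)]
        return forename, surname, postcodes
    if rng.random() < params.name_variant_rate:
        variants = _names.NICKNAMES.get(forename)
        if variants:
            forename = variants[int(rng.integers(0, len(variants)))]
    if rng.random() < params.typo_rate:
        if rng.random() < 0.5:
            forename = _typo(rng, forename)
        else:
            surname = _typo(rng, surname)
    if rng.random() < params.stale_address_rate:
        # the person moved; the study's address is out of date
        postcodes = [_rand_postcode(rng, bool(rng.random() < params.in_area_rate))]
    else:
        postcodes = [person.current_postcode] if person.current_postcode else []
        # police sometimes also hold an older address
        if person.postcodes[:-1] and rng.random() < 0.3:
            old = person.postcodes[:-1]
            postcodes.append(old[int(rng.integers(0, len(old)))])
    return forename, surname, postcodes


def generate_police_register(
    cohort: list[CohortRecord],
    params: GenParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PoliceSubject], list[tuple[str, str]]]:
    """Generate the police subject register and the ground-truth pair table.

    A fraction ``offending_rate`` of cohort members appear in the register;
    of those, ``fragmentation_rate`` are recorded under two offender_ids.
    ``n_background`` decoy identities born in the same window are added.
    Returns ``(subjects, truth)`` where truth is a list of
    ``(study_id, offender_id)`` pairs.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = rng or np.random.default_rng(params.seed + 1)
    subjects: list[PoliceSubject] = []
    truth: list[tuple[str, str]] = []
    serial = 0

    def _new_oid() -> str:
        nonlocal serial
        serial += 1
        return f"OF{serial:06d}"

    for person in cohort:
        if rng.random() >= params.offending_rate:
            continue
        n_ids = 2 if rng.random() < params.fragmentation_rate else 1
        for _ in range(n_ids):
            forename, surname, postcodes = _corrupt_identity(rng, person, params)
            oid = _new_oid()
            subjects.append(
                PoliceSubject(
                    offender_id=oid,
                    forename=forename,
                    surname=surname,
                    dob=person.dob,
                    sex=person.sex,
                    postcodes=postcodes,
                    truth_study_id=person.study_id,
                )
            )
            truth.append((person.study_id, oid))
    for _ in range(params.n_background):
        sex = "M" if rng.random() < 0.5 else "F"
        dob = _rand_date(rng, params.dob_start, params.dob_end)
        pcs = [_rand_postcode(rng, bool(rng.random() < params.in_area_rate))]
        if rng.random() < 0.3:
            pcs.append(_rand_postcode(rng, True))
        subjects.append(
            PoliceSubject(
                offender_id=_new_oid(),
                forename=_sample_forename(rng, sex),
                surname=_names.SURNAMES[int(rng.integers(0, len(_names.SURNAMES)))],
                dob=dob,
                sex=sex,
                postcodes=pcs,
                truth_study_id=None,
            )
        )
    return subjects, truth


def _classification_terms(disposal: str, terms: list[str], from_date: date, era_boundary: date) -> list[str]:
    if from_date < era_boundary and disposal in LEGACY_PROSECUTED:
        return ["suspect", "prosecuted"]
    return list(terms)


def _outcome_rank(code: str) -> int:
    return int(code[2:])


def generate_events(
    subjects: list[PoliceSubject],
    params: GenParams,
    rng: Optional[np.random.Generator] = None,
) -> list[CrimeEvent]:
    """Generate the event table: one row per (occurrence, offender).

    Group crimes share an occurrence_id across their offenders' rows and
    carry offence-level fields (dates, offence code, outcome code = the
    most serious across the group) while the concatenated classification
    terms are per offender.  Events before the recording-era boundary use
    the legacy "prosecuted" term for TICs and out-of-court disposals.
    """
    if not subjects:
        raise ValueError("subjects must be non-empty")
    rng = rng or np.random.default_rng(params.seed + 2)
    from .severity import OFFENCE_CATALOGUE

    occ_serial = 0
    case_serial = 0
    events: list[CrimeEvent] = []
    p_geo = 1.0 / params.events_mean
    # each subject's number of occurrences (geometric: most offend once)
    counts = {s.offender_id: int(rng.geometric(p_geo)) for s in subjects}
    floor = date(2003, 1, 1)

    subj_by_id = {s.offender_id: s for s in subjects}
    order = [s.offender_id for s in subjects]

    def _draw_disposal() -> tuple[str, str, list[str]]:
        if rng.random() < ELIGIBLE_EVENT_RATE:
            name = _DISPOSAL_NAMES[int(rng.choice(len(_DISPOSAL_NAMES), p=_DISPOSAL_WEIGHTS))]
            code, terms = DISPOSALS[name]
            return name, code, terms
        code, terms = INELIGIBLE_OUTCOMES[int(rng.integers(0, len(INELIGIBLE_OUTCOMES)))]
        return "ineligible", code, terms

    for oid in order:
        subject = subj_by_id[oid]
        start = max(subject.dob + timedelta(days=3653), floor)  # age >= 10
        end = params.extraction_date - timedelta(days=14)
        if start >= end:
            continue
        for _ in range(counts[oid]):
            occ_serial += 1
            occurrence_id = f"OCC{occ_serial:07d}"
            from_date = _rand_date(rng, start, end)
            gap = rng.random()
            if gap < 0.53:
                delta = 0
            elif gap < 0.74:
                delta = 1
            elif gap < 0.93:
                delta = int(rng.integers(2, 10))
            else:
                delta = int(rng.integers(10, 500))
            reported = min(from_date + timedelta(days=delta), params.extraction_date)
            offence = OFFENCE_CATALOGUE[int(rng.integers(0, len(OFFENCE_CATALOGUE)))]
            mopi = int(rng.choice([1, 2, 3], p=[0.03, 0.12, 0.85]))

            participants = [subject]
            if rng.random() < params.group_crime_rate and len(subjects) > 1:
                extra = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
                for _ in range(extra):
                    other = subj_by_id[order[int(rng.integers(0, len(order)))]]
                    if all(other.offender_id != p.offender_id for p in participants):
                        participants.append(other)
            disposals = [_draw_disposal() for _ in participants]
            offence_outcome = min((d[1] for d in disposals), key=_outcome_rank)
            drugs = offence.group == "Drug offences" or rng.random() < 0.03
            da = rng.random() < 0.05
            knife = rng.random() < 0.02
            for (name, _code, terms), person in zip(disposals, participants):
                alcohol = bool(rng.random() < 0.5) if rng.random() < 0.018 else None
                substance = (
                    ["alcohol", "drugs", "alcohol and drugs", "not affected"][int(rng.integers(0, 4))]
                    if rng.random() < 0.048
                    else None
                )
                casefile_id = casefile_date = verdict = None
                if (
                    name == "charged"
                    and from_date >= params.court_data_start
                    and rng.random() < 0.8
                ):
                    case_serial += 1
                    casefile_id = f"CF{case_serial:06d}"
                    casefile_date = reported + timedelta(days=int(rng.integers(20, 180)))
                    if rng.random() < 0.38:
                        verdict = "guilty" if rng.random() < 0.8 else "not guilty"
                events.append(
                    CrimeEvent(
                        occurrence_id=occurrence_id,
                        offender_id=person.offender_id,
                        created_date=reported,
                        reported_date=reported,
                        from_date=from_date,
                        ho_code=offence.ho_code,
                        offence_group=offence.group,
                        offender_count=len(participants),
                        outcome_code=offence_outcome if len(participants) > 1 else _code,
                        classification_terms=_classification_terms(
                            name, terms, from_date, params.era_boundary
                        ),
                        da_flag=da,
                        knife_flag=knife,
                        drugs_flag=drugs,
                        alcohol_flag=alcohol,
                        substance=substance,
                        mopi_group=mopi,
                        casefile_id=casefile_id,
                        casefile_date=casefile_date,
                        verdict=verdict,
                    )
                )
    return events


def apply_retention(
    events: list[CrimeEvent],
    extraction_date: date,
    *,
    electronic_start: date = date(2007, 1, 1),
    pre_electronic_drop: float = 1.0,
    group3_clear_years: float = 6.0,
    rng: Optional[np.random.Generator] = None,
) -> list[CrimeEvent]:
    """Simulate MoPI review-and-deletion plus paper-era record loss.

    Per offender, the review category is the most serious (lowest-numbered)
    MoPI group across their offences.  Offenders reviewed under Group 3
    have all records deleted once a clear period (no subsequent offence)
    of at least ``group3_clear_years`` precedes ``extraction_date``; Group
    1/2 records are retained (deletion would need a manual review).  The
    review is simulated as a single sweep at extraction.  Events predating
    the electronic system are additionally dropped at
    ``pre_electronic_drop`` (default: all, emulating paper-era loss).
    """
    for ev in events:
        if ev.mopi_group not in (1, 2, 3):
            raise ValueError(f"event {ev.occurrence_id} lacks a valid mopi_group")
    by_offender: dict[str, list[CrimeEvent]] = {}
    for ev in events:
        by_offender.setdefault(ev.offender_id, []).append(ev)
    deleted_offenders = set()
    for oid, evs in by_offender.items():
        category = min(ev.mopi_group for ev in evs)
        if category != 3:
            continue
        last = max(ev.from_date for ev in evs)
        clear_days = (extraction_date - last).days
        if clear_days >= group3_clear_years * 365.25:
            deleted_offenders.add(oid)
    kept = []
    if rng is None:
        rng = np.random.default_rng(0)
    for ev in events:
        if ev.offender_id in deleted_offenders:
            continue
        if ev.from_date < electronic_start and rng.random() < pre_electronic_drop:
            continue
        kept.append(ev)
    return kept


def generate_all(params: GenParams):
    """Generate cohort, register, truth table and retention-censored events."""
    rng = np.random.default_rng(params.seed)
    cohort = generate_cohort(params, rng)
    subjects, truth = generate_police_register(cohort, params, rng)
    events = generate_events(subjects, params, rng)
    events = apply_retention(
        events,
        params.extraction_date,
        electronic_start=params.electronic_start,
        pre_electronic_drop=params.pre_electronic_drop,
        rng=rng,
    )
    return cohort, subjects, truth, events
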