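"""Generator contracts: determinism, configured rates, era terms, retention."""

from datetime import date

import numpy as np
import pytest
from scipy import stats

from coplink import io
from coplink.records import CrimeEvent, GenParams
from coplink.synthgen import (
    apply_retention,
    generate_cohort,
    generate_events,
    generate_police_register,
)

from conftest import SMALL


def binom_bounds(n, p, alpha=0.01):
    lo = stats.binom.ppf(alpha / 2, n, p)
    hi = stats.binom.ppf(1 - alpha / 2, n, p)
    return lo, hi


def test_seed_determinism_byte_identical():
    params = SMALL
    a = io.cohort_to_frame(generate_cohort(params)).to_csv()
    b = io.cohort_to_frame(generate_cohort(params)).to_csv()
    assert a == b


def test_different_seed_differs():
    a = io.cohort_to_frame(generate_cohort(SMALL)).to_csv()
    b = io.cohort_to_frame(generate_cohort(SMALL.replace(seed=99))).to_csv()
    assert a != b


def test_twin_rate_zero_means_no_twins():
    cohort = generate_cohort(SMALL.replace(twin_rate=0.0))
    assert all(r.twin_group is None for r in cohort)


def test_twin_share_within_binomial_bounds():
    """At twin_rate=0.02 the realised twin share sits in the binomial 99% band."""
    params = GenParams(n_cohort=10000, twin_rate=0.02, seed=5)
    cohort = generate_cohort(params)
    n_twins = sum(1 for r in cohort if r.twin_group)
    lo, hi = binom_bounds(params.n_cohort, params.twin_rate)
    assert lo <= n_twins <= hi


def test_cohort_dob_window_and_structure():
    cohort = generate_cohort(SMALL)
    assert len(cohort) == SMALL.n_cohort
    for r in cohort:
        assert SMALL.dob_start <= r.dob <= SMALL.dob_end
        # address intervals chronologically ordered and non-overlapping
        for a, b in zip(r.addresses, r.addresses[1:]):
            assert a.to_date == b.from_date
    by_twin = {}
    for r in cohort:
        if r.twin_group:
            by_twin.setdefault(r.twin_group, []).append(r)
    for pair in by_twin.values():
        assert len(pair) == 2
        assert pair[0].dob == pair[1].dob
        assert pair[0].surname == pair[1].surname
        assert pair[0].forename[0] != pair[1].forename[0]


def test_offender_count_within_binomial_bounds():
    params = GenParams(n_cohort=5000, offending_rate=0.15, seed=3)
    cohort = generate_cohort(params)
    _, truth = generate_police_register(cohort, params)
    n_offenders = len({s for s, _ in truth})
    lo, hi = binom_bounds(params.n_cohort, params.offending_rate)
    assert lo <= n_offenders <= hi


def test_fragmentation_zero_is_one_to_one():
    params = SMALL.replace(fragmentation_rate=0.0)
    _, truth = generate_police_register(generate_cohort(params), params)
    studies = [s for s, _ in truth]
    assert len(studies) == len(set(studies))


def test_noiseless_register_agrees_exactly(noiseless_world):
    cohort, subjects, truth, _ = noiseless_world
    people = {r.study_id: r for r in cohort}
    by_oid = {s.offender_id: s for s in subjects}
    for study_id, offender_id in truth:
        person, subject = people[study_id], by_oid[offender_id]
        assert person.forename == subject.forename
        assert person.surname == subject.surname
        assert person.dob == subject.dob


def test_ground_truth_consistency(small_world):
    cohort, subjects, truth, _ = small_world
    register_ids = {s.offender_id for s in subjects}
    background = {s.offender_id for s in subjects if s.truth_study_id is None}
    for _, offender_id in truth:
        assert offender_id in register_ids
        assert offender_id not in background


def test_group_crimes_share_occurrence(small_world):
    _, _, _, events = small_world
    by_occ = {}
    for ev in events:
        by_occ.setdefault(ev.occurrence_id, []).append(ev)
    for rows in by_occ.values():
        counts = {r.offender_count for r in rows}
        assert len(counts) == 1
        # retention may delete one participant's rows, never add extras
        assert len(rows) <= counts.pop()
        assert len({r.from_date for r in rows}) == 1


def test_event_dates_ordered(small_world):
    _, _, _, events = small_world
    assert all(ev.from_date <= ev.reported_date for ev in events)


def test_pre_era_disposals_use_legacy_prosecuted_term(small_world):
    """Cautions and out-of-court disposals before the recording-system change
    appear under the single legacy term, never their modern names."""
    _, _, _, events = small_world
    era = SMALL.era_boundary
    modern = {"cautioned", "community resolution", "penalty notice for disorder",
              "cannabis warning", "tic", "adult conditional caution"}
    pre = [ev for ev in events if ev.from_date < era]
    assert pre, "expected some pre-boundary events"
    for ev in pre:
        assert not (modern & set(ev.classification_terms))
    assert any("prosecuted" in ev.classification_terms for ev in pre)
    post = [ev for ev in events if ev.from_date >= era]
    assert all("prosecuted" not in ev.classification_terms for ev in post)


def test_casefiles_only_after_court_data_start(small_world):
    _, _, _, events = small_world
    for ev in events:
        if ev.casefile_id:
            assert ev.from_date >= SMALL.court_data_start


# --- MoPI retention ---------------------------------------------------------

def _event(oid, year, mopi, occ="X"):
    d = date(year, 6, 1)
    return CrimeEvent(
        occurrence_id=f"{occ}{oid}{year}",
        offender_id=oid,
        created_date=d,
        reported_date=d,
        from_date=d,
        ho_code="046/10",
        offence_group="Theft",
        offender_count=1,
        outcome_code="OC1",
        classification_terms=["charged"],
        mopi_group=mopi,
    )


def test_group3_deleted_after_clear_period():
    out = apply_retention([_event("A", 2010, 3)], date(2021, 7, 1))
    assert out == []


def test_group1_retained_regardless_of_clear_period():
    events = [_event("B", 2010, 1)]
    out = apply_retention(events, date(2021, 7, 1))
    assert len(out) == 1


def test_most_serious_offence_sets_review_category():
    events = [_event("C", 2010, 3), _event("C", 2012, 1)]
    out = apply_retention(events, date(2021, 7, 1))
    assert len(out) == 2


def test_group3_retained_within_clear_period():
    out = apply_retention([_event("D", 2017, 3)], date(2021, 7, 1))
    assert len(out) == 1


def test_pre_electronic_records_dropped():
    out = apply_retention([_event("E", 2005, 1)], date(2021, 7, 1))
    assert out == []
    kept = apply_retention(
        [_event("E", 2005, 1)], date(2021, 7, 1), pre_electronic_drop=0.0
    )
    assert len(kept) == 1


def test_missing_mopi_group_rejected():
    ev = _event("F", 2019, 3)
    ev.mopi_group = None
    with pytest.raises(ValueError):
        apply_retention([ev], date(2021, 7, 1))


@pytest.mark.parametrize("years", [(4.0, 6.0), (6.0, 10.0)])
def test_retention_monotone_in_clear_period(small_world, years):
    """A longer clear-period threshold never deletes more records."""
    _, _, _, _ = small_world
    rng = np.random.default_rng(2)
    events = [
        _event(f"O{i}", int(rng.integers(2008, 2021)), int(rng.choice([1, 2, 3])), occ=str(k))
        for k, i in enumerate(rng.integers(0, 40, size=200))
    ]
    short, long = years
    n_short = len(apply_retention(events, date(2021, 7, 1), group3_clear_years=short))
    n_long = len(apply_retention(events, date(2021, 7, 1), group3_clear_years=long))
    assert n_short <= n_long


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        GenParams(typo_rate=1.5)
    with pytest.raises(ValueError):
        GenParams(dob_start=date(1994, 1, 1), dob_end=date(1993, 1, 1))
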