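"""Stage 2: select eligible event records by disposal outcome.

Police outcome data are recorded at offence level, so single-offender and
group crimes need different handling.  For a crime with one offender the
22-category Home Office outcome code is effectively individual-level and
a record is eligible when the code is OC1 (charged), OC2/OC3 (cautioned),
OC4 (taken into consideration), OC6 (penalty notice for disorder), OC7
(cannabis warning) or OC8 (community resolution).  For group crimes the
offence-level code reflects the most serious outcome of the whole group,
so eligibility comes instead from the offender's own concatenated
classification terms; before the September-2015 recording-system change
the single legacy term "prosecuted" covered TICs and all out-of-court
disposals, and it is honoured whenever present.

Term matching is whole-term after splitting the concatenated string on
";" — substring matching would let "charged" claim "discharged".
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .records import OUTCOME_CODES, CrimeEvent
from .review import LinkTable

ELIGIBLE_OUTCOME_CODES = frozenset({"OC1", "OC2", "OC3", "OC4", "OC6", "OC7", "OC8"})

ELIGIBLE_TERMS = frozenset(
    {
        "charged",
        "tic",
        "cautioned",
        "adult conditional caution",
        "postal requisition",
        "reported for summons",
        "cannabis warning",
        "penalty notice for disorder",
        "community resolution",
        "prosecuted",
    }
)

DEFAULT_ERA_BOUNDARY = date(2015, 9, 1)


def is_eligible_single(outcome_code: str) -> bool:
    """Disposal eligibility for a single-offender crime, from its outcome code."""
    if outcome_code not in OUTCOME_CODES:
        raise ValueError(f"unknown Home Office outcome code {outcome_code!r}")
    return outcome_code in ELIGIBLE_OUTCOME_CODES


def _normalise_terms(terms) -> list[str]:
    if terms is None:
        return []
    if isinstance(terms, str):
        terms = terms.split(";")
    return [t.strip().lower() for t in terms if t and t.strip()]


def is_eligible_group(
    classification_terms,
    event_date: date | None = None,
    era_boundary: date = DEFAULT_ERA_BOUNDARY,
) -> bool:
    """Disposal eligibility for one offender of a group crime.

    ``classification_terms`` may be a list of terms or the raw
    ";"-concatenated string.  The legacy "prosecuted" term is expected
    only before ``era_boundary`` but counts whenever present.
    """
    terms = _normalise_terms(classification_terms)
    return any(t in ELIGIBLE_TERMS for t in terms)


def event_is_eligible(event: CrimeEvent, era_boundary: date = DEFAULT_ERA_BOUNDARY) -> bool:
    """Row-level eligibility: outcome code for lone offenders, terms for groups."""
    if event.offender_count < 1:
        raise ValueError("offender_count must be >= 1")
    if event.offender_count == 1:
        return is_eligible_single(event.outcome_code)
    return is_eligible_group(event.classification_terms, event.from_date, era_boundary)


def filter_events(
    events: Iterable[CrimeEvent],
    link_table: LinkTable,
    era_boundary: date = DEFAULT_ERA_BOUNDARY,
) -> pd.DataFrame:
    """Join events to linked participants and keep eligible rows only.

    Returns a DataFrame keyed by (study_id, occurrence_id) with one row per
    eligible (offender, occurrence) record.  Events whose offender_id is
    not in the link table are dropped; a group crime is included only for
    the linked offenders whose own terms are eligible.
    """
    offender_to_study = {r.offender_id: r.study_id for r in link_table.rows}
    rows = []
    for ev in events:
        study_id = offender_to_study.get(ev.offender_id)
        if study_id is None:
            continue
        if not event_is_eligible(ev, era_boundary):
            continue
        rows.append(
            {
                "study_id": study_id,
                "occurrence_id": ev.occurrence_id,
                "offender_id": ev.offender_id,
                "created_date": ev.created_date,
                "reported_date": ev.reported_date,
                "from_date": ev.from_date,
                "ho_code": ev.ho_code,
                "offence_group": ev.offence_group,
                "offender_count": ev.offender_count,
                "outcome_code": ev.outcome_code,
                "da_flag": ev.da_flag,
                "knife_flag": ev.knife_flag,
                "drugs_flag": ev.drugs_flag,
                "alcohol_flag": ev.alcohol_flag,
                "substance": ev.substance,
                "casefile_id": ev.casefile_id,
                "casefile_date": ev.casefile_date,
                "verdict": ev.verdict,
            }
        )
    columns = [
        "study_id", "occurrence_id", "offender_id", "created_date",
        "reported_date", "from_date", "ho_code", "offence_group",
        "offender_count", "outcome_code", "da_flag", "knife_flag",
        "drugs_flag", "alcohol_flag", "substance", "casefile_id",
        "casefile_date", "verdict",
    ]
    return pd.DataFrame(rows, columns=columns)


def count_records_and_offences(filtered: pd.DataFrame) -> tuple[int, int, int]:
    """(records, offences, individuals): rows, distinct occurrences, distinct
    participants.  Group crimes make records outnumber offences."""
    if filtered.empty:
        return (0, 0, 0)
    return (
        len(filtered),
        filtered["occurrence_id"].nunique(),
        filtered["study_id"].nunique(),
    )
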