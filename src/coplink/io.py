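"""CSV serialisation for every pipeline table.

All dates are ISO 8601.  Address histories are packed into a single
column as ``postcode=from=to`` segments joined by ``|`` (``to`` empty for
the current address); postcode lists and classification terms use ``|``
and ``;`` respectively.  The subjects file never carries the ground-truth
study id — truth lives in its own file.
"""

from __future__ import annotations

from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .records import (
    AddressInterval,
    CohortRecord,
    CrimeEvent,
    LinkTable,
    MatchCandidate,
    PoliceSubject,
    Postcode,
)


def _d(x: Optional[date]) -> str:
    return x.isoformat() if x else ""


def _parse_date(x) -> Optional[date]:
    if x is None or x == "" or (isinstance(x, float) and pd.isna(x)):
        return None
    if isinstance(x, date):
        return x
    return datetime.strptime(str(x)[:10], "%Y-%m-%d").date()


def _pack_addresses(addresses: Iterable[AddressInterval]) -> str:
    return "|".join(f"{a.postcode}={_d(a.from_date)}={_d(a.to_date)}" for a in addresses)


def _unpack_addresses(packed: str) -> list[AddressInterval]:
    out = []
    if not packed or pd.isna(packed):
        return out
    for part in str(packed).split("|"):
        pc, frm, to = part.split("=")
        out.append(AddressInterval(Postcode.parse(pc), _parse_date(frm), _parse_date(to)))
    return out


# --- cohort -----------------------------------------------------------------

def cohort_to_frame(cohort: Iterable[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": r.study_id,
            "forename": r.forename,
            "surname": r.surname,
            "dob": _d(r.dob),
            "sex": r.sex,
            "addresses": _pack_addresses(r.addresses),
            "twin_group": r.twin_group or "",
            "linkage_permitted": r.linkage_permitted,
        }
        for r in cohort
    )


def frame_to_cohort(df: pd.DataFrame) -> list[CohortRecord]:
    return [
        CohortRecord(
            study_id=row.study_id,
            forename=row.forename,
            surname=row.surname,
            dob=_parse_date(row.dob),
            sex=row.sex,
            addresses=_unpack_addresses(row.addresses),
            twin_group=row.twin_group or None if isinstance(row.twin_group, str) else None,
            linkage_permitted=bool(row.linkage_permitted),
        )
        for row in df.itertuples()
    ]


# --- police subjects --------------------------------------------------------

def subjects_to_frame(subjects: Iterable[PoliceSubject]) -> pd.DataFrame:
    """Pipeline-input view of the register: ground truth is not emitted."""
    return pd.DataFrame(
        {
            "offender_id": s.offender_id,
            "forename": s.forename,
            "surname": s.surname,
            "dob": _d(s.dob),
            "sex": s.sex,
            "postcodes": "|".join(str(p) for p in s.postcodes),
        }
        for s in subjects
    )


def frame_to_subjects(df: pd.DataFrame) -> list[PoliceSubject]:
    return [
        PoliceSubject(
            offender_id=row.offender_id,
            forename=row.forename,
            surname=row.surname,
            dob=_parse_date(row.dob),
            sex=row.sex,
            postcodes=[
                Postcode.parse(p) for p in str(row.postcodes).split("|") if p and p != "nan"
            ],
        )
        for row in df.itertuples()
    ]


def truth_to_frame(truth: Iterable[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(truth, columns=["study_id", "offender_id"])


# --- events -----------------------------------------------------------------

_EVENT_COLUMNS = [
    "occurrence_id", "offender_id", "created_date", "reported_date",
    "from_date", "ho_code", "offence_group", "offender_count",
    "outcome_code", "classification_terms", "da_flag", "knife_flag",
    "drugs_flag", "alcohol_flag", "substance", "mopi_group",
    "casefile_id", "casefile_date", "verdict",
]


def events_to_frame(events: Iterable[CrimeEvent]) -> pd.DataFrame:
    rows = [
        {
            "occurrence_id": e.occurrence_id,
            "offender_id": e.offender_id,
            "created_date": _d(e.created_date),
            "reported_date": _d(e.reported_date),
            "from_date": _d(e.from_date),
            "ho_code": e.ho_code,
            "offence_group": e.offence_group,
            "offender_count": e.offender_count,
            "outcome_code": e.outcome_code,
            "classification_terms": ";".join(e.classification_terms),
            "da_flag": e.da_flag,
            "knife_flag": e.knife_flag,
            "drugs_flag": e.drugs_flag,
            "alcohol_flag": e.alcohol_flag,
            "substance": e.substance or "",
            "mopi_group": e.mopi_group,
            "casefile_id": e.casefile_id or "",
            "casefile_date": _d(e.casefile_date),
            "verdict": e.verdict or "",
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[CrimeEvent]:
    def _opt_bool(x):
        if pd.isna(x) or x == "":
            return None
        return bool(x) if not isinstance(x, str) else x.lower() in ("true", "1", "yes")

    def _opt_str(x):
        return None if (pd.isna(x) or x == "") else str(x)

    out = []
    for row in df.itertuples():
        out.append(
            CrimeEvent(
                occurrence_id=row.occurrence_id,
                offender_id=row.offender_id,
                created_date=_parse_date(row.created_date),
                reported_date=_parse_date(row.reported_date),
                from_date=_parse_date(row.from_date),
                ho_code=row.ho_code,
                offence_group=row.offence_group,
                offender_count=int(row.offender_count),
                outcome_code=row.outcome_code,
                classification_terms=[
                    t for t in str(row.classification_terms).split(";") if t
                ],
                da_flag=_opt_bool(row.da_flag),
                knife_flag=_opt_bool(row.knife_flag),
                drugs_flag=_opt_bool(row.drugs_flag),
                alcohol_flag=_opt_bool(row.alcohol_flag),
                substance=_opt_str(row.substance),
                mopi_group=int(row.mopi_group) if not pd.isna(row.mopi_group) else None,
                casefile_id=_opt_str(row.casefile_id),
                casefile_date=_parse_date(row.casefile_date),
                verdict=_opt_str(row.verdict),
            )
        )
    return out


# --- match candidates / link table ------------------------------------------

_AGREEMENT_KEYS = [
    "forename_exact", "forename_first2", "surname_exact",
    "dob_exact", "sex_exact", "full_postcode", "outward_postcode",
]


def candidates_to_frame(candidates: Iterable[MatchCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "study_id": c.study_id,
            "offender_id": c.offender_id,
            "method": c.method,
            "strength": c.strength if c.strength is not None else "",
            "score": c.score if c.score is not None else "",
            "status": c.status,
        }
        for k in _AGREEMENT_KEYS:
            row[k] = bool(c.agreements.get(k, False))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["study_id", "offender_id", "method", "strength", "score", "status"]
        + _AGREEMENT_KEYS,
    )


def frame_to_candidates(df: pd.DataFrame) -> list[MatchCandidate]:
    out = []
    for row in df.itertuples():
        strength = None if row.strength in ("", None) or pd.isna(row.strength) else int(row.strength)
        score = None if row.score in ("", None) or pd.isna(row.score) else float(row.score)
        agreements = {k: bool(getattr(row, k)) for k in _AGREEMENT_KEYS}
        out.append(
            MatchCandidate(
                study_id=row.study_id,
                offender_id=row.offender_id,
                method=row.method,
                strength=strength,
                score=score,
                agreements=agreements,
                status=row.status,
            )
        )
    return out


def link_table_to_frame(table: LinkTable) -> pd.DataFrame:
    return candidates_to_frame(table.rows)


def frame_to_link_table(df: pd.DataFrame, ledger: dict | None = None) -> LinkTable:
    return LinkTable(rows=frame_to_candidates(df), ledger=dict(ledger or {}))


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True, dtype={"twin_group": str}).fillna("")
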