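"""Per-birthday residence flags for denominator definition.

A regional police force only records crimes committed in its area, so a
participant with no linked record may simply have lived elsewhere.  These
flags mark, for each birthday from age 10 (the age of criminal
responsibility) to 28, whether the participant's address history places
them inside the policing area, letting analyses restrict to person-years
actually at risk of acquiring a local record.
"""

from __future__ import annotations

from datetime import date
from typing import Callable, Iterable, Sequence

import pandas as pd

from .records import AddressInterval, CohortRecord, Postcode

DEFAULT_AGES = range(10, 29)


def _birthday(dob: date, age: int) -> date:
    try:
        return dob.replace(year=dob.year + age)
    except ValueError:  # 29 Feb on a non-leap year
        return dob.replace(year=dob.year + age, day=28)


def residence_flags(
    address_history: Sequence[AddressInterval],
    dob: date,
    area_predicate: Callable[[Postcode], bool],
    ages: Iterable[int] = DEFAULT_AGES,
) -> dict[int, dict]:
    """Flag, per birthday age, whether an in-area address covers that day.

    Returns ``{age: {"in_area": bool, "coverage_gap": bool}}``; a birthday
    not covered by any address interval yields ``in_area=False`` with the
    gap marker set, so "not resident" and "address unknown" stay
    distinguishable.  A birthday on an interval boundary counts as covered
    by the interval ending that day.
    """
    if dob is None:
        raise ValueError("date of birth is required to derive birthday flags")
    out: dict[int, dict] = {}
    for age in ages:
        day = _birthday(dob, age)
        covering = [iv for iv in address_history if iv.covers(day)]
        if not covering:
            out[age] = {"in_area": False, "coverage_gap": True}
        else:
            out[age] = {
                "in_area": any(area_predicate(iv.postcode) for iv in covering),
                "coverage_gap": False,
            }
    return out


def cohort_residence_flags(
    cohort: Sequence[CohortRecord],
    area_predicate: Callable[[Postcode], bool],
    ages: Iterable[int] = DEFAULT_AGES,
) -> pd.DataFrame:
    """One row per participant with age10..age28 in-area flags and gap markers."""
    ages = list(ages)
    rows = []
    for person in cohort:
        flags = residence_flags(person.addresses, person.dob, area_predicate, ages)
        row = {"study_id": person.study_id}
        for age in ages:
            row[f"age{age}"] = flags[age]["in_area"]
            row[f"gap{age}"] = flags[age]["coverage_gap"]
        rows.append(row)
    return pd.DataFrame(rows)


def denominator_summary(flags: pd.DataFrame) -> dict:
    """Per-age in-area proportions plus the every-birthday-resident proportion."""
    age_cols = sorted(
        (c for c in flags.columns if c.startswith("age")),
        key=lambda c: int(c[3:]),
    )
    per_age = {c: float(flags[c].mean()) for c in age_cols}
    every = float(flags[age_cols].all(axis=1).mean()) if age_cols else 1.0
    return {"per_age": per_age, "every_birthday": every, "n": len(flags)}
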