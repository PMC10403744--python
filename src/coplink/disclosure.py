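"""Disclosure control: pseudonymisation, age conversion, top-coding and
small-cell suppression.

Linked event records leave the safe setting only after identifier columns
are replaced by keyed-hash tokens, dates are converted to ages in whole
months (month and year of offence are retained), heavy-tailed variables
are top-coded, and any frequency table released alongside has small cells
suppressed — including complementary suppression, since a lone suppressed
cell can be recovered from published margins.
"""

from __future__ import annotations

import hashlib
import hmac
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import CohortRecord

# fields the source systems populate too rarely to be analytically useful;
# dropped from release when their missingness exceeds the threshold
DROPPABLE_FIELDS = ("alcohol_flag", "substance", "verdict")
DEFAULT_MISSINGNESS_THRESHOLD = 0.90
DEFAULT_SEVERITY_CUTOFF = 10.0
DEFAULT_OFFENDER_COUNT_CUTOFF = 5
SUPPRESSED = "-"


def pseudonymise_id(raw_id: str, salt: str) -> str:
    """Deterministic keyed-hash token for an identifier.

    Same id, same salt -> same token, so shared occurrence_ids keep their
    linking function; the token reveals nothing about the raw id without
    the salt.
    """
    if not raw_id:
        raise ValueError("cannot pseudonymise an empty identifier")
    digest = hmac.new(salt.encode(), str(raw_id).encode(), hashlib.sha256)
    return digest.hexdigest()[:12].upper()


def date_to_age_months(dob: date, event_date: date) -> int:
    """Age in completed calendar months at ``event_date``.

    The month is counted only once the day-of-month is reached, so the
    day before a birthday is one month short of a whole year.
    """
    if event_date < dob:
        raise ValueError(f"event date {event_date} precedes date of birth {dob}")
    months = (event_date.year - dob.year) * 12 + (event_date.month - dob.month)
    if event_date.day < dob.day:
        months -= 1
    return months


def top_code(value, cutoff: float, label: str | None = None):
    """Replace values at or above ``cutoff`` by a capped category label."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return value
    if np.isinf(cutoff) or value < cutoff:
        return value
    return label if label is not None else f"{cutoff:g}+"


# ---------------------------------------------------------------------------
# small-cell suppression

def _recoverable_cells(table: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Suppressed cells whose value is pinned down by margins + published cells.

    Solved as interval protection: for each suppressed cell, min/max its
    value over non-negative solutions consistent with the row and column
    totals; a zero-width interval means the cell is recoverable.
    """
    from scipy.optimize import linprog

    cells = list(zip(*np.nonzero(mask)))
    if not cells:
        return []
    index = {cell: k for k, cell in enumerate(cells)}
    n = len(cells)
    a_eq, b_eq = [], []
    for i in range(table.shape[0]):
        in_row = [index[(i, j)] for j in range(table.shape[1]) if mask[i, j]]
        if in_row:
            row = np.zeros(n)
            row[in_row] = 1.0
            a_eq.append(row)
            b_eq.append(table[i, mask[i]].sum())
    for j in range(table.shape[1]):
        in_col = [index[(i, j)] for i in range(table.shape[0]) if mask[i, j]]
        if in_col:
            col = np.zeros(n)
            col[in_col] = 1.0
            a_eq.append(col)
            b_eq.append(table[mask[:, j], j].sum())
    a_eq = np.array(a_eq)
    b_eq = np.array(b_eq)
    recoverable = []
    for cell, k in index.items():
        c = np.zeros(n)
        c[k] = 1.0
        lo = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
        hi = linprog(-c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
        if not (lo.success and hi.success):
            continue
        if hi.fun is not None and lo.fun is not None and (-hi.fun) - lo.fun < 0.5:
            recoverable.append(cell)
    return recoverable


def suppress_small_cells(freq_table: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Primary + complementary suppression of a count table.

    Cells with 0 < count < threshold are suppressed outright.  Additional
    cells are then suppressed greedily (smallest positive count sharing a
    row or column with an exposed cell first) until no suppressed count
    can be recovered from the published cells and the row/column margins,
    which are assumed to be released.
    """
    values = freq_table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("frequency table must be non-negative")
    mask = (values > 0) & (values < threshold)
    if not mask.any():
        return freq_table.copy()
    n_rows, n_cols = values.shape
    while True:
        exposed = _recoverable_cells(values, mask)
        if not exposed:
            break
        progressed = False
        for (i, j) in exposed:
            # close the smallest-loss 2x2 rectangle through the exposed cell:
            # a suppressed rectangle is irreducible under row/column margins
            best = None
            for r in range(n_rows):
                if r == i:
                    continue
                for c in range(n_cols):
                    if c == j:
                        continue
                    loss = sum(
                        values[x, y]
                        for x, y in ((i, c), (r, j), (r, c))
                        if not mask[x, y]
                    )
                    zeros = sum(
                        1
                        for x, y in ((i, c), (r, j), (r, c))
                        if not mask[x, y] and values[x, y] == 0
                    )
                    key = (zeros, loss)  # avoid zero cells: they hide nothing
                    if best is None or key < best[0]:
                        best = (key, r, c)
            if best is None:
                continue
            _, r, c = best
            for x, y in ((i, c), (r, j), (r, c)):
                mask[x, y] = True
            progressed = True
            break
        if not progressed:  # single row/column: nothing left to hide behind
            break
    out = freq_table.copy().astype(object)
    out[pd.DataFrame(mask, index=out.index, columns=out.columns)] = pd.NA
    return out


def scan_for_leaks(frame: pd.DataFrame, raw_strings: Iterable[str]) -> list[str]:
    """Raw identifier strings that appear anywhere in a release table."""
    needles = {s for s in raw_strings if s and len(str(s)) >= 3}
    haystack = "\n".join(
        frame.astype(str).fillna("").to_csv(index=False).upper().splitlines()
    )
    return sorted(s for s in needles if str(s).upper() in haystack)


# ---------------------------------------------------------------------------
# release construction

RELEASE_COLUMNS = [
    "study_id",
    "has_record",
    "pseudo_occurrence_id",
    "pseudo_casefile_id",
    "age_at_offence_months",
    "age_created_months",
    "age_reported_months",
    "age_casefile_months",
    "offence_month",
    "offence_year",
    "offence_group",
    "severity_topcoded",
    "offender_count_topcoded",
    "da_flag",
    "knife_flag",
    "drugs_flag",
    "alcohol_flag",
    "substance",
    "verdict",
]


def build_release(
    linked_events: pd.DataFrame,
    cohort: Sequence[CohortRecord],
    config: Mapping | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Transform linked events into research-ready release records.

    Emits one row per eligible linked record (``has_record=True``) plus one
    ``has_record=False`` row for every linkage-permitted participant with
    no eligible record, so analysts get a complete denominator.  Returns
    ``(release, drop_report)`` where the report lists fields withheld for
    excessive missingness.
    """
    cfg = dict(config or {})
    salt = str(cfg.get("salt", "release-salt"))
    sev_cut = float(cfg.get("severity_cutoff", DEFAULT_SEVERITY_CUTOFF))
    cnt_cut = int(cfg.get("offender_count_cutoff", DEFAULT_OFFENDER_COUNT_CUTOFF))
    miss_thr = float(cfg.get("missingness_threshold", DEFAULT_MISSINGNESS_THRESHOLD))

    dobs = {r.study_id: r.dob for r in cohort}
    permitted = [r.study_id for r in cohort if r.linkage_permitted]

    rows = []
    for _, ev in linked_events.iterrows():
        sid = ev["study_id"]
        dob = dobs.get(sid)
        if dob is None:
            raise ValueError(f"linked participant {sid} has no date of birth on roster")
        from_d, rep_d, cre_d = ev["from_date"], ev["reported_date"], ev["created_date"]
        case_d = ev.get("casefile_date")
        rows.append(
            {
                "study_id": sid,
                "has_record": True,
                "pseudo_occurrence_id": pseudonymise_id(ev["occurrence_id"], salt),
                "pseudo_casefile_id": (
                    pseudonymise_id(ev["casefile_id"], salt) if ev.get("casefile_id") else pd.NA
                ),
                "age_at_offence_months": date_to_age_months(dob, from_d),
                "age_created_months": date_to_age_months(dob, cre_d),
                "age_reported_months": date_to_age_months(dob, rep_d),
                "age_casefile_months": (
                    date_to_age_months(dob, case_d) if isinstance(case_d, date) else pd.NA
                ),
                "offence_month": from_d.month,
                "offence_year": from_d.year,
                "offence_group": ev["offence_group"],
                "severity_topcoded": top_code(ev.get("severity"), sev_cut),
                "offender_count_topcoded": top_code(int(ev["offender_count"]), cnt_cut),
                "da_flag": ev.get("da_flag"),
                "knife_flag": ev.get("knife_flag"),
                "drugs_flag": ev.get("drugs_flag"),
                "alcohol_flag": ev.get("alcohol_flag"),
                "substance": ev.get("substance"),
                "verdict": ev.get("verdict"),
            }
        )
    release = pd.DataFrame(rows, columns=RELEASE_COLUMNS)

    drop_report = {"missingness": {}, "dropped_fields": []}
    for field in DROPPABLE_FIELDS:
        if len(release) == 0:
            break
        missing = release[field].isna().mean()
        drop_report["missingness"][field] = round(float(missing), 4)
        if missing > miss_thr:
            release = release.drop(columns=[field])
            drop_report["dropped_fields"].append(field)

    linked_ids = set(release["study_id"]) if len(release) else set()
    blank = {c: pd.NA for c in release.columns}
    no_record = [
        {**blank, "study_id": sid, "has_record": False}
        for sid in permitted
        if sid not in linked_ids
    ]
    release = pd.concat([release, pd.DataFrame(no_record, columns=release.columns)],
                        ignore_index=True)
    drop_report["n_record_rows"] = int(release["has_record"].sum())
    drop_report["n_no_record_rows"] = len(no_record)
    return release, drop_report
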