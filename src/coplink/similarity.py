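"""Field comparators for probabilistic matching.

Short personal names are compared with Jaro-Winkler similarity, dates
component-wise with credit for day/month transposition, and postcodes on a
full/outward/none tier.  All comparators are symmetric and return values
in [0, 1], with 1 reserved for identical values.
"""

from __future__ import annotations

import unicodedata
from datetime import date
from typing import Union

Comparable = Union[str, date, "PostcodeLike"]


def normalise_name(name: str) -> str:
    """Case-fold, strip accents and punctuation, collapse whitespace."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    cleaned = "".join(c if c.isalnum() or c.isspace() else " " for c in stripped)
    return " ".join(cleaned.upper().split())


def jaro(a: str, b: str) -> float:
    """Jaro similarity between two strings."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = True
                match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # count transpositions between the two matched subsequences
    sa = [c for c, m in zip(a, match_a) if m]
    sb = [c for c, m in zip(b, match_b) if m]
    transpositions = sum(ca != cb for ca, cb in zip(sa, sb)) // 2
    m = matches
    return (m / la + m / lb + (m - transpositions) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler similarity: Jaro boosted for a shared prefix (<= 4 chars)."""
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a[:4], b[:4]):
        if ca != cb:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


def date_similarity(a: date, b: date) -> float:
    """Component-wise date agreement with partial credit.

    Identical dates score 1; a day/month transposition in the same year
    scores 0.85 (treated as a likely keying error); otherwise the score is
    the fraction of (day, month, year) components that agree.
    """
    if a == b:
        return 1.0
    if a.year == b.year and a.day == b.month and a.month == b.day:
        return 0.85
    agree = (a.day == b.day) + (a.month == b.month) + (a.year == b.year)
    return agree / 3.0


def postcode_tiered(a, b) -> float:
    """Tiered postcode agreement: 1 full, 0.5 outward-only, 0 otherwise.

    Accepts single postcodes or iterables of postcodes (address histories);
    the best tier across the two sets wins.
    """
    set_a = _as_postcode_list(a)
    set_b = _as_postcode_list(b)
    if not set_a or not set_b:
        return 0.0
    full_a = {(p.outward, p.inward) for p in set_a}
    full_b = {(p.outward, p.inward) for p in set_b}
    if full_a & full_b:
        return 1.0
    if {p.outward for p in set_a} & {p.outward for p in set_b}:
        return 0.5
    return 0.0


def _as_postcode_list(value) -> list:
    from .records import Postcode  # local import to avoid a cycle

    if value is None:
        return []
    if isinstance(value, Postcode):
        return [value]
    if isinstance(value, str):
        return [Postcode.parse(value)] if value.strip() else []
    return [Postcode.parse(p) if isinstance(p, str) else p for p in value]


COMPARATORS = {
    "exact": lambda a, b: 1.0 if a == b else 0.0,
    "string_similarity": lambda a, b: jaro_winkler(normalise_name(a), normalise_name(b)),
    "date_components": date_similarity,
    "postcode_tiered": postcode_tiered,
}


def field_similarity(a, b, comparator: str) -> float:
    """Dispatch to a named comparator.  Missing values must be handled upstream."""
    try:
        fn = COMPARATORS[comparator]
    except KeyError:
        raise ValueError(f"unknown comparator {comparator!r}") from None
    return fn(a, b)
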