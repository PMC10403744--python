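"""Crime-severity scoring: base harm score x cumulative multipliers.

Every Home Office offence code carries a base harm score in [0.01, 100]
reflecting the harm of the offence rather than its volume.  The released
severity value multiplies that base by cumulative percentage uplifts when
aggravating factors are tagged: +30% domestic abuse, +50% hate, +5% drug,
+10% firearm, +30% safeguarding children, applied in that order.  No
intermediate rounding is performed, so the result is invariant to the
order in which the multipliers are applied (a property the test suite
checks explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .records import SeverityFlags

# (flag attribute, uplift) in the order the multipliers are defined
MULTIPLIERS = (
    ("domestic_abuse", 1.30),
    ("hate", 1.50),
    ("drug", 1.05),
    ("firearm", 1.10),
    ("safeguarding_children", 1.30),
)

MIN_HARM = 0.01
MAX_HARM = 100.0


@dataclass(frozen=True)
class Offence:
    ho_code: str
    description: str
    group: str
    harm: float


# Bundled catalogue.  The eight offences whose harm scores are in the
# public domain carry those exact values; the remainder are synthetic
# low-harm offences (codes and scores invented) so that every one of the
# twelve offence groups is populated.  Real harm tables are not published
# in full; users can supply their own via ``HarmTable``.
OFFENCE_CATALOGUE = [
    Offence("092/01", "intent to supply class A drugs", "Drug offences", 0.8),
    Offence("005/01", "wounding with intent to do serious bodily harm", "Violence against the person", 1.45),
    Offence("019/08", "rape", "Sexual offences", 2.9),
    Offence("106/01", "conspiring to traffic a person into the UK for exploitation", "Miscellaneous crimes against society", 8.0),
    Offence("086/02", "causing or inciting child pornography", "Sexual offences", 10.0),
    Offence("004/01", "manslaughter", "Violence against the person", 30.0),
    Offence("114/01", "use of noxious substance in terrorism offence", "Miscellaneous crimes against society", 50.0),
    Offence("001/01", "murder", "Violence against the person", 100.0),
    # synthetic low-harm offences (invented codes and scores)
    Offence("105/10", "common assault", "Violence against the person", 0.1),
    Offence("008/30", "assault occasioning actual bodily harm", "Violence against the person", 0.25),
    Offence("092/20", "possession of cannabis", "Drug offences", 0.02),
    Offence("092/35", "possession of class A drug", "Drug offences", 0.05),
    Offence("046/10", "shoplifting", "Theft", 0.02),
    Offence("049/01", "theft from the person", "Theft", 0.08),
    Offence("028/01", "burglary dwelling", "Burglary", 0.3),
    Offence("030/01", "burglary non-dwelling", "Burglary", 0.15),
    Offence("125/22", "public fear alarm or distress", "Public order offences", 0.01),
    Offence("066/20", "affray", "Public order offences", 0.05),
    Offence("056/01", "arson", "Arson and criminal damage", 0.6),
    Offence("058/07", "criminal damage under 5000", "Arson and criminal damage", 0.02),
    Offence("034/01", "robbery of personal property", "Robbery", 0.9),
    Offence("053/30", "fraud by false representation", "Fraud", 0.06),
    Offence("081/01", "possession of offensive weapon", "Possession of weapons", 0.2),
    Offence("037/02", "aggravated vehicle taking", "Vehicle offences", 0.12),
    Offence("048/01", "vehicle interference", "Vehicle offences", 0.02),
    Offence("802/01", "drunk and disorderly", "Miscellaneous crimes against society", 0.01),
]

OFFENCE_GROUPS = sorted({o.group for o in OFFENCE_CATALOGUE})


class HarmTable:
    """Lookup from Home Office offence code to base harm score.

    Scores outside [0.01, 100] are rejected.  Published harm tables have no
    offence scoring strictly between 3 and 8; a user table violating that
    gap raises a warning rather than an error since the constraint's
    rationale is not public.
    """

    def __init__(self, scores: Mapping[str, float]):
        import warnings

        for code, value in scores.items():
            if not (MIN_HARM <= value <= MAX_HARM):
                raise ValueError(f"harm score for {code} out of range: {value}")
            if 3.0 < value < 8.0:
                warnings.warn(
                    f"harm score for {code} is {value}: published tables have no "
                    "score strictly between 3 and 8",
                    stacklevel=2,
                )
        self._scores = dict(scores)

    def __contains__(self, code: str) -> bool:
        return code in self._scores

    def __getitem__(self, code: str) -> float:
        return base_harm(code, self)

    def get(self, code: str, default=None):
        return self._scores.get(code, default)

    @classmethod
    def default(cls) -> "HarmTable":
        return cls({o.ho_code: o.harm for o in OFFENCE_CATALOGUE})


def base_harm(ho_code: str, table: HarmTable) -> float:
    """Base harm score for an offence code; unknown codes are an error."""
    value = table.get(ho_code)
    if value is None:
        raise KeyError(f"no harm score for Home Office code {ho_code!r}")
    return value


def apply_multipliers(base: float, flags: SeverityFlags) -> float:
    """Inflate a base harm score by the cumulative aggravating-factor uplifts."""
    if base <= 0:
        raise ValueError("base harm score must be positive")
    value = base
    for attr, uplift in MULTIPLIERS:
        if getattr(flags, attr):
            value *= uplift
    return value


def severity_score(ho_code: str, flags: SeverityFlags, table: HarmTable | None = None) -> float:
    table = table or HarmTable.default()
    return apply_multipliers(base_harm(ho_code, table), flags)


def score_events(events_df, table: HarmTable | None = None):
    """Append a ``severity`` column to a linked-events DataFrame.

    Domestic-abuse and drugs flags come from the event row; the remaining
    aggravating factors are not carried by the event table and default to
    absent.
    """
    table = table or HarmTable.default()
    df = events_df.copy()

    def _score(row):
        flags = SeverityFlags(
            domestic_abuse=bool(row.get("da_flag")),
            drug=bool(row.get("drugs_flag")),
        )
        return apply_multipliers(base_harm(row["ho_code"], table), flags)

    df["severity"] = df.apply(_score, axis=1)
    return df
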