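"""Core record types shared across the linkage pipeline.

The pipeline links a birth-cohort roster to a regional police register in
two stages: identity matching on personal identifiers (forename, surname,
date of birth, sex, postcode history) and subsequent extraction/filtering
of per-offence event records.  These dataclasses are the in-memory
currency of stage 1; stage 2 operates on pandas DataFrames with the
column layout documented in :mod:`coplink.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Optional


@dataclass(frozen=True)
class Postcode:
    """A UK-shaped postcode split into its outward (post town) and inward parts."""

    outward: str
    inward: str

    def __post_init__(self) -> None:
        if not self.outward:
            raise ValueError("outward part of a postcode must be non-empty")

    def __str__(self) -> str:
        return f"{self.outward} {self.inward}" if self.inward else self.outward

    @classmethod
    def parse(cls, text: str) -> "Postcode":
        text = text.strip().upper()
        if " " in text:
            outward, inward = text.split(None, 1)
        elif len(text) > 3:
            outward, inward = text[:-3], text[-3:]
        else:
            outward, inward = text, ""
        return cls(outward=outward, inward=inward.strip())


@dataclass
class AddressInterval:
    """One spell at an address; intervals are half-open [from_date, to_date)."""

    postcode: Postcode
    from_date: date
    to_date: Optional[date]  # None = still current

    def covers(self, day: date) -> bool:
        if day < self.from_date:
            return False
        # A date falling on the boundary counts as covered by the interval
        # ending that day (documented convention).
        return self.to_date is None or day <= self.to_date


@dataclass
class CohortRecord:
    """One study participant's identifiers as held by the cohort."""

    study_id: str
    forename: str
    surname: str
    dob: date
    sex: str  # "M" or "F"
    addresses: list[AddressInterval] = field(default_factory=list)
    twin_group: Optional[str] = None
    linkage_permitted: bool = True

    @property
    def postcodes(self) -> list[Postcode]:
        return [a.postcode for a in self.addresses]

    @property
    def current_postcode(self) -> Optional[Postcode]:
        return self.addresses[-1].postcode if self.addresses else None


@dataclass
class PoliceSubject:
    """One police-register identity (offender_id) with its identifiers.

    ``truth_study_id`` is ground truth used only for evaluation; it is never
    written to the pipeline's input files.
    """

    offender_id: str
    forename: str
    surname: str
    dob: date
    sex: str
    postcodes: list[Postcode] = field(default_factory=list)
    truth_study_id: Optional[str] = None


# Home Office outcome codes: the 22-category disposal classification.
OUTCOME_CODES = tuple(f"OC{i}" for i in range(1, 23))


@dataclass
class CrimeEvent:
    """One offence record for one offender identity.

    A group crime (offender_count > 1) is represented by several rows
    sharing the same occurrence_id, one per participating offender.
    """

    occurrence_id: str
    offender_id: str
    created_date: date
    reported_date: date
    from_date: date
    ho_code: str
    offence_group: str
    offender_count: int
    outcome_code: str
    classification_terms: list[str]
    da_flag: Optional[bool] = None
    knife_flag: Optional[bool] = None
    drugs_flag: Optional[bool] = None
    alcohol_flag: Optional[bool] = None
    substance: Optional[str] = None
    mopi_group: Optional[int] = None
    casefile_id: Optional[str] = None
    casefile_date: Optional[date] = None
    verdict: Optional[str] = None

    def __post_init__(self) -> None:
        if self.offender_count < 1:
            raise ValueError("offender_count must be >= 1")
        if self.from_date > self.reported_date:
            raise ValueError("from_date must be <= reported_date")
        if len(self.classification_terms) > 6:
            raise ValueError("at most six classification terms per offender")
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(f"unknown outcome code {self.outcome_code!r}")


@dataclass
class MatchCandidate:
    """A scored (study_id, offender_id) pair with its provenance and fate."""

    study_id: str
    offender_id: str
    method: str  # "deterministic" | "probabilistic"
    strength: Optional[int] = None  # 1/2/3, deterministic only
    score: Optional[float] = None  # probabilistic only
    agreements: dict = field(default_factory=dict)
    status: str = "accepted"

    def __post_init__(self) -> None:
        if self.method == "deterministic" and self.strength is None:
            raise ValueError("deterministic candidates carry a match strength")
        if self.method == "probabilistic" and self.score is None:
            raise ValueError("probabilistic candidates carry a score")


@dataclass
class LinkTable:
    """Final ID match table plus a removal ledger keyed by reason."""

    rows: list[MatchCandidate]
    ledger: dict = field(default_factory=dict)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.study_id, r.offender_id) for r in self.rows}

    def study_ids(self) -> set[str]:
        return {r.study_id for r in self.rows}

    def offender_ids(self) -> set[str]:
        return {r.offender_id for r in self.rows}


@dataclass
class SeverityFlags:
    """Aggravating-factor tags that inflate an offence's base harm score."""

    domestic_abuse: bool = False
    hate: bool = False
    drug: bool = False
    firearm: bool = False
    safeguarding_children: bool = False


@dataclass
class GenParams:
    """Parameters of the synthetic cohort/register/event generator.

    Defaults emulate the study conditions: a ~14% offending prevalence, a
    small rate of police-side identity fragmentation, realistic identifier
    corruption (nickname variants, single-character typos, stale addresses,
    occasional wholly fake names), pre-2007 paper-era censoring, and the
    September 2015 change in disposal terminology.
    """

    n_cohort: int = 2000
    n_background: int = 500
    offending_rate: float = 0.14
    fragmentation_rate: float = 0.01
    twin_rate: float = 0.02
    name_variant_rate: float = 0.05
    typo_rate: float = 0.02
    stale_address_rate: float = 0.20
    fake_id_rate: float = 0.01
    group_crime_rate: float = 0.12
    consent_rate: float = 0.86
    in_area_rate: float = 0.90
    events_mean: float = 2.0
    era_boundary: date = date(2015, 9, 1)
    electronic_start: date = date(2007, 1, 1)
    court_data_start: date = date(2015, 11, 1)
    extraction_date: date = date(2021, 7, 1)
    dob_start: date = date(1991, 1, 1)
    dob_end: date = date(1993, 1, 31)
    pre_electronic_drop: float = 1.0
    seed: int = 0

    _RATE_FIELDS = (
        "offending_rate",
        "fragmentation_rate",
        "twin_rate",
        "name_variant_rate",
        "typo_rate",
        "stale_address_rate",
        "fake_id_rate",
        "group_crime_rate",
        "consent_rate",
        "in_area_rate",
        "pre_electronic_drop",
    )

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cohort < 0 or self.n_background < 0:
            raise ValueError("population sizes must be non-negative")
        if self.dob_start > self.dob_end:
            raise ValueError("dob window is empty")
        if self.events_mean < 1.0:
            raise ValueError("events_mean must be >= 1")

    def replace(self, **kw) -> "GenParams":
        return dataclasses.replace(self, **kw)

    def noiseless(self, **kw) -> "GenParams":
        """A copy with every identifier-corruption process switched off."""
        return self.replace(
            name_variant_rate=0.0,
            typo_rate=0.0,
            stale_address_rate=0.0,
            fake_id_rate=0.0,
            **kw,
        )
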