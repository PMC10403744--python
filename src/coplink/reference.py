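"""Published headline counts from the cohort-to-regional-police linkage that
this pipeline models, with the arithmetic that connects them.

The real identifiers and event records are access-controlled, so these
counts are the public face of that linkage: the deterministic tier table,
the flow from probabilistic matching through review to linked
individuals, and the offence-group record counts by sex.  They serve two
purposes here: the flow arithmetic is recomputed by the same accounting
functions the pipeline uses on synthetic data, and the offence-group
table exercises the share/suppression machinery on realistic margins.
"""

from __future__ import annotations

# Deterministic matches by postcode strength tier
# (1 = full postcode, 2 = outward part only, 3 = names and dob alone)
DETERMINISTIC_TIER_COUNTS = {1: 956, 2: 403, 3: 517}

# Unique offender_ids matched after probabilistic linkage + review
PROBABILISTIC_TOTAL_OFFENDER_IDS = 2292

# Individuals each holding two offender_ids (police-side fragmentation)
DUAL_OFFENDER_ID_INDIVIDUALS = 19

# Review/deduplication removals
TWIN_CHECK_REMOVALS = 37
LOW_CONFIDENCE_REMOVALS = 34

# Participants with permission to link, and those with >= 1 eligible record
PERMITTED_PARTICIPANTS = 12662
LINKED_PARTICIPANTS = 1757

# Event records extracted for matched individuals / surviving the
# disposal-eligibility filter, and the distinct offences they represent
RECORDS_EXTRACTED = 11681
RECORDS_ELIGIBLE = 6413
OFFENCES_ELIGIBLE = 6283

# Offence-group record counts (overall, male, female); None = suppressed cell
OFFENCE_GROUP_RECORDS = {
    "Arson and criminal damage": (807, 732, 75),
    "Burglary": (466, 451, 15),
    "Drug offences": (1237, 1095, 142),
    "Fraud": (44, None, None),
    "Miscellaneous crimes against society": (157, 131, 26),
    "Possession of weapons": (85, 77, 8),
    "Public order offences": (683, 572, 111),
    "Robbery": (102, 88, 14),
    "Sexual offences": (45, None, None),
    "Theft": (1077, 622, 455),
    "Vehicle offences": (277, 268, 9),
    "Violence against the person": (1433, 1141, 292),
}
MALE_RECORDS = 5255
FEMALE_RECORDS = 1158


def flow_arithmetic() -> dict:
    """Recompute the linkage flow quantities from the published counts.

    deterministic total = sum of tier counts; probabilistic additions =
    matched offender_ids minus deterministic; linked individuals = matched
    offender_ids minus the fragmented surplus; percentage linked = linked
    participants over permitted participants.
    """
    det_total = sum(DETERMINISTIC_TIER_COUNTS.values())
    prob_additions = PROBABILISTIC_TOTAL_OFFENDER_IDS - det_total
    individuals = PROBABILISTIC_TOTAL_OFFENDER_IDS - DUAL_OFFENDER_ID_INDIVIDUALS
    pct_linked = 100.0 * LINKED_PARTICIPANTS / PERMITTED_PARTICIPANTS
    return {
        "deterministic_total": det_total,
        "probabilistic_additions": prob_additions,
        "linked_individuals": individuals,
        "pct_participants_linked": pct_linked,
    }


def offence_group_shares() -> dict[str, float]:
    """Offence-group percentages of eligible records, to one decimal."""
    return {
        group: round(100.0 * counts[0] / RECORDS_ELIGIBLE, 1)
        for group, counts in OFFENCE_GROUP_RECORDS.items()
    }
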