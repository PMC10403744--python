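"""Shared fixtures: small synthetic worlds and full pipeline runs.

Generation is fully seeded, so fixtures are deterministic across runs and
safe to share at session scope.
"""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

from coplink.records import AddressInterval, CohortRecord, GenParams, PoliceSubject, Postcode
from coplink.synthgen import generate_all

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


SMALL = GenParams(n_cohort=400, n_background=120, seed=11)


@pytest.fixture(scope="session")
def small_world():
    """A small corrupted world: (cohort, subjects, truth, events)."""
    return generate_all(SMALL)


@pytest.fixture(scope="session")
def noiseless_world():
    return generate_all(SMALL.noiseless())


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline at the default study conditions."""
    import coplink

    out = tmp_path_factory.mktemp("run_default")
    manifest = coplink.run_pipeline({}, out, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    import coplink

    out = tmp_path_factory.mktemp("run_noiseless")
    cfg = {
        "gen": {
            "name_variant_rate": 0.0,
            "typo_rate": 0.0,
            "stale_address_rate": 0.0,
            "fake_id_rate": 0.0,
        }
    }
    manifest = coplink.run_pipeline(cfg, out, seed=7)
    return out, manifest


def make_person(
    study_id="ST1",
    forename="CATHERINE",
    surname="DENHURST",
    dob=date(1992, 4, 15),
    sex="F",
    postcodes=("AV1 2DD",),
    twin_group=None,
    permitted=True,
) -> CohortRecord:
    addresses = [
        AddressInterval(Postcode.parse(pc), date(1991, 1, 1), None) for pc in postcodes
    ]
    return CohortRecord(
        study_id=study_id,
        forename=forename,
        surname=surname,
        dob=dob,
        sex=sex,
        addresses=addresses,
        twin_group=twin_group,
        linkage_permitted=permitted,
    )


def make_subject(
    offender_id="OF1",
    forename="CATHERINE",
    surname="DENHURST",
    dob=date(1992, 4, 15),
    sex="F",
    postcodes=("AV1 2DD",),
) -> PoliceSubject:
    return PoliceSubject(
        offender_id=offender_id,
        forename=forename,
        surname=surname,
        dob=dob,
        sex=sex,
        postcodes=[Postcode.parse(pc) for pc in postcodes],
    )
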