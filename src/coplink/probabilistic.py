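"""Fellegi-Sunter probabilistic matching with blocking and similarity comparisons.

Each identifier field carries an m-probability (chance the field agrees on
a true match) and a u-probability (chance it agrees on a non-match).  A
field that agrees contributes log2(m/u) to the pair's score, a field that
disagrees contributes log2((1-m)/(1-u)), and a field missing on either
side contributes nothing.  "Agrees" means the field comparator's
similarity reaches the field's threshold, which lets the score absorb
short-form names, typographical errors and partial postcode agreement.
Pairs scoring at or above a decision threshold are designated matches;
one-to-one resolution and manual-review rules are applied downstream.

m-probabilities are configuration (the error processes of the source
systems are not observable from one extract); u-probabilities are by
default estimated from value frequencies in the data, since the chance
agreement rate is exactly a collision probability.  An optional EM
routine refines m and u from the observed agreement patterns.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .deterministic import candidate_agreements
from .records import CohortRecord, MatchCandidate, PoliceSubject
from .similarity import field_similarity, normalise_name

_U_FLOOR, _U_CEIL = 1e-4, 0.6


@dataclass(frozen=True)
class FieldModel:
    """Comparison model for one identifier field."""

    field: str
    m_prob: float
    u_prob: float
    comparator: str
    similarity_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.m_prob < 1.0 and 0.0 < self.u_prob < 1.0):
            raise ValueError("m and u probabilities must lie in (0, 1)")
        if self.m_prob <= self.u_prob:
            raise ValueError(
                f"{self.field}: m_prob must exceed u_prob "
                f"({self.m_prob} <= {self.u_prob})"
            )

    @property
    def agreement_weight(self) -> float:
        return math.log2(self.m_prob / self.u_prob)

    @property
    def disagreement_weight(self) -> float:
        return math.log2((1.0 - self.m_prob) / (1.0 - self.u_prob))


def default_models() -> list[FieldModel]:
    """Default field models; u-probabilities are placeholders until estimated."""
    return [
        FieldModel("forename", 0.95, 0.02, "string_similarity", 0.85),
        FieldModel("surname", 0.95, 0.01, "string_similarity", 0.85),
        FieldModel("dob", 0.95, 0.002, "date_components", 0.85),
        FieldModel("sex", 0.97, 0.5, "exact", 1.0),
        # postcode m is deliberately modest (study-held addresses go stale)
        # and only full-postcode agreement counts as scoring evidence: an
        # outward part is shared by thousands of households, so tier-2
        # agreement is left to the deterministic strength variable
        FieldModel("postcode", 0.70, 0.001, "postcode_tiered", 1.0),
    ]


def _field_value(record, field: str):
    if field == "forename":
        return normalise_name(record.forename) or None
    if field == "surname":
        return normalise_name(record.surname) or None
    if field == "dob":
        return record.dob
    if field == "sex":
        return record.sex or None
    if field == "postcode":
        return record.postcodes or None
    raise KeyError(field)


def estimate_u(
    cohort: Sequence[CohortRecord],
    subjects: Sequence[PoliceSubject],
    models: Iterable[FieldModel],
) -> list[FieldModel]:
    """Replace each model's u with the empirical chance-agreement probability.

    For a field with value distribution p (cohort) and q (register) the
    probability two unrelated records agree is the collision probability
    sum_v p_v q_v.  For postcodes the collision is computed at the level
    the model's threshold treats as agreement: full postcodes at the
    default threshold of 1, outward parts below it.
    """
    out = []
    for model in models:
        if model.field == "postcode":
            level = (lambda p: str(p)) if model.similarity_threshold > 0.5 else (lambda p: p.outward)
            pa = Counter(level(p) for r in cohort for p in r.postcodes[:1])
            pb = Counter(level(p) for r in subjects for p in r.postcodes[:1])
        else:
            pa = Counter(_field_value(r, model.field) for r in cohort)
            pb = Counter(_field_value(r, model.field) for r in subjects)
            pa.pop(None, None)
            pb.pop(None, None)
        na, nb = sum(pa.values()), sum(pb.values())
        if na == 0 or nb == 0:
            out.append(model)
            continue
        u = sum(pa[v] / na * pb.get(v, 0) / nb for v in pa)
        u = min(max(u, _U_FLOOR), _U_CEIL)
        if u >= model.m_prob:
            u = model.m_prob / 2.0
        out.append(replace(model, u_prob=u))
    return out


def score_pair(
    person: CohortRecord, subject: PoliceSubject, models: Iterable[FieldModel]
) -> float:
    """Summed field weights for one pair (missing fields contribute nothing)."""
    return score_pair_detail(person, subject, models)[0]


def score_pair_detail(
    person: CohortRecord, subject: PoliceSubject, models: Iterable[FieldModel]
) -> tuple[float, dict]:
    score = 0.0
    detail: dict = {}
    for model in models:
        a = _field_value(person, model.field)
        b = _field_value(subject, model.field)
        if a is None or b is None:
            detail[model.field] = None
            continue
        sim = field_similarity(a, b, model.comparator)
        agrees = sim >= model.similarity_threshold
        score += model.agreement_weight if agrees else model.disagreement_weight
        detail[model.field] = sim
    return score, detail


# ---------------------------------------------------------------------------
# blocking

def _blocking_keys(record, scheme_key: str):
    if scheme_key == "dob":
        return [record.dob]
    if scheme_key == "dobyear_surname_initial":
        s = normalise_name(record.surname)
        return [(record.dob.year, s[0])] if s else []
    if scheme_key == "surname_sex":
        s = normalise_name(record.surname)
        return [(s, record.sex)] if s else []
    raise ValueError(f"unknown blocking key {scheme_key!r}")


DEFAULT_SCHEME = ("dob", "dobyear_surname_initial", "surname_sex")


def block_candidates(
    cohort: Sequence[CohortRecord],
    subjects: Sequence[PoliceSubject],
    scheme: Sequence[str] = DEFAULT_SCHEME,
) -> list[tuple[CohortRecord, PoliceSubject]]:
    """Union of record pairs sharing any blocking key in the scheme."""
    if not scheme:
        raise ValueError("blocking scheme must contain at least one key")
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[CohortRecord, PoliceSubject]] = []
    for key_name in scheme:
        index: dict = {}
        for person in cohort:
            for key in _blocking_keys(person, key_name):
                index.setdefault(key, []).append(person)
        for subject in subjects:
            for key in _blocking_keys(subject, key_name):
                for person in index.get(key, []):
                    pair_id = (person.study_id, subject.offender_id)
                    if pair_id not in seen:
                        seen.add(pair_id)
                        pairs.append((person, subject))
    return pairs


def score_candidates(
    pairs: Iterable[tuple[CohortRecord, PoliceSubject]],
    models: Iterable[FieldModel],
) -> list[tuple[CohortRecord, PoliceSubject, float, dict]]:
    models = list(models)
    return [(p, s, *score_pair_detail(p, s, models)) for p, s in pairs]


# With the default field models a pair agreeing on dob and sex plus exactly
# one of {forename, surname, postcode} scores ~10.5-12.5, while any true
# configuration retaining two such agreements scores >= ~17.  The default
# threshold sits between: a match must bring at least two independent
# identifier agreements beyond date of birth and sex.
DEFAULT_THRESHOLD = 14.0


def classify(
    scored_pairs: Iterable[tuple[CohortRecord, PoliceSubject, float, dict]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchCandidate]:
    """Designate every pair scoring at or above the threshold a match.

    Duplicate/one-to-many resolution is deferred to the review stage.
    """
    out = []
    for person, subject, score, detail in scored_pairs:
        if score >= threshold:
            agreements = candidate_agreements(person, subject)
            agreements["similarities"] = detail
            out.append(
                MatchCandidate(
                    study_id=person.study_id,
                    offender_id=subject.offender_id,
                    method="probabilistic",
                    score=score,
                    agreements=agreements,
                )
            )
    return out


def probabilistic_link(
    cohort: Sequence[CohortRecord],
    subjects: Sequence[PoliceSubject],
    models: Optional[Sequence[FieldModel]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    scheme: Sequence[str] = DEFAULT_SCHEME,
    estimate_u_from_data: bool = True,
) -> list[MatchCandidate]:
    """Blocking + scoring + threshold classification in one call."""
    models = list(models) if models is not None else default_models()
    if estimate_u_from_data:
        models = estimate_u(cohort, subjects, models)
    pairs = block_candidates(cohort, subjects, scheme)
    return classify(score_candidates(pairs, models), threshold)


def em_refine(
    patterns: np.ndarray,
    models: Sequence[FieldModel],
    prior_match: float = 0.05,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> list[FieldModel]:
    """Refine m/u probabilities by EM over binary agreement patterns.

    ``patterns`` is an (n_pairs, n_fields) 0/1 array of field agreements
    (missing comparisons should be imputed with the field's u before
    calling, or the rows dropped).  Uses the standard two-class latent
    mixture: each pair is a match with probability lambda, fields agree
    independently given the class.
    """
    x = np.asarray(patterns, dtype=float)
    m = np.array([mod.m_prob for mod in models])
    u = np.array([mod.u_prob for mod in models])
    lam = prior_match
    for _ in range(n_iter):
        log_m = x @ np.log(m) + (1 - x) @ np.log(1 - m)
        log_u = x @ np.log(u) + (1 - x) @ np.log(1 - u)
        num = lam * np.exp(log_m)
        den = num + (1 - lam) * np.exp(log_u)
        g = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        new_m = (g[:, None] * x).sum(axis=0) / max(g.sum(), 1e-12)
        new_u = ((1 - g)[:, None] * x).sum(axis=0) / max((1 - g).sum(), 1e-12)
        new_lam = g.mean()
        new_m = np.clip(new_m, 1e-4, 1 - 1e-4)
        new_u = np.clip(new_u, 1e-4, 1 - 1e-4)
        if (
            np.abs(new_m - m).max() < tol
            and np.abs(new_u - u).max() < tol
            and abs(new_lam - lam) < tol
        ):
            m, u, lam = new_m, new_u, new_lam
            break
        m, u, lam = new_m, new_u, new_lam
    out = []
    for mod, mi, ui in zip(models, m, u):
        if mi <= ui:  # degenerate field: keep the configured model
            out.append(mod)
        else:
            out.append(replace(mod, m_prob=float(mi), u_prob=float(ui)))
    return out
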