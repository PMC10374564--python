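"""Three-generation pedigrees and the Longevity Relatives Count (LRC) score.

The LRC score quantifies a person's family history of longevity as the
weighted proportion of their ancestral blood relatives who belonged to the
top 10% survivors of their own sex- and birth-year-specific cohort:

    LRC_i = sum_k w_k * I(P_k >= 0.9) / sum_k w_k

where ``k`` runs over the usable ancestors of person ``i``, ``P_k`` is the
cohort survival percentile of ancestor ``k`` and the weights ``w_k`` are
relationship coefficients (0.5 for a parent, 0.25 for an aunt/uncle or
grandparent by default, i.e. expected genetic relatedness).

Index persons (IPs, generation F3) contribute two ancestral generations —
parents, aunts/uncles (children of the grandparents other than the parents)
and grandparents — while partners of IPs contribute one generation, their
own parents.  Families are defined by IP siblings who share both parents.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .lifetables import LifetableCollection, PercentileResult

__all__ = [
    "Person",
    "Pedigree",
    "AncestorRecord",
    "LRCScore",
    "LRCPolicy",
    "PedigreeError",
    "LRCUndefinedError",
    "read_pedigree",
    "identify_ancestors",
    "relationship_weight",
    "lrc_score",
    "assign_lrc_group",
    "DEFAULT_WEIGHTS",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree file (cycles, duplicates, bad links)."""


class LRCUndefinedError(ValueError):
    """No usable ancestor remains after the censoring policy; score undefined."""


class LRCPolicy(str, enum.Enum):
    """How ancestors who are not (yet) dead enter the score.

    * ``exclude_alive`` — alive ancestors are dropped from numerator and
      denominator (rule used for IPs in a questionnaire/registry cohort with
      living aunts and uncles).
    * ``impute_alive`` — alive ancestors get a single-imputation death age
      of censor age + remaining life expectancy (rule used for partners'
      parents, known only up to a last observation age).
    * ``require_extinct`` — any non-dead ancestor is an error (register
      cohorts restricted to extinct birth cohorts).
    """

    EXCLUDE_ALIVE = "exclude_alive"
    IMPUTE_ALIVE = "impute_alive"
    REQUIRE_EXTINCT = "require_extinct"


@dataclass(frozen=True)
class Person:
    id: str
    sex: str
    birth_year: int
    vital_status: str  # dead | alive | missing_age
    age: float | None = None  # death age if dead, last-observation age if alive
    father_id: str | None = None
    mother_id: str | None = None
    role: str | None = None  # IP | partner | parent | aunt_uncle | grandparent | parent_of_partner

    def __post_init__(self) -> None:
        if self.vital_status not in ("dead", "alive", "missing_age"):
            raise PedigreeError(
                f"person {self.id}: bad vital_status {self.vital_status!r}"
            )
        if self.vital_status == "dead" and self.age is None:
            raise PedigreeError(f"person {self.id}: dead but no death age")


@dataclass(frozen=True)
class AncestorRecord:
    """One ancestor's contribution to an LRC score."""

    person_id: str
    relation: str  # parent | aunt_uncle | grandparent
    weight: float
    percentile: PercentileResult | None = None
    excluded_reason: str | None = None

    @property
    def usable(self) -> bool:
        return self.excluded_reason is None and self.percentile is not None

    @property
    def top10(self) -> bool:
        return bool(self.percentile is not None and self.percentile.is_top10)


@dataclass(frozen=True)
class LRCScore:
    """LRC score with bookkeeping of which ancestors entered it."""

    value: float
    n_ancestors_used: int
    weighted_total: float
    n_excluded: int
    exclusion_reasons: tuple[str, ...] = ()
    records: tuple[AncestorRecord, ...] = ()


@dataclass
class Pedigree:
    """Person graph plus family assignment (IP sibs sharing both parents)."""

    persons: dict[str, Person] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)

    def person(self, pid: str) -> Person:
        return self.persons[pid]

    def children_of(self, father_id: str | None, mother_id: str | None) -> list[Person]:
        return [
            p
            for p in self.persons.values()
            if p.father_id == father_id and p.mother_id == mother_id
            and father_id is not None and mother_id is not None
        ]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = defaultdict(list)
        for pid, fid in self.family_of.items():
            fams[fid].append(pid)
        return dict(fams)


DEFAULT_WEIGHTS: dict[str, float] = {
    "parent": 0.5,
    "aunt_uncle": 0.25,
    "grandparent": 0.25,
}


def relationship_weight(relation: str, weights: dict[str, float] | None = None) -> float:
    """Relationship coefficient w_k for an admitted ancestral relation."""
    table = DEFAULT_WEIGHTS if weights is None else weights
    if relation not in table:
        raise PedigreeError(f"unknown ancestral relation {relation!r}")
    w = table[relation]
    if not (0.0 < w <= 1.0):
        raise PedigreeError(f"weight for {relation!r} must lie in (0, 1], got {w}")
    return w


_PEDIGREE_COLUMNS = ("id", "father_id", "mother_id", "sex", "birth_year", "vital_status", "age")


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV and build families from IPs' shared parents.

    Columns: id, father_id, mother_id, sex, birth_year, vital_status, age,
    optional role_hint.  Empty parent ids mean unknown.  Raises
    :class:`PedigreeError` on duplicate ids, self-parenting or ancestral
    cycles.
    """
    df = pd.read_csv(path, dtype={"id": str, "father_id": str, "mother_id": str})
    for col in _PEDIGREE_COLUMNS:
        if col not in df.columns:
            raise PedigreeError(f"pedigree file {path} missing column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise PedigreeError(f"duplicate person id {dup!r}")

    ped = Pedigree()
    for _, row in df.iterrows():
        fid = row["father_id"] if isinstance(row["father_id"], str) and row["father_id"] else None
        mid = row["mother_id"] if isinstance(row["mother_id"], str) and row["mother_id"] else None
        age = None if pd.isna(row["age"]) else float(row["age"])
        role = None
        if "role_hint" in df.columns and isinstance(row.get("role_hint"), str):
            role = row["role_hint"]
        p = Person(
            id=str(row["id"]),
            sex=str(row["sex"]),
            birth_year=int(row["birth_year"]),
            vital_status=str(row["vital_status"]),
            age=age,
            father_id=fid,
            mother_id=mid,
            role=role,
        )
        if p.id in (p.father_id, p.mother_id):
            raise PedigreeError(f"person {p.id} listed as their own parent")
        ped.persons[p.id] = p

    _check_acyclic(ped)
    _assign_families(ped)
    return ped


def _check_acyclic(ped: Pedigree) -> None:
    state: dict[str, int] = {}  # 0=visiting, 1=done

    def visit(pid: str) -> None:
        stack = [(pid, iter(_parents(ped, pid)))]
        state[pid] = 0
        while stack:
            cur, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in ped.persons:
                    continue
                st = state.get(nxt)
                if st == 0:
                    raise PedigreeError(f"ancestral cycle involving person {nxt!r}")
                if st is None:
                    state[nxt] = 0
                    stack.append((nxt, iter(_parents(ped, nxt))))
                    advanced = True
                    break
            if not advanced:
                state[cur] = 1
                stack.pop()

    for pid in ped.persons:
        if pid not in state:
            visit(pid)


def _parents(ped: Pedigree, pid: str) -> list[str]:
    p = ped.persons[pid]
    return [x for x in (p.father_id, p.mother_id) if x is not None]


def _assign_families(ped: Pedigree) -> None:
    """Family id per IP sibship: IPs sharing both parents get one family.

    Partners inherit the family of their IP only when explicitly linked via
    role metadata; in file-driven use the partner's family is assigned by
    the pipeline when pairing IPs and partners.  Persons without an IP role
    but with both parents shared with an IP join that IP's family.
    """
    sib_key: dict[str, tuple[str | None, str | None]] = {}
    for pid, p in ped.persons.items():
        if p.role == "IP":
            sib_key[pid] = (p.father_id, p.mother_id)
    fam_ids: dict[tuple[str | None, str | None], str] = {}
    for pid in sorted(sib_key):
        key = sib_key[pid]
        if key not in fam_ids:
            fam_ids[key] = f"fam{len(fam_ids) + 1:05d}"
        ped.family_of[pid] = fam_ids[key]


def identify_ancestors(
    ped: Pedigree, person: Person, weights: dict[str, float] | None = None
) -> list[AncestorRecord]:
    """List the ancestors whose longevity enters this person's LRC score.

    IPs: parents, aunts/uncles (other children of the grandparents) and
    grandparents — two ancestral generations.  Partners: their own parents
    only.  Missing parent links simply yield fewer ancestors; aunts/uncles
    on a side with unknown grandparents are undiscoverable.
    """
    if person.role not in ("IP", "partner"):
        raise PedigreeError(
            f"LRC ancestors are defined for IPs and partners, not role {person.role!r}"
        )
    records: list[AncestorRecord] = []

    parents = [ped.persons[pid] for pid in _parents(ped, person.id) if pid in ped.persons]
    for par in parents:
        records.append(
            AncestorRecord(par.id, "parent", relationship_weight("parent", weights))
        )
    if person.role == "partner":
        return records

    parent_ids = {p.id for p in parents}
    grandparent_ids: set[str] = set()
    for par in parents:
        gp_ids = [g for g in (par.father_id, par.mother_id) if g in ped.persons]
        for g in gp_ids:
            grandparent_ids.add(g)
        # full siblings of this parent = other children of both grandparents
        if par.father_id is not None and par.mother_id is not None:
            for sib in ped.children_of(par.father_id, par.mother_id):
                if sib.id not in parent_ids:
                    records.append(
                        AncestorRecord(
                            sib.id, "aunt_uncle", relationship_weight("aunt_uncle", weights)
                        )
                    )
    for g in sorted(grandparent_ids):
        records.append(
            AncestorRecord(g, "grandparent", relationship_weight("grandparent", weights))
        )
    return records


def _resolve_percentile(
    ped: Pedigree,
    rec: AncestorRecord,
    lifetables: LifetableCollection,
    policy: LRCPolicy,
) -> AncestorRecord:
    person = ped.persons[rec.person_id]
    if person.vital_status == "missing_age" or person.age is None:
        return AncestorRecord(rec.person_id, rec.relation, rec.weight,
                              excluded_reason="missing_age")
    lt = lifetables.get(person.sex, person.birth_year)
    if person.vital_status == "dead":
        return AncestorRecord(
            rec.person_id, rec.relation, rec.weight,
            percentile=lt.survival_percentile(person.age),
        )
    # alive at last observation
    if policy is LRCPolicy.EXCLUDE_ALIVE:
        return AncestorRecord(rec.person_id, rec.relation, rec.weight,
                              excluded_reason="alive")
    if policy is LRCPolicy.REQUIRE_EXTINCT:
        raise LRCUndefinedError(
            f"ancestor {person.id} is alive but the policy requires extinct cohorts"
        )
    imputed_age = lt.impute_death_age(person.age)
    return AncestorRecord(
        rec.person_id, rec.relation, rec.weight,
        percentile=lt.survival_percentile(imputed_age, imputed=True),
    )


def lrc_score(
    person: Person,
    ped: Pedigree,
    lifetables: LifetableCollection,
    policy: LRCPolicy | str = LRCPolicy.EXCLUDE_ALIVE,
    weights: dict[str, float] | None = None,
) -> LRCScore:
    """Compute LRC_i = sum_k w_k I(P_k >= 0.9) / sum_k w_k over usable ancestors.

    Raises :class:`LRCUndefinedError` when no usable ancestor remains after
    applying the censoring ``policy`` (the person is then dropped upstream
    with a logged reason).
    """
    policy = LRCPolicy(policy)
    stubs = identify_ancestors(ped, person, weights)
    records = [_resolve_percentile(ped, r, lifetables, policy) for r in stubs]
    usable = [r for r in records if r.usable]
    if not usable:
        raise LRCUndefinedError(
            f"person {person.id}: no usable ancestor under policy {policy.value}"
        )
    wsum = sum(r.weight for r in usable)
    num = sum(r.weight for r in usable if r.top10)
    excluded = [r for r in records if not r.usable]
    return LRCScore(
        value=num / wsum,
        n_ancestors_used=len(usable),
        weighted_total=wsum,
        n_excluded=len(excluded),
        exclusion_reasons=tuple(r.excluded_reason or "" for r in excluded),
        records=tuple(records),
    )


def assign_lrc_group(score: float, role: str) -> str:
    """Map an LRC score to the mutually exclusive analysis groups.

    IPs: ``g1`` for LRC >= 0.60, ``g2`` for 0.1 <= LRC < 0.60, ``none``
    below 0.1 (excluded and logged — in the motivating designs every IP has
    a long-lived parent, so this stratum is normally empty).  Partners:
    ``g3`` for LRC > 0, ``g4`` for LRC == 0.
    """
    if role == "IP":
        if score >= 0.60:
            return "g1"
        if score >= 0.1:
            return "g2"
        return "none"
    if role == "partner":
        return "g3" if score > 0 else "g4"
    raise PedigreeError(f"LRC groups are defined for IPs and partners, not {role!r}")
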