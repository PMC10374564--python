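"""Diagnosis and medication records into analysis-ready survival datasets.

Diseases are clustered into three categories from ICD-10 codes: metabolic,
malignant, and age-related — the latter always the union of the first two,
never mapped directly.  Three risk-set constructions are supported:

* first disease — persons disease-free at inclusion, followed to their
  first event of a category;
* two diseases — time from inclusion to the second event of a category;
  persons with exactly one event by end of follow-up are excluded (the
  censored set are the persons with zero events);
* first-to-second — persons with a first event (possibly before inclusion)
  enter at that event's age and are followed to the next event of the
  target category.

Medication use is reduced to per-person indicators for ATC classes A
(alimentary tract/metabolism), B (blood), and C (cardiovascular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DiseaseEvent",
    "CategoryMap",
    "SurvivalRecord",
    "BuilderResult",
    "classify_disease",
    "build_first_disease_records",
    "build_two_disease_records",
    "build_first_to_second_records",
    "build_medication_records",
    "read_events",
    "DEFAULT_CATEGORY_MAP",
    "EPS_TIE",
    "EventError",
]

#: tie offset when a second event carries the same recorded age as the first
EPS_TIE = 1.0 / 365.25

CATEGORIES = ("metabolic", "malignant", "age_related")


class EventError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseEvent:
    person_id: str
    icd10: str
    age: float

    def __post_init__(self) -> None:
        if not self.icd10:
            raise EventError(f"person {self.person_id}: empty ICD-10 code")
        if self.age < 0:
            raise EventError(f"person {self.person_id}: negative diagnosis age")


class CategoryMap:
    """Ordered ICD-10 prefix patterns -> {metabolic, malignant}.

    Classification is by longest matching prefix; unmatched codes return
    ``None``.  ``age_related`` is the union of the two base categories and
    is never a direct target.
    """

    def __init__(self, entries: list[tuple[str, str]]):
        if not entries:
            raise EventError("category map must not be empty")
        for prefix, cat in entries:
            if cat not in ("metabolic", "malignant"):
                raise EventError(
                    f"category map targets must be metabolic/malignant, got {cat!r} "
                    "(age_related is the union and never mapped directly)"
                )
        self.entries = list(entries)

    def classify(self, icd10: str) -> str | None:
        code = icd10.strip().upper()
        best: tuple[int, str] | None = None
        for prefix, cat in self.entries:
            if code.startswith(prefix) and (best is None or len(prefix) > best[0]):
                best = (len(prefix), cat)
        return best[1] if best else None

    def matches(self, icd10: str, category: str) -> bool:
        cat = self.classify(icd10)
        if category == "age_related":
            return cat is not None
        return cat == category

    @classmethod
    def from_yaml(cls, path) -> "CategoryMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([(str(e["prefix"]), str(e["category"])) for e in raw])


def _chapter_range(letter: str, lo: int, hi: int, category: str) -> list[tuple[str, str]]:
    return [(f"{letter}{i:02d}", category) for i in range(lo, hi + 1)]


#: Approximate default grouping: malignant = C00–C97 and in-situ/benign
#: neoplasm block D00–D48; metabolic = endocrine/metabolic chapter E plus
#: circulatory chapter I, pairing with ATC-A/B/C medication classes.
DEFAULT_CATEGORY_MAP = CategoryMap(
    _chapter_range("C", 0, 97, "malignant")
    + _chapter_range("D", 0, 48, "malignant")
    + _chapter_range("E", 0, 90, "metabolic")
    + _chapter_range("I", 0, 99, "metabolic")
)


def classify_disease(event: DiseaseEvent, cmap: CategoryMap = DEFAULT_CATEGORY_MAP) -> str | None:
    """Category of one diagnosis (or None if outside the configured map)."""
    return cmap.classify(event.icd10)


@dataclass(frozen=True)
class SurvivalRecord:
    """(entry, exit, event) triple — the unit of every survival fit."""

    person_id: str
    family_id: str
    entry_age: float
    exit_age: float
    event: int
    covariates: dict = field(default_factory=dict)
    analysis_tag: str = ""

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise EventError(
                f"person {self.person_id}: entry_age {self.entry_age} must be "
                f"< exit_age {self.exit_age}"
            )
        if self.event not in (0, 1):
            raise EventError(f"person {self.person_id}: event must be 0/1")


@dataclass
class BuilderResult:
    """Survival records plus conservation bookkeeping (excluded + retained = input)."""

    records: list[SurvivalRecord]
    n_input: int
    exclusions: dict[str, int]

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def read_events(path) -> list[DiseaseEvent]:
    """Events CSV with columns person_id, icd10, age."""
    df = pd.read_csv(path, dtype={"person_id": str, "icd10": str})
    return [
        DiseaseEvent(str(r.person_id), str(r.icd10), float(r.age))
        for r in df.itertuples()
    ]


def _events_by_person(
    events: list[DiseaseEvent], cmap: CategoryMap, category: str
) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for ev in events:
        if cmap.matches(ev.icd10, category):
            out.setdefault(ev.person_id, []).append(ev.age)
    for ages in out.values():
        ages.sort()
    return out


def diagnosis_age_from_year(diag_year: int, birth_year: int) -> float:
    """Mid-year convention when only the diagnosis year is recorded."""
    return (diag_year - birth_year) + 0.5


def build_first_disease_records(
    events: list[DiseaseEvent],
    persons: pd.DataFrame,
    category: str,
    cmap: CategoryMap = DEFAULT_CATEGORY_MAP,
    analysis_tag: str = "first_disease",
) -> BuilderResult:
    """Time from inclusion to first event of ``category``.

    ``persons`` needs columns person_id, family_id, inclusion_age,
    censor_age plus any covariate columns; extra columns are carried into
    the record's covariates.  Persons with any categorized (age-related)
    disease at or before inclusion are excluded — the analysis starts from
    a disease-free state.
    """
    any_cat = _events_by_person(events, cmap, "age_related")
    target = _events_by_person(events, cmap, category)
    records: list[SurvivalRecord] = []
    exclusions: dict[str, int] = {"diseased_at_inclusion": 0, "missing_inclusion_age": 0,
                                  "no_followup": 0}
    for row in persons.itertuples():
        pid = str(row.person_id)
        if pd.isna(row.inclusion_age):
            exclusions["missing_inclusion_age"] += 1
            continue
        entry = float(row.inclusion_age)
        if any(a <= entry for a in any_cat.get(pid, [])):
            exclusions["diseased_at_inclusion"] += 1
            continue
        post = [a for a in target.get(pid, []) if a > entry]
        if post:
            exit_age, event = post[0], 1
        else:
            exit_age, event = float(row.censor_age), 0
        if not entry < exit_age:
            exclusions["no_followup"] += 1
            continue
        records.append(_make_record(row, pid, entry, exit_age, event, analysis_tag))
    return BuilderResult(records, len(persons), exclusions)


def build_two_disease_records(
    events: list[DiseaseEvent],
    persons: pd.DataFrame,
    category: str,
    cmap: CategoryMap = DEFAULT_CATEGORY_MAP,
    analysis_tag: str = "two_diseases",
) -> BuilderResult:
    """Time from inclusion to the second event of ``category``.

    The censored set are persons with zero categorized events by end of
    follow-up; persons with exactly one event are excluded outright, so the
    risk set is smaller than in the first-disease analysis.
    """
    any_cat = _events_by_person(events, cmap, "age_related")
    target = _events_by_person(events, cmap, category)
    records: list[SurvivalRecord] = []
    exclusions: dict[str, int] = {"diseased_at_inclusion": 0, "missing_inclusion_age": 0,
                                  "one_disease_only": 0, "no_followup": 0}
    for row in persons.itertuples():
        pid = str(row.person_id)
        if pd.isna(row.inclusion_age):
            exclusions["missing_inclusion_age"] += 1
            continue
        entry = float(row.inclusion_age)
        if any(a <= entry for a in any_cat.get(pid, [])):
            exclusions["diseased_at_inclusion"] += 1
            continue
        post = [a for a in target.get(pid, []) if a > entry]
        if len(post) >= 2:
            exit_age, event = post[1], 1
            if exit_age <= post[0]:
                exit_age = post[0] + EPS_TIE
        elif len(post) == 1:
            exclusions["one_disease_only"] += 1
            continue
        else:
            exit_age, event = float(row.censor_age), 0
        if not entry < exit_age:
            exclusions["no_followup"] += 1
            continue
        records.append(_make_record(row, pid, entry, exit_age, event, analysis_tag))
    return BuilderResult(records, len(persons), exclusions)


def build_first_to_second_records(
    events: list[DiseaseEvent],
    persons: pd.DataFrame,
    first_category: str,
    second_category: str,
    cmap: CategoryMap = DEFAULT_CATEGORY_MAP,
    analysis_tag: str = "first_to_second",
) -> BuilderResult:
    """Time from first event of ``first_category`` to first subsequent event
    of ``second_category``.

    Entry is the first event's age, which may pre-date study inclusion (one
    disease before the start of follow-up is allowed here).  A second event
    recorded at the same age as the first is shifted forward by one day to
    preserve entry < exit.
    """
    by_person: dict[str, list[DiseaseEvent]] = {}
    for ev in events:
        by_person.setdefault(ev.person_id, []).append(ev)
    for evs in by_person.values():
        evs.sort(key=lambda e: e.age)

    records: list[SurvivalRecord] = []
    exclusions: dict[str, int] = {"no_first_disease": 0, "no_followup": 0}
    for row in persons.itertuples():
        pid = str(row.person_id)
        evs = by_person.get(pid, [])
        firsts = [e for e in evs if cmap.matches(e.icd10, first_category)]
        if not firsts:
            exclusions["no_first_disease"] += 1
            continue
        index_event = firsts[0]
        entry = index_event.age
        # a *distinct* diagnosis of the target category at or after entry;
        # same-age ties are pushed forward one day to keep entry < exit
        later = [
            e for e in evs
            if e is not index_event and cmap.matches(e.icd10, second_category)
            and e.age >= entry
        ]
        if later:
            exit_age, event = max(later[0].age, entry + EPS_TIE), 1
        else:
            exit_age, event = float(row.censor_age), 0
        if not entry < exit_age:
            exclusions["no_followup"] += 1
            continue
        records.append(_make_record(row, pid, entry, exit_age, event, analysis_tag))
    return BuilderResult(records, len(persons), exclusions)


_META_COLS = {"person_id", "family_id", "inclusion_age", "censor_age", "Index"}


def _make_record(row, pid: str, entry: float, exit_age: float, event: int,
                 tag: str) -> SurvivalRecord:
    cov = {k: v for k, v in row._asdict().items() if k not in _META_COLS}
    return SurvivalRecord(
        person_id=pid,
        family_id=str(row.family_id),
        entry_age=entry,
        exit_age=exit_age,
        event=event,
        covariates=cov,
        analysis_tag=tag,
    )


ATC_CLASSES = ("A", "B", "C")


def build_medication_records(med_table: pd.DataFrame, roster: list[str]) -> pd.DataFrame:
    """Per-person ATC class-A/B/C use indicators.

    ``med_table`` has columns person_id, atc_code.  ``roster`` lists the
    persons for whom medication data was collected: a roster member with no
    rows gets all-false indicators, a person absent from the roster yields
    no record at all (missing, not false).  Malformed ATC codes are skipped
    with a warning.
    """
    use: dict[str, set[str]] = {pid: set() for pid in roster}
    for r in med_table.itertuples():
        pid = str(r.person_id)
        code = str(r.atc_code).strip().upper()
        if not code or not code[0].isalpha():
            warnings.warn(f"skipping malformed ATC code {r.atc_code!r} for {pid}")
            continue
        if pid in use and code[0] in ATC_CLASSES:
            use[pid].add(code[0])
    rows = [
        {"person_id": pid, **{f"atc_{c.lower()}": int(c in use[pid]) for c in ATC_CLASSES}}
        for pid in roster
    ]
    return pd.DataFrame(rows, columns=["person_id", "atc_a", "atc_b", "atc_c"])
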