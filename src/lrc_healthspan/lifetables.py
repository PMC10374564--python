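"""Cohort lifetables: hazards, cumulative hazards, survival percentiles.

A cohort lifetable gives, for one birth year and one sex, the yearly hazard
of dying between ages ``x`` and ``x+1`` (``h_x``) for integer ages
``x = 0..omega``.  From these hazards we derive the cumulative hazard
``H(x)``, the survival function ``S(x) = exp(-H(x))``, birth-cohort/sex
specific survival percentiles, remaining life expectancy ``e_x``, and single
imputation of death ages for right-censored relatives.

The percentile convention is the fraction of the birth cohort dead before
the attained age, ``P = 1 - S(age)``; "top 10% survivor" means ``P >= 0.9``.

CSV interchange format: columns ``cohort_year`` (int), ``sex`` ({F, M}),
``age`` (int, contiguous from 0), ``hazard`` (per year).  Tables published
as yearly death probabilities ``q_x`` (HMD style) convert via
``h = -log(1 - q)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortLifetable",
    "LifetableCollection",
    "PercentileResult",
    "read_lifetables",
    "write_lifetables",
    "cumulative_hazard",
    "survival_percentile",
    "remaining_life_expectancy",
    "impute_death_age",
    "LifetableError",
]

#: hard cap for constant-hazard extrapolation beyond the last tabulated age
MAX_AGE = 120.0

TOP10_THRESHOLD = 0.9


class LifetableError(ValueError):
    """Raised for malformed lifetable input or out-of-domain queries."""


@dataclass(frozen=True)
class PercentileResult:
    """Survival percentile of one person within their birth cohort.

    ``percentile`` is the fraction of the cohort dead before ``age_used``;
    ``is_top10`` marks membership of the top 10% survivors (P >= 0.9).
    ``imputed`` is set when ``age_used`` came from single imputation rather
    than an observed death age.
    """

    percentile: float
    is_top10: bool
    age_used: float
    imputed: bool = False


@dataclass(frozen=True)
class CohortLifetable:
    """Yearly mortality hazards for one sex and birth year."""

    sex: str
    birth_year: int
    hazards: np.ndarray
    source_tag: str = "observed"

    def __post_init__(self) -> None:
        h = np.asarray(self.hazards, dtype=float)
        if h.ndim != 1 or h.size == 0:
            raise LifetableError("hazard sequence must be a non-empty 1-D array")
        if np.any(h < 0) or not np.all(np.isfinite(h)):
            raise LifetableError(
                f"negative or non-finite hazard in table ({self.sex}, {self.birth_year})"
            )
        if self.sex not in ("F", "M"):
            raise LifetableError(f"sex must be 'F' or 'M', got {self.sex!r}")
        object.__setattr__(self, "hazards", h)

    @property
    def omega(self) -> int:
        """Last tabulated integer age."""
        return self.hazards.size - 1

    def cumulative_hazard(self, age: float) -> float:
        """H(age) under piecewise-constant yearly hazards.

        For fractional ages H is interpolated linearly within the year.
        Beyond the last tabulated age the final hazard is held constant up
        to ``MAX_AGE``.
        """
        if age < 0:
            raise LifetableError(f"age must be non-negative, got {age}")
        age = min(float(age), MAX_AGE)
        h = self.hazards
        cum = np.concatenate(([0.0], np.cumsum(h)))
        if age <= self.omega + 1:
            k = int(math.floor(age))
            if k == self.omega + 1:  # age exactly omega+1
                return float(cum[-1])
            return float(cum[k] + (age - k) * h[k])
        # constant-hazard continuation with h_omega
        return float(cum[-1] + (age - (self.omega + 1)) * h[-1])

    def survival(self, age: float) -> float:
        """S(age) = exp(-H(age))."""
        return math.exp(-self.cumulative_hazard(age))

    def survival_percentile(
        self, age_at_death: float, *, imputed: bool = False
    ) -> PercentileResult:
        """Cohort survival percentile P = 1 - S(age_at_death).

        A person with P >= 0.9 outlived at least 90% of their sex- and
        birth-year-specific cohort and counts as a top-10% survivor.
        """
        p = 1.0 - self.survival(age_at_death)
        return PercentileResult(
            percentile=p,
            is_top10=p >= TOP10_THRESHOLD,
            age_used=float(age_at_death),
            imputed=imputed,
        )

    def _cumhaz_uncapped(self, age: float) -> float:
        """H(age) with constant-hazard continuation and no age cap (internal,
        used so that life-expectancy tails are exact geometric sums)."""
        h = self.hazards
        cum = np.concatenate(([0.0], np.cumsum(h)))
        if age <= self.omega + 1:
            k = int(math.floor(age))
            if k == self.omega + 1:
                return float(cum[-1])
            return float(cum[k] + (age - k) * h[k])
        return float(cum[-1] + (age - (self.omega + 1)) * h[-1])

    def remaining_life_expectancy(self, x: float, *, half_correction: float = 0.5) -> float:
        """Expected additional years of life given survival to age ``x``.

        Discrete sum e_x = sum_{k>=1} S(x+k)/S(x) + 0.5, the half-year term
        being the usual continuity correction for deaths occurring mid
        interval.  Within the table the sum is evaluated term by term; the
        tail beyond the last tabulated age is a geometric series under the
        constant-hazard closure and is summed in closed form, so constant
        hazard tables reproduce e_x = e^{-h}/(1 - e^{-h}) + 1/2 exactly.
        """
        sx = math.exp(-self._cumhaz_uncapped(x))
        if sx <= 0.0:
            raise LifetableError(f"S({x}) = 0; remaining life expectancy undefined")
        h_last = float(self.hazards[-1])
        k0 = max(0, int(math.floor(self.omega + 1 - x)))
        total = 0.0
        for k in range(1, k0 + 1):
            total += math.exp(-self._cumhaz_uncapped(x + k))
        # geometric tail: S(x + k0 + j) = S(x + k0) * q^j with q = e^{-h_omega}
        if h_last <= 0.0:
            raise LifetableError(
                "terminal hazard is zero; remaining life expectancy diverges"
            )
        q = math.exp(-h_last)
        s_edge = math.exp(-self._cumhaz_uncapped(x + k0))
        total += s_edge * q / (1.0 - q)
        return total / sx + half_correction

    def impute_death_age(self, censor_age: float) -> float:
        """Single-imputation death age for a person alive at ``censor_age``.

        Returns censor_age + remaining life expectancy at that age; results
        derived from it must be flagged imputed downstream.
        """
        if censor_age < 0:
            raise LifetableError(f"censor age must be non-negative, got {censor_age}")
        return censor_age + self.remaining_life_expectancy(censor_age)


@dataclass
class LifetableCollection:
    """Map (sex, birth_year) -> CohortLifetable with strict lookup."""

    tables: dict[tuple[str, int], CohortLifetable] = field(default_factory=dict)

    def add(self, table: CohortLifetable) -> None:
        self.tables[(table.sex, table.birth_year)] = table

    def get(self, sex: str, birth_year: int) -> CohortLifetable:
        key = (sex, int(birth_year))
        if key not in self.tables:
            raise LifetableError(
                f"no lifetable for sex={sex!r}, birth_year={birth_year}; "
                "missing cohorts are an error, not a fallback"
            )
        return self.tables[key]

    def __len__(self) -> int:
        return len(self.tables)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.tables


_REQUIRED_COLUMNS = ("cohort_year", "sex", "age", "hazard")


def read_lifetables(path) -> LifetableCollection:
    """Read a lifetable CSV into a :class:`LifetableCollection`.

    The file must have columns cohort_year, sex, age, hazard with ages per
    (sex, cohort) contiguous from 0 and all hazards non-negative.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise LifetableError(f"lifetable file {path} missing column {col!r}")
    bad = df.index[df["hazard"] < 0]
    if len(bad):
        row = df.loc[bad[0]]
        raise LifetableError(
            f"negative hazard at row {bad[0]} "
            f"(cohort_year={row['cohort_year']}, sex={row['sex']}, age={row['age']})"
        )
    coll = LifetableCollection()
    for (sex, year), grp in df.groupby(["sex", "cohort_year"], sort=True):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if not np.array_equal(ages, np.arange(len(ages))):
            raise LifetableError(
                f"ages for cohort_year={year}, sex={sex} are not contiguous from 0"
            )
        coll.add(
            CohortLifetable(
                sex=str(sex), birth_year=int(year), hazards=grp["hazard"].to_numpy()
            )
        )
    return coll


def cumulative_hazard(lt: CohortLifetable, age: float) -> float:
    """Functional alias for :meth:`CohortLifetable.cumulative_hazard`."""
    return lt.cumulative_hazard(age)


def survival_percentile(
    lt: CohortLifetable, age_at_death: float, *, imputed: bool = False
) -> PercentileResult:
    """Functional alias for :meth:`CohortLifetable.survival_percentile`."""
    return lt.survival_percentile(age_at_death, imputed=imputed)


def remaining_life_expectancy(lt: CohortLifetable, x: float) -> float:
    """Functional alias for :meth:`CohortLifetable.remaining_life_expectancy`."""
    return lt.remaining_life_expectancy(x)


def impute_death_age(lt: CohortLifetable, censor_age: float) -> float:
    """Functional alias for :meth:`CohortLifetable.impute_death_age`."""
    return lt.impute_death_age(censor_age)


def write_lifetables(coll: LifetableCollection, path) -> None:
    """Write a collection back to the CSV interchange format."""
    rows = []
    for (sex, year) in sorted(coll.tables):
        lt = coll.tables[(sex, year)]
        for age, h in enumerate(lt.hazards):
            rows.append((year, sex, age, h))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)
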