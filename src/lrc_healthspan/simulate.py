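"""Synthetic three-generation cohorts with known ground truth.

The generator emulates the structure the analysis assumes: families of
four grandparents (F1), a parental sibship on each side (F2: parents plus
aunts/uncles), a sibship of index persons (F3 IPs) and, in the
questionnaire-style design, a partner per IP with two own parents.
Lifespans are drawn from Gompertz–Makeham cohort hazards multiplied by a
gamma family frailty (familial clustering of lifespan); disease onsets are
drawn from Weibull baselines with a log-hazard coefficient ``beta_d`` on
the person's own computed LRC score plus a shared family disease frailty,
so the injected effect size has a defined truth value that the pipeline
should recover.  Medication indicators follow a random-intercept logistic
model and the continuous health score a random-intercept linear model
with group shifts.

Everything is deterministic under the master seed: sub-streams are drawn
from ``numpy.random.SeedSequence(master_seed, spawn_key=(k,))`` with a
fixed stream index per purpose, so adding a stream never perturbs others.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetables import CohortLifetable, LifetableCollection, write_lifetables
from .pedigree import LRCPolicy, LRCUndefinedError, Pedigree, Person, lrc_score

__all__ = ["SimulationConfig", "SyntheticCohort", "gen_lifetable", "gen_pedigree",
           "gen_health_histories", "generate_cohort", "draw_death_age"]

_STREAMS = {
    "pedigree": 1,
    "mortality": 2,
    "disease": 3,
    "medication": 4,
    "score": 5,
    "missing": 6,
}


@dataclass
class SimulationConfig:
    """Generating parameters; defaults emulate a questionnaire-style
    (LLS-like) three-generation longevity cohort."""

    n_families: int = 200
    style: str = "lls"  # lls | sedd
    # sibship sizes (1 + Poisson(mean - 1))
    f3_sibship_mean: float = 2.58
    f2_sibship_mean: float = 2.8
    partner_fraction: float = 0.45
    # Gompertz-Makeham h(x) = a exp(bx) + c per sex, with cohort drift on a
    gompertz_a_female: float = 7e-5
    gompertz_a_male: float = 1.1e-4
    gompertz_b: float = 0.092
    makeham_c: float = 1.5e-3
    cohort_drift: float = 0.004  # relative decline of a per birth year
    drift_reference_year: int = 1900
    # familial mortality frailty (gamma, mean 1)
    theta_m: float = 0.2
    # disease model: per-category Weibull (shape, scale in years)
    weibull_metabolic: tuple[float, float] = (6.0, 82.0)
    weibull_malignant: tuple[float, float] = (6.5, 96.0)
    second_gap_weibull: tuple[float, float] = (1.4, 9.0)
    beta_d: float = math.log(0.6)  # log-HR per unit LRC on disease hazards
    theta_d: float = 0.2  # family disease frailty variance (gamma, mean 1)
    # study timeline
    inclusion_year: int = 2002
    inclusion_age_window: tuple[float, float] = (55.0, 65.0)
    morbidity_followup_years: float = 16.0
    mortality_end_year: int = 2021
    # birth-cohort windows (inclusive) per generation
    f1_birth_years: tuple[int, int] = (1870, 1894)
    f2_birth_years: tuple[int, int] = (1900, 1925)
    missing_age_fraction: float = 0.02
    # medication model: logit p = g0[class] + g1 * LRC + u_i, u_i ~ N(0, s^2)
    med_intercepts: dict = field(
        default_factory=lambda: {"A": -1.4, "B": -2.2, "C": -0.7}
    )
    med_lrc_coef: float = -0.6
    med_sigma: float = 0.5
    # health score: mu + delta_g[group] + N(0, sf) family + N(0, se) residual
    score_mu: float = 0.0
    score_delta: dict = field(
        default_factory=lambda: {"g1": -0.098, "g2": -0.032, "g3": -0.016,
                                 "g4": 0.0, "none": 0.0}
    )
    score_sigma_family: float = 0.10
    score_sigma_resid: float = 0.25
    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.Generator(np.random.PCG64(ss))

    def for_sedd(self) -> "SimulationConfig":
        """Register-style variant: IPs only, extinct ancestral cohorts."""
        cfg = SimulationConfig(**asdict(self))
        cfg.style = "sedd"
        cfg.partner_fraction = 0.0
        cfg.f3_sibship_mean = 1.67
        cfg.f1_birth_years = (1845, 1870)
        cfg.f2_birth_years = (1875, 1905)
        cfg.inclusion_year = 1990
        cfg.morbidity_followup_years = 26.0
        cfg.mortality_end_year = 2015
        cfg.missing_age_fraction = 0.0
        return cfg


def gen_lifetable(
    a: float, b: float, c: float, sex: str, cohort_year: int, omega: int = 99
) -> CohortLifetable:
    """Gompertz–Makeham cohort lifetable h_x = a e^{bx} + c, x = 0..omega."""
    if a < 0 or c < 0:
        raise ValueError("Gompertz a and Makeham c must be non-negative")
    x = np.arange(omega + 1)
    h = a * np.exp(b * x) + c
    if np.any(h <= 0):
        raise ValueError("parameters yield non-positive hazards")
    return CohortLifetable(sex=sex, birth_year=cohort_year, hazards=h,
                           source_tag="synthetic")


def _cohort_params(cfg: SimulationConfig, sex: str, year: int) -> tuple[float, float, float]:
    a0 = cfg.gompertz_a_female if sex == "F" else cfg.gompertz_a_male
    a = a0 * math.exp(-cfg.cohort_drift * (year - cfg.drift_reference_year))
    return a, cfg.gompertz_b, cfg.makeham_c


def draw_death_age(
    lt: CohortLifetable,
    frailty: float,
    rng: np.random.Generator,
    min_age: float = 0.0,
) -> float:
    """Inverse-CDF draw of a death age under hazard ``frailty * h_x``.

    ``min_age`` conditions the draw on survival to that age (used for study
    participants, who by design were alive at inclusion).
    """
    target = lt._cumhaz_uncapped(min_age) + rng.exponential() / frailty
    h = lt.hazards
    cum = np.concatenate(([0.0], np.cumsum(h)))
    if target >= cum[-1]:
        # constant-hazard continuation beyond the table, capped at 120
        extra = (target - cum[-1]) / h[-1]
        return min(float(lt.omega + 1 + extra), 120.0)
    k = int(np.searchsorted(cum, target, side="right") - 1)
    return k + (target - cum[k]) / h[k]


class _PersonFactory:
    def __init__(self):
        self.rows: list[dict] = []
        self.counter = 0

    def add(self, *, sex, birth_year, role, father_id=None, mother_id=None) -> str:
        self.counter += 1
        pid = f"p{self.counter:06d}"
        self.rows.append(
            dict(id=pid, father_id=father_id, mother_id=mother_id, sex=sex,
                 birth_year=int(birth_year), role_hint=role)
        )
        return pid


def gen_pedigree(cfg: SimulationConfig):
    """Generate families, lifespans and lifetables.

    Returns (pedigree_df, lifetables, meta_df) where meta_df carries the
    per-person family id, analysis family id and mortality frailty.
    """
    rng = cfg.rng("pedigree")
    mrng = cfg.rng("mortality")
    miss_rng = cfg.rng("missing")
    fac = _PersonFactory()
    meta: list[dict] = []

    def sib_n(mean: float) -> int:
        return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))

    years_needed: set[tuple[str, int]] = set()
    draft: list[dict] = []

    for fi in range(cfg.n_families):
        fam_id = f"fam{fi + 1:05d}"
        frailty_blood = mrng.gamma(1.0 / cfg.theta_m, cfg.theta_m) if cfg.theta_m > 0 else 1.0

        def birth(lo_hi):
            return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

        # F1 grandparents: paternal and maternal couples
        gps = {}
        for side in ("pat", "mat"):
            gf = fac.add(sex="M", birth_year=birth(cfg.f1_birth_years), role="grandparent")
            gm = fac.add(sex="F", birth_year=birth(cfg.f1_birth_years), role="grandparent")
            gps[side] = (gf, gm)
            for pid in (gf, gm):
                draft.append(dict(pid=pid, fam=fam_id, frailty=frailty_blood, f3=False))

        # F2 sibships: first child is the parent, the rest aunts/uncles
        parents = {}
        for side in ("pat", "mat"):
            gf, gm = gps[side]
            n = sib_n(cfg.f2_sibship_mean)
            for j in range(n):
                sex = "M" if (side == "pat" and j == 0) else (
                    "F" if (side == "mat" and j == 0) else ("M" if rng.random() < 0.5 else "F")
                )
                role = "parent" if j == 0 else "aunt_uncle"
                pid = fac.add(sex=sex, birth_year=birth(cfg.f2_birth_years), role=role,
                              father_id=gf, mother_id=gm)
                if j == 0:
                    parents[side] = pid
                draft.append(dict(pid=pid, fam=fam_id, frailty=frailty_blood, f3=False))

        # F3 IPs; birth year back-computed from the inclusion-age window
        n_ips = sib_n(cfg.f3_sibship_mean)
        for j in range(n_ips):
            incl_age = rng.uniform(*cfg.inclusion_age_window)
            by = int(cfg.inclusion_year - incl_age)
            sex = "M" if rng.random() < 0.5 else "F"
            pid = fac.add(sex=sex, birth_year=by, role="IP",
                          father_id=parents["pat"], mother_id=parents["mat"])
            draft.append(dict(pid=pid, fam=fam_id, frailty=frailty_blood, f3=True,
                              inclusion_age=incl_age))
            # partner household: own frailty, own parents, same analysis family
            if rng.random() < cfg.partner_fraction:
                frailty_part = (
                    mrng.gamma(1.0 / cfg.theta_m, cfg.theta_m) if cfg.theta_m > 0 else 1.0
                )
                pf = fac.add(sex="M", birth_year=birth(cfg.f2_birth_years),
                             role="parent_of_partner")
                pm = fac.add(sex="F", birth_year=birth(cfg.f2_birth_years),
                             role="parent_of_partner")
                psex = "F" if sex == "M" else "M"
                p_incl = rng.uniform(*cfg.inclusion_age_window)
                ppid = fac.add(sex=psex, birth_year=int(cfg.inclusion_year - p_incl),
                               role="partner", father_id=pf, mother_id=pm)
                for q in (pf, pm):
                    draft.append(dict(pid=q, fam=fam_id, frailty=frailty_part, f3=False))
                draft.append(dict(pid=ppid, fam=fam_id, frailty=frailty_part, f3=True,
                                  inclusion_age=p_incl))

    ped_df = pd.DataFrame(fac.rows)
    by_pid = {r["id"]: r for r in fac.rows}
    for d in draft:
        years_needed.add((by_pid[d["pid"]]["sex"], by_pid[d["pid"]]["birth_year"]))

    lts = LifetableCollection()
    for sex, year in sorted(years_needed):
        a, b, c = _cohort_params(cfg, sex, year)
        lts.add(gen_lifetable(a, b, c, sex, year))

    # lifespans: ancestors censored at the mortality end year, F3 likewise
    ages, statuses = {}, {}
    for d in draft:
        row = by_pid[d["pid"]]
        lt = lts.get(row["sex"], row["birth_year"])
        # F3 study participants are alive at inclusion by design
        min_age = d.get("inclusion_age", 0.0) if d["f3"] else 0.0
        death_age = draw_death_age(lt, d["frailty"], mrng, min_age=min_age)
        censor_age = cfg.mortality_end_year - row["birth_year"]
        if death_age <= censor_age:
            ages[d["pid"]], statuses[d["pid"]] = death_age, "dead"
        else:
            ages[d["pid"]], statuses[d["pid"]] = float(censor_age), "alive"
        if (
            cfg.missing_age_fraction > 0
            and row["role_hint"] in ("parent", "aunt_uncle", "grandparent",
                                     "parent_of_partner")
            and miss_rng.random() < cfg.missing_age_fraction
        ):
            ages[d["pid"]], statuses[d["pid"]] = np.nan, "missing_age"

    ped_df["vital_status"] = [statuses[p] for p in ped_df["id"]]
    ped_df["age"] = [ages[p] for p in ped_df["id"]]

    meta = pd.DataFrame(
        [
            dict(
                person_id=d["pid"],
                family_id=d["fam"],
                mortality_frailty=d["frailty"],
                is_f3=d["f3"],
                inclusion_age=d.get("inclusion_age", np.nan),
            )
            for d in draft
        ]
    )
    return ped_df, lts, meta


def pedigree_from_frame(ped_df: pd.DataFrame) -> Pedigree:
    """In-memory equivalent of reading the pedigree CSV."""
    ped = Pedigree()
    for r in ped_df.itertuples():
        age = None if (isinstance(r.age, float) and math.isnan(r.age)) else float(r.age)
        ped.persons[r.id] = Person(
            id=r.id,
            sex=r.sex,
            birth_year=int(r.birth_year),
            vital_status=r.vital_status,
            age=age,
            father_id=r.father_id if isinstance(r.father_id, str) else None,
            mother_id=r.mother_id if isinstance(r.mother_id, str) else None,
            role=r.role_hint,
        )
    return ped


_ICD_CODES = {"metabolic": ("E11", "I10", "I25", "E78"),
              "malignant": ("C50", "C61", "C18", "C34")}


def gen_health_histories(
    cfg: SimulationConfig,
    ped_df: pd.DataFrame,
    meta: pd.DataFrame,
    scores: dict[str, float],
    groups: dict[str, str],
):
    """Events, medication and health scores for the F3 generation.

    Disease onsets per base category follow a Weibull baseline with
    multiplier ``exp(beta_d * LRC + log v_i)``; ``v_i`` is a gamma family
    disease frailty shared within the analysis family.  Events are kept
    while they occur before the morbidity censoring age, which is the
    earlier of death and end of follow-up.
    """
    rng = cfg.rng("disease")
    med_rng = cfg.rng("medication")
    score_rng = cfg.rng("score")

    fam_ids = sorted(meta["family_id"].unique())
    v_fam = {
        f: (rng.gamma(1.0 / cfg.theta_d, cfg.theta_d) if cfg.theta_d > 0 else 1.0)
        for f in fam_ids
    }
    med_u = {f: med_rng.normal(0.0, cfg.med_sigma) for f in fam_ids}
    score_u = {f: score_rng.normal(0.0, cfg.score_sigma_family) for f in fam_ids}

    f3 = meta[meta["is_f3"]].merge(
        ped_df[["id", "sex", "birth_year"]], left_on="person_id", right_on="id"
    )
    ages = dict(zip(ped_df["id"], ped_df["age"]))

    ev_rows, med_rows, score_rows = [], [], []
    for r in f3.itertuples():
        pid = r.person_id
        if pid not in scores:
            continue
        lrc = scores[pid]
        mult = math.exp(cfg.beta_d * lrc) * v_fam[r.family_id]
        censor_age = min(
            float(ages[pid]), r.inclusion_age + cfg.morbidity_followup_years
        )
        for cat, (shape, scale) in (
            ("metabolic", cfg.weibull_metabolic),
            ("malignant", cfg.weibull_malignant),
        ):
            t1 = scale * (rng.exponential() / mult) ** (1.0 / shape)
            if t1 < censor_age:
                code = _ICD_CODES[cat][int(rng.integers(len(_ICD_CODES[cat])))]
                ev_rows.append(dict(person_id=pid, icd10=code, age=round(t1, 3)))
                gshape, gscale = cfg.second_gap_weibull
                gap = gscale * (rng.exponential() / mult) ** (1.0 / gshape)
                t2 = t1 + max(gap, 1.0 / 365.25)
                if t2 < censor_age:
                    code2 = _ICD_CODES[cat][int(rng.integers(len(_ICD_CODES[cat])))]
                    ev_rows.append(dict(person_id=pid, icd10=code2, age=round(t2, 3)))

        for klass, g0 in sorted(cfg.med_intercepts.items()):
            eta = g0 + cfg.med_lrc_coef * lrc + med_u[r.family_id]
            if med_rng.random() < 1.0 / (1.0 + math.exp(-eta)):
                med_rows.append(dict(person_id=pid, atc_code=f"{klass}10AB01"))

        g = groups.get(pid, "none")
        score_rows.append(
            dict(
                person_id=pid,
                score=cfg.score_mu
                + cfg.score_delta.get(g, 0.0)
                + score_u[r.family_id]
                + score_rng.normal(0.0, cfg.score_sigma_resid),
            )
        )

    events = pd.DataFrame(ev_rows, columns=["person_id", "icd10", "age"])
    meds = pd.DataFrame(med_rows, columns=["person_id", "atc_code"])
    score_df = pd.DataFrame(score_rows, columns=["person_id", "score"])
    return events, meds, score_df


@dataclass
class SyntheticCohort:
    """Generated cohort: frames, lifetables, computed scores and the truth."""

    pedigree: pd.DataFrame
    lifetables: LifetableCollection
    meta: pd.DataFrame
    events: pd.DataFrame
    medication: pd.DataFrame
    scores_df: pd.DataFrame
    lrc: dict[str, float]
    groups: dict[str, str]
    truth: dict

    def persons_table(self) -> pd.DataFrame:
        """Analysis roster for the survival-record builders."""
        ped = self.pedigree.set_index("id")
        rows = []
        cfg_follow = self.truth["config"]["morbidity_followup_years"]
        for r in self.meta[self.meta["is_f3"]].itertuples():
            pid = r.person_id
            if pid not in self.lrc:
                continue
            age = float(ped.loc[pid, "age"])
            rows.append(
                dict(
                    person_id=pid,
                    family_id=r.family_id,
                    inclusion_age=float(r.inclusion_age),
                    censor_age=min(age, float(r.inclusion_age) + cfg_follow),
                    sex=ped.loc[pid, "sex"],
                    role=ped.loc[pid, "role_hint"],
                    lrc=self.lrc[pid],
                    lrc_group=self.groups[pid],
                )
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "lifetables": out / "lifetables.csv",
            "pedigree": out / "pedigree.csv",
            "persons": out / "persons.csv",
            "events": out / "events.csv",
            "medication": out / "medication.csv",
            "scores": out / "scores.csv",
            "truth": out / "truth.json",
        }
        write_lifetables(self.lifetables, paths["lifetables"])
        self.pedigree.to_csv(paths["pedigree"], index=False)
        self.persons_table().to_csv(paths["persons"], index=False)
        self.events.to_csv(paths["events"], index=False)
        self.medication.to_csv(paths["medication"], index=False)
        self.scores_df.to_csv(paths["scores"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=str)
        return paths


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Full two-phase generation: pedigree + lifespans, then LRC scores on
    the generated ancestors, then LRC-dependent health histories."""
    from .pedigree import assign_lrc_group

    ped_df, lts, meta = gen_pedigree(cfg)
    ped = pedigree_from_frame(ped_df)

    policy_ip = (
        LRCPolicy.REQUIRE_EXTINCT if cfg.style == "sedd" else LRCPolicy.EXCLUDE_ALIVE
    )
    lrc: dict[str, float] = {}
    groups: dict[str, str] = {}
    for r in meta[meta["is_f3"]].itertuples():
        person = ped.persons[r.person_id]
        policy = LRCPolicy.IMPUTE_ALIVE if person.role == "partner" else policy_ip
        try:
            s = lrc_score(person, ped, lts, policy=policy)
        except LRCUndefinedError:
            continue
        lrc[r.person_id] = s.value
        groups[r.person_id] = assign_lrc_group(s.value, person.role)

    events, meds, score_df = gen_health_histories(cfg, ped_df, meta, lrc, groups)
    truth = {"config": asdict(cfg), "n_scored": len(lrc)}
    return SyntheticCohort(
        pedigree=ped_df,
        lifetables=lts,
        meta=meta,
        events=events,
        medication=meds,
        scores_df=score_df,
        lrc=lrc,
        groups=groups,
        truth=truth,
    )
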