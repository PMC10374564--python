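"""End-to-end orchestration: inputs -> LRC scores -> analysis tables.

``run_pipeline`` mirrors the reporting layout of a familial-longevity
healthspan study:

* ``table2`` — IP vs partner disease incidence (first disease, two
  diseases, first-to-second disease) per category, gamma-frailty Cox
  adjusted for sex with age handled by left truncation;
* ``table3`` — LRC-group contrasts (g1/g2/g3 vs g4) for first disease,
  two age-related diseases and cardiovascular-class medication use;
* ``table4`` — quantitative LRC per 0.1, first disease per category (plus
  death as an outcome in register-style runs);
* ``fig2`` — medication odds ratios (ATC A/B/C), random-intercept
  logistic regression adjusted for age at inclusion and sex;
* ``fig3`` — left-truncated Kaplan–Meier curves of metabolic disease
  incidence with median onset ages and group delays;
* ``fig4`` — health-score contrasts between LRC groups, random-intercept
  linear model adjusted for sex, age at inclusion and medication use.

All estimates carry Wald 95% CIs, p-values and N/event counts; the
reference level is always the partner / LRC_g4 / no-exposure group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import inference as inf
from .lifetables import read_lifetables
from .pedigree import LRCPolicy, LRCUndefinedError, assign_lrc_group, lrc_score, read_pedigree

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "write_results",
           "PipelineError", "proportion", "score_cohort"]

ALL_ANALYSES = ("table2", "table3", "table4", "fig2", "fig3", "fig4")
CATEGORIES = ("age_related", "metabolic", "malignant")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def proportion(k: int, n: int, ndigits: int = 2) -> float:
    """Event proportion as printed in the result tables (e.g. 362 of 917 -> 0.39)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(k / n, ndigits)


@dataclass
class RunConfig:
    lifetables: str
    pedigree: str
    persons: str
    events: str
    medication: str | None = None
    scores: str | None = None
    style: str = "lls"  # lls | sedd
    category_map: str | None = None
    ip_policy: str = "exclude_alive"
    partner_policy: str = "impute_alive"
    analyses: tuple[str, ...] = ALL_ANALYSES
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style == "sedd":
            self.ip_policy = "require_extinct"
            # partner-based analyses are undefined without partners
            self.analyses = tuple(
                a for a in self.analyses if a not in ("table2", "fig2", "fig4")
            )
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise PipelineError("config", f"unknown analyses {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        try:
            return cls(**raw)
        except TypeError as err:
            raise PipelineError("config", str(err)) from err

    _PATH_FIELDS = ("lifetables", "pedigree", "persons", "events", "medication",
                    "scores", "category_map", "outdir")

    def content_hash(self) -> str:
        """Fingerprint of the analytic configuration (policies, analyses,
        style, seed).  File locations are excluded so that the same analysis
        run from different directories hashes identically."""
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k not in self._PATH_FIELDS},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    km_series: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def score_cohort(ped, lifetables, persons: pd.DataFrame, ip_policy, partner_policy):
    """LRC score + group for every F3 person in the roster.

    Returns (scored persons frame, exclusion tally).  Persons whose score
    is undefined under the policy (no usable ancestor) are dropped with a
    logged reason, as are IPs below the lowest group cutoff.
    """
    rows = []
    excl = {"undefined_score": 0, "lrc_below_grouping_range": 0}
    for r in persons.itertuples():
        person = ped.persons[str(r.person_id)]
        policy = LRCPolicy(partner_policy if person.role == "partner" else ip_policy)
        try:
            s = lrc_score(person, ped, lifetables, policy=policy)
        except LRCUndefinedError:
            excl["undefined_score"] += 1
            continue
        group = assign_lrc_group(s.value, person.role)
        if group == "none":
            excl["lrc_below_grouping_range"] += 1
        rows.append(
            dict(
                person_id=str(r.person_id),
                family_id=str(r.family_id),
                inclusion_age=float(r.inclusion_age),
                censor_age=float(r.censor_age),
                sex=person.sex,
                role=person.role,
                lrc=s.value,
                lrc_group=group,
                n_ancestors_used=s.n_ancestors_used,
                n_ancestors_excluded=s.n_excluded,
            )
        )
    return pd.DataFrame(rows), excl


def _cov_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["sex01"] = (out["sex"] == "F").astype(float)
    out["is_ip"] = (out["role"] == "IP").astype(float)
    for g in ("g1", "g2", "g3"):
        out[f"lrc_{g}"] = (out["lrc_group"] == g).astype(float)
    return out


def _fit_row(term, n, n_events, est, ci, p):
    return dict(term=term, n=int(n), events=int(n_events), estimate=float(est),
                ci_low=float(ci[0]), ci_high=float(ci[1]), p=float(p))


def _cox_table(records, covariates, contrast: str, extra_terms=()):
    # a covariate constant over the records, or a dummy whose level has no
    # events, has no estimable hazard ratio (monotone likelihood)
    def estimable(c):
        vals = {r.covariates[c] for r in records}
        if len(vals) < 2:
            return False
        if vals <= {0, 1, 0.0, 1.0}:
            ev1 = sum(r.event for r in records if r.covariates[c] == 1)
            ev0 = sum(r.event for r in records if r.covariates[c] == 0)
            return ev1 > 0 and ev0 > 0
        return True

    usable = [c for c in covariates if estimable(c)]
    fit = inf.cox_frailty_fit(records, usable)
    s = fit.summary().set_index("term")
    rows = []
    for term in (contrast, *extra_terms):
        if term in s.index:
            r = s.loc[term]
            rows.append((term, r["hr"], (r["ci_low"], r["ci_high"]), r["p"]))
        else:
            rows.append((term, float("nan"), (float("nan"), float("nan")), float("nan")))
    return fit, rows


def _build_records(builder, *args, **kwargs):
    res = builder(*args, **kwargs)
    return res


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the configured analyses and return the results bundle."""
    try:
        lts = read_lifetables(config.lifetables)
        ped = read_pedigree(config.pedigree)
        persons_raw = pd.read_csv(config.persons, dtype={"person_id": str, "family_id": str})
        all_events = ev.read_events(config.events)
        meds = (
            pd.read_csv(config.medication, dtype={"person_id": str})
            if config.medication
            else None
        )
        scores = (
            pd.read_csv(config.scores, dtype={"person_id": str})
            if config.scores
            else None
        )
        cmap = (
            ev.CategoryMap.from_yaml(config.category_map)
            if config.category_map
            else ev.DEFAULT_CATEGORY_MAP
        )
    except (OSError, ValueError) as err:
        raise PipelineError("read_inputs", str(err)) from err

    try:
        scored, lrc_excl = score_cohort(
            ped, lts, persons_raw, config.ip_policy, config.partner_policy
        )
    except (KeyError, ValueError) as err:
        raise PipelineError("lrc_scoring", str(err)) from err
    if scored.empty:
        raise PipelineError("lrc_scoring", "no person received an LRC score")
    cov = _cov_frame(scored)

    bundle = ResultsBundle()
    bundle.provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "style": config.style,
        "n_persons_scored": int(len(scored)),
        "lrc_exclusions": lrc_excl,
        "builder_exclusions": {},
        "group_counts": scored["lrc_group"].value_counts().to_dict(),
    }

    def persons_for_cox(extra_cols):
        cols = ["person_id", "family_id", "inclusion_age", "censor_age"] + extra_cols
        return cov[cols]

    try:
        if "table2" in config.analyses:
            bundle.tables["table2"] = _table2(all_events, persons_for_cox, cmap, bundle)
        if "table3" in config.analyses:
            bundle.tables["table3"] = _table3(
                all_events, persons_for_cox, cov, meds, cmap, bundle
            )
        if "table4" in config.analyses:
            bundle.tables["table4"] = _table4(
                all_events, persons_for_cox, cov, ped, cmap, config.style, bundle
            )
        if "fig2" in config.analyses and meds is not None:
            bundle.tables["fig2"] = _fig2(cov, meds)
        if "fig3" in config.analyses:
            _fig3(all_events, persons_for_cox, cov, cmap, bundle)
        if "fig4" in config.analyses and scores is not None:
            bundle.tables["fig4"] = _fig4(cov, scores, meds)
    except (inf.ConvergenceError, inf.SeparationError) as err:
        raise PipelineError("model_fit", str(err)) from err
    except ValueError as err:
        raise PipelineError("analysis", str(err)) from err

    return bundle


def _table2(all_events, persons_for_cox, cmap, bundle) -> pd.DataFrame:
    rows = []
    persons = persons_for_cox(["sex01", "is_ip"])
    panels = {
        "A_first_disease": lambda cat: ev.build_first_disease_records(
            all_events, persons, cat, cmap
        ),
        "B_two_diseases": lambda cat: ev.build_two_disease_records(
            all_events, persons, cat, cmap
        ),
        "C_first_to_second": lambda cat: ev.build_first_to_second_records(
            all_events, persons, "age_related", cat, cmap
        ),
    }
    for panel, build in panels.items():
        for cat in CATEGORIES:
            res = build(cat)
            bundle.provenance["builder_exclusions"][f"table2/{panel}/{cat}"] = res.exclusions
            if not res.records or sum(r.event for r in res.records) == 0:
                continue
            fit, terms = _cox_table(res.records, ["is_ip", "sex01"], "is_ip")
            n_ip = sum(1 for r in res.records if r.covariates["is_ip"] == 1)
            ev_ip = sum(r.event for r in res.records if r.covariates["is_ip"] == 1)
            _, hr, ci, p = terms[0]
            rows.append(
                dict(panel=panel, category=cat, **_fit_row("IP_vs_partner", n_ip, ev_ip, hr, ci, p))
            )
            n_ref = len(res.records) - n_ip
            ev_ref = fit.n_events - ev_ip
            rows.append(
                dict(panel=panel, category=cat,
                     **_fit_row("partner_ref", n_ref, ev_ref, 1.0, (1.0, 1.0), 1.0))
            )
    return pd.DataFrame(rows)


_GROUP_TERMS = ("lrc_g1", "lrc_g2", "lrc_g3")


def _table3(all_events, persons_for_cox, cov, meds, cmap, bundle) -> pd.DataFrame:
    rows = []
    grouped = cov[cov["lrc_group"].isin(["g1", "g2", "g3", "g4"])]
    persons = persons_for_cox(["sex01", "lrc_g1", "lrc_g2", "lrc_g3", "lrc_group"])
    persons = persons[persons["lrc_group"].isin(["g1", "g2", "g3", "g4"])]

    specs = [("A_first_disease", cat, ev.build_first_disease_records) for cat in CATEGORIES]
    specs.append(("B_two_diseases", "age_related", ev.build_two_disease_records))
    for panel, cat, builder in specs:
        res = builder(all_events, persons, cat, cmap)
        bundle.provenance["builder_exclusions"][f"table3/{panel}/{cat}"] = res.exclusions
        if not res.records or sum(r.event for r in res.records) == 0:
            continue
        fit, terms = _cox_table(
            res.records, [*_GROUP_TERMS, "sex01"], _GROUP_TERMS[0], _GROUP_TERMS[1:]
        )
        for term, hr, ci, p in terms:
            g = term.replace("lrc_", "")
            n_g = sum(1 for r in res.records if r.covariates["lrc_group"] == g)
            ev_g = sum(r.event for r in res.records if r.covariates["lrc_group"] == g)
            rows.append(dict(panel=panel, category=cat, **_fit_row(term, n_g, ev_g, hr, ci, p)))
        n4 = sum(1 for r in res.records if r.covariates["lrc_group"] == "g4")
        ev4 = sum(r.event for r in res.records if r.covariates["lrc_group"] == "g4")
        rows.append(dict(panel=panel, category=cat,
                         **_fit_row("g4_ref", n4, ev4, 1.0, (1.0, 1.0), 1.0)))

    if meds is not None and not grouped.empty:
        med_ind = ev.build_medication_records(meds, list(grouped["person_id"]))
        df = grouped.merge(med_ind, on="person_id")
        if df["atc_c"].nunique() == 2:
            fit = inf.logistic_mixed_fit(
                df["atc_c"],
                df[["lrc_g1", "lrc_g2", "lrc_g3", "inclusion_age", "sex01"]],
                df["family_id"],
            )
            s = fit.summary().set_index("term")
            for term in _GROUP_TERMS:
                g = term.replace("lrc_", "")
                sub = df[df["lrc_group"] == g]
                rows.append(
                    dict(panel="C_medication_atc_c", category="medication",
                         **_fit_row(term, len(sub), sub["atc_c"].sum(),
                                    s.loc[term, "or"],
                                    (s.loc[term, "ci_low"], s.loc[term, "ci_high"]),
                                    s.loc[term, "p"]))
                )
            sub = df[df["lrc_group"] == "g4"]
            rows.append(dict(panel="C_medication_atc_c", category="medication",
                             **_fit_row("g4_ref", len(sub), sub["atc_c"].sum(),
                                        1.0, (1.0, 1.0), 1.0)))
    return pd.DataFrame(rows)


def _table4(all_events, persons_for_cox, cov, ped, cmap, style, bundle) -> pd.DataFrame:
    rows = []
    persons = persons_for_cox(["sex01", "lrc"])
    for cat in CATEGORIES:
        res = ev.build_first_disease_records(all_events, persons, cat, cmap)
        bundle.provenance["builder_exclusions"][f"table4/first_disease/{cat}"] = res.exclusions
        if not res.records or sum(r.event for r in res.records) == 0:
            continue
        fit = inf.cox_frailty_fit(res.records, ["lrc", "sex01"])
        hr, ci = inf.scaled_hr(fit, "lrc", scale=0.1)
        p = fit.p_values[fit.covariate_names.index("lrc")]
        rows.append(dict(panel="first_disease", category=cat,
                         **_fit_row("lrc_per_0.1", len(res.records), fit.n_events, hr, ci, p)))
    if style == "sedd":
        # death as an outcome: entry at inclusion, exit at death/last observation
        recs = []
        for r in cov.itertuples():
            person = ped.persons[r.person_id]
            exit_age = float(person.age)
            if exit_age <= r.inclusion_age:
                continue
            recs.append(
                ev.SurvivalRecord(
                    person_id=r.person_id, family_id=r.family_id,
                    entry_age=float(r.inclusion_age), exit_age=exit_age,
                    event=int(person.vital_status == "dead"),
                    covariates={"lrc": r.lrc, "sex01": r.sex01},
                    analysis_tag="death",
                )
            )
        if recs and sum(x.event for x in recs) > 0:
            fit = inf.cox_frailty_fit(recs, ["lrc", "sex01"])
            hr, ci = inf.scaled_hr(fit, "lrc", scale=0.1)
            p = fit.p_values[fit.covariate_names.index("lrc")]
            rows.append(dict(panel="death", category="death",
                             **_fit_row("lrc_per_0.1", len(recs), fit.n_events, hr, ci, p)))
    return pd.DataFrame(rows)


def _fig2(cov, meds) -> pd.DataFrame:
    rows = []
    med_ind = ev.build_medication_records(meds, list(cov["person_id"]))
    df = cov.merge(med_ind, on="person_id")
    for klass in ("atc_a", "atc_b", "atc_c"):
        if df[klass].nunique() < 2:
            continue
        fit = inf.logistic_mixed_fit(
            df[klass], df[["is_ip", "inclusion_age", "sex01"]], df["family_id"]
        )
        s = fit.summary().set_index("term")
        sub = df[df["is_ip"] == 1]
        rows.append(dict(outcome=klass,
                         **_fit_row("IP_vs_partner", len(sub), sub[klass].sum(),
                                    s.loc["is_ip", "or"],
                                    (s.loc["is_ip", "ci_low"], s.loc["is_ip", "ci_high"]),
                                    s.loc["is_ip", "p"])))
    return pd.DataFrame(rows)


def _fig3(all_events, persons_for_cox, cov, cmap, bundle) -> None:
    persons = persons_for_cox(["sex01", "lrc_group", "is_ip"])
    res = ev.build_first_disease_records(all_events, persons, "metabolic", cmap)
    curves: dict[str, inf.KMCurve] = {}
    for label, pred in (
        ("IP", lambda r: r.covariates["is_ip"] == 1),
        ("partner", lambda r: r.covariates["is_ip"] == 0),
        ("g1", lambda r: r.covariates["lrc_group"] == "g1"),
        ("g2", lambda r: r.covariates["lrc_group"] == "g2"),
        ("g3", lambda r: r.covariates["lrc_group"] == "g3"),
        ("g4", lambda r: r.covariates["lrc_group"] == "g4"),
    ):
        sub = [r for r in res.records if pred(r)]
        if len(sub) >= 2 and any(r.event for r in sub):
            curves[label] = inf.km_estimate(sub)
            bundle.km_series[f"metabolic_{label}"] = curves[label].to_frame()
    medians = {k: inf.median_onset_age(c) for k, c in curves.items()}
    delays = {}
    if "g4" in curves:
        for k in ("g1", "g2", "g3"):
            if k in curves:
                d = inf.onset_delay(curves[k], curves["g4"])
                delays[f"{k}_vs_g4"] = d
    bundle.tables["fig3"] = pd.DataFrame(
        [
            dict(series=k, median_onset_age=medians.get(k), n=c.n)
            for k, c in curves.items()
        ]
        + [dict(series=f"delay_{k}", median_onset_age=v, n=np.nan)
           for k, v in delays.items()]
    )


def _fig4(cov, scores, meds) -> pd.DataFrame:
    df = cov[cov["lrc_group"].isin(["g1", "g2", "g3", "g4"])].merge(
        scores, on="person_id"
    )
    if meds is not None:
        med_ind = ev.build_medication_records(meds, list(df["person_id"]))
        med_ind["med_any"] = med_ind[["atc_a", "atc_b", "atc_c"]].max(axis=1)
        df = df.merge(med_ind[["person_id", "med_any"]], on="person_id")
    else:
        df["med_any"] = 0.0
    fit = inf.linear_mixed_fit(
        df["score"],
        df[["lrc_g1", "lrc_g2", "lrc_g3", "sex01", "inclusion_age", "med_any"]],
        df["family_id"],
    )
    s = fit.summary().set_index("term")
    rows = []
    for term in _GROUP_TERMS:
        g = term.replace("lrc_", "")
        sub = df[df["lrc_group"] == g]
        rows.append(dict(**_fit_row(term, len(sub), 0, s.loc[term, "coef"],
                                    (s.loc[term, "ci_low"], s.loc[term, "ci_high"]),
                                    s.loc[term, "p"])))
    sub = df[df["lrc_group"] == "g4"]
    rows.append(dict(**_fit_row("g4_ref", len(sub), 0, 0.0, (0.0, 0.0), 1.0)))
    return pd.DataFrame(rows)


def write_results(bundle: ResultsBundle, outdir) -> dict[str, Path]:
    """Write one CSV per table analog, KM series CSVs and provenance JSON.

    Output is deterministic: fixed float formatting and sorted JSON keys, so
    identical bundles serialize byte-identically.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise PipelineError("write_results", f"cannot create {out}: {err}") from err
    paths: dict[str, Path] = {}
    for name, df in sorted(bundle.tables.items()):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    for name, df in sorted(bundle.km_series.items()):
        p = out / f"km_{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[f"km_{name}"] = p
    prov = out / "provenance.json"
    with open(prov, "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True, default=str)
    paths["provenance"] = prov
    return paths
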