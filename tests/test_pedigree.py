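import numpy as np
import pandas as pd
import pytest

from lrc_healthspan.lifetables import CohortLifetable, LifetableCollection
from lrc_healthspan.pedigree import (
    LRCPolicy,
    LRCUndefinedError,
    PedigreeError,
    assign_lrc_group,
    identify_ancestors,
    lrc_score,
    read_pedigree,
    relationship_weight,
)
from lrc_healthspan.simulate import pedigree_from_frame

from conftest import TOP10_AGE, fig1_rows

BELOW = 40.0       # death age below the top-10% boundary for lambda=0.05
ABOVE = TOP10_AGE + 1.0


class TestReadPedigree:
    def test_fig1_shaped_file(self, fig1_frame, tmp_path):
        p = tmp_path / "ped.csv"
        fig1_frame.to_csv(p, index=False)
        ped = read_pedigree(p)
        assert len(ped.persons) == 12
        assert len(ped.families()) == 1

    def test_self_parenting_rejected(self, tmp_path):
        df = pd.DataFrame(
            [dict(id="a", father_id="a", mother_id=None, sex="M", birth_year=1900,
                  vital_status="dead", age=50.0)]
        )
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(PedigreeError, match="own parent"):
            read_pedigree(p)

    def test_cycle_rejected(self, tmp_path):
        df = pd.DataFrame(
            [
                dict(id="a", father_id="b", mother_id=None, sex="M", birth_year=1900,
                     vital_status="dead", age=50.0),
                dict(id="b", father_id="a", mother_id=None, sex="M", birth_year=1900,
                     vital_status="dead", age=50.0),
            ]
        )
        p = tmp_path / "cyc.csv"
        df.to_csv(p, index=False)
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(p)

    def test_duplicate_id_rejected(self, tmp_path):
        df = pd.DataFrame(
            [dict(id="a", father_id=None, mother_id=None, sex="M", birth_year=1900,
                  vital_status="dead", age=50.0)] * 2
        )
        p = tmp_path / "dup.csv"
        df.to_csv(p, index=False)
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(p)

    def test_ip_sibs_share_family(self, tmp_path):
        rows = fig1_rows()
        rows.append(
            dict(id="ip2", father_id="dad", mother_id="mom", sex="M", birth_year=1942,
                 vital_status="alive", age=60.0, role_hint="IP")
        )
        p = tmp_path / "sib.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        ped = read_pedigree(p)
        assert ped.family_of["ip"] == ped.family_of["ip2"]


class TestIdentifyAncestors:
    def test_full_ip_has_eight(self, fig1_pedigree):
        anc = identify_ancestors(fig1_pedigree, fig1_pedigree.persons["ip"])
        by_rel = {}
        for a in anc:
            by_rel.setdefault(a.relation, []).append(a)
        assert len(anc) == 8
        assert len(by_rel["parent"]) == 2
        assert len(by_rel["aunt_uncle"]) == 2
        assert len(by_rel["grandparent"]) == 4

    def test_partner_gets_parents_only(self, fig1_pedigree):
        anc = identify_ancestors(fig1_pedigree, fig1_pedigree.persons["par"])
        assert len(anc) == 2
        assert {a.relation for a in anc} == {"parent"}

    def test_unknown_grandparents_hide_aunts(self):
        rows = [r for r in fig1_rows() if r["id"] not in ("gf1", "gm1", "au1")]
        for r in rows:
            if r["id"] == "dad":
                r["father_id"] = r["mother_id"] = None
        ped = pedigree_from_frame(pd.DataFrame(rows))
        anc = identify_ancestors(ped, ped.persons["ip"])
        # paternal side contributes only the father now
        assert sum(a.relation == "aunt_uncle" for a in anc) == 1
        assert sum(a.relation == "grandparent" for a in anc) == 2

    def test_other_roles_rejected(self, fig1_pedigree):
        with pytest.raises(PedigreeError):
            identify_ancestors(fig1_pedigree, fig1_pedigree.persons["dad"])


class TestWeights:
    def test_defaults(self):
        assert relationship_weight("parent") == 0.5
        assert relationship_weight("aunt_uncle") == 0.25
        assert relationship_weight("grandparent") == 0.25

    def test_unknown_relation(self):
        with pytest.raises(PedigreeError):
            relationship_weight("cousin")

    def test_bounds(self):
        for rel in ("parent", "aunt_uncle", "grandparent"):
            assert 0 < relationship_weight(rel) <= 1


class TestLRCScore:
    def test_indicator_extremes(self, const_collection):
        for age, expect in ((ABOVE, 1.0), (BELOW, 0.0)):
            ped = pedigree_from_frame(
                pd.DataFrame(fig1_rows(parent_age=age, other_age=age))
            )
            s = lrc_score(ped.persons["ip"], ped, const_collection)
            assert s.value == expect

    def test_equal_weights_half_top10_scores_half(self, const_collection):
        # four grandparents (equal weight 0.25), two long-lived: LRC = 0.5
        rows = [r for r in fig1_rows(parent_age=BELOW, other_age=BELOW)
                if r["id"] not in ("au1", "au2")]
        for r in rows:
            if r["id"] in ("gf1", "gm1"):
                r["age"] = ABOVE
            if r["id"] in ("dad", "mom"):
                r["vital_status"], r["age"] = "alive", 60.0  # excluded by policy
        ped = pedigree_from_frame(pd.DataFrame(rows))
        s = lrc_score(ped.persons["ip"], ped, const_collection,
                      policy=LRCPolicy.EXCLUDE_ALIVE)
        assert s.value == 0.5
        assert s.n_ancestors_used == 4

    def test_fig1_parents_only_scores_04(self, fig1_pedigree, const_collection):
        # weights 2*0.5 + 2*0.25 + 4*0.25 = 2.5; both parents top-10%: 1/2.5
        s = lrc_score(fig1_pedigree.persons["ip"], fig1_pedigree, const_collection)
        assert s.value == pytest.approx(0.4)
        assert s.weighted_total == pytest.approx(2.5)

    def test_exclude_alive_policy(self, const_collection):
        rows = fig1_rows()
        for r in rows:
            if r["id"] == "au1":
                r["vital_status"], r["age"] = "alive", 70.0
        ped = pedigree_from_frame(pd.DataFrame(rows))
        s = lrc_score(ped.persons["ip"], ped, const_collection,
                      policy=LRCPolicy.EXCLUDE_ALIVE)
        assert s.n_ancestors_used == 7
        assert "alive" in s.exclusion_reasons

    def test_impute_alive_boundary_flip(self, const_collection):
        # an alive parent of a partner whose imputed age crosses the top-10%
        # threshold must count as long-lived
        lam = 0.05
        e = np.exp(-lam) / (1 - np.exp(-lam)) + 0.5
        censor_high = TOP10_AGE - e + 1.0   # imputed age just above threshold
        censor_low = TOP10_AGE - e - 5.0
        for censor, expect in ((censor_high, 0.5), (censor_low, 0.0)):
            rows = fig1_rows(other_age=BELOW)
            for r in rows:
                if r["id"] == "pfa":
                    r["vital_status"], r["age"] = "alive", censor
            ped = pedigree_from_frame(pd.DataFrame(rows))
            s = lrc_score(ped.persons["par"], ped, const_collection,
                          policy=LRCPolicy.IMPUTE_ALIVE)
            assert s.value == expect

    def test_missing_age_excluded_both_sides(self, const_collection):
        rows = fig1_rows()
        for r in rows:
            if r["id"] == "gf1":
                r["vital_status"], r["age"] = "missing_age", np.nan
        ped = pedigree_from_frame(pd.DataFrame(rows))
        s = lrc_score(ped.persons["ip"], ped, const_collection)
        assert s.n_ancestors_used == 7
        assert s.weighted_total == pytest.approx(2.25)
        assert s.value == pytest.approx(1.0 / 2.25)

    def test_require_extinct_raises_on_alive(self, const_collection):
        rows = fig1_rows()
        for r in rows:
            if r["id"] == "au1":
                r["vital_status"], r["age"] = "alive", 70.0
        ped = pedigree_from_frame(pd.DataFrame(rows))
        with pytest.raises(LRCUndefinedError):
            lrc_score(ped.persons["ip"], ped, const_collection,
                      policy=LRCPolicy.REQUIRE_EXTINCT)

    def test_no_usable_ancestor_is_undefined(self, const_collection):
        rows = fig1_rows()
        for r in rows:
            if r["id"] in ("pfa", "pmo"):
                r["vital_status"], r["age"] = "alive", 60.0
        ped = pedigree_from_frame(pd.DataFrame(rows))
        with pytest.raises(LRCUndefinedError):
            lrc_score(ped.persons["par"], ped, const_collection,
                      policy=LRCPolicy.EXCLUDE_ALIVE)

    def test_weight_rescaling_invariance(self, fig1_pedigree, const_collection):
        base = lrc_score(fig1_pedigree.persons["ip"], fig1_pedigree, const_collection)
        scaled = lrc_score(
            fig1_pedigree.persons["ip"], fig1_pedigree, const_collection,
            weights={"parent": 0.25, "aunt_uncle": 0.125, "grandparent": 0.125},
        )
        assert scaled.value == pytest.approx(base.value)

    def test_brute_force_oracle_random_pedigrees(self, const_collection):
        """Weighted-indicator formula vs an explicit loop over ancestors."""
        rng = np.random.default_rng(123)
        weights = {"parent": 0.5, "aunt_uncle": 0.25, "grandparent": 0.25}
        for _ in range(300):
            ages = {pid: (ABOVE if rng.random() < 0.4 else BELOW)
                    for pid in ("gf1", "gm1", "gf2", "gm2", "dad", "mom", "au1", "au2")}
            rows = fig1_rows()
            for r in rows:
                if r["id"] in ages:
                    r["age"] = ages[r["id"]]
            ped = pedigree_from_frame(pd.DataFrame(rows))
            s = lrc_score(ped.persons["ip"], ped, const_collection)
            # independent evaluation: loop over the known ancestor set
            num = den = 0.0
            rel = {"dad": "parent", "mom": "parent", "au1": "aunt_uncle",
                   "au2": "aunt_uncle", "gf1": "grandparent", "gm1": "grandparent",
                   "gf2": "grandparent", "gm2": "grandparent"}
            for pid, relation in rel.items():
                w = weights[relation]
                den += w
                if ages[pid] >= TOP10_AGE:
                    num += w
            assert s.value == pytest.approx(num / den)

    def test_adding_ancestor_monotonicity(self, const_collection):
        """A non-top-10% ancestor never raises the score; a top-10% one
        never lowers it."""
        base_rows = [r for r in fig1_rows(parent_age=ABOVE, other_age=BELOW)
                     if r["id"] not in ("au1",)]
        ped0 = pedigree_from_frame(pd.DataFrame(base_rows))
        s0 = lrc_score(ped0.persons["ip"], ped0, const_collection).value
        for age, cmp in ((BELOW, np.less_equal), (ABOVE, np.greater_equal)):
            rows = [dict(r) for r in base_rows]
            rows.append(dict(id="au1", father_id="gf1", mother_id="gm1", sex="M",
                             birth_year=1912, vital_status="dead", age=age,
                             role_hint="aunt_uncle"))
            ped1 = pedigree_from_frame(pd.DataFrame(rows))
            s1 = lrc_score(ped1.persons["ip"], ped1, const_collection).value
            assert cmp(s1, s0)


class TestGroups:
    @pytest.mark.parametrize(
        "score,role,expect",
        [
            (0.60, "IP", "g1"),
            (0.75, "IP", "g1"),
            (0.59, "IP", "g2"),
            (0.10, "IP", "g2"),
            (0.05, "IP", "none"),
            (0.0, "partner", "g4"),
            (0.01, "partner", "g3"),
            (1.0, "partner", "g3"),
        ],
    )
    def test_cutpoints(self, score, role, expect):
        assert assign_lrc_group(score, role) == expect

    def test_bad_role(self):
        with pytest.raises(PedigreeError):
            assign_lrc_group(0.5, "grandparent")
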