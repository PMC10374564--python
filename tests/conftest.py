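import numpy as np
import pandas as pd
import pytest

from lrc_healthspan.lifetables import CohortLifetable, LifetableCollection
from lrc_healthspan.simulate import pedigree_from_frame

LAMBDA = 0.05
#: age at which a constant-hazard(0.05) cohort reaches the top-10% boundary
TOP10_AGE = np.log(10.0) / LAMBDA


@pytest.fixture
def const_lifetable():
    """Constant-hazard table: every closed form is exponential."""
    return CohortLifetable("F", 1900, np.full(100, LAMBDA))


@pytest.fixture
def const_collection():
    """Constant-hazard tables for both sexes across the birth years the toy
    pedigrees use."""
    coll = LifetableCollection()
    for sex in "FM":
        for year in range(1840, 1961):
            coll.add(CohortLifetable(sex, year, np.full(100, LAMBDA)))
    return coll


def fig1_rows(parent_age=TOP10_AGE + 1.0, other_age=40.0, ip_alive_age=62.0):
    """A three-generation family shaped like the conceptual pedigree:
    1 IP, 1 partner (with own parents), 2 parents, 2 aunts/uncles,
    4 grandparents.  Defaults put only the two parents in the top 10%."""
    rows = []

    def add(i, sex, by, vs, age, f=None, m=None, role=None):
        rows.append(
            dict(id=i, father_id=f, mother_id=m, sex=sex, birth_year=by,
                 vital_status=vs, age=age, role_hint=role)
        )

    add("gf1", "M", 1880, "dead", other_age, role="grandparent")
    add("gm1", "F", 1880, "dead", other_age, role="grandparent")
    add("gf2", "M", 1880, "dead", other_age, role="grandparent")
    add("gm2", "F", 1880, "dead", other_age, role="grandparent")
    add("dad", "M", 1910, "dead", parent_age, "gf1", "gm1", "parent")
    add("mom", "F", 1910, "dead", parent_age, "gf2", "gm2", "parent")
    add("au1", "M", 1912, "dead", other_age, "gf1", "gm1", "aunt_uncle")
    add("au2", "F", 1912, "dead", other_age, "gf2", "gm2", "aunt_uncle")
    add("ip", "F", 1940, "alive", ip_alive_age, "dad", "mom", "IP")
    add("pfa", "M", 1912, "dead", other_age, role="parent_of_partner")
    add("pmo", "F", 1912, "dead", other_age, role="parent_of_partner")
    add("par", "M", 1940, "alive", ip_alive_age, "pfa", "pmo", "partner")
    return rows


@pytest.fixture
def fig1_pedigree():
    return pedigree_from_frame(pd.DataFrame(fig1_rows()))


@pytest.fixture
def fig1_frame():
    return pd.DataFrame(fig1_rows())


def make_records(entry, exit_, event, fam=None, **covs):
    """Build SurvivalRecords from parallel arrays."""
    from lrc_healthspan.events import SurvivalRecord

    n = len(entry)
    fam = fam if fam is not None else [f"f{i}" for i in range(n)]
    return [
        SurvivalRecord(
            person_id=str(i),
            family_id=str(fam[i]),
            entry_age=float(entry[i]),
            exit_age=float(exit_[i]),
            event=int(event[i]),
            covariates={k: float(v[i]) for k, v in covs.items()},
        )
        for i in range(n)
    ]
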