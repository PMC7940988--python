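"""Shared fixtures: small rosters, sessions, and fast sampler budgets."""

import datetime as dt
import textwrap

import numpy as np
import pytest

from cofeed.demography import Demography, DemographyTable, Individual
from cofeed.sampler import SamplerSettings
from cofeed.scans import SessionScans


def make_individual(
    id="a1",
    sex="female",
    birth=dt.date(2000, 3, 15),
    mother=None,
    entry=dt.date(2005, 1, 1),
    exit=dt.date(2020, 12, 31),
):
    return Individual(id=id, sex=sex, birth_date=birth, mother_id=mother,
                      entry_date=entry, exit_date=exit)


@pytest.fixture
def small_table():
    """Three-individual roster: mother, her juvenile offspring, unrelated male."""
    mom = make_individual("mom", "female", dt.date(1995, 5, 1))
    kid = make_individual("kid", "female", dt.date(2010, 4, 1), mother="mom",
                          entry=dt.date(2010, 4, 1))
    male = make_individual("m1", "male", dt.date(1998, 2, 1))
    return DemographyTable("g1", (mom, kid, male))


@pytest.fixture
def small_demography(small_table):
    return Demography({"g1": small_table})


@pytest.fixture
def demography_csv(tmp_path):
    """Minimal demography file covering one group over two years."""
    text = textwrap.dedent(
        """\
        id,group,sex,birth_date,mother_id,entry_date,exit_date
        mom,g1,female,1995-05-01,,2005-01-01,2020-12-31
        kid,g1,female,2010-04-01,mom,2010-04-01,2020-12-31
        m1,g1,male,1998-02-01,,2005-01-01,2020-12-31
        """
    )
    path = tmp_path / "demography.csv"
    path.write_text(text)
    return path


def make_session(
    counts=(5, 4, 3),
    n_at_risk=10,
    group="g1",
    year=2015,
    session="s1",
    assay="peanut_swing",
    identities=None,
):
    times = tuple(15.0 * j for j in range(len(counts)))
    return SessionScans(
        group_id=group,
        year=year,
        session_id=session,
        assay=assay,
        n_at_risk=n_at_risk,
        times_s=times,
        counts=tuple(counts),
        identities=identities,
    )


@pytest.fixture
def fast_sampler():
    """Small but convergent ensemble budget for unit-test fits."""
    return SamplerSettings(warmup=400, steps=300, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
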