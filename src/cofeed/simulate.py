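"""Synthetic study generator with known ground truth.

Emulates the study design: four neighboring chimpanzee groups followed over
eight annual waves, with group sizes, percent-female bands, and
maternal-kin prevalence patterned on the study populations (large
female-biased groups alongside a small male-biased group). Each group-year
contributes several ~2-minute assay sessions; the depleting-resource assay
consumes the patch as a function of realized attendance, while the
constant-resource variant holds it fixed. Identity-resolved scans can be
layered on top for the dyadic network analysis.

Every draw flows through one seeded :class:`numpy.random.Generator`, so a
given (config, seed) pair reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from .demography import (
    COVARIATE_NAMES,
    Demography,
    DemographyTable,
    Individual,
    build_covariates,
    census_date,
    classify,
    has_dependent_infant,
    roster_at,
)
from .scans import SessionScans


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


#: Group-size ranges (min, max) across years, one per group.
DEFAULT_SIZE_RANGES = ((23, 25), (42, 52), (10, 14), (11, 13))
#: Percent-female bands maintained per group.
DEFAULT_PCT_FEMALE = ((0.56, 0.67), (0.61, 0.71), (0.57, 0.67), (0.18, 0.38))
#: Initial probability that a non-adult founder is linked to a resident mother.
DEFAULT_KIN_LINK_P = (0.75, 0.91, 0.49, 0.36)


@dataclasses.dataclass
class SimConfig:
    """Study design and simulation truth.

    Truth parameters are on the logit scale: ``alpha`` is the baseline
    logit maximal tolerance, ``sigma_g``/``sigma_gy`` the group and
    group-year SDs, ``beta`` the effects of the standardized covariates
    (ordered as :data:`~cofeed.demography.COVARIATE_NAMES`), and ``kappa``
    the per-capita depletion rate of the resource patch.
    """

    n_groups: int = 4
    years: tuple[int, ...] = tuple(range(2011, 2019))
    group_size_ranges: tuple[tuple[int, int], ...] = DEFAULT_SIZE_RANGES
    pct_female_bands: tuple[tuple[float, float], ...] = DEFAULT_PCT_FEMALE
    kin_link_p: tuple[float, ...] = DEFAULT_KIN_LINK_P
    sessions_per_group_year: int = 6
    n_scans: int = 9
    scan_interval_s: float = 15.0
    assay: str = "peanut_swing"
    depletion_rule: str = "exponential"
    turnover_per_year: int = 2
    exclude_infants_from_risk: bool = True
    # simulation truth
    alpha: float = 0.2
    sigma_g: float = 0.5
    sigma_gy: float = 0.2
    beta: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    kappa: float = 1.0
    #: fixed group effects u_g (one per group); None draws u_g ~ N(0, sigma_g)
    group_effects: tuple[float, ...] | None = None
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 2:
            raise ConfigError("n_scans must be >= 2")
        if self.scan_interval_s <= 0:
            raise ConfigError("scan_interval_s must be > 0")
        if self.kappa < 0 or self.sigma_g < 0 or self.sigma_gy < 0:
            raise ConfigError("kappa, sigma_g, sigma_gy must be >= 0")
        if len(self.group_size_ranges) < self.n_groups:
            raise ConfigError("need one group_size_range per group")
        for lo, hi in self.group_size_ranges[: self.n_groups]:
            if lo > hi or lo < 2:
                raise ConfigError(f"infeasible group size range ({lo}, {hi})")
        if len(self.beta) != len(self.covariate_names):
            raise ConfigError("beta must have one entry per covariate")

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(f"g{i + 1}" for i in range(self.n_groups))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --------------------------------------------------------------------------
# demography generation
# --------------------------------------------------------------------------


@dataclasses.dataclass
class _Member:
    id: str
    sex: str
    birth_date: dt.date
    mother_id: str | None
    entry_date: dt.date
    exit_date: dt.date | None  # None while still resident


def _age_on(birth: dt.date, date: dt.date) -> int:
    return date.year - birth.year - ((date.month, date.day) < (birth.month, birth.day))


def _birth_date_for_age(age: int, year: int, rng: np.random.Generator) -> dt.date:
    # month in Jan-Jun so the July-1 census age equals ``age`` exactly
    return dt.date(year - age, int(rng.integers(1, 7)), int(rng.integers(1, 29)))


def _pick_sex(
    n_female: int, n_total: int, band: tuple[float, float], rng: np.random.Generator
) -> str:
    """Sex of an added member, keeping the resident female fraction in band."""
    lo, hi = band
    if (n_female + 1) / (n_total + 1) > hi:
        return "male"
    if n_female / (n_total + 1) < lo:
        return "female"
    return "female" if rng.random() < (lo + hi) / 2 else "male"


def _generate_group(
    gid: str,
    size_range: tuple[int, int],
    female_band: tuple[float, float],
    kin_p: float,
    years: Sequence[int],
    turnover: int,
    rng: np.random.Generator,
) -> DemographyTable:
    lo, hi = size_range
    first, last = years[0], years[-1]
    horizon = dt.date(last, 12, 31)
    serial = 0

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"{gid}-{serial:03d}"

    members: list[_Member] = []
    # founding cohort, resident since before the first study year
    n0 = int(rng.integers(lo, hi + 1))
    n_female = 0
    founding = dt.date(first - 1, 1, 1)
    for _ in range(n0):
        sex = _pick_sex(n_female, len(members), female_band, rng)
        n_female += sex == "female"
        age = int(rng.integers(13, 31)) if rng.random() < 0.6 else int(rng.integers(0, 13))
        members.append(
            _Member(new_id(), sex, _birth_date_for_age(age, first, rng), None, founding, None)
        )
    # maternal links among founders
    for m in members:
        age = _age_on(m.birth_date, census_date(first))
        candidates = [
            f
            for f in members
            if f.sex == "female"
            and f is not m
            and _age_on(f.birth_date, m.birth_date) >= 13
        ]
        if candidates and rng.random() < kin_p * (1.0 if age < 13 else 0.35):
            m.mother_id = candidates[int(rng.integers(len(candidates)))].id

    def residents(date: dt.date) -> list[_Member]:
        return [
            m
            for m in members
            if m.entry_date <= date and (m.exit_date is None or m.exit_date >= date)
        ]

    def add_member(year: int) -> None:
        res = residents(census_date(year))
        nf = sum(m.sex == "female" for m in res)
        sex = _pick_sex(nf, len(res), female_band, rng)
        mothers = [
            m
            for m in res
            if m.sex == "female" and 13 <= _age_on(m.birth_date, census_date(year)) <= 38
        ]
        if mothers and rng.random() < 0.7:  # birth
            mother = mothers[int(rng.integers(len(mothers)))]
            birth = dt.date(year, int(rng.integers(1, 7)), int(rng.integers(1, 29)))
            members.append(_Member(new_id(), sex, birth, mother.id, birth, None))
        else:  # adult transfer
            age = int(rng.integers(13, 26))
            members.append(
                _Member(
                    new_id(),
                    sex,
                    _birth_date_for_age(age, year, rng),
                    None,
                    dt.date(year, int(rng.integers(1, 7)), 1),
                    None,
                )
            )

    def remove_member(year: int) -> None:
        res = residents(census_date(year))
        nf = sum(m.sex == "female" for m in res)
        band_lo, band_hi = female_band
        def keeps_band(m: _Member) -> bool:
            f = nf - (m.sex == "female")
            n = len(res) - 1
            return n > 0 and band_lo <= f / n <= band_hi
        removable = [m for m in res if m.entry_date.year < year]
        pool = [m for m in removable if keeps_band(m)] or removable or res
        chosen = pool[int(rng.integers(len(pool)))]
        # exit just before the census; never before the member's own entry
        chosen.exit_date = max(dt.date(year, 3, 1), chosen.entry_date)

    target = n0
    for year in years[1:]:
        step = int(rng.integers(-2, 3))
        target = int(np.clip(target + step, lo, hi))
        # turnover events first (birth + matched removal keeps size constant)
        for _ in range(turnover):
            add_member(year)
            remove_member(year)
        current = len(residents(census_date(year)))
        while current < target:
            add_member(year)
            current += 1
        while current > target:
            remove_member(year)
            current -= 1

    individuals = tuple(
        Individual(
            id=m.id,
            sex=m.sex,
            birth_date=m.birth_date,
            mother_id=m.mother_id,
            entry_date=m.entry_date,
            exit_date=m.exit_date if m.exit_date is not None else horizon,
        )
        for m in members
    )
    return DemographyTable(gid, individuals)


def generate_demography(cfg: SimConfig, rng: np.random.Generator | None = None) -> Demography:
    """Simulate per-group rosters whose yearly sizes stay in the configured ranges."""
    rng = cfg.rng() if rng is None else rng
    groups = {}
    for i, gid in enumerate(cfg.group_ids):
        groups[gid] = _generate_group(
            gid,
            cfg.group_size_ranges[i],
            cfg.pct_female_bands[i],
            cfg.kin_link_p[i],
            cfg.years,
            cfg.turnover_per_year,
            rng,
        )
    return Demography(groups)


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------


def at_risk_ids(
    dem: Demography, gid: str, year: int, exclude_infants: bool = True
) -> list[str]:
    """Ids of individuals eligible to attend a session in ``gid`` x ``year``.

    Infants under three travel with their mothers and are not independent
    attendees, so they are excluded from the binomial denominator by default.
    """
    date = census_date(year)
    roster = roster_at(dem[gid], date)
    out = []
    for ind in roster:
        if exclude_infants and classify(ind, date).age_class == "infant_lt3":
            continue
        out.append(ind.id)
    return sorted(out)


def generate_sessions(
    cfg: SimConfig,
    covariates,
    demography: Demography,
    rng: np.random.Generator | None = None,
) -> tuple[list[SessionScans], dict]:
    """Draw scan counts for every group-year session plus a truth record.

    The per-session law: theta[g, y] = expit(alpha + u_g + X[g,y].beta +
    v_{g,y}); the resource starts at 1 and depletes after each scan as a
    function of realized attendance (held at 1 for the juice-pipe assay).
    The truth record stores every latent draw needed to score estimators.
    """
    rng = cfg.rng() if rng is None else rng
    keyed = covariates.set_index(["group", "year"])
    if cfg.group_effects is not None:
        if len(cfg.group_effects) != cfg.n_groups:
            raise ConfigError("group_effects needs one entry per group")
        u = dict(zip(cfg.group_ids, cfg.group_effects))
    else:
        u = {g: cfg.sigma_g * rng.standard_normal() for g in cfg.group_ids}
    beta = np.asarray(cfg.beta, dtype=float)

    sessions: list[SessionScans] = []
    truth_cells = {}
    truth_r = {}
    times = tuple(cfg.scan_interval_s * j for j in range(cfg.n_scans))
    for gid in cfg.group_ids:
        for year in cfg.years:
            rec = keyed.loc[(gid, year)]
            x = np.array([float(rec[n + "_z"]) for n in cfg.covariate_names])
            v = cfg.sigma_gy * rng.standard_normal()
            eta = cfg.alpha + u[gid] + float(x @ beta) + v
            theta = float(special.expit(eta))
            n_risk = len(
                at_risk_ids(demography, gid, year, cfg.exclude_infants_from_risk)
            )
            truth_cells[(gid, year)] = {"theta": theta, "v": v, "n_at_risk": n_risk}
            for s in range(cfg.sessions_per_group_year):
                sid = f"{gid}-{year}-s{s + 1}"
                counts = []
                r = 1.0
                r_traj = []
                for _ in range(cfg.n_scans):
                    r_traj.append(r)
                    k = int(rng.binomial(n_risk, theta * r))
                    counts.append(k)
                    if cfg.assay != "juice_pipe":
                        if cfg.depletion_rule == "exponential":
                            r *= float(np.exp(-cfg.kappa * k / n_risk))
                        else:
                            r = max(0.0, r - cfg.kappa * k / n_risk)
                sessions.append(
                    SessionScans(
                        group_id=gid,
                        year=year,
                        session_id=sid,
                        assay=cfg.assay,
                        n_at_risk=n_risk,
                        times_s=times,
                        counts=tuple(counts),
                    )
                )
                truth_r[sid] = r_traj
    truth = {
        "alpha": cfg.alpha,
        "sigma_g": cfg.sigma_g,
        "sigma_gy": cfg.sigma_gy,
        "kappa": cfg.kappa if cfg.assay != "juice_pipe" else 0.0,
        "beta": list(cfg.beta),
        "u": u,
        "cells": truth_cells,
        "resource": truth_r,
        "seed": cfg.seed,
        "assay": cfg.assay,
    }
    return sessions, truth


def truth_json(truth: dict) -> dict:
    """JSON-serializable copy of a truth record (tuple keys flattened)."""
    out = dict(truth)
    out["cells"] = {f"{g}|{y}": v for (g, y), v in truth["cells"].items()}
    return out


def simulate_study(
    cfg: SimConfig,
) -> tuple[Demography, "object", list[SessionScans], dict]:
    """Demography + covariates + sessions from one seeded stream."""
    rng = cfg.rng()
    dem = generate_demography(cfg, rng)
    cov = build_covariates(dem, cfg.years)
    sessions, truth = generate_sessions(cfg, cov, dem, rng)
    return dem, cov, sessions, truth


# --------------------------------------------------------------------------
# identity-resolved scans
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ClassPropensities:
    """Log-weights governing who attends, given the drawn head-counts.

    ``class_effects`` maps "ageclass/sex" labels to attendance log-weights;
    ``female_infant_effect`` shifts females with a dependent infant;
    ``dyad_interactions`` maps (female_status, male_age_class) to a
    log-weight applied to such females for every already-present male of
    that age class (state-dependent sampling, which induces dyadic
    structure); ``individual_sd`` adds individual-level log-normal noise.
    ``female_status`` is "with_infant" or "without_infant".
    """

    class_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    female_infant_effect: float = 0.0
    dyad_interactions: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=dict
    )
    individual_sd: float = 0.0


def generate_identities(
    sessions: Sequence[SessionScans],
    demography: Demography,
    propensities: ClassPropensities | None = None,
    rng: np.random.Generator | None = None,
    exclude_infants: bool = True,
) -> list[SessionScans]:
    """Attach attendee identities to each scan, preserving marginal counts.

    Attendees are drawn without replacement with probability proportional
    to exp(individual log-weight); dyadic interaction terms modify a
    female's weight according to the males already selected for the scan.
    """
    props = propensities or ClassPropensities()
    rng = np.random.default_rng(0) if rng is None else rng
    out = []
    noise_cache: dict[str, float] = {}
    for session in sessions:
        date = census_date(session.year)
        roster = roster_at(demography[session.group_id], date)
        eligible = [
            ind
            for ind in roster
            if not (exclude_infants and classify(ind, date).age_class == "infant_lt3")
        ]
        if len(eligible) != session.n_at_risk:
            raise ValueError(
                f"session {session.session_id!r}: roster yields {len(eligible)} "
                f"at-risk individuals but session records n_at_risk={session.n_at_risk}"
            )
        base = {}
        info = {}
        for ind in eligible:
            cls = classify(ind, date)
            w = props.class_effects.get(cls.label, 0.0)
            with_inf = has_dependent_infant(ind, roster, date)
            if ind.sex == "female" and with_inf:
                w += props.female_infant_effect
            if props.individual_sd > 0:
                if ind.id not in noise_cache:
                    noise_cache[ind.id] = props.individual_sd * rng.standard_normal()
                w += noise_cache[ind.id]
            base[ind.id] = w
            info[ind.id] = (ind.sex, cls.age_class, with_inf)
        ids = [ind.id for ind in eligible]
        identities = []
        for k in session.counts:
            chosen: list[str] = []
            available = list(ids)
            for _ in range(k):
                logw = []
                for cand in available:
                    w = base[cand]
                    sex, _, with_inf = info[cand]
                    if sex == "female" and props.dyad_interactions:
                        status = "with_infant" if with_inf else "without_infant"
                        for other in chosen:
                            osex, oage, _ = info[other]
                            if osex == "male":
                                w += props.dyad_interactions.get((status, oage), 0.0)
                    logw.append(w)
                p = np.exp(np.array(logw) - max(logw))
                p /= p.sum()
                pick = int(rng.choice(len(available), p=p))
                chosen.append(available.pop(pick))
            identities.append(frozenset(chosen))
        out.append(dataclasses.replace(session, identities=tuple(identities)))
    return out
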