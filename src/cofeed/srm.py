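"""Symmetric social relations model (SRM) for food-zone scans.

Two logistic random-effects models are fitted to identity-resolved scans:

* presence:     logit P(i in zone at a scan)      = mu  + e . x_i  + a_i
* coresidence:  logit P(i and j both in zone)     = mu' + c . x_ij + a'_i + a'_j + d_ij

with individual effects a_i ~ N(0, sigma_a), a'_i ~ N(0, sigma_a')
(multi-membership: the same a'_i enters every dyad containing i) and
symmetric dyad effects d_ij ~ N(0, sigma_d). Individual covariates x_i are
sex-by-age-class indicators plus a female-with-dependent-infant indicator;
dyad covariates x_ij cross female infant status with the age class of a
male partner. Coresidence is undirected, so the directed SRM's
sender/receiver pair collapses to the single a' effect.

Scans are treated as repeated Bernoulli trials and aggregated into
binomial blocks per individual (or dyad) and covariate profile. The dyad
effects d_ij are integrated out of the likelihood by Gauss-Hermite
quadrature, which keeps the sampled parameter count small; conditional
posterior draws of each d_ij are recovered afterwards from the same
quadrature grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .demography import (
    AGE_CLASS_LABELS,
    Demography,
    ValidationError,
    census_date,
    classify,
    has_dependent_infant,
    roster_at,
)
from .sampler import EnsembleDraws, SamplerSettings, run_ensemble, spread_init
from .scans import SessionScans

MALE_AGE_CLASSES = AGE_CLASS_LABELS
FEMALE_STATUSES = ("with_infant", "without_infant")

_GH_NODES = 21


@dataclasses.dataclass
class DyadObservations:
    """Aggregated individual-presence and dyadic-coresidence records.

    Scan-level Bernoulli outcomes are grouped into binomial blocks: one
    block per individual (or unordered dyad) and covariate profile.
    ``ind_block_of`` / ``dyad_block_of`` map blocks to their individual or
    dyad; dyad blocks are stored contiguously per dyad.
    """

    ids: list[str]
    ind_cat_labels: list[str]
    ind_block_of: np.ndarray  # (Bi,) individual index per block
    ind_X: np.ndarray  # (Bi, Ki)
    ind_y: np.ndarray  # (Bi,) presences
    ind_trials: np.ndarray  # (Bi,) scans
    dyads: np.ndarray  # (D, 2) individual index pairs, i < j
    dyad_cat_labels: list[str]
    dyad_block_of: np.ndarray  # (Bd,) dyad index per block, sorted
    dyad_X: np.ndarray  # (Bd, Kd)
    dyad_y: np.ndarray  # (Bd,) coresidences
    dyad_trials: np.ndarray  # (Bd,) scans
    n_individual_obs: int
    n_dyadic_obs: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dyad_block_of) < 0):
            raise ValidationError("dyad blocks must be sorted by dyad index")
        if np.any(self.ind_y > self.ind_trials) or np.any(self.dyad_y > self.dyad_trials):
            raise ValidationError("block successes exceed trials")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)

    def category_counts(self) -> pd.DataFrame:
        rows = [
            {"effect": "presence", "category": lab,
             "n_obs": int(self.ind_trials[self.ind_X[:, j] != 0].sum())}
            for j, lab in enumerate(self.ind_cat_labels)
        ] + [
            {"effect": "coresidence", "category": lab,
             "n_obs": int(self.dyad_trials[self.dyad_X[:, j] != 0].sum())}
            for j, lab in enumerate(self.dyad_cat_labels)
        ]
        return pd.DataFrame(rows)


def individual_categories(sex: str, age_class: str, with_infant: bool) -> dict[str, float]:
    cats = {f"{age_class}/{sex}": 1.0}
    if sex == "female" and with_infant:
        cats["female_with_infant"] = 1.0
    return cats


def dyad_categories(
    info_a: tuple[str, str, bool], info_b: tuple[str, str, bool]
) -> dict[str, float]:
    """Female-infant-status x male-age-class indicators for one dyad.

    ``info`` tuples are (sex, age_class, has_dependent_infant). Dyads that
    are not female-male pairs carry no indicator (baseline).
    """
    out: dict[str, float] = {}
    for fem, male in ((info_a, info_b), (info_b, info_a)):
        if fem[0] == "female" and male[0] == "male":
            status = "with_infant" if fem[2] else "without_infant"
            key = f"female_{status}*male_{male[1]}"
            out[key] = out.get(key, 0.0) + 1.0
    return out


def scan_presence(session: SessionScans, ids: Sequence[str]) -> np.ndarray:
    """(n_scans, n_ids) presence indicator matrix for one session."""
    if session.identities is None:
        raise ValidationError(f"session {session.session_id!r} has no identities")
    pos = {i: k for k, i in enumerate(ids)}
    out = np.zeros((session.n_scans, len(ids)), dtype=bool)
    for j, present in enumerate(session.identities):
        for i in present:
            out[j, pos[i]] = True
    return out


def build_dyadic_dataset(
    sessions: Sequence[SessionScans],
    demography: Demography,
    exclude_infants: bool = True,
) -> DyadObservations:
    """Assemble SRM observations from identity-resolved sessions.

    One individual record per (at-risk resident, scan) and one dyadic
    record per unordered at-risk pair per scan; coresidence(i, j) is the
    conjunction of the two presences. Categories are evaluated at each
    session's census date, so infant status is time-varying. Construction
    is deterministic and idempotent.
    """
    with_ids = [s for s in sessions if s.identities is not None]
    if not with_ids:
        raise ValidationError("no identity-resolved sessions supplied")

    all_ids: set[str] = set()
    per_session: list[tuple[SessionScans, list[str], dict]] = []
    for s in with_ids:
        date = census_date(s.year)
        roster = roster_at(demography[s.group_id], date)
        roster_ids = {ind.id for ind in roster}
        for present in s.identities:
            missing = sorted(present - roster_ids)
            if missing:
                raise ValidationError(
                    f"identity {missing[0]!r} not on the {s.group_id!r} roster "
                    f"on {date} (session {s.session_id!r})"
                )
        eligible = [
            ind for ind in roster
            if not (exclude_infants and classify(ind, date).age_class == "infant_lt3")
        ]
        info = {
            ind.id: (ind.sex, classify(ind, date).age_class,
                     has_dependent_infant(ind, roster, date))
            for ind in eligible
        }
        ids = sorted(info)
        all_ids.update(ids)
        per_session.append((s, ids, info))

    id_list = sorted(all_ids)
    id_pos = {i: k for k, i in enumerate(id_list)}

    # accumulate per (individual, category-profile) and (dyad, profile)
    ind_acc: dict[tuple[int, tuple], list[int]] = {}
    dyad_acc: dict[tuple[tuple[int, int], tuple], list[int]] = {}
    n_ind_obs = 0
    n_dyad_obs = 0
    ind_cats: set[str] = set()
    dyad_cats: set[str] = set()
    for s, ids, info in per_session:
        P = scan_presence(s, ids)
        n_scans, n = P.shape
        n_ind_obs += n_scans * n
        n_dyad_obs += n_scans * (n * (n - 1) // 2)
        cat_i = {i: individual_categories(*info[i]) for i in ids}
        for k, i in enumerate(ids):
            ind_cats.update(cat_i[i])
            key = (id_pos[i], tuple(sorted(cat_i[i].items())))
            acc = ind_acc.setdefault(key, [0, 0])
            acc[0] += int(P[:, k].sum())
            acc[1] += n_scans
        for k1 in range(n):
            for k2 in range(k1 + 1, n):
                i, j = ids[k1], ids[k2]
                pair = tuple(sorted((id_pos[i], id_pos[j])))
                cats = dyad_categories(info[i], info[j])
                dyad_cats.update(cats)
                key = (pair, tuple(sorted(cats.items())))
                acc = dyad_acc.setdefault(key, [0, 0])
                acc[0] += int((P[:, k1] & P[:, k2]).sum())
                acc[1] += n_scans

    ind_cat_labels = sorted(ind_cats)
    dyad_cat_labels = sorted(dyad_cats)

    ind_rows = sorted(ind_acc.items())
    Bi = len(ind_rows)
    ind_block_of = np.array([k for (k, _), _ in ind_rows], dtype=int)
    ind_X = np.zeros((Bi, len(ind_cat_labels)))
    ind_y = np.zeros(Bi, dtype=int)
    ind_trials = np.zeros(Bi, dtype=int)
    for b, ((_, cats), (y, t)) in enumerate(ind_rows):
        for lab, val in cats:
            ind_X[b, ind_cat_labels.index(lab)] = val
        ind_y[b], ind_trials[b] = y, t

    dyad_keys = sorted({pair for (pair, _), _ in dyad_acc.items()})
    dyad_index = {pair: d for d, pair in enumerate(dyad_keys)}
    dyad_rows = sorted(dyad_acc.items(), key=lambda kv: (dyad_index[kv[0][0]], kv[0][1]))
    Bd = len(dyad_rows)
    dyad_block_of = np.array([dyad_index[pair] for (pair, _), _ in dyad_rows], dtype=int)
    dyad_X = np.zeros((Bd, len(dyad_cat_labels)))
    dyad_y = np.zeros(Bd, dtype=int)
    dyad_trials = np.zeros(Bd, dtype=int)
    for b, ((_, cats), (y, t)) in enumerate(dyad_rows):
        for lab, val in cats:
            dyad_X[b, dyad_cat_labels.index(lab)] = val
        dyad_y[b], dyad_trials[b] = y, t

    return DyadObservations(
        ids=id_list,
        ind_cat_labels=ind_cat_labels,
        ind_block_of=ind_block_of,
        ind_X=ind_X,
        ind_y=ind_y,
        ind_trials=ind_trials,
        dyads=np.array(dyad_keys, dtype=int).reshape(-1, 2),
        dyad_cat_labels=dyad_cat_labels,
        dyad_block_of=dyad_block_of,
        dyad_X=dyad_X,
        dyad_y=dyad_y,
        dyad_trials=dyad_trials,
        n_individual_obs=n_ind_obs,
        n_dyadic_obs=n_dyad_obs,
    )


@dataclasses.dataclass
class SRMSpec:
    """Priors and sampler budget for both SRM submodels."""

    prior_intercept_sd: float = 2.5
    prior_effect_sd: float = 1.0
    prior_sigma_sd: float = 1.0
    gh_nodes: int = _GH_NODES
    sampler: SamplerSettings = dataclasses.field(default_factory=SamplerSettings)


class _PresenceModel:
    """mu + e . x_i + a_i, a_i ~ N(0, sigma_a); explicit a_i."""

    def __init__(self, obs: DyadObservations, spec: SRMSpec) -> None:
        self.obs, self.spec = obs, spec
        self.n_cats = len(obs.ind_cat_labels)
        self.n_ind = obs.n_individuals
        self.ndim = 1 + self.n_cats + 1 + self.n_ind  # mu, e, log_sigma_a, z_a
        k = obs.ind_y.astype(float)
        n = obs.ind_trials.astype(float)
        self._const = float(
            np.sum(special.gammaln(n + 1) - special.gammaln(k + 1)
                   - special.gammaln(n - k + 1))
        )

    def unpack(self, P: np.ndarray):
        c = self.n_cats
        mu = P[:, 0:1]
        e = P[:, 1:1 + c]
        log_sa = P[:, 1 + c:2 + c]
        z = P[:, 2 + c:]
        return mu, e, log_sa, z

    def log_prob(self, P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        mu, e, log_sa, z = self.unpack(P)
        sa = np.exp(log_sa)
        spec = self.spec
        lp = -0.5 * (mu[:, 0] / spec.prior_intercept_sd) ** 2
        lp += -0.5 * np.sum((e / spec.prior_effect_sd) ** 2, axis=1)
        lp += (-0.5 * (sa[:, 0] / spec.prior_sigma_sd) ** 2) + log_sa[:, 0]
        lp += -0.5 * np.sum(z**2, axis=1)
        a = sa * z
        eta = mu + e @ self.obs.ind_X.T + a[:, self.obs.ind_block_of]
        k = self.obs.ind_y[None, :]
        n = self.obs.ind_trials[None, :]
        ll = k * special.log_expit(eta) + (n - k) * special.log_expit(-eta)
        return lp + ll.sum(axis=1) + self._const


class _CoresidenceModel:
    """mu' + c . x_ij + a'_i + a'_j + d_ij; d integrated by quadrature."""

    def __init__(self, obs: DyadObservations, spec: SRMSpec) -> None:
        self.obs, self.spec = obs, spec
        self.n_cats = len(obs.dyad_cat_labels)
        self.n_ind = obs.n_individuals
        # mu', c, log_sigma_ap, log_sigma_d, z_ap
        self.ndim = 1 + self.n_cats + 2 + self.n_ind
        k = obs.dyad_y.astype(float)
        n = obs.dyad_trials.astype(float)
        self._const = float(
            np.sum(special.gammaln(n + 1) - special.gammaln(k + 1)
                   - special.gammaln(n - k + 1))
        )
        nodes, weights = np.polynomial.hermite_e.hermegauss(spec.gh_nodes)
        # standard-normal quadrature: E f(d) ~ sum w_l f(sigma_d * x_l)
        self._nodes = nodes  # (L,)
        self._logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
        # block boundaries per dyad (blocks are contiguous, sorted)
        change = np.flatnonzero(np.diff(obs.dyad_block_of)) + 1
        self._starts = np.concatenate([[0], change])

    def unpack(self, P: np.ndarray):
        c = self.n_cats
        mu = P[:, 0:1]
        cc = P[:, 1:1 + c]
        log_sap = P[:, 1 + c:2 + c]
        log_sd = P[:, 2 + c:3 + c]
        z = P[:, 3 + c:]
        return mu, cc, log_sap, log_sd, z

    def _block_eta(self, P: np.ndarray) -> np.ndarray:
        mu, cc, log_sap, _, z = self.unpack(P)
        ap = np.exp(log_sap) * z  # (W, N)
        i, j = self.obs.dyads[:, 0], self.obs.dyads[:, 1]
        a_pair = ap[:, i] + ap[:, j]  # (W, D)
        return mu + cc @ self.obs.dyad_X.T + a_pair[:, self.obs.dyad_block_of]

    def log_prior(self, P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        mu, cc, log_sap, log_sd, z = self.unpack(P)
        spec = self.spec
        lp = -0.5 * (mu[:, 0] / spec.prior_intercept_sd) ** 2
        lp += -0.5 * np.sum((cc / spec.prior_effect_sd) ** 2, axis=1)
        for ls in (log_sap, log_sd):
            s = np.exp(ls)
            lp += (-0.5 * (s[:, 0] / spec.prior_sigma_sd) ** 2) + ls[:, 0]
        lp += -0.5 * np.sum(z**2, axis=1)
        return lp

    def marginal_loglik(self, P: np.ndarray) -> np.ndarray:
        """Binomial log likelihood with d_ij integrated out by quadrature."""
        P = np.atleast_2d(P)
        _, _, _, log_sd, _ = self.unpack(P)
        eta = self._block_eta(P)  # (W, Bd)
        sd = np.exp(log_sd)  # (W, 1)
        d = sd[:, :, None] * self._nodes[None, None, :]  # (W, 1, L)
        eta_l = eta[:, :, None] + d  # (W, Bd, L)
        k = self.obs.dyad_y[None, :, None]
        n = self.obs.dyad_trials[None, :, None]
        ll_blocks = k * special.log_expit(eta_l) + (n - k) * special.log_expit(-eta_l)
        per_dyad = np.add.reduceat(ll_blocks, self._starts, axis=1)  # (W, D, L)
        lik = special.logsumexp(per_dyad + self._logw[None, None, :], axis=2)
        return lik.sum(axis=1) + self._const

    def log_prob(self, P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        return self.log_prior(P) + self.marginal_loglik(P)

    def conditional_dyad_effects(self, P: np.ndarray) -> np.ndarray:
        """Posterior mean of each d_ij given the sampled parameters, (W, D)."""
        P = np.atleast_2d(P)
        _, _, _, log_sd, _ = self.unpack(P)
        eta = self._block_eta(P)
        sd = np.exp(log_sd)
        d = sd[:, :, None] * self._nodes[None, None, :]
        eta_l = eta[:, :, None] + d
        k = self.obs.dyad_y[None, :, None]
        n = self.obs.dyad_trials[None, :, None]
        ll = k * special.log_expit(eta_l) + (n - k) * special.log_expit(-eta_l)
        per_dyad = np.add.reduceat(ll, self._starts, axis=1) + self._logw[None, None, :]
        w = np.exp(per_dyad - special.logsumexp(per_dyad, axis=2, keepdims=True))
        d_vals = sd[:, :, None] * self._nodes[None, None, :]  # (W, 1, L)
        return np.sum(w * d_vals, axis=2)


class SocialRelationsModel:
    """Symmetric SRM over presence and coresidence records.

    Fit requires at least 3 individuals and at least 2 scans' worth of
    trials. Degenerate outcomes (all zero or all one) produce a
    prior-dominated fit with a warning rather than an error.
    """

    def __init__(self, obs: DyadObservations, spec: SRMSpec | None = None) -> None:
        if obs.n_individuals < 3:
            raise ValidationError("SRM needs at least 3 individuals")
        if int(obs.ind_trials.sum()) < 2 * obs.n_individuals:
            raise ValidationError("SRM needs at least 2 scans per individual")
        self.obs = obs
        self.spec = spec or SRMSpec()
        y_i, t_i = obs.ind_y.sum(), obs.ind_trials.sum()
        y_d, t_d = obs.dyad_y.sum(), obs.dyad_trials.sum()
        if y_i in (0, t_i) or y_d in (0, t_d):
            warnings.warn(
                "degenerate outcomes (all zero or all one); the fit will be "
                "prior-dominated",
                UserWarning,
                stacklevel=2,
            )
        self._presence = _PresenceModel(obs, self.spec)
        self._coresidence = _CoresidenceModel(obs, self.spec)

    def fit(self, seed: int | None = None) -> "SRMResults":
        settings = self.spec.sampler
        if seed is not None:
            settings = dataclasses.replace(settings, seed=int(seed))
        draws = {}
        for offset, (name, sub) in enumerate(
            (("presence", self._presence), ("coresidence", self._coresidence))
        ):
            sub_settings = dataclasses.replace(settings, seed=settings.seed + offset)
            rng = np.random.default_rng(sub_settings.seed)
            center = np.zeros(sub.ndim)
            rate = (
                self.obs.ind_y.sum() / max(self.obs.ind_trials.sum(), 1)
                if name == "presence"
                else self.obs.dyad_y.sum() / max(self.obs.dyad_trials.sum(), 1)
            )
            center[0] = special.logit(np.clip(rate, 0.02, 0.98))
            nwalkers = sub_settings.walkers_for(sub.ndim)
            init = spread_init(center, nwalkers, rng)
            draws[name] = run_ensemble(sub.log_prob, init, sub_settings)
        return SRMResults(self, draws["presence"], draws["coresidence"])


class SRMResults:
    """Posterior draws for the presence and coresidence submodels."""

    def __init__(
        self,
        model: SocialRelationsModel,
        presence: EnsembleDraws,
        coresidence: EnsembleDraws,
    ) -> None:
        self.model = model
        self.obs = model.obs
        self.raw_presence = presence
        self.raw_coresidence = coresidence
        mu, e, log_sa, z = model._presence.unpack(presence.flat)
        self.presence_intercept = mu[:, 0]
        self.presence_effects = e
        self.sigma_a = np.exp(log_sa)[:, 0]
        self.a = np.exp(log_sa) * z
        mu2, cc, log_sap, log_sd, _ = model._coresidence.unpack(coresidence.flat)
        self.coresidence_intercept = mu2[:, 0]
        self.coresidence_effects = cc
        self.sigma_a_prime = np.exp(log_sap)[:, 0]
        self.sigma_d = np.exp(log_sd)[:, 0]
        self.diagnostics = {
            "presence": presence.diagnostics(),
            "coresidence": coresidence.diagnostics(),
        }

    def dyad_effects(self, max_draws: int = 200) -> np.ndarray:
        """Conditional posterior means of d_ij on a thinned draw subset."""
        flat = self.raw_coresidence.flat
        step = max(1, flat.shape[0] // max_draws)
        return self.model._coresidence.conditional_dyad_effects(flat[::step])

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        return srm_summary(self, level=level)


def _age_of_label(label: str) -> str:
    for age in AGE_CLASS_LABELS:
        if age in label:
            return age
    return "other"


def srm_summary(results: SRMResults, level: float = 0.90) -> pd.DataFrame:
    """Interval table for category effects, clustered by age class.

    One row per category effect in each submodel, with the per-category
    observation count, posterior median, and central credible interval.
    """
    from .tolerance import equal_tailed_interval

    counts = results.obs.category_counts().set_index(["effect", "category"])["n_obs"]
    rows = []
    for effect, labels, draws in (
        ("presence", results.obs.ind_cat_labels, results.presence_effects),
        ("coresidence", results.obs.dyad_cat_labels, results.coresidence_effects),
    ):
        lo, hi = equal_tailed_interval(draws, level)
        med = np.median(draws, axis=0)
        for j, lab in enumerate(labels):
            rows.append(
                {
                    "effect": effect,
                    "age_class": _age_of_label(lab),
                    "category": lab,
                    "median": med[j],
                    "lower": lo[j],
                    "upper": hi[j],
                    "n_obs": int(counts.get((effect, lab), 0)),
                }
            )
    frame = pd.DataFrame(rows)
    age_order = {a: i for i, a in enumerate(AGE_CLASS_LABELS)}
    age_order["other"] = len(age_order)
    return (
        frame.sort_values(
            ["effect", "age_class", "category"],
            key=lambda s: s.map(age_order) if s.name == "age_class" else s,
        ).reset_index(drop=True)
    )


# --------------------------------------------------------------------------
# direct-law simulator for parameter recovery
# --------------------------------------------------------------------------


def simulate_srm_observations(
    n_individuals: int = 20,
    n_scans: int = 60,
    intercept_presence: float = -0.5,
    intercept_coresidence: float = -1.0,
    presence_effects: Mapping[str, float] | None = None,
    coresidence_effects: Mapping[str, float] | None = None,
    sigma_a: float = 1.0,
    sigma_a_prime: float = 0.5,
    sigma_d: float = 0.5,
    seed: int = 0,
) -> tuple[DyadObservations, dict]:
    """Draw SRM observations directly from the model law (known truth).

    Individuals are assigned sex/age classes round-robin over a fixed
    catalogue (adult and juvenile/adolescent males and females, some adult
    females with dependent infants), so every default category receives
    members. Presence and coresidence channels are drawn independently
    from their respective logistic laws, which is exactly the structure
    the estimator assumes; use :func:`cofeed.simulate.generate_identities`
    for design-level (scan-sampling) data instead.
    """
    rng = np.random.default_rng(seed)
    catalogue = [
        ("female", "adult_13plus", True),
        ("female", "adult_13plus", False),
        ("male", "adult_13plus", False),
        ("male", "adolescent_9_12", False),
        ("female", "juvenile_5_8", False),
        ("male", "juvenile_5_8", False),
    ]
    infos = [catalogue[i % len(catalogue)] for i in range(n_individuals)]
    ids = [f"i{k + 1:03d}" for k in range(n_individuals)]

    ind_cats = sorted({lab for info in infos for lab in individual_categories(*info)})
    pe = {lab: 0.0 for lab in ind_cats}
    pe.update(presence_effects or {})
    dyad_pairs = [(i, j) for i in range(n_individuals) for j in range(i + 1, n_individuals)]
    dyad_cat_maps = [dyad_categories(infos[i], infos[j]) for i, j in dyad_pairs]
    dyad_cats = sorted({lab for m in dyad_cat_maps for lab in m})
    ce = {lab: 0.0 for lab in dyad_cats}
    ce.update(coresidence_effects or {})

    a = sigma_a * rng.standard_normal(n_individuals)
    ap = sigma_a_prime * rng.standard_normal(n_individuals)
    d = sigma_d * rng.standard_normal(len(dyad_pairs))

    ind_X = np.zeros((n_individuals, len(ind_cats)))
    for k, info in enumerate(infos):
        for lab, val in individual_categories(*info).items():
            ind_X[k, ind_cats.index(lab)] = val
    eta_i = intercept_presence + ind_X @ np.array([pe[lab] for lab in ind_cats]) + a
    ind_y = rng.binomial(n_scans, special.expit(eta_i))

    dyad_X = np.zeros((len(dyad_pairs), len(dyad_cats)))
    for r, m in enumerate(dyad_cat_maps):
        for lab, val in m.items():
            dyad_X[r, dyad_cats.index(lab)] = val
    i_idx = np.array([i for i, _ in dyad_pairs])
    j_idx = np.array([j for _, j in dyad_pairs])
    eta_d = (
        intercept_coresidence
        + dyad_X @ np.array([ce[lab] for lab in dyad_cats])
        + ap[i_idx]
        + ap[j_idx]
        + d
    )
    dyad_y = rng.binomial(n_scans, special.expit(eta_d))

    obs = DyadObservations(
        ids=ids,
        ind_cat_labels=ind_cats,
        ind_block_of=np.arange(n_individuals),
        ind_X=ind_X,
        ind_y=ind_y,
        ind_trials=np.full(n_individuals, n_scans),
        dyads=np.array(dyad_pairs, dtype=int),
        dyad_cat_labels=dyad_cats,
        dyad_block_of=np.arange(len(dyad_pairs)),
        dyad_X=dyad_X,
        dyad_y=dyad_y,
        dyad_trials=np.full(len(dyad_pairs), n_scans),
        n_individual_obs=n_individuals * n_scans,
        n_dyadic_obs=len(dyad_pairs) * n_scans,
    )
    truth = {
        "sigma_a": sigma_a,
        "sigma_a_prime": sigma_a_prime,
        "sigma_d": sigma_d,
        "a": a,
        "a_prime": ap,
        "d": d,
        "presence_effects": pe,
        "coresidence_effects": ce,
        "intercepts": (intercept_presence, intercept_coresidence),
        "seed": seed,
    }
    return obs, truth


def fit_srm(
    obs: DyadObservations, spec: SRMSpec | None = None, seed: int | None = None
) -> SRMResults:
    """One-call SRM fit (see :class:`SocialRelationsModel`)."""
    return SocialRelationsModel(obs, spec=spec).fit(seed=seed)
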