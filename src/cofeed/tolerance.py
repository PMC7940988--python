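"""Hierarchical Bayesian model of maximal cofeeding tolerance.

The estimand theta[g, y] is the *maximal* (initial) cofeeding tolerance of
group g in year y: the probability that an at-risk individual is in the
food zone before any of the resource has been consumed. Scan counts k_j in
a session are Binomial(n_at_risk, theta * r_j), where r_j is the remaining
resource fraction implied by the attendance observed before scan j (see
:mod:`cofeed.depletion`). On the logit scale,

    logit theta[g, y] = alpha + u_g + X[g, y] . beta(_g) + v_{g, y}

with group effects u_g ~ Normal(0, sigma_g), group-year effects
v_{g,y} ~ Normal(0, sigma_gy), and optional demographic covariate effects
that are either shared across groups ("between" specification) or
group-specific random vectors beta_g ~ Normal(beta_bar, tau) ("within"
specification). Covariates enter jointly with the depletion likelihood, so
theta uncertainty propagates into the effect estimates.

Sampling uses a non-centered parameterization throughout, with scale
parameters on the log scale (half-Normal priors plus the log Jacobian).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import depletion
from .demography import COVARIATE_NAMES, ValidationError
from .sampler import EnsembleDraws, SamplerSettings, run_ensemble, spread_init
from .scans import SessionScans, cell_index

EFFECTS_MODES = ("none", "between", "within")


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceeded their thresholds; results carry the flag."""


class CollinearityWarning(UserWarning):
    """Covariate design carries no usable variation for some coefficients."""


@dataclasses.dataclass
class ToleranceModelSpec:
    """Model structure, priors, and sampler budget.

    ``theta_prior``: "hierarchical" is the study model; "flat" replaces the
    hierarchy with an independent Uniform(0, 1) prior on each cell's theta
    (useful for conjugate checks and single-cell fits).
    """

    depletion_rule: str = "exponential"
    estimate_kappa: bool = True
    kappa_per_group: bool = False
    fixed_kappa: float = 0.0
    theta_prior: str = "hierarchical"
    prior_alpha_sd: float = 1.5
    prior_sigma_sd: float = 1.0
    prior_kappa_sd: float = 1.0
    prior_beta_sd: float = 1.0
    prior_tau_sd: float = 1.0
    sampler: SamplerSettings = dataclasses.field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if self.depletion_rule not in depletion.DEPLETION_RULES:
            raise ValueError(f"unknown depletion rule {self.depletion_rule!r}")
        if self.theta_prior not in ("hierarchical", "flat"):
            raise ValueError(f"unknown theta prior {self.theta_prior!r}")
        if self.fixed_kappa < 0:
            raise ValueError("fixed_kappa must be >= 0")
        for name in ("prior_alpha_sd", "prior_sigma_sd", "prior_kappa_sd",
                     "prior_beta_sd", "prior_tau_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class CofeedingToleranceModel:
    """Joint depletion + tolerance (+ covariate) model over scan sessions.

    Parameters
    ----------
    sessions
        Validated :class:`~cofeed.scans.SessionScans`; at least one.
    covariates
        Group-year covariate table from
        :func:`cofeed.demography.build_covariates`. Required when
        ``effects != "none"``; must cover every fitted cell.
    effects
        "none" (intercept-only hierarchy), "between" (single shared
        coefficient vector), or "within" (group-specific coefficient
        vectors with a population mean).
    """

    def __init__(
        self,
        sessions: Sequence[SessionScans],
        covariates: pd.DataFrame | None = None,
        effects: str = "none",
        covariate_names: Sequence[str] = COVARIATE_NAMES,
        spec: ToleranceModelSpec | None = None,
    ) -> None:
        if not sessions:
            raise ValidationError("no sessions supplied")
        if effects not in EFFECTS_MODES:
            raise ValueError(f"effects must be one of {EFFECTS_MODES}")
        self.spec = spec or ToleranceModelSpec()
        self.effects = effects
        self.covariate_names = tuple(covariate_names)
        self.sessions = list(sessions)

        self.cells, self._cell_of_session = cell_index(self.sessions)
        self.groups = sorted({g for g, _ in self.cells})
        self.years = sorted({y for _, y in self.cells})
        self._group_of_cell = np.array(
            [self.groups.index(g) for g, _ in self.cells], dtype=int
        )

        self._build_count_arrays()
        self._build_design(covariates)
        self._layout()

    # ------------------------------------------------------------------ data
    def _build_count_arrays(self) -> None:
        S = len(self.sessions)
        jmax = max(s.n_scans for s in self.sessions)
        self._K = np.zeros((S, jmax))
        self._NmK = np.zeros((S, jmax))
        self._C = np.zeros((S, jmax))
        const = 0.0
        any_depleting = False
        for i, s in enumerate(self.sessions):
            j = s.n_scans
            k = np.asarray(s.counts, dtype=float)
            self._K[i, :j] = k
            self._NmK[i, :j] = s.n_at_risk - k
            depleting = s.assay != "juice_pipe" and self.spec.depletion_rule != "none"
            if depleting:
                any_depleting = True
                self._C[i, :j] = depletion.cumulative_consumption(s.counts, s.n_at_risk)
            n = float(s.n_at_risk)
            const += float(
                np.sum(
                    special.gammaln(n + 1)
                    - special.gammaln(k + 1)
                    - special.gammaln(n - k + 1)
                )
            )
        self._loglik_const = const
        # kappa enters the likelihood only through depleting sessions
        self.has_kappa = (
            self.spec.estimate_kappa
            and any_depleting
            and self.spec.depletion_rule != "none"
        )

    def _build_design(self, covariates: pd.DataFrame | None) -> None:
        if self.effects == "none":
            self._X = None
            self.covariates = covariates
            return
        if covariates is None:
            raise ValidationError("covariate effects requested but no covariate table given")
        self.covariates = covariates
        keyed = covariates.set_index(["group", "year"])
        rows = []
        for g, y in self.cells:
            try:
                rec = keyed.loc[(g, y)]
            except KeyError:
                raise ValidationError(f"no covariate record for group {g!r}, year {y}")
            rows.append([float(rec[name + "_z"]) for name in self.covariate_names])
        X = np.asarray(rows, dtype=float)
        if self.effects == "within":
            # group-mean centering: group-specific coefficients see only
            # within-group covariate *change*, so stable between-group
            # differences cannot leak into the within-group effects
            for gi in range(len(self.groups)):
                mask = self._group_of_cell == gi
                X[mask] -= X[mask].mean(axis=0)
        self._X = X
        self._check_collinearity()

    def _check_collinearity(self) -> None:
        X = self._X
        degenerate = []
        for j, name in enumerate(self.covariate_names):
            if self.effects == "within":
                # usable only if some group shows within-group variation
                ok = any(
                    np.ptp(X[self._group_of_cell == gi, j]) > 1e-12
                    for gi in range(len(self.groups))
                )
            else:
                ok = np.ptp(X[:, j]) > 1e-12
            if not ok:
                degenerate.append(name)
        if degenerate:
            kind = "within-group" if self.effects == "within" else "between-cell"
            warnings.warn(
                f"covariate column(s) {degenerate} carry no {kind} variation; "
                "their coefficients will be prior-dominated",
                CollinearityWarning,
                stacklevel=3,
            )

    # -------------------------------------------------------------- parameters
    def _layout(self) -> None:
        ncells, G = len(self.cells), len(self.groups)
        p = len(self.covariate_names)
        idx: dict[str, slice] = {}
        pos = 0

        def take(name: str, size: int) -> None:
            nonlocal pos
            idx[name] = slice(pos, pos + size)
            pos += size

        if self.spec.theta_prior == "flat":
            take("eta", ncells)
        else:
            take("alpha", 1)
            take("log_sigma_g", 1)
            take("log_sigma_gy", 1)
            take("z_g", G)
            take("z_gy", ncells)
            if self.effects == "between":
                take("beta", p)
            elif self.effects == "within":
                take("beta_bar", p)
                take("log_tau", p)
                take("z_beta", G * p)
        if self.has_kappa:
            take("log_kappa", G if self.spec.kappa_per_group else 1)
        self._idx = idx
        self.ndim = pos

    def _eta(self, P: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
        """(W, ndim) -> logit theta per cell, (W, ncells).

        ``X`` overrides the fitted design matrix (used by counterfactual
        prediction); the computation path is otherwise identical, so an
        unmodified ``X`` reproduces the factual draws bit-exactly.
        """
        idx = self._idx
        if self.spec.theta_prior == "flat":
            return P[:, idx["eta"]]
        if X is None:
            X = self._X
        alpha = P[:, idx["alpha"]]
        sg = np.exp(P[:, idx["log_sigma_g"]])
        sgy = np.exp(P[:, idx["log_sigma_gy"]])
        zg = P[:, idx["z_g"]]
        zc = P[:, idx["z_gy"]]
        eta = alpha + sg * zg[:, self._group_of_cell] + sgy * zc
        if self.effects == "between":
            eta = eta + P[:, idx["beta"]] @ X.T
        elif self.effects == "within":
            beta_g = self._beta_g(P)  # (W, G, p)
            per_group = np.einsum("wgp,cp->wgc", beta_g, X)
            eta = eta + np.take_along_axis(
                per_group, self._group_of_cell[None, None, :], axis=1
            )[:, 0, :]
        return eta

    def _beta_g(self, P: np.ndarray) -> np.ndarray:
        idx = self._idx
        G, p = len(self.groups), len(self.covariate_names)
        bbar = P[:, idx["beta_bar"]]
        tau = np.exp(P[:, idx["log_tau"]])
        zb = P[:, idx["z_beta"]].reshape(-1, G, p)
        return bbar[:, None, :] + tau[:, None, :] * zb

    # -------------------------------------------------------------- posterior
    def _log_prior(self, P: np.ndarray) -> np.ndarray:
        idx = self._idx
        spec = self.spec
        lp = np.zeros(P.shape[0])
        if spec.theta_prior == "flat":
            eta = P[:, idx["eta"]]
            # Uniform(0,1) on theta => log|d theta / d eta|
            lp += np.sum(special.log_expit(eta) + special.log_expit(-eta), axis=1)
        else:
            lp += -0.5 * np.sum((P[:, idx["alpha"]] / spec.prior_alpha_sd) ** 2, axis=1)
            for name in ("log_sigma_g", "log_sigma_gy"):
                ls = P[:, idx[name]]
                s = np.exp(ls)
                lp += np.sum(-0.5 * (s / spec.prior_sigma_sd) ** 2 + ls, axis=1)
            lp += -0.5 * np.sum(P[:, idx["z_g"]] ** 2, axis=1)
            lp += -0.5 * np.sum(P[:, idx["z_gy"]] ** 2, axis=1)
            if self.effects == "between":
                lp += -0.5 * np.sum((P[:, idx["beta"]] / spec.prior_beta_sd) ** 2, axis=1)
            elif self.effects == "within":
                lp += -0.5 * np.sum(
                    (P[:, idx["beta_bar"]] / spec.prior_beta_sd) ** 2, axis=1
                )
                lt = P[:, idx["log_tau"]]
                t = np.exp(lt)
                lp += np.sum(-0.5 * (t / spec.prior_tau_sd) ** 2 + lt, axis=1)
                lp += -0.5 * np.sum(P[:, idx["z_beta"]] ** 2, axis=1)
        if self.has_kappa:
            lk = P[:, idx["log_kappa"]]
            kap = np.exp(lk)
            lp += np.sum(-0.5 * (kap / spec.prior_kappa_sd) ** 2 + lk, axis=1)
        return lp

    def _log_lik(self, P: np.ndarray) -> np.ndarray:
        theta = special.expit(self._eta(P))  # (W, ncells)
        theta_s = theta[:, self._cell_of_session][:, :, None]  # (W, S, 1)
        if self.has_kappa:
            kap = np.exp(P[:, self._idx["log_kappa"]])  # (W, 1) or (W, G)
            if self.spec.kappa_per_group:
                g_of_s = self._group_of_cell[self._cell_of_session]
                kappa = kap[:, g_of_s][:, :, None]  # (W, S, 1)
            else:
                kappa = kap[:, :, None]  # (W, 1, 1)
        else:
            kappa = self.spec.fixed_kappa
        if self.spec.depletion_rule == "linear_floor":
            r = np.clip(1.0 - kappa * self._C[None, :, :], 0.0, 1.0)
        else:  # exponential (C is zero for constant-resource sessions)
            r = np.exp(-kappa * self._C[None, :, :])
        p = theta_s * r
        ll = special.xlogy(self._K[None, :, :], p) + special.xlog1py(
            self._NmK[None, :, :], -p
        )
        return ll.sum(axis=(1, 2)) + self._loglik_const

    def log_prob(self, P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        lp = self._log_prior(P)
        ok = np.isfinite(lp)
        out = np.full(P.shape[0], -np.inf)
        if np.any(ok):
            out[ok] = lp[ok] + self._log_lik(P[ok])
        return out

    def _init_center(self) -> np.ndarray:
        center = np.zeros(self.ndim)
        first_rate = np.array(
            [s.counts[0] / s.n_at_risk for s in self.sessions], dtype=float
        )
        a0 = special.logit(np.clip(first_rate.mean(), 0.05, 0.95))
        idx = self._idx
        if self.spec.theta_prior == "flat":
            center[idx["eta"]] = a0
        else:
            center[idx["alpha"]] = a0
            center[idx["log_sigma_g"]] = np.log(0.3)
            center[idx["log_sigma_gy"]] = np.log(0.3)
            if self.effects == "within":
                center[idx["log_tau"]] = np.log(0.3)
        if self.has_kappa:
            center[idx["log_kappa"]] = 0.0
        return center

    def fit(self, seed: int | None = None) -> "ToleranceResults":
        """Sample the posterior and return a results object."""
        settings = self.spec.sampler
        if seed is not None:
            settings = dataclasses.replace(settings, seed=int(seed))
        rng = np.random.default_rng(settings.seed)
        nwalkers = settings.walkers_for(self.ndim)
        init = spread_init(self._init_center(), nwalkers, rng)
        draws = run_ensemble(self.log_prob, init, settings)
        results = ToleranceResults(self, draws)
        if results.diagnostics["max_rhat"] > 1.01:
            warnings.warn(
                f"split-R-hat {results.diagnostics['max_rhat']:.3f} exceeds 1.01; "
                "treat interval summaries with caution",
                ConvergenceWarning,
                stacklevel=2,
            )
        return results


class ToleranceResults:
    """Posterior draws of theta[g, y], hyperparameters, and covariate effects.

    Draw arrays are flat over (kept step, walker). ``theta`` has one column
    per fitted group-year cell, ordered as ``model.cells``.
    """

    def __init__(self, model: CofeedingToleranceModel, raw: EnsembleDraws) -> None:
        self.model = model
        self.raw = raw
        flat = raw.flat
        idx = model._idx
        self.theta = special.expit(model._eta(flat))
        if model.has_kappa:
            kap = np.exp(flat[:, idx["log_kappa"]])
            # one shared column, or one per group when kappa varies by group
            self.kappa = kap[:, 0] if kap.shape[1] == 1 else kap
        else:
            self.kappa = None
        if model.spec.theta_prior == "hierarchical":
            self.alpha = flat[:, idx["alpha"]][:, 0]
            self.sigma_g = np.exp(flat[:, idx["log_sigma_g"]])[:, 0]
            self.sigma_gy = np.exp(flat[:, idx["log_sigma_gy"]])[:, 0]
            self.u = self.sigma_g[:, None] * flat[:, idx["z_g"]]
            self.v = self.sigma_gy[:, None] * flat[:, idx["z_gy"]]
        else:
            self.alpha = self.sigma_g = self.sigma_gy = self.u = self.v = None
        if model.effects == "between":
            self.beta = flat[:, idx["beta"]]
            self.beta_bar = self.beta
            self.beta_g = None
        elif model.effects == "within":
            self.beta_bar = flat[:, idx["beta_bar"]]
            self.beta_g = model._beta_g(flat)
            self.beta = None
        else:
            self.beta = self.beta_bar = self.beta_g = None
        self.diagnostics = raw.diagnostics()

    # ------------------------------------------------------------- accessors
    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def cells(self) -> list[tuple[str, int]]:
        return self.model.cells

    def theta_grid(self) -> np.ndarray:
        """Draws on a (n_draws, n_groups, n_years) grid; NaN where unobserved."""
        m = self.model
        out = np.full((self.n_draws, len(m.groups), len(m.years)), np.nan)
        for c, (g, y) in enumerate(m.cells):
            out[:, m.groups.index(g), m.years.index(y)] = self.theta[:, c]
        return out

    def ess_of(self, derived_flat: np.ndarray) -> float:
        """Bulk ESS of a scalar derived quantity given per-draw values."""
        import arviz as az

        from .sampler import _pseudo_chains

        steps, walkers, _ = self.raw.chain.shape
        shaped = derived_flat.reshape(steps, walkers, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(
                az.ess(az.convert_to_dataset(_pseudo_chains(shaped)))["x"].to_numpy()[0]
            )

    # ------------------------------------------------------------- summaries
    def summary(self, level: float = 0.90) -> pd.DataFrame:
        """Per group-year posterior median and equal-tailed credible interval."""
        return summarize_tolerance(self, level=level)

    def effect_summary(self, level: float = 0.90) -> pd.DataFrame:
        from .covariates import effect_summary

        return effect_summary(self, level=level)

    def decompose(self):
        from .variation import decompose

        return decompose(self)

    def counterfactual(self, scenario: Sequence[str] | str = "all", pin_to: float = 0.0):
        from .variation import counterfactual_predict

        return counterfactual_predict(self, scenario=scenario, pin_to=pin_to)

    def to_frame(self) -> pd.DataFrame:
        """Flat draw table (one column per cell theta plus hyperparameters)."""
        data = {
            f"theta[{g},{y}]": self.theta[:, c] for c, (g, y) in enumerate(self.cells)
        }
        if self.alpha is not None:
            data["alpha"] = self.alpha
            data["sigma_g"] = self.sigma_g
            data["sigma_gy"] = self.sigma_gy
        if self.kappa is not None:
            if self.kappa.ndim == 1:
                data["kappa"] = self.kappa
            else:
                for gi, g in enumerate(self.model.groups):
                    data[f"kappa[{g}]"] = self.kappa[:, gi]
        if self.beta is not None:
            for j, name in enumerate(self.model.covariate_names):
                data[f"beta[{name}]"] = self.beta[:, j]
        if self.beta_g is not None:
            for j, name in enumerate(self.model.covariate_names):
                data[f"beta_bar[{name}]"] = self.beta_bar[:, j]
                for gi, g in enumerate(self.model.groups):
                    data[f"beta[{g},{name}]"] = self.beta_g[:, gi, j]
        return pd.DataFrame(data)


def equal_tailed_interval(draws: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 < level < 1.0:
        raise ValueError(f"interval level must lie in (0, 1), got {level}")
    lo = (1.0 - level) / 2.0
    return (
        np.quantile(draws, lo, axis=0),
        np.quantile(draws, 1.0 - lo, axis=0),
    )


def summarize_tolerance(results: ToleranceResults, level: float = 0.90) -> pd.DataFrame:
    """Group-year table of posterior medians and central credible intervals."""
    lo, hi = equal_tailed_interval(results.theta, level)
    med = np.median(results.theta, axis=0)
    rows = [
        {
            "group": g,
            "year": y,
            "median": med[c],
            "lower": lo[c],
            "upper": hi[c],
            "level": level,
        }
        for c, (g, y) in enumerate(results.cells)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["group", "year"])
        .reset_index(drop=True)
    )


def fit_tolerance(
    sessions: Sequence[SessionScans],
    spec: ToleranceModelSpec | None = None,
    covariates: pd.DataFrame | None = None,
    effects: str = "none",
    seed: int | None = None,
) -> ToleranceResults:
    """One-call fit of the tolerance model (see :class:`CofeedingToleranceModel`)."""
    model = CofeedingToleranceModel(
        sessions, covariates=covariates, effects=effects, spec=spec
    )
    return model.fit(seed=seed)
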