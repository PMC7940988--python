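"""Variation decomposition, counterfactual prediction, and assay comparison.

These operations consume :class:`~cofeed.tolerance.ToleranceResults` draws.
The decomposition asks where tolerance varies more: across groups within a
year, or across years within a group. Counterfactual prediction pins
selected demographic covariates at a reference value (the grand mean, 0 on
the standardized scale) and recomputes theta draw by draw, keeping the
group effects u_g and residuals v_{g,y} at their posterior values — an
intervention on composition only, which shows how much of the inter-group
spread demography accounts for.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demography import ValidationError
from .simulate import ConfigError
from .tolerance import ToleranceResults, equal_tailed_interval


@dataclasses.dataclass
class VariationSummary:
    """Draw-aligned SDs of theta across groups (per year) and years (per group).

    ``pr_contrast_positive`` is the posterior probability that the mean
    within-year across-group SD exceeds the mean within-group across-year
    SD; draws where the contrast is exactly zero count half (so a
    completely degenerate posterior reports 0.5).
    """

    years: list[int]
    groups: list[str]
    across_group_sd: np.ndarray  # (ndraws, n_years)
    across_year_sd: np.ndarray  # (ndraws, n_groups)
    contrast: np.ndarray  # (ndraws,)
    pr_contrast_positive: float

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        rows = []
        for j, y in enumerate(self.years):
            lo, hi = equal_tailed_interval(self.across_group_sd[:, j], level)
            rows.append(
                {"scope": "year", "label": y, "median": np.median(self.across_group_sd[:, j]),
                 "lower": float(lo), "upper": float(hi)}
            )
        for i, g in enumerate(self.groups):
            lo, hi = equal_tailed_interval(self.across_year_sd[:, i], level)
            rows.append(
                {"scope": "group", "label": g, "median": np.median(self.across_year_sd[:, i]),
                 "lower": float(lo), "upper": float(hi)}
            )
        lo, hi = equal_tailed_interval(self.contrast, level)
        rows.append(
            {"scope": "contrast", "label": "inter-group minus intra-group",
             "median": np.median(self.contrast), "lower": float(lo), "upper": float(hi)}
        )
        return pd.DataFrame(rows)


def _sd(values: np.ndarray, axis: int) -> np.ndarray:
    # sample SD over the cells present (NaN marks unobserved cells)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(values, axis=axis, ddof=1)


def decompose(results: ToleranceResults) -> VariationSummary:
    """Across-group vs across-year variation in maximal cofeeding tolerance."""
    grid = results.theta_grid()  # (ndraws, G, Y)
    _, G, Y = grid.shape
    if G < 2 or Y < 2:
        raise ValidationError("decomposition needs at least 2 groups and 2 years")
    across_group = _sd(grid, axis=1)  # (ndraws, Y)
    across_year = _sd(grid, axis=2)  # (ndraws, G)
    contrast = np.nanmean(across_group, axis=1) - np.nanmean(across_year, axis=1)
    pr = float(np.mean(contrast > 0) + 0.5 * np.mean(contrast == 0))
    return VariationSummary(
        years=list(results.model.years),
        groups=list(results.model.groups),
        across_group_sd=across_group,
        across_year_sd=across_year,
        contrast=contrast,
        pr_contrast_positive=pr,
    )


@dataclasses.dataclass
class CounterfactualResult:
    """Counterfactual theta draws with covariates pinned to a reference value."""

    pinned: list[str]
    pin_to: float
    theta_factual: np.ndarray  # (ndraws, ncells)
    theta_counterfactual: np.ndarray
    cells: list[tuple[str, int]]
    groups: list[str]
    between_sd_factual: np.ndarray  # (ndraws,)
    between_sd_counterfactual: np.ndarray

    @property
    def attenuation_ratio(self) -> float:
        """Posterior-mean between-group SD, counterfactual over factual."""
        denom = float(np.mean(self.between_sd_factual))
        if denom == 0.0:
            return 1.0
        return float(np.mean(self.between_sd_counterfactual)) / denom

    def group_means(self, counterfactual: bool = True) -> pd.DataFrame:
        theta = self.theta_counterfactual if counterfactual else self.theta_factual
        gidx = {g: [c for c, (gg, _) in enumerate(self.cells) if gg == g] for g in self.groups}
        rows = []
        for g, cols in gidx.items():
            m = theta[:, cols].mean(axis=1)
            lo, hi = equal_tailed_interval(m, 0.90)
            rows.append({"group": g, "mean": float(np.mean(m)), "lower": float(lo), "upper": float(hi)})
        return pd.DataFrame(rows)


def counterfactual_predict(
    results: ToleranceResults,
    scenario: Sequence[str] | str = "all",
    pin_to: float = 0.0,
) -> CounterfactualResult:
    """Recompute theta draws with selected covariates pinned.

    ``scenario`` is "all", or a list of covariate names to pin (an empty
    list is the identity and returns the factual draws bit-exactly). Group
    random effects and group-year residuals stay at their posterior draws.
    """
    model = results.model
    if model.effects == "none" or model._X is None:
        raise ValidationError("counterfactual prediction needs a covariate model")
    names = list(model.covariate_names)
    if isinstance(scenario, str):
        pinned = names if scenario == "all" else [scenario]
    else:
        pinned = list(scenario)
    unknown = [n for n in pinned if n not in names]
    if unknown:
        raise ConfigError(f"scenario names unknown covariate(s) {unknown}")
    X_cf = model._X.copy()
    for n in pinned:
        X_cf[:, names.index(n)] = pin_to
    from scipy import special

    flat = results.raw.flat
    theta_cf = special.expit(model._eta(flat, X=X_cf))
    theta_f = results.theta

    def between_sd(theta: np.ndarray) -> np.ndarray:
        gmeans = []
        for g in model.groups:
            cols = [c for c, (gg, _) in enumerate(model.cells) if gg == g]
            gmeans.append(theta[:, cols].mean(axis=1))
        return np.std(np.column_stack(gmeans), axis=1, ddof=1)

    return CounterfactualResult(
        pinned=pinned,
        pin_to=pin_to,
        theta_factual=theta_f,
        theta_counterfactual=theta_cf,
        cells=list(model.cells),
        groups=list(model.groups),
        between_sd_factual=between_sd(theta_f),
        between_sd_counterfactual=between_sd(theta_cf),
    )


@dataclasses.dataclass
class AssayComparison:
    """Rank agreement and precision of two assays over the same groups."""

    year: int
    groups: list[str]
    ranking_probs: dict[tuple[str, ...], float]  # most-to-least tolerant
    kendall_tau: float
    width_ratio: float  # mean 90% interval width, second assay / first
    median_first: np.ndarray
    median_second: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = [
            {"ordering": " > ".join(order), "probability": p}
            for order, p in sorted(
                self.ranking_probs.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(rows)


def _year_theta(results: ToleranceResults, year: int) -> np.ndarray:
    cols = {g: c for c, (g, y) in enumerate(results.cells) if y == year}
    return np.column_stack([results.theta[:, cols[g]] for g in results.model.groups])


def compare_assays(
    results_first: ToleranceResults,
    results_second: ToleranceResults,
    year: int | None = None,
    level: float = 0.90,
) -> AssayComparison:
    """Compare group tolerance estimates from two assays in a common year.

    Typical use: ``results_first`` from the depleting assay (peanut swing),
    ``results_second`` from the constant-resource assay (juice pipe).
    """
    g1, g2 = results_first.model.groups, results_second.model.groups
    if g1 != g2:
        raise ValidationError(f"group sets differ between assays: {g1} vs {g2}")
    common_years = sorted(
        set(results_first.model.years) & set(results_second.model.years)
    )
    if year is None:
        if not common_years:
            raise ValidationError("assays share no common year")
        year = common_years[-1]
    elif year not in common_years:
        raise ValidationError(f"year {year} not present in both posteriors")

    th1 = _year_theta(results_first, year)
    th2 = _year_theta(results_second, year)
    groups = list(g1)

    order_counts: dict[tuple[str, ...], int] = {}
    both = np.vstack([th1, th2])
    order_idx = np.argsort(-both, axis=1)
    for row in order_idx:
        key = tuple(groups[i] for i in row)
        order_counts[key] = order_counts.get(key, 0) + 1
    total = both.shape[0]
    ranking_probs = {k: v / total for k, v in order_counts.items()}

    med1, med2 = np.median(th1, axis=0), np.median(th2, axis=0)
    tau = float(stats.kendalltau(med1, med2).statistic)

    def mean_width(th: np.ndarray) -> float:
        lo, hi = equal_tailed_interval(th, level)
        return float(np.mean(hi - lo))

    w1, w2 = mean_width(th1), mean_width(th2)
    return AssayComparison(
        year=year,
        groups=groups,
        ranking_probs=ranking_probs,
        kendall_tau=tau,
        width_ratio=w2 / w1 if w1 > 0 else np.inf,
        median_first=med1,
        median_second=med2,
    )
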