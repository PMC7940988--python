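"""Demographic effect estimation: within-group and between-group models.

Both specifications estimate how standardized demographic covariates shift
logit maximal cofeeding tolerance, jointly with the depletion likelihood.
The within-group model gives each group its own coefficient vector
beta_g ~ Normal(beta_bar, tau) whose population mean beta_bar summarizes
effects of covariate *change within* groups; the between-group model shares
one vector across groups, so it can pick up effects carried by stable
*differences among* groups (group random intercepts are retained in both).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .tolerance import (
    CofeedingToleranceModel,
    ToleranceModelSpec,
    ToleranceResults,
    equal_tailed_interval,
)


def fit_within_group(
    sessions,
    covariates: pd.DataFrame,
    spec: ToleranceModelSpec | None = None,
    seed: int | None = None,
) -> ToleranceResults:
    """Fit the multi-level model with group-specific coefficient vectors."""
    model = CofeedingToleranceModel(
        sessions, covariates=covariates, effects="within", spec=spec
    )
    return model.fit(seed=seed)


def fit_between_group(
    sessions,
    covariates: pd.DataFrame,
    spec: ToleranceModelSpec | None = None,
    seed: int | None = None,
) -> ToleranceResults:
    """Fit the model with a single coefficient vector shared across groups."""
    model = CofeedingToleranceModel(
        sessions, covariates=covariates, effects="between", spec=spec
    )
    return model.fit(seed=seed)


def _summary_rows(
    draws: np.ndarray, names: Sequence[str], scope: str, level: float
) -> list[dict]:
    lo, hi = equal_tailed_interval(draws, level)
    med = np.median(draws, axis=0)
    pr_pos = np.mean(draws > 0, axis=0) + 0.5 * np.mean(draws == 0, axis=0)
    return [
        {
            "covariate": name,
            "scope": scope,
            "median": med[j],
            "lower": lo[j],
            "upper": hi[j],
            "pr_positive": pr_pos[j],
        }
        for j, name in enumerate(names)
    ]


def effect_summary(results: ToleranceResults, level: float = 0.90) -> pd.DataFrame:
    """Covariate-effect table: one row per covariate per group plus 'overall'.

    ``pr_positive`` is the posterior probability that the effect is
    positive (draws exactly at zero count half).
    """
    model = results.model
    if model.effects == "none":
        raise ValueError("model was fitted without covariate effects")
    names = list(model.covariate_names)
    rows: list[dict] = []
    if model.effects == "within":
        for gi, g in enumerate(model.groups):
            rows += _summary_rows(results.beta_g[:, gi, :], names, g, level)
        rows += _summary_rows(results.beta_bar, names, "overall", level)
    else:
        rows += _summary_rows(results.beta, names, "overall", level)
    out = pd.DataFrame(rows)
    out["level"] = level
    # deterministic ordering: covariates in design order, groups then overall
    scope_order = {g: i for i, g in enumerate(model.groups)}
    scope_order["overall"] = len(model.groups)
    out = out.sort_values(
        ["covariate", "scope"],
        key=lambda s: s.map(
            {n: i for i, n in enumerate(names)} if s.name == "covariate" else scope_order
        ),
    ).reset_index(drop=True)
    return out
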