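"""Within-session resource depletion and the scan-count likelihood.

The probability that an individual is in the food zone at scan j is the
product of the group-year's maximal (initial) cofeeding tolerance theta and
the remaining resource fraction r_j. The resource trajectory is driven by
the realized attendance counts observed before each scan (a plug-in rule):

    exponential:  r_1 = 1,  r_{j+1} = r_j * exp(-kappa * k_j / n_at_risk)
    linear_floor: r_1 = 1,  r_{j+1} = max(0, r_j - kappa * k_j / n_at_risk)
    none:         r_j = 1  (constant resource, e.g. the juice-pipe assay)

Scan counts are conditionally independent Binomial(n_at_risk, theta * r_j)
given the trajectory.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import special

DEPLETION_RULES = ("exponential", "linear_floor", "none")


def cumulative_consumption(counts: Sequence[int], n_at_risk: int) -> np.ndarray:
    """Per-capita attendance accumulated before each scan (first entry 0)."""
    k = np.asarray(counts, dtype=float)
    out = np.zeros(k.shape[-1])
    out[1:] = np.cumsum(k[:-1]) / float(n_at_risk)
    return out


def resource_trajectory(
    counts: Sequence[int],
    n_at_risk: int,
    kappa: float,
    rule: str = "exponential",
) -> np.ndarray:
    """Remaining resource fraction at each scan, plus the post-session state.

    Returns ``len(counts) + 1`` values: r_1 = 1 applies to the first scan,
    each subsequent entry is the fraction left after the preceding scan's
    attendance, and the final entry is the state after the last scan. The
    trajectory is monotonically non-increasing and stays in [0, 1].
    """
    if rule not in DEPLETION_RULES:
        raise ValueError(f"unknown depletion rule {rule!r}; expected one of {DEPLETION_RULES}")
    if kappa < 0:
        raise ValueError(f"depletion rate kappa must be >= 0, got {kappa}")
    if n_at_risk < 1:
        raise ValueError("n_at_risk must be >= 1")
    k = np.asarray(counts)
    if np.any(k < 0):
        raise ValueError("scan counts must be non-negative")
    c = np.append(
        cumulative_consumption(counts, n_at_risk), np.sum(k) / float(n_at_risk)
    )
    if rule == "none":
        return np.ones_like(c)
    if rule == "exponential":
        return np.exp(-kappa * c)
    return np.clip(1.0 - kappa * c, 0.0, 1.0)


def binomial_loglik(counts, n_at_risk, p) -> np.ndarray:
    """Elementwise Binomial log-pmf, safe at p in {0, 1}."""
    k = np.asarray(counts, dtype=float)
    n = float(n_at_risk)
    const = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    p = np.asarray(p, dtype=float)
    return const + special.xlogy(k, p) + special.xlog1py(n - k, -p)


def session_loglik(
    session,
    theta: float,
    kappa: float = 0.0,
    rule: str = "exponential",
) -> float:
    """Log-probability of one session's scan counts given theta and kappa.

    theta is the maximal cofeeding tolerance (the zone-occupancy probability
    before any depletion); it must lie strictly inside (0, 1).
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in the open interval (0, 1), got {theta}")
    effective_rule = "none" if session.assay == "juice_pipe" else rule
    r = resource_trajectory(session.counts, session.n_at_risk, kappa, effective_rule)
    r = r[: len(session.counts)]  # the post-session state carries no likelihood
    return float(np.sum(binomial_loglik(session.counts, session.n_at_risk, theta * r)))
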