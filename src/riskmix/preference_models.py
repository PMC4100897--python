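"""Deterministic preference functionals: CRRA utility, EUT and RDU values.

Two CRRA variants coexist deliberately.  The literal form u(x) = x^(1-r)/(1-r)
is what the likelihoods use, so estimated (r, mu) stay on the scale on which
such models are conventionally reported.  The normalized form
(x^(1-r) - 1)/(1-r) differs by an affine shift that leaves all utility
*differences* (hence indifference points) unchanged but is continuous through
r = 1; it backs the crossover computation in :mod:`riskmix.task_design` and is
exposed here for completeness.

Rank-dependent utility (RDU) replaces outcome probabilities with decision
weights built from the inverse-S weighting function
w(p) = p^g / (p^g + (1-p)^g)^(1/g); g = 1 recovers expected utility exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .task_design import Lottery

__all__ = [
    "PreferenceParams",
    "crra_utility",
    "crra_utility_normalized",
    "tk_weight",
    "eut_value",
    "decision_weights",
    "rdu_value",
]

#: half-width of the r-neighbourhood of 1 in which the log limit is used
R_ONE_TOL = 1e-6


@dataclass(frozen=True)
class PreferenceParams:
    """Risk-preference parameters: CRRA coefficient r and weighting curvature gamma.

    gamma = 1 means linear weighting, i.e. expected utility.
    """

    r: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DomainError(f"gamma must be positive, got {self.gamma}")


def crra_utility(x, r: float):
    """CRRA utility x^(1-r)/(1-r); the log limit is substituted within 1e-6 of r=1.

    Accepts scalars or arrays; prizes must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("CRRA utility requires strictly positive prizes")
    if abs(1.0 - r) <= R_ONE_TOL:
        out = np.log(x)
    else:
        out = x ** (1.0 - r) / (1.0 - r)
    return out if out.ndim else float(out)


def crra_utility_normalized(x, r: float):
    """Normalized CRRA (x^(1-r) - 1)/(1-r), continuous through r = 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("CRRA utility requires strictly positive prizes")
    if abs(1.0 - r) <= R_ONE_TOL:
        out = np.log(x)
    else:
        out = (x ** (1.0 - r) - 1.0) / (1.0 - r)
    return out if out.ndim else float(out)


def tk_weight(p, gamma: float):
    """Inverse-S probability weighting w(p) = p^g / (p^g + (1-p)^g)^(1/g).

    w(0) = 0 and w(1) = 1 for every gamma > 0; gamma = 1 is the identity.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be positive, got {gamma}")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    # evaluated in log space so extreme gamma cannot overflow p**gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
        log_den = np.logaddexp(gamma * log_p, gamma * log_q) / gamma
        w = np.exp(gamma * log_p - log_den)
    out = np.where(p == 0.0, 0.0, np.where(p == 1.0, 1.0, w))
    return out if out.ndim else float(out)


def eut_value(lottery: Lottery, params: PreferenceParams) -> float:
    """Expected utility: sum of p_i * u(x_i) under CRRA with coefficient r."""
    u = crra_utility(np.asarray(lottery.prizes), params.r)
    return float(np.dot(lottery.probabilities, u))


def _merge_ties(probs: np.ndarray, prizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # collapse equal prizes so ranking is well defined; a one-outcome lottery
    # then bypasses weighting entirely (w(1) = 1)
    uniq, inv = np.unique(prizes, return_inverse=True)
    merged = np.zeros_like(uniq)
    np.add.at(merged, inv, probs)
    return merged, uniq


def decision_weights(lottery: Lottery, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Rank-dependent decision weights and the correspondingly ordered prizes.

    Outcomes are ranked best to worst; the weight on the k-th best outcome is
    w(P(at least as good as k)) - w(P(strictly better than k)).  Equal prizes
    within an option are merged before ranking, so a degenerate option gets
    the single weight w(1) = 1.  Returns ``(weights, prizes)``, best first.
    """
    probs, prizes = _merge_ties(
        np.asarray(lottery.probabilities, dtype=float),
        np.asarray(lottery.prizes, dtype=float),
    )
    order = np.argsort(prizes)[::-1]  # best first
    probs, prizes = probs[order], prizes[order]
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard accumulated rounding
    w_cum = np.asarray(tk_weight(cum, gamma))
    weights = np.diff(np.concatenate(([0.0], w_cum)))
    return weights, prizes


def rdu_value(lottery: Lottery, params: PreferenceParams) -> float:
    """Rank-dependent utility with cumulative decision weights.

    For a two-outcome lottery this is the familiar
    w(p_best) u(x_best) + (1 - w(p_best)) u(x_worst).
    """
    weights, prizes = decision_weights(lottery, params.gamma)
    u = crra_utility(prizes, params.r)
    return float(np.dot(weights, u))
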