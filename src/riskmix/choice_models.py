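"""Stochastic choice rules: the five error specifications.

Given the deterministic values V_A, V_B of the two options of an MPL row,
each specification maps the value difference to a probability of choosing
option B:

* Fechner (strong utility), probit or logit link: P(B) = F((V_B - V_A)/mu).
* Contextual utility (moderate utility), probit or logit link: the Fechner
  index is further divided by nu, the utility range over all prizes of the
  pair.  nu changes from pair to pair, so this is pair-specific
  heteroskedasticity; the rescaled difference always lies in [-1, 1].
* Luce (strict utility): P(B) = V_B^(1/mu) / (V_A^(1/mu) + V_B^(1/mu)),
  requiring positive option values.  Algebraically this equals a logit link
  applied to (ln V_B - ln V_A)/mu, the classical strict-to-strong utility
  identity.

The Luce rule is evaluated with u(x) = x^(1-r), valid for r < 1: the factor
1/(1-r) of the literal CRRA form cancels in the ratio when positive, and for
r >= 1 the rule is undefined for negative-utility prizes, so that region is
excluded from its domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit, ndtr

from .exceptions import DomainError
from .preference_models import (
    PreferenceParams,
    crra_utility,
    decision_weights,
    eut_value,
    rdu_value,
)
from .task_design import LotteryPair

__all__ = [
    "ErrorFamily",
    "Link",
    "ErrorSpec",
    "ERROR_SPECS",
    "NoiseParams",
    "ContextualRange",
    "option_value",
    "latent_index",
    "contextual_range",
    "choose_b_probability",
]


class ErrorFamily(str, Enum):
    FECHNER = "FECHNER"
    CONTEXTUAL = "CONTEXTUAL"
    LUCE_STRICT = "LUCE_STRICT"


class Link(str, Enum):
    PROBIT = "PROBIT"
    LOGIT = "LOGIT"
    NONE = "NONE"


@dataclass(frozen=True)
class ErrorSpec:
    """One of the five admissible error specifications (FP, FL, CP, CL, LUCE)."""

    family: ErrorFamily
    link: Link

    def __post_init__(self) -> None:
        if self.family is ErrorFamily.LUCE_STRICT:
            if self.link is not Link.NONE:
                raise DomainError("LUCE_STRICT takes no link function")
        elif self.link not in (Link.PROBIT, Link.LOGIT):
            raise DomainError(f"{self.family.value} requires a probit or logit link")

    @property
    def code(self) -> str:
        if self.family is ErrorFamily.LUCE_STRICT:
            return "LUCE"
        return ("F" if self.family is ErrorFamily.FECHNER else "C") + (
            "P" if self.link is Link.PROBIT else "L"
        )

    @classmethod
    def from_code(cls, code: str) -> "ErrorSpec":
        try:
            return ERROR_SPECS[code.upper()]
        except KeyError:
            raise DomainError(
                f"unknown error spec {code!r}; admissible: {sorted(ERROR_SPECS)}"
            ) from None

    def __str__(self) -> str:
        return self.code


#: The five admissible specifications, by short code.
ERROR_SPECS: dict[str, ErrorSpec] = {
    "FP": ErrorSpec(ErrorFamily.FECHNER, Link.PROBIT),
    "FL": ErrorSpec(ErrorFamily.FECHNER, Link.LOGIT),
    "CP": ErrorSpec(ErrorFamily.CONTEXTUAL, Link.PROBIT),
    "CL": ErrorSpec(ErrorFamily.CONTEXTUAL, Link.LOGIT),
    "LUCE": ErrorSpec(ErrorFamily.LUCE_STRICT, Link.NONE),
}


@dataclass(frozen=True)
class NoiseParams:
    """Noise scale mu of the stochastic choice rule (strictly positive)."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise DomainError(f"mu must be strictly positive, got {self.mu}")


@dataclass(frozen=True)
class ContextualRange:
    """Utility range nu of a lottery pair (max minus min prize utility)."""

    nu: float

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise DomainError(f"nu must be positive, got {self.nu}")


def option_value(lottery, functional: str, params: PreferenceParams) -> float:
    """Deterministic value of one option under ``functional`` ('EUT' or 'RDU')."""
    if functional == "EUT":
        return eut_value(lottery, params)
    if functional == "RDU":
        return rdu_value(lottery, params)
    raise DomainError(f"unknown functional {functional!r}")


def latent_index(
    pair: LotteryPair,
    functional: str,
    params: PreferenceParams,
    noise: NoiseParams,
) -> float:
    """Fechner latent index (V_B - V_A)/mu."""
    v_a = option_value(pair.option_a, functional, params)
    v_b = option_value(pair.option_b, functional, params)
    return (v_b - v_a) / noise.mu


def contextual_range(pair: LotteryPair, params: PreferenceParams) -> ContextualRange:
    """nu = u(max prize) - u(min prize), prizes pooled over both options.

    Probability weighting does not enter: nu is defined over prizes alone.
    """
    prizes = pair.all_prizes
    if max(prizes) == min(prizes):
        raise DomainError("degenerate pair: all prizes equal, contextual range is zero")
    u_hi = crra_utility(max(prizes), params.r)
    u_lo = crra_utility(min(prizes), params.r)
    return ContextualRange(nu=u_hi - u_lo)


def _luce_log_value(lottery, functional: str, params: PreferenceParams) -> float:
    # strictly positive option value with u(x) = x^(1-r), r < 1, returned in logs;
    # under RDU the outcome probabilities are replaced by rank decision weights
    if params.r >= 1.0:
        raise DomainError(
            "LUCE_STRICT requires r < 1 so that option values x^(1-r) stay positive"
        )
    if functional == "RDU":
        weights, prizes = decision_weights(lottery, params.gamma)
    elif functional == "EUT":
        weights = np.asarray(lottery.probabilities, dtype=float)
        prizes = np.asarray(lottery.prizes, dtype=float)
    else:
        raise DomainError(f"unknown functional {functional!r}")
    v = float(np.dot(weights, prizes ** (1.0 - params.r)))
    if v <= 0:
        raise DomainError("LUCE_STRICT requires strictly positive option values")
    return np.log(v)


def choose_b_probability(
    pair: LotteryPair,
    functional: str,
    params: PreferenceParams,
    noise: NoiseParams,
    spec: ErrorSpec,
) -> float:
    """Probability of choosing option B under the given error specification."""
    if spec.family is ErrorFamily.LUCE_STRICT:
        log_a = _luce_log_value(pair.option_a, functional, params)
        log_b = _luce_log_value(pair.option_b, functional, params)
        return float(expit((log_b - log_a) / noise.mu))

    index = latent_index(pair, functional, params, noise)
    if spec.family is ErrorFamily.CONTEXTUAL:
        index /= contextual_range(pair, params).nu
    if spec.link is Link.PROBIT:
        return float(ndtr(index))
    return float(expit(index))
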