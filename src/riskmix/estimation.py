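"""Maximum-likelihood estimation of the structural choice models.

The likelihood of one response is the probability the chosen option is chosen
(log P(B) or log P(A)); an expressed indifference contributes the 50/50
mixture of the two, which for a binary pair is exactly log 0.5 no matter the
parameters.  Under the choice-level mixture functional each record's
likelihood is pi_EUT * L_EUT + (1 - pi_EUT) * L_RDU, mixed at the probability
level before taking logs, with a noise scale mu shared by the two components.

Estimation maximizes the sample log-likelihood over an unconstrained internal
parameterization (mu = exp(m), gamma = exp(g), pi_EUT = logistic(q), r free)
from a deterministic grid of starting values; the reported covariance is the
cluster-robust sandwich A^-1 B A^-1 with scores summed within subjects,
rescaled with C/(C-1) for C clusters, and mapped to the natural scale by the
delta method.

Because a Holt-Laury dataset has only 20 distinct (pair, response) cells per
design, the likelihood is evaluated on a compiled per-pair representation
(:class:`CompiledDataset`): option values are computed once per unique pair
and aggregated with response counts, which makes a full multi-start fit a
matter of milliseconds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit, ndtr
from scipy.stats import chi2

from .choice_models import ERROR_SPECS, ErrorFamily, ErrorSpec, Link, NoiseParams, choose_b_probability
from .exceptions import ConvergenceError, DomainError, ValidationError
from .preference_models import PreferenceParams, tk_weight
from .task_design import ChoiceDataset, ChoiceRecord, LotteryPair, RESPONSES

__all__ = [
    "FUNCTIONALS",
    "ModelSpec",
    "ParameterVector",
    "FitOptions",
    "FitResult",
    "WaldResult",
    "CompiledDataset",
    "compile_dataset",
    "record_loglik",
    "dataset_loglik",
    "fit_mle",
    "cluster_sandwich_vcov",
    "wald_test",
    "link_crosscheck",
]

logger = logging.getLogger(__name__)

FUNCTIONALS = ("EUT", "RDU", "MIXTURE")

#: free parameters per functional, in reporting order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "EUT": ("r", "mu"),
    "RDU": ("r", "gamma", "mu"),
    "MIXTURE": ("r_eut", "r_rdu", "gamma", "mu", "pi_eut"),
}

_PROB_CLIP = 1e-12
_LN_HALF = math.log(0.5)
#: r grid point kept strictly below 1 for the Luce spec
_LUCE_R_MAX = 0.999


@dataclass(frozen=True)
class ModelSpec:
    """A preference functional paired with an error specification (15 combinations)."""

    functional: str
    error: ErrorSpec

    def __post_init__(self) -> None:
        if self.functional not in FUNCTIONALS:
            raise DomainError(
                f"functional must be one of {FUNCTIONALS}, got {self.functional!r}"
            )

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.functional]

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    @property
    def code(self) -> str:
        tag = "MIX" if self.functional == "MIXTURE" else self.functional
        return f"{tag}-{self.error.code}"

    @classmethod
    def from_code(cls, code: str) -> "ModelSpec":
        try:
            func_tag, err_tag = code.upper().split("-", 1)
        except ValueError:
            raise DomainError(
                f"model code {code!r} must look like 'EUT-FP' or 'MIX-CP'"
            ) from None
        functional = {"EUT": "EUT", "RDU": "RDU", "MIX": "MIXTURE", "MIXTURE": "MIXTURE"}.get(
            func_tag
        )
        if functional is None:
            raise DomainError(f"unknown functional tag {func_tag!r}")
        return cls(functional, ErrorSpec.from_code(err_tag))

    def __str__(self) -> str:
        return self.code


def all_model_specs() -> list[ModelSpec]:
    """The 15 admissible functional x error-spec combinations."""
    return [
        ModelSpec(f, ERROR_SPECS[e])
        for f in FUNCTIONALS
        for e in ("FP", "FL", "CP", "CL", "LUCE")
    ]


@dataclass(frozen=True)
class ParameterVector:
    """Natural-scale parameters; only the fields of the functional are set.

    EUT uses (r_eut, mu); RDU uses (r_rdu, gamma, mu); the mixture uses all
    five.  ``pi_eut`` is the probability a choice is generated by the EUT
    component, so pi_rdu = 1 - pi_eut.
    """

    r_eut: float | None = None
    r_rdu: float | None = None
    gamma: float | None = None
    mu: float | None = None
    pi_eut: float | None = None

    def __post_init__(self) -> None:
        if self.mu is not None and self.mu <= 0:
            raise DomainError(f"mu must be positive, got {self.mu}")
        if self.gamma is not None and self.gamma <= 0:
            raise DomainError(f"gamma must be positive, got {self.gamma}")
        # closed interval: boundary values are admissible for evaluation
        # (collapse checks); the logit transform keeps *fitted* values interior
        if self.pi_eut is not None and not (0.0 <= self.pi_eut <= 1.0):
            raise DomainError(f"pi_eut must lie in [0, 1], got {self.pi_eut}")

    @property
    def pi_rdu(self) -> float | None:
        return None if self.pi_eut is None else 1.0 - self.pi_eut

    @classmethod
    def for_eut(cls, r: float, mu: float) -> "ParameterVector":
        return cls(r_eut=r, mu=mu)

    @classmethod
    def for_rdu(cls, r: float, gamma: float, mu: float) -> "ParameterVector":
        return cls(r_rdu=r, gamma=gamma, mu=mu)

    @classmethod
    def for_mixture(
        cls, r_eut: float, r_rdu: float, gamma: float, mu: float, pi_eut: float
    ) -> "ParameterVector":
        return cls(r_eut=r_eut, r_rdu=r_rdu, gamma=gamma, mu=mu, pi_eut=pi_eut)

    def get(self, name: str, functional: str) -> float:
        """Value of parameter ``name`` ('r' resolves per functional)."""
        if name == "r":
            name = "r_eut" if functional == "EUT" else "r_rdu"
        value = getattr(self, name)
        if value is None:
            raise DomainError(f"parameter {name!r} is not set for {functional}")
        return float(value)

    def as_array(self, functional: str) -> np.ndarray:
        return np.array(
            [self.get(name, functional) for name in PARAM_NAMES[functional]], dtype=float
        )

    @classmethod
    def from_array(cls, values: Sequence[float], functional: str) -> "ParameterVector":
        names = PARAM_NAMES[functional]
        if len(values) != len(names):
            raise DomainError(
                f"{functional} expects {len(names)} parameters {names}, got {len(values)}"
            )
        kwargs: dict[str, float] = {}
        for name, v in zip(names, values):
            if name == "r":
                name = "r_eut" if functional == "EUT" else "r_rdu"
            kwargs[name] = float(v)
        return cls(**kwargs)

    def to_dict(self, functional: str) -> dict[str, float]:
        return {n: self.get(n, functional) for n in PARAM_NAMES[functional]}


# ---------------------------------------------------------------------------
# compiled dataset and vectorized likelihood kernel
# ---------------------------------------------------------------------------


@dataclass
class CompiledDataset:
    """Array form of a :class:`ChoiceDataset` for fast likelihood evaluation.

    Each unique (task, row) pair appears once; records are reduced to a pair
    index, a response code (0 = A, 1 = B, 2 = indifferent) and a cluster
    index, plus a (n_pairs, 3) response-count matrix for aggregated sums.
    """

    # per-pair arrays, options' outcomes sorted high prize first
    p_a_hi: np.ndarray
    a_hi: np.ndarray
    a_lo: np.ndarray
    p_b_hi: np.ndarray
    b_hi: np.ndarray
    b_lo: np.ndarray
    prize_max: np.ndarray
    prize_min: np.ndarray
    # per-record arrays
    pair_idx: np.ndarray
    resp: np.ndarray
    cluster_idx: np.ndarray
    counts: np.ndarray
    cluster_labels: list[str]
    pair_keys: list[tuple[str, int]]

    @property
    def n_obs(self) -> int:
        return int(self.pair_idx.size)

    @property
    def n_pairs(self) -> int:
        return int(self.p_a_hi.size)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)


def _two_outcome(lottery) -> tuple[float, float, float]:
    """(p_high, x_high, x_low) of a one- or two-outcome lottery."""
    probs = np.asarray(lottery.probabilities, float)
    prizes = np.asarray(lottery.prizes, float)
    if prizes.size == 1:
        return 1.0, float(prizes[0]), float(prizes[0])
    if prizes.size != 2:
        raise ValidationError(
            "the compiled likelihood supports one- or two-outcome options only"
        )
    hi = int(np.argmax(prizes))
    lo = 1 - hi
    return float(probs[hi]), float(prizes[hi]), float(prizes[lo])


def compile_dataset(dataset: ChoiceDataset) -> CompiledDataset:
    pair_keys = sorted({(r.task_id, r.row_index) for r in dataset.records})
    key_index = {k: i for i, k in enumerate(pair_keys)}
    n_pairs = len(pair_keys)
    arrays = {name: np.empty(n_pairs) for name in ("p_a_hi", "a_hi", "a_lo", "p_b_hi", "b_hi", "b_lo")}
    for k, (task_id, row) in enumerate(pair_keys):
        pair = dataset.designs[task_id].pair(row)
        arrays["p_a_hi"][k], arrays["a_hi"][k], arrays["a_lo"][k] = _two_outcome(pair.option_a)
        arrays["p_b_hi"][k], arrays["b_hi"][k], arrays["b_lo"][k] = _two_outcome(pair.option_b)
    prize_stack = np.stack([arrays["a_hi"], arrays["a_lo"], arrays["b_hi"], arrays["b_lo"]])
    cluster_labels = dataset.subjects
    cluster_index = {s: i for i, s in enumerate(cluster_labels)}
    resp_index = {code: i for i, code in enumerate(RESPONSES)}
    pair_idx = np.array([key_index[(r.task_id, r.row_index)] for r in dataset.records])
    resp = np.array([resp_index[r.response] for r in dataset.records], dtype=np.int64)
    cluster_idx = np.array([cluster_index[r.subject_id] for r in dataset.records])
    counts = np.zeros((n_pairs, 3))
    np.add.at(counts, (pair_idx, resp), 1.0)
    return CompiledDataset(
        p_a_hi=arrays["p_a_hi"],
        a_hi=arrays["a_hi"],
        a_lo=arrays["a_lo"],
        p_b_hi=arrays["p_b_hi"],
        b_hi=arrays["b_hi"],
        b_lo=arrays["b_lo"],
        prize_max=prize_stack.max(axis=0),
        prize_min=prize_stack.min(axis=0),
        pair_idx=pair_idx,
        resp=resp,
        cluster_idx=cluster_idx,
        counts=counts,
        cluster_labels=cluster_labels,
        pair_keys=pair_keys,
    )


def _u_literal(x: np.ndarray, r: float) -> np.ndarray:
    if abs(1.0 - r) <= 1e-6:
        return np.log(x)
    return x ** (1.0 - r) / (1.0 - r)


def _pair_choose_b(
    compiled: CompiledDataset,
    functional: str,
    error: ErrorSpec,
    r: float,
    gamma: float,
    mu: float,
) -> np.ndarray:
    """P(choose B) for every unique pair, vectorized."""
    if functional == "RDU":
        w_a = np.asarray(tk_weight(compiled.p_a_hi, gamma))
        w_b = np.asarray(tk_weight(compiled.p_b_hi, gamma))
    else:
        w_a, w_b = compiled.p_a_hi, compiled.p_b_hi

    if error.family is ErrorFamily.LUCE_STRICT:
        if r >= 1.0:
            raise DomainError(
                "LUCE_STRICT requires r < 1 so that option values x^(1-r) stay positive"
            )
        e = 1.0 - r
        v_a = w_a * compiled.a_hi**e + (1.0 - w_a) * compiled.a_lo**e
        v_b = w_b * compiled.b_hi**e + (1.0 - w_b) * compiled.b_lo**e
        return expit((np.log(v_b) - np.log(v_a)) / mu)

    u_a_hi = _u_literal(compiled.a_hi, r)
    u_a_lo = _u_literal(compiled.a_lo, r)
    u_b_hi = _u_literal(compiled.b_hi, r)
    u_b_lo = _u_literal(compiled.b_lo, r)
    v_a = w_a * u_a_hi + (1.0 - w_a) * u_a_lo
    v_b = w_b * u_b_hi + (1.0 - w_b) * u_b_lo
    index = (v_b - v_a) / mu
    if error.family is ErrorFamily.CONTEXTUAL:
        nu = _u_literal(compiled.prize_max, r) - _u_literal(compiled.prize_min, r)
        index = index / nu
    if error.link is Link.PROBIT:
        return np.asarray(ndtr(index))
    return expit(index)


def _clip_probs(p: np.ndarray) -> np.ndarray:
    n_out = int(np.count_nonzero((p < _PROB_CLIP) | (p > 1.0 - _PROB_CLIP)))
    if n_out:
        logger.debug("clipped %d choice probabilities to [%g, %g]", n_out, _PROB_CLIP, 1 - _PROB_CLIP)
    return np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)


def _loglik_cells(
    compiled: CompiledDataset, spec: ModelSpec, params: ParameterVector
) -> np.ndarray:
    """(n_pairs, 3) matrix of log-likelihood per response code (A, B, indifferent)."""
    if spec.functional == "MIXTURE":
        pb_e = _pair_choose_b(compiled, "EUT", spec.error, params.get("r_eut", "MIXTURE"), 1.0, params.get("mu", "MIXTURE"))
        pb_r = _pair_choose_b(
            compiled,
            "RDU",
            spec.error,
            params.get("r_rdu", "MIXTURE"),
            params.get("gamma", "MIXTURE"),
            params.get("mu", "MIXTURE"),
        )
        pi = params.get("pi_eut", "MIXTURE")
        l_b = _clip_probs(pi * pb_e + (1.0 - pi) * pb_r)
    else:
        gamma = params.get("gamma", "RDU") if spec.functional == "RDU" else 1.0
        pb = _pair_choose_b(
            compiled,
            spec.functional,
            spec.error,
            params.get("r", spec.functional),
            gamma,
            params.get("mu", spec.functional),
        )
        l_b = _clip_probs(pb)
    cells = np.empty((compiled.n_pairs, 3))
    cells[:, 0] = np.log1p(-l_b)
    cells[:, 1] = np.log(l_b)
    cells[:, 2] = _LN_HALF
    return cells


def _total_loglik(compiled: CompiledDataset, spec: ModelSpec, params: ParameterVector) -> float:
    return float(np.sum(compiled.counts * _loglik_cells(compiled, spec, params)))


def _per_obs_loglik(
    compiled: CompiledDataset, spec: ModelSpec, params: ParameterVector
) -> np.ndarray:
    cells = _loglik_cells(compiled, spec, params)
    return cells[compiled.pair_idx, compiled.resp]


# ---------------------------------------------------------------------------
# public likelihood API
# ---------------------------------------------------------------------------


def record_loglik(
    record: ChoiceRecord, pair: LotteryPair, spec: ModelSpec, params: ParameterVector
) -> float:
    """Log-likelihood of one response under ``spec``.

    This scalar path goes through :mod:`riskmix.choice_models` option by
    option; the vectorized kernel used in fitting must agree with it.
    """

    def component_pb(functional: str) -> float:
        pp = PreferenceParams(
            r=params.get("r_eut" if functional == "EUT" else "r_rdu", "MIXTURE")
            if spec.functional == "MIXTURE"
            else params.get("r", spec.functional),
            gamma=params.get("gamma", spec.functional) if functional == "RDU" else 1.0,
        )
        return choose_b_probability(
            pair, functional, pp, NoiseParams(params.get("mu", spec.functional)), spec.error
        )

    if spec.functional == "MIXTURE":
        pi = params.get("pi_eut", "MIXTURE")
        p_b = pi * component_pb("EUT") + (1.0 - pi) * component_pb("RDU")
    else:
        p_b = component_pb(spec.functional)
    p_b = float(np.clip(p_b, _PROB_CLIP, 1.0 - _PROB_CLIP))
    if record.response == "B":
        return math.log(p_b)
    if record.response == "A":
        return math.log1p(-p_b)
    return _LN_HALF


def dataset_loglik(
    dataset: ChoiceDataset | CompiledDataset, spec: ModelSpec, params: ParameterVector
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the per-observation vector (record order)."""
    compiled = dataset if isinstance(dataset, CompiledDataset) else compile_dataset(dataset)
    per_obs = _per_obs_loglik(compiled, spec, params)
    return float(per_obs.sum()), per_obs


# ---------------------------------------------------------------------------
# internal parameterization
# ---------------------------------------------------------------------------

_R_BOUND = 10.0
_INTERNAL_BOUNDS = {
    "r": (-_R_BOUND, _R_BOUND),
    "gamma": (-7.0, 7.0),  # on log scale
    "mu": (-16.0, 10.0),  # on log scale
    "pi_eut": (-15.0, 15.0),  # on logit scale
}


def _base_name(name: str) -> str:
    return "r" if name in ("r", "r_eut", "r_rdu") else name


def _to_internal(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty(len(names))
    for j, name in enumerate(names):
        base = _base_name(name)
        if base == "r":
            out[j] = values[j]
        elif base in ("gamma", "mu"):
            out[j] = math.log(values[j])
        else:
            out[j] = logit(values[j])
    return out


def _to_natural(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty(len(names))
    for j, name in enumerate(names):
        base = _base_name(name)
        if base == "r":
            out[j] = theta[j]
        elif base in ("gamma", "mu"):
            out[j] = math.exp(theta[j])
        else:
            out[j] = expit(theta[j])
    return out


def _jacobian_natural(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Diagonal d(natural)/d(internal) for the delta method."""
    diag = np.empty(len(names))
    for j, name in enumerate(names):
        base = _base_name(name)
        if base == "r":
            diag[j] = 1.0
        elif base in ("gamma", "mu"):
            diag[j] = math.exp(theta[j])
        else:
            p = expit(theta[j])
            diag[j] = p * (1.0 - p)
    return np.diag(diag)


def _bounds_for(spec: ModelSpec) -> list[tuple[float, float]]:
    bounds = []
    for name in spec.param_names:
        lo, hi = _INTERNAL_BOUNDS[_base_name(name)]
        if _base_name(name) == "r" and spec.error.family is ErrorFamily.LUCE_STRICT:
            hi = _LUCE_R_MAX
        bounds.append((lo, hi))
    return bounds


# ---------------------------------------------------------------------------
# multi-start schedule
# ---------------------------------------------------------------------------

R_STARTS = (-1.0, -0.5, 0.0, 0.5, 0.9)
GAMMA_STARTS = (0.5, 1.0, 2.0)
MU_STARTS = (0.1, 0.5, 1.0)
PI_STARTS = (0.2, 0.5, 0.8)

# thinned grids for the 5-parameter mixture and for inner Monte-Carlo loops
_MIX_R_STARTS = (-0.5, 0.5)
_FAST_STARTS = {
    "EUT": {"r": (0.0, 0.5), "mu": (0.1, 0.5)},
    "RDU": {"r": (-0.5, 0.5), "gamma": (0.5, 2.0), "mu": (0.2,)},
    "MIXTURE": {
        "r_eut": (0.2,),
        "r_rdu": (-0.5, 0.5),
        "gamma": (0.5, 2.0),
        "mu": (0.2,),
        "pi_eut": (0.3,),
    },
}


def _start_grid(spec: ModelSpec, profile: str) -> list[np.ndarray]:
    if profile == "fast":
        grids = [_FAST_STARTS[spec.functional][name] for name in spec.param_names]
    elif spec.functional == "EUT":
        grids = [R_STARTS, MU_STARTS]
    elif spec.functional == "RDU":
        grids = [R_STARTS, GAMMA_STARTS, MU_STARTS]
    else:
        grids = [_MIX_R_STARTS, _MIX_R_STARTS, (0.5, 2.0), (0.1, 0.5), (0.2, 0.8)]
    starts = [np.array(combo, dtype=float) for combo in itertools.product(*grids)]
    if spec.error.family is ErrorFamily.LUCE_STRICT:
        for s in starts:
            for j, name in enumerate(spec.param_names):
                if _base_name(name) == "r":
                    s[j] = min(s[j], 0.9)
    return starts


@dataclass
class FitOptions:
    """Optimizer controls for :func:`fit_mle`."""

    starts: str = "default"  # "default" | "fast"
    extra_starts: list[ParameterVector] = field(default_factory=list)
    warm_start: ParameterVector | None = None
    warm_only: bool = False
    gtol: float = 1e-8
    maxiter: int = 500
    compute_vcov: bool = True
    tie_tol: float = 1e-6


@dataclass
class WaldResult:
    """Quadratic-form Wald test of linear equality constraints."""

    statistic: float
    df: int
    p_value: float
    constraints: dict[str, float]


@dataclass
class FitResult:
    """A converged maximum-likelihood fit with cluster-robust inference."""

    spec: ModelSpec
    params: ParameterVector
    estimates: np.ndarray
    names: tuple[str, ...]
    loglik: float
    per_obs_loglik: np.ndarray
    theta_internal: np.ndarray
    vcov: np.ndarray | None
    vcov_internal: np.ndarray | None
    n_obs: int
    n_clusters: int
    k_params: int
    convergence: dict
    flags: list[str]
    cluster_idx: np.ndarray

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray | None:
        if self.se is None:
            return None
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.estimates - z * self.se, self.estimates + z * self.se])

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def std_error(self, name: str) -> float:
        se = self.se
        if se is None:
            raise ConvergenceError("no covariance available for this fit")
        return float(se[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "model": self.spec.code,
            "estimates": dict(zip(self.names, map(float, self.estimates))),
            "std_errors": None if self.se is None else dict(zip(self.names, map(float, self.se))),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "k_params": self.k_params,
            "convergence": self.convergence,
            "flags": self.flags,
            "vcov": None if self.vcov is None else self.vcov.tolist(),
        }


def _negloglik_fn(compiled: CompiledDataset, spec: ModelSpec) -> Callable[[np.ndarray], float]:
    names = spec.param_names

    def negll(theta: np.ndarray) -> float:
        params = ParameterVector.from_array(_to_natural(theta, names), spec.functional)
        try:
            with np.errstate(over="ignore", under="ignore", invalid="ignore"):
                value = -_total_loglik(compiled, spec, params)
        except (DomainError, FloatingPointError):
            return 1e12
        return value if np.isfinite(value) else 1e12

    return negll


def fit_mle(
    dataset: ChoiceDataset | CompiledDataset,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the sample log-likelihood of ``spec`` by deterministic multi-start.

    Starting values come from a fixed grid (see :data:`R_STARTS` etc.); the
    best local optimum wins, with ties below ``tie_tol`` resolved in favour of
    the earliest start so refits are reproducible.  Boundary solutions and
    degenerate response patterns are flagged, never silently returned.
    """
    options = options or FitOptions()
    compiled = dataset if isinstance(dataset, CompiledDataset) else compile_dataset(dataset)
    if compiled.n_clusters < 2:
        raise ValidationError("estimation requires at least 2 subject clusters")

    flags: list[str] = []
    n_a = compiled.counts[:, 0].sum()
    n_b = compiled.counts[:, 1].sum()
    if n_a == 0 or n_b == 0:
        flags.append("degenerate_responses: every non-indifferent choice is the same option")

    names = spec.param_names
    bounds = _bounds_for(spec)
    negll = _negloglik_fn(compiled, spec)

    start_vectors: list[np.ndarray] = []
    if options.warm_start is not None:
        start_vectors.append(options.warm_start.as_array(spec.functional))
    if not (options.warm_start is not None and options.warm_only):
        start_vectors.extend(_start_grid(spec, options.starts))
        start_vectors.extend(s.as_array(spec.functional) for s in options.extra_starts)

    best: optimize.OptimizeResult | None = None
    best_idx = -1
    n_success = 0
    for idx, natural in enumerate(start_vectors):
        theta0 = np.clip(
            _to_internal(natural, names),
            [lo for lo, _ in bounds],
            [hi for _, hi in bounds],
        )
        res = optimize.minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-13, "gtol": options.gtol},
        )
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_success += 1
        if best is None or res.fun < best.fun - options.tie_tol:
            best, best_idx = res, idx
    if best is None:
        raise ConvergenceError(f"no start converged for {spec.code}")
    if n_success == 0:
        flags.append("no_start_reported_success")

    theta = np.asarray(best.x, dtype=float)
    for j, (lo, hi) in enumerate(bounds):
        if theta[j] - lo < 1e-6 or hi - theta[j] < 1e-6:
            flags.append(f"boundary: {names[j]} at internal bound")
    natural = _to_natural(theta, names)
    params = ParameterVector.from_array(natural, spec.functional)
    if params.pi_eut is not None and min(params.pi_eut, 1.0 - params.pi_eut) < 1e-4:
        flags.append("boundary: pi_eut within 1e-4 of 0/1")
    if params.mu is not None and not (1e-6 < params.mu < 1e4):
        flags.append("boundary: mu at an extreme value")

    per_obs = _per_obs_loglik(compiled, spec, params)
    loglik = float(per_obs.sum())
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else float("nan")

    fit = FitResult(
        spec=spec,
        params=params,
        estimates=natural,
        names=names,
        loglik=loglik,
        per_obs_loglik=per_obs,
        theta_internal=theta,
        vcov=None,
        vcov_internal=None,
        n_obs=compiled.n_obs,
        n_clusters=compiled.n_clusters,
        k_params=spec.k_params,
        convergence={
            "n_starts": len(start_vectors),
            "n_success": n_success,
            "best_start": best_idx,
            "max_abs_grad": grad_norm,
            "message": str(best.message),
        },
        flags=flags,
        cluster_idx=compiled.cluster_idx.copy(),
    )
    if options.compute_vcov:
        try:
            fit.vcov, fit.vcov_internal = _sandwich(compiled, spec, theta)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            fit.flags.append(f"vcov_failed: {exc}")
    return fit


# ---------------------------------------------------------------------------
# cluster-robust sandwich covariance
# ---------------------------------------------------------------------------


def _fd_steps(theta: np.ndarray) -> np.ndarray:
    return 1e-5 * (1.0 + np.abs(theta))


def _score_matrix(
    compiled: CompiledDataset, spec: ModelSpec, theta: np.ndarray
) -> np.ndarray:
    """Per-observation score vectors d loglik_i / d theta (central differences)."""
    names = spec.param_names
    k = len(theta)
    h = _fd_steps(theta)
    scores = np.empty((compiled.n_obs, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        lp = _per_obs_loglik(compiled, spec, ParameterVector.from_array(_to_natural(tp, names), spec.functional))
        lm = _per_obs_loglik(compiled, spec, ParameterVector.from_array(_to_natural(tm, names), spec.functional))
        scores[:, j] = (lp - lm) / (2.0 * h[j])
    return scores


def _hessian(compiled: CompiledDataset, spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian of the total log-likelihood."""
    names = spec.param_names

    def ll(t: np.ndarray) -> float:
        return _total_loglik(
            compiled, spec, ParameterVector.from_array(_to_natural(t, names), spec.functional)
        )

    k = len(theta)
    h = _fd_steps(theta)
    hess = np.empty((k, k))
    f0 = ll(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                hess[i, i] = (ll(tp) - 2.0 * f0 + ll(tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h[i]
                tpp[j] += h[j]
                tpm[i] += h[i]
                tpm[j] -= h[j]
                tmp[i] -= h[i]
                tmp[j] += h[j]
                tmm[i] -= h[i]
                tmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (
                    4.0 * h[i] * h[j]
                )
    return hess


def _sandwich(
    compiled: CompiledDataset, spec: ModelSpec, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-robust A^-1 B A^-1 on internal scale, delta-mapped to natural scale."""
    a_mat = -_hessian(compiled, spec, theta)  # observed information
    cond = np.linalg.cond(a_mat)
    if not np.isfinite(cond) or cond > 1e10:
        raise ConvergenceError(
            f"observed information is (near-)singular: condition number {cond:.3e}"
        )
    scores = _score_matrix(compiled, spec, theta)
    n_clusters = compiled.n_clusters
    cluster_scores = np.zeros((n_clusters, len(theta)))
    np.add.at(cluster_scores, compiled.cluster_idx, scores)
    b_mat = cluster_scores.T @ cluster_scores
    b_mat *= n_clusters / (n_clusters - 1.0)
    a_inv = np.linalg.inv(a_mat)
    v_int = a_inv @ b_mat @ a_inv
    v_int = (v_int + v_int.T) / 2.0
    jac = _jacobian_natural(theta, spec.param_names)
    v_nat = jac @ v_int @ jac
    return (v_nat + v_nat.T) / 2.0, v_int


def cluster_sandwich_vcov(fit: FitResult, dataset: ChoiceDataset | CompiledDataset) -> np.ndarray:
    """Recompute the cluster-robust covariance of ``fit`` on ``dataset``.

    Scores are summed within subject clusters, the outer-product middle term
    is rescaled by C/(C-1), and the result is delta-mapped to the natural
    reporting scale.
    """
    compiled = dataset if isinstance(dataset, CompiledDataset) else compile_dataset(dataset)
    v_nat, _ = _sandwich(compiled, fit.spec, fit.theta_internal)
    return v_nat


def wald_test(fit: FitResult, constraints: Mapping[str, float]) -> WaldResult:
    """Wald test of simple equality constraints, e.g. ``{"gamma": 1.0}``.

    The statistic is the quadratic form (est - q)' [R V R']^-1 (est - q) on
    the natural reporting scale, referred to chi-squared with one degree of
    freedom per constraint.  Inference for constraints on the boundary of the
    parameter space (pi_eut at 0 or 1) is nonstandard; the statistic is
    reported as-is.
    """
    if not constraints:
        raise DomainError("at least one constraint is required")
    if fit.vcov is None:
        raise ConvergenceError("fit has no covariance matrix; cannot run a Wald test")
    for name in constraints:
        if name not in fit.names:
            raise DomainError(
                f"parameter {name!r} is not free in {fit.spec.code} (free: {fit.names})"
            )
    idx = [fit.names.index(name) for name in constraints]
    diff = np.array([fit.estimates[i] - q for i, q in zip(idx, constraints.values())])
    sub_v = fit.vcov[np.ix_(idx, idx)]
    stat = float(diff @ np.linalg.solve(sub_v, diff))
    df = len(idx)
    return WaldResult(
        statistic=stat, df=df, p_value=float(chi2.sf(stat, df)), constraints=dict(constraints)
    )


def link_crosscheck(fit_probit: FitResult, fit_logit: FitResult, tol: float = 0.1) -> str | None:
    """Compare probit and logit fits of the same functional.

    Probit and logit links should deliver nearly identical preference
    estimates (they differ essentially by a scale factor on mu); a large
    discrepancy in any shared non-noise parameter is evidence that one
    optimizer run found a local maximum.  Returns a warning message, or None.
    """
    shared = [n for n in fit_probit.names if n in fit_logit.names and n != "mu"]
    worst = 0.0
    for name in shared:
        worst = max(worst, abs(fit_probit.estimate(name) - fit_logit.estimate(name)))
    if worst > tol:
        return (
            f"probit and logit estimates of {fit_probit.spec.functional} disagree by "
            f"{worst:.3f} (> {tol}); possible local maximum"
        )
    return None
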