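"""Model judging: information criteria, non-nested tests, out-of-sample fit.

Three complementary families of evidence are computed for a set of fitted
models:

* **Information criteria.**  AIC = 2k - 2 LL and BIC = k ln(n) - 2 LL with n
  the number of choice records; both penalize the extra parameters of RDU and
  mixture functionals.
* **Non-nested tests.**  The Vuong statistic is the standardized sum of
  per-record log-likelihood ratios m_i = ll_f,i - ll_g,i; under the null that
  the models are equally close to the truth it is asymptotically standard
  normal, and a large positive value favours model f.  The Clarke test is its
  distribution-free counterpart: an exact binomial sign test on the same m_i
  (ties dropped), with one-sided p-values in both directions.  These tests
  are meaningful for non-nested pairs, i.e. different error specifications
  within one preference functional.
* **Out-of-sample log-likelihood (OSLLF).**  Grouped cross-validation that
  leaves one subject (all of their choices) out at a time, refits, and scores
  the held-out subject at the leave-that-subject-out estimate; the total over
  subjects estimates predictive fit without an explicit complexity penalty.

Pairwise sign tests need not be transitive; :func:`selection_battery` reports
any preference cycles it finds instead of hiding them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .estimation import (
    FitOptions,
    FitResult,
    ModelSpec,
    compile_dataset,
    dataset_loglik,
    fit_mle,
)
from .exceptions import ConvergenceError, DegenerateComparisonError, DomainError, ValidationError
from .task_design import ChoiceDataset

__all__ = [
    "TestResult",
    "OSLLFResult",
    "SelectionReport",
    "information_criteria",
    "vuong_test",
    "clarke_test",
    "osllf_grouped_cv",
    "selection_battery",
]

_TIE_TOL = 1e-12


def information_criteria(fit: FitResult, n_obs: int | None = None) -> tuple[float, float]:
    """(AIC, BIC) of a fit; BIC uses the number of choice records as sample size."""
    n = fit.n_obs if n_obs is None else int(n_obs)
    aic = 2.0 * fit.k_params - 2.0 * fit.loglik
    bic = fit.k_params * math.log(n) - 2.0 * fit.loglik
    return aic, bic


@dataclass
class TestResult:
    """Outcome of a pairwise model-comparison test."""

    statistic: float
    p_value: float
    direction: str  # which model the evidence favours
    n_effective: int


def _ll_diffs(fit_f: FitResult, fit_g: FitResult) -> np.ndarray:
    lf = np.asarray(fit_f.per_obs_loglik)
    lg = np.asarray(fit_g.per_obs_loglik)
    if lf.shape != lg.shape:
        raise ValidationError(
            "the two fits score different record sets "
            f"({lf.shape} vs {lg.shape}); refit on identical data"
        )
    return lf - lg


def vuong_test(
    fit_f: FitResult,
    fit_g: FitResult,
    variance: str = "ml",
    cluster: bool = False,
    correction: bool = False,
) -> TestResult:
    """Vuong non-nested test on per-observation log-likelihood ratios.

    statistic = sum(m_i) / (sqrt(n) * sd(m_i)); positive favours ``fit_f``.
    The reported p-value is the one-sided upper tail of the standard normal.
    ``variance``: "ml" uses the maximum-likelihood sd (ddof=0), "unbiased"
    uses ddof=1.  With ``cluster=True`` the ratios are first summed within
    subject clusters and the statistic is formed over cluster sums.  With
    ``correction=True`` a BIC-type penalty (k_f - k_g)/2 * ln(n) is
    subtracted from the numerator, relevant only when the models differ in k.
    """
    m = _ll_diffs(fit_f, fit_g)
    n_all = m.size
    if cluster:
        idx = np.asarray(fit_f.cluster_idx)
        sums = np.zeros(idx.max() + 1)
        np.add.at(sums, idx, m)
        m = sums
    n = m.size
    ddof = 0 if variance == "ml" else 1
    sd = float(np.std(m, ddof=ddof))
    if sd < _TIE_TOL:
        raise DegenerateComparisonError(
            "per-observation log-likelihoods are identical; Vuong statistic undefined"
        )
    numerator = float(m.sum())
    if correction:
        numerator -= (fit_f.k_params - fit_g.k_params) / 2.0 * math.log(n_all)
    stat = numerator / (math.sqrt(n) * sd)
    return TestResult(
        statistic=stat,
        p_value=float(norm.sf(stat)),
        direction=fit_f.spec.code if stat > 0 else fit_g.spec.code,
        n_effective=n,
    )


def clarke_test(fit_f: FitResult, fit_g: FitResult, direction: str = "greater") -> TestResult:
    """Clarke paired sign test: an exact binomial test on the sign of the m_i.

    Exact zeros (to 1e-12) are dropped.  ``direction="greater"`` tests the
    one-sided alternative that ``fit_f`` is better (p = P(Bin(n, 1/2) >= B)
    with B the count of positive differences); ``direction="less"`` tests the
    opposite tail (p = P(Bin(n, 1/2) <= B)).
    """
    if direction not in ("greater", "less"):
        raise DomainError(f"direction must be 'greater' or 'less', got {direction!r}")
    m = _ll_diffs(fit_f, fit_g)
    m = m[np.abs(m) > _TIE_TOL]
    n_eff = int(m.size)
    if n_eff == 0:
        raise DegenerateComparisonError(
            "all per-observation log-likelihood differences are zero"
        )
    b = int(np.count_nonzero(m > 0))
    if direction == "greater":
        p = float(binom.sf(b - 1, n_eff, 0.5))  # P(X >= b)
        favoured = fit_f.spec.code if b > n_eff / 2 else fit_g.spec.code
    else:
        p = float(binom.cdf(b, n_eff, 0.5))  # P(X <= b)
        favoured = fit_g.spec.code if b < n_eff / 2 else fit_f.spec.code
    return TestResult(statistic=float(b), p_value=p, direction=favoured, n_effective=n_eff)


@dataclass
class OSLLFResult:
    """Grouped-cross-validated out-of-sample log-likelihood."""

    total: float
    per_cluster: dict[str, float]
    failed_clusters: list[str]


def osllf_grouped_cv(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    options: FitOptions | None = None,
    full_fit: FitResult | None = None,
    allow_failures: bool = False,
    fit_fn=None,
    loglik_fn=None,
) -> OSLLFResult:
    """Leave-one-subject-out out-of-sample log-likelihood.

    Each subject in turn is removed; the model is refitted on the remaining
    subjects, warm-started at the full-sample estimate; the held-out
    subject's records are scored at the refitted parameters and the
    contributions summed.  A refit failure normally raises; with
    ``allow_failures=True`` the cluster is excluded and reported.

    ``fit_fn(dataset, spec, options) -> FitResult-like`` and
    ``loglik_fn(dataset, spec, params) -> (total, per_obs)`` may be injected
    (e.g. for fixed reference models); they default to :func:`fit_mle` and
    :func:`dataset_loglik`.
    """
    subjects = dataset.subjects
    if len(subjects) < 3:
        raise ValidationError("grouped cross-validation requires at least 3 subjects")
    fit_fn = fit_fn or fit_mle
    loglik_fn = loglik_fn or dataset_loglik
    options = options or FitOptions(starts="fast")
    if full_fit is None:
        full_fit = fit_fn(dataset, spec, options)
    per_cluster: dict[str, float] = {}
    failed: list[str] = []
    for subject in subjects:
        train = dataset.drop_subject(subject)
        held = dataset.subset([subject])
        warm_options = FitOptions(
            starts=options.starts,
            warm_start=full_fit.params,
            warm_only=True,
            gtol=options.gtol,
            maxiter=options.maxiter,
            compute_vcov=False,
        )
        try:
            refit = fit_fn(train, spec, warm_options)
        except ConvergenceError:
            # fall back to the multi-start grid before giving up on the cluster
            try:
                refit = fit_fn(
                    train,
                    spec,
                    FitOptions(starts=options.starts, compute_vcov=False),
                )
            except ConvergenceError:
                if not allow_failures:
                    raise
                failed.append(subject)
                continue
        held_ll, _ = loglik_fn(held, spec, refit.params)
        per_cluster[subject] = float(held_ll)
    return OSLLFResult(
        total=float(sum(per_cluster.values())), per_cluster=per_cluster, failed_clusters=failed
    )


@dataclass
class SelectionReport:
    """Criteria and pairwise tests for a battery of fitted models."""

    fits: dict[str, FitResult]
    models: pd.DataFrame
    vuong: dict[tuple[str, str], TestResult]
    clarke: dict[tuple[str, str, str], TestResult]
    best_within: dict[tuple[str, str], str]  # (functional, criterion) -> model code
    best_overall: dict[str, str]  # criterion -> model code
    cycles: list[tuple[str, str, str]] = field(default_factory=list)

    def vuong_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_f": f,
                "model_g": g,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "favoured": t.direction,
            }
            for (f, g), t in self.vuong.items()
        ]
        return pd.DataFrame(rows)

    def clarke_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model_f": f,
                "model_g": g,
                "direction": d,
                "n_positive": int(t.statistic),
                "n_effective": t.n_effective,
                "p_value": t.p_value,
                "favoured": t.direction,
            }
            for (f, g, d), t in self.clarke.items()
        ]
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        lines = ["Model criteria", "=" * 78]
        lines.append(self.models.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        if self.vuong:
            lines += ["", "Vuong tests (positive statistic favours model_f)", "-" * 78]
            lines.append(
                self.vuong_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}")
            )
        if self.clarke:
            lines += ["", "Clarke sign tests (one-sided, both directions)", "-" * 78]
            lines.append(
                self.clarke_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")
            )
        lines += ["", "Best within functional:"]
        for (functional, criterion), code in sorted(self.best_within.items()):
            lines.append(f"  {functional:8s} {criterion:6s} -> {code}")
        lines.append("Best overall:")
        for criterion, code in sorted(self.best_overall.items()):
            lines.append(f"  {criterion:6s} -> {code}")
        if self.cycles:
            lines += ["", "Clarke preference cycles (pairwise winners are not transitive):"]
            for a, b, c in self.cycles:
                lines.append(f"  {a} > {b} > {c} > {a}")
        return "\n".join(lines)


def _clarke_winner(report_clarke, f: str, g: str, alpha: float = 0.05) -> str | None:
    tg = report_clarke.get((f, g, "greater"))
    tl = report_clarke.get((f, g, "less"))
    if tg is not None and tg.p_value < alpha:
        return f
    if tl is not None and tl.p_value < alpha:
        return g
    return None


def selection_battery(
    dataset: ChoiceDataset,
    specs: list[ModelSpec],
    options: FitOptions | None = None,
    cv: bool = True,
    cv_allow_failures: bool = True,
    fits: dict[str, FitResult] | None = None,
) -> SelectionReport:
    """Fit (or reuse) every spec and assemble criteria plus pairwise tests.

    Vuong and both one-sided Clarke tests are run for every unordered pair of
    *error specifications within the same preference functional* (non-nested
    pairs); AIC, BIC and - when ``cv`` is on - the grouped-CV OSLLF are
    tabulated per model, with best-within-functional and best-overall flags.
    """
    if not specs:
        raise ValidationError("at least one model spec is required")
    options = options or FitOptions()
    compiled = compile_dataset(dataset)
    fits = dict(fits) if fits else {}
    for spec in specs:
        if spec.code not in fits:
            fits[spec.code] = fit_mle(compiled, spec, options)

    rows = []
    osllf: dict[str, float] = {}
    for spec in specs:
        fit = fits[spec.code]
        aic, bic = information_criteria(fit)
        row = {
            "model": spec.code,
            "functional": spec.functional,
            "error": spec.error.code,
            "k": fit.k_params,
            "loglik": fit.loglik,
            "AIC": aic,
            "BIC": bic,
        }
        if cv:
            cv_options = FitOptions(starts="fast", compute_vcov=False)
            result = osllf_grouped_cv(
                dataset, spec, cv_options, full_fit=fit, allow_failures=cv_allow_failures
            )
            osllf[spec.code] = result.total
            row["OSLLF"] = result.total
        rows.append(row)
    models = pd.DataFrame(rows)

    vuong: dict[tuple[str, str], TestResult] = {}
    clarke: dict[tuple[str, str, str], TestResult] = {}
    by_functional: dict[str, list[ModelSpec]] = {}
    for spec in specs:
        by_functional.setdefault(spec.functional, []).append(spec)
    for functional, group in by_functional.items():
        for sf, sg in itertools.combinations(group, 2):
            ff, fg = fits[sf.code], fits[sg.code]
            try:
                vuong[(sf.code, sg.code)] = vuong_test(ff, fg)
                clarke[(sf.code, sg.code, "greater")] = clarke_test(ff, fg, "greater")
                clarke[(sf.code, sg.code, "less")] = clarke_test(ff, fg, "less")
            except DegenerateComparisonError:
                continue

    criteria = ["AIC", "BIC"] + (["OSLLF"] if cv else [])
    best_within: dict[tuple[str, str], str] = {}
    best_overall: dict[str, str] = {}
    for criterion in criteria:
        sub = models
        for functional in by_functional:
            grp = sub[sub.functional == functional]
            best_within[(functional, criterion)] = (
                grp.loc[grp[criterion].idxmin(), "model"]
                if criterion != "OSLLF"
                else grp.loc[grp[criterion].idxmax(), "model"]
            )
        best_overall[criterion] = (
            sub.loc[sub[criterion].idxmin(), "model"]
            if criterion != "OSLLF"
            else sub.loc[sub[criterion].idxmax(), "model"]
        )

    cycles: list[tuple[str, str, str]] = []
    for functional, group in by_functional.items():
        codes = [s.code for s in group]
        wins: dict[tuple[str, str], str] = {}
        for f, g in itertools.combinations(codes, 2):
            w = _clarke_winner(clarke, f, g)
            if w is not None:
                wins[(f, g)] = w

        def beat(a: str, b: str) -> bool:
            key = (a, b) if (a, b) in wins else (b, a)
            return wins.get(key) == a

        for a, b, c in itertools.permutations(codes, 3):
            if a < b and a < c and beat(a, b) and beat(b, c) and beat(c, a):
                cycles.append((a, b, c))

    return SelectionReport(
        fits=fits,
        models=models,
        vuong=vuong,
        clarke=clarke,
        best_within=best_within,
        best_overall=best_overall,
        cycles=cycles,
    )
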