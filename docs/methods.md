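# Methods

## Models

### Preference functionals

Utility over money is CRRA.  Two algebraic variants are used deliberately:

* the *literal* form u(x) = x^(1−r)/(1−r), which is what the likelihoods
  evaluate, so that the estimated (r, μ) pairs live on the scale on which
  such models are conventionally reported;
* the *normalized* form (x^(1−r) − 1)/(1−r), an affine shift of the same
  preferences that is continuous through r = 1.  It backs the crossover
  (indifference-point) solver, where the search has to pass through r = 1,
  and removes the spurious root at r = 1 that the unshifted x^(1−r) form
  introduces when the 1/(1−r) factor is dropped.

Both agree on every preference comparison.  Inside likelihoods the literal
form is evaluated with a log-limit patch in the 1e-6 neighbourhood of r = 1;
since the noise scale μ is a free parameter, the likelihood value at any
r ≠ 1 is unaffected by the affine representation chosen.

Expected utility is Σ pᵢ u(xᵢ).  Rank-dependent utility applies decision
weights built from the inverse-S weighting function
w(p) = p^γ / (p^γ + (1−p)^γ)^(1/γ); the weight of the k-th best outcome is
w(P(at least as good)) − w(P(strictly better)).  For the two-outcome design
options this reduces to w(p_best)·u(x_best) + (1 − w(p_best))·u(x_worst).
Equal prizes within an option are merged before ranking, which makes the
degenerate last-row options one-outcome lotteries with weight w(1) = 1.  The
general n-outcome cumulative form is implemented but exercised only against
the two-outcome closed form, since the price-list design never needs more.
w(p) is evaluated in log space (logaddexp), so extreme curvature (γ in the
hundreds, reachable during optimization on the log scale) cannot overflow.

### Error specifications

Five stochastic choice rules map option values to P(choose B):

| code | rule |
|------|------|
| FP / FL | Φ or Λ of (V_B − V_A)/μ (Fechner / strong utility) |
| CP / CL | Φ or Λ of (V_B − V_A)/(ν·μ) (contextual / moderate utility) |
| LUCE | V_B^(1/μ) / (V_A^(1/μ) + V_B^(1/μ)) (strict utility) |

ν is the utility range over all four prizes of the pair, computed from
*unweighted* prize utilities (probability weighting does not enter a range
over prizes), so under RDU the same ν applies.  The rescaled contextual
index always lies in [−1, 1] for this design.

The Luce rule needs strictly positive option values raised to 1/μ.  Because
the constant 1/(1−r) cancels from the ratio whenever it is positive, the
rule is evaluated with u(x) = x^(1−r) and restricted to r < 1 (the optimizer
caps r at 0.999 for this specification); r ≥ 1 would make utilities
negative and the ratio undefined.  This restriction is this implementation's
choice of domain, consistent with all Luce-based estimates we are aware of
falling well below r = 1.  The rule is computed as a logit of
(ln V_B − ln V_A)/μ, which is algebraically identical (the strict-to-strong
utility equivalence) and numerically stabler; the identity is asserted in
the tests against the literal ratio.

### Likelihood

Responses are A, B, or INDIFFERENT.  A and B contribute log P(choice);
indifference contributes log(½P(A) + ½P(B)) = log ½ exactly, so indifferent
records shift the log-likelihood by a constant and cannot move any estimate
(asserted end-to-end in the tests).  The mixture functional mixes at the
probability level per record: L = π_EUT·L_EUT + (1 − π_EUT)·L_RDU, with one
shared μ, before the log.  Mixing is at the *choice* level — each choice,
not each subject, has its own latent class; a subject-level variant exists
in the simulator only, as a diagnostic.

Choice probabilities are clipped to [1e-12, 1 − 1e-12] before logs; clip
events are counted and logged at debug level.

A Holt–Laury dataset has at most 20 distinct (pair, response-class) cells
per design, so the likelihood is evaluated on a compiled representation:
option values per unique pair, aggregated with response counts.  A full
likelihood evaluation is a few numpy operations on length-20 arrays, which
is what makes the multi-start fits and the leave-one-subject-out
cross-validation cheap (a full 84-subject CV refit loop for the mixture
takes ~3 s on one core).

## Estimation

Internal parameterization: μ = exp(m), γ = exp(g), π_EUT = logistic(q),
r free.  This keeps the optimizer unconstrained in the interior; wide
internal bounds (|r| ≤ 10, |g| ≤ 7, m ∈ [−16, 10], |q| ≤ 15) only guard
against numerical runaway, and solutions within 1e-6 of them are flagged as
boundary solutions.  Optimization is L-BFGS-B with numerical gradients,
gradient tolerance 1e-8, from a deterministic multi-start grid:

* EUT: r ∈ {−1, −0.5, 0, 0.5, 0.9} × μ ∈ {0.1, 0.5, 1} (15 starts);
* RDU: the same r and μ grids × γ ∈ {0.5, 1, 2} (45 starts);
* mixture: a thinned product r_EUT, r_RDU ∈ {−0.5, 0.5}, γ ∈ {0.5, 2},
  μ ∈ {0.1, 0.5}, π ∈ {0.2, 0.8} (32 starts) — the full five-way product
  would cost ~20× more for no observed gain in located optima.

Best log-likelihood wins; ties below 1e-6 go to the earliest start, so
refits are reproducible.  A "fast" profile with 4–8 starts serves the inner
loops of Monte-Carlo studies and cross-validation (CV refits warm-start at
the full-sample estimate and fall back to the grid on failure).  Probit and
logit fits of the same functional should agree in the preference parameters
(they differ by a link scale factor absorbed into μ); `link_crosscheck`
warns when they disagree by more than 0.1, the standard symptom of a local
maximum.

Covariance: cluster-robust sandwich A⁻¹BA⁻¹ with A the observed information
(central finite differences, step 1e-5·(1 + |θ|)) and B the outer product of
per-subject score sums times C/(C−1) for C clusters, computed on the
internal scale and delta-mapped to the natural scale (Jacobian diag(1, γ, μ,
π(1−π)) as applicable).  A condition number above 1e10 raises rather than
silently inverting.  Wald tests are quadratic forms on the natural scale
against χ² with one degree of freedom per constraint; constraints that pin
π_EUT to 0 or 1 sit on the boundary of the parameter space, where the χ²
reference is nonstandard — the statistic is reported in the conventional
form regardless, as is customary in this literature.

## Model judging

AIC = 2k − 2LL, BIC = k·ln(n) − 2LL with n the number of choice records.
The Vuong statistic is Σmᵢ / (√n·sd(mᵢ)) on per-record log-likelihood
ratios, ML (ddof = 0) standard deviation by default, one-sided upper-tail
normal p-value; options expose the unbiased-sd variant, a per-subject
clustered variant, and a BIC-type correction for comparisons with unequal k
(within one functional all k are equal, so the correction vanishes where the
battery uses the test).  The Clarke test drops zero differences (|m| ≤
1e-12), counts positives, and reports exact binomial tail probabilities in
both one-sided directions; no continuity correction.  Pairwise sign tests
are not transitive in general, and the battery searches for and reports
preference cycles instead of suppressing them.

OSLLF leaves one subject (their full 20 choices) out at a time, refits, and
sums the held-out log-likelihoods evaluated at the leave-that-subject-out
estimates.  Refit failures are flagged per cluster and excluded only when
the caller opts in.

## The synthetic generator

The generator emulates the study conditions the analysis assumes: 84
subjects, each answering both the baseline and the five-fold-scaled 10-row
lists (20 choices), responses drawn independently from the model's own
choice probabilities, and — for the mixture — the latent EUT/RDU class drawn
per choice with probability π_EUT.  Parameter presets for all 15 models use
the published estimates; the default truth is the mixture contextual-probit
preset (r_EUT = 0.409, r_RDU = −0.291, γ = 0.391, μ = 0.106, π_EUT = 0.316).
Indifference carries no parametric information, so it is injected
exogenously at a configurable rate (default 0; the empirical rate in the
original sessions is not published).

What the generator does *not* emulate: subject-level preference
heterogeneity (every subject shares the truth parameters; clustering in the
data arises only through the design), order or session effects, and
covariates.  Recovery results on these data therefore speak to the
estimator and the identification of the model, not to robustness against
heterogeneity misspecification.

## Known limitations

* **Mixture identification at experimental scale.**  The choice-level
  mixture under contextual probit is multimodal at 84×20 observations: a
  component with extreme weighting curvature (γ ≳ 4, w(p) nearly a step
  function) combined with shifted (r, μ) reproduces almost the same choice
  probabilities as the generating overweighting component, and on a sizable
  share of simulated replications that rival mode *is* the global maximum
  likelihood point, typically by well under one log-likelihood point.
  Monte-Carlo recovery of γ and π_EUT at the default truth is accordingly
  poor even though each located mode is sharply estimated; r_EUT and the
  fit/selection behaviour are much less affected.  Model *ranking* (AIC,
  OSLLF) is robust to this: the mixture still dominates a misspecified EUT
  regardless of which mode wins.  Users fitting mixtures to data of this
  size should compare probit/logit solutions and inspect multiple starts
  before interpreting γ and π.
* Wald inference at π boundaries is reported conventionally despite the
  nonstandard reference distribution.
* Only two-outcome-per-option price lists are supported end-to-end; the
  n-outcome RDU machinery exists but has no design builder.
* No loss-domain lotteries, trembles, random-preference errors, or
  subject-level mixtures; no Bayesian or hierarchical estimation.

## Monte-Carlo problem sizes

The shipped studies use the study-scale design throughout: 84 subjects × 20
choices, 50 replications for recovery and selection-consistency runs, and
full leave-one-subject-out CV (84 refits per model per replication).  These
sizes are the package's reference conditions; the compiled likelihood keeps
them inexpensive.
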