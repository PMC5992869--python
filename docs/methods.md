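# Methods

## Model

The life course is a discrete-time absorbing Markov chain in column-to-row
(column-stochastic) orientation.  Transient states 1..ω are living age
classes or stages; absorbing states 1..α are death states, optionally
classified by cause.  The full transition matrix is the block matrix
P = [[U, 0], [M, I_α]].  For age-classified models U carries the survival
probabilities p_j on the subdiagonal; an optional corner entry p_ω < 1
makes the last class open-ended (age-invariant survival, geometric tail).
Stage-classified chains are supported by constructing `TransientMatrix`
directly from an arbitrary substochastic U with spectral radius < 1.

One time step equals one age-class width (1 year by default); all reward
and longevity units follow it.  The fundamental matrix N = (I − U)⁻¹ is
obtained by a dense linear solve (`scipy.linalg.solve`), not explicit
inversion; the contract is a relative residual of (I − U)N = I below
1e−10, which fails loudly for (numerically) non-absorbing chains.  The
moments of remaining longevity — which count the step in which death
occurs, so η₁ ≥ 1 — are η₁ᵀ = 1ᵀN, η₂ᵀ = η₁ᵀ(2N − I),
η₃ᵀ = η₁ᵀ(6N² − 6N + I); the η₃ coefficient pattern is cross-checked
against exhaustive enumeration of lifetime distributions in the test suite.

Rewards are random variables attached to transitions; their k-th raw
moments (about zero) fill matrices R_k, entry (i, j) for the transition
j → i.  The accumulated lifetime reward has raw moment vectors ρ̃_k over
starting classes satisfying the recursion

    ρ̃_m = Nᵀ Z (P ∘ R_m)ᵀ 1 + Σ_{k=1}^{m−1} C(m,k) Nᵀ (U ∘ R̃_{m−k})ᵀ ρ̃_k,

with Z = [I | 0] and R̃_k = Z R_k Zᵀ.  The general recursion is the single
implementation for every order (default maximum 3, arbitrary m supported
when R provides the moments); the order-specific formulas exist only as
test oracles.  Summary statistics: V = ρ̃₂ − ρ̃₁∘ρ̃₁, SD = √V, CV = SD/ρ̃₁
(missing where the mean is 0), Sk = (ρ̃₃ − 3ρ̃₁∘ρ̃₂ + 2ρ̃₁³)/V^{3/2}
(missing where V = 0).  Statistics are reported for every transient
starting state, the open-ended class included.

## Reward constructions and conventions

**Binary outcomes.**  The reward for a year lived in class j is a
Bernoulli variable: 1 with the prevalence v_j, else 0.  Rewards attach to
the *origin* class j of every transition out of j.  Individuals dying
during a step are credited a fraction `death_credit` of the year, default
1/2, exposed as a parameter.  Two constructions of the higher moments are
implemented because they genuinely differ on the death row:

* `paper_literal` (default): R₃ = R₂ = R₁, i.e. the half-credit death
  entry v_j/2 is reused unchanged for all orders;
* `moment_consistent`: strict Bernoulli raw moments, death-row k-th moment
  v_j · (1/2)^k.

The two agree on all living transitions (Bernoulli moments of a 0/1
variable are all v).  Neither is "the" correct convention — they encode
slightly different random variables for the death-year credit — so the
mode in force is recorded in every output file and result object rather
than silently fixed.  Setting v ≡ 1 yields total longevity; with
`death_credit=1` the accumulated reward is exactly the time to absorption
and reproduces η₁..η₃ (a test invariant).

**Grouped and ordinal outcomes.**  Prevalences of mutually exclusive
outcomes add; any nonempty proper subset of n outcomes defines a binary
condition (2ⁿ − 2 in total).  For n ordered levels the n − 1
order-preserving cuts are enumerated explicitly.

**Interval-scale outcomes.**  Living transitions out of class j carry the
empirical raw moments m₁..m₃ of the outcome in class j (computed from
microdata or supplied pre-aggregated); death transitions follow the same
death-credit convention as the binary case.  Raw moments are about zero.

**Fixed rewards and the variance decomposition.**  Replacing R_k by the
elementwise powers of R₁ keeps every per-transition mean but removes the
per-transition variance; the lifetime variance under fixed rewards is the
among-trajectory component, and the within-trajectory component is the
difference from the total.  The decomposition is exact by construction;
within-components in (−1e−9, 0) from floating-point cancellation are
clamped to zero, anything more negative raises.

**Sullivan consistency.**  With L_j(x) = N_{j,x} · (p_j + (1 − p_j)·c),
where p_j is the probability of surviving the step and c the death credit,
the prevalence-weighted sum Σ_{j≥x} L_j v_j equals ρ̃₁[x] for binary
rewards *exactly*, in both moment modes (the first moments coincide).
This is the L construction `occupancy_person_years` implements; other a_x
conventions would make the match approximate.

**DALYs.**  The chain carries two absorbing states: death from the focal
cause and death from all other causes, with per-age cause-1 probability
q_j ≤ 1 − p_j supplied directly (or as a fraction of deaths via the CLI).
Survival transitions out of class j carry the disability reward —
severity s_j with probability v_j, so k-th moment s_j^k v_j; the
focal-cause death transition from class j carries the remaining-longevity
moments η_k[j] of the *standard* (reference) schedule at the matched class
index; other-cause deaths and absorbing-origin columns carry nothing.
Focal and standard schedules must share one age grid.  No disability
credit is given in the year of death (configurable in principle, default
off), and no GBD-style age-weighting or discounting is applied.  Because
each transition carries exactly one reward type, the mean DALY is exactly
the sum of the YLL and YLD component means, which are reported separately.

## Numerical choices

* Column conservation of P is enforced at 1e−9 on construction (inputs
  are parsed from finite-precision text); analytic identities in tests are
  held to 1e−10..1e−12.
* Variances in (−1e−9, 0) are clamped to zero with a logged warning;
  beyond that an `InconsistentMomentsError` is raised — cancellation in
  ρ̃₂ − ρ̃₁² is the only legitimate source of tiny negatives.
* CV and skewness use NaN (empty CSV fields) for their degenerate cases
  (zero mean, zero variance) rather than ±inf, including in the
  open-ended last class.
* Reward matrices are stored densely per origin class; entries on
  impossible transitions are irrelevant because rewards enter only through
  Hadamard products with P or U.  The one exception is the DALY YLL row,
  which is explicitly masked to transitions with q_j > 0 so that the
  stored matrices honour the "rewards only where transitions exist"
  convention.

## Oracles

Two independent reference implementations validate the recursion.
`enumerate_exact` walks the entire (path × reward-realization) space of a
bounded chain with exact probabilities (capped at 10⁶ outcomes) — on
hundreds of random chains with ω ≤ 3 the analytic moments match it to
1e−12, which is the package's core correctness property.
`simulate_rewards` samples whole lifetimes with a single seeded generator
(reproducible by construction) and agrees with the analytic mean and SD to
within 4 standard errors at 10⁵ replicates on the 41-class synthetic
cohort.  Interval-scale outcomes specify moments, not a distribution, so
the oracles check them through explicit discrete samplers whose raw
moments match the reward matrices (asserted by `RewardSampler.check_moments`
before every comparison).  A step cap of ~10× the longest mean lifetime
guards the simulator against non-absorbing misconfiguration.

## Synthetic cohort

The generator emulates a survey-plus-life-table study of older Europeans,
ages 50–90 with calculations truncated at 90 (the last class is certainly
fatal; truncation cuts lifetimes rather than conditioning on death before
90).  Mortality is Gompertz, q(x) = 0.004·e^{0.088(x−50)} for the default
male cohort (≈0.4% at 50, doubling every ~8 years — a realistic modern
European male schedule); the ADL-free prevalence declines logistically
from ≈0.98 toward a midpoint at age 92 (≈0.97 at 50, ≈0.56 at 90); grip
strength has an age-linear mean falling from 46 kg at 50 by 0.4 kg/year,
constant CV 0.21 and constant skewness −0.1.  The female preset lowers
mortality and grip level.  Schedules are deterministic parametric curves;
the seed drives only the skew-normal grip microdata (80 observations per
age class).  Under these conditions the canonical patterns emerge:
healthy expectancy below total expectancy everywhere, SD of remaining
healthy life declining with age, CV slowly rising, skewness negative at
the youngest ages.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: survey weighting and nonresponse, abridged
or smoothed life tables, cohort effects, and any year-to-year correlation
in an individual's health state.  The last point is intrinsic to
prevalence-based analysis itself: health status is drawn independently at
each age, so the within-trajectory variance is that of independent
Bernoulli draws, not of persistent disability spells.  Incidence-based
multistate models, parameter-uncertainty propagation and sensitivity
analysis via matrix calculus are out of scope.

## Problem sizes

Test and validation runs use ω ≤ 3 chains for exhaustive enumeration
(hundreds of chains, exact to 1e−12), the 41-class cohort for end-to-end
checks, and 10⁵ Monte-Carlo replicates — sizes at which the enumeration
space stays exact and the whole suite runs in seconds while exercising
every code path at the tolerances stated above.
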