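# Methods

## The generative model

A meta-changing environment is a discrete stochastic process over J
nutrients whose transition statistics are selected by a hidden regime
("switch state") chain with K states.  The initial nutrient C₀ is drawn
from π_c0, the initial regime S₁ from π_s1, and thereafter

- S_t | S_{t−1}=i ~ Multinomial(π_i), one regime per observed transition;
- C_t | C_{t−1}=i, S_t=j ~ Multinomial(π′_ij).

All probability vectors carry Dirichlet priors.  The alignment
convention used throughout (generator, enumeration oracle, particle
filter) is that S₁ governs the first transition C₀→C₁; a history of
T+1 observations therefore involves T regime values and T−1 regime
transitions.

**Hyperparameters.** Defaults: α_s1, α_c0, α_c are all-ones vectors;
the regime-transition prior α_s gives self-transitions pseudo-count 2
and all other entries 1, a weakly sticky prior reflecting that regimes
persist.  All are overridable (`Hyperparameters`, model-spec YAML).

## Collapsed inference

By Dirichlet-Multinomial conjugacy the transition parameters integrate
out, leaving count matrices as sufficient statistics: S[i,j] (regime
i→j transitions) and C[i,j,k] (nutrient i→j under regime k).  The
collapsed predictives are the Pólya-urn ratios

    P(S_{t+1}=j | S_t=i) = (α_s⁽ʲ⁾ + S[i,j]) / Σ_k (α_s⁽ᵏ⁾ + S[i,k])
    P(C_{t+1}=c | C_t=b, S_{t+1}=k) = (α_c⁽ᶜ⁾ + C[b,c,k]) / Σ_j (α_c⁽ʲ⁾ + C[b,j,k])

**Exact oracle.** `exact_posterior_predictive` sums over every regime
trajectory, scoring each by the sequential product of collapsed ratios,
and caps the enumeration at K^T ≤ 4096 trajectories (T ≤ 12 for K=2);
beyond that it raises rather than approximating.  The test suite checks
it against an independently coded batch closed form (log-gamma
marginal likelihoods over complete assignments) to 1e-10, and checks
that for K=1 it reduces exactly to the flat Markov model.

**Particle filter.** Each particle is {s, S, C}.  Per observation:
(1) the one-step-ahead predictive is emitted (weighted average over
particles of Σ_{s′} P(s′|s)·P(c|c_prev,s′)); (2) each particle samples
its next regime from its own collapsed switch row, recording the draw
into S *after* sampling; (3) weights are multiplied by the collapsed
probability of the observed nutrient transition under the particle's
regime, renormalized, and the transition is recorded into C — so every
probability conditions only on strictly past events.  Initial regimes
are drawn from the prior with uniform weights; N=200 particles by
default.  Systematic resampling (count statistics copied by value)
triggers when the effective sample size drops below N/2; an
always-resample mode is available since the original schedule is a
judgment call either way.  One root seed drives a single generator for
the whole filter pass, so (model, history, N, seed) determine all
outputs.

## Growth model

Populations grow exponentially at the matched nutrient's rate and not
at all when mismatched (V₁₂ = V₂₁ = 0), with no switching cost.
Actions commit at time t and take effect at t+k with lag k=1: the
population multiplier at step t+1 is exp(μ_c·dt) for the matched
fraction and 1 otherwise.  Bet-hedging fractions are deterministic
population partitions (infinite-population limit), so the multiplier is
the fraction-weighted mixture.  A sharp consequence of the lag, used as
a test: in a strictly alternating environment the plastic policy is
always mismatched and its population is frozen.

**Default rates.** μ_Glu = 0.6, μ_Gal = μ_Mal = 0.3 e-folds per step —
the 2:1 glucose:galactose ratio observed in yeast growth-rate data,
with absolute scale set to give a few e-folds per regime sojourn.
A helper converts doublings/hour to e-fold rates (×ln 2).

**Rate estimation.** `estimate_growth_rate` fits a smoothing spline
(GCV-selected penalty) to log population vs. time and reports the
maximum of the fitted derivative — the "exponential phase" convention
used for OD growth curves (least-squares slope fallback below 8
points).  For whole-run policy comparisons `compare_policies` uses the
*time-averaged* derivative instead: the maximum picks the best
transient regime and would score any policy that ever matches glucose
identically, which is not a meaningful whole-run comparison.

**Policy comparison.** Each replicate samples one environment shared by
all policies (common random numbers); predictive policies share a
single particle-filter pass per replicate; per-policy RNG streams are
keyed by policy name so results are invariant to policy ordering.
Confidence intervals are 95% percentile bootstrap (10,000 resamples of
the replicate means).  Defaults: 20 replicates of 200 steps.

**Regime settings.** The two-regime glucose/galactose environment
(periodic alternation vs. constant glucose) is parameterized by
p₁ = P(periodic→periodic) and p₂ = P(constant→periodic).  The "periodic"
regime is implemented as near-deterministic alternation with slack
ε = 0.02 (configurable, including ε = 0) so the generative environment
and the inference model share support.  For the fitness study the four
settings (p₁, p₂) ∈ {(0.95, 0.05), (0.95, 0.1), (0.9, 0.05), (0.9, 0.1)}
give mean regime sojourns of 10–20 steps — matching the 20-step regime
blocks used in the re-adaptation analysis, long enough for regimes to
be learnable, short enough that both regimes are visited repeatedly in
200 steps.  The three-nutrient archetype matrices are parameterized
constructors (persistence 0.9 by default): published versions of these
environments exist only as heat maps, so the archetypes reproduce their
qualitative structure, not exact values.

## Closed-form policy analysis

For known two-nutrient Markov environments the expected rates are
unweighted sums of the conditional rates over the two previous states:
R(π₁) = V₁₁[θ_gg + θ_galg], R(π₂) = V₂₂[(1−θ_gg) + (1−θ_galg)], and the
four-case piecewise R(π₃) that picks, per previous state, glucose iff
its successor probability is ≥ 0.5.  A stationary-distribution-weighted
variant is available behind `weighted=True` for users who prefer a
time-average interpretation; the unweighted form is the default.  Note
that R(π₃) dominates both constitutive policies on the whole parameter
square exactly when V₁₁ = V₂₂; with unequal rates the most-probable-
nutrient choice is not rate-optimal and the glucose-only policy wins in
part of the space — which is precisely what the fold-change grid maps.
Grid cells where R(π₁) = 0 are reported as NaN, never infinity.

## Transition-counter circuit

Eight species: the two sugars (clamped inputs), two sensors, two
activators, two counters.  Each sugar catalytically produces the sensor
for the *other* sugar; sensor + own sugar reversibly form an activator;
the activator catalytically produces a counter species.  An activator
can therefore only form at an actual switch (the sensor pool must have
been armed by the previous sugar), and the counter increments once per
directed switch.  Rate-law conventions: catalytic steps are linear in
the modifier; binding is mass-action in both reactants with first-order
reverse; degradation is first-order.

Default constants (arbitrary units): sensor production 0.5 and
degradation 0.2 (time constant 5, well below the 50-unit pulses),
binding 1.0 / unbinding 0.1, activator degradation 0.2, counter
production 0.5, counter degradation 1e-4 (500× slower than sensors, so
counter levels are effectively stable over a 200-unit run).  Exact
published constants for this architecture are not available; these
values satisfy the architecture's stated constraints (fast
sensor/activator turnover, very slow counter decay, symmetric branches)
and all quantitative readouts are parameter-robust integer counts and
ratios, calibrated against a single-switch simulation rather than
absolute concentrations.  Integration is LSODA with rtol 1e-8 / atol
1e-10, segment-by-segment at input discontinuities, output every 0.1
time units; trajectories are clipped at zero (tolerance-level
undershoot only).

## Problem sizes used in the checks

Oracle-equivalence runs use 20 histories of 6 transitions (64
trajectories each) at N ∈ {50, 500, 4000–5000} particles; the
re-adaptation signature uses 50 filter seeds on an 80-step trace at
N=200; the fitness study uses 4 settings × 20 replicates × 200 steps;
Monte-Carlo conjugacy checks use 20,000–40,000 Dirichlet draws per
configuration.

## Limitations

- The environment and model are first-order Markov given the regime;
  long-memory environments are out of scope.
- K is fixed in advance (default 2); no nonparametric regime inference.
- Growth ignores death, extinction risk, switching costs, and finite-
  population stochasticity in bet-hedging fractions.
- The circuit model is deterministic mass-action chemistry: no
  molecular noise, gene-expression variability, or dilution by cell
  division; counter dynamic range is bounded by the slow degradation.
- Synthetic environments are the only data source; passing tests show
  internal consistency of model, inference and simulation, not fidelity
  to any particular natural environment.
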