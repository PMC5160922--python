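# metachange

Bayesian inference and growth-policy simulation for microbes in
**meta-changing nutrient environments** — discrete environments (e.g.
glucose/galactose fluctuations in the gut) whose fluctuation statistics
themselves change over time, driven by regimes the cell cannot observe.

## The model

The environment emits one nutrient per time step.  A hidden "switch
state" chain S₁..S_T (K regimes) selects which nutrient transition
matrix is active, and the nutrient C_t is drawn conditional on C_{t−1}
and S_t:

    S_t | S_{t−1}=i  ~ Multinomial(π_i)         π_i   ~ Dirichlet(α_s)
    C_t | C_{t−1}=i, S_t=j ~ Multinomial(π′_ij)  π′_ij ~ Dirichlet(α_c)

The quantity every adaptive policy consumes is the **posterior
predictive distribution** P(C_{t+1} | C_{0:t}).  Because the Dirichlet
priors are conjugate, all transition probabilities integrate out
analytically, leaving transition *counts* as sufficient statistics.  The
package provides:

- **`environments`** — Markov and hidden-regime environment generators
  (two- and three-nutrient, with constructors for periodic/constant
  glucose–galactose regimes and three multi-nutrient archetypes);
- **`dbn`** — collapsed Dirichlet-Multinomial predictive probabilities,
  prior sampling, an exact enumeration oracle for short histories, and a
  flat (no-hidden-state) Markov baseline;
- **`particle`** — a particle filter estimating the posterior predictive
  in real time; each particle is {s, **S**, **C**} (current regime plus
  private count matrices), with collapsed predict/update steps and
  systematic resampling (default 200 particles);
- **`policies` / `growth`** — posterior-predictive, plastic, random,
  constant and bet-hedging growth policies, simulated with exponential
  growth, zero mismatched growth and a one-step action lag; spline-based
  growth-rate estimation and bootstrap policy comparisons;
- **`analytic`** — closed-form expected growth rates R(π₁), R(π₂), R(π₃)
  for two-nutrient Markov environments and the fold-change grid
  R(π₃)/R(π₁);
- **`circuit`** — a mass-action ODE model of an eight-component
  molecular circuit that *counts directed nutrient transitions* in the
  plateau levels of slowly degrading memory species — the count
  statistics collapsed inference needs, implemented in chemistry.

## Worked example

Counting nutrient switches with the molecular circuit
(`python examples/transition_counter.py`):

```
GluToGal: final level 9.52 a.u., single-switch increment 4.79 -> count = 2, spikes at t = [52, 152]
GalToGlu: final level 4.76 a.u., single-switch increment 4.79 -> count = 1, spikes at t = [102]
```

Under alternating glucose/galactose doses switching at t = 50, 100 and
150, the Glu→Gal memory species spikes at each glucose→galactose switch
(t≈50 and t≈150) and the Gal→Glu species at the single reverse switch
(t≈100).  Dividing final plateau levels by the calibrated single-switch
increment recovers the integer counts 2 and 1 — the circuit has stably
memorized the environment's transition history.

Policy fitness in a meta-changing environment
(`python examples/policy_fitness.py`):

```
                 policy    p1    p2  mean_rate  ci_lo  ci_hi  n_sims
   posterior_predictive 0.950 0.050      0.465  0.448  0.484      10
posterior_predictive_bh 0.950 0.050      0.420  0.403  0.439      10
                plastic 0.950 0.050      0.265  0.203  0.325      10
                 random 0.950 0.050      0.265  0.251  0.279      10
              random_bh 0.950 0.050      0.293  0.283  0.302      10
               constant 0.950 0.050      0.430  0.400  0.459      10
```

Rates are e-folds per step (glucose supports 0.6, galactose 0.3).  The
inference-based policy learns the alternation inside periodic regimes
and outperforms the plastic policy (always one step behind a perfectly
periodic environment), the random policy, and constitutive glucose use.

The other examples show the closed-form policy analysis
(`markov_policy_analysis.py`) and the hidden-regime re-adaptation
signature (`regime_inference.py`).  A thin CLI exposes the same
machinery (`metachange simulate-env | filter | compare-policies |
analytic-grid | circuit-sim`).

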