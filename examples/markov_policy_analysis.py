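"""Closed-form policy analysis in a two-nutrient Markov environment.

Computes the expected growth rates of the glucose-only, galactose-only
and most-probable-nutrient (posterior predictive) policies as a function
of the environment's transition probabilities, and summarizes the
fold-change grid of predictive over glucose-only growth.
"""

import numpy as np

from metachange import (
    MarkovPolicyInputs,
    expected_rate_galactose_only,
    expected_rate_glucose_only,
    expected_rate_posterior_predictive,
    fold_change_grid,
)

# A "periodic-ish" environment: glucose rarely repeats, galactose usually
# returns to glucose.  Rates: glucose supports twice the galactose rate.
inp = MarkovPolicyInputs(theta_gg=0.2, theta_galg=0.9, v11=0.6, v22=0.3)

r1 = expected_rate_glucose_only(inp)
r2 = expected_rate_galactose_only(inp)
r3 = expected_rate_posterior_predictive(inp)
print(f"theta_Glu->Glu = {inp.theta_gg}, theta_Gal->Glu = {inp.theta_galg}")
print(f"R(glucose-only)          = {r1:.3f}")
print(f"R(galactose-only)        = {r2:.3f}")
print(f"R(posterior predictive)  = {r3:.3f}  (fold change vs glucose-only: {r3 / r1:.3f})")
print("-> anticipating the alternation beats constitutively tuning to glucose here.\n")

thetas, grid = fold_change_grid(101, v11=0.6, v22=0.3)
upper = grid[np.ix_(thetas >= 0.5, thetas >= 0.5)]
print(f"fold-change grid over (theta_Glu->Glu, theta_Gal->Glu) in [{thetas[0]:.2f}, 1]^2:")
print(f"  cells where predictive wins  (ratio > 1): {(grid > 1).mean():.1%}")
print(f"  cells where glucose-only wins (ratio < 1): {(grid < 1).mean():.1%}")
print(f"  quadrant theta >= 0.5 is identically 1.0: {bool(np.all(upper == 1.0))}")
print("-> with unequal rates, probability matching only pays off in part of the space.")
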