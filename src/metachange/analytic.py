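"""Closed-form expected growth rates in two-nutrient Markov environments.

For an environment with transition probabilities theta_Glu->Glu and
theta_Gal->Glu, growth rate V11 when correctly tuned to glucose, V22
when correctly tuned to galactose, and zero growth when mismatched, the
expected growth rates of the constitutive policies are obtained by
summing the conditional rate R(pi | C_{t-1}) over the two possible
previous states:

    R(pi1) = V11 * [theta_gg + theta_galg]                (glucose-only)
    R(pi2) = V22 * [(1 - theta_gg) + (1 - theta_galg)]    (galactose-only)

The posterior-predictive policy picks, for each previous state, the
nutrient most likely to come next, giving a four-case piecewise form
R(pi3).  By construction R(pi3) >= max(R(pi1), R(pi2)).  These sums are
unweighted over the previous state; a variant weighting by the chain's
stationary distribution is available via ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovPolicyInputs",
    "expected_rate_glucose_only",
    "expected_rate_galactose_only",
    "expected_rate_posterior_predictive",
    "fold_change_grid",
]


@dataclass(frozen=True)
class MarkovPolicyInputs:
    """Environment and growth parameters of the two-nutrient closed forms."""

    theta_gg: float  # P(Glu -> Glu)
    theta_galg: float  # P(Gal -> Glu)
    v11: float  # growth rate tuned to Glu in Glu
    v22: float  # growth rate tuned to Gal in Gal

    def __post_init__(self) -> None:
        if not (0 <= self.theta_gg <= 1 and 0 <= self.theta_galg <= 1):
            raise ValueError("transition probabilities must be in [0, 1]")
        if self.v11 < 0 or self.v22 < 0:
            raise ValueError("growth rates must be nonnegative")


def _stationary_weights(theta_gg: float, theta_galg: float) -> np.ndarray:
    """Stationary distribution of the 2-state chain over (Glu, Gal)."""
    denom = (1 - theta_gg) + theta_galg
    if denom == 0:  # absorbing glucose
        return np.array([1.0, 0.0])
    w_glu = theta_galg / denom
    return np.array([w_glu, 1 - w_glu])


def _combine(cond_prev_glu: float, cond_prev_gal: float, inp: MarkovPolicyInputs, weighted: bool) -> float:
    if not weighted:
        return cond_prev_glu + cond_prev_gal
    w = _stationary_weights(inp.theta_gg, inp.theta_galg)
    return float(w[0] * cond_prev_glu + w[1] * cond_prev_gal)


def expected_rate_glucose_only(inp: MarkovPolicyInputs, weighted: bool = False) -> float:
    """R(pi1) = V11 * [theta_gg + theta_galg]."""
    return _combine(inp.v11 * inp.theta_gg, inp.v11 * inp.theta_galg, inp, weighted)


def expected_rate_galactose_only(inp: MarkovPolicyInputs, weighted: bool = False) -> float:
    """R(pi2) = V22 * [(1 - theta_gg) + (1 - theta_galg)]."""
    return _combine(inp.v22 * (1 - inp.theta_gg), inp.v22 * (1 - inp.theta_galg), inp, weighted)


def expected_rate_posterior_predictive(inp: MarkovPolicyInputs, weighted: bool = False) -> float:
    """R(pi3): per previous state, the better of tuning to Glu or Gal.

    Four cases on (theta_gg >= 0.5, theta_galg >= 0.5); at exactly 0.5
    the glucose branch is used (the ">= 0.5" case assignment).
    """
    glu_term = inp.v11 * inp.theta_gg if inp.theta_gg >= 0.5 else inp.v22 * (1 - inp.theta_gg)
    gal_term = inp.v11 * inp.theta_galg if inp.theta_galg >= 0.5 else inp.v22 * (1 - inp.theta_galg)
    return _combine(glu_term, gal_term, inp, weighted)


def fold_change_grid(
    resolution: int,
    v11: float,
    v22: float,
    delta: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid of R(pi3)/R(pi1) over (theta_gg, theta_galg) in [delta, 1]^2.

    Returns ``(thetas, grid)`` where ``grid[i, j]`` is the fold change at
    theta_gg = thetas[i], theta_galg = thetas[j].  Cells where R(pi1) is
    zero are NaN (undefined ratio, never infinity).  ``delta`` > 0 keeps
    the default grid away from the R(pi1) = 0 corner.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if v11 <= 0:
        raise ValueError("v11 must be positive (glucose-only rate is the denominator)")
    thetas = np.linspace(delta, 1.0, resolution)
    grid = np.empty((resolution, resolution))
    for i, tg in enumerate(thetas):
        for j, tgal in enumerate(thetas):
            inp = MarkovPolicyInputs(tg, tgal, v11, v22)
            r1 = expected_rate_glucose_only(inp)
            r3 = expected_rate_posterior_predictive(inp)
            grid[i, j] = np.nan if r1 == 0 else r3 / r1
    return thetas, grid
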