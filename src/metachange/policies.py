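"""Growth policies: mappings from beliefs or history to population actions.

Winner-take-all policies commit the whole population to one nutrient;
bet-hedging policies split the population into fractions.  The
posterior-predictive policy consumes the belief state P(C_{t+1}|C_{0:t})
produced by the inference machinery; the plastic policy tunes to the
nutrient observed last; random and constant policies are baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Action", "PolicySpec", "POLICY_NAMES", "act", "analytic_pp_action"]

POLICY_NAMES = (
    "posterior_predictive",
    "plastic",
    "random",
    "constant",
    "posterior_predictive_bh",
    "random_bh",
)

# Policies whose action depends on the inferred posterior predictive belief.
BELIEF_POLICIES = ("posterior_predictive", "posterior_predictive_bh")


@dataclass(frozen=True)
class Action:
    """Either a single tuned nutrient or a bet-hedging fraction vector."""

    nutrient: int | None = None
    fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.nutrient is None) == (self.fractions is None):
            raise ValueError("action must set exactly one of nutrient / fractions")
        if self.fractions is not None:
            f = np.asarray(self.fractions, dtype=float)
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("bet-hedging fractions must be nonnegative and sum to 1")
            object.__setattr__(self, "fractions", f)

    @property
    def is_bet_hedging(self) -> bool:
        return self.fractions is not None


@dataclass(frozen=True)
class PolicySpec:
    """Named policy with its parameters.

    ``target`` is the fixed nutrient of the constant policy (default 0,
    the preferred nutrient); ``tie_break`` resolves exact belief ties in
    the winner-take-all posterior-predictive policy.
    """

    name: str
    target: int = 0
    tie_break: int = 0

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ValueError(f"unknown policy {self.name!r}; choose from {POLICY_NAMES}")

    @property
    def needs_belief(self) -> bool:
        return self.name in BELIEF_POLICIES

    @property
    def is_bet_hedging(self) -> bool:
        return self.name.endswith("_bh")


def _argmax_with_tiebreak(belief: np.ndarray, tie_break: int) -> int:
    best = belief.max()
    winners = np.flatnonzero(belief >= best - 1e-12)
    if tie_break in winners:
        return int(tie_break)
    return int(winners[0])


def act(
    policy: PolicySpec,
    belief: np.ndarray | None = None,
    last_observed: int | None = None,
    rng: np.random.Generator | None = None,
    J: int | None = None,
) -> Action:
    """Produce the policy's action for one time step.

    ``belief`` (a J-vector) is required for the posterior-predictive
    policies, ``last_observed`` for the plastic policy, ``rng`` for the
    random policy and ``J`` (number of nutrients) wherever it cannot be
    inferred from the other inputs.
    """
    if belief is not None:
        belief = np.asarray(belief, dtype=float)
        J = belief.size
    name = policy.name
    if name == "posterior_predictive":
        if belief is None:
            raise ValueError("posterior_predictive policy requires a belief")
        return Action(nutrient=_argmax_with_tiebreak(belief, policy.tie_break))
    if name == "posterior_predictive_bh":
        if belief is None:
            raise ValueError("posterior_predictive_bh policy requires a belief")
        return Action(fractions=belief / belief.sum())
    if name == "plastic":
        if last_observed is None:
            raise ValueError("plastic policy requires the last observed nutrient")
        return Action(nutrient=int(last_observed))
    if name == "random":
        if rng is None or J is None:
            raise ValueError("random policy requires an rng and the number of nutrients J")
        return Action(nutrient=int(rng.integers(J)))
    if name == "random_bh":
        if J is None:
            raise ValueError("random_bh policy requires the number of nutrients J")
        return Action(fractions=np.full(J, 1.0 / J))
    if name == "constant":
        return Action(nutrient=policy.target)
    raise AssertionError("unreachable")


def analytic_pp_action(theta_gg: float, theta_galg: float, c_prev: int) -> Action:
    """Most-probable-successor action in a known two-nutrient Markov environment.

    With transition probabilities theta_Glu->Glu and theta_Gal->Glu
    given, tunes to glucose iff the successor of the previous state is
    more likely to be glucose (strictly > 0.5), else galactose.
    """
    if not (0 <= theta_gg <= 1 and 0 <= theta_galg <= 1):
        raise ValueError("transition probabilities must be in [0, 1]")
    p_glu = theta_gg if c_prev == 0 else theta_galg
    return Action(nutrient=0 if p_glu > 0.5 else 1)
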