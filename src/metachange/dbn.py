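"""Dynamic Bayesian model of meta-changing nutrient environments.

The generative model is a switching state-space model: a hidden regime
("switch state") chain S_1..S_T selects, at each step, which nutrient
transition matrix produces C_t from C_{t-1}.  All transition probability
vectors carry Dirichlet priors, so they can be integrated out
analytically (Dirichlet-Multinomial conjugacy), leaving transition
*count* matrices as the sufficient statistics:

* ``S[i, j]``    — times hidden state i moved to hidden state j,
* ``C[i, j, k]`` — times nutrient i moved to nutrient j under hidden state k.

This module provides the collapsed predictive probabilities, prior
sampling, an exact enumeration oracle for the posterior predictive
distribution P(C_{t+1} | C_{0:t}) (feasible for short histories), and a
flat Markov baseline with no hidden states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environments import NutrientSequence, default_alphabet

__all__ = [
    "Hyperparameters",
    "ModelSpec",
    "CountStatistics",
    "EnumerationError",
    "collapsed_switch_prob",
    "collapsed_switch_row",
    "collapsed_nutrient_prob",
    "collapsed_nutrient_row",
    "sample_from_prior",
    "exact_posterior_predictive",
    "flat_markov_posterior_predictive",
    "flat_predictive_sequence",
]


class EnumerationError(ValueError):
    """Raised when exact enumeration over switch trajectories is infeasible."""


# Largest number of switch trajectories the exact oracle will enumerate.
MAX_TRAJECTORIES = 4096


@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet hyperparameters of the model.

    Defaults follow the standard weakly informative setting: all-ones
    vectors everywhere, except that hidden-state self-transitions get
    pseudo-count 2 (vs. 1 for entering another state), a weakly "sticky"
    prior on regimes.
    """

    alpha_s1: np.ndarray  # (K,) prior on the initial switch state
    alpha_c0: np.ndarray  # (J,) prior on the initial nutrient
    alpha_c: np.ndarray  # (J,) prior row for nutrient transitions
    alpha_s_self: float = 2.0
    alpha_s_other: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_s1", "alpha_c0", "alpha_c"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or np.any(v <= 0):
                raise ValueError(f"{name} must be a 1-D strictly positive vector")
            object.__setattr__(self, name, v)
        if self.alpha_s_self <= 0 or self.alpha_s_other <= 0:
            raise ValueError("switch hyperparameters must be strictly positive")

    @classmethod
    def default(cls, K: int, J: int) -> "Hyperparameters":
        return cls(alpha_s1=np.ones(K), alpha_c0=np.ones(J), alpha_c=np.ones(J))

    def switch_alpha(self, K: int) -> np.ndarray:
        """Full (K, K) hyperparameter matrix for switch transitions."""
        a = np.full((K, K), self.alpha_s_other, dtype=float)
        np.fill_diagonal(a, self.alpha_s_self)
        return a


@dataclass(frozen=True)
class ModelSpec:
    """Model dimensions (K hidden states, J nutrients) plus hyperparameters."""

    K: int
    J: int
    hyper: Hyperparameters | None = None

    def __post_init__(self) -> None:
        if self.K < 1 or self.J < 2:
            raise ValueError("need K >= 1 hidden states and J >= 2 nutrients")
        hyper = self.hyper if self.hyper is not None else Hyperparameters.default(self.K, self.J)
        if hyper.alpha_s1.size != self.K or hyper.alpha_c0.size != self.J or hyper.alpha_c.size != self.J:
            raise ValueError("hyperparameter vector sizes do not match K, J")
        object.__setattr__(self, "hyper", hyper)


@dataclass
class CountStatistics:
    """Transition-count sufficient statistics (S hidden, C nutrient-per-hidden)."""

    S: np.ndarray  # (K, K) int
    C: np.ndarray  # (J, J, K) int

    @classmethod
    def zeros(cls, K: int, J: int) -> "CountStatistics":
        return cls(S=np.zeros((K, K), dtype=np.int64), C=np.zeros((J, J, K), dtype=np.int64))

    def copy(self) -> "CountStatistics":
        return CountStatistics(S=self.S.copy(), C=self.C.copy())


def collapsed_switch_row(stats: CountStatistics, hyper: Hyperparameters, i: int) -> np.ndarray:
    """Collapsed predictive distribution over the next switch state given state i."""
    K = stats.S.shape[0]
    row = np.full(K, hyper.alpha_s_other, dtype=float)
    row[i] = hyper.alpha_s_self
    row = row + stats.S[i]
    return row / row.sum()


def collapsed_switch_prob(stats: CountStatistics, hyper: Hyperparameters, i: int, j: int) -> float:
    """P(S_{t+1}=j | S_t=i, counts): (alpha_s^(j) + S[i,j]) / sum_k (alpha_s^(k) + S[i,k])."""
    return float(collapsed_switch_row(stats, hyper, i)[j])


def collapsed_nutrient_row(
    stats: CountStatistics, hyper: Hyperparameters, c_prev: int, s: int
) -> np.ndarray:
    """Collapsed predictive distribution over the next nutrient given (c_prev, s)."""
    row = hyper.alpha_c + stats.C[c_prev, :, s]
    return row / row.sum()


def collapsed_nutrient_prob(
    stats: CountStatistics, hyper: Hyperparameters, c_prev: int, c_next: int, s: int
) -> float:
    """P(C_{t+1}=c_next | C_t=c_prev, S_{t+1}=s, counts), the Dirichlet-Multinomial ratio."""
    return float(collapsed_nutrient_row(stats, hyper, c_prev, s)[c_next])


def sample_from_prior(spec: ModelSpec, T: int, seed: int) -> NutrientSequence:
    """Draw transition parameters from their priors once, then simulate the chain."""
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    rng = np.random.default_rng(seed)
    K, J, hyper = spec.K, spec.J, spec.hyper
    pi_s1 = rng.dirichlet(hyper.alpha_s1)
    switch_alpha = hyper.switch_alpha(K)
    pi_s = np.stack([rng.dirichlet(switch_alpha[i]) for i in range(K)])
    pi_c0 = rng.dirichlet(hyper.alpha_c0)
    pi_c = np.stack(
        [[rng.dirichlet(hyper.alpha_c) for _ in range(K)] for _ in range(J)]
    )  # (J, K, J): previous nutrient, switch state -> next-nutrient distribution

    obs = np.empty(T + 1, dtype=np.int64)
    states = np.empty(T, dtype=np.int64)
    obs[0] = rng.choice(J, p=pi_c0)
    s = rng.choice(K, p=pi_s1)
    for t in range(1, T + 1):
        states[t - 1] = s
        obs[t] = rng.choice(J, p=pi_c[obs[t - 1], s])
        if t < T:
            s = rng.choice(K, p=pi_s[s])
    return NutrientSequence(default_alphabet(J), obs, true_switch_states=states, seed=seed)


def exact_posterior_predictive(history: NutrientSequence, spec: ModelSpec) -> np.ndarray:
    """Exact posterior predictive P(C_{T+1} | C_{0:T}) by trajectory enumeration.

    Sums over every hidden switch trajectory s_{1:T}; along each
    trajectory the transition parameters are integrated out analytically
    via the collapsed counts.  Feasible only while K**T stays small
    (<= 4096 trajectories); serves as the ground-truth oracle for the
    particle filter.
    """
    obs = history.observations
    T = len(obs) - 1  # number of observed transitions
    K, J, hyper = spec.K, spec.J, spec.hyper
    if K**T > MAX_TRAJECTORIES:
        raise EnumerationError(
            f"enumeration infeasible: K**T = {K}**{T} exceeds {MAX_TRAJECTORIES} trajectories"
        )
    if T == 0:
        # No transitions observed: every hidden state predicts the same
        # zero-count nutrient row, so the prediction is the prior row.
        return hyper.alpha_c / hyper.alpha_c.sum()

    alpha_s1 = hyper.alpha_s1 / hyper.alpha_s1.sum()
    accum = np.zeros(J)
    total = 0.0

    def recurse(t: int, s_prev: int, stats: CountStatistics, weight: float) -> None:
        nonlocal total
        if t > T:
            switch = collapsed_switch_row(stats, hyper, s_prev)
            pred = np.zeros(J)
            for s_next in range(K):
                pred += switch[s_next] * collapsed_nutrient_row(stats, hyper, obs[T], s_next)
            accum[:] += weight * pred
            total += weight
            return
        for s in range(K):
            p_s = alpha_s1[s] if t == 1 else collapsed_switch_prob(stats, hyper, s_prev, s)
            p_c = collapsed_nutrient_prob(stats, hyper, obs[t - 1], obs[t], s)
            w = weight * p_s * p_c
            nxt = stats.copy()
            if t > 1:
                nxt.S[s_prev, s] += 1
            nxt.C[obs[t - 1], obs[t], s] += 1
            recurse(t + 1, s, nxt, w)

    recurse(1, -1, CountStatistics.zeros(K, J), 1.0)
    return accum / total


def flat_markov_posterior_predictive(history: NutrientSequence, alpha: np.ndarray) -> np.ndarray:
    """Posterior predictive of a flat Markov model (no hidden states).

    Counts the observed nutrient transitions and returns the collapsed
    Dirichlet-Multinomial row for the current nutrient:
    (alpha + n(c_T, .)) / sum(alpha + n(c_T, .)).
    """
    obs = history.observations
    alpha = np.asarray(alpha, dtype=float)
    J = alpha.size
    counts = np.zeros((J, J))
    np.add.at(counts, (obs[:-1], obs[1:]), 1)
    row = alpha + counts[obs[-1]]
    return row / row.sum()


def flat_predictive_sequence(history: NutrientSequence, alpha: np.ndarray) -> np.ndarray:
    """One-step-ahead flat-model predictions along a trace.

    Row t (t = 0..T-1) is P(C_{t+1} | C_{0:t}), i.e. the prediction made
    *before* observing C_{t+1}.
    """
    obs = history.observations
    alpha = np.asarray(alpha, dtype=float)
    J = alpha.size
    counts = np.zeros((J, J))
    out = np.empty((len(obs) - 1, J))
    for t in range(len(obs) - 1):
        row = alpha + counts[obs[t]]
        out[t] = row / row.sum()
        counts[obs[t], obs[t + 1]] += 1
    return out
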