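"""Discrete Markov and meta-changing nutrient environments.

An environment is a sequence of discrete nutrient states (e.g. glucose,
galactose, maltose).  Plain Markov environments are parameterized by a
row-stochastic transition matrix over nutrients.  Meta-changing
environments add an unobservable "switch state" chain: each switch state
selects a different nutrient transition matrix, so the *statistics* of
the fluctuations themselves change over time (e.g. a regime of periodic
glucose/galactose alternation vs. a regime of constant glucose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NutrientAlphabet",
    "MarkovEnvSpec",
    "MetaEnvSpec",
    "NutrientSequence",
    "GLU_GAL",
    "GLU_GAL_MAL",
    "sample_markov_env",
    "sample_meta_env",
    "make_two_state_glu_gal_spec",
    "make_multinutrient_archetypes",
    "alternating_constant_trace",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class NutrientAlphabet:
    """Ordered set of nutrient names; index 0 is the preferred nutrient."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("alphabet needs at least two nutrients")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate nutrient labels: {labels}")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, name: str) -> int:
        try:
            return self.labels.index(name)
        except ValueError:
            raise KeyError(f"unknown nutrient {name!r}; alphabet is {self.labels}") from None


GLU_GAL = NutrientAlphabet(("Glu", "Gal"))
GLU_GAL_MAL = NutrientAlphabet(("Glu", "Gal", "Mal"))


def default_alphabet(J: int) -> NutrientAlphabet:
    """Standard alphabet for a given number of nutrients."""
    if J == 2:
        return GLU_GAL
    if J == 3:
        return GLU_GAL_MAL
    return NutrientAlphabet(tuple(f"N{i}" for i in range(J)))


def _check_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError(f"{name} has entries outside [0, 1]")
    row_sums = m.sum(axis=1)
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > _ROW_TOL)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{name} row {i} sums to {row_sums[i]:.12g}, expected 1 (within {_ROW_TOL:g})"
        )
    return m


@dataclass(frozen=True)
class MarkovEnvSpec:
    """A flat Markov nutrient environment: one transition matrix."""

    alphabet: NutrientAlphabet
    transition_matrix: np.ndarray
    initial_state: int = 0

    def __post_init__(self) -> None:
        m = _check_stochastic(self.transition_matrix, "transition_matrix")
        if m.shape[0] != self.alphabet.size:
            raise ValueError("transition_matrix size does not match alphabet")
        object.__setattr__(self, "transition_matrix", m)
        if not 0 <= self.initial_state < self.alphabet.size:
            raise ValueError(f"initial_state {self.initial_state} out of range")


@dataclass(frozen=True)
class MetaEnvSpec:
    """A meta-changing environment driven by a hidden switch-state chain.

    ``switch_matrix[i, j]`` is the probability the hidden regime moves
    from state i to state j; ``state_matrices[k]`` is the nutrient
    transition matrix active while the hidden state is k.
    """

    alphabet: NutrientAlphabet
    switch_matrix: np.ndarray
    state_matrices: np.ndarray  # (K, J, J)
    initial_switch_state: int = 0
    initial_nutrient: int = 0

    def __post_init__(self) -> None:
        sw = _check_stochastic(self.switch_matrix, "switch_matrix")
        mats = np.asarray(self.state_matrices, dtype=float)
        if mats.ndim != 3 or mats.shape[0] != sw.shape[0]:
            raise ValueError("state_matrices must be (K, J, J) matching switch_matrix")
        for k in range(mats.shape[0]):
            _check_stochastic(mats[k], f"state_matrices[{k}]")
        if mats.shape[1] != self.alphabet.size:
            raise ValueError("state_matrices size does not match alphabet")
        object.__setattr__(self, "switch_matrix", sw)
        object.__setattr__(self, "state_matrices", mats)
        if not 0 <= self.initial_switch_state < sw.shape[0]:
            raise ValueError("initial_switch_state out of range")
        if not 0 <= self.initial_nutrient < self.alphabet.size:
            raise ValueError("initial_nutrient out of range")

    @property
    def K(self) -> int:
        return self.switch_matrix.shape[0]


@dataclass
class NutrientSequence:
    """An observed nutrient trace C_0..C_T, optionally with the true hidden states."""

    alphabet: NutrientAlphabet
    observations: np.ndarray
    true_switch_states: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=np.int64)
        if obs.ndim != 1 or obs.size == 0:
            raise ValueError("observations must be a non-empty 1-D sequence")
        if obs.min() < 0 or obs.max() >= self.alphabet.size:
            raise ValueError("observation index outside alphabet")
        self.observations = obs
        if self.true_switch_states is not None:
            ss = np.asarray(self.true_switch_states, dtype=np.int64)
            # switch states start at t=1: one per observed transition
            if ss.size != obs.size - 1:
                raise ValueError(
                    f"expected {obs.size - 1} switch states (one per transition), got {ss.size}"
                )
            self.true_switch_states = ss

    def __len__(self) -> int:
        return int(self.observations.size)

    @property
    def n_transitions(self) -> int:
        return len(self) - 1

    def labels(self) -> list[str]:
        return [self.alphabet.labels[i] for i in self.observations]


def sample_markov_env(spec: MarkovEnvSpec, T: int, seed: int) -> NutrientSequence:
    """Sample a length-(T+1) nutrient trace from a flat Markov environment."""
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    rng = np.random.default_rng(seed)
    obs = np.empty(T + 1, dtype=np.int64)
    obs[0] = spec.initial_state
    J = spec.alphabet.size
    for t in range(1, T + 1):
        obs[t] = rng.choice(J, p=spec.transition_matrix[obs[t - 1]])
    return NutrientSequence(spec.alphabet, obs, seed=seed)


def sample_meta_env(spec: MetaEnvSpec, T: int, seed: int) -> NutrientSequence:
    """Sample a meta-changing trace; the true switch states are recorded.

    The hidden chain starts at ``initial_switch_state`` (its first value
    S_1 governs the first nutrient transition C_0 -> C_1) and evolves by
    ``switch_matrix``; each C_t is drawn from the active state matrix's
    row for C_{t-1}.
    """
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    rng = np.random.default_rng(seed)
    K = spec.K
    J = spec.alphabet.size
    obs = np.empty(T + 1, dtype=np.int64)
    states = np.empty(T, dtype=np.int64)
    obs[0] = spec.initial_nutrient
    s = spec.initial_switch_state
    for t in range(1, T + 1):
        states[t - 1] = s
        obs[t] = rng.choice(J, p=spec.state_matrices[s, obs[t - 1]])
        s = rng.choice(K, p=spec.switch_matrix[s])
    return NutrientSequence(spec.alphabet, obs, true_switch_states=states, seed=seed)


def make_two_state_glu_gal_spec(
    p1: float, p2: float, eps: float = 0.02, initial_switch_state: int = 0
) -> MetaEnvSpec:
    """Two-regime glucose/galactose meta-environment.

    Regime 0 alternates Glu<->Gal (near-deterministically, with slack
    ``eps``); regime 1 is (near-)constant glucose.  ``p1`` is the
    probability the periodic regime persists, ``p2`` the probability the
    constant regime switches back to periodic.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("p1, p2 must be probabilities")
    if not 0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    periodic = np.array([[eps, 1 - eps], [1 - eps, eps]])
    constant = np.array([[1 - eps, eps], [1 - eps, eps]])
    switch = np.array([[p1, 1 - p1], [p2, 1 - p2]])
    return MetaEnvSpec(
        alphabet=GLU_GAL,
        switch_matrix=switch,
        state_matrices=np.stack([periodic, constant]),
        initial_switch_state=initial_switch_state,
        initial_nutrient=0,
    )


def make_multinutrient_archetypes(persistence: float = 0.9) -> list[MarkovEnvSpec]:
    """Three qualitative 3-nutrient (Glu/Gal/Mal) Markov environments.

    1. persistent stretches of each nutrient (sticky diagonal);
    2. periodic Glu<->Gal switching mixed with persistent Mal stretches;
    3. chained structure: Glu signals upcoming Gal, Gal signals an
       upcoming persistent Mal stretch.

    ``persistence`` is the dominant-row probability mass (> 0.5).
    """
    if not 0.5 < persistence < 1:
        raise ValueError("persistence must be in (0.5, 1)")
    p = persistence
    r = (1 - p) / 2
    persistent = np.array(
        [
            [p, r, r],
            [r, p, r],
            [r, r, p],
        ]
    )
    periodic_mal = np.array(
        [
            [r, p, r],  # Glu -> mostly Gal
            [p, r, r],  # Gal -> mostly Glu
            [r, r, p],  # Mal persists
        ]
    )
    chained = np.array(
        [
            [r, p, r],  # Glu signals Gal
            [r, r, p],  # Gal signals Mal
            [1 - p, 0.0, p],  # Mal persists, then resets to Glu
        ]
    )
    return [
        MarkovEnvSpec(GLU_GAL_MAL, persistent),
        MarkovEnvSpec(GLU_GAL_MAL, periodic_mal),
        MarkovEnvSpec(GLU_GAL_MAL, chained),
    ]


def alternating_constant_trace(
    block_len: int = 20, n_blocks: int = 4, start: int = 0
) -> NutrientSequence:
    """Deterministic regime-block trace: alternating, constant, alternating, ...

    Odd blocks alternate Glu/Gal every step; even blocks hold constant
    glucose.  Used to probe the re-adaptation signature: a model with
    hidden regimes should re-enter a previously seen regime faster the
    second time it appears.
    """
    obs: list[int] = []
    cur = start
    for b in range(n_blocks):
        if b % 2 == 0:  # periodic block
            for _ in range(block_len):
                obs.append(cur)
                cur = 1 - cur
        else:  # constant glucose block
            obs.extend([0] * block_len)
            cur = 1  # alternation resumes with galactose after constant Glu
    return NutrientSequence(GLU_GAL, np.array(obs, dtype=np.int64))
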