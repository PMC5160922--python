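"""Real-time posterior predictive estimation by particle filtering.

Each particle is a hypothesis about the hidden regime trajectory,
summarized by its current switch state ``s`` and its private
transition-count sufficient statistics (``S`` over hidden states, ``C``
over nutrients per hidden state).  Because the Dirichlet priors are
conjugate, no transition probabilities need to be stored: the predict
step samples the next hidden state from the collapsed
Dirichlet-Multinomial row, and the update step reweights each particle
by the collapsed probability of the observed nutrient transition.

The ensemble is stored as stacked arrays (one row per particle) so all
steps are vectorized; ``Particle`` views are available for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dbn import CountStatistics, ModelSpec
from .environments import NutrientSequence

__all__ = [
    "Particle",
    "ParticleEnsemble",
    "FilterResult",
    "init_ensemble",
    "predict_step",
    "update_step",
    "resample",
    "effective_sample_size",
    "predictive_estimate",
    "filter_sequence",
]

_WEIGHT_TOL = 1e-9


@dataclass
class Particle:
    """Single-particle view: current hidden state plus its count statistics."""

    s: int
    stats: CountStatistics


@dataclass
class ParticleEnsemble:
    """Weighted set of N particles, stored columnar for vectorized updates."""

    spec: ModelSpec
    s: np.ndarray  # (N,) current switch state per particle
    S: np.ndarray  # (N, K, K) switch transition counts
    C: np.ndarray  # (N, J, J, K) nutrient transition counts
    weights: np.ndarray  # (N,) normalized
    rng: np.random.Generator
    t: int = 0

    @property
    def n_particles(self) -> int:
        return self.s.size

    def particle(self, i: int) -> Particle:
        return Particle(s=int(self.s[i]), stats=CountStatistics(S=self.S[i].copy(), C=self.C[i].copy()))

    def _check(self) -> None:
        total = self.weights.sum()
        if not np.isfinite(total) or abs(total - 1.0) > _WEIGHT_TOL:
            raise RuntimeError(f"particle weights sum to {total}, expected 1")


def init_ensemble(spec: ModelSpec, N: int, seed: int | np.random.Generator) -> ParticleEnsemble:
    """Initialize N particles: hidden states drawn from the prior, zero counts."""
    if N < 1:
        raise ValueError("need at least one particle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K, J = spec.K, spec.J
    p_s1 = spec.hyper.alpha_s1 / spec.hyper.alpha_s1.sum()
    s = rng.choice(K, size=N, p=p_s1)
    return ParticleEnsemble(
        spec=spec,
        s=s.astype(np.int64),
        S=np.zeros((N, K, K), dtype=np.int64),
        C=np.zeros((N, J, J, K), dtype=np.int64),
        weights=np.full(N, 1.0 / N),
        rng=rng,
        t=0,
    )


def _switch_rows(ens: ParticleEnsemble) -> np.ndarray:
    """Collapsed next-switch-state distribution for each particle, shape (N, K)."""
    spec = ens.spec
    alpha = spec.hyper.switch_alpha(spec.K)  # (K, K)
    rows = alpha[ens.s] + ens.S[np.arange(ens.n_particles), ens.s]  # (N, K)
    return rows / rows.sum(axis=1, keepdims=True)


def predict_step(ens: ParticleEnsemble) -> ParticleEnsemble:
    """Advance each particle's hidden state by one step (in place).

    The new state is sampled from the particle's own collapsed switch
    row; the sampled transition is then recorded into its S counts, so
    subsequent probabilities condition on it.
    """
    probs = _switch_rows(ens)
    u = ens.rng.random(ens.n_particles)
    new_s = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    new_s = np.minimum(new_s, ens.spec.K - 1)
    idx = np.arange(ens.n_particles)
    ens.S[idx, ens.s, new_s] += 1
    ens.s = new_s.astype(np.int64)
    return ens


def update_step(ens: ParticleEnsemble, c_prev: int, c_obs: int) -> ParticleEnsemble:
    """Reweight by the likelihood of the observed transition, record it (in place).

    Each weight is multiplied by the particle's collapsed probability of
    c_prev -> c_obs under its current hidden state; weights are then
    renormalized and the observed transition is added to the particle's
    C counts under that state.
    """
    idx = np.arange(ens.n_particles)
    rows = ens.spec.hyper.alpha_c + ens.C[idx, c_prev, :, ens.s]  # (N, J)
    lik = rows[:, c_obs] / rows.sum(axis=1)
    ens.weights = ens.weights * lik
    total = ens.weights.sum()
    if total <= 0 or not np.isfinite(total):
        raise RuntimeError("particle weights degenerated to zero total")
    ens.weights /= total
    ens.C[idx, c_prev, c_obs, ens.s] += 1
    ens.t += 1
    return ens


def effective_sample_size(ens: ParticleEnsemble) -> float:
    return float(1.0 / np.sum(ens.weights**2))


def resample(ens: ParticleEnsemble) -> ParticleEnsemble:
    """Systematic resampling proportional to the weights (in place).

    Count statistics are copied by value, so resampled particles never
    share mutable counts; weights reset to uniform.
    """
    N = ens.n_particles
    positions = (np.arange(N) + ens.rng.random()) / N
    indices = np.searchsorted(np.cumsum(ens.weights), positions, side="right")
    indices = np.minimum(indices, N - 1)
    ens.s = ens.s[indices].copy()
    ens.S = ens.S[indices].copy()
    ens.C = ens.C[indices].copy()
    ens.weights = np.full(N, 1.0 / N)
    return ens


def predictive_estimate(ens: ParticleEnsemble, c_prev: int) -> np.ndarray:
    """Posterior predictive over the next nutrient, marginalizing hidden states.

    For each particle, sums over its possible next hidden states s':
    P(s' | s) * P(c | c_prev, s'), then averages over particles by
    weight.  Returns a normalized J-vector.
    """
    spec = ens.spec
    N, K, J = ens.n_particles, spec.K, spec.J
    switch = _switch_rows(ens)  # (N, K)
    rows = spec.hyper.alpha_c + ens.C[:, c_prev, :, :]  # (N, J, K)
    nutrient = rows / rows.sum(axis=1, keepdims=True)  # (N, J, K): P(c | c_prev, s')
    per_particle = np.einsum("nk,njk->nj", switch, nutrient)
    out = ens.weights @ per_particle
    return out / out.sum()


@dataclass
class FilterResult:
    """Output of a full filtering pass over a nutrient trace."""

    predictive: np.ndarray  # (T, J): row t predicts C_{t+1} from C_{0:t}
    ess: np.ndarray  # (T,) effective sample size after each update
    resampled: np.ndarray  # (T,) bool, whether resampling was triggered
    final_prediction: np.ndarray  # (J,): P(C_{T+1} | full history)
    ensemble: ParticleEnsemble


def filter_sequence(
    history: NutrientSequence,
    spec: ModelSpec,
    N: int = 200,
    seed: int | np.random.Generator = 0,
    resample_mode: str = "ess",
    ess_fraction: float = 0.5,
) -> FilterResult:
    """Run the full predict/update/resample cycle over a trace.

    Emits one predictive distribution per observed transition: row t
    (0-based) is the estimate of P(C_{t+1} | C_{0:t}) formed *before*
    C_{t+1} is consumed.  ``resample_mode`` is ``"ess"`` (systematic
    resampling when ESS < ess_fraction * N) or ``"always"``.
    """
    if resample_mode not in ("ess", "always"):
        raise ValueError(f"unknown resample_mode {resample_mode!r}")
    obs = history.observations
    T = len(obs) - 1
    if T < 1:
        raise ValueError("history must contain at least one transition")
    ens = init_ensemble(spec, N, seed)
    preds = np.empty((T, spec.J))
    ess = np.empty(T)
    did_resample = np.zeros(T, dtype=bool)
    for t in range(T):
        preds[t] = predictive_estimate(ens, int(obs[t]))
        if t > 0:
            # The initial hidden states were already drawn from the prior
            # at init time; prediction draws start with the second transition.
            predict_step(ens)
        update_step(ens, int(obs[t]), int(obs[t + 1]))
        ess[t] = effective_sample_size(ens)
        if resample_mode == "always" or ess[t] < ess_fraction * N:
            resample(ens)
            did_resample[t] = True
    final = predictive_estimate(ens, int(obs[T]))
    return FilterResult(
        predictive=preds, ess=ess, resampled=did_resample, final_prediction=final, ensemble=ens
    )
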