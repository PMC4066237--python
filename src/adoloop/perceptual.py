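"""Perceptual learning in a volatile oddball environment, observed through EEG.

The simulated subject is a three-level hierarchical Gaussian filter (HGF):
a binary stimulus category x1 (0 standard, 1 deviant) is Bernoulli with
probability s(x2); the tendency x2 performs a Gaussian random walk whose
step variance exp(kappa * x3 + omega) is modulated by a log-volatility
state x3, itself a random walk with variance vartheta.  After each
stimulus the agent updates its beliefs with the closed-form one-step
variational scheme for the binary HGF; the Kullback-Leibler divergence
between the level-2 prediction and posterior is the trial's Bayesian
surprise, which (scaled by a weight h and corrupted by Gaussian noise)
yields a simulated single-trial EEG response magnitude of the
mismatch-negativity kind.

Five candidate models (M1..M5) differ only in (omega, kappa, vartheta):
a null non-learning model, two two-level models with low/high learning
rate, and their three-level volatility-tracking counterparts.  Because
each model's surprise trace is a deterministic function of the stimulus
sequence, the experimenter's inversion of the response model is exact
sequential linear-Gaussian (conjugate in h with known noise precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .design import PredictiveDensity, laplace_chernoff_bound
from .inference import GaussianBelief, ModelSet, ModelSpec, kl_gaussian, sigmoid

__all__ = [
    "HGFParams",
    "AgentState",
    "ResponseParams",
    "StimulusSequence",
    "TABLE_MODELS",
    "MODEL_IDS",
    "N_TRIALS",
    "default_agent_state",
    "hgf_predict",
    "hgf_update",
    "hgf_step",
    "bayesian_surprise",
    "simulate_eeg",
    "generate_stimuli",
    "surprise_model_spec",
    "perceptual_model_set",
    "SurpriseInverter",
    "ado_stimulus_choice",
]

N_TRIALS = 350
_EXP_CAP = 50.0
_VAR_FLOOR = 1e-8

# (omega, kappa, vartheta) for the five candidate models.  M1 is the null
# model (zero walk variance: no learning); M2/M3 are two-level with low /
# high base learning rate; M4/M5 add a third level tracking volatility.
TABLE_MODELS = {
    "M1": (-math.inf, 0.0, None),
    "M2": (-5.0, 0.0, None),
    "M3": (-4.0, 0.0, None),
    "M4": (-5.0, 1.0, 0.2),
    "M5": (-4.0, 1.0, 0.2),
}
MODEL_IDS = tuple(TABLE_MODELS)

# Replication defaults for the response model: amplitude weight and noise
# precision (inverse variance) of the simulated EEG magnitudes.
DEFAULT_H = -10.0
DEFAULT_LAMBDA = 100.0
# Experimenter's prior on the unknown weight h.
H_PRIOR_MEAN = 0.0
H_PRIOR_VARIANCE = 100.0


@dataclass(frozen=True)
class HGFParams:
    """Fixed learning parameters of the hierarchical filter.

    omega : base log-volatility of the level-2 walk (log-variance units).
    kappa : coupling of level 3 onto the level-2 walk variance; kappa = 0
        truncates the hierarchy to two levels.
    vartheta : variance of the level-3 random walk; required iff kappa > 0.
    """

    omega: float
    kappa: float = 0.0
    vartheta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.kappa > 0 and (self.vartheta is None or self.vartheta <= 0):
            raise ValueError("vartheta must be positive when kappa > 0")


@dataclass(frozen=True)
class AgentState:
    """Sufficient statistics of the agent's beliefs over x2 and x3."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.sigma3 <= 0:
            raise ValueError("belief variances must be positive")


@dataclass(frozen=True)
class ResponseParams:
    """Surprise-to-amplitude weight h and noise precision lambda."""

    h: float = DEFAULT_H
    noise_precision: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.noise_precision <= 0:
            raise ValueError("noise precision must be positive")


@dataclass(frozen=True)
class StimulusSequence:
    """Binary stimulus categories and their generating deviant probabilities."""

    categories: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        cats = np.asarray(self.categories, dtype=int)
        probs = np.asarray(self.probabilities, dtype=float)
        if cats.shape != probs.shape:
            raise ValueError("categories and probabilities must align")
        if not np.all((cats == 0) | (cats == 1)):
            raise ValueError("categories must be 0 (standard) or 1 (deviant)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "probabilities", probs)

    def __len__(self) -> int:
        return self.categories.size


def default_agent_state() -> AgentState:
    """Initial beliefs: uninformed about the deviant tendency (mu2 = 0) and
    with the log-volatility belief centred so that the level-2 walk variance
    equals exp(omega), preserving the factorial model structure (two- and
    three-level variants share the same base learning rate)."""
    return AgentState(mu2=0.0, sigma2=1.0, mu3=0.0, sigma3=1.0, trial_index=0)


def hgf_predict(state: AgentState) -> float:
    """Agent's prior predictive probability of a deviant on the coming trial."""
    return float(sigmoid(state.mu2))


def _walk_variance(params: HGFParams, mu3: float) -> float:
    arg = params.kappa * mu3 + params.omega
    if arg == -math.inf:
        return 0.0
    return math.exp(min(arg, _EXP_CAP))


def hgf_step(state: AgentState, u: int, params: HGFParams) -> tuple[AgentState, float]:
    """One trial of the binary hierarchical filter: updated state and surprise.

    Implements the closed-form one-step update: the level-2 prediction
    inflates the belief variance by the walk variance exp(kappa mu3 + omega),
    the binary observation is assimilated with precision weighting, and
    (when kappa > 0) level 3 is updated from the volatility prediction
    error.  The returned surprise is KL(posterior || prediction) at level 2
    in nats.  The null model (omega = -inf, kappa = 0) has zero walk
    variance and is treated as a frozen, non-learning agent.
    """
    if u not in (0, 1):
        raise ValueError("stimulus category must be 0 or 1")
    w = _walk_variance(params, state.mu3)
    if w == 0.0 and params.kappa == 0.0:
        # Null agent: beliefs never move, surprise is identically zero.
        return replace(state, trial_index=state.trial_index + 1), 0.0

    sigma2_hat = state.sigma2 + w
    mu1_hat = float(sigmoid(state.mu2))
    delta1 = u - mu1_hat
    pi2 = 1.0 / sigma2_hat + mu1_hat * (1.0 - mu1_hat)
    sigma2_new = max(1.0 / pi2, _VAR_FLOOR)
    mu2_new = state.mu2 + sigma2_new * delta1

    if params.kappa > 0:
        pi3_hat = 1.0 / (state.sigma3 + params.vartheta)
        w2 = w / sigma2_hat
        r2 = (w - state.sigma2) / (w + state.sigma2)
        delta2 = (sigma2_new + (mu2_new - state.mu2) ** 2) / sigma2_hat - 1.0
        pi3 = pi3_hat + 0.5 * params.kappa ** 2 * w2 * (w2 + r2 * delta2)
        # Guard against precision collapse from a strongly negative
        # volatility prediction error.
        pi3 = max(pi3, _VAR_FLOOR)
        sigma3_new = max(1.0 / pi3, _VAR_FLOOR)
        mu3_new = state.mu3 + 0.5 * sigma3_new * params.kappa * w2 * delta2
    else:
        sigma3_new = state.sigma3
        mu3_new = state.mu3

    new_state = AgentState(
        mu2=mu2_new, sigma2=sigma2_new,
        mu3=mu3_new, sigma3=sigma3_new,
        trial_index=state.trial_index + 1,
    )
    prior = GaussianBelief(np.array([state.mu2]), np.array([[sigma2_hat]]))
    post = GaussianBelief(np.array([mu2_new]), np.array([[sigma2_new]]))
    return new_state, kl_gaussian(post, prior)


def hgf_update(state: AgentState, u: int, params: HGFParams) -> AgentState:
    """One-step belief update after observing stimulus category u."""
    return hgf_step(state, u, params)[0]


def bayesian_surprise(
    before: AgentState,
    after: AgentState,
    params: Optional[HGFParams] = None,
) -> float:
    """KL divergence (nats) between the level-2 posterior and its prediction.

    The prediction is the pre-trial belief with its variance inflated by
    the level-2 walk variance; pass ``params`` to include that inflation
    (without it the raw pre-trial belief is used).
    """
    if after.mu2 == before.mu2 and after.sigma2 == before.sigma2:
        return 0.0
    prior_var = before.sigma2
    if params is not None:
        prior_var += _walk_variance(params, before.mu3)
    prior = GaussianBelief(np.array([before.mu2]), np.array([[prior_var]]))
    post = GaussianBelief(np.array([after.mu2]), np.array([[after.sigma2]]))
    return kl_gaussian(post, prior)


def simulate_eeg(bs: float, response: ResponseParams, rng: np.random.Generator) -> float:
    """Noisy weighted surprise: y = h * BS + N(0, 1/lambda)."""
    return float(response.h * bs + rng.normal(0.0, 1.0 / math.sqrt(response.noise_precision)))


def generate_stimuli(design: str, rng: np.random.Generator, n_trials: int = N_TRIALS) -> StimulusSequence:
    """Stimulus schedule for the 'stable' or 'volatile' classical design.

    stable: deviant probability 0.2 on every trial.  volatile: 100 trials
    at 0.2, then 50 at 0.1, 50 at 0.3, 50 at 0.1, then 100 at 0.2 (scaled
    proportionally if n_trials differs from 350).
    """
    if design == "stable":
        probs = np.full(n_trials, 0.2)
    elif design == "volatile":
        blocks = [(100, 0.2), (50, 0.1), (50, 0.3), (50, 0.1), (100, 0.2)]
        if n_trials != N_TRIALS:
            scale = n_trials / N_TRIALS
            blocks = [(max(1, round(n * scale)), p) for n, p in blocks]
        probs = np.concatenate([np.full(n, p) for n, p in blocks])[:n_trials]
        if probs.size < n_trials:
            probs = np.concatenate([probs, np.full(n_trials - probs.size, 0.2)])
    else:
        raise ValueError("design must be 'stable' or 'volatile'")
    cats = (rng.random(probs.size) < probs).astype(int)
    return StimulusSequence(cats, probs)


def surprise_model_spec(
    model_id: str,
    noise_precision: float = DEFAULT_LAMBDA,
    h_prior: Optional[GaussianBelief] = None,
) -> ModelSpec:
    """Candidate generative model Mk for the simulated EEG amplitudes.

    The evolution map runs the hierarchical filter with the model's fixed
    (omega, kappa, vartheta); the observation map is linear in the unknown
    surprise-to-amplitude weight h given the trial's surprise, with known
    noise precision, so the h-posterior and evidence are conjugate.
    """
    if model_id not in TABLE_MODELS:
        raise ValueError(f"unknown model id {model_id!r}")
    omega, kappa, vartheta = TABLE_MODELS[model_id]
    params = HGFParams(omega=omega, kappa=kappa, vartheta=vartheta)
    if h_prior is None:
        h_prior = GaussianBelief(np.array([H_PRIOR_MEAN]), np.array([[H_PRIOR_VARIANCE]]))

    def observe(theta, u, state):
        # state carries the trial's Bayesian surprise (deterministic given
        # the stimulus history); the amplitude is linear in h.
        return float(theta[0]) * float(state)

    def evolve(state, u, theta):
        return hgf_update(state, u, params)

    return ModelSpec(
        name=model_id,
        observe=observe,
        evolve=evolve,
        parameter_prior=h_prior,
        observation_noise_variance=1.0 / noise_precision,
        fixed_hyperparameters={
            "omega": omega, "kappa": kappa, "vartheta": vartheta,
            "noise_precision": noise_precision,
        },
    )


def perceptual_model_set(noise_precision: float = DEFAULT_LAMBDA) -> ModelSet:
    """The five candidate models with a uniform prior."""
    models = tuple(surprise_model_spec(mid, noise_precision) for mid in MODEL_IDS)
    return ModelSet(models=models, probabilities=np.full(len(models), 1.0 / len(models)))


class SurpriseInverter:
    """Exact online inversion of one candidate surprise model.

    Tracks the model's agent replica (deterministic given the stimulus
    history), the conjugate Gaussian posterior over the weight h, and the
    accumulated log evidence Σ_t log p(y_t | y_1:t-1, M).
    """

    def __init__(self, spec: ModelSpec, initial_state: Optional[AgentState] = None) -> None:
        self.spec = spec
        hp = spec.fixed_hyperparameters
        self.params = HGFParams(hp["omega"], hp["kappa"], hp["vartheta"])
        self.noise_precision = hp["noise_precision"]
        self.state = initial_state if initial_state is not None else default_agent_state()
        self.h_mean = float(spec.parameter_prior.mean[0])
        self.h_var = float(spec.parameter_prior.covariance[0, 0])
        self.log_evidence = 0.0

    @property
    def h_belief(self) -> GaussianBelief:
        return GaussianBelief(np.array([self.h_mean]), np.array([[self.h_var]]))

    def predicted_surprise(self, u: int) -> float:
        """Surprise this model's agent would register if the next stimulus were u."""
        return hgf_step(self.state, u, self.params)[1]

    def predictive_amplitude(self, u: int) -> PredictiveDensity:
        bs = self.predicted_surprise(u)
        mean = self.h_mean * bs
        var = bs ** 2 * self.h_var + 1.0 / self.noise_precision
        return PredictiveDensity(self.spec.name, mean, var)

    def update(self, u: int, y: float) -> float:
        """Assimilate one (stimulus, amplitude) pair; return the evidence increment."""
        self.state, bs = hgf_step(self.state, u, self.params)
        pred_mean = self.h_mean * bs
        pred_var = bs ** 2 * self.h_var + 1.0 / self.noise_precision
        increment = float(
            -0.5 * math.log(2.0 * math.pi * pred_var)
            - 0.5 * (y - pred_mean) ** 2 / pred_var
        )
        self.log_evidence += increment
        if bs != 0.0:
            prec = 1.0 / self.h_var + self.noise_precision * bs ** 2
            self.h_mean = (self.h_mean / self.h_var + self.noise_precision * bs * y) / prec
            self.h_var = 1.0 / prec
        return increment


def ado_stimulus_choice(
    model_set: ModelSet,
    agent_replicas: Sequence[AgentState],
    h_beliefs: Sequence[GaussianBelief],
) -> int:
    """Pick the next stimulus category minimizing the selection-error bound.

    For each candidate u in {0, 1} and each candidate model, the predicted
    amplitude is Gaussian with mean h_hat * BS(u) and variance
    BS(u)^2 var(h) + 1/lambda; the Laplace-Chernoff bound across models
    (weighted by the current model posterior) scores the candidate.  Ties
    break to the standard (u = 0).
    """
    bounds = []
    for u in (0, 1):
        preds = []
        for spec, state, hb in zip(model_set.models, agent_replicas, h_beliefs):
            hp = spec.fixed_hyperparameters
            params = HGFParams(hp["omega"], hp["kappa"], hp["vartheta"])
            bs = hgf_step(state, u, params)[1]
            mean = float(hb.mean[0]) * bs
            var = bs ** 2 * float(hb.covariance[0, 0]) + 1.0 / hp["noise_precision"]
            preds.append(PredictiveDensity(spec.name, mean, var))
        bounds.append(laplace_chernoff_bound(preds, model_set.probabilities, clip=False))
    return 0 if bounds[0] <= bounds[1] else 1
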