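"""Memory-retention study: power vs exponential forgetting under three designs.

A study phase presents n = 30 items; after a lag time t (the design
variable, in seconds) the number of correctly recalled items y is
observed.  Two candidate retention curves compete:

    POW:  p = a (t + 1)^(-b)
    EXP:  p = a exp(-b t)

y | p is binomial(n, p); inference uses the moment-matched normal
approximation ``y ~ N(n p, n p (1 - p))``, appropriate at n = 30.  Three
lag-selection policies are provided: uniform-random lags on [0, 100] s, a
fixed geometric-like set of ten lags presented in random order, and
adaptive design optimization over an integer lag grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import DesignSpace, select_design
from .inference import GaussianBelief, ModelSet, ModelSpec

__all__ = [
    "RetentionParams",
    "RecallTrial",
    "N_ITEMS",
    "FIXED_LAGS",
    "pow_predict",
    "exp_predict",
    "simulate_recall",
    "normal_approx_observation",
    "retention_model_set",
    "draw_participants",
    "study1_design_policy",
    "RandomLagPolicy",
    "FixedTenPolicy",
    "AdoLagPolicy",
]

N_ITEMS = 30
FIXED_LAGS = (0.0, 1.0, 2.0, 4.0, 7.0, 12.0, 21.0, 35.0, 59.0, 99.0)
LAG_GRID = tuple(float(t) for t in range(101))
RECALL_OUTCOMES = tuple(float(k) for k in range(N_ITEMS + 1))
# Relative floor on the moment-matched variance, keeping the likelihood
# proper when the predicted recall probability hits 0 or 1.
VARIANCE_FLOOR_FRACTION = 1e-3

# Parameter priors (mean, scale) under the N(m, s) notation; the scale is
# read as a variance by default, or as a standard deviation when
# prior_scale='std'.
PRIORS = {
    "POW": {"a": (0.75, 2.0), "b": (0.85, 2.0)},
    "EXP": {"a": (0.90, 2.0), "b": (0.15, 2.0)},
}
# Population distributions from which simulated participants are drawn.
PARTICIPANT_DISTRIBUTION = {"a": (0.8, 0.5), "b": (0.4, 0.5)}


@dataclass(frozen=True)
class RetentionParams:
    """Recall scale ``a`` and decay rate ``b`` of a forgetting curve."""

    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b])


@dataclass(frozen=True)
class RecallTrial:
    lag_time: float
    correct_count: int
    n_items: int = N_ITEMS

    def __post_init__(self) -> None:
        if not (0 <= self.correct_count <= self.n_items):
            raise ValueError("correct_count must lie in [0, n_items]")
        if self.lag_time < 0:
            raise ValueError("lag_time must be nonnegative")


def pow_predict(params, t) -> float:
    """Power forgetting curve a (t+1)^(-b), clipped to [0, 1]."""
    a, b = (params.a, params.b) if isinstance(params, RetentionParams) else (params[0], params[1])
    arg = np.clip(-b * np.log1p(np.asarray(t, dtype=float)), -50.0, 50.0)
    return float(np.clip(a * np.exp(arg), 0.0, 1.0))


def exp_predict(params, t) -> float:
    """Exponential forgetting curve a exp(-b t), clipped to [0, 1]."""
    a, b = (params.a, params.b) if isinstance(params, RetentionParams) else (params[0], params[1])
    arg = np.clip(-b * np.asarray(t, dtype=float), -50.0, 50.0)
    return float(np.clip(a * np.exp(arg), 0.0, 1.0))


def simulate_recall(p: float, n_items: int, rng: np.random.Generator) -> int:
    """Binomial draw of the number of recalled items at success probability p."""
    return int(rng.binomial(n_items, float(np.clip(p, 0.0, 1.0))))


def _scale_to_variance(scale: float, prior_scale: str) -> float:
    if prior_scale == "variance":
        return scale
    if prior_scale == "std":
        return scale ** 2
    raise ValueError("prior_scale must be 'variance' or 'std'")


def normal_approx_observation(
    model: str,
    n_items: int = N_ITEMS,
    prior_scale: str = "variance",
) -> ModelSpec:
    """ModelSpec for POW or EXP with the moment-matched normal likelihood.

    The observation map returns ``n p(theta, t)`` and the (heteroscedastic)
    noise variance ``n p (1 - p)``, floored at ``1e-3 n``.
    """
    model = model.upper()
    if model not in PRIORS:
        raise ValueError("model must be 'POW' or 'EXP'")
    curve = pow_predict if model == "POW" else exp_predict
    floor = VARIANCE_FLOOR_FRACTION * n_items

    def observe(theta, t, state=None):
        return n_items * curve(theta, t)

    def noise(theta, t, state=None):
        p = curve(theta, t)
        return max(n_items * p * (1.0 - p), floor)

    spec = PRIORS[model]
    mean = np.array([spec["a"][0], spec["b"][0]])
    cov = np.diag([_scale_to_variance(spec["a"][1], prior_scale),
                   _scale_to_variance(spec["b"][1], prior_scale)])
    return ModelSpec(
        name=model,
        observe=observe,
        parameter_prior=GaussianBelief(mean, cov),
        observation_noise_variance=noise,
        fixed_hyperparameters={"n_items": n_items},
    )


def retention_model_set(n_items: int = N_ITEMS, prior_scale: str = "variance") -> ModelSet:
    """POW and EXP with equal prior probability 1/2 each."""
    return ModelSet(
        models=(
            normal_approx_observation("POW", n_items, prior_scale),
            normal_approx_observation("EXP", n_items, prior_scale),
        ),
        probabilities=np.array([0.5, 0.5]),
    )


def draw_participants(
    n: int,
    rng: np.random.Generator,
    prior_scale: str = "variance",
) -> tuple[list[RetentionParams], int]:
    """Draw participant (a, b) pairs from the population distribution.

    Draws with a <= 0 predict zero recall at every lag and are re-drawn;
    the redraw count is returned for logging.
    """
    sd_a = np.sqrt(_scale_to_variance(PARTICIPANT_DISTRIBUTION["a"][1], prior_scale))
    sd_b = np.sqrt(_scale_to_variance(PARTICIPANT_DISTRIBUTION["b"][1], prior_scale))
    out: list[RetentionParams] = []
    redraws = 0
    while len(out) < n:
        a = rng.normal(PARTICIPANT_DISTRIBUTION["a"][0], sd_a)
        b = rng.normal(PARTICIPANT_DISTRIBUTION["b"][0], sd_b)
        if a <= 0:
            redraws += 1
            continue
        out.append(RetentionParams(a, b))
    return out, redraws


class RandomLagPolicy:
    """Uniform-random lag on [0, 100] s at every stage."""

    name = "random"

    def propose(self, stage: int, rng: np.random.Generator, model_set=None, beliefs=None):
        return float(rng.uniform(0.0, 100.0))


class FixedTenPolicy:
    """The ten printed lags, each presented exactly once in a random order."""

    name = "fixed10"

    def __init__(self) -> None:
        self._order: list[float] | None = None

    def propose(self, stage: int, rng: np.random.Generator, model_set=None, beliefs=None):
        if self._order is None:
            self._order = [FIXED_LAGS[i] for i in rng.permutation(len(FIXED_LAGS))]
        if stage >= len(self._order):
            raise ValueError("fixed10 design has exactly 10 stages")
        return self._order[stage]


class AdoLagPolicy:
    """Adaptive lag selection minimizing the model-selection error criterion.

    The exact enumerated Bayes error over recall counts 0..30 is the
    default criterion; the Laplace-Chernoff bound is available as a cheap
    analytic alternative.
    """

    name = "ado"

    def __init__(self, criterion: str = "exact", grid: Sequence[float] = LAG_GRID) -> None:
        self.criterion = criterion
        self.space = DesignSpace(tuple(grid))
        self.last_scores: np.ndarray | None = None

    def propose(self, stage: int, rng: np.random.Generator, model_set=None, beliefs=None):
        u_star, scores = select_design(
            self.space, model_set, beliefs,
            criterion=self.criterion,
            outcomes=RECALL_OUTCOMES if self.criterion == "exact" else None,
        )
        self.last_scores = scores
        return float(u_star)


def study1_design_policy(kind: str, criterion: str = "exact"):
    """Construct a fresh lag-selection policy: 'ado', 'random' or 'fixed10'."""
    if kind == "random":
        return RandomLagPolicy()
    if kind == "fixed10":
        return FixedTenPolicy()
    if kind == "ado":
        return AdoLagPolicy(criterion=criterion)
    raise ValueError(f"unknown design policy {kind!r}")
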