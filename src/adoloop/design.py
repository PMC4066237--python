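"""Design efficiency: predictive densities and model-selection error criteria.

Given per-model Gaussian predictive densities over the next observation,
the probability of selecting the wrong model admits an analytic upper
bound — the Laplace-Chernoff bound — obtained from the Chernoff exponent
at s = 1/2 (the Bhattacharyya distance) between each pair of predictives.
Minimizing the bound over a finite set of candidate designs selects the
design most likely to discriminate the models; "design efficiency" is the
negative of the bound.  For discrete observables the exact Bayes-optimal
selection error can be enumerated and serves as an oracle for the bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .inference import GaussianBelief, ModelSet, ModelSpec

__all__ = [
    "DesignSpace",
    "PredictiveDensity",
    "predictive_density",
    "laplace_chernoff_bound",
    "exact_error_rate",
    "select_design",
    "discretize_predictive",
]


@dataclass(frozen=True)
class DesignSpace:
    """A finite, ordered set of candidate values of the control variable u."""

    candidates: tuple

    def __post_init__(self) -> None:
        cands = tuple(self.candidates)
        if len(cands) == 0:
            raise ValueError("design space must be non-empty")
        if len(set(cands)) != len(cands):
            raise ValueError("design candidates must be unique")
        object.__setattr__(self, "candidates", cands)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class PredictiveDensity:
    """Gaussian predictive over the next observation under one model.

    ``discrete_support``, when present, is a list of ``(outcome, probability)``
    pairs from integrating the Gaussian over outcome bins; it enables exact
    enumeration of the selection error.
    """

    model_name: str
    mean: float
    variance: float
    discrete_support: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("predictive variance must be positive")
        if self.discrete_support is not None:
            support = tuple((o, float(p)) for o, p in self.discrete_support)
            total = sum(p for _, p in support)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("discrete support probabilities must sum to 1")
            object.__setattr__(self, "discrete_support", support)


def predictive_density(model: ModelSpec, belief: GaussianBelief, u, state=None) -> PredictiveDensity:
    """First-order (linearized) Gaussian predictive for the next observation.

    mean = g(mu, u); variance = grad_g' Sigma grad_g + observation noise,
    with the gradient of the observation map taken at the belief mean by
    central differences.
    """
    mu = belief.mean
    mean = float(model.observe(mu, u, state))
    grad = np.empty(mu.size)
    for i in range(mu.size):
        h = 1e-6 * (1.0 + abs(mu[i]))
        mp = mu.copy(); mp[i] += h
        mm = mu.copy(); mm[i] -= h
        grad[i] = (model.observe(mp, u, state) - model.observe(mm, u, state)) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise ValueError(f"gradient of observation map for {model.name!r} failed at belief mean")
    var = float(grad @ belief.covariance @ grad) + model.noise_variance(mu, u, state)
    return PredictiveDensity(model.name, mean, var)


def discretize_predictive(pred: PredictiveDensity, outcomes: Sequence[float]) -> PredictiveDensity:
    """Integrate a Gaussian predictive over unit-width bins centred on ``outcomes``.

    Probabilities are renormalized over the given outcome set so the support
    is a proper pmf (the tails outside the outcome range are folded in by
    normalization).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    sd = np.sqrt(pred.variance)
    upper = stats.norm.cdf((outcomes + 0.5 - pred.mean) / sd)
    lower = stats.norm.cdf((outcomes - 0.5 - pred.mean) / sd)
    pmf = upper - lower
    total = pmf.sum()
    if total <= 0:
        # Predictive mass lies entirely outside the outcome range; put all
        # mass on the nearest outcome.
        pmf = np.zeros_like(outcomes)
        pmf[int(np.argmin(np.abs(outcomes - pred.mean)))] = 1.0
    else:
        pmf = pmf / total
    support = tuple(zip(outcomes.tolist(), pmf.tolist()))
    return PredictiveDensity(pred.model_name, pred.mean, pred.variance, support)


def _bhattacharyya_gaussian(m1: float, v1: float, m2: float, v2: float) -> float:
    vbar = 0.5 * (v1 + v2)
    return 0.125 * (m1 - m2) ** 2 / vbar + 0.5 * np.log(vbar / np.sqrt(v1 * v2))


def laplace_chernoff_bound(
    predictives: Sequence[PredictiveDensity], probabilities, clip: bool = True
) -> float:
    """Upper bound on the next-observation model-selection error rate.

    For each pair (i, j) of models with Gaussian predictives, the Chernoff
    bound at s = 1/2 is ``sqrt(p_i p_j) exp(-D_B(i, j))`` with ``D_B`` the
    Bhattacharyya distance.  For more than two models the pairwise bounds
    are summed (union bound).  The result is clipped to ``1 - max(p)``, the
    error of blind guessing; pass ``clip=False`` when ranking designs, where
    the raw union preserves ordering that the clip would flatten.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (len(predictives),):
        raise ValueError("probabilities length must match predictives")
    if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be a distribution")
    bound = 0.0
    for i in range(len(predictives)):
        for j in range(i + 1, len(predictives)):
            db = _bhattacharyya_gaussian(
                predictives[i].mean, predictives[i].variance,
                predictives[j].mean, predictives[j].variance,
            )
            bound += np.sqrt(probs[i] * probs[j]) * np.exp(-db)
    if clip:
        bound = min(bound, 1.0 - np.max(probs))
    return float(bound)


def exact_error_rate(discrete_predictives: Sequence[PredictiveDensity], probabilities) -> float:
    """Bayes-optimal model-selection error by full enumeration of outcomes.

    ``sum_y [ p(y) - max_m p(m) p(y|m) ]``, i.e. the residual probability
    mass after assigning each outcome to its best model.  All predictives
    must carry a ``discrete_support`` over an identical outcome set.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (len(discrete_predictives),):
        raise ValueError("probabilities length must match predictives")
    supports = []
    outcome_sets = []
    for pred in discrete_predictives:
        if pred.discrete_support is None:
            raise ValueError(f"predictive for {pred.model_name!r} lacks a discrete support")
        outcomes = tuple(o for o, _ in pred.discrete_support)
        outcome_sets.append(outcomes)
        supports.append(np.array([p for _, p in pred.discrete_support]))
    if len(set(outcome_sets)) != 1:
        raise ValueError("all discrete supports must share the same outcome set")
    pmf = np.vstack(supports)                      # (models, outcomes)
    joint = probs[:, None] * pmf
    return float(np.sum(joint.sum(axis=0) - joint.max(axis=0)))


def select_design(
    space: DesignSpace,
    model_set: ModelSet,
    beliefs: Sequence[GaussianBelief],
    criterion: str = "chernoff",
    states: Optional[Sequence] = None,
    outcomes: Optional[Sequence[float]] = None,
):
    """Pick the candidate design minimizing the selection-error criterion.

    criterion='chernoff' scores each candidate with the Laplace-Chernoff
    bound; criterion='exact' discretizes each Gaussian predictive over
    ``outcomes`` and scores with the enumerated Bayes error.  Ties break to
    the smallest candidate index.

    Returns ``(u_star, scores)`` with one score per candidate.
    """
    if criterion not in ("chernoff", "exact"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "exact" and outcomes is None:
        raise ValueError("criterion 'exact' requires a discrete outcome set")
    if states is None:
        states = [None] * len(model_set.models)
    scores = np.empty(len(space))
    for k, u in enumerate(space.candidates):
        preds = [
            predictive_density(m, b, u, s)
            for m, b, s in zip(model_set.models, beliefs, states)
        ]
        if criterion == "exact":
            preds = [discretize_predictive(p, outcomes) for p in preds]
            scores[k] = exact_error_rate(preds, model_set.probabilities)
        else:
            scores[k] = laplace_chernoff_bound(preds, model_set.probabilities, clip=False)
    u_star = space.candidates[int(np.argmin(scores))]
    return u_star, scores


def export_design_scores(path, space: DesignSpace, chernoff_scores=None, exact_scores=None):
    """Write per-candidate criterion scores as CSV (u, chernoff, exact)."""
    import pandas as pd

    data = {"u": list(space.candidates)}
    if chernoff_scores is not None:
        data["chernoff_score"] = np.asarray(chernoff_scores)
    if exact_scores is not None:
        data["exact_score"] = np.asarray(exact_scores)
    df = pd.DataFrame(data)
    df.to_csv(path, index=False)
    return df
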