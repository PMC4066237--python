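"""Belief representations, Gaussian information measures and Laplace model inversion.

The central abstraction is a generative model written as a pair of maps:
an (optional) evolution map ``f`` that propagates hidden states across
trials, and an observation map ``g`` that sends parameters, design and
state to a predicted observation mean.  Inference over the parameters is
performed by a Gauss-Newton search for the maximum a posteriori (MAP)
estimate followed by a Laplace (second-order) approximation of the
posterior and of the log model evidence.  Model comparison then reduces
to combining per-model log evidences with a prior over models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "GaussianBelief",
    "ModelSpec",
    "ModelSet",
    "sigmoid",
    "kl_gaussian",
    "laplace_fit",
    "update_model_posterior",
    "LaplaceFitError",
]

# Jitter added to a covariance factorization on failure; repeated failure
# (after _MAX_JITTER_TRIES escalations) raises rather than degrading silently.
_JITTER = 1e-10
_MAX_JITTER_TRIES = 8


class LaplaceFitError(RuntimeError):
    """MAP search failed to converge or a covariance factorization failed."""


def _chol_psd(a: np.ndarray) -> np.ndarray:
    """Cholesky factor with escalating jitter on failure."""
    jitter = 0.0
    for attempt in range(_MAX_JITTER_TRIES):
        try:
            return linalg.cholesky(a + jitter * np.eye(a.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = _JITTER * (10.0 ** attempt) if jitter == 0.0 else jitter * 10.0
    raise LaplaceFitError("covariance matrix is not positive definite (jitter exhausted)")


@dataclass(frozen=True)
class GaussianBelief:
    """A multivariate Gaussian summary of a belief over parameters or observables.

    Parameters
    ----------
    mean : array-like, shape (d,)
    covariance : array-like, shape (d, d)
        Must be symmetric positive definite.
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if mean.ndim != 1:
            raise ValueError("mean must be a vector")
        if cov.shape != (mean.size, mean.size):
            raise ValueError(f"covariance shape {cov.shape} does not match dimension {mean.size}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
        if not np.all(np.isfinite(eigvals)) or np.min(eigvals) <= 0.0:
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", 0.5 * (cov + cov.T))

    @property
    def dim(self) -> int:
        return self.mean.size

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "covariance": self.covariance.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "GaussianBelief":
        data = json.loads(payload)
        return cls(np.asarray(data["mean"]), np.asarray(data["covariance"]))


@dataclass(frozen=True)
class ModelSpec:
    """A candidate generative model.

    ``observe(params, u, state)`` returns the predicted observation mean.
    ``evolve(state, u, params)``, when present, propagates a hidden state
    across trials.  ``observation_noise_variance`` is either a positive
    scalar or a callable ``(params, u, state) -> variance`` for
    heteroscedastic likelihoods (e.g. a moment-matched binomial).
    """

    name: str
    observe: Callable[[np.ndarray, object, object], float]
    parameter_prior: GaussianBelief
    observation_noise_variance: float | Callable[[np.ndarray, object, object], float]
    evolve: Optional[Callable[[object, object, np.ndarray], object]] = None
    fixed_hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not callable(self.observation_noise_variance):
            if float(self.observation_noise_variance) <= 0:
                raise ValueError("observation_noise_variance must be positive")

    def noise_variance(self, params: np.ndarray, u: object, state: object = None) -> float:
        if callable(self.observation_noise_variance):
            return float(self.observation_noise_variance(params, u, state))
        return float(self.observation_noise_variance)


@dataclass(frozen=True)
class ModelSet:
    """An ordered collection of candidate models with a prior/posterior over them."""

    models: tuple
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        models = tuple(self.models)
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.shape != (len(models),):
            raise ValueError("probabilities length must match number of models")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "probabilities", np.clip(probs, 0.0, 1.0))

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.models]


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), saturating at extreme arguments."""
    x = np.clip(x, -50.0, 50.0)
    return 1.0 / (1.0 + np.exp(-x))


def kl_gaussian(p: GaussianBelief, q: GaussianBelief) -> float:
    """KL(p || q) between two Gaussian beliefs, in nats.

    Uses the closed form
    ``0.5 * (tr(Sq^-1 Sp) + (mq-mp)' Sq^-1 (mq-mp) - d + ln det Sq - ln det Sp)``.
    """
    if p.dim != q.dim:
        raise ValueError(f"dimension mismatch: {p.dim} vs {q.dim}")
    lp = _chol_psd(p.covariance)
    lq = _chol_psd(q.covariance)
    d = p.dim
    # Solve against q's factor once for both trace and quadratic terms.
    a = linalg.solve_triangular(lq, lp, lower=True)
    trace_term = float(np.sum(a * a))
    diff = q.mean - p.mean
    b = linalg.solve_triangular(lq, diff, lower=True)
    quad = float(b @ b)
    logdet_q = 2.0 * float(np.sum(np.log(np.diag(lq))))
    logdet_p = 2.0 * float(np.sum(np.log(np.diag(lp))))
    return max(0.0, 0.5 * (trace_term + quad - d + logdet_q - logdet_p))


def _finite_diff_grad(fun: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    """Central finite-difference gradient of a scalar function."""
    g = np.empty_like(x)
    for i in range(x.size):
        h = 1e-6 * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2.0 * h)
    return g


def _predicted_means_and_variances(model, params, designs, states):
    mu = np.array([model.observe(params, u, s) for u, s in zip(designs, states)])
    var = np.array([model.noise_variance(params, u, s) for u, s in zip(designs, states)])
    return mu, var


def laplace_fit(
    model: ModelSpec,
    observations: Sequence[float],
    designs: Sequence,
    states: Optional[Sequence] = None,
    prior: Optional[GaussianBelief] = None,
    max_iter: int = 200,
    step_tol: float = 1e-6,
) -> tuple[GaussianBelief, float]:
    """Laplace (Gauss-Newton) approximation to the parameter posterior and log evidence.

    Maximizes the log joint ``sum_i log N(y_i; g(theta, u_i), sigma_i^2(theta))
    + log N(theta; prior)`` with a damped Gauss-Newton iteration, then forms
    the posterior covariance ``(J' W J + S0^-1)^-1`` at the MAP and the free
    energy

    ``F = loglik(theta*) - 0.5 q(theta*) + 0.5 ln det(S_post) - 0.5 ln det(S0)``

    where ``q`` is the prior Mahalanobis term.  For observation maps linear
    in the parameters with constant noise this equals the exact log marginal
    likelihood.  With no observations the prior and ``F = 0`` are returned.

    Returns
    -------
    (posterior, log_evidence)

    Raises
    ------
    LaplaceFitError
        If the MAP search does not converge within ``max_iter`` iterations.
    """
    prior = prior if prior is not None else model.parameter_prior
    y = np.asarray(observations, dtype=float)
    designs = list(designs)
    if len(designs) != y.size:
        raise ValueError("observations and designs must have equal length")
    if states is None:
        states = [None] * y.size
    if y.size == 0:
        return prior, 0.0

    mu0 = prior.mean
    l0 = _chol_psd(prior.covariance)
    prior_prec = linalg.cho_solve((l0, True), np.eye(mu0.size))
    logdet_prior = 2.0 * float(np.sum(np.log(np.diag(l0))))

    def neg_log_post(theta: np.ndarray) -> float:
        mu, var = _predicted_means_and_variances(model, theta, designs, states)
        r = y - mu
        d0 = theta - mu0
        return float(
            0.5 * np.sum(r * r / var)
            + 0.5 * np.sum(np.log(2.0 * np.pi * var))
            + 0.5 * d0 @ prior_prec @ d0
        )

    theta = mu0.copy()
    obj = neg_log_post(theta)
    converged = y.size == 0
    for _ in range(max_iter):
        mu, var = _predicted_means_and_variances(model, theta, designs, states)
        # Jacobian of the observation means, by central differences.
        jac = np.empty((y.size, theta.size))
        for i in range(theta.size):
            h = 1e-6 * (1.0 + abs(theta[i]))
            tp = theta.copy(); tp[i] += h
            tm = theta.copy(); tm[i] -= h
            mp, _ = _predicted_means_and_variances(model, tp, designs, states)
            mm, _ = _predicted_means_and_variances(model, tm, designs, states)
            jac[:, i] = (mp - mm) / (2.0 * h)
        w = 1.0 / var
        grad = _finite_diff_grad(neg_log_post, theta)
        hess = jac.T @ (jac * w[:, None]) + prior_prec
        lh = _chol_psd(hess)
        step = -linalg.cho_solve((lh, True), grad)
        # Backtracking line search on the full objective.
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            cand_obj = neg_log_post(cand)
            if np.isfinite(cand_obj) and cand_obj < obj - 1e-12 * (1.0 + abs(obj)):
                break
            alpha *= 0.5
        else:
            converged = True  # no further descent possible: stationary
            break
        step_size = float(np.max(np.abs(alpha * step)))
        theta = cand
        obj = cand_obj
        if step_size < step_tol:
            converged = True
            break
    # Clipped or floored prediction regimes create curved, nearly flat
    # ridges and kinks where the Gauss-Newton metric is poor or the search
    # stalls at a non-optimal stationary point; polish with a derivative-free
    # simplex search from both the Gauss-Newton solution and the prior mean,
    # keeping any materially better optimum.
    from scipy import optimize

    best_alt = None
    for start in (theta, mu0):
        res = optimize.minimize(
            neg_log_post, start, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
            if best_alt is None or res.fun < best_alt[1]:
                best_alt = (np.asarray(res.x, dtype=float), float(res.fun))
    if best_alt is None and not converged:
        raise LaplaceFitError(
            f"MAP search for model {model.name!r} did not converge in {max_iter} iterations"
        )
    if best_alt is not None and best_alt[1] < obj - 1e-6 * (1.0 + abs(obj)):
        theta, obj = best_alt

    mu, var = _predicted_means_and_variances(model, theta, designs, states)
    jac = np.empty((y.size, theta.size))
    for i in range(theta.size):
        h = 1e-6 * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        mp, _ = _predicted_means_and_variances(model, tp, designs, states)
        mm, _ = _predicted_means_and_variances(model, tm, designs, states)
        jac[:, i] = (mp - mm) / (2.0 * h)
    w = 1.0 / var
    hess = jac.T @ (jac * w[:, None]) + prior_prec
    lh = _chol_psd(hess)
    post_cov = linalg.cho_solve((lh, True), np.eye(theta.size))
    post_cov = 0.5 * (post_cov + post_cov.T)
    posterior = GaussianBelief(theta, post_cov)

    r = y - mu
    loglik = float(-0.5 * np.sum(r * r / var) - 0.5 * np.sum(np.log(2.0 * np.pi * var)))
    d0 = theta - mu0
    quad = float(d0 @ prior_prec @ d0)
    logdet_post = -2.0 * float(np.sum(np.log(np.diag(lh))))
    log_evidence = loglik - 0.5 * quad + 0.5 * (logdet_post - logdet_prior)
    return posterior, log_evidence


def update_model_posterior(model_set: ModelSet, log_evidences: Sequence[float]) -> ModelSet:
    """Bayes-update the probabilities of a model set with per-model log evidences.

    Computed in log space so large evidence gaps do not underflow.
    """
    log_ev = np.asarray(log_evidences, dtype=float)
    if log_ev.shape != (len(model_set.models),):
        raise ValueError("log_evidences length must match number of models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")
    with np.errstate(divide="ignore"):
        log_prior = np.log(model_set.probabilities)
    log_post = log_prior + log_ev
    log_post -= np.max(log_post[np.isfinite(log_post)])
    post = np.exp(log_post)
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("model posterior has no mass (all-zero after update)")
    return replace(model_set, probabilities=post / total)
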