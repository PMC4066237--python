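"""Experiment orchestration: trial loops, stopping, batch replication.

A run couples (a) a simulated subject — the true generative process —
(b) a set of candidate models inverted online, and (c) a design policy
that proposes the next control variable.  The full trial horizon is
always simulated; the first crossing of the model-posterior threshold is
recorded rather than truncating, so group-average posterior curves cover
every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import ModelSet, laplace_fit, update_model_posterior
from .perceptual import (
    HGFParams,
    ResponseParams,
    SurpriseInverter,
    TABLE_MODELS,
    ado_stimulus_choice,
    default_agent_state,
    generate_stimuli,
    hgf_step,
    perceptual_model_set,
    simulate_eeg,
)
from .retention import (
    RetentionParams,
    draw_participants,
    pow_predict,
    retention_model_set,
    simulate_recall,
    study1_design_policy,
)

__all__ = [
    "TrialRecord",
    "ExperimentResult",
    "run_retention_experiment",
    "run_perceptual_experiment",
    "run_study1_batch",
    "run_study2_batch",
    "summarize_study1",
    "summarize_study2",
]


@dataclass(frozen=True)
class TrialRecord:
    index: int                       # 1-based trial/stage number
    design: float
    observation: float
    log_evidences: np.ndarray        # cumulative, per model
    model_posteriors: np.ndarray

    def __post_init__(self) -> None:
        post = np.asarray(self.model_posteriors, dtype=float)
        if abs(post.sum() - 1.0) > 1e-9:
            raise ValueError("model posteriors must sum to 1")
        object.__setattr__(self, "model_posteriors", post)
        object.__setattr__(self, "log_evidences", np.asarray(self.log_evidences, dtype=float))


@dataclass
class ExperimentResult:
    true_model: str
    policy: str
    model_names: list[str]
    trials: list[TrialRecord]
    conclusive: bool
    selected_model: Optional[str]
    trials_to_criterion: Optional[int]
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conclusive != (self.trials_to_criterion is not None):
            raise ValueError("conclusive must match trials_to_criterion presence")

    def posterior_curve(self, model_name: str) -> np.ndarray:
        k = self.model_names.index(model_name)
        return np.array([t.model_posteriors[k] for t in self.trials])

    @property
    def designs(self) -> np.ndarray:
        return np.array([t.design for t in self.trials])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {"trial": t.index, "u": t.design, "y": t.observation}
            for name, le, po in zip(self.model_names, t.log_evidences, t.model_posteriors):
                row[f"logEv_{name}"] = le
                row[f"p_{name}"] = po
            rows.append(row)
        return pd.DataFrame(rows)


def _first_crossing(curves: np.ndarray, threshold: float, which: Optional[int]) -> Optional[int]:
    """First 1-based trial index at which the tracked posterior reaches threshold."""
    tracked = curves.max(axis=1) if which is None else curves[:, which]
    hits = np.nonzero(tracked >= threshold)[0]
    return int(hits[0]) + 1 if hits.size else None


def run_retention_experiment(
    true_params: RetentionParams,
    policy,
    rng: np.random.Generator,
    seed: int = -1,
    max_trials: int = 10,
    threshold: float = 0.95,
    prior_scale: str = "variance",
    model_set: Optional[ModelSet] = None,
) -> ExperimentResult:
    """One simulated retention experiment (true model POW).

    At each stage the policy proposes a lag, a binomial recall count is
    drawn from the true power-law curve, both candidate models are
    re-inverted on all data so far (Laplace), and the model posterior is
    refreshed from the initial 1/2-1/2 prior and the full-data evidences.
    """
    if not (0.5 < threshold < 1.0):
        raise ValueError("threshold must lie in (0.5, 1)")
    base = model_set if model_set is not None else retention_model_set(prior_scale=prior_scale)
    beliefs = [m.parameter_prior for m in base.models]
    current = base
    lags: list[float] = []
    ys: list[float] = []
    records: list[TrialRecord] = []
    for stage in range(max_trials):
        u = float(policy.propose(stage, rng, model_set=current, beliefs=beliefs))
        y = simulate_recall(pow_predict(true_params, u), base.models[0].fixed_hyperparameters["n_items"], rng)
        lags.append(u)
        ys.append(float(y))
        log_evs = []
        new_beliefs = []
        for model in base.models:
            post, le = laplace_fit(model, ys, lags)
            new_beliefs.append(post)
            log_evs.append(le)
        beliefs = new_beliefs
        current = update_model_posterior(base, log_evs)
        records.append(TrialRecord(stage + 1, u, float(y), np.array(log_evs), current.probabilities))
    curves = np.vstack([t.model_posteriors for t in records])
    ttc = _first_crossing(curves, threshold, which=None)
    selected = None
    if ttc is not None:
        selected = base.names[int(np.argmax(records[ttc - 1].model_posteriors))]
    return ExperimentResult(
        true_model="POW",
        policy=getattr(policy, "name", "custom"),
        model_names=base.names,
        trials=records,
        conclusive=ttc is not None,
        selected_model=selected,
        trials_to_criterion=ttc,
        seed=seed,
        metadata={"true_a": true_params.a, "true_b": true_params.b},
    )


def run_perceptual_experiment(
    true_model: str,
    design: str,
    rng: np.random.Generator,
    seed: int = -1,
    n_trials: int = 350,
    threshold: float = 0.95,
    response: Optional[ResponseParams] = None,
) -> ExperimentResult:
    """One simulated oddball EEG experiment under a stable/volatile/ado design.

    The subject is a hierarchical filter with the true model's fixed
    parameters; each trial's amplitude is the weighted level-2 Bayesian
    surprise plus noise.  All five candidate models are inverted online
    (exact conjugate evidence in the weight h).  The experiment is
    conclusive when the true model's posterior reaches the threshold.
    """
    if true_model not in TABLE_MODELS:
        raise ValueError(f"unknown true model {true_model!r}")
    if not (0.5 < threshold < 1.0):
        raise ValueError("threshold must lie in (0.5, 1)")
    response = response if response is not None else ResponseParams()
    base = perceptual_model_set(noise_precision=response.noise_precision)
    inverters = [SurpriseInverter(spec) for spec in base.models]
    true_idx = base.names.index(true_model)
    omega, kappa, vartheta = TABLE_MODELS[true_model]
    true_params = HGFParams(omega, kappa, vartheta)
    true_state = default_agent_state()

    schedule = None
    if design in ("stable", "volatile"):
        schedule = generate_stimuli(design, rng, n_trials)
    elif design != "ado":
        raise ValueError("design must be 'stable', 'volatile' or 'ado'")

    current = base
    records: list[TrialRecord] = []
    for t in range(n_trials):
        if schedule is not None:
            u = int(schedule.categories[t])
        else:
            u = ado_stimulus_choice(
                current,
                [inv.state for inv in inverters],
                [inv.h_belief for inv in inverters],
            )
        true_state, bs_true = hgf_step(true_state, u, true_params)
        y = simulate_eeg(bs_true, response, rng)
        for inv in inverters:
            inv.update(u, y)
        cum = np.array([inv.log_evidence for inv in inverters])
        current = update_model_posterior(base, cum)
        records.append(TrialRecord(t + 1, float(u), y, cum, current.probabilities))
    curves = np.vstack([t.model_posteriors for t in records])
    ttc = _first_crossing(curves, threshold, which=true_idx)
    return ExperimentResult(
        true_model=true_model,
        policy=design,
        model_names=base.names,
        trials=records,
        conclusive=ttc is not None,
        selected_model=true_model if ttc is not None else None,
        trials_to_criterion=ttc,
        seed=seed,
        metadata={"response_h": response.h, "noise_precision": response.noise_precision},
    )


def _spawn_rngs(master_seed: int, n: int) -> tuple[list[np.random.Generator], list[int]]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    return [np.random.default_rng(c) for c in children], seeds


def run_study1_batch(
    seed: int,
    n_participants: int = 30,
    policies: Sequence[str] = ("ado", "random", "fixed10"),
    max_trials: int = 10,
    threshold: float = 0.95,
    prior_scale: str = "variance",
    ado_criterion: str = "exact",
) -> dict[str, list[ExperimentResult]]:
    """Replicate the retention study: one participant cohort, every policy.

    The same cohort of drawn (a, b) participants is reused across policies
    so that design comparisons are paired, as in a within-cohort analysis.
    """
    cohort_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    participants, redraws = draw_participants(n_participants, cohort_rng, prior_scale)
    results: dict[str, list[ExperimentResult]] = {}
    for p_idx, policy_kind in enumerate(policies):
        rngs, seeds = _spawn_rngs(seed + 1000 * (p_idx + 1), n_participants)
        runs = []
        for part, rng, s in zip(participants, rngs, seeds):
            policy = study1_design_policy(policy_kind, criterion=ado_criterion)
            runs.append(
                run_retention_experiment(
                    part, policy, rng, seed=s,
                    max_trials=max_trials, threshold=threshold,
                    prior_scale=prior_scale,
                )
            )
        for r in runs:
            r.metadata["cohort_redraws"] = redraws
        results[policy_kind] = runs
    return results


def run_study2_batch(
    seed: int,
    n_per_model: int = 15,
    designs: Sequence[str] = ("stable", "volatile", "ado"),
    true_models: Sequence[str] = tuple(TABLE_MODELS),
    n_trials: int = 350,
    threshold: float = 0.95,
) -> dict[str, list[ExperimentResult]]:
    """Replicate the perceptual study: n_per_model subjects per true model, every design."""
    results: dict[str, list[ExperimentResult]] = {}
    n_total = n_per_model * len(true_models)
    for d_idx, design in enumerate(designs):
        rngs, seeds = _spawn_rngs(seed + 1000 * (d_idx + 1), n_total)
        runs = []
        k = 0
        for tm in true_models:
            for _ in range(n_per_model):
                runs.append(
                    run_perceptual_experiment(
                        tm, design, rngs[k], seed=seeds[k],
                        n_trials=n_trials, threshold=threshold,
                    )
                )
                k += 1
        results[design] = runs
    return results


def _mean_posterior_curve(runs: Sequence[ExperimentResult], model_name: str) -> np.ndarray:
    return np.vstack([r.posterior_curve(model_name) for r in runs]).mean(axis=0)


def summarize_study1(results: dict[str, list[ExperimentResult]], threshold: float = 0.95) -> dict:
    """Per-policy mean lag, mean-posterior curve, stages-to-criterion summary."""
    summary: dict = {}
    for policy, runs in results.items():
        lags = np.concatenate([r.designs for r in runs])
        curve = _mean_posterior_curve(runs, "POW")
        hits = np.nonzero(curve >= threshold)[0]
        ttc = [r.trials_to_criterion for r in runs if r.conclusive]
        summary[policy] = {
            "n_experiments": len(runs),
            "mean_lag": float(lags.mean()),
            "lag_histogram": np.histogram(lags, bins=np.arange(0, 101, 5))[0].tolist(),
            "mean_posterior_true_by_stage": curve.tolist(),
            "group_curve_stage_at_criterion": (int(hits[0]) + 1) if hits.size else None,
            "nonconclusive_fraction": float(np.mean([not r.conclusive for r in runs])),
            "mean_trials_to_criterion": float(np.mean(ttc)) if ttc else None,
        }
    return summary


def summarize_study2(results: dict[str, list[ExperimentResult]]) -> dict:
    """Per-design non-conclusive rate, trials-to-criterion and posterior curves."""
    summary: dict = {}
    for design, runs in results.items():
        ttc = [r.trials_to_criterion for r in runs if r.conclusive]
        by_model: dict = {}
        for tm in sorted({r.true_model for r in runs}):
            sub = [r for r in runs if r.true_model == tm]
            sub_ttc = [r.trials_to_criterion for r in sub if r.conclusive]
            by_model[tm] = {
                "n": len(sub),
                "nonconclusive_percent": 100.0 * np.mean([not r.conclusive for r in sub]),
                "mean_trials_to_criterion": float(np.mean(sub_ttc)) if sub_ttc else None,
                "mean_posterior_true_curve": _mean_posterior_curve(sub, tm).tolist(),
            }
        summary[design] = {
            "n_experiments": len(runs),
            "nonconclusive_percent": 100.0 * np.mean([not r.conclusive for r in runs]),
            "mean_trials_to_criterion": float(np.mean(ttc)) if ttc else None,
            "by_true_model": by_model,
        }
    return summary
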