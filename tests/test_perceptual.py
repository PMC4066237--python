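"""Hierarchical-filter agent, Bayesian surprise, EEG model and the five-model family."""

import numpy as np
import pytest

from adoloop.design import PredictiveDensity
from adoloop.inference import GaussianBelief, ModelSet, laplace_fit, update_model_posterior
from adoloop.perceptual import (
    AgentState,
    HGFParams,
    ResponseParams,
    SurpriseInverter,
    TABLE_MODELS,
    ado_stimulus_choice,
    bayesian_surprise,
    default_agent_state,
    generate_stimuli,
    hgf_predict,
    hgf_step,
    hgf_update,
    perceptual_model_set,
    simulate_eeg,
    surprise_model_spec,
)


def _trace(model_id, categories):
    omega, kappa, vartheta = TABLE_MODELS[model_id]
    params = HGFParams(omega, kappa, vartheta)
    state = default_agent_state()
    out = []
    for u in categories:
        state, bs = hgf_step(state, int(u), params)
        out.append(bs)
    return np.array(out)


class TestHGFPrediction:
    def test_neutral_tendency_predicts_half(self):
        assert hgf_predict(default_agent_state()) == 0.5

    def test_log_odds_four_predicts_point_eight(self):
        state = AgentState(mu2=np.log(4.0), sigma2=1.0, mu3=0.0, sigma3=1.0)
        assert hgf_predict(state) == pytest.approx(0.8)

    def test_extreme_negative_tendency_predicts_zero(self):
        state = AgentState(mu2=-100.0, sigma2=1.0, mu3=0.0, sigma3=1.0)
        assert hgf_predict(state) == pytest.approx(0.0, abs=1e-20)


class TestHGFUpdate:
    def test_null_model_state_frozen(self):
        params = HGFParams(omega=-np.inf, kappa=0.0)
        state = default_agent_state()
        for u in (0, 1, 1, 0):
            new = hgf_update(state, u, params)
            assert (new.mu2, new.sigma2, new.mu3, new.sigma3) == (
                state.mu2, state.sigma2, state.mu3, state.sigma3
            )
            state = new

    def test_two_level_model_leaves_level3_inert(self):
        params = HGFParams(omega=-4.0, kappa=0.0)
        state = default_agent_state()
        for u in (1, 0, 1, 1):
            state = hgf_update(state, u, params)
            assert state.mu3 == default_agent_state().mu3
            assert state.sigma3 == default_agent_state().sigma3

    def test_update_moves_belief_toward_observation(self):
        params = HGFParams(omega=-4.0, kappa=0.0)
        after = hgf_update(default_agent_state(), 1, params)
        assert hgf_predict(after) > 0.5
        after0 = hgf_update(default_agent_state(), 0, params)
        assert hgf_predict(after0) < 0.5

    def test_variances_stay_positive_over_long_runs(self, rng):
        params = HGFParams(omega=-4.0, kappa=1.0, vartheta=0.2)
        state = default_agent_state()
        for u in (rng.random(500) < 0.3).astype(int):
            state = hgf_update(state, int(u), params)
            assert state.sigma2 > 0 and state.sigma3 > 0

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            hgf_update(default_agent_state(), 2, HGFParams(-4.0))

    def test_kappa_positive_requires_vartheta(self):
        with pytest.raises(ValueError, match="vartheta"):
            HGFParams(omega=-4.0, kappa=1.0)


class TestBayesianSurprise:
    def test_unchanged_beliefs_give_zero(self):
        s = default_agent_state()
        assert bayesian_surprise(s, s) == 0.0

    def test_null_model_surprise_identically_zero(self, rng):
        cats = (rng.random(200) < 0.2).astype(int)
        assert np.all(_trace("M1", cats) == 0.0)

    def test_rare_outcome_more_surprising_than_expected_one(self):
        # Long run of standards, then one deviant: the deviant's surprise
        # must exceed the preceding standard's.
        params = HGFParams(*TABLE_MODELS["M3"])
        state = default_agent_state()
        for _ in range(30):
            state, bs_standard = hgf_step(state, 0, params)
        _, bs_deviant = hgf_step(state, 1, params)
        assert bs_deviant > bs_standard

    def test_deterministic_traces(self, rng):
        cats = (rng.random(100) < 0.2).astype(int)
        t1 = _trace("M4", cats)
        t2 = _trace("M4", cats)
        np.testing.assert_array_equal(t1, t2)


class TestEEGSimulation:
    def test_amplitude_mean_and_noise_scale(self, rng):
        resp = ResponseParams()  # h = -10, precision 100
        draws = np.array([simulate_eeg(0.3, resp, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(-3.0, abs=0.01)
        assert draws.std() == pytest.approx(0.1, abs=0.005)

    def test_replication_defaults(self):
        resp = ResponseParams()
        assert resp.h == -10.0
        assert resp.noise_precision == 100.0


class TestStimulusSchedules:
    def test_lengths_and_blocks(self, rng):
        vol = generate_stimuli("volatile", rng)
        assert len(vol) == 350
        expected = np.concatenate([
            np.full(100, 0.2), np.full(50, 0.1), np.full(50, 0.3),
            np.full(50, 0.1), np.full(100, 0.2),
        ])
        np.testing.assert_allclose(vol.probabilities, expected)

    def test_stable_empirical_rate(self, rng):
        rates = [generate_stimuli("stable", rng).categories.mean() for _ in range(10)]
        assert np.mean(rates) == pytest.approx(0.2, abs=0.03)

    def test_unknown_design_rejected(self, rng):
        with pytest.raises(ValueError, match="design"):
            generate_stimuli("chaotic", rng)


class TestModelFamily:
    def test_table_parameter_audit(self):
        expected = {
            "M1": (-np.inf, 0.0, None),
            "M2": (-5.0, 0.0, None),
            "M3": (-4.0, 0.0, None),
            "M4": (-5.0, 1.0, 0.2),
            "M5": (-4.0, 1.0, 0.2),
        }
        for mid, (om, ka, vt) in expected.items():
            spec = surprise_model_spec(mid)
            hp = spec.fixed_hyperparameters
            assert hp["omega"] == om and hp["kappa"] == ka and hp["vartheta"] == vt

    def test_null_model_evidence_is_pure_noise_likelihood(self, rng):
        y = rng.normal(0, 0.1, 100)
        inv = SurpriseInverter(surprise_model_spec("M1"))
        for yy in y:
            inv.update(0, yy)
        expected = np.sum(-0.5 * np.log(2 * np.pi * 0.01) - 0.5 * y ** 2 / 0.01)
        assert inv.log_evidence == pytest.approx(expected, rel=1e-12)

    def test_weight_recovery_under_true_model(self, rng):
        seq = generate_stimuli("volatile", rng)
        resp = ResponseParams()
        true_trace = _trace("M5", seq.categories)
        inv = SurpriseInverter(surprise_model_spec("M5"))
        for u, bs in zip(seq.categories, true_trace):
            y = simulate_eeg(bs, resp, rng)
            inv.update(int(u), y)
        assert abs(inv.h_mean - (-10.0)) < 3 * np.sqrt(inv.h_var)

    def test_sequential_inversion_matches_batch_laplace_fit(self, rng):
        """Dual route: online conjugate updating vs batch Laplace inversion."""
        seq = generate_stimuli("stable", rng, n_trials=80)
        resp = ResponseParams()
        trace = _trace("M3", seq.categories)
        ys = [simulate_eeg(bs, resp, rng) for bs in trace]
        inv = SurpriseInverter(surprise_model_spec("M3"))
        for u, y in zip(seq.categories, ys):
            inv.update(int(u), y)
        spec = surprise_model_spec("M3")
        post, log_ev = laplace_fit(spec, ys, list(range(80)), states=list(trace))
        assert post.mean[0] == pytest.approx(inv.h_mean, abs=1e-6)
        assert post.covariance[0, 0] == pytest.approx(inv.h_var, rel=1e-6)
        assert log_ev == pytest.approx(inv.log_evidence, abs=1e-6)


class TestLearningRateOrdering:
    def test_high_rate_model_accumulates_more_early_surprise(self, rng):
        cats = (rng.random(350) < 0.2).astype(int)
        bs2, bs3 = _trace("M2", cats), _trace("M3", cats)
        assert bs3[:50].sum() > bs2[:50].sum()

    def test_sibling_traces_coincide_before_volatility_then_diverge(self, rng):
        vol = generate_stimuli("volatile", rng)
        bs2, bs4 = _trace("M2", vol.categories), _trace("M4", vol.categories)
        early = np.abs(bs2[:50] - bs4[:50]).mean()
        during = np.abs(bs2[150:250] - bs4[150:250]).mean()
        assert early < 0.1 * np.abs(bs2[:50]).mean()
        assert during > early


class TestAdoStimulusChoice:
    @staticmethod
    def _set_with(posteriors):
        base = perceptual_model_set()
        return ModelSet(base.models, np.asarray(posteriors))

    def test_identical_predictions_tie_break_to_standard(self):
        # All-null family: every model predicts pure noise for both stimuli.
        base = perceptual_model_set()
        states = [default_agent_state()] * 5
        # Replace with M1-like states under the null model only works via the
        # specs; identical h beliefs centred at 0 give identical predictives.
        h0 = GaussianBelief([0.0], [[1e-12]])
        u = ado_stimulus_choice(base, states, [h0] * 5)
        assert u == 0

    def test_full_run_uses_both_categories(self, study2_batch):
        for run in study2_batch["ado"][:10]:
            rate = run.designs.mean()
            assert 0.0 < rate < 1.0
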