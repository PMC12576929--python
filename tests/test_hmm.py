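import itertools

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from movekba.hmm import (
    DecodedTrack,
    HMMParams,
    StepTurnSeries,
    emission_density,
    fit_hmm,
    hmm_loglik,
    state_proportions,
    steps_and_turns,
    viterbi_decode,
    _log_emission_matrix,
)
from movekba.synthetic import default_config, simulate_hmm_series

TRUTH = HMMParams.from_config(default_config())


def random_series(rng, T):
    steps = rng.gamma(2.0, 0.3, T)
    turns = np.concatenate([[np.nan], rng.uniform(-np.pi, np.pi, T - 1)])
    return StepTurnSeries(steps, turns)


def brute_force(params, series):
    """Exhaustive path sum and argmax over all 3^T state sequences."""
    logb = _log_emission_matrix(params, series)
    T = len(series)
    total = -np.inf
    best, best_path = -np.inf, None
    for path in itertools.product(range(3), repeat=T):
        lp = np.log(params.delta[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(params.gamma[path[t - 1], path[t]]) + logb[t, path[t]]
        total = np.logaddexp(total, lp)
        if lp > best:
            best, best_path = lp, path
    return total, best_path


class TestStepsAndTurns:
    def test_straight_line_zero_turn(self):
        xy = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        st = steps_and_turns(xy)
        np.testing.assert_allclose(st.turns[1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(st.steps, 1.0)

    def test_right_angle(self):
        xy = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        st = steps_and_turns(xy)
        assert st.turns[1] == pytest.approx(np.pi / 2)

    def test_reversal_wraps_to_pi(self):
        xy = np.array([[0, 0], [1, 0], [0, 0]], dtype=float)
        st = steps_and_turns(xy)
        assert st.turns[1] == pytest.approx(np.pi)

    def test_too_few_fixes(self):
        with pytest.raises(ValueError):
            steps_and_turns(np.array([[0, 0], [1, 1]], dtype=float))


class TestEmissionDensity:
    def test_gamma_mean_sd_conversion(self):
        # mean 0.98, sd 0.32 -> shape 9.3789, rate 9.5703
        shape, rate = (0.98 / 0.32) ** 2, 0.98 / 0.32**2
        assert shape == pytest.approx(9.3789, abs=1e-4)
        assert rate == pytest.approx(9.5703, abs=1e-4)
        d = emission_density(TRUTH, 2, 0.9, None)
        assert d == pytest.approx(gamma_dist.pdf(0.9, a=shape, scale=1 / rate), rel=1e-10)

    def test_uniform_von_mises_limit(self):
        p = HMMParams(
            step_mean=[1, 1, 1], step_sd=[1, 1, 1], turn_mu=[0, 0, 0],
            turn_kappa=[0, 0, 0], gamma=np.full((3, 3), 1 / 3), delta=np.full(3, 1 / 3),
        )
        base = emission_density(p, 0, 1.0, None)
        for angle in (-3.0, 0.0, 1.2):
            assert emission_density(p, 0, 1.0, angle) == pytest.approx(
                base / (2 * np.pi), rel=1e-12
            )

    def test_unimodal_for_shape_above_one(self):
        m, s = TRUTH.step_mean[2], TRUTH.step_sd[2]
        at_mean = emission_density(TRUTH, 2, m, None)
        at_tail = emission_density(TRUTH, 2, m + 3 * s, None)
        assert at_mean > at_tail

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            emission_density(TRUTH, 0, -0.1, None)


class TestLoglik:
    def test_single_observation_degenerate_delta(self):
        p = HMMParams(
            step_mean=TRUTH.step_mean, step_sd=TRUTH.step_sd,
            turn_mu=TRUTH.turn_mu, turn_kappa=TRUTH.turn_kappa,
            gamma=TRUTH.gamma, delta=[1.0, 0.0, 0.0],
        )
        s = StepTurnSeries([0.1], [np.nan])
        expect = np.log(emission_density(p, 0, 0.1, None))
        assert hmm_loglik(p, [s]) == pytest.approx(expect, abs=1e-12)

    def test_single_observation_general_delta(self):
        s = StepTurnSeries([0.5], [np.nan])
        expect = np.log(
            sum(TRUTH.delta[i] * emission_density(TRUTH, i, 0.5, None) for i in range(3))
        )
        assert hmm_loglik(TRUTH, [s]) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_path_sum(self, seed):
        rng = np.random.default_rng(seed)
        s = random_series(rng, 6)
        total, _ = brute_force(TRUTH, s)
        assert hmm_loglik(TRUTH, [s]) == pytest.approx(total, abs=1e-9)

    def test_invariant_to_state_permutation(self):
        rng = np.random.default_rng(3)
        s = random_series(rng, 20)
        perm = [2, 0, 1]
        permuted = HMMParams(
            step_mean=TRUTH.step_mean[perm], step_sd=TRUTH.step_sd[perm],
            turn_mu=TRUTH.turn_mu[perm], turn_kappa=TRUTH.turn_kappa[perm],
            gamma=TRUTH.gamma[np.ix_(perm, perm)], delta=TRUTH.delta[perm],
        )
        assert hmm_loglik(permuted, [s]) == pytest.approx(hmm_loglik(TRUTH, [s]), abs=1e-9)

    def test_nan_observation_identified(self):
        with pytest.raises(ValueError, match="index 1"):
            StepTurnSeries([0.1, np.nan, 0.2], [np.nan, 0.0, 0.0])


class TestViterbi:
    @pytest.mark.parametrize("T", [2, 4, 8])
    def test_matches_exhaustive_argmax(self, T):
        rng = np.random.default_rng(T)
        s = random_series(rng, T)
        _, best_path = brute_force(TRUTH, s)
        assert tuple(viterbi_decode(TRUTH, s).states) == best_path

    def test_separable_emissions_recover_truth(self):
        cfg = default_config()
        sep = HMMParams(
            step_mean=[0.05, 0.5, 3.0], step_sd=[0.01, 0.05, 0.2],
            turn_mu=[0, 0, 0], turn_kappa=[50, 50, 50],
            gamma=cfg.transition_matrix, delta=cfg.initial_distribution,
        )
        rng = np.random.default_rng(0)
        states = rng.integers(0, 3, 200)
        steps = rng.gamma(
            (np.array(sep.step_mean) / np.array(sep.step_sd))[states] ** 2,
            (np.array(sep.step_sd) ** 2 / np.array(sep.step_mean))[states],
        )
        turns = np.concatenate([[np.nan], rng.vonmises(0, 50, 199)])
        decoded = viterbi_decode(sep, StepTurnSeries(steps, turns))
        assert (decoded.states == states).mean() > 0.99

    def test_sticky_chain_stays_in_initial_state(self):
        p = HMMParams(
            step_mean=[1, 1, 1], step_sd=[1, 1, 1], turn_mu=[0, 0, 0],
            turn_kappa=[0, 0, 0],
            gamma=np.eye(3) * 0.999 + (1 - 0.999) / 2 * (1 - np.eye(3)),
            delta=[0.0, 0.0, 1.0],
        )
        rng = np.random.default_rng(1)
        s = random_series(rng, 10)
        assert (viterbi_decode(p, s).states == 2).all()


class TestFit:
    def test_parameter_recovery_free_running(self):
        cfg = default_config()
        series = [
            steps_and_turns(simulate_hmm_series(cfg, 300, seed=2000 + i))
            for i in range(20)
        ]
        rng = np.random.default_rng(11)
        u = rng.uniform(0.8, 1.2, 9)
        init = HMMParams(
            step_mean=TRUTH.step_mean * u[:3], step_sd=TRUTH.step_sd * u[3:6],
            turn_mu=TRUTH.turn_mu, turn_kappa=TRUTH.turn_kappa * u[6:9],
            gamma=TRUTH.gamma, delta=TRUTH.delta,
        )
        fit = fit_hmm(series, init, n_restarts=2, seed=5)
        np.testing.assert_allclose(fit.params.step_mean, TRUTH.step_mean, rtol=0.05)
        # MLE dominance on the same data
        assert fit.loglik >= hmm_loglik(TRUTH, series) - 1e-6

    def test_states_relabelled_by_step_mean(self):
        p = TRUTH.relabelled_by_step_mean()
        assert np.all(np.diff(p.step_mean) > 0)


class TestStateProportions:
    def test_counting(self):
        d = DecodedTrack("t1", np.array([0, 0, 1, 2]))
        out = state_proportions([d])
        np.testing.assert_allclose(out.loc["all"], [0.5, 0.25, 0.25])

    def test_weighted_grand_mean(self):
        d1 = DecodedTrack("t1", np.array([0, 0, 1, 1]))  # colony A: (.5,.5,0)
        d2 = DecodedTrack("t2", np.array([2, 2, 2, 2]))  # colony B: (0,0,1)
        out = state_proportions(
            [d1, d2], colony_of={"t1": "A", "t2": "B"},
            individuals_per_colony={"A": 3, "B": 1},
        )
        np.testing.assert_allclose(out.loc["grand_mean"], [0.375, 0.375, 0.25])

    def test_rows_sum_to_one(self):
        d = DecodedTrack("t1", np.array([0, 1, 2, 2, 1]))
        out = state_proportions([d])
        assert out.loc["all"].sum() == pytest.approx(1.0, abs=1e-12)
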