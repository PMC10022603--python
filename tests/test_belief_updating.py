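"""Softmax message passing: fixed points, gradient flow, free energy."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import livingpresent as lp
from livingpresent.temporal_graph import TimeIndex

from conftest import random_instance, random_model


def _uniform_state(n, index=TimeIndex(0, 0)):
    return lp.BeliefState(np.full(n, 1.0 / n), index)


def _delta_state(n, k, index=TimeIndex(0, 0)):
    p = np.zeros(n)
    p[k] = 1.0
    return lp.BeliefState(p, index)


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(lp.softmax([0.0, 0.0]), [0.5, 0.5])

    def test_inverts_logs_up_to_normalization(self):
        out = lp.softmax(np.log([0.8, 0.2]))
        assert np.allclose(out, [0.8, 0.2])

    def test_large_inputs_are_max_shifted(self):
        out = lp.softmax([1000.0, 1000.0, 999.0])
        # closed form after subtracting the max: [1, 1, e^-1] normalized
        z = 2.0 + math.exp(-1.0)
        assert np.all(np.isfinite(out))
        assert np.allclose(out, [1 / z, 1 / z, math.exp(-1.0) / z])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lp.softmax([np.inf, 0.0])
        with pytest.raises(ValueError):
            lp.softmax([np.nan, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.floats(-100, 100))
    def test_normalized_and_shift_invariant(self, values, shift):
        v = np.asarray(values)
        out = lp.softmax(v)
        assert out.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(out, lp.softmax(v + shift), atol=1e-12)


class TestPresentMomentInference:
    def test_uniform_messages_give_uniform_present(self):
        n = 3
        model = lp.GenerativeModel(A=np.full((n, n), 1 / n), B=(np.eye(n),),
                                   D=np.full(n, 1 / n))
        out = lp.present_moment_inference(
            _uniform_state(n, TimeIndex(0, 1)), _uniform_state(n, TimeIndex(1, 1)),
            lp.Observation(TimeIndex(1, -1), 0), model)
        assert np.allclose(out.probabilities, 1 / n)

    def test_agreeing_messages_give_certainty(self):
        n = 3
        model = lp.GenerativeModel(A=np.eye(n), B=(np.eye(n),),
                                   D=np.full(n, 1 / n))
        out = lp.present_moment_inference(
            _delta_state(n, 2, TimeIndex(0, 1)), _delta_state(n, 2, TimeIndex(1, 1)),
            lp.Observation(TimeIndex(1, -1), 2), model)
        assert out.probabilities[2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_product_of_factors_oracle(self):
        """Log-domain softmax equals the linear-domain product of the three
        probability factors, renormalized."""
        rng = np.random.default_rng(3)
        model = random_model(rng, n_states=3, n_outcomes=4)
        prot = rng.dirichlet(np.ones(3))
        prim = rng.dirichlet(np.ones(3))
        o = 2
        out = lp.present_moment_inference(
            lp.BeliefState(prot, TimeIndex(0, 1)),
            lp.BeliefState(prim, TimeIndex(1, 1)),
            lp.Observation(TimeIndex(1, -1), o), model)
        joint = prot * prim * model.A[o, :]
        assert np.allclose(out.probabilities, joint / joint.sum(), atol=1e-12)

    def test_output_index_is_one_subjective_step_down(self):
        model = random_model(np.random.default_rng(0), 3, 3)
        out = lp.present_moment_inference(
            _uniform_state(3, TimeIndex(0, 1)), _uniform_state(3, TimeIndex(1, 1)),
            lp.Observation(TimeIndex(1, -1), 0), model)
        assert out.index == TimeIndex(1, 0)

    def test_dimension_mismatch_rejected(self):
        model = random_model(np.random.default_rng(0), 3, 3)
        with pytest.raises(ValueError):
            lp.present_moment_inference(
                _uniform_state(4, TimeIndex(0, 1)),
                _uniform_state(3, TimeIndex(1, 1)),
                lp.Observation(TimeIndex(1, -1), 0), model)


class TestStationaryUpdate:
    def test_consistent_deterministic_messages_give_certainty(self):
        model = lp.GenerativeModel(A=np.eye(3), B=(np.eye(3),),
                                   D=np.array([0.0, 1.0, 0.0]))
        lattice = lp.BeliefLattice.from_observations(model, [1, 1, 1])
        out = lp.stationary_update(lattice, TimeIndex(0, 1))
        assert out.probabilities[1] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_model_gives_uniform_posterior(self):
        n = 4
        model = lp.GenerativeModel(A=np.full((n, n), 1 / n),
                                   B=(np.full((n, n), 1 / n),),
                                   D=np.full(n, 1 / n))
        lattice = lp.BeliefLattice.from_observations(model, [0, 1, 2])
        out = lp.stationary_update(lattice, TimeIndex(0, 1))
        assert np.allclose(out.probabilities, 1 / n)

    def test_fixed_point_residual_vanishes(self):
        """Substituting the converged beliefs back into the update map
        reproduces them."""
        rng = np.random.default_rng(17)
        model = random_model(rng, n_states=3, n_outcomes=3)
        obs = [int(x) for x in rng.integers(0, 3, 5)]
        lattice = lp.BeliefLattice.from_observations(model, obs)
        solved, record = lp.solve_stationary(
            lattice, lp.UpdateConfig(tolerance=1e-12))
        assert record.converged
        assert lp.lattice_residual(solved) < 1e-8
        for idx, state in solved.belief_items():
            again = lp.stationary_update(solved, idx)
            assert np.allclose(again.probabilities, state.probabilities,
                               atol=1e-8)

    def test_convention_mismatch_rejected(self):
        model = random_model(np.random.default_rng(0), 3, 3)
        lattice = lp.BeliefLattice.from_observations(model, [0, 1],
                                                     convention="integrated")
        with pytest.raises(ValueError, match="convention"):
            lp.stationary_update(lattice, TimeIndex(0, 0),
                                 lp.UpdateConfig(index_convention="stationary"))

    def test_unknown_coordinate_rejected(self):
        model = random_model(np.random.default_rng(0), 3, 3)
        lattice = lp.BeliefLattice.from_observations(model, [0, 1])
        with pytest.raises(KeyError):
            lp.stationary_update(lattice, TimeIndex(5, 0))


class TestGradientSweep:
    def test_already_converged_lattice_stops_immediately(self):
        rng = np.random.default_rng(2)
        model, obs = random_instance(rng)
        lattice = lp.BeliefLattice.from_observations(model, obs)
        solved, _ = lp.solve_stationary(lattice,
                                        lp.UpdateConfig(tolerance=1e-13))
        again, record = lp.gradient_sweep(solved)
        assert record.converged
        assert record.iterations == 1
        assert record.max_change_trace[0] < 1e-10

    def test_agrees_with_direct_fixed_point_iteration(self):
        rng = np.random.default_rng(4)
        model = random_model(rng, n_states=4, n_outcomes=4)
        obs = [int(x) for x in rng.integers(0, 4, 5)]
        lattice = lp.BeliefLattice.from_observations(model, obs)
        swept, rec1 = lp.gradient_sweep(lattice, lp.UpdateConfig(step_size=0.1))
        solved, rec2 = lp.solve_stationary(lattice,
                                           lp.UpdateConfig(tolerance=1e-12))
        assert rec1.converged and rec2.converged
        assert np.abs(swept.beliefs - solved.beliefs).max() < 1e-6

    def test_overlarge_step_flags_non_convergence(self):
        """A near-deterministic instance oscillates under dt = 2 but relaxes
        under dt = 0.1 (instance located by a sweep over dt)."""
        eps = 0.02
        perm = np.roll(np.eye(3), 1, axis=0)
        b = (1 - eps) * perm + eps / 2 * (1 - perm)
        a = (1 - eps) * np.eye(3) + eps / 2 * (1 - np.eye(3))
        model = lp.GenerativeModel(A=a, B=(b,), D=np.full(3, 1 / 3))
        obs = [2, 1, 1, 0, 0, 0]
        lattice = lp.BeliefLattice.from_observations(model, obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stiff = lp.UpdateConfig(step_size=2.0, max_iterations=500)
        _, record = lp.gradient_sweep(lattice, stiff)
        assert not record.converged
        assert record.final_residual > 1e-3
        _, tame = lp.gradient_sweep(lattice, lp.UpdateConfig())
        assert tame.converged

    def test_integrated_convention_reaches_the_same_beliefs(self):
        rng = np.random.default_rng(9)
        model, obs = random_instance(rng)
        stat, _ = lp.gradient_sweep(
            lp.BeliefLattice.from_observations(model, obs))
        integ, _ = lp.gradient_sweep(
            lp.BeliefLattice.from_observations(model, obs,
                                               convention="integrated"),
            lp.UpdateConfig(index_convention="integrated"))
        assert np.abs(stat.beliefs - integ.beliefs).max() < 1e-9


class TestFreeEnergy:
    def test_perfect_fit_is_zero(self):
        model = lp.GenerativeModel(A=np.eye(3),
                                   B=(np.roll(np.eye(3), 1, axis=0),),
                                   D=np.array([1.0, 0.0, 0.0]))
        obs = [0, 1, 2]
        beliefs = np.eye(3)  # delta on the true path 0 -> 1 -> 2
        lattice = lp.BeliefLattice(model, obs, beliefs=beliefs)
        assert lp.free_energy(lattice).value == pytest.approx(0.0, abs=1e-12)

    def test_uniform_model_without_observations_is_zero(self):
        """Entropy exactly cancels the expected transition surprise."""
        n = 4
        model = lp.GenerativeModel(A=np.full((n, n), 1 / n),
                                   B=(np.full((n, n), 1 / n),),
                                   D=np.full(n, 1 / n))
        lattice = lp.BeliefLattice(model, [None] * 5)
        assert lp.free_energy(lattice).value == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_sums_to_value(self):
        rng = np.random.default_rng(21)
        model, obs = random_instance(rng)
        lattice, _ = lp.gradient_sweep(
            lp.BeliefLattice.from_observations(model, obs))
        fe = lp.free_energy(lattice)
        assert fe.value == pytest.approx(sum(t.total for t in fe.decomposition),
                                         abs=1e-9)

    def test_bounds_negative_log_evidence(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            model, obs = random_instance(rng)
            lattice, _ = lp.gradient_sweep(
                lp.BeliefLattice.from_observations(model, obs))
            exact = lp.forward_backward(model, obs)
            assert lp.free_energy(lattice).value >= -exact.log_evidence - 1e-9


class TestSurprisal:
    def test_anticipated_outcome_costs_nothing(self):
        model = lp.GenerativeModel(A=np.eye(3), B=(np.eye(3),),
                                   D=np.full(3, 1 / 3))
        assert lp.surprisal(model, _delta_state(3, 1), 1) == 0.0

    def test_uniform_predictive_costs_log_n(self):
        n = 4
        model = lp.GenerativeModel(A=np.eye(n), B=(np.eye(n),),
                                   D=np.full(n, 1 / n))
        for o in range(n):
            assert lp.surprisal(model, _uniform_state(n), o) == \
                pytest.approx(math.log(4))

    def test_impossible_outcome_is_infinitely_surprising(self):
        model = lp.make_melody_model(1.0, 0.0)
        predictive = _delta_state(5, 3)  # certain of toneD after A, B, C
        assert lp.surprisal(model, predictive, 4) == float("inf")
        assert lp.surprisal(model, predictive, 3) == 0.0


class TestPhenomenologicalStructure:
    def test_present_depends_on_both_past_and_future_messages(self):
        """Perturbing either the retained observation or the protention
        changes the inferred present on a non-degenerate model."""
        rng = np.random.default_rng(12)
        model = random_model(rng, n_states=3, n_outcomes=3)
        prot = lp.BeliefState(rng.dirichlet(np.ones(3)), TimeIndex(0, 1))
        prim = lp.BeliefState(rng.dirichlet(np.ones(3)), TimeIndex(1, 1))
        base = lp.present_moment_inference(
            prot, prim, lp.Observation(TimeIndex(1, -1), 0), model)
        other_obs = lp.present_moment_inference(
            prot, prim, lp.Observation(TimeIndex(1, -1), 1), model)
        assert np.abs(base.probabilities - other_obs.probabilities).max() > 1e-6
        nudged = lp.BeliefState(rng.dirichlet(np.ones(3)), TimeIndex(0, 1))
        other_prot = lp.present_moment_inference(
            nudged, prim, lp.Observation(TimeIndex(1, -1), 0), model)
        assert np.abs(base.probabilities - other_prot.probabilities).max() > 1e-6

    def test_integrated_updates_read_two_objective_times(self):
        rng = np.random.default_rng(13)
        model, obs = random_instance(rng)
        lattice = lp.BeliefLattice.from_observations(model, obs,
                                                     convention="integrated")
        interior = [lattice.hidden_index(p) for p in range(1, len(obs) - 1)]
        for target in interior:
            consumed = lp.consumed_indices(lattice, target)
            objectives = {ix.objective for ix in consumed.values()}
            assert len(objectives) >= 2


class TestConfigAndState:
    def test_invalid_config_values_rejected(self):
        for kwargs in ({"step_size": 0.0}, {"tolerance": -1.0},
                       {"log_floor": 0.0}, {"max_iterations": 0},
                       {"index_convention": "sideways"}):
            with pytest.raises(ValueError):
                lp.UpdateConfig(**kwargs)

    def test_overshooting_step_warns(self):
        with pytest.warns(RuntimeWarning):
            lp.UpdateConfig(step_size=1.5)

    def test_denormalized_belief_rejected(self):
        with pytest.raises(ValueError):
            lp.BeliefState(np.array([0.5, 0.4]), TimeIndex(0, 0))
        with pytest.raises(ValueError):
            lp.BeliefState(np.array([1.5, -0.5]), TimeIndex(0, 0))

    def test_lattice_frame_is_tidy(self):
        model = lp.make_melody_model(1.0, 0.0)
        lattice, _ = lp.gradient_sweep(
            lp.BeliefLattice.from_observations(model, [0, 1]))
        frame = lp.lattice_to_frame(lattice)
        assert set(frame.columns) == {"objective_t", "subjective_tau",
                                      "state_label", "probability"}
        assert len(frame) == 2 * 5
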