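import numpy as np
import pytest
from scipy.optimize import bisect

import spectmap as sm
from spectmap.priors import PotentialSpec, RegularizationMap, eight_neighborhood
from spectmap.recon import (
    LocalRegSpec,
    ReconConfig,
    ReconState,
    REGION_HOT,
    initial_estimate,
    map_ent_loc_update,
    map_ent_update,
    map_ent_update_additive,
    map_gibbs_update,
    mlem_update,
    osem_pass,
    osem_subsets,
    poisson_log_likelihood,
    run_reconstruction,
    update_region_map,
)


def scalar_model(a=1.0):
    return sm.MatrixModel(np.array([[a]]), image_shape=(1, 1), sino_shape=(1, 1))


class TestPoissonLogLikelihood:
    def test_all_zero(self):
        assert poisson_log_likelihood(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0

    def test_single_bin_value(self):
        assert poisson_log_likelihood(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(-1.0)

    def test_maximized_at_mean_equal_counts(self):
        g = np.array([[5.0]])
        grid = np.linspace(0.01, 20, 4000)
        vals = [poisson_log_likelihood(g, np.array([[m]])) for m in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(5.0, abs=0.01)

    def test_impossible_observation(self):
        assert poisson_log_likelihood(np.array([[1.0]]), np.array([[0.0]])) == -np.inf

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            poisson_log_likelihood(np.zeros((1, 2)), np.zeros((2, 1)))


class TestMLEM:
    def test_scalar_closed_form(self):
        state = ReconState(np.array([[1.0]]))
        out = mlem_update(state, scalar_model(), np.array([[5.0]]))
        assert out.estimate[0, 0] == pytest.approx(5.0)
        assert out.iteration == 1

    def test_consistent_data_is_fixed_point(self, toy_model):
        f = np.array([[2.0, 3.0]])
        g = toy_model.forward(f)
        out = mlem_update(ReconState(f), toy_model, g)
        np.testing.assert_allclose(out.estimate, f, rtol=1e-12)

    def test_converges_to_bruteforce_mle(self, toy_model):
        rng = np.random.default_rng(7)
        g = rng.poisson(toy_model.forward(np.array([[2.0, 3.0]]))).astype(float)
        state = ReconState(np.ones((1, 2)))
        for _ in range(500):
            state = mlem_update(state, toy_model, g)
        ours = poisson_log_likelihood(g, toy_model.forward(state.estimate))
        # dense grid search over the two activities
        grid = np.linspace(0.01, 8, 400)
        best = -np.inf
        for f1 in grid:
            for f2 in grid:
                ll = poisson_log_likelihood(g, toy_model.forward(np.array([[f1, f2]])))
                best = max(best, ll)
        assert ours >= best - 1e-6

    def test_monotone_log_likelihood(self, toy_model):
        rng = np.random.default_rng(3)
        g = rng.poisson(toy_model.forward(np.array([[1.0, 4.0]])) * 20).astype(float)
        state = ReconState(np.ones((1, 2)))
        prev = -np.inf
        for _ in range(50):
            state = mlem_update(state, toy_model, g)
            ll = poisson_log_likelihood(g, toy_model.forward(state.estimate))
            assert ll >= prev - 1e-9
            prev = ll

    def test_count_preservation_at_fixed_point(self, toy_model):
        rng = np.random.default_rng(5)
        g = rng.poisson(toy_model.forward(np.array([[2.0, 1.0]])) * 30).astype(float)
        state = ReconState(np.ones((1, 2)))
        for _ in range(2000):
            state = mlem_update(state, toy_model, g)
        assert toy_model.forward(state.estimate).sum() == pytest.approx(g.sum(), rel=1e-6)

    def test_zero_pixels_stay_zero(self, toy_model):
        f = np.array([[0.0, 2.0]])
        out = mlem_update(ReconState(f), toy_model, np.full((3, 1), 4.0))
        assert out.estimate[0, 0] == 0.0


class TestOSEM:
    def test_one_subset_is_mlem(self, small_model):
        rng = np.random.default_rng(0)
        g = rng.poisson(5.0, size=small_model.sino_shape).astype(float)
        f0 = np.ones(small_model.image_shape)
        a = mlem_update(ReconState(f0.copy()), small_model, g).estimate
        b = osem_pass(ReconState(f0.copy()), small_model, g, n_subsets=1).estimate
        np.testing.assert_array_equal(a, b)

    def test_subsets_partition_views(self):
        subsets = osem_subsets(64, 8)
        allv = np.concatenate(subsets)
        assert len(allv) == 64
        assert set(allv.tolist()) == set(range(64))

    def test_invalid_subset_count(self):
        with pytest.raises(ValueError):
            osem_subsets(64, 7)

    def test_one_pass_beats_one_mlem_iteration_on_clean_data(self, small_model, small_bundle):
        truth = small_bundle.activity
        g = small_model.forward(truth)  # consistent noise-free data
        f0 = initial_estimate(ReconConfig(algorithm="mlem"), small_model, g)
        em = mlem_update(ReconState(f0.copy()), small_model, g).estimate
        os8 = osem_pass(ReconState(f0.copy()), small_model, g, n_subsets=8).estimate
        assert np.linalg.norm(os8 - truth) < np.linalg.norm(em - truth)


class TestMapGibbs:
    def test_beta_zero_is_mlem(self, toy_model):
        g = np.full((3, 1), 4.0)
        f = np.array([[1.0, 2.0]])
        a = mlem_update(ReconState(f.copy()), toy_model, g).estimate
        b = map_gibbs_update(
            ReconState(f.copy()), toy_model, g, 0.0, eight_neighborhood(), PotentialSpec()
        ).estimate
        np.testing.assert_array_equal(a, b)

    def test_uniform_image_gradient_free(self):
        # 2x2 image, uniform sensitivity: prior gradient vanishes on a flat image
        A = np.tile(np.eye(4), (1, 1))
        model = sm.MatrixModel(A, image_shape=(2, 2), sino_shape=(4, 1))
        g = np.full((4, 1), 3.0)
        f = np.full((2, 2), 2.0)
        a = mlem_update(ReconState(f.copy()), model, g).estimate
        b = map_gibbs_update(
            ReconState(f.copy()), model, g, 0.7, eight_neighborhood(), PotentialSpec("huber", 1.0)
        ).estimate
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_fixed_point_satisfies_stationarity(self):
        """OSL fixed point: A'(g/Af) = A'1 + beta * dU/df."""
        rng = np.random.default_rng(11)
        A = rng.random((6, 4)) + 0.1
        model = sm.MatrixModel(A, image_shape=(2, 2), sino_shape=(6, 1))
        g = rng.poisson(model.forward(np.array([[1.0, 2.0], [2.0, 1.0]])) * 50).astype(float)
        # delta on the scale of the solution's neighbor differences
        beta, nb, pot = 0.5, eight_neighborhood(), PotentialSpec("huber", 30.0)
        state = ReconState(np.ones((2, 2)))
        for _ in range(2000):
            state = map_gibbs_update(state, model, g, beta, nb, pot)
        f = state.estimate
        mean = model.forward(f)
        lhs = model.backward(np.where(mean > 0, g / mean, 0.0))
        rhs = model.sensitivity_image() + beta * sm.gibbs_energy(f, nb, pot).gradient
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)


class TestMapEnt:
    def test_initialization_is_inverse_e(self, toy_model):
        cfg = ReconConfig(algorithm="map-ent")
        f0 = initial_estimate(cfg, toy_model, np.ones((3, 1)))
        np.testing.assert_array_equal(f0, np.full((1, 2), 1.0 / np.e))

    def test_consistent_data_is_fixed_point(self, toy_model):
        f = np.array([[2.0, 3.0]])
        g = toy_model.forward(f)
        out = map_ent_update(ReconState(f.copy()), toy_model, g, gamma=0.3)
        np.testing.assert_allclose(out.estimate, f, rtol=1e-12)

    def test_scalar_converges_to_counts(self):
        model = scalar_model()
        g = np.array([[5.0]])
        state = ReconState(np.array([[1.0 / np.e]]))
        for _ in range(200):
            state = map_ent_update(state, model, g, gamma=0.1)
        assert abs(state.estimate[0, 0] - 5.0) < 1e-6

    def test_strict_positivity_preserved(self, toy_model):
        state = ReconState(np.full((1, 2), 1.0 / np.e))
        for _ in range(20):
            state = map_ent_update(state, toy_model, np.full((3, 1), 2.0), gamma=0.2)
            assert np.all(state.estimate > 0)

    def test_nonpositive_estimate_rejected(self, toy_model):
        with pytest.raises(ValueError):
            map_ent_update(ReconState(np.zeros((1, 2))), toy_model, np.ones((3, 1)), gamma=0.1)


class TestMapEntAdditive:
    def test_zero_exponent_gives_inverse_e(self, toy_model):
        f = np.array([[2.0, 3.0]])
        g = toy_model.forward(f)  # consistent -> exponent 0
        out = map_ent_update_additive(ReconState(f.copy()), toy_model, g, gamma=0.3)
        np.testing.assert_allclose(out.estimate, np.full((1, 2), 1.0 / np.e), rtol=1e-12)

    def test_first_iterate_matches_multiplicative_from_inverse_e(self, toy_model):
        g = np.array([[4.0], [2.0], [3.0]])
        f0 = np.full((1, 2), 1.0 / np.e)
        a = map_ent_update(ReconState(f0.copy()), toy_model, g, gamma=0.2).estimate
        b = map_ent_update_additive(ReconState(f0.copy()), toy_model, g, gamma=0.2).estimate
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-15)

    def test_scalar_fixed_point_matches_bisection_oracle(self):
        """The update's fixed point solves f = exp(-1 + gamma (g/f - 1))."""
        gamma, gval = 0.2, 5.0
        model = scalar_model()
        root = bisect(lambda f: f - np.exp(-1 + gamma * (gval / f - 1.0)), 0.01, 10.0, xtol=1e-14)
        out = map_ent_update_additive(
            ReconState(np.array([[root]])), model, np.array([[gval]]), gamma
        )
        assert out.estimate[0, 0] == pytest.approx(root, abs=1e-10)


class TestMapEntLocal:
    def test_uniform_gamma_is_global_update(self, toy_model):
        g = np.array([[4.0], [2.0], [3.0]])
        f0 = np.full((1, 2), 0.5)
        reg = RegularizationMap(np.zeros((1, 2), dtype=int), {0: 0.2})
        a = map_ent_update(ReconState(f0.copy()), toy_model, g, gamma=0.2).estimate
        b = map_ent_loc_update(ReconState(f0.copy()), toy_model, g, reg).estimate
        np.testing.assert_array_equal(a, b)

    def test_consistent_data_fixed_point_any_reg(self, toy_model):
        f = np.array([[2.0, 3.0]])
        g = toy_model.forward(f)
        reg = RegularizationMap(np.array([[0, 1]]), {0: 0.1, 1: 0.7})
        out = map_ent_loc_update(ReconState(f.copy()), toy_model, g, reg)
        np.testing.assert_allclose(out.estimate, f, rtol=1e-12)

    def test_log_changes_proportional_to_gamma(self):
        # symmetric 2-pixel system: identical exponent base, gammas 0.1 / 0.4
        model = sm.MatrixModel(np.eye(2), image_shape=(1, 2), sino_shape=(2, 1))
        g = np.array([[5.0], [5.0]])
        f0 = np.full((1, 2), 2.0)
        reg = RegularizationMap(np.array([[0, 1]]), {0: 0.1, 1: 0.4})
        out = map_ent_loc_update(ReconState(f0.copy()), model, g, reg)
        log_change = np.log(out.estimate / f0)
        assert log_change[0, 1] / log_change[0, 0] == pytest.approx(4.0, abs=1e-10)


class TestRegionMap:
    def _state(self, estimate, it):
        return ReconState(np.asarray(estimate, dtype=float), iteration=it)

    def test_inactive_before_switch(self):
        est = np.full((4, 4), 5.0)
        local = LocalRegSpec(np.ones((4, 4), bool), 0.1, 0.4, switch_iteration=5, healthy_level=1.0)
        reg = update_region_map(self._state(est, 2), local, gamma_global=0.2)
        assert not np.any(reg.region_labels == REGION_HOT)

    def test_uniform_at_healthy_level_never_hot(self):
        est = np.full((4, 4), 1.0)
        local = LocalRegSpec(np.ones((4, 4), bool), 0.1, 0.4, switch_iteration=0, healthy_level=1.0)
        reg = update_region_map(self._state(est, 50), local, gamma_global=0.2)
        assert not np.any(reg.region_labels == REGION_HOT)

    def test_plateau_above_threshold_labeled_hot(self):
        est = np.full((4, 4), 1.0)
        est[1, 1:4] = 1.5  # 3-pixel plateau at 1.5x healthy level
        local = LocalRegSpec(
            np.ones((4, 4), bool), 0.1, 0.4, switch_iteration=3, healthy_level=1.0, threshold_margin=0.1
        )
        reg = update_region_map(self._state(est, 3), local, gamma_global=0.2)
        expected_hot = est > 1.1
        np.testing.assert_array_equal(reg.region_labels == REGION_HOT, expected_hot)
        assert int(expected_hot.sum()) == 3

    def test_labels_frozen_when_not_refreshing(self):
        organ = np.ones((3, 3), bool)
        local = LocalRegSpec(organ, 0.1, 0.4, switch_iteration=1, healthy_level=1.0, refresh_labels=False)
        est1 = np.full((3, 3), 1.0)
        est1[0, 0] = 2.0
        state = self._state(est1, 1)
        reg1 = update_region_map(state, local, gamma_global=0.2)
        state.region_map = reg1
        state.estimate = np.full((3, 3), 2.0)  # everything now above threshold
        state.iteration = 2
        reg2 = update_region_map(state, local, gamma_global=0.2)
        np.testing.assert_array_equal(reg1.region_labels, reg2.region_labels)

    def test_outside_organ_keeps_global_label(self):
        organ = np.zeros((3, 3), bool)
        organ[1, 1] = True
        local = LocalRegSpec(organ, 0.1, 0.4, switch_iteration=0, healthy_level=1.0)
        reg = update_region_map(self._state(np.full((3, 3), 5.0), 1), local, gamma_global=0.2)
        assert reg.region_labels[0, 0] == 0
        assert reg.gamma_per_region[0] == 0.2

    def test_empty_organ_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LocalRegSpec(np.zeros((2, 2), bool), 0.1, 0.4)


class TestRunReconstruction:
    def test_zero_iterations_returns_initialization(self, toy_model):
        cfg = ReconConfig(algorithm="mlem", n_iterations=0)
        g = np.full((3, 1), 2.0)
        state = run_reconstruction(cfg, toy_model, g)
        np.testing.assert_array_equal(state.estimate, initial_estimate(cfg, toy_model, g))
        assert state.iteration == 0

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ReconConfig(algorithm="fbp")

    def test_checkpoint_bookkeeping(self, toy_model):
        cfg = ReconConfig(algorithm="mlem", n_iterations=20, checkpoints=(10, 15, 20), track_objective=False)
        state = run_reconstruction(cfg, toy_model, np.full((3, 1), 2.0))
        assert sorted(state.checkpoints) == [10, 15, 20]

    def test_mlem_objective_history_non_decreasing(self, toy_model):
        rng = np.random.default_rng(9)
        g = rng.poisson(toy_model.forward(np.array([[1.0, 3.0]])) * 10).astype(float)
        cfg = ReconConfig(algorithm="mlem", n_iterations=50)
        state = run_reconstruction(cfg, toy_model, g)
        ll = [h["loglik"] for h in state.objective_history]
        assert len(ll) == 51
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_map_ent_loc_records_region_map(self, toy_model):
        local = LocalRegSpec(np.array([[True, True]]), 0.1, 0.4, switch_iteration=1, healthy_level=1.0)
        cfg = ReconConfig(algorithm="map-ent-loc", n_iterations=3, gamma=0.2, local=local, track_objective=False)
        state = run_reconstruction(cfg, toy_model, np.full((3, 1), 2.0))
        assert state.region_map is not None
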