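import numpy as np
import pytest

from varimap.lddmm import (
    AtlasMeasure,
    FlowKernel,
    GeodesicState,
    MappingConfig,
    estimate_feature_laws,
    hamiltonian,
    kl_prior,
    match_single_modality,
    shoot,
    velocity_divergence,
    velocity_field,
)
from varimap.lddmm import _ham_grads
from varimap.varifold import FeatureSpace, SpaceKernel

from conftest import random_measure


def random_state(rng, n, w_scale=1.0, mom_scale=0.1):
    return GeodesicState(
        rng.random((n, 3)), w_scale * (rng.random(n) + 0.5),
        mom_scale * rng.standard_normal((n, 3)),
        mom_scale * rng.standard_normal(n),
    )


def eq14_velocity(state, fk, query):
    """Independent direct evaluation of the velocity formula."""
    out = np.zeros((len(query), 3))
    for m, q in enumerate(query):
        for i in range(len(state.x)):
            d = q - state.x[i]
            k = fk.weight * np.exp(-np.dot(d, d) / (2 * fk.sigma**2))
            out[m] += k * state.rho_x[i]
            out[m] += d / fk.sigma**2 * state.w[i] * state.rho_w[i] * k
    return out


class TestVelocity:
    def test_zero_momenta_zero_velocity(self, rng):
        st = GeodesicState(rng.random((4, 3)), np.ones(4),
                           np.zeros((4, 3)), np.zeros(4))
        fk = FlowKernel(0.5)
        q = rng.random((6, 3))
        assert np.allclose(velocity_field(st, fk, q), 0.0)
        assert np.allclose(velocity_divergence(st, fk, q), 0.0)

    def test_single_particle_at_center(self):
        st = GeodesicState([[0.2, 0.1, 0.0]], [1.0], [[1.0, -2.0, 0.5]], [0.0])
        fk = FlowKernel(0.3)
        v = velocity_field(st, fk, [[0.2, 0.1, 0.0]])
        np.testing.assert_allclose(v[0], [1.0, -2.0, 0.5])
        # odd gradient term vanishes at the particle for pure space momentum
        div = velocity_divergence(st, fk, [[0.2, 0.1, 0.0]])
        assert div[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_formula(self, rng):
        st = random_state(rng, 5)
        fk = FlowKernel(0.4, 1.2)
        q = rng.random((7, 3))
        np.testing.assert_allclose(velocity_field(st, fk, q),
                                   eq14_velocity(st, fk, q), atol=1e-8)

    def test_divergence_matches_finite_differences(self, rng):
        st = random_state(rng, 5)
        fk = FlowKernel(0.4)
        q = rng.random((4, 3))
        div = velocity_divergence(st, fk, q)
        eps = 1e-6
        fd = np.zeros(len(q))
        for k in range(3):
            dq = np.zeros(3)
            dq[k] = eps
            fd += (velocity_field(st, fk, q + dq)[:, k]
                   - velocity_field(st, fk, q - dq)[:, k]) / (2 * eps)
        np.testing.assert_allclose(div, fd, atol=1e-5)


class TestHamiltonian:
    def test_zero_momenta(self, rng):
        st = GeodesicState(rng.random((3, 3)), np.ones(3),
                           np.zeros((3, 3)), np.zeros(3))
        assert hamiltonian(st, FlowKernel(0.5)) == 0.0

    def test_one_landmark_closed_form(self):
        rho = np.array([0.4, -0.2, 0.7])
        st = GeodesicState([[0, 0, 0]], [1.0], [rho], [0.0])
        assert hamiltonian(st, FlowKernel(0.5)) == pytest.approx(
            0.5 * np.dot(rho, rho))

    def test_gradients_match_finite_differences(self, rng):
        st = random_state(rng, 5, w_scale=0.3)
        fk = FlowKernel(0.4, 1.1)
        h, dx, dw, drx, drw = _ham_grads(st.x, st.w, st.rho_x, st.rho_w, fk)
        eps = 1e-6

        def ham(x, w, rx, rw):
            return _ham_grads(x, w, rx, rw, fk)[0]

        for arr, grad in ((st.x, dx), (st.w, dw), (st.rho_x, drx),
                          (st.rho_w, drw)):
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                up, dn = arr.copy(), arr.copy()
                up[i] += eps
                dn[i] -= eps
                args_up = [st.x, st.w, st.rho_x, st.rho_w]
                args_dn = [st.x, st.w, st.rho_x, st.rho_w]
                for slot, a in enumerate(args_up):
                    if a is arr:
                        args_up[slot] = up
                        args_dn[slot] = dn
                fd[i] = (ham(*args_up) - ham(*args_dn)) / (2 * eps)
            np.testing.assert_allclose(grad, fd, atol=1e-7)

    def test_conserved_along_geodesic(self, rng):
        st = random_state(rng, 8, w_scale=0.2, mom_scale=0.15)
        fk = FlowKernel(0.4)
        traj, _ = shoot(st, fk, 20)
        h0 = hamiltonian(traj[0], fk)
        h1 = hamiltonian(traj[-1], fk)
        assert abs(h1 - h0) / abs(h0) < 1e-4


class TestShoot:
    def test_zero_momenta_is_identity(self, rng):
        x = rng.random((5, 3))
        w = rng.random(5) + 0.5
        st = GeodesicState(x, w, np.zeros((5, 3)), np.zeros(5))
        _, diffeo = shoot(st, FlowKernel(0.5), 5)
        np.testing.assert_allclose(diffeo.mapped_positions, x, atol=1e-14)
        np.testing.assert_allclose(diffeo.jacobian_dets, 1.0, atol=1e-14)

    def test_one_landmark_translation(self):
        st = GeodesicState([[0, 0, 0]], [1.0], [[1.0, 0, 0]], [0.0])
        _, diffeo = shoot(st, FlowKernel(0.5), 40)
        np.testing.assert_allclose(diffeo.mapped_positions[0], [1.0, 0, 0],
                                   atol=1e-3)
        assert diffeo.jacobian_dets[0] == pytest.approx(1.0, abs=1e-10)

    def test_drift_decreases_with_step_count(self, rng):
        st = random_state(rng, 6, w_scale=0.2, mom_scale=0.2)
        fk = FlowKernel(0.4)
        drifts = {}
        for n_steps in (10, 40):
            traj, _ = shoot(st, fk, n_steps)
            h0 = hamiltonian(traj[0], fk)
            drifts[n_steps] = abs(hamiltonian(traj[-1], fk) - h0) / abs(h0)
        assert drifts[10] < 1e-3
        assert drifts[40] < 1e-4
        assert drifts[40] < drifts[10]

    def test_midpoint_composition(self, rng):
        # half-momenta shoot covers [0, 1/2] of the full geodesic; re-shooting
        # from its endpoint state covers [1/2, 1]
        st = random_state(rng, 5, w_scale=0.2, mom_scale=0.15)
        fk = FlowKernel(0.4)
        full, _ = shoot(st, fk, 40)
        half = GeodesicState(st.x, st.w, st.rho_x / 2, st.rho_w / 2)
        first, _ = shoot(half, fk, 40)
        second, _ = shoot(first[-1].copy(), fk, 40)
        np.testing.assert_allclose(second[-1].x, full[-1].x, atol=1e-6)
        np.testing.assert_allclose(second[-1].w, full[-1].w, atol=1e-6)

    def test_blowup_names_the_step(self):
        st = GeodesicState([[0, 0, 0], [0.05, 0, 0]], [50.0, 50.0],
                           np.zeros((2, 3)), [80.0, 80.0])
        with pytest.raises(FloatingPointError, match="step"):
            shoot(st, FlowKernel(0.1), 10)


class TestKLPrior:
    def test_uniform_laws_zero(self):
        laws = np.full((3, 4), 0.7)
        assert kl_prior(laws, [1.0, 2.0, 3.0], [1.0, 1.0]) == 0.0

    def test_concentrated_law_log2(self):
        # one region, two features, all mass on the first
        val = kl_prior(np.array([[1.0, 0.0]]), [1.0], [1.0])
        assert val == pytest.approx(np.log(2.0))

    def test_linear_in_region_mass(self, rng):
        laws = rng.random((2, 3))
        m_t = [1.0, 1.0, 1.0]
        base = kl_prior(laws, [1.0, 1.0], m_t)
        doubled = kl_prior(laws, [2.0, 1.0], m_t)
        only_first = kl_prior(laws, [1.0, 0.0], m_t)
        assert doubled - base == pytest.approx(only_first)

    def test_nonnegative(self, rng):
        for _ in range(10):
            laws = rng.random((3, 5))
            assert kl_prior(laws, rng.random(3), rng.random(5) + 0.1) >= 0.0

    def test_zero_target_mass_rejected(self):
        with pytest.raises(ValueError):
            kl_prior(np.ones((1, 2)), [1.0], [0.0])


class TestMatching:
    def test_identity_target_keeps_near_zero_momenta(self, grid_measure):
        cfg = MappingConfig(flow_kernel=FlowKernel(0.5),
                            space_kernel=SpaceKernel(((0.2, 1.0),)),
                            max_iter=40)
        res = match_single_modality(grid_measure, grid_measure.copy(), cfg)
        initial_scale = res.trajectory[0] if res.trajectory else 1.0
        assert res.objective <= 1e-6 * max(initial_scale, 1.0)
        assert np.abs(res.rho_x0).max() < 1e-3

    def test_objective_trajectory_non_increasing(self, grid_measure, rng):
        target = grid_measure.copy()
        target.positions = target.positions + [0.08, 0.0, 0.0]
        cfg = MappingConfig(flow_kernel=FlowKernel(0.5),
                            space_kernel=SpaceKernel(((0.2, 1.0),)),
                            max_iter=30)
        res = match_single_modality(grid_measure, target, cfg)
        trace = np.array(res.trajectory)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_mismatched_spaces_error(self, rng):
        mu = random_measure(rng, 4, FeatureSpace(("a", "b")))
        nu = random_measure(rng, 4, FeatureSpace(("c", "d")))
        with pytest.raises(ValueError):
            match_single_modality(mu, nu, MappingConfig())


class TestLawEstimation:
    def test_loss_invariant_to_feature_relabeling(self, rng):
        from varimap.fixtures import make_four_region_phantom

        atlas, target = make_four_region_phantom(n_grid=6)
        ks = SpaceKernel(((0.15, 1.0),))
        laws, loss = estimate_feature_laws(
            atlas.positions, atlas.weights, atlas.region_probs, target, ks)
        perm = np.array([2, 0, 3, 1])
        tgt2 = target.copy()
        tgt2.feature_dists = target.feature_dists[:, perm]
        laws2, loss2 = estimate_feature_laws(
            atlas.positions, atlas.weights, atlas.region_probs, tgt2, ks)
        assert loss2 == pytest.approx(loss, rel=1e-8)
        np.testing.assert_allclose(laws2, laws[:, perm], atol=1e-8)

    def test_recovers_concentrated_laws_at_identity(self):
        from varimap.fixtures import make_four_region_phantom

        atlas, target = make_four_region_phantom(n_grid=6)
        ks = SpaceKernel(((0.15, 1.0),))
        laws, loss = estimate_feature_laws(
            atlas.positions, atlas.weights, atlas.region_probs, target, ks)
        pbar = laws / laws.sum(axis=1, keepdims=True)
        assert np.all(np.diag(pbar) > 0.99)
        assert loss < 1e-8 * (target.weights.sum()) ** 2


class TestAtlasMeasure:
    def test_region_probs_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AtlasMeasure([[0, 0, 0]], [1.0], [[0.4, 0.4]],
                         FeatureSpace(("l1", "l2")))

    def test_mixture_measure(self):
        atlas = AtlasMeasure([[0, 0, 0], [1, 0, 0]], [1.0, 2.0],
                             [[1.0, 0.0], [0.0, 1.0]],
                             FeatureSpace(("l1", "l2")),
                             FeatureSpace(("f1", "f2", "f3")))
        laws = np.array([[3.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        mix = atlas.with_laws(laws)
        np.testing.assert_allclose(mix.feature_dists,
                                   [[3, 0, 0], [0, 1, 1]])
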