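import numpy as np
import pytest

from varimap.fixtures import make_curvilinear_arc
from varimap.resampling import (
    ResamplingConfig,
    approximation_objective,
    grid_resample_baseline,
    init_lattice_approximation,
    kmeans_baseline,
    optimize_joint,
    optimize_weights_features,
    resample,
)
from varimap.varifold import FeatureSpace, ParticleMeasure

from conftest import random_measure


@pytest.fixture
def arc():
    return make_curvilinear_arc(seed=0, n_points=300)


class TestInit:
    def test_single_cube_collapses_to_one_particle(self, rng):
        space = FeatureSpace(("a", "b"))
        mu = random_measure(rng, 20, space, scale=0.05)
        cfg = ResamplingConfig(sigma=1.0, seed=0)
        out = init_lattice_approximation(mu, cfg)
        assert len(out.measure) == 1
        assert out.measure.total_mass == pytest.approx(mu.total_mass)

    def test_one_particle_per_cube_preserved(self):
        space = FeatureSpace(("a",))
        pos = np.array([[0.05, 0.05, 0.05], [0.95, 0.05, 0.05]])
        mu = ParticleMeasure(pos, [2.0, 3.0], np.ones((2, 1)), space)
        out = init_lattice_approximation(mu, ResamplingConfig(sigma=0.5))
        got = out.measure
        np.testing.assert_allclose(np.sort(got.weights), [2.0, 3.0])
        assert {tuple(p) for p in got.positions} == {tuple(p) for p in pos}

    def test_mass_bookkeeping_exact(self, rng):
        space = FeatureSpace(("a", "b", "c"))
        mu = random_measure(rng, 200, space, scale=2.0)
        out = init_lattice_approximation(mu, ResamplingConfig(sigma=0.4))
        assert out.measure.total_mass == pytest.approx(mu.total_mass, rel=1e-12)
        # uniform initial laws
        np.testing.assert_allclose(out.measure.feature_dists, 1.0 / 3)

    def test_empty_measure_rejected(self):
        space = FeatureSpace(("a",))
        mu = ParticleMeasure(np.empty((0, 3)), [], np.empty((0, 1)), space)
        with pytest.raises(ValueError, match="empty"):
            init_lattice_approximation(mu, ResamplingConfig(sigma=0.2))


class TestStages:
    def test_single_feature_concentrates(self, rng):
        space = FeatureSpace(("only",))
        mu = random_measure(rng, 60, space, scale=0.6)
        cfg = ResamplingConfig(sigma=0.2, seed=1)
        stage0 = init_lattice_approximation(mu, cfg)
        stage1 = optimize_weights_features(stage0, mu, cfg)
        assert stage1.final_objective < stage0.final_objective or \
            stage0.final_objective < 1e-12
        np.testing.assert_allclose(stage1.measure.feature_dists, 1.0)

    def test_already_optimal_stays_put(self):
        space = FeatureSpace(("a", "b"))
        pos = np.array([[0.1, 0.1, 0.0], [0.9, 0.9, 0.0]])
        mu = ParticleMeasure(pos, [1.0, 1.0], [[0.5, 0.5], [0.5, 0.5]], space)
        cfg = ResamplingConfig(sigma=0.5, seed=0)
        # the approximation with identical support and laws is exact
        stage0 = init_lattice_approximation(mu, cfg)
        stage1 = optimize_weights_features(stage0, mu, cfg)
        assert stage1.final_objective == pytest.approx(0.0, abs=1e-10)

    def test_striped_field_laws_track_local_majority(self, rng):
        space = FeatureSpace(("left", "right"))
        pos = rng.random((400, 3)) * [1.0, 0.5, 0.0]
        labels = (pos[:, 0] > 0.5).astype(int)
        mu = ParticleMeasure(pos, np.ones(400), np.eye(2)[labels], space)
        cfg = ResamplingConfig(sigma=0.12, seed=0)
        out = optimize_weights_features(
            init_lattice_approximation(mu, cfg), mu, cfg)
        est = out.measure.feature_dists[:, 1]
        # windowed empirical fraction of the "right" label near each particle
        truth = []
        for p in out.measure.positions:
            sel = np.linalg.norm(pos - p, axis=1) < cfg.sigma
            truth.append(labels[sel].mean())
        r = np.corrcoef(est, truth)[0, 1]
        assert r > 0.9

    def test_joint_stage_moves_particles_onto_arc(self, arc):
        cfg = ResamplingConfig(sigma=0.12, seed=0)
        stage1 = optimize_weights_features(
            init_lattice_approximation(arc, cfg), arc, cfg)
        stage2 = optimize_joint(stage1, arc, cfg)

        def mean_dist_to_arc(measure):
            r = np.linalg.norm(measure.positions[:, :2], axis=1)
            return np.abs(r - 1.0).mean()

        assert mean_dist_to_arc(stage2.measure) < mean_dist_to_arc(
            stage1.measure)
        assert stage2.final_objective <= stage1.final_objective + 1e-12

    def test_near_interpolation_regime_barely_moves(self, rng):
        space = FeatureSpace(("a",))
        pos = rng.random((15, 3)) * 4.0  # spacing >> sigma
        mu = ParticleMeasure(pos, np.ones(15), np.ones((15, 1)), space)
        cfg = ResamplingConfig(sigma=0.01, seed=0)
        out = resample(mu, cfg)
        assert out.displacements.mean() < 0.05 * cfg.sigma

    def test_deterministic_for_fixed_seed(self, arc):
        cfg = ResamplingConfig(sigma=0.15, seed=7)
        a = resample(arc, cfg)
        b = resample(arc, cfg)
        np.testing.assert_array_equal(a.measure.positions, b.measure.positions)
        np.testing.assert_array_equal(a.measure.weights, b.measure.weights)

    def test_objective_monotone_across_stages(self, arc):
        cfg = ResamplingConfig(sigma=0.15, seed=0)
        out = resample(arc, cfg)
        traj = out.objective_trajectory
        assert len(traj) == 3  # init, weights stage, joint stage
        assert traj[0] >= traj[1] >= traj[2]


class TestObjective:
    def test_zero_for_identical(self, rng):
        mu = random_measure(rng, 10, FeatureSpace(("a", "b")))
        cfg = ResamplingConfig(sigma=0.3)
        assert approximation_objective(mu, mu.copy(), cfg.kernel) == \
            pytest.approx(0.0, abs=1e-9)

    def test_single_particle_closed_form(self):
        space = FeatureSpace(("a",))
        mu = ParticleMeasure([[0, 0, 0]], [1.0], [[1.0]], space)
        nu = ParticleMeasure([[0.3, 0, 0]], [2.0], [[1.0]], space)
        ks = ResamplingConfig(sigma=0.5).kernel
        k = np.exp(-0.09 / (2 * 0.25))
        want = 1.0 - 2 * 2.0 * k + 4.0
        assert approximation_objective(mu, nu, ks) == pytest.approx(want)

    def test_truncated_matches_exact_on_compact_cloud(self, rng):
        mu = random_measure(rng, 30, FeatureSpace(("a", "b")), scale=0.2)
        nu = random_measure(rng, 25, FeatureSpace(("a", "b")), scale=0.2)
        ks = ResamplingConfig(sigma=0.25).kernel
        exact = approximation_objective(mu, nu, ks)
        trunc = approximation_objective(mu, nu, ks, cutoff=1.0)
        assert trunc == pytest.approx(exact, rel=1e-6)


class TestBaselines:
    def test_kmeans_k_equals_n_recovers_measure(self, rng):
        mu = random_measure(rng, 12, FeatureSpace(("a", "b")))
        out = kmeans_baseline(mu, 12, seed=0)
        order = np.argsort(out.positions[:, 0])
        ref = np.argsort(mu.positions[:, 0])
        np.testing.assert_allclose(out.positions[order], mu.positions[ref])
        np.testing.assert_allclose(out.weights[order], mu.weights[ref])

    def test_kmeans_single_cluster_is_position_mean(self, rng):
        mu = random_measure(rng, 20, FeatureSpace(("a",)))
        out = kmeans_baseline(mu, 1, seed=0)
        # Lloyd on positions only: the centroid is the unweighted mean
        np.testing.assert_allclose(out.positions[0], mu.positions.mean(axis=0),
                                   atol=1e-9)
        assert out.total_mass == pytest.approx(mu.total_mass)

    def test_kmeans_two_blobs(self, rng):
        space = FeatureSpace(("a",))
        blob1 = rng.normal(0.0, 0.05, (30, 3))
        blob2 = rng.normal(5.0, 0.05, (30, 3))
        mu = ParticleMeasure(np.vstack([blob1, blob2]), np.ones(60),
                             np.ones((60, 1)), space)
        out = kmeans_baseline(mu, 2, seed=0)
        centers = np.sort(out.positions[:, 0])
        assert abs(centers[0] - 0.0) < 0.1 and abs(centers[1] - 5.0) < 0.1

    def test_kmeans_budget_check(self, rng):
        mu = random_measure(rng, 5, FeatureSpace(("a",)))
        with pytest.raises(ValueError):
            kmeans_baseline(mu, 6)

    def test_grid_single_particle_keeps_node_mass(self):
        space = FeatureSpace(("a",))
        mu = ParticleMeasure([[0.1, 0.2, 0.3]], [2.5], [[1.0]], space)
        out = grid_resample_baseline(mu, sigma=0.2)
        assert len(out) == 1
        assert out.weights[0] == pytest.approx(2.5)

    def test_grid_conserves_mass(self, rng):
        mu = random_measure(rng, 150, FeatureSpace(("a", "b")), scale=1.5)
        out = grid_resample_baseline(mu, sigma=0.3)
        assert out.total_mass == pytest.approx(mu.total_mass, abs=1e-9)

    def test_grid_uniform_field_near_uniform_nodes(self, rng):
        space = FeatureSpace(("a",))
        g = (np.arange(20) + 0.5) / 20
        xx, yy = np.meshgrid(g, g)
        pos = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(400)])
        mu = ParticleMeasure(pos, np.ones(400), np.ones((400, 1)), space)
        out = grid_resample_baseline(mu, sigma=0.1)
        # interior nodes (away from the domain edge) receive even mass
        interior = np.all((out.positions[:, :2] > 0.25)
                          & (out.positions[:, :2] < 0.75), axis=1)
        w = out.weights[interior]
        assert w.std() / w.mean() < 0.05


class TestHierarchy:
    def test_scale_ordering(self, arc):
        coarse = resample(arc, ResamplingConfig(sigma=0.3, seed=0))
        fine = resample(arc, ResamplingConfig(sigma=0.1, seed=0))
        assert len(coarse.measure) < len(fine.measure)
        ks = ResamplingConfig(sigma=0.1).kernel
        d_fine = approximation_objective(fine.measure, arc, ks)
        d_coarse = approximation_objective(coarse.measure, arc, ks)
        assert d_fine <= d_coarse
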