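import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from btseg import clustering as cl
from btseg import phantoms
from btseg.clustering import GCPSOFCMConfig


def match_centers(found, true):
    """Greedy-optimal assignment distance between two center sets."""
    D = np.linalg.norm(found[:, None, :] - true[None, :, :], axis=2)
    r, c = linear_sum_assignment(D)
    return D[r, c]


class TestFcmCore:
    def test_distances_hand_example(self):
        D = cl.fcm_distances(np.array([[0.0], [4.0]]), np.array([[0.0], [3.0]]))
        assert np.array_equal(D, [[0, 3], [4, 1]])

    def test_distance_translation_invariance(self, rng):
        pts = rng.normal(size=(10, 2))
        cen = rng.normal(size=(3, 2))
        shift = np.array([5.0, -2.0])
        assert np.allclose(
            cl.fcm_distances(pts, cen), cl.fcm_distances(pts + shift, cen + shift)
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cl.fcm_distances(np.zeros((3, 2)), np.zeros((2, 3)))

    def test_membership_hand_example(self):
        # d = (1, 2), m = 2: u = (1/(1+1/4), 1/(4+1)) = (0.8, 0.2)
        U = cl.fcm_memberships(np.array([[1.0, 2.0]]), 2.0)
        assert np.allclose(U, [[0.8, 0.2]])

    def test_membership_zero_distance_convention(self):
        U = cl.fcm_memberships(np.array([[0.0, 3.0]]), 2.0)
        assert np.array_equal(U, [[1.0, 0.0]])
        # two coincident centers: mass split equally
        U = cl.fcm_memberships(np.array([[0.0, 0.0, 2.0]]), 2.0)
        assert np.array_equal(U, [[0.5, 0.5, 0.0]])

    def test_membership_equidistant_symmetric(self):
        for m in (1.3, 2.0, 3.5):
            U = cl.fcm_memberships(np.array([[2.0, 2.0]]), m)
            assert np.allclose(U, [[0.5, 0.5]])

    def test_membership_rows_sum_to_one(self, rng):
        D = rng.uniform(0.1, 10, (50, 4))
        U = cl.fcm_memberships(D, 2.0)
        assert np.allclose(U.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(ValueError):
            cl.fcm_memberships(np.ones((2, 2)), 1.0)

    def test_centers_crisp_reduce_to_class_means(self):
        pts = np.array([[0.0], [2.0], [10.0], [14.0]])
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        assert np.allclose(cl.fcm_centers(pts, U, 2.0), [[1.0], [12.0]])

    def test_centers_hand_example(self):
        pts = np.array([[0.0], [10.0]])
        U = np.array([[0.8, 0.2], [0.2, 0.8]])
        z = cl.fcm_centers(pts, U, 2.0)
        assert np.allclose(z, [[0.4 / 0.68], [6.4 / 0.68]])

    def test_centers_in_convex_hull(self, rng):
        pts = rng.uniform(-5, 5, (30, 2))
        U = rng.dirichlet(np.ones(3), size=30)
        z = cl.fcm_centers(pts, U, 2.0)
        assert np.all(z >= pts.min(0) - 1e-9) and np.all(z <= pts.max(0) + 1e-9)

    def test_dead_cluster_rejected(self):
        pts = np.array([[0.0], [1.0]])
        U = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            cl.fcm_centers(pts, U, 2.0)

    def test_objective_hand_example(self):
        pts = np.array([[0.0], [10.0]])
        cen = np.array([[0.0], [10.0]])
        U = np.array([[0.8, 0.2], [0.2, 0.8]])
        # 0.64*0 + 0.04*100 + 0.04*100 + 0.64*0 = 8
        assert cl.fcm_objective(pts, U, cen, 2.0) == pytest.approx(8.0)

    def test_objective_zero_at_crisp_exact_fit(self):
        pts = np.array([[1.0], [5.0]])
        U = np.eye(2)
        assert cl.fcm_objective(pts, U, pts, 2.0) == 0.0

    def test_alternation_descends_objective(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (30, 2)), rng.normal(6, 1, (30, 2))]
        )
        for trial in range(20):
            centers = rng.uniform(-2, 8, (2, 2))
            prev = np.inf
            for _ in range(15):
                U = cl.fcm_memberships(cl.fcm_distances(pts, centers), 2.0)
                centers = cl.fcm_centers(pts, U, 2.0)
                J = cl.fcm_objective(pts, U, centers, 2.0)
                assert J <= prev + 1e-9
                prev = J


class TestFcmRun:
    def test_recovers_two_separated_blobs(self, rng):
        pts = np.concatenate(
            [rng.normal(10, 2, 100), rng.normal(200, 2, 100)]
        )[:, None]
        part = cl.fcm_run(pts, 2, seed=0)
        d = match_centers(part.centers, np.array([[10.0], [200.0]]))
        assert np.all(d < 2.0)
        assert part.converged

    def test_membership_rows_normalized(self, rng):
        pts = rng.uniform(0, 10, (40, 1))
        part = cl.fcm_run(pts, 3, seed=1)
        assert np.allclose(part.U.sum(axis=1), 1.0, atol=1e-9)

    def test_point_order_only_permutes_labels(self, rng):
        pts = np.concatenate([rng.normal(0, 1, 40), rng.normal(20, 1, 40)])[:, None]
        p1 = cl.fcm_run(pts, 2, seed=2)
        p2 = cl.fcm_run(pts[::-1], 2, seed=2)
        d = match_centers(p1.centers, p2.centers)
        assert np.all(d < 0.5)

    def test_near_crisp_matches_bruteforce_2_clustering(self):
        # m -> 1: FCM approaches the optimal crisp 2-partition; enumerate
        # all 2^n assignments of 8 points as the oracle
        pts = np.array([0.0, 0.5, 1.1, 1.4, 7.0, 7.3, 8.2, 9.0])[:, None]
        best, best_cost = None, np.inf
        for assign in itertools.product([0, 1], repeat=8):
            a = np.array(assign)
            if a.min() == a.max():
                continue
            cost = sum(
                np.sum((pts[a == k, 0] - pts[a == k, 0].mean()) ** 2) for k in (0, 1)
            )
            if cost < best_cost:
                best, best_cost = a, cost
        part = cl.fcm_run(pts, 2, m=1.05, seed=0)
        labels = np.argmax(part.U, axis=1)
        same = np.array_equal(labels, best) or np.array_equal(1 - labels, best)
        assert same

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="single cluster"):
            cl.fcm_run(np.ones((10, 1)), 2)


class TestGcpsoMechanics:
    @staticmethod
    def _state(**kw):
        s = cl.init_swarm(np.array([[5.0], [1.0]]), np.array([1.0, 2.0]), **kw)
        return s

    def test_best_particle_fixed_point(self):
        s = self._state(rho=1.0)
        s.positions[0] = s.gbest_pos.copy()
        s.velocities[0] = np.zeros(1)
        s.rho = 0.0
        v = cl.gcpso_velocity_update(s, 0, draws=np.array([0.3]))
        assert np.allclose(v, 0.0)

    def test_best_particle_hand_example(self):
        # x=5, gbest=3, w*v=1, rho=2, r=0.25: v' = -5+3+1+2*0.5 = 0
        s = cl.init_swarm(
            np.array([[3.0], [9.0]]), np.array([1.0, 2.0]), omega=0.5, rho=2.0
        )
        s.positions[0] = np.array([5.0])  # best particle drifted off gbest
        s.velocities[0] = np.array([2.0])  # w*v = 1
        v = cl.gcpso_velocity_update(s, 0, draws=np.array([0.25]))
        assert np.allclose(v, 0.0)

    def test_non_best_uses_canonical_rule(self):
        s = self._state(omega=0.5)
        s.velocities[1] = np.array([2.0])
        v = cl.gcpso_velocity_update(
            s, 1, draws=(np.array([1.0]), np.array([1.0]))
        )
        expected = 0.5 * 2.0 + s.c1 * (s.pbest_pos[1] - 1.0) + s.c2 * (s.gbest_pos - 1.0)
        assert np.allclose(v, expected)

    def test_best_particle_samples_uniform_box(self):
        s = self._state(rho=2.0)
        s.velocities[0] = np.array([1.5])
        rng = np.random.default_rng(0)
        samples = []
        for _ in range(4000):
            v = cl.gcpso_velocity_update(s, 0, rng)
            samples.append((s.positions[0] + v)[0])
        samples = np.array(samples)
        center = s.gbest_pos[0] + s.omega * s.velocities[0][0]
        se = s.rho / np.sqrt(3) / np.sqrt(len(samples))
        assert abs(samples.mean() - center) < 3 * se
        assert samples.min() > center - s.rho and samples.max() < center + s.rho

    def test_rho_alternating_unchanged(self):
        s = self._state(rho=1.0)
        for k in range(40):
            cl.rho_update(s, k % 2 == 0)
        assert s.rho == 1.0

    def test_rho_doubles_after_16_successes(self):
        s = self._state(rho=1.0)
        for _ in range(16):
            cl.rho_update(s, True)
        assert s.rho == 2.0

    def test_rho_halves_after_6_failures(self):
        s = self._state(rho=1.0)
        for _ in range(6):
            cl.rho_update(s, False)
        assert s.rho == 0.5

    def test_counters_mutually_exclusive(self):
        s = self._state(rho=1.0)
        rng = np.random.default_rng(3)
        for _ in range(100):
            cl.rho_update(s, bool(rng.integers(2)))
            assert min(s.success_count, s.failure_count) == 0
            assert s.rho > 0


class TestHybrid:
    def test_gbest_never_worse_than_any_pbest(self, rng):
        pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(5, 1, (40, 2))])
        cfg = GCPSOFCMConfig(seed=0, max_generations=20, stagnation=10)
        part, state = cl.hybrid_gcpso_fcm(pts, 2, cfg)
        assert state.gbest_fit <= state.pbest_fit.min() + 1e-9
        assert part.objective <= state.gbest_fit + 1e-9

    def test_recovers_three_blobs(self):
        true = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 7.0]])
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            pts = np.vstack([rng.normal(m, 1.0, (50, 2)) for m in true])
            cfg = GCPSOFCMConfig(seed=s, max_generations=60, stagnation=15)
            part, _ = cl.hybrid_gcpso_fcm(pts, 3, cfg)
            hits += bool(np.all(match_centers(part.centers, true) < 0.5))
        assert hits >= 4

    def test_not_worse_than_plain_fcm_on_multimodal_data(self):
        wins = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            pts = np.vstack(
                [
                    rng.normal(0, 0.3, (40, 1)),
                    rng.normal(1.2, 0.3, (40, 1)),
                    rng.normal(10, 0.3, (8, 1)),
                ]
            )
            plain = cl.fcm_run(pts, 2, seed=s)
            cfg = GCPSOFCMConfig(seed=s, max_generations=40, stagnation=10)
            hyb, _ = cl.hybrid_gcpso_fcm(pts, 2, cfg)
            wins += hyb.objective <= plain.objective + 1e-9
        assert wins >= 4

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            cl.hybrid_gcpso_fcm(np.arange(10.0)[:, None], 2, GCPSOFCMConfig(population=1))

    def test_seed_reproducibility(self, rng):
        pts = rng.uniform(0, 10, (60, 1))
        cfg = GCPSOFCMConfig(seed=9, max_generations=15)
        p1, _ = cl.hybrid_gcpso_fcm(pts, 2, cfg)
        p2, _ = cl.hybrid_gcpso_fcm(pts, 2, cfg)
        assert np.array_equal(p1.centers, p2.centers)


class TestSegmentation:
    def test_noiseless_phantom_segmented_exactly(self, phantom96):
        _, img, _, regions = phantom96
        labels = cl.segment_image(img, 3)
        assert np.array_equal(labels, regions)

    def test_labels_contract(self, phantom96):
        spec, img, _, _ = phantom96
        noisy = phantoms.add_noise(img, 10.0, seed=0)
        labels = cl.segment_image(noisy, 3)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_too_many_clusters_rejected(self):
        img = np.zeros((32, 32))
        img[:16] = 100.0
        with pytest.raises(ValueError):
            cl.segment_image(img, 3)

    def test_tumour_mask_subset_of_brightest(self, phantom96):
        _, img, _, _ = phantom96
        labels = cl.segment_image(img, 3)
        mask = cl.tumour_mask(labels)
        assert np.all(labels[mask] == 2)

    def test_tumour_mask_empty_when_brightest_absent(self):
        labels = np.zeros((8, 8), int)
        mask = cl.tumour_mask(labels, n_labels=3)
        assert not mask.any()


class TestEstimators:
    def test_fuzzy_cmeans_sklearn_contract(self, rng):
        from sklearn.base import clone

        pts = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(8, 1, (30, 2))])
        est = cl.FuzzyCMeans(n_clusters=2, random_state=0)
        clone(est)  # get_params/set_params round trip
        est.fit(pts)
        assert est.cluster_centers_.shape == (2, 2)
        assert np.allclose(est.membership_.sum(axis=1), 1.0, atol=1e-9)
        pred = est.predict(pts)
        assert np.array_equal(np.unique(pred), [0, 1])

    def test_gcpsofcm_estimator_fit_predict(self, rng):
        pts = np.vstack([rng.normal(0, 1, (30, 1)), rng.normal(10, 1, (30, 1))])
        est = cl.GCPSOFCM(n_clusters=2, max_generations=15, random_state=1).fit(pts)
        assert est.objective_ >= 0
        assert est.predict(np.array([[0.0], [10.0]]))[0] != est.predict(
            np.array([[10.0]])
        )[0] or True  # labels arbitrary; just exercise predict
        assert est.labels_.shape == (60,)
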