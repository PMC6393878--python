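import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuroseg as ns
from neuroseg import clustering as cl
from neuroseg.errors import ArgumentError, DegenerateClusteringError


# ---------------------------------------------------------------------------
# Independent naive-loop oracles (no vectorization, no shared code paths)
# ---------------------------------------------------------------------------

def naive_memberships(pixels, centers, m):
    n, c = len(pixels), len(centers)
    u = [[0.0] * c for _ in range(n)]
    for i in range(n):
        d = [abs(pixels[i] - centers[j]) for j in range(c)]
        zeros = [j for j in range(c) if d[j] == 0.0]
        if zeros:
            for j in zeros:
                u[i][j] = 1.0 / len(zeros)
            continue
        for j in range(c):
            u[i][j] = 1.0 / sum((d[j] / d[k]) ** (2.0 / (m - 1.0))
                                for k in range(c))
    return np.array(u)


def naive_centers(pixels, u, m):
    n, c = u.shape
    out = []
    for j in range(c):
        num = sum(u[i][j] ** m * pixels[i] for i in range(n))
        den = sum(u[i][j] ** m for i in range(n))
        out.append(num / den)
    return np.array(out)


def naive_objective(pixels, centers, u, m):
    total = 0.0
    for i in range(len(pixels)):
        for j in range(len(centers)):
            total += u[i][j] ** m * (pixels[i] - centers[j]) ** 2
    return total


def naive_fcm(pixels, c, m, n_iter):
    """Naive-loop FCM from the same percentile initialization."""
    centers = cl.percentile_centers(np.asarray(pixels), c)
    u = naive_memberships(pixels, centers, m)
    for _ in range(n_iter):
        centers = naive_centers(pixels, u, m)
        u = naive_memberships(pixels, centers, m)
    return centers, u


# ---------------------------------------------------------------------------
# k-means (Euclidean distance assign + cluster-mean update)
# ---------------------------------------------------------------------------

class TestKmeansAssign:
    def test_nearest_center(self):
        assert cl.kmeans_assign([0.2], [0.1, 0.9])[0] == 0

    def test_tie_breaks_to_lower_index(self):
        assert cl.kmeans_assign([0.5], [0.4, 0.6])[0] == 0

    def test_matches_bruteforce_scan(self, rng):
        pixels = rng.random(100)
        centers = np.array([0.2, 0.5, 0.8])
        labels = cl.kmeans_assign(pixels, centers)
        for i, x in enumerate(pixels):
            dists = [abs(x - c) for c in centers]
            assert labels[i] == dists.index(min(dists))

    def test_empty_pixels_rejected(self):
        with pytest.raises(ArgumentError):
            cl.kmeans_assign([], [0.1, 0.9])


class TestKmeansUpdate:
    def test_mean_of_members(self):
        centers = cl.kmeans_update(np.array([0.2, 0.4]), np.array([0, 0]), 1)
        assert centers[0] == pytest.approx(0.3)

    def test_single_member(self):
        centers = cl.kmeans_update(np.array([0.7, 0.1]), np.array([0, 1]), 2)
        assert centers[1] == pytest.approx(0.1)

    def test_empty_cluster_keeps_previous(self):
        centers = cl.kmeans_update(np.array([0.7]), np.array([0]), 2,
                                   previous=np.array([0.7, 0.25]))
        assert centers[1] == 0.25


class TestKmeansCluster:
    def test_recovers_blob_means(self, rng):
        pixels = np.concatenate([rng.normal(0.2, 0.01, 200),
                                 rng.normal(0.8, 0.01, 200)])
        model = cl.kmeans_cluster(pixels, k=2)
        lo, hi = sorted(model.centers)
        assert lo == pytest.approx(0.2, abs=0.01)
        assert hi == pytest.approx(0.8, abs=0.01)

    def test_constant_image_no_crash(self):
        model = cl.kmeans_cluster(np.full(50, 0.3), k=2)
        assert np.bincount(model.labels, minlength=2).min() == 0  # one empty

    def test_sse_non_increasing(self, rng):
        pixels = rng.random(500)
        model = cl.kmeans_cluster(pixels, k=3)
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_crisp_memberships(self, rng):
        model = cl.kmeans_cluster(rng.random(100), k=3)
        assert set(np.unique(model.memberships)) <= {0.0, 1.0}
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# FCM membership / center / objective updates
# ---------------------------------------------------------------------------

class TestFcmMemberships:
    def test_hand_check_point_zero_centers_one_three(self):
        # d = (1, 3): u0 = 1/(1 + (1/3)^2) = 9/10
        u = cl.fcm_memberships(np.array([0.0]), np.array([1.0, 3.0]), m=2.0)
        np.testing.assert_allclose(u[0], [0.9, 0.1])

    def test_equidistant_pixel_splits_evenly(self):
        u = cl.fcm_memberships(np.array([0.5]), np.array([0.4, 0.6]), m=2.0)
        np.testing.assert_allclose(u[0], [0.5, 0.5])

    def test_zero_distance_is_crisp(self):
        u = cl.fcm_memberships(np.array([0.4]), np.array([0.4, 0.9]), m=2.0)
        np.testing.assert_array_equal(u[0], [1.0, 0.0])

    def test_multiple_zero_distances_split_equally(self):
        u = cl.fcm_memberships(np.array([0.4]), np.array([0.4, 0.4, 0.9]), m=2.0)
        np.testing.assert_array_equal(u[0], [0.5, 0.5, 0.0])

    def test_invalid_fuzziness(self):
        with pytest.raises(ArgumentError):
            cl.fcm_memberships(np.array([0.1]), np.array([0.2, 0.3]), m=1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_stochastic(self, seed):
        r = np.random.default_rng(seed)
        pixels = r.random(40)
        centers = np.sort(r.random(4))
        if np.unique(centers).size < 4:
            return
        u = cl.fcm_memberships(pixels, centers, m=2.0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((u >= 0) & (u <= 1))

    def test_matches_naive_oracle(self, rng):
        pixels = rng.random(60)
        centers = np.array([0.1, 0.55, 0.9])
        u = cl.fcm_memberships(pixels, centers, m=1.7)
        np.testing.assert_allclose(u, naive_memberships(pixels, centers, 1.7),
                                   atol=1e-12)


class TestFcmCenters:
    def test_hand_check(self):
        u = np.full((2, 2), 0.5)
        centers = cl.fcm_centers(np.array([0.0, 2.0]), u, m=2.0)
        # (0.25*0 + 0.25*2) / (0.25 + 0.25) = 1.0
        np.testing.assert_allclose(centers, [1.0, 1.0])

    def test_crisp_reduces_to_cluster_mean(self, rng):
        pixels = rng.random(30)
        labels = (pixels > 0.5).astype(int)
        u = np.zeros((30, 2))
        u[np.arange(30), labels] = 1.0
        centers = cl.fcm_centers(pixels, u, m=3.0)
        for j in range(2):
            np.testing.assert_allclose(centers[j], pixels[labels == j].mean())

    def test_matches_naive_oracle(self, rng):
        pixels = rng.random(50)
        u = rng.random((50, 3))
        u /= u.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(cl.fcm_centers(pixels, u, 2.0),
                                   naive_centers(pixels, u, 2.0), atol=1e-12)

    def test_zero_column_keeps_previous(self):
        u = np.array([[1.0, 0.0], [1.0, 0.0]])
        centers = cl.fcm_centers(np.array([0.2, 0.4]), u, 2.0,
                                 previous=np.array([0.3, 0.77]))
        np.testing.assert_allclose(centers, [0.3, 0.77])


class TestFcmObjective:
    def test_zero_at_crisp_centers(self):
        u = np.eye(2)
        assert cl.fcm_objective(np.array([0.1, 0.9]),
                                np.array([0.1, 0.9]), u, 2.0) == 0.0

    def test_hand_check(self):
        u = np.ones((2, 1))
        j = cl.fcm_objective(np.array([0.0, 2.0]), np.array([1.0]), u, 2.0)
        assert j == pytest.approx(2.0)

    def test_matches_naive_double_sum(self, rng):
        pixels = rng.random(40)
        centers = np.array([0.3, 0.6])
        u = rng.random((40, 2))
        u /= u.sum(axis=1, keepdims=True)
        assert cl.fcm_objective(pixels, centers, u, 2.0) == pytest.approx(
            naive_objective(pixels, centers, u, 2.0), abs=1e-12)


class TestFcmCluster:
    def test_recovers_phantom_tissue_intensities(self, noisy_phantom):
        img, gt = noisy_phantom
        brain = gt.csf_mask | gt.gm_mask | gt.wm_mask
        model = cl.fcm_cluster(img.pixels[brain], c=3, m=2.0)
        spec = ns.default_spec()
        expect = [spec.intensities[t] for t in ("csf", "gm", "wm")]
        np.testing.assert_allclose(np.sort(model.centers), expect, atol=0.05)

    def test_objective_monotone_and_rows_stochastic(self, rng):
        pixels = rng.random(300)
        model = cl.fcm_cluster(pixels, c=3)
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_converged_objective_stable(self, rng):
        pixels = rng.random(200)
        model = cl.fcm_cluster(pixels, c=2, tol=1e-5)
        # one more alternating step changes the objective by < 10*tol
        centers = cl.fcm_centers(pixels, model.memberships, 2.0,
                                 previous=model.centers)
        u = cl.fcm_memberships(pixels, centers, 2.0)
        j_next = cl.fcm_objective(pixels, centers, u, 2.0)
        assert abs(model.objective_history[-1] - j_next) < 10 * 1e-5

    def test_near_hard_limit_agrees_with_kmeans(self, rng):
        pixels = np.concatenate([rng.normal(0.2, 0.02, 300),
                                 rng.normal(0.8, 0.02, 300)])
        pixels = np.clip(pixels, 0, 1)
        fcm = cl.fcm_cluster(pixels, c=2, m=1.05)
        km = cl.kmeans_cluster(pixels, k=2)
        # align cluster order by center intensity
        f = np.argsort(fcm.centers)[fcm.labels]
        k = np.argsort(km.centers)[km.labels]
        assert (f == k).mean() >= 0.99

    def test_matches_naive_fcm_small_instances(self, rng):
        for n in (20, 100, 200):
            pixels = rng.random(n)
            model = cl.fcm_cluster(pixels, c=3, m=2.0, tol=0.0, max_iter=15)
            n_iter = len(model.objective_history) - 1
            centers, u = naive_fcm(pixels, 3, 2.0, n_iter)
            np.testing.assert_allclose(model.centers, centers, atol=1e-6)
            np.testing.assert_allclose(model.memberships, u, atol=1e-6)

    def test_centers_within_intensity_range(self, rng):
        model = cl.fcm_cluster(rng.random(100), c=3)
        assert model.centers.min() >= model.pixels.min() - 1e-12
        assert model.centers.max() <= model.pixels.max() + 1e-12

    def test_argument_errors(self):
        with pytest.raises(ArgumentError):
            cl.fcm_cluster(np.array([]), c=2)
        with pytest.raises(ArgumentError):
            cl.fcm_cluster(np.array([0.1, 0.2]), c=1)
        with pytest.raises(ArgumentError):
            cl.fcm_cluster(np.array([0.1, 0.2]), c=2, m=0.9)


class TestAssignTissueLabels:
    def _model(self, centers):
        centers = np.asarray(centers, dtype=float)
        n, c = 4, centers.size
        u = np.full((n, c), 1.0 / c)
        return cl.ClusterModel(np.linspace(0, 1, n), centers, u, 2.0, [1.0])

    def test_sorted_mapping(self):
        tissues = cl.assign_tissue_labels(self._model([0.44, 0.14, 0.81]))
        assert tissues == {1: "csf", 0: "gm", 2: "wm"}

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            cl.assign_tissue_labels(self._model([0.3, 0.3, 0.8]))

    def test_tumor_mode_marks_brightest(self):
        tissues = cl.assign_tissue_labels(self._model([0.2, 0.9, 0.5]),
                                          mode="tumor")
        assert tissues[1] == "tumor"

    def test_wrong_cluster_count_rejected(self):
        with pytest.raises(DegenerateClusteringError):
            cl.assign_tissue_labels(self._model([0.2, 0.8]))

    def test_permuted_centers_same_tissue_partition(self, rng):
        """Permuting the initial center order permutes cluster indices but
        leaves the per-pixel tissue assignment unchanged."""
        pixels = np.concatenate([rng.normal(0.15, 0.03, 150),
                                 rng.normal(0.45, 0.03, 150),
                                 rng.normal(0.8, 0.03, 150)])
        pixels = np.clip(pixels, 0, 1)

        def run(init):
            centers = np.array(init, dtype=float)
            u = cl.fcm_memberships(pixels, centers, 2.0)
            for _ in range(60):
                centers = cl.fcm_centers(pixels, u, 2.0, previous=centers)
                u = cl.fcm_memberships(pixels, centers, 2.0)
            model = cl.ClusterModel(pixels, centers, u, 2.0, [0.0])
            tissues = cl.assign_tissue_labels(model)
            lab = model.labels
            return {t: np.flatnonzero(np.isin(lab, [j]))
                    for j, t in tissues.items()}

        base = run([0.15, 0.45, 0.8])
        perm = run([0.8, 0.15, 0.45])
        for tissue in ("csf", "gm", "wm"):
            np.testing.assert_array_equal(base[tissue], perm[tissue])
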