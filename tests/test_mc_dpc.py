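"""Density-peak clustering on the projective sphere and bundle statistics."""

import numpy as np
import pytest

import fibert1 as f
from fibert1.mc_dpc import (
    angular_distance,
    assign_bundle,
    cluster_stats,
    compare_bundles,
    density_peak_cluster,
    geometric_median_orientation,
    significance_tier,
    OrientationCluster,
)

X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


def jittered_bundle(axis, n, spread_deg, rng):
    """n unit vectors scattered within spread_deg of +/- axis."""
    out = []
    while len(out) < n:
        v = axis + rng.normal(0, np.sin(np.deg2rad(spread_deg)), 3)
        v /= np.linalg.norm(v)
        if np.degrees(angular_distance(v, axis)) <= spread_deg:
            out.append(v * rng.choice([-1.0, 1.0]))
    return np.asarray(out)


class TestAngularDistance:
    def test_identity_and_antipode(self):
        assert angular_distance(X, X) == 0.0
        assert angular_distance(X, -X) == 0.0

    def test_orthogonal(self):
        assert angular_distance(X, Y) == pytest.approx(np.pi / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angular_distance(np.zeros(3), X)


class TestDensityPeakCluster:
    def test_two_orthogonal_bundles_pure(self):
        rng = np.random.default_rng(1)
        a = jittered_bundle(X, 20, 5, rng)
        b = jittered_bundle(Z, 20, 5, rng)
        orientations = np.vstack([a, b])
        labels, centers = density_peak_cluster(orientations, dc_deg=20)
        assert len(centers) == 2
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_single_tight_bundle(self):
        rng = np.random.default_rng(2)
        orientations = jittered_bundle(Y, 30, 8, rng)
        labels, centers = density_peak_cluster(orientations, dc_deg=20)
        assert len(centers) == 1
        assert np.all(labels == 0)

    def test_singleton(self):
        labels, centers = density_peak_cluster(X[None, :])
        assert list(labels) == [0] and list(centers) == [0]

    def test_antipodal_flip_invariance(self):
        rng = np.random.default_rng(3)
        orientations = np.vstack(
            [jittered_bundle(X, 15, 5, rng), jittered_bundle(Z, 15, 5, rng)]
        )
        labels, _ = density_peak_cluster(orientations, dc_deg=20)
        flip = rng.choice([-1.0, 1.0], size=len(orientations))
        labels_f, _ = density_peak_cluster(orientations * flip[:, None], dc_deg=20)
        assert np.array_equal(labels, labels_f)

    def test_brute_force_reference(self):
        """Assignments equal an independent plain-loop implementation of
        the same rule on small problems."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(5, 50))
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            w = rng.uniform(0.1, 1.0, n)
            labels, centers = density_peak_cluster(v, w, dc_deg=25)

            # reference: O(n^2) loops, same definitions
            dc = np.deg2rad(25)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    dist[i, j] = angular_distance(v[i], v[j])
            rho = np.array([
                sum(w[j] for j in range(n) if j != i and dist[i, j] < dc)
                for i in range(n)
            ])
            order = np.argsort(-rho, kind="stable")
            delta = np.zeros(n)
            parent = np.full(n, -1)
            delta[order[0]] = dist[order[0]].max()
            for r in range(1, n):
                i = order[r]
                denser = order[:r]
                j = min(denser, key=lambda d: dist[i, d])
                parent[i], delta[i] = j, dist[i, j]
            gamma = rho * delta
            gorder = np.argsort(-gamma, kind="stable")
            g = gamma[gorder]
            drops = g[:-1] - g[1:]
            k = int(np.argmax(drops)) + 1 if n > 1 and g[0] > 0 else 1
            ref_centers = list(gorder[:k])
            if order[0] not in ref_centers:
                ref_centers.append(order[0])
            ref_labels = np.full(n, -1)
            for ci, c in enumerate(ref_centers):
                ref_labels[c] = ci
            for r in range(n):
                i = order[r]
                if ref_labels[i] == -1:
                    ref_labels[i] = ref_labels[parent[i]]
            assert np.array_equal(labels, ref_labels)
            assert np.array_equal(centers, ref_centers)

    @pytest.mark.parametrize("dc_deg", [10, 20, 30, 40])
    def test_two_bundle_stability_band(self, dc_deg):
        rng = np.random.default_rng(6)
        orientations = np.vstack(
            [jittered_bundle(X, 25, 4, rng), jittered_bundle(Z, 25, 4, rng)]
        )
        _, centers = density_peak_cluster(orientations, dc_deg=dc_deg)
        assert len(centers) == 2


class TestGeometricMedian:
    def test_single_direction(self):
        m = geometric_median_orientation(np.vstack([Z, Z, -Z]))
        assert abs(m @ Z) == pytest.approx(1.0)

    def test_sign_alignment(self):
        rng = np.random.default_rng(7)
        v = jittered_bundle(X, 40, 6, rng)
        m = geometric_median_orientation(v)
        assert np.degrees(angular_distance(m, X)) < 3.0
        assert np.isclose(np.linalg.norm(m), 1.0)


class TestClusterStats:
    def test_two_fiber_r1_recovery(self, crossing_ensemble, crossing_voxel):
        """Cluster medians of E[R1] within 10% of truth, correctly
        paired with their orientations, on the noise-free crossing."""
        summary = cluster_stats(crossing_ensemble)
        assert len(summary) == 2
        truth = {  # orientation -> r1
            0: (crossing_voxel.components.orientations[0],
                crossing_voxel.components.r1[0]),
            1: (crossing_voxel.components.orientations[1],
                crossing_voxel.components.r1[1]),
        }
        for cl in summary.clusters:
            devs = [
                np.degrees(angular_distance(cl.median_orientation, u))
                for u, _ in truth.values()
            ]
            true_r1 = list(truth.values())[int(np.argmin(devs))][1]
            sub = summary.table[
                (summary.table.cluster == cl.index) & (summary.table.chi == "r1")
            ]
            assert float(sub["median"].iloc[0]) == pytest.approx(true_r1, rel=0.10)

    def test_cluster_weights_normalized(self, crossing_ensemble):
        summary = cluster_stats(crossing_ensemble)
        per_cluster = summary.table.drop_duplicates("cluster")
        assert per_cluster["w_norm"].sum() == pytest.approx(1.0)

    def test_t1_not_reciprocal_r1(self, crossing_ensemble):
        """E[T1] >= 1/E[R1] (Jensen); equality only without
        within-cluster R1 spread."""
        summary = cluster_stats(crossing_ensemble)
        for _, sub in summary.table.groupby("cluster"):
            t1 = float(sub.loc[sub.chi == "t1", "median"].iloc[0])
            r1 = float(sub.loc[sub.chi == "r1", "median"].iloc[0])
            assert t1 >= 1.0 / r1 - 1e-6


class TestAssignBundle:
    def make_cluster(self, direction):
        return OrientationCluster(0, np.asarray(direction, dtype=float))

    def test_axis_aligned(self):
        assert assign_bundle(self.make_cluster(X)) == "x"
        assert assign_bundle(self.make_cluster(-Y)) == "y"

    def test_near_z(self):
        direction = np.array([np.sin(np.deg2rad(30)), 0, np.cos(np.deg2rad(30))])
        assert assign_bundle(self.make_cluster(direction)) == "z"

    def test_named_bundles(self):
        names = {"x": "CC", "y": "CING", "z": "CST"}
        assert assign_bundle(self.make_cluster(X), names=names) == "CC"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        axes = {"x": X, "y": Y, "z": Z}
        for _ in range(100):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            got = assign_bundle(self.make_cluster(v))
            expect = min(axes, key=lambda k: angular_distance(v, axes[k]))
            assert got == expect


class TestCompareBundles:
    def test_identical_groups_no_star(self):
        report = compare_bundles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert report["p"] >= 0.99
        assert report["tier"] == ""

    def test_exact_enumeration_u0(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20 = 0.1
        (2 of the C(6,3)=20 rank arrangements are as extreme)."""
        report = compare_bundles([1, 2, 3], [4, 5, 6])
        assert report["u"] == 0.0
        assert report["p"] == pytest.approx(0.1, abs=1e-12)

    def test_tier_thresholds(self):
        assert significance_tier(0.005) == "***"
        assert significance_tier(0.03) == "**"
        assert significance_tier(0.07) == "*"
        assert significance_tier(0.10) == ""
        assert significance_tier(0.5) == ""

    def test_all_tied(self):
        report = compare_bundles([2.0, 2.0], [2.0, 2.0, 2.0])
        assert report["p"] == 1.0 and report["tier"] == ""

    def test_power_with_true_gap(self):
        """Bundles separated by a true R1 gap of 0.2 /s with modest
        bootstrap scatter are detected at the *** tier."""
        rng = np.random.default_rng(10)
        a = rng.normal(0.8, 0.02, 24)
        b = rng.normal(1.0, 0.02, 24)
        assert compare_bundles(a, b)["tier"] == "***"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_bundles([], [1.0])
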