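"""Alpha shapes, cluster measures, corona composition, radial profiles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay

from nanocorona import (
    ClusterLabeling,
    CoronaSceneConfig,
    GeometryError,
    ShellGeometry,
    alpha_shape,
    cluster_stats,
    corona_composition,
    radial_profile,
    shell_scene,
)

from oracles import brute_force_alpha_measure


def c_shape_points(n=200, seed=3):
    """A concave 'C' of points: 270 degrees of an annulus, radius 1000 nm."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 1.5 * np.pi, n)
    r = rng.uniform(600.0, 1000.0, n)
    return np.c_[r * np.cos(theta), r * np.sin(theta)]


class TestAlphaShape:
    def test_unit_square_convex_limit(self):
        """Square of side 1000 nm at alpha = inf has measure 1 um^2."""
        pts = np.array([[0, 0], [1000, 0], [0, 1000], [1000, 1000]], dtype=float)
        hull = alpha_shape(pts, np.inf)
        assert hull.measure == pytest.approx(1.0, rel=1e-12)

    def test_right_triangle_single_simplex(self):
        """Right triangle with 1000 nm legs: area 0.5 um^2."""
        pts = np.array([[0, 0], [1000, 0], [0, 1000]], dtype=float)
        hull = alpha_shape(pts, 1e9)
        assert hull.measure == pytest.approx(0.5, rel=1e-12)
        assert len(hull.simplices) == 1

    def test_concave_c_matches_brute_force_oracle(self):
        """Auto alpha on a 'C': strictly below convex measure, equal to the
        closed-form circumradius-filter oracle to 1e-9 relative."""
        pts = c_shape_points()
        hull = alpha_shape(pts, "auto")
        convex = ConvexHull(pts).volume / 1e6
        assert hull.measure < convex
        oracle = brute_force_alpha_measure(pts, Delaunay(pts).simplices, hull.alpha)
        assert hull.measure == pytest.approx(oracle / 1e6, rel=1e-9)

    def test_auto_alpha_uses_every_point_in_one_region(self):
        """At the critical alpha every point is a vertex of a kept simplex
        and the kept simplices form one facet-connected region; no smaller
        spectrum value achieves both."""
        pts = c_shape_points(n=80, seed=9)
        hull = alpha_shape(pts, "auto")
        assert set(hull.simplices.ravel()) == set(range(len(pts)))

        def regions(simplices):
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(len(simplices)))
            facets = {}
            for si, s in enumerate(simplices):
                for drop in range(len(s)):
                    f = tuple(sorted(v for j, v in enumerate(s) if j != drop))
                    if f in facets:
                        g.add_edge(si, facets[f])
                    facets[f] = si
            return nx.number_connected_components(g)

        assert regions(hull.simplices) == 1
        radii = np.unique(hull.circumradii)
        below = radii[radii < hull.alpha]
        if below.size:
            smaller = alpha_shape(pts, float(below[-1]))
            covers = set(smaller.simplices.ravel()) == set(range(len(pts)))
            assert not (covers and regions(smaller.simplices) == 1)

    @pytest.mark.parametrize("d", [2, 3])
    def test_convex_limit_and_monotonicity(self, rng, d):
        """Measure at alpha = inf equals the convex hull measure (1e-9
        relative) and grows monotonically along an increasing alpha ladder."""
        for _ in range(5):
            pts = rng.uniform(0, 1000, size=(int(rng.integers(20, 60)), d))
            hull_inf = alpha_shape(pts, np.inf)
            convex = ConvexHull(pts).volume / (1e6 if d == 2 else 1e9)
            assert hull_inf.measure == pytest.approx(convex, rel=1e-9)
            ladder = [alpha_shape(pts, a).measure for a in (100, 200, 400, 800, 1600)]
            assert all(a <= b + 1e-15 for a, b in zip(ladder, ladder[1:]))

    def test_scaling_equivariance(self, rng):
        """Scaling coordinates by s scales measures by s^d."""
        pts = rng.uniform(0, 1000, size=(50, 3))
        s = 2.5
        h1 = alpha_shape(pts, 300.0)
        h2 = alpha_shape(pts * s, 300.0 * s)
        assert h2.measure == pytest.approx(h1.measure * s**3, rel=1e-9)

    def test_collinear_points_raise_geometry_error(self):
        pts = np.c_[np.arange(10.0), np.arange(10.0)]
        with pytest.raises(GeometryError):
            alpha_shape(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(GeometryError, match="at least"):
            alpha_shape(np.zeros((2, 2)))


class TestClusterStats:
    def test_uniform_disk_density_recovery(self, rng):
        """1000 points uniform in a 500 nm disk: density within 10% of the
        analytic 1000 / (pi * 0.25) per um^2."""
        n = 1000
        r = 500.0 * np.sqrt(rng.random(n))
        theta = rng.uniform(0, 2 * np.pi, n)
        pts = np.c_[r * np.cos(theta), r * np.sin(theta)]
        labeling = ClusterLabeling(np.zeros(n, dtype=int))
        stats, summary = cluster_stats(pts, labeling, "auto")
        analytic = n / (np.pi * 0.25)
        assert stats["density"].iloc[0] == pytest.approx(analytic, rel=0.10)
        assert summary["median_density"] == stats["density"].iloc[0]

    def test_single_cluster_median_is_its_value(self, rng):
        pts = rng.uniform(0, 1000, size=(30, 2))
        stats, summary = cluster_stats(pts, ClusterLabeling(np.zeros(30, int)))
        assert summary["median_measure"] == stats["measure"].iloc[0]

    def test_median_of_three_measures(self):
        """Clusters with measures {1, 2, 9} um^2 have median measure 2."""
        sides = [np.sqrt(m) * 1000 for m in (1.0, 2.0, 9.0)]  # squares, um^2
        pts, labels = [], []
        rng = np.random.default_rng(0)
        for i, side in enumerate(sides):
            corners = np.array([[0, 0], [side, 0], [0, side], [side, side]])
            fill = rng.uniform(0, side, size=(30, 2))
            block = np.vstack([corners, fill]) + i * 50_000.0
            pts.append(block)
            labels.append(np.full(len(block), i))
        stats, summary = cluster_stats(
            np.vstack(pts), ClusterLabeling(np.concatenate(labels)), np.inf
        )
        assert summary["median_measure"] == pytest.approx(2.0, rel=1e-9)

    def test_tiny_clusters_flagged_and_excluded_from_medians(self, rng):
        pts = np.vstack([rng.uniform(0, 1000, size=(40, 2)), [[5000.0, 5000.0]] * 2])
        labels = np.r_[np.zeros(40, int), np.ones(2, int)]
        stats, summary = cluster_stats(pts, ClusterLabeling(labels))
        assert not stats.loc[1, "valid_geometry"]
        assert summary["n_valid"] == 1
        assert summary["median_measure"] == stats.loc[0, "measure"]


class TestCoronaComposition:
    def test_pure_channel_object_is_initial(self, rng):
        pts1 = rng.normal(0, 50, size=(100, 2))
        lab1 = ClusterLabeling(np.zeros(100, int))
        empty = np.empty((0, 2))
        lab2 = ClusterLabeling(np.empty(0, dtype=int))
        comp = corona_composition(pts1, lab1, empty, lab2, purity=0.9)
        assert list(comp["class"]) == ["initial"]

    def test_planted_composition_class_counts(self):
        """10 planted objects with fractions {1.0 x3, 0.0 x4, 0.5 x3} yield
        class counts (initial, exchanged, mixed) = (3, 4, 3)."""
        rng = np.random.default_rng(12)
        fractions = [1.0] * 3 + [0.0] * 4 + [0.5] * 3
        pts1, pts2, lab1, lab2 = [], [], [], []
        k1 = k2 = 0
        for i, f in enumerate(fractions):
            center = np.array([i * 5000.0, 0.0])
            n1, n2 = int(200 * f), 200 - int(200 * f)
            if n1:
                pts1.append(center + rng.normal(0, 60, size=(n1, 2)))
                lab1.append(np.full(n1, k1))
                k1 += 1
            if n2:
                pts2.append(center + rng.normal(0, 60, size=(n2, 2)))
                lab2.append(np.full(n2, k2))
                k2 += 1
        comp = corona_composition(
            np.vstack(pts1),
            ClusterLabeling(np.concatenate(lab1)),
            np.vstack(pts2),
            ClusterLabeling(np.concatenate(lab2)),
            purity=0.9,
        )
        counts = comp["class"].value_counts()
        assert counts["initial"] == 3
        assert counts["exchanged"] == 4
        assert counts["mixed"] == 3
        assert counts.sum() == len(comp) == 10

    def test_boundary_fraction_falls_to_pure_class(self):
        """f exactly equal to the purity threshold classifies as 'initial'."""
        rng = np.random.default_rng(5)
        pts1 = rng.normal(0, 10, size=(90, 2))
        pts2 = rng.normal(0, 10, size=(10, 2))
        comp = corona_composition(
            pts1,
            ClusterLabeling(np.zeros(90, int)),
            pts2,
            ClusterLabeling(np.zeros(10, int)),
            purity=0.9,
        )
        assert comp["fraction_ch1"].iloc[0] == pytest.approx(0.9)
        assert comp["class"].iloc[0] == "initial"

    def test_distant_clusters_stay_single_channel(self, rng):
        pts1 = rng.normal(0, 30, size=(50, 2))
        pts2 = rng.normal(10_000, 30, size=(50, 2))
        comp = corona_composition(
            pts1,
            ClusterLabeling(np.zeros(50, int)),
            pts2,
            ClusterLabeling(np.zeros(50, int)),
            match_radius=250.0,
        )
        assert sorted(comp["class"]) == ["exchanged", "initial"]


class TestRadialProfile:
    def test_core_diameter_closed_form_noise_free(self):
        """Shell scene, core 350 nm, no noise: 2 r90 within 3% of
        2 R (0.9)^(1/3) = 350 * 0.9655 ~ 337.9 nm at n = 1e4."""
        config = CoronaSceneConfig(
            field_size=(5000.0, 5000.0, 800.0),
            n_agglomerates=1,
            shell=ShellGeometry(350.0, 600.0),
            channel_fractions=1.0,
            fluorophores_per_cluster=10_000,
            mean_blinks=1.0,
            localization_precision=(0.0, 0.0),
            background_rate=0.0,
            seed=2,
        )
        table, _ = shell_scene(config)
        profile = radial_profile({"ch1": table.coords()})
        expected = 350.0 * 0.9 ** (1.0 / 3.0)
        assert profile.core_diameter == pytest.approx(expected, rel=0.03)

    def test_all_points_at_centroid_zero_core(self):
        profile = radial_profile({"ch1": np.zeros((20, 3))})
        assert profile.core_diameter == 0.0
        assert profile.valid

    def test_secondary_layer_empty_inside_core(self):
        """Channel-2 uniform-in-shell points leave the innermost bins empty."""
        config = CoronaSceneConfig(
            field_size=(5000.0, 5000.0, 800.0),
            n_agglomerates=1,
            shell=ShellGeometry(350.0, 600.0),
            channel_fractions=0.5,
            fluorophores_per_cluster=2000,
            mean_blinks=1.0,
            localization_precision=(0.0, 0.0),
            background_rate=0.0,
            seed=4,
        )
        table, _ = shell_scene(config)
        by_channel = {
            ch: table.select_channel(ch).coords() for ch in table.channels
        }
        profile = radial_profile(by_channel, n_bins=30)
        inner = profile.bin_edges[1:] <= 175.0
        assert profile.counts["ch2"][inner].sum() == 0
        assert profile.counts["ch1"][inner].sum() > 0

    def test_too_few_reference_points_flagged(self):
        profile = radial_profile({"ch1": np.zeros((5, 2))})
        assert not profile.valid and profile.core_diameter is None
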