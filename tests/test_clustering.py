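"""k-means segmentation: initialisation, Lloyd convergence, summaries, export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import stratavis as sv
from stratavis.cluster import init_centers, load_exported_clusters
from stratavis.simulate import ITEM_NAMES


def brute_force_min_ss(points: np.ndarray, k: int) -> float:
    """Global k-means optimum by enumerating every assignment of n points
    to at most k clusters (independent oracle, tiny n only)."""
    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        ss = 0.0
        for j in range(k):
            members = points[labels == j]
            if len(members):
                ss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, ss)
    return best


class TestInitCenters:
    def test_forgy_with_k_equal_n_is_a_permutation_of_the_points(self, rng):
        pts = rng.random((6, 3))
        centers = init_centers(pts, 6, "forgy", seed=0)
        assert {tuple(c) for c in centers} == {tuple(p) for p in pts}

    def test_forgy_seeded_selection_is_identical_across_runs(self, rng):
        pts = rng.random((30, 3))
        a = init_centers(pts, 4, "forgy", seed=11)
        b = init_centers(pts, 4, "forgy", seed=11)
        assert np.array_equal(a, b)

    def test_forgy_counts_distinct_points(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="distinct"):
            init_centers(pts, 3, "forgy")

    def test_random_draws_stay_inside_the_unit_cylinder(self, rng):
        pts = rng.random((5, 3))
        centers = init_centers(pts, 10_000, "random", seed=2, cylinder=(1.0, 1.0))
        r = np.hypot(centers[:, 0], centers[:, 1])
        assert np.all(r <= 1.0) and np.all((centers[:, 2] >= 0) & (centers[:, 2] <= 1))

    def test_random_without_cylinder_uses_bounding_box(self, rng):
        pts = rng.uniform(-2, 5, (20, 2))
        centers = init_centers(pts, 1000, "random", seed=3)
        assert np.all(centers >= pts.min(axis=0)) and np.all(centers <= pts.max(axis=0))

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            init_centers(rng.random((4, 2)), 0, "forgy")


class TestKMeans:
    def test_k1_center_is_the_global_mean(self, rng):
        pts = rng.random((40, 3))
        m = sv.kmeans(pts, 1, "forgy", seed=0)
        assert np.allclose(m.centers[0], pts.mean(axis=0), atol=1e-12)
        assert m.converged and m.n_iterations <= 2

    def test_two_point_masses_split_exactly(self):
        pts = np.array([[1.0, 0, 0]] * 5 + [[-1.0, 0, 0]] * 5)
        m = sv.kmeans(pts, 2, "forgy", seed=0)
        assert m.inertia == pytest.approx(0.0, abs=1e-18)
        assert {tuple(c) for c in m.centers} == {(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0)}

    def test_objective_non_increasing_every_iteration(self, rng):
        for seed in range(5):
            pts = rng.random((100, 3))
            m = sv.kmeans(pts, 4, "random", seed=seed, cylinder=(1.0, 1.0))
            hist = np.array(m.inertia_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_converges_on_the_synthetic_cohort(self, cohort500_layout):
        _, _, u, points = cohort500_layout
        pts = np.array([[p.x, p.y, p.z] for p in points])
        m = sv.kmeans(pts, 5, "forgy", seed=0)
        assert m.converged and m.n_iterations <= 300

    def test_forgy_fixed_seed_bit_identical_across_runs(self, rng):
        pts = rng.random((60, 3))
        runs = [sv.kmeans(pts, 3, "forgy", seed=9) for _ in range(3)]
        for m in runs[1:]:
            assert np.array_equal(m.centers, runs[0].centers)
            assert np.array_equal(m.assignments, runs[0].assignments)
            assert m.inertia == runs[0].inertia

    def test_converged_ss_never_beats_enumerated_optimum(self, rng):
        """Lloyd fixed points are bounded below by the global optimum from
        exhaustive partition enumeration on tiny random instances."""
        for trial in range(3):
            pts = rng.random((9, 2))
            for k in (2, 3):
                opt = brute_force_min_ss(pts, k)
                inertias = [sv.kmeans(pts, k, "forgy", seed=s).inertia for s in range(10)]
                assert min(inertias) >= opt - 1e-9

    def test_reaches_enumerated_optimum_on_separated_tiny_instances(self, rng):
        """On instances with real cluster structure, one of 10 restarts
        attains the enumerated global optimum exactly."""
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        for trial in range(3):
            pts = centers[np.arange(9) % 3] + 0.3 * rng.random((9, 2))
            for k in (2, 3):
                opt = brute_force_min_ss(pts, k)
                inertias = [sv.kmeans(pts, k, "forgy", seed=s).inertia for s in range(10)]
                assert min(inertias) == pytest.approx(opt, abs=1e-9)

    def test_empty_cluster_repair_keeps_k_clusters(self):
        # forgy can't produce an empty cluster start; random pivots can
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        for seed in range(20):
            m = sv.kmeans(pts, 2, "random", seed=seed)
            assert len(np.unique(m.assignments)) == 2

    def test_stage_recovery_on_separated_cohort(self, cohort500_layout):
        """k=5 in normalised feature space recovers the five stages
        (ARI >= 0.9, best of 5 seeds)."""
        table, _, u, _ = cohort500_layout
        truth = table.df.loc[u.row_ids, "diagnosis"]
        best = max(
            adjusted_rand_score(
                truth, sv.kmeans(u.u, 5, "forgy", seed=s, space="feature").assignments
            )
            for s in range(5)
        )
        assert best >= 0.9

    def test_invalid_k_rejected(self, rng):
        pts = rng.random((5, 2))
        for k in (0, 6):
            with pytest.raises(ValueError):
                sv.kmeans(pts, k)


class TestSummaries:
    def test_single_cluster_means_and_medians(self, toy_table):
        model = sv.ClusterModel(
            k=1, init="forgy", seed=0, centers=np.zeros((1, 2)),
            assignments=np.zeros(6, dtype=int), n_iterations=1, converged=True,
            inertia=0.0, row_ids=toy_table.row_ids,
        )
        s = sv.summarize_clusters(model, toy_table)
        assert s.sizes == {0: 6}
        assert s.numeric_stats.loc[(0, "item_01"), "mean"] == pytest.approx(11 / 6)
        assert s.numeric_stats.loc[(0, "item_02"), "median"] == pytest.approx(2.0)
        assert s.categorical_shares["diagnosis"].loc[0, "AD"] == pytest.approx(2 / 6)

    def test_cluster_of_1_2_3_has_mean_2_median_2(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=pd.Index(list("abc"), name="id"))
        t = sv.DataTable(df, [sv.VariableSpec("v", "numeric", 0.0, 3.0)])
        model = sv.ClusterModel(
            k=1, init="forgy", seed=0, centers=np.zeros((1, 1)),
            assignments=np.zeros(3, dtype=int), n_iterations=1, converged=True,
            inertia=0.0, row_ids=list("abc"),
        )
        s = sv.summarize_clusters(model, t)
        assert s.numeric_stats.loc[(0, "v"), "mean"] == 2.0
        assert s.numeric_stats.loc[(0, "v"), "median"] == 2.0

    def test_sizes_match_assignment_counts(self, cohort500_layout):
        table, _, u, points = cohort500_layout
        pts = np.array([[p.x, p.y, p.z] for p in points])
        m = sv.kmeans(pts, 5, "forgy", seed=1, row_ids=u.row_ids)
        s = sv.summarize_clusters(m, table)
        counts = np.bincount(m.assignments, minlength=5)
        assert [s.sizes.get(c, 0) for c in range(5)] == counts.tolist()
        assert sum(s.sizes.values()) == len(u.row_ids)


class TestExport:
    def test_export_preserves_rows_and_round_trips(self, tmp_path, cohort500_layout):
        table, _, u, points = cohort500_layout
        pts = np.array([[p.x, p.y, p.z] for p in points])
        m = sv.kmeans(pts, 5, "forgy", seed=1, row_ids=u.row_ids)
        path = sv.export_clusters(m, table, tmp_path / "clusters.csv", points=points)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + table.n_rows
        back, assignments = load_exported_clusters(path)
        assert np.array_equal(assignments, m.assignments)
        assert back.row_ids == m.row_ids

    def test_labels_with_commas_are_quoted_and_survive(self, tmp_path):
        df = pd.DataFrame(
            {"stage": ['AD, late', 'AD, "early"', "MCI"], "v": [1.0, 2.0, 3.0]},
            index=pd.Index(list("abc"), name="id"),
        )
        t = sv.DataTable(
            df,
            [
                sv.VariableSpec("stage", "categorical", categories=('AD, late', 'AD, "early"', "MCI")),
                sv.VariableSpec("v", "numeric", 0.0, 3.0),
            ],
        )
        model = sv.ClusterModel(
            k=1, init="forgy", seed=0, centers=np.zeros((1, 1)),
            assignments=np.zeros(3, dtype=int), n_iterations=1, converged=True,
            inertia=0.0, row_ids=list("abc"),
        )
        path = sv.export_clusters(model, t, tmp_path / "c.csv")
        back, _ = load_exported_clusters(path)
        assert back.df["stage"].tolist() == df["stage"].tolist()
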