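"""kNN construction, the Cuzick-Edwards test and the elevation comparisons."""

import numpy as np
import pandas as pd
import pytest

from matrilog.spatial import (
    cuzick_edwards,
    elevation_tests,
    knn_neighbors,
    run_clustering_suite,
    tk_statistic,
    two_sample_equal_variance_test,
)

from oracles import exact_permutation_p, knn_bruteforce


class TestKnn:
    def test_collinear_tie_broken_by_lower_index(self):
        pts = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)]
        nbrs = knn_neighbors(pts, k=1)
        assert nbrs[1, 0] == 0  # middle point: both endpoints equidistant

    def test_square_edge_neighbours(self):
        pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
        nbrs = knn_neighbors(pts, k=2, metric="planar")
        assert set(nbrs[0]) == {1, 2}
        assert set(nbrs[3]) == {1, 2}

    def test_matches_bruteforce_on_random_points(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(33, 39, 50), rng.uniform(-86, -79, 50)])
        nbrs = knn_neighbors(pts, k=3)
        assert nbrs.tolist() == knn_bruteforce([tuple(p) for p in pts], 3)

    def test_coincident_points_allowed(self):
        pts = [(35.0, -83.0), (35.0, -83.0), (36.0, -83.0)]
        nbrs = knn_neighbors(pts, k=1)
        assert nbrs[0, 0] == 1 and nbrs[1, 0] == 0

    def test_k_too_large_is_error(self):
        with pytest.raises(ValueError):
            knn_neighbors([(0.0, 0.0), (1.0, 1.0)], k=2)


class TestCuzickEdwards:
    def _points(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return np.column_stack([rng.uniform(33, 39, n), rng.uniform(-86, -79, n)])

    def test_monte_carlo_matches_exact_permutation_p(self):
        """On 6 points with 2 cases the exact null has C(6,2)=15 labelings."""
        pts = self._points(6, seed=2)
        labels = [True, True, False, False, False, False]
        exact = exact_permutation_p([tuple(p) for p in pts], labels, k=1)
        res = cuzick_edwards(pts, labels, k=1, n_reps=9999, seed=3)
        tol = 4 * np.sqrt(exact * (1 - exact) / 9999) + 2 / 10000
        assert abs(res.p_raw - exact) <= tol

    def test_monte_carlo_matches_exact_on_eight_points_k2(self):
        pts = self._points(8, seed=9)
        labels = [True, False, True, False, True, False, False, False]
        exact = exact_permutation_p([tuple(p) for p in pts], labels, k=2)
        res = cuzick_edwards(pts, labels, k=2, n_reps=9999, seed=4)
        tol = 4 * np.sqrt(exact * (1 - exact) / 9999) + 2 / 10000
        assert abs(res.p_raw - exact) <= tol

    def test_label_equivalent_configuration_gives_p_one(self):
        """With k=n-1 every permutation yields the same statistic."""
        pts = self._points(6, seed=1)
        labels = [True] * 5 + [False]
        res = cuzick_edwards(pts, labels, k=5, n_reps=999, seed=0)
        assert res.t_obs == 5 * 4
        assert res.p_raw == 1.0

    def test_t_obs_monotone_in_k(self):
        pts = self._points(20, seed=8)
        labels = np.zeros(20, dtype=bool)
        labels[:7] = True
        previous = -1
        for k in range(1, 6):
            res = cuzick_edwards(pts, labels, k=k, n_reps=99, seed=1)
            assert res.t_obs >= previous
            previous = res.t_obs

    def test_p_never_zero_and_in_unit_interval(self):
        pts = np.array([[0, 0], [0, 0.01], [0, 0.02], [5, 5], [5, 5.01], [5, 5.02]], dtype=float)
        labels = [True, True, True, False, False, False]  # maximal clustering
        res = cuzick_edwards(pts, labels, k=2, n_reps=999, seed=0)
        assert 0 < res.p_raw <= 1

    def test_all_case_labelling_rejected(self):
        pts = self._points(5)
        with pytest.raises(ValueError):
            cuzick_edwards(pts, [True] * 5, k=1)

    def test_case_control_swap_not_assumed_symmetric(self):
        """Unbalanced labelings and their complements give different exact p-values."""
        pts = [(0.0, 0.165), (0.0, 0.41), (0.0, 2.698), (0.0, 6.37), (0.0, 8.133), (0.0, 9.128)]
        labels = [True, True, False, False, False, False]
        flipped = [not v for v in labels]
        assert exact_permutation_p(pts, labels, 1) != exact_permutation_p(pts, flipped, 1)

    def test_fixed_seed_is_reproducible(self):
        pts = self._points(30, seed=6)
        labels = np.zeros(30, dtype=bool)
        labels[:9] = True
        a = cuzick_edwards(pts, labels, k=3, n_reps=999, seed=42)
        b = cuzick_edwards(pts, labels, k=3, n_reps=999, seed=42)
        assert (a.t_obs, a.p_raw, a.p_bonferroni) == (b.t_obs, b.p_raw, b.p_bonferroni)


class TestClusteringSuite:
    def _class_table(self, n_mf=10, n_omh=12, n_sh=20, seed=3, clustered=False):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, n in (("MF", n_mf), ("OMH", n_omh), ("SH", n_sh)):
            for i in range(n):
                if cls == "MF" and clustered:
                    lat, lon = 35.0 + rng.normal(0, 0.05), -83.0 + rng.normal(0, 0.05)
                else:
                    lat, lon = rng.uniform(33, 39), rng.uniform(-86, -79)
                rows.append(
                    {"log_id": f"{cls}{i}", "log_class": cls, "latitude": lat,
                     "longitude": lon, "elevation": rng.uniform(300, 1700)}
                )
        return pd.DataFrame(rows)

    def test_suite_shape_and_bonferroni(self):
        table = self._class_table()
        out = run_clustering_suite(table, n_reps=199, seed=1)
        assert len(out) == 15  # 3 schemes x 5 k values
        assert np.allclose(out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * 5))

    def test_planted_cluster_detected(self):
        table = self._class_table(clustered=True)
        out = run_clustering_suite(table, n_reps=999, seed=2, schemes=("combined",))
        assert (out["p_bonferroni"] < 0.05).any()

    def test_control_scheme_counts_echoed(self):
        table = self._class_table(n_mf=19, n_omh=22, n_sh=47)
        out = run_clustering_suite(table, k_values=(1,), n_reps=99, seed=0)
        counts = out.set_index("scheme")[["n_cases", "n_controls"]]
        assert counts.loc["omh"].tolist() == [19, 22]
        assert counts.loc["sh"].tolist() == [19, 47]
        assert counts.loc["combined"].tolist() == [19, 69]

    def test_too_few_cases_is_error(self):
        table = self._class_table(n_mf=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            run_clustering_suite(table, n_reps=99, seed=0)


class TestElevation:
    def test_identical_groups_give_t_zero(self):
        res = two_sample_equal_variance_test([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_closed_form_small_groups(self):
        res = two_sample_equal_variance_test([1, 2, 3], [4, 5, 6])
        assert round(res.t, 3) == -3.674
        assert res.df == 4

    def test_df_structure_for_19_vs_69(self):
        rng = np.random.default_rng(0)
        res = two_sample_equal_variance_test(rng.normal(size=19), rng.normal(size=69))
        assert res.df == 86

    def test_f_statistic_puts_larger_variance_on_top(self):
        res = two_sample_equal_variance_test([0.0, 10.0, 20.0], [1.0, 1.1, 1.2])
        assert res.f_stat >= 1.0
        assert res.f_df == (2, 2)

    def test_missing_elevations_excluded_with_warning(self):
        table = pd.DataFrame(
            {
                "log_id": list("abcdefgh"),
                "log_class": ["MF", "MF", "MF", "OMH", "OMH", "SH", "SH", "SH"],
                "latitude": [35.0] * 8,
                "longitude": [-83.0] * 8,
                "elevation": [900.0, 950.0, np.nan, 800.0, 850.0, 700.0, 750.0, 720.0],
            }
        )
        with pytest.warns(UserWarning, match="missing elevation"):
            out = elevation_tests(table)
        assert out.loc[out["scheme"] == "omh", "n_cases"].item() == 2
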