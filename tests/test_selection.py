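"""Edge/internal sample selection and kernel scale selection."""

import numpy as np
import pytest

from kdaloc import evaluation, kda, selection, synthetic
from kdaloc.dataset import LabeledDataset
from kdaloc.selection import (
    grid_search,
    neighborhood_radius,
    objective,
    select_edge_internal,
    select_scale,
)


class TestNeighborhoodRadius:
    def test_identical_points_zero_radius(self):
        X = np.zeros((6, 2))
        assert neighborhood_radius(X, np.arange(3), u=2) == 0.0

    def test_two_points_hand_value(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert neighborhood_radius(X, np.array([0, 1]), u=1) == pytest.approx(2.0)

    def test_matches_sort_based_brute_force(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((30, 3))
        members = np.arange(0, 30, 2)
        u = 5
        expected = np.mean(
            [sorted(np.linalg.norm(X - X[i], axis=1))[u] for i in members]
        )  # index u because the sorted list starts with the zero self-distance
        assert neighborhood_radius(X, members, u) == pytest.approx(expected)

    def test_u_out_of_range(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="out of range"):
            neighborhood_radius(X, np.arange(4), u=4)


class TestSelectEdgeInternal:
    def test_surrounded_gaussian_class_rule_by_rule(self):
        # class 0: tight cluster at the origin; class 1: ring at radius 4
        # with a few points pulled inward so the outer class-0 points have
        # impure neighborhoods
        rng = np.random.default_rng(5)
        inner = rng.standard_normal((40, 2))
        angles = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        ring = 4.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        ring[:5] *= 0.45  # intruders near the inner class's outskirts
        X = np.concatenate([inner, ring])
        y = np.repeat([0, 1], [40, 20])
        data = LabeledDataset(X, y)
        split = select_edge_internal(data, u=3)

        assert split.class_index == 0
        assert set(split.internal) & set(split.edge) == set()
        geo = split.geometry
        members = data.class_indices(0)
        from scipy.spatial.distance import cdist

        D = cdist(data.X[members], data.X)
        other = data.y != 0
        for pos, idx in enumerate(members):
            dist = geo.per_sample_dist[pos]
            impure = (D[pos, other] <= geo.radius).any()
            if idx in split.edge:
                assert dist > geo.median_dist and impure
            elif idx in split.internal:
                assert dist < geo.median_dist and not impure
            else:  # unassigned: fails at least one clause of each rule
                assert not (dist > geo.median_dist and impure)
                assert not (dist < geo.median_dist and not impure)

    def test_point_exactly_at_median_unassigned(self):
        # class 0 on a line, centroid at the origin, distances 4,1,0,1,4 so
        # the median distance 1 is attained exactly by two samples
        X = np.array(
            [[-4.0, 0], [-1.0, 0], [0.0, 0], [1.0, 0], [4.0, 0], [5.0, 0], [6.0, 0]]
        )
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        data = LabeledDataset(X, y)
        split = select_edge_internal(data, u=2)
        assert split.geometry.median_dist == 1.0
        for idx in (1, 3):  # exactly at the median: strict rules assign neither
            assert idx not in split.edge and idx not in split.internal
        assert 4 in split.edge  # far out with an other-class neighbor
        assert 2 in split.internal  # at the centroid with a pure neighborhood

    def test_spherical_shell_not_all_edge(self):
        data = synthetic.preset("shell", seed=0)
        split = select_edge_internal(data, u=8)
        n_class = data.class_sizes[split.class_index]
        assert 0 < split.edge.size < n_class
        assert split.internal.size > 0

    def test_disjoint_and_strict_on_random_datasets(self):
        hits = 0
        for seed in range(50):
            data = synthetic.make_rings(seed=seed)
            try:
                split = select_edge_internal(data, u=8)
            except ValueError:
                continue
            hits += 1
            assert set(split.internal).isdisjoint(split.edge)
            members = set(data.class_indices(split.class_index))
            assert set(split.internal) <= members and set(split.edge) <= members
        assert hits >= 40  # the rules are non-degenerate on most draws


class TestObjective:
    def test_hand_value(self):
        # (0.9 - 0.3) / std([0.1, 0.1, 0.3]) with n-1 denominator = 5.196
        f = objective(np.array([0.9]), np.array([0.1, 0.1, 0.3]))
        assert f == pytest.approx(5.196, abs=1e-3)

    def test_zero_spread_flagged_as_nan(self):
        assert np.isnan(objective(np.array([0.5, 0.5]), np.array([0.5, 0.5, 0.5])))

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        e, i = rng.uniform(0.5, 1, 4), rng.uniform(0, 0.5, 6)
        assert objective(3.7 * e, 3.7 * i) == pytest.approx(objective(e, i))

    def test_monotone_in_max_edge_error(self):
        i = np.array([0.1, 0.2, 0.15])
        f_low = objective(np.array([0.5]), i)
        f_high = objective(np.array([0.8]), i)
        assert f_high > f_low

    def test_small_internal_set_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            objective(np.array([0.9]), np.array([0.1]))


class TestSelectScale:
    def test_single_candidate_returned(self, rings):
        res = select_scale(rings, candidates=[1.5], d=1, u=8)
        assert res.best == 1.5

    def test_candidate_order_irrelevant(self, rings):
        fwd = select_scale(rings, d=1, u=8)
        rev = select_scale(rings, list(reversed(selection.DEFAULT_CANDIDATES)), d=1, u=8)
        assert fwd.best == rev.best

    def test_exactly_one_fit_per_candidate_and_no_classifier(self, rings, monkeypatch):
        fits = []
        real_fit = kda.fit_kda
        monkeypatch.setattr(kda, "fit_kda", lambda *a, **k: fits.append(1) or real_fit(*a, **k))
        knn_calls = []
        real_loo = evaluation.loo_knn_counts
        monkeypatch.setattr(
            evaluation, "loo_knn_counts", lambda *a, **k: knn_calls.append(1) or real_loo(*a, **k)
        )
        res = select_scale(rings, d=1, u=8)
        assert len(fits) == len(selection.DEFAULT_CANDIDATES)
        assert len(knn_calls) == 0
        assert res.diagnostics["n_kda_fits"] == len(selection.DEFAULT_CANDIDATES)
        assert res.diagnostics["n_classifier_passes"] == 0

    def test_agrees_with_grid_search_accuracy_on_rings(self):
        wins = 0
        for seed in range(5):
            data = synthetic.make_rings(seed=seed)
            proposed = select_scale(data, d=1, u=8)
            grid = grid_search(data, d=1, knn_k=5)
            counts = evaluation.jackknife(data, proposed.best, 1, knn_k=5, mode="fast")
            q = evaluation.metrics(counts).q
            wins += q == max(grid.objective_values)
        assert wins >= 4

    def test_downstream_accuracy_invariant_in_u(self):
        data = synthetic.preset("demo-rings", seed=0)
        accs = set()
        for u in (6, 7, 8, 9, 10):
            res = select_scale(data, d=1, u=u)
            counts = evaluation.jackknife(data, res.best, 1, knn_k=5, mode="fast")
            accs.add(evaluation.metrics(counts).q)
        assert len(accs) == 1


class TestGridSearch:
    def test_single_candidate_returned(self, rings):
        assert grid_search(rings, candidates=[2.5], d=1, knn_k=5).best == 2.5

    def test_separated_blobs_tie_to_smallest_scale(self):
        data = synthetic.make_blobs(n_classes=2, n_per_class=15, separation=20.0, noise_sd=0.5, seed=2)
        res = grid_search(data, d=1, knn_k=5)
        assert res.best == min(selection.DEFAULT_CANDIDATES)
        assert all(q == 1.0 for q in res.objective_values)

    def test_per_candidate_accuracy_decomposes(self, rings):
        res = grid_search(rings, d=1, knn_k=5)
        for s, q in zip(res.candidates, res.objective_values):
            model = kda.fit_kda(rings, s, 1)
            counts = evaluation.loo_knn_counts(model.project(rings.X), rings.y, 5)
            assert evaluation.metrics(counts).q == q
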