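import itertools

import numpy as np
import pytest
from sklearn.base import clone

from apconn import (
    DiscriminantEdgeSelector,
    difference_matrix,
    resampling_protocol,
    select_consistent,
    select_high_accuracy,
    top_connections,
)
from apconn.selection import ConnectionSet, ResamplingIteration


def _diff_from(mat):
    mat = np.asarray(mat, float)
    from apconn.selection import DifferenceMatrix

    return DifferenceMatrix(
        D_abs=np.abs(mat), D_signed=mat, n_controls=1, n_patients=1
    )


class TestDifferenceMatrix:
    def test_identical_groups_zero(self):
        K = np.random.default_rng(0).uniform(size=(3, 6, 6))
        K = (K + K.transpose(0, 2, 1)) / 2
        D = difference_matrix(K, K.copy())
        np.testing.assert_array_equal(D.D_abs, 0.0)

    def test_sign_is_patient_minus_control(self):
        Kc = np.full((1, 4, 4), 0.3)
        Kp = np.full((1, 4, 4), 0.8)
        D = difference_matrix(Kc, Kp)
        assert D.D_signed[0, 1] == pytest.approx(0.5)  # increased in patients
        assert D.D_abs[0, 1] == pytest.approx(0.5)

    def test_single_subject_groups_exact(self):
        rng = np.random.default_rng(1)
        Kc, Kp = rng.uniform(size=(4, 4)), rng.uniform(size=(4, 4))
        D = difference_matrix([Kc], [Kp])
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(D.D_signed[off], (Kp - Kc)[off])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            difference_matrix([], [np.eye(3)])


class TestTopConnections:
    def test_unique_maximum(self):
        m = np.zeros((4, 4))
        m[1, 3] = m[3, 1] = 0.9
        out = top_connections(_diff_from(m), h=1)
        assert out.edges == [(1, 3)]

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(-1, 1, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        D = _diff_from(m)
        got = top_connections(D, h=5).edges
        brute = sorted(
            itertools.combinations(range(8), 2),
            key=lambda e: (-abs(m[e]), e[0], e[1]),
        )[:5]
        assert got == brute

    def test_ties_break_lexicographically(self):
        m = np.zeros((4, 4))
        for i, j in [(0, 2), (1, 3), (0, 1)]:
            m[i, j] = m[j, i] = 0.5
        out = top_connections(_diff_from(m), h=2)
        assert out.edges == [(0, 1), (0, 2)]

    def test_oversized_h_returns_all_with_warning(self):
        D = _diff_from(np.zeros((4, 4)))
        with pytest.warns(UserWarning, match="candidate pool"):
            out = top_connections(D, h=100)
        assert len(out) == 6


class TestResamplingProtocol:
    @pytest.fixture(scope="class")
    def protocol_run(self, benchmark_dataset, benchmark_K):
        dataset, truth = benchmark_dataset
        iters = resampling_protocol(
            (benchmark_K, dataset.y), h=25, n_iter=20, seed=42
        )
        return iters, truth

    def test_seeded_determinism(self, benchmark_dataset, benchmark_K, protocol_run):
        dataset, _ = benchmark_dataset
        again = resampling_protocol(
            (benchmark_K, dataset.y), h=25, n_iter=20, seed=42
        )
        first, _ = protocol_run
        for a, b in zip(first, again):
            np.testing.assert_array_equal(a.train_idx, b.train_idx)
            assert a.connections.edges == b.connections.edges
            assert a.accuracy == b.accuracy

    def test_accuracies_are_rates(self, protocol_run):
        iters, _ = protocol_run
        assert len(iters) == 20
        assert all(0.0 <= it.accuracy <= 1.0 for it in iters)

    def test_planted_edges_selected_every_iteration(self, protocol_run):
        iters, truth = protocol_run
        planted = set(truth.planted_edges)
        for it in iters:
            got = set(it.connections.edges)
            assert len(planted & got) >= 0.9 * len(planted)

    def test_splits_are_stratified_halves(self, protocol_run, benchmark_dataset):
        iters, _ = protocol_run
        dataset, _ = benchmark_dataset
        y = dataset.y
        for it in iters:
            assert len(it.train_idx) == len(it.test_idx) == len(y) // 2
            assert np.sum(y[it.train_idx] == "patient") == 10
            assert np.sum(y[it.test_idx] == "control") == 10

    def test_subject_order_invariance(self, benchmark_dataset, benchmark_K):
        # shuffling the manifest order must not change the selected edges
        from apconn import GroupDataset

        dataset, _ = benchmark_dataset
        iters = resampling_protocol(dataset, h=10, n_iter=5, seed=9, K_stack=benchmark_K)
        perm = np.random.default_rng(3).permutation(len(dataset.subjects))
        shuffled = GroupDataset(
            subjects=[dataset.subjects[i] for i in perm],
            labels=[dataset.labels[i] for i in perm],
        )
        iters_p = resampling_protocol(
            shuffled, h=10, n_iter=5, seed=9, K_stack=benchmark_K[perm]
        )
        sel = select_consistent(iters, h=10).selected.edges
        sel_p = select_consistent(iters_p, h=10).selected.edges
        assert sel == sel_p
        for a, b in zip(iters, iters_p):
            assert a.accuracy == b.accuracy

    def test_too_small_group_rejected(self):
        K = np.random.default_rng(4).uniform(size=(3, 4, 4))
        with pytest.raises(ValueError):
            resampling_protocol((K, np.array(["control", "patient", "patient"])), h=2)


def _toy_iteration(edges, accuracy, scores=None):
    edges = [tuple(e) for e in edges]
    return ResamplingIteration(
        train_idx=np.arange(2),
        test_idx=np.arange(2, 4),
        connections=ConnectionSet(
            edges=edges,
            scores=np.ones(len(edges)) if scores is None else np.asarray(scores),
            h=len(edges),
        ),
        accuracy=accuracy,
    )


class TestHighAccuracySelection:
    def test_argmax_iteration_wins(self):
        iters = [
            _toy_iteration([(0, 1)], 0.6),
            _toy_iteration([(1, 2)], 0.9),
            _toy_iteration([(2, 3)], 0.7),
        ]
        assert select_high_accuracy(iters).selected.edges == [(1, 2)]

    def test_tie_goes_to_first_iteration(self):
        iters = [_toy_iteration([(0, 1)], 0.8), _toy_iteration([(1, 2)], 0.8)]
        assert select_high_accuracy(iters).selected.edges == [(0, 1)]

    def test_matches_recorded_accuracy_scan(self):
        rng = np.random.default_rng(5)
        iters = [
            _toy_iteration([(i, i + 1)], float(rng.uniform()))
            for i in range(10)
        ]
        best = max(range(10), key=lambda i: iters[i].accuracy)
        assert select_high_accuracy(iters).selected.edges == iters[best].connections.edges


class TestConsistentSelection:
    def test_frequency_dominates(self):
        iters = [_toy_iteration([(0, 1), (2, 3)], 0.5) for _ in range(5)]
        iters.append(_toy_iteration([(0, 1), (4, 5)], 0.5))
        sel = select_consistent(iters, h=2).selected
        assert sel.edges[0] == (0, 1)
        assert sel.edges[1] == (2, 3)

    def test_oversized_h_returns_pool(self):
        iters = [_toy_iteration([(0, 1)], 0.5)]
        with pytest.warns(UserWarning, match="pooled candidate"):
            sel = select_consistent(iters, h=10).selected
        assert sel.edges == [(0, 1)]

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(6)
        all_edges = list(itertools.combinations(range(6), 2))
        iters = []
        for _ in range(20):
            pick = rng.choice(len(all_edges), size=4, replace=False)
            iters.append(_toy_iteration([all_edges[p] for p in pick], 0.5))
        result = select_consistent(iters, h=5)
        counts: dict = {}
        for it in iters:
            for e in it.connections.edges:
                counts[e] = counts.get(e, 0) + 1
        top_freqs = sorted(counts.values(), reverse=True)[:5]
        got_freqs = [counts[e] for e in result.selected.edges]
        assert got_freqs == top_freqs

    def test_frequency_map_totals(self):
        rng = np.random.default_rng(7)
        all_edges = list(itertools.combinations(range(6), 2))
        iters = []
        for _ in range(12):
            pick = rng.choice(len(all_edges), size=3, replace=False)
            iters.append(_toy_iteration([all_edges[p] for p in pick], 0.5))
        result = select_consistent(iters, h=3)
        assert sum(result.frequency.values()) == 12 * 3


class TestDiscriminantEdgeSelector:
    def test_keeps_largest_mean_gaps(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(20, 10))
        y = np.array(["control"] * 10 + ["patient"] * 10)
        X[y == "patient", 3] += 0.9
        X[y == "patient", 7] -= 0.8
        sel = DiscriminantEdgeSelector(h=2).fit(X, y)
        assert set(np.flatnonzero(sel.get_support())) == {3, 7}

    def test_sklearn_protocol(self):
        sel = DiscriminantEdgeSelector(h=5)
        assert clone(sel).get_params()["h"] == 5
        X = np.random.default_rng(9).uniform(size=(8, 6))
        y = np.array(["a", "b"] * 4)
        Xt = sel.fit_transform(X, y)
        assert Xt.shape == (8, 5)
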