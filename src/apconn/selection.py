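"""Group difference statistic and discriminant-connection selection.

The difference statistic over one connection (i, j) is

    D(i, j) = | mean_controls K(i, j) - mean_patients K(i, j) |,

the absolute difference of the group-mean community matrices.  Its sign is
reported as patients minus controls, so a positive signed value means
increased co-clustering (connectivity) in patients.

Two selectors operate on a repeated-resampling protocol: in each of
``n_iter`` iterations the subjects are split 50/50 (stratified by group),
D is computed from the training half only, the top-h connections by D are
taken, a linear SVM is trained on those features and scored on the test
half.  The *high-accuracy* selector returns the edge set of the iteration
with the best test accuracy; the *consistent* selector pools every
iteration's top-h sets and returns the h most frequently selected edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split

from .community import CommunityMatrix, edge_list
from .io import GroupDataset

# h grids explored at full scale; clipped to the candidate-pool size on
# small problems.
H_GRID_HIGH_ACCURACY = tuple(range(350, 601, 50))
H_GRID_CONSISTENT = tuple(range(50, 1001, 50))

__all__ = [
    "DifferenceMatrix",
    "ConnectionSet",
    "SelectionResult",
    "ResamplingIteration",
    "difference_matrix",
    "top_connections",
    "resampling_protocol",
    "select_high_accuracy",
    "select_consistent",
    "DiscriminantEdgeSelector",
    "H_GRID_HIGH_ACCURACY",
    "H_GRID_CONSISTENT",
]


@dataclass
class DifferenceMatrix:
    """Signed and absolute group-mean community differences per edge."""

    D_abs: np.ndarray
    D_signed: np.ndarray
    n_controls: int
    n_patients: int

    @property
    def n_regions(self) -> int:
        return self.D_abs.shape[0]


@dataclass
class ConnectionSet:
    """An ordered set of (i, j) edges with their selection scores."""

    edges: list[tuple[int, int]]
    scores: np.ndarray
    h: int

    def __post_init__(self) -> None:
        self.edges = [(int(i), int(j)) for i, j in self.edges]
        self.scores = np.asarray(self.scores, float)
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in connection set")
        for i, j in self.edges:
            if i >= j:
                raise ValueError(f"edge ({i}, {j}) is not upper-triangle (i < j)")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ResamplingIteration:
    """One train/test split with its selected edges and test accuracy."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    connections: ConnectionSet
    accuracy: float
    report: "object | None" = None
    n_redraws: int = 0


@dataclass
class SelectionResult:
    """Final discriminant-connection choice with provenance."""

    method: str
    selected: ConnectionSet
    per_iteration_accuracy: list[float]
    frequency: dict[tuple[int, int], int] = field(default_factory=dict)
    seed: int | None = None
    n_iterations: int = 0


def _as_K_stack(mats) -> np.ndarray:
    if isinstance(mats, np.ndarray) and mats.ndim == 3:
        return mats
    return np.stack([m.K if isinstance(m, CommunityMatrix) else np.asarray(m) for m in mats])


def difference_matrix(controls, patients) -> DifferenceMatrix:
    """D_signed = mean(patients) - mean(controls); D_abs = |D_signed|."""
    Kc = _as_K_stack(controls)
    Kp = _as_K_stack(patients)
    if Kc.shape[0] == 0 or Kp.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if Kc.shape[1:] != Kp.shape[1:]:
        raise ValueError(f"group matrix shapes differ: {Kc.shape[1:]} vs {Kp.shape[1:]}")
    D_signed = Kp.mean(axis=0) - Kc.mean(axis=0)
    np.fill_diagonal(D_signed, 0.0)
    return DifferenceMatrix(
        D_abs=np.abs(D_signed),
        D_signed=D_signed,
        n_controls=Kc.shape[0],
        n_patients=Kp.shape[0],
    )


def top_connections(D: DifferenceMatrix, h: int) -> ConnectionSet:
    """The h upper-triangle edges with largest D_abs (ties: lexicographic)."""
    if h < 1:
        raise ValueError("h must be >= 1")
    edges = edge_list(D.n_regions)
    iu, ju = edges[:, 0], edges[:, 1]
    vals = D.D_abs[iu, ju]
    if h > len(vals):
        warnings.warn(
            f"h={h} exceeds the {len(vals)}-edge candidate pool; returning all",
            stacklevel=2,
        )
        h = len(vals)
    order = np.lexsort((ju, iu, -vals))[:h]
    return ConnectionSet(
        edges=[tuple(e) for e in edges[order]], scores=vals[order], h=h
    )


def _split_half_stratified(y: np.ndarray, rng_seed: int, max_redraws: int = 100):
    """Stratified 50/50 split; re-drawn if either half misses a class."""
    idx = np.arange(len(y))
    redraws = 0
    seed = int(rng_seed)
    while True:
        train, test = train_test_split(
            idx, train_size=0.5, stratify=y, random_state=seed % (2**32 - 1)
        )
        if len(set(y[train])) == 2 and len(set(y[test])) == 2:
            return np.sort(train), np.sort(test), redraws
        redraws += 1
        seed += 1
        if redraws > max_redraws:
            raise ValueError("could not draw a non-degenerate 50/50 split")


def resampling_protocol(
    data: "GroupDataset | tuple[np.ndarray, np.ndarray]",
    h: int,
    n_iter: int = 100,
    seed: int = 0,
    K_stack: np.ndarray | None = None,
    n_grid=None,
) -> list[ResamplingIteration]:
    """Run the repeated 50/50 selection-and-evaluation protocol.

    ``data`` is either a :class:`~apconn.io.GroupDataset` (community
    matrices are then computed with :func:`~apconn.community.subject_community`,
    or taken from ``K_stack`` if supplied) or a pre-computed
    ``(K_stack, labels)`` pair with ``K_stack`` of shape (n_subjects, N, N).

    Each iteration computes D from the training half only — the test half
    never influences which connections are selected.
    """
    from .classify import build_features, train_and_evaluate  # cycle-free at call time
    from .community import DEFAULT_N_GRID, subject_community

    if isinstance(data, GroupDataset):
        y = data.y
        if K_stack is None:
            grid = DEFAULT_N_GRID if n_grid is None else n_grid
            K_stack = np.stack(
                [subject_community(s, n_grid=grid).K for s in data.subjects]
            )
        # canonical subject order: results do not depend on manifest order
        order = np.argsort([s.subject_id for s in data.subjects], kind="stable")
    else:
        K_stack, y = data
        K_stack = _as_K_stack(K_stack)
        y = np.asarray(y)
        order = np.arange(len(y))
    K_stack = K_stack[order]
    y = y[order]
    if min(np.sum(y == "control"), np.sum(y == "patient")) < 2:
        raise ValueError("each group needs at least 2 subjects for a 50/50 split")

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_iter)
    iterations: list[ResamplingIteration] = []
    for it in range(n_iter):
        train, test, redraws = _split_half_stratified(y, sub_seeds[it])
        D = difference_matrix(
            K_stack[train][y[train] == "control"], K_stack[train][y[train] == "patient"]
        )
        conns = top_connections(D, h)
        ft_train = build_features(K_stack[train], conns, y=y[train])
        ft_test = build_features(K_stack[test], conns, y=y[test])
        report = train_and_evaluate(ft_train, ft_test)
        iterations.append(
            ResamplingIteration(
                train_idx=np.sort(order[train]),
                test_idx=np.sort(order[test]),
                connections=conns,
                accuracy=report.accuracy,
                report=report,
                n_redraws=redraws,
            )
        )
    return iterations


def select_high_accuracy(iterations: list[ResamplingIteration]) -> SelectionResult:
    """Edge set of the iteration with maximal test accuracy (ties: first)."""
    if not iterations:
        raise ValueError("no iterations recorded")
    accs = [it.accuracy for it in iterations]
    best = int(np.argmax(accs))
    return SelectionResult(
        method="high_accuracy",
        selected=iterations[best].connections,
        per_iteration_accuracy=accs,
        n_iterations=len(iterations),
    )


def select_consistent(iterations: list[ResamplingIteration], h: int) -> SelectionResult:
    """The h edges most frequently in the per-iteration top-h sets.

    Frequency ties are broken by higher mean D_abs across the iterations in
    which the edge was selected, then lexicographically by (i, j).
    """
    if not iterations:
        raise ValueError("no iterations recorded")
    freq: dict[tuple[int, int], int] = {}
    score_sum: dict[tuple[int, int], float] = {}
    for it in iterations:
        for e, sc in zip(it.connections.edges, it.connections.scores):
            freq[e] = freq.get(e, 0) + 1
            score_sum[e] = score_sum.get(e, 0.0) + float(sc)
    pool = sorted(
        freq, key=lambda e: (-freq[e], -(score_sum[e] / freq[e]), e[0], e[1])
    )
    if h > len(pool):
        warnings.warn(
            f"h={h} exceeds the {len(pool)}-edge pooled candidate set; returning all",
            stacklevel=2,
        )
    chosen = pool[:h]
    return SelectionResult(
        method="consistent",
        selected=ConnectionSet(
            edges=chosen,
            scores=np.array([freq[e] for e in chosen], float),
            h=h,
        ),
        per_iteration_accuracy=[it.accuracy for it in iterations],
        frequency=dict(freq),
        n_iterations=len(iterations),
    )


class DiscriminantEdgeSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector keeping the h columns with largest
    absolute between-group mean difference.

    Operates on any (n_samples, n_features) matrix whose columns are edge
    features (e.g. the output of
    :class:`~apconn.community.CommunityMatrixTransformer`) and a binary
    label vector.  Ties are broken toward the lower column index, mirroring
    the lexicographic edge rule.
    """

    def __init__(self, h: int = 10):
        self.h = h

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        diff = X[y == self.classes_[1]].mean(axis=0) - X[y == self.classes_[0]].mean(axis=0)
        self.scores_ = np.abs(diff)
        self.signed_scores_ = diff
        self.n_features_in_ = X.shape[1]
        h = min(self.h, self.n_features_in_)
        order = np.lexsort((np.arange(self.n_features_in_), -self.scores_))
        mask = np.zeros(self.n_features_in_, bool)
        mask[order[:h]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        return self.support_
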