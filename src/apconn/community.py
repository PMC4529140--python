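"""Multi-level clustering: per-level connectivity matrices and the community matrix.

For one subject, affinity propagation is run once per neighbourhood size n in
a grid (default 5, 10, ..., 30).  Each run yields a binary connectivity
matrix C_l with C_l(i, j) = 1 when regions i and j share a cluster.  The
community matrix K is the element-wise mean of the L level matrices, so
K(i, j) estimates the probability that i and j belong to the same functional
community: small n inflates preferences and yields many clusters, large n
yields few, and pairs that stay together across the whole sweep are the
consistently connected ones.

Downstream code enumerates connections over the strict upper triangle
(i < j, lexicographic), giving N(N-1)/2 distinct edges — 4005 for the
90-region cortical parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .ap import APConfig, ClusterAssignment, ap_cluster
from .io import RegionTimeSeries
from .similarity import cosine_dissimilarity, preference_vector

DEFAULT_N_GRID = (5, 10, 15, 20, 25, 30)

__all__ = [
    "DEFAULT_N_GRID",
    "ConnectivityMatrix",
    "CommunityMatrix",
    "connectivity_matrix",
    "community_matrix",
    "subject_community",
    "edge_list",
    "n_edges",
    "clip_n_grid",
    "CommunityMatrixTransformer",
]


@dataclass
class ConnectivityMatrix:
    """Binary co-clustering matrix from one AP level."""

    C: np.ndarray
    level_n: int


@dataclass
class CommunityMatrix:
    """Mean co-clustering fraction across L levels for one subject."""

    K: np.ndarray
    L: int
    subject_id: str = ""
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.K.shape[0]


def connectivity_matrix(assignment: ClusterAssignment, level_n: int = 0) -> ConnectivityMatrix:
    """C(i, j) = 1 iff i and j share a cluster; diagonal 1."""
    m = assignment.membership
    C = (m[:, None] == m[None, :]).astype(float)
    return ConnectivityMatrix(C=C, level_n=level_n)


def community_matrix(mats: list[ConnectivityMatrix], subject_id: str = "") -> CommunityMatrix:
    """Element-wise mean of the level-wise connectivity matrices."""
    if not mats:
        raise ValueError("need at least one connectivity matrix")
    shapes = {m.C.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"connectivity matrices disagree in shape: {shapes}")
    K = np.mean([m.C for m in mats], axis=0)
    return CommunityMatrix(K=K, L=len(mats), subject_id=subject_id)


def clip_n_grid(n_grid, n_regions: int) -> tuple[int, ...]:
    """Restrict a neighbourhood-size grid to the valid range [1, N-1].

    Values above N-1 are clamped and duplicates dropped (order kept), so
    small fixtures remain runnable with a correspondingly smaller L.
    """
    out: list[int] = []
    for n in n_grid:
        n = int(min(max(n, 1), n_regions - 1))
        if n not in out:
            out.append(n)
    if not out:
        raise ValueError("empty neighbourhood grid")
    return tuple(out)


def subject_community(
    x: RegionTimeSeries,
    n_grid=DEFAULT_N_GRID,
    cfg: APConfig | None = None,
) -> CommunityMatrix:
    """Full per-subject sweep: similarity -> preferences -> AP -> mean K."""
    cfg = cfg or APConfig()
    sim = cosine_dissimilarity(x)
    grid = clip_n_grid(n_grid, x.n_regions)
    mats, diag = [], []
    for n in grid:
        pref = preference_vector(sim, n)
        assign = ap_cluster(sim, pref, cfg)
        mats.append(connectivity_matrix(assign, level_n=n))
        diag.append(
            {
                "n": n,
                "n_clusters": assign.n_clusters,
                "converged": bool(assign.converged),
                "n_iter": assign.n_iter,
            }
        )
    K = community_matrix(mats, subject_id=x.subject_id)
    K.diagnostics = diag
    return K


def edge_list(n_regions: int) -> np.ndarray:
    """Strict upper-triangle (i < j) edge pairs in lexicographic order."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return np.column_stack([iu, ju])


def n_edges(n_regions: int) -> int:
    """Number of distinct region pairs, N(N-1)/2."""
    return n_regions * (n_regions - 1) // 2


class CommunityMatrixTransformer(TransformerMixin, BaseEstimator):
    """Map subjects' region time series to community-matrix edge features.

    Input ``X`` is an array of shape (n_subjects, n_regions, n_timepoints)
    or a list of :class:`RegionTimeSeries`.  Output is
    (n_subjects, N(N-1)/2): each subject's community matrix vectorised over
    the strict upper triangle in lexicographic order.  The transform is
    stateless and deterministic; ``fit`` only records dimensions.

    Parameters
    ----------
    n_grid : sequence of int
        Neighbourhood sizes, one AP level each (clipped to [1, N-1]).
    damping, max_iter, conv_window
        Message-passing controls, see :class:`~apconn.ap.APConfig`.
    """

    def __init__(self, n_grid=DEFAULT_N_GRID, damping=0.5, max_iter=1000, conv_window=50):
        self.n_grid = n_grid
        self.damping = damping
        self.max_iter = max_iter
        self.conv_window = conv_window

    def _as_series(self, X) -> list[RegionTimeSeries]:
        if len(X) == 0:
            raise ValueError("no subjects given")
        out = []
        for i, x in enumerate(X):
            if isinstance(x, RegionTimeSeries):
                out.append(x)
            else:
                arr = np.asarray(x, float)
                out.append(
                    RegionTimeSeries(
                        subject_id=f"s{i}",
                        region_labels=[f"r{k}" for k in range(arr.shape[0])],
                        data=arr,
                    )
                )
        return out

    def fit(self, X, y=None):
        subjects = self._as_series(X)
        self.n_regions_ = subjects[0].n_regions
        self.edge_list_ = edge_list(self.n_regions_)
        self.n_levels_ = len(clip_n_grid(self.n_grid, self.n_regions_))
        return self

    def transform(self, X) -> np.ndarray:
        subjects = self._as_series(X)
        if not hasattr(self, "n_regions_"):
            self.fit(X)
        cfg = APConfig(
            damping=self.damping, max_iter=self.max_iter, conv_window=self.conv_window
        )
        iu, ju = self.edge_list_[:, 0], self.edge_list_[:, 1]
        feats = np.empty((len(subjects), len(iu)))
        self.communities_ = []
        for s, x in enumerate(subjects):
            K = subject_community(x, n_grid=self.n_grid, cfg=cfg)
            self.communities_.append(K)
            feats[s] = K.K[iu, ju]
        return feats
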