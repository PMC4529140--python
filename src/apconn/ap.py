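"""Affinity-propagation clustering by responsibility/availability message passing.

Each data point is a candidate exemplar.  Two messages circulate until a
stable exemplar set emerges:

* responsibility r(i, j) — how strongly i favours j as its exemplar:
      r(i, j) = s(i, j) - max_{j' != j} { a(i, j') + s(i, j') }
* availability a(i, j) — how appropriate it is for i to pick j:
      a(i, j) = min{ 0, r(j, j) + sum_{i' not in {i, j}} max(0, r(i', j)) }
  with the self-availability a(j, j) = sum_{i' != j} max(0, r(i', j)).

Preferences p(i) sit on the diagonal of the working similarity matrix and
steer how many exemplars emerge.  Messages are damped,
``m_new = lambda * m_old + (1 - lambda) * m_computed``, to avoid
oscillation.  Everything here is deterministic: no noise is injected, and
every tie is broken toward the lowest region index.  Exactly symmetric
degenerate inputs may therefore oscillate; they are bounded by ``max_iter``
and resolved by the tie rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import PreferenceVector, SimilarityMatrix

__all__ = [
    "APConfig",
    "ClusterAssignment",
    "update_responsibility",
    "update_availability",
    "ap_cluster",
]


@dataclass(frozen=True)
class APConfig:
    """Damping and stopping control for the message-passing loop.

    damping : in [0.5, 1); weight on the previous message.
    max_iter : hard iteration cap.
    conv_window : iterations the exemplar set must stay unchanged to declare
        convergence.
    """

    damping: float = 0.5
    max_iter: int = 1000
    conv_window: int = 50

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ValueError(f"damping must lie in [0.5, 1), got {self.damping}")
        if self.conv_window < 1:
            raise ValueError("conv_window must be >= 1")
        if self.max_iter < self.conv_window:
            raise ValueError("max_iter must be >= conv_window")


@dataclass
class ClusterAssignment:
    """Exemplars and per-region memberships from one AP run."""

    exemplars: np.ndarray
    membership: np.ndarray
    n_clusters: int
    converged: bool
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        self.membership = np.asarray(self.membership, dtype=int)
        if self.n_clusters < 1:
            raise ValueError("at least one cluster required")
        if not set(self.membership) <= set(self.exemplars):
            raise ValueError("membership refers to a non-exemplar index")
        if not np.all(self.membership[self.exemplars] == self.exemplars):
            raise ValueError("an exemplar is not its own member")


def _check_finite(*mats: np.ndarray) -> None:
    for m in mats:
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite message/similarity matrix")


def update_responsibility(
    s: np.ndarray,
    a: np.ndarray,
    r_old: np.ndarray | None = None,
    damping: float = 0.0,
) -> np.ndarray:
    """One responsibility sweep; damped against ``r_old`` when given."""
    s = np.asarray(s, float)
    a = np.asarray(a, float)
    _check_finite(s, a)
    n = s.shape[0]
    comp = a + s
    idx = np.argmax(comp, axis=1)
    first = comp[np.arange(n), idx]
    comp_masked = comp.copy()
    comp_masked[np.arange(n), idx] = -np.inf
    second = np.max(comp_masked, axis=1)
    r = s - first[:, None]
    r[np.arange(n), idx] = s[np.arange(n), idx] - second
    if r_old is not None:
        r = damping * np.asarray(r_old, float) + (1.0 - damping) * r
    return r


def update_availability(
    r: np.ndarray,
    a_old: np.ndarray | None = None,
    damping: float = 0.0,
) -> np.ndarray:
    """One availability sweep; damped against ``a_old`` when given."""
    r = np.asarray(r, float)
    _check_finite(r)
    rp = np.maximum(r, 0.0)
    np.fill_diagonal(rp, r.diagonal())  # r(j,j) enters unclipped
    colsum = rp.sum(axis=0)
    a = np.minimum(0.0, colsum[None, :] - rp)
    np.fill_diagonal(a, colsum - r.diagonal())
    if a_old is not None:
        a = damping * np.asarray(a_old, float) + (1.0 - damping) * a
    return a


def ap_cluster(
    sim: SimilarityMatrix,
    pref: PreferenceVector,
    cfg: APConfig | None = None,
) -> ClusterAssignment:
    """Run affinity propagation on ``sim.s_ap`` with ``pref.p`` on the diagonal.

    Stops when the exemplar set {k : r(k,k) + a(k,k) > 0} has been unchanged
    for ``cfg.conv_window`` consecutive iterations, or at ``cfg.max_iter``.
    Non-exemplars join the exemplar with maximal s_ap (ties: lowest index);
    exemplars always belong to themselves.
    """
    cfg = cfg or APConfig()
    s = np.asarray(sim.s_ap, float).copy()
    N = s.shape[0]
    if pref.p.shape[0] != N:
        raise ValueError("preference vector length does not match similarity size")
    np.fill_diagonal(s, pref.p)
    _check_finite(s)

    r = np.zeros_like(s)
    a = np.zeros_like(s)
    lam = cfg.damping
    last: frozenset[int] = frozenset()
    stable = 0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        r = update_responsibility(s, a, r_old=r, damping=lam)
        a = update_availability(r, a_old=a, damping=lam)
        ex = frozenset(np.flatnonzero(np.diag(r) + np.diag(a) > 0).tolist())
        if ex and ex == last:
            stable += 1
            if stable >= cfg.conv_window:
                converged = True
                break
        else:
            stable = 1 if ex else 0
        last = ex

    exemplars = np.flatnonzero(np.diag(r) + np.diag(a) > 0)
    if exemplars.size == 0:
        # degenerate run: promote the best candidate, flag non-convergence
        exemplars = np.array([int(np.argmax(np.diag(r) + np.diag(a)))])
        converged = False

    sub = sim.s_ap[:, exemplars]  # raw similarity, preferences excluded
    membership = exemplars[np.argmax(sub, axis=1)]
    membership[exemplars] = exemplars
    return ClusterAssignment(
        exemplars=exemplars,
        membership=membership,
        n_clusters=int(exemplars.size),
        converged=converged,
        n_iter=it,
    )
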