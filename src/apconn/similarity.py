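"""Pairwise signal similarity and neighbourhood preferences.

The dissimilarity between two region signals is one minus their cosine,

    S(i, j) = 1 - <x_i, x_j> / sqrt(<x_i, x_i> <x_j, x_j>),

which lies in [0, 2]: 0 for identical direction, 1 for orthogonal, 2 for
anti-parallel.  Because band-passed BOLD signals are effectively zero-mean,
S coincides with one minus the Pearson correlation on real inputs.

Affinity propagation wants larger-is-more-similar inputs, so clustering runs
on ``s_ap = -S``; the raw S is retained for reporting.  The preference p(i)
seeded on the diagonal is the mean s_ap over the n most-similar neighbours
of i (self excluded) — regions sitting inside a tight community get high
preferences and are likely exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionTimeSeries

__all__ = ["SimilarityMatrix", "PreferenceVector", "cosine_dissimilarity", "preference_vector"]


@dataclass
class SimilarityMatrix:
    """Cosine dissimilarity S (range [0, 2]) and its AP-oriented negative."""

    S: np.ndarray
    s_ap: np.ndarray
    region_labels: list[str]

    @property
    def n_regions(self) -> int:
        return self.S.shape[0]


@dataclass
class PreferenceVector:
    """Per-region exemplar preferences from the n closest neighbours."""

    p: np.ndarray
    n: int


def cosine_dissimilarity(x: RegionTimeSeries | np.ndarray, region_labels=None) -> SimilarityMatrix:
    """Cosine dissimilarity between all pairs of region signals."""
    if isinstance(x, RegionTimeSeries):
        data, labels = x.data, x.region_labels
    else:
        data = np.asarray(x, dtype=float)
        labels = list(region_labels) if region_labels is not None else [
            f"r{i}" for i in range(data.shape[0])
        ]
    norms = np.linalg.norm(data, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm signal at region {labels[int(np.argmin(norms))]!r}")
    unit = data / norms[:, None]
    S = 1.0 - unit @ unit.T
    S = np.clip((S + S.T) / 2.0, 0.0, 2.0)  # exact symmetry, numeric range
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(S=S, s_ap=-S, region_labels=list(labels))


def preference_vector(sim: SimilarityMatrix, n: int) -> PreferenceVector:
    """Mean similarity of each region to its n most-similar neighbours.

    The diagonal (self-similarity) is excluded from the candidate pool;
    "most similar" is evaluated on the s_ap scale.
    """
    N = sim.n_regions
    if not 1 <= n <= N - 1:
        raise ValueError(f"n must be in [1, {N - 1}], got {n}")
    s = sim.s_ap.copy()
    np.fill_diagonal(s, -np.inf)
    # n largest per row = last n columns after partition
    top = np.partition(s, N - 1 - n, axis=1)[:, N - n:]
    return PreferenceVector(p=top.mean(axis=1), n=n)
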