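"""Synthetic two-group region time-series datasets with planted structure.

Subjects are drawn as T independent samples of a zero-mean multivariate
normal whose correlation matrix carries (a) a block structure — regions in
the same block correlate at ``rho_within``, others at ``rho_between`` — and
(b) a set of planted edges whose correlation differs between the control
and patient groups.  Independent Gaussian noise of standard deviation
``noise_sd`` is added on top.  Because the whole pipeline depends only on
second-order signal structure, Gaussian signals suffice; realistic BOLD
spectra, hemodynamics and motion artifacts are deliberately not modelled.

The implied matrices are projected to the nearest valid correlation matrix
before sampling; the projection must not move any planted correlation by
more than 0.1 or the requested settings are rejected as infeasible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

from .io import GroupDataset, RegionTimeSeries, write_subject_matrix

__all__ = [
    "PlantedEdge",
    "SimulationSpec",
    "GroundTruth",
    "simulate_dataset",
    "write_fixture",
    "planted_benchmark_spec",
]


@dataclass(frozen=True)
class PlantedEdge:
    """One region pair whose correlation is group-dependent."""

    i: int
    j: int
    rho_control: float
    rho_patient: float


@dataclass
class SimulationSpec:
    """Generator settings for one two-group dataset.

    blocks : partition of region indices into clusters (singletons allowed).
    rho_within, rho_between : baseline correlations inside/between blocks.
    planted_edges : per-edge group-specific correlation overrides.
    noise_sd : sd of the additive white noise (signal sd is 1), shrinking
        observed correlations by a factor 1 / (1 + noise_sd**2).
    """

    n_regions: int
    n_timepoints: int = 200
    subjects_per_group: tuple[int, int] = (20, 20)
    blocks: tuple[tuple[int, ...], ...] = ()
    rho_within: float = 0.8
    rho_between: float = 0.0
    planted_edges: tuple[PlantedEdge, ...] = ()
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.subjects_per_group) < 1:
            raise ValueError("each group needs at least one subject")
        if not self.rho_within > self.rho_between:
            raise ValueError("rho_within must exceed rho_between")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        covered = [i for b in self.blocks for i in b]
        if sorted(covered) != list(range(self.n_regions)):
            raise ValueError("blocks must partition range(n_regions)")
        for e in self.planted_edges:
            if e.i == e.j:
                raise ValueError("planted edge endpoints must differ")
            if e.rho_control == e.rho_patient:
                raise ValueError(
                    f"planted edge ({e.i}, {e.j}) has zero between-group gap"
                )


@dataclass
class GroundTruth:
    """What was planted: per-region block labels and the altered edges."""

    block_labels: np.ndarray
    planted_edges: list[tuple[int, int]]
    corr_control: np.ndarray = field(default=None, repr=False)
    corr_patient: np.ndarray = field(default=None, repr=False)


def _group_correlation(spec: SimulationSpec, group: str) -> np.ndarray:
    N = spec.n_regions
    labels = np.empty(N, int)
    for b, members in enumerate(spec.blocks):
        labels[list(members)] = b
    C = np.where(labels[:, None] == labels[None, :], spec.rho_within, spec.rho_between)
    np.fill_diagonal(C, 1.0)
    for e in spec.planted_edges:
        rho = e.rho_control if group == "control" else e.rho_patient
        C[e.i, e.j] = C[e.j, e.i] = rho
    fixed = corr_nearest(C, threshold=1e-10, n_fact=200)
    for e in spec.planted_edges:
        target = e.rho_control if group == "control" else e.rho_patient
        drift = abs(fixed[e.i, e.j] - target)
        if drift > 0.1:
            raise ValueError(
                f"nearest-correlation projection moved planted edge "
                f"({e.i}, {e.j}) by {drift:.3f} (> 0.1); weaken the requested "
                f"correlations"
            )
    return fixed


def simulate_dataset(spec: SimulationSpec) -> tuple[GroupDataset, GroundTruth]:
    """Draw the two groups of subjects described by ``spec``.

    Deterministic under ``spec.seed``.  Region labels follow an AAL-style
    lateralised convention (``r00-L``, ``r00-R``, ...) so hemisphere-aware
    summaries are exercised end to end.
    """
    corr = {g: _group_correlation(spec, g) for g in ("control", "patient")}
    rng = np.random.default_rng(spec.seed)
    N, T = spec.n_regions, spec.n_timepoints
    labels = [f"r{i // 2:02d}-{'L' if i % 2 == 0 else 'R'}" for i in range(N)]

    # sample through a symmetric PSD square root; eigh is deterministic
    roots = {}
    for g, C in corr.items():
        w, v = np.linalg.eigh(C)
        roots[g] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    subjects, groups = [], []
    for g, count in zip(("control", "patient"), spec.subjects_per_group):
        for k in range(count):
            z = rng.standard_normal((T, N))
            signal = (z @ roots[g]).T  # N x T, target correlation
            noise = rng.normal(0.0, spec.noise_sd, size=(N, T))
            subjects.append(
                RegionTimeSeries(
                    subject_id=f"{g}_{k:03d}",
                    region_labels=labels,
                    data=signal + noise,
                )
            )
            groups.append(g)

    block_labels = np.empty(N, int)
    for b, members in enumerate(spec.blocks):
        block_labels[list(members)] = b
    truth = GroundTruth(
        block_labels=block_labels,
        planted_edges=[(min(e.i, e.j), max(e.i, e.j)) for e in spec.planted_edges],
        corr_control=corr["control"],
        corr_patient=corr["patient"],
    )
    return GroupDataset(subjects=subjects, labels=groups), truth


def write_fixture(dataset: GroupDataset, directory: str | os.PathLike) -> str:
    """Write one matrix TSV per subject plus a manifest; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for s, g in zip(dataset.subjects, dataset.labels):
        fname = f"{s.subject_id}.tsv"
        write_subject_matrix(s, os.path.join(directory, fname))
        rows.append((s.subject_id, g, fname))
    manifest = os.path.join(directory, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup\tmatrix_path\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest


def planted_benchmark_spec(
    seed: int = 0,
    subjects_per_group: tuple[int, int] = (20, 20),
    n_timepoints: int = 200,
) -> SimulationSpec:
    """The standard planted-effect benchmark used throughout the test-bed.

    Three correlated blocks (sizes 6, 7, 7) plus three initially unattached
    regions; in patients each unattached region joins one whole block at
    the within-block correlation, planting 6 + 7 + 7 = 20 edges whose
    co-clustering probability shifts strongly between groups.  Joining a
    block wholesale keeps the patient correlation matrix valid without any
    meaningful projection drift.
    """
    blocks = (
        tuple(range(0, 6)),
        tuple(range(6, 13)),
        tuple(range(13, 20)),
        (20,),
        (21,),
        (22,),
    )
    planted = []
    for free, members in zip((20, 21, 22), blocks[:3]):
        planted.extend(
            PlantedEdge(i=min(free, m), j=max(free, m), rho_control=0.0, rho_patient=0.8)
            for m in members
        )
    return SimulationSpec(
        n_regions=23,
        n_timepoints=n_timepoints,
        subjects_per_group=subjects_per_group,
        blocks=blocks,
        rho_within=0.8,
        rho_between=0.0,
        planted_edges=tuple(planted),
        noise_sd=0.2,
        seed=seed,
    )
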