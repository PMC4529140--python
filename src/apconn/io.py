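"""Reading and writing of region time-series matrices, group manifests and
community matrices.

The canonical on-disk input is a pair of artifacts:

* one tab-delimited matrix file per subject — first column the region label,
  header row the time indices, remaining columns the BOLD samples;
* a manifest TSV with columns ``subject_id``, ``group``, ``matrix_path``
  assigning each subject to the ``control`` or ``patient`` group.

An optional convenience path extracts region-mean time series from a 4D
volume plus an integer label atlas (any format nibabel reads).  All
preprocessing (motion correction, normalisation, band-pass filtering,
nuisance regression) is assumed to have happened upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_TOKENS = ("control", "patient")

__all__ = [
    "RegionTimeSeries",
    "GroupDataset",
    "read_subject_matrix",
    "write_subject_matrix",
    "read_manifest",
    "write_community_matrix",
    "extract_region_series",
]


@dataclass
class RegionTimeSeries:
    """One subject's region-by-time signal matrix.

    Parameters
    ----------
    subject_id : str
        Identifier carried through to reports.
    region_labels : list of str
        Ordered region names; length N.
    data : ndarray of shape (N, T)
        BOLD signal, one row per region.  Arbitrary units.
    """

    subject_id: str
    region_labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D region-by-time matrix")
        n, t = self.data.shape
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if t < 2:
            raise ValueError(f"need at least 2 time points, got {t}")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {n} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at region {self.region_labels[bad[0]]!r}, "
                f"time point {bad[1]}"
            )
        norms = np.linalg.norm(self.data, axis=1)
        if np.any(norms == 0):
            idx = int(np.argmin(norms))
            raise ValueError(
                f"region {self.region_labels[idx]!r} has zero-norm signal"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class GroupDataset:
    """A two-group collection of subjects sharing one region ordering."""

    subjects: list[RegionTimeSeries]
    labels: list[str]
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.labels):
            raise ValueError("one label per subject required")
        bad = set(self.labels) - set(GROUP_TOKENS)
        if bad:
            raise ValueError(
                f"unknown group token(s) {sorted(bad)}; allowed: {list(GROUP_TOKENS)}"
            )
        if not self.region_labels and self.subjects:
            self.region_labels = list(self.subjects[0].region_labels)
        for s in self.subjects:
            if list(s.region_labels) != list(self.region_labels):
                mism = next(
                    (a, b)
                    for a, b in zip(s.region_labels, self.region_labels)
                    if a != b
                )
                raise ValueError(
                    f"subject {s.subject_id!r}: region label {mism[0]!r} does not "
                    f"match expected {mism[1]!r}"
                )
        for tok in GROUP_TOKENS:
            if tok not in self.labels:
                raise ValueError(f"group {tok!r} is empty")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def indices(self, group: str) -> np.ndarray:
        """Positions of subjects belonging to ``group``."""
        return np.flatnonzero(np.asarray(self.labels) == group)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels)


def read_subject_matrix(path: str | os.PathLike, subject_id: str | None = None) -> RegionTimeSeries:
    """Load one subject's region-by-time matrix from a TSV file.

    The file must have a header row of time indices and the region label in
    the first column.  Malformed numbers are reported with their row and
    column; zero-norm rows are rejected with the offending region named.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = raw.astype(float)  # correctly-rounded, lossless round-trip
    except ValueError:
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: cannot parse value {raw.iat[r, c]!r} at region "
            f"{raw.index[r]!r}, time column {raw.columns[c]!r}"
        ) from None
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    return RegionTimeSeries(
        subject_id=subject_id,
        region_labels=[str(l) for l in raw.index],
        data=numeric.to_numpy(dtype=float),
    )


def write_subject_matrix(x: RegionTimeSeries, path: str | os.PathLike) -> None:
    """Write a subject matrix as TSV (lossless round-trip with the reader)."""
    df = pd.DataFrame(
        x.data, index=x.region_labels, columns=range(x.n_timepoints)
    )
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_manifest(path: str | os.PathLike) -> GroupDataset:
    """Load a manifest TSV (subject_id, group, matrix_path) into a GroupDataset.

    ``matrix_path`` entries are resolved relative to the manifest's directory.
    Region labels of the first listed subject define the canonical order; any
    deviation in later subjects is an error.
    """
    base = os.path.dirname(os.path.abspath(path))
    man = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "matrix_path"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    subjects, labels = [], []
    for row in man.itertuples(index=False):
        if row.group not in GROUP_TOKENS:
            raise ValueError(
                f"subject {row.subject_id!r}: unknown group {row.group!r}; "
                f"allowed tokens: {list(GROUP_TOKENS)}"
            )
        mpath = row.matrix_path
        if not os.path.isabs(mpath):
            mpath = os.path.join(base, mpath)
        subjects.append(read_subject_matrix(mpath, subject_id=row.subject_id))
        labels.append(row.group)
    return GroupDataset(subjects=subjects, labels=labels)


def write_community_matrix(K: np.ndarray, region_labels: list[str], path: str | os.PathLike) -> None:
    """Write a square region-by-region matrix as TSV with labelled axes."""
    df = pd.DataFrame(K, index=region_labels, columns=region_labels)
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.17g")


def extract_region_series(
    volume4d,
    atlas,
    label_table: dict[int, str],
    subject_id: str = "subject",
) -> RegionTimeSeries:
    """Average voxel time series within each atlas label.

    Parameters
    ----------
    volume4d : nibabel image or ndarray of shape (X, Y, Z, T)
        The 4D functional volume.
    atlas : nibabel image or ndarray of shape (X, Y, Z)
        Integer label volume on the same spatial grid.
    label_table : mapping of int label -> region name
        Extraction order follows the mapping's insertion order.

    Returns
    -------
    RegionTimeSeries
        Row r is the mean over voxels carrying label r, per time point.
    """
    vol = np.asanyarray(volume4d.dataobj) if hasattr(volume4d, "dataobj") else np.asarray(volume4d)
    atl = np.asanyarray(atlas.dataobj) if hasattr(atlas, "dataobj") else np.asarray(atlas)
    atl = np.rint(atl).astype(int)
    if vol.ndim != 4:
        raise ValueError("volume4d must be 4-dimensional")
    if atl.shape != vol.shape[:3]:
        raise ValueError(
            f"atlas grid {atl.shape} does not match volume grid {vol.shape[:3]}"
        )
    if hasattr(volume4d, "affine") and hasattr(atlas, "affine"):
        if not np.allclose(volume4d.affine, atlas.affine, atol=1e-4):
            raise ValueError("volume and atlas affines differ")
    rows, labels = [], []
    for lab, name in label_table.items():
        mask = atl == int(lab)
        if not mask.any():
            raise ValueError(f"label {lab} ({name!r}) absent from atlas")
        rows.append(vol[mask].mean(axis=0))
        labels.append(name)
    return RegionTimeSeries(
        subject_id=subject_id, region_labels=labels, data=np.vstack(rows)
    )
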