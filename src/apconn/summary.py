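"""Region-group alteration summaries of selected discriminant connections.

Given a selected edge set and the signed difference matrix (patients minus
controls), edges are tallied per pair of user-supplied region groups (brain
lobes, resting-state networks, ...) as increased (positive sign) or
decreased (negative sign) connectivity.  A separate tally counts
inter-hemispheric edges and the bilaterally homologous subset, parsed from
an AAL-style "<stem>-L"/"<stem>-R" label convention.

Group memberships are user configuration (TSV: region_label, group_label) —
regions a scheme does not cover are tallied as unmapped, which supports
partial partitions such as resting-state networks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field


import pandas as pd

from .selection import ConnectionSet, DifferenceMatrix

__all__ = [
    "RegionGrouping",
    "AlterationSummary",
    "read_grouping",
    "aggregate_alterations",
    "hemisphere_tally",
]


@dataclass
class RegionGrouping:
    """Named mapping of region labels to group labels (possibly partial)."""

    name: str
    membership: dict[str, str]

    def validate(self, region_labels: list[str]) -> None:
        known = set(region_labels)
        bad = [r for r in self.membership if r not in known]
        if bad:
            raise ValueError(
                f"grouping {self.name!r} references unknown region(s): {bad[:5]}"
            )


@dataclass
class AlterationSummary:
    """Counts of increased/decreased selected edges per ordered group pair."""

    grouping_name: str = ""
    pair_counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    unmapped: int = 0
    zero_signed: int = 0
    # hemisphere tallies (filled by hemisphere_tally)
    inter_hemispheric: dict[str, int] = field(default_factory=lambda: {"increased": 0, "decreased": 0})
    homologous: dict[str, int] = field(default_factory=lambda: {"increased": 0, "decreased": 0})
    unlateralized: int = 0

    def total_mapped(self) -> int:
        return sum(c["increased"] + c["decreased"] for c in self.pair_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_i": g1, "group_j": g2, "increased": c["increased"], "decreased": c["decreased"]}
            for (g1, g2), c in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["group_i", "group_j", "increased", "decreased"])


def read_grouping(path: str | os.PathLike, name: str | None = None) -> RegionGrouping:
    """Load a grouping config TSV with columns region_label, group_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"region_label", "group_label"} - set(df.columns)
    if missing:
        raise ValueError(f"grouping file missing column(s): {sorted(missing)}")
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return RegionGrouping(
        name=name, membership=dict(zip(df.region_label, df.group_label))
    )


def aggregate_alterations(
    selected: ConnectionSet,
    D: DifferenceMatrix,
    grouping: RegionGrouping,
    region_labels: list[str],
) -> AlterationSummary:
    """Tally selected edges per (group, group) pair, split by sign of D_signed.

    Every selected edge lands in exactly one bucket: a mapped group pair
    (unordered, stored with g1 <= g2), the unmapped tally (either endpoint
    not covered by the grouping), or the zero-signed tally.
    """
    grouping.validate(region_labels)
    out = AlterationSummary(grouping_name=grouping.name)
    for i, j in selected.edges:
        g1 = grouping.membership.get(region_labels[i])
        g2 = grouping.membership.get(region_labels[j])
        if g1 is None or g2 is None:
            out.unmapped += 1
            continue
        sign = float(D.D_signed[i, j])
        if sign == 0.0:
            out.zero_signed += 1
            continue
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        bucket = out.pair_counts.setdefault(key, {"increased": 0, "decreased": 0})
        bucket["increased" if sign > 0 else "decreased"] += 1
    return out


def _parse_hemisphere(label: str, suffixes: tuple[str, str]) -> tuple[str, str] | None:
    """Return (stem, side) or None when the label carries no suffix."""
    for side, suf in zip(("L", "R"), suffixes):
        if label.endswith(suf):
            return label[: -len(suf)], side
    return None


def hemisphere_tally(
    selected: ConnectionSet,
    D: DifferenceMatrix,
    region_labels: list[str],
    suffixes: tuple[str, str] = ("-L", "-R"),
) -> AlterationSummary:
    """Count inter-hemispheric and bilaterally homologous selected edges.

    Homologous = same label stem with opposite hemisphere suffixes (e.g.
    ``cuneus-L`` / ``cuneus-R``).  Labels without a recognised suffix are
    tallied as unlateralized and excluded from the hemisphere counts.
    """
    import warnings

    out = AlterationSummary(grouping_name="hemispheres")
    for i, j in selected.edges:
        pi = _parse_hemisphere(region_labels[i], suffixes)
        pj = _parse_hemisphere(region_labels[j], suffixes)
        if pi is None or pj is None:
            out.unlateralized += 1
            warnings.warn(
                f"edge ({region_labels[i]!r}, {region_labels[j]!r}) has "
                f"unlateralized endpoint(s); expected suffixes {suffixes}",
                stacklevel=2,
            )
            continue
        sign = float(D.D_signed[i, j])
        direction = "increased" if sign > 0 else "decreased"
        if pi[1] != pj[1]:
            if sign != 0.0:
                out.inter_hemispheric[direction] += 1
                if pi[0] == pj[0]:
                    out.homologous[direction] += 1
            else:
                out.zero_signed += 1
    return out
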