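"""Group summary tables, the morphospecies-vs-haplogroup census and
richness extrapolation.

Terminology: following common (if loose) barcoding usage, a group's
"variation" (sometimes called its variance) is the MAXIMUM pairwise
p-distance among its members — not the statistical variance and not a
mean. Between-group distances are minima (optionally also maxima) over
all cross-group specimen pairs. The census counts how many threshold
haplogroups hide under each morphology-based species label; the excess of
haplogroups over morphospecies is the number of additional candidate
species, and scaling a known regional species estimate by the
haplogroup-to-morphospecies ratio gives a crude projected richness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from motupipe.delimit import MOTUPartition
from motupipe.distances import DistanceMatrix
from motupipe.io_metadata import SpecimenRecord


def group_variation(members: Sequence[str], D: DistanceMatrix) -> float | None:
    """Maximum pairwise p-distance within a group; ``None`` for singletons."""
    if not members:
        raise ValueError("empty group")
    if len(members) == 1:
        return None
    idx = [D.index(m) for m in members]
    sub = D.values[np.ix_(idx, idx)]
    return float(sub.max())


@dataclass
class GroupSummaryTable:
    """Per-haplogroup summary with pairwise between-group distances.

    ``min_between[i][j]`` (and ``max_between`` when built in min-max mode)
    hold unrounded percent distances, ``None`` on the diagonal; rounding
    to one decimal happens only when the table is written out.
    """

    labels: list[str]
    localities: list[str]
    ns: list[int]
    variations: list[float | None]
    min_between: list[list[float | None]]
    max_between: list[list[float | None]] | None = None

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def total_specimens(self) -> int:
        return sum(self.ns)


def _locality_summary(
    members: Sequence[str], records: Sequence[SpecimenRecord] | None
) -> str:
    if not records:
        return ""
    loc_by_id = {r.specimen_id: r.locality for r in records}
    seen: list[str] = []
    for m in members:
        loc = loc_by_id.get(m, "")
        if loc and loc not in seen:
            seen.append(loc)
    return "/".join(seen)


def between_group_table(
    partition: MOTUPartition,
    D: DistanceMatrix,
    mode: str = "min",
    records: Sequence[SpecimenRecord] | None = None,
) -> GroupSummaryTable:
    """Between-group minimum (and optionally maximum) distance table.

    For every pair of haplogroups the minimum (mode ``"min"``) or minimum
    and maximum (mode ``"min-max"``) over all cross-group specimen pairs
    is tabulated, together with each group's n, locality summary and
    within-group variation.
    """
    if mode not in ("min", "min-max"):
        raise ValueError(f"unknown mode {mode!r}")
    if partition.n_groups < 2:
        raise ValueError("between-group table needs at least 2 groups")
    labels = list(partition.groups)
    member_idx = {
        lab: [D.index(m) for m in members]
        for lab, members in partition.groups.items()
    }
    k = len(labels)
    mins: list[list[float | None]] = [[None] * k for _ in range(k)]
    maxs: list[list[float | None]] = [[None] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            cross = D.values[np.ix_(member_idx[labels[i]], member_idx[labels[j]])]
            mins[i][j] = mins[j][i] = float(cross.min())
            maxs[i][j] = maxs[j][i] = float(cross.max())
    return GroupSummaryTable(
        labels=labels,
        localities=[
            _locality_summary(partition.groups[lab], records) for lab in labels
        ],
        ns=[len(partition.groups[lab]) for lab in labels],
        variations=[
            group_variation(partition.groups[lab], D) for lab in labels
        ],
        min_between=mins,
        max_between=maxs if mode == "min-max" else None,
    )


@dataclass
class CensusReport:
    """Headline counts of the morphospecies-vs-haplogroup comparison."""

    n_specimens: int
    n_morphospecies: int
    n_haplogroups: int
    per_morphospecies: dict[str, int]
    n_single_haplogroup_species: int
    n_single_locality_groups: int

    @property
    def n_additional_candidates(self) -> int:
        return self.n_haplogroups - self.n_morphospecies

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_specimens": self.n_specimens,
                "n_morphospecies": self.n_morphospecies,
                "n_haplogroups": self.n_haplogroups,
                "n_additional_candidates": self.n_additional_candidates,
                "per_morphospecies": self.per_morphospecies,
                "n_single_haplogroup_species": self.n_single_haplogroup_species,
                "n_single_locality_groups": self.n_single_locality_groups,
            },
            indent=2,
            sort_keys=True,
        )


def haplogroup_census(
    partition: MOTUPartition, records: Sequence[SpecimenRecord]
) -> CensusReport:
    """Count haplogroups per morphospecies over a delimited partition.

    Each haplogroup is attributed to the morphospecies of its first
    member (in practice threshold groups are morphospecies-pure unless
    contamination slipped through QC), so per-species counts sum to the
    total number of haplogroups.
    """
    morpho = {r.specimen_id: r.morphospecies for r in records}
    loc = {r.specimen_id: r.locality for r in records}
    missing = partition.specimen_ids - set(morpho)
    if missing:
        raise ValueError(
            "specimens without morphospecies labels: " + ", ".join(sorted(missing))
        )
    per: dict[str, int] = {}
    single_locality = 0
    for members in partition.groups.values():
        sp = morpho[members[0]]
        per[sp] = per.get(sp, 0) + 1
        if len({loc[m] for m in members if loc[m]}) <= 1:
            single_locality += 1
    return CensusReport(
        n_specimens=len(partition.specimen_ids),
        n_morphospecies=len(per),
        n_haplogroups=partition.n_groups,
        per_morphospecies=per,
        n_single_haplogroup_species=sum(1 for v in per.values() if v == 1),
        n_single_locality_groups=single_locality,
    )


@dataclass
class RichnessExtrapolation:
    """Ratio-scaled projection of known species richness.

    ``projected = known * n_haplogroups / n_morphospecies``. This simple
    scaling assumes the sampled morphospecies split into cryptic lineages
    at the same rate as unsampled ones; it is a back-of-the-envelope
    figure, not an estimator with confidence bounds.
    """

    known_morphospecies_estimate: float
    inflation_ratio: float
    projected_species: float

    @property
    def projected_species_rounded(self) -> int:
        return int(round(self.projected_species))


def richness_extrapolation(
    known: float, census: CensusReport
) -> RichnessExtrapolation:
    """Scale a known richness estimate by the haplogroup inflation ratio."""
    if census.n_morphospecies <= 0:
        raise ValueError("census has no morphospecies")
    ratio = census.n_haplogroups / census.n_morphospecies
    return RichnessExtrapolation(
        known_morphospecies_estimate=known,
        inflation_ratio=ratio,
        projected_species=known * ratio,
    )
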