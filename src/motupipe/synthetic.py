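"""Synthetic COI-like datasets with planted haplogroup structure.

The generator emulates what a barcode survey of a speciose reef-fish genus
looks like: protein-coding, essentially indel-free ~650 bp sequences
grouped into morphospecies, each morphospecies containing one to eight
haplogroups whose within-group variation is typically below 2% and whose
between-group separations run from just above 2% to over 20%, plus the
occasional pathology — a nuclear-pseudogene-like sequence with in-frame
stop codons, a too-short sequence, and a cross-species contaminant.

Geometry is a star, not a coalescent: each species has an ancestor, each
haplogroup a founder at a controlled number of substitutions from that
ancestor, and members radiate from the founder. All substitution site
sets within one species are drawn disjointly (sampling sites without
replacement), so planted p-distances are exact sums of substitution
counts with no back-mutation noise, and every tabulated within/between
value can be predicted arithmetically. Substitutions are biased 8:1:1
toward third:second:first codon positions so that the data stay
realistically translatable even at high nucleotide divergence.

Caveat on targets: with a star geometry the distance between two groups
is the sum of their founder radii, so per-group minimum-separation
targets are all achieved exactly only when at least two groups of a
species share the smallest target (the radii then solve the system); a
uniquely smallest target is overshot, which is verified and recorded.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from motupipe.io_metadata import BarcodeSequence, Dataset, SpecimenRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: substitution weight by codon position (1st, 2nd, 3rd)
POSITION_WEIGHTS = (1.0, 1.0, 8.0)


@dataclass(frozen=True)
class HaplogroupSpec:
    """One planted haplogroup: size and divergence targets in percent."""

    n_specimens: int
    target_within_max: float = 0.5
    target_min_to_sibling: float = 0.0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("haplogroup needs at least one specimen")
        if self.target_within_max < 0 or self.target_min_to_sibling < 0:
            raise ValueError("divergence targets must be non-negative")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    localities: tuple[str, ...]
    haplogroups: tuple[HaplogroupSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "localities", tuple(self.localities))
        object.__setattr__(self, "haplogroups", tuple(self.haplogroups))
        if len(self.haplogroups) > 1:
            worst_within = max(h.target_within_max for h in self.haplogroups)
            best_between = min(h.target_min_to_sibling for h in self.haplogroups)
            if worst_within >= best_between:
                raise ValueError(
                    f"infeasible geometry for {self.name!r}: within-group target "
                    f"{worst_within}% is not below between-group target "
                    f"{best_between}%"
                )


@dataclass(frozen=True)
class AnomalySpec:
    n_stop_codon_seqs: int = 0
    n_contaminants: int = 0
    n_short_seqs: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    species: tuple[SpeciesSpec, ...]
    n_codons: int = 217
    genetic_code: int = 2
    #: substitutions from the root ancestor to each species ancestor, percent of sites
    species_radius_pct: float = 10.0
    anomalies: AnomalySpec = AnomalySpec()

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.n_codons < 50:
            raise ValueError("n_codons must be at least 50")

    @property
    def n_sites(self) -> int:
        return 3 * self.n_codons


@dataclass
class GroupTruth:
    """Arithmetic ground truth for one planted haplogroup."""

    species: str
    index: int  # 1-based within the species
    radius_subs: int
    member_subs: dict[str, int]  # specimen id -> substitutions from the founder


@dataclass
class PlantedTruth:
    """Planted partition plus the arithmetic needed to predict all tables."""

    partition: dict[str, list[str]]  # group label -> clean member ids
    groups: dict[str, GroupTruth]
    n_sites: int
    seed: int
    anomalies: dict[str, list[str]] = field(
        default_factory=lambda: {"stop_codon": [], "contaminant": [], "short": []}
    )
    target_report: list[dict] = field(default_factory=list)

    @property
    def n_haplogroups(self) -> int:
        return len(self.partition)

    @property
    def clean_ids(self) -> set[str]:
        return {m for members in self.partition.values() for m in members}

    @property
    def anomalous_ids(self) -> set[str]:
        return {m for ids in self.anomalies.values() for m in ids}

    def _pct(self, subs: int) -> float:
        return 100.0 * subs / self.n_sites

    def expected_within_max(self, label: str) -> float | None:
        """Max within-group p-distance predicted from substitution counts."""
        ms = sorted(
            self.groups[label].member_subs[m] for m in self.partition[label]
        )
        if len(ms) < 2:
            return None
        return self._pct(ms[-1] + ms[-2])

    def expected_between(self, label_a: str, label_b: str) -> tuple[float, float]:
        """(min, max) p-distance between two groups of the SAME species."""
        ga, gb = self.groups[label_a], self.groups[label_b]
        if ga.species != gb.species:
            raise ValueError("between-group prediction is exact only within a species")
        ma = [ga.member_subs[m] for m in self.partition[label_a]]
        mb = [gb.member_subs[m] for m in self.partition[label_b]]
        base = ga.radius_subs + gb.radius_subs
        return self._pct(base + min(ma) + min(mb)), self._pct(base + max(ma) + max(mb))

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_sites": self.n_sites,
                "partition": self.partition,
                "anomalies": self.anomalies,
                "target_report": self.target_report,
            },
            indent=2,
            sort_keys=True,
        )


def _stop_set(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def sample_ancestor(
    cfg: SimulationConfig | None = None,
    *,
    n_codons: int | None = None,
    genetic_code: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Uniform random stop-free codon sequence.

    Codons are drawn uniformly from the 64 triplets, rejecting stop codons
    of the configured code. With a :class:`SimulationConfig` the sequence
    is fully determined by ``cfg.seed``.
    """
    if cfg is not None:
        n_codons = cfg.n_codons
        genetic_code = cfg.genetic_code
        rng = rng or np.random.default_rng(cfg.seed)
    if n_codons is None or n_codons < 50:
        raise ValueError("need at least 50 codons")
    genetic_code = genetic_code or 2
    rng = rng if rng is not None else np.random.default_rng()
    stops = _stop_set(genetic_code)
    codons = []
    while len(codons) < n_codons:
        codon = "".join(BASES[b] for b in rng.integers(0, 4, size=3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


def _site_weights(n_sites: int) -> np.ndarray:
    w = np.empty(n_sites)
    for pos in range(3):
        w[pos::3] = POSITION_WEIGHTS[pos]
    return w


def _draw_sites(
    rng: np.random.Generator,
    available: np.ndarray,
    n: int,
    weights: np.ndarray,
) -> np.ndarray:
    """Draw ``n`` distinct sites from the available pool, 3rd-position biased."""
    pool = np.flatnonzero(available)
    if n > pool.size:
        raise ValueError(
            "infeasible geometry: the configured divergences need more "
            "substitution sites than the sequence provides"
        )
    if n == 0:
        return np.empty(0, dtype=int)
    p = weights[pool] / weights[pool].sum()
    chosen = rng.choice(pool, size=n, replace=False, p=p)
    available[chosen] = False
    return chosen


def _fix_stops(
    seq: list[str], parent: str, mutated: set[int], genetic_code: int,
    rng: np.random.Generator,
) -> None:
    """Re-draw mutated bases inside any codon that became a stop."""
    stops = _stop_set(genetic_code)
    for c in {s // 3 for s in mutated}:
        codon_sites = [3 * c, 3 * c + 1, 3 * c + 2]
        if "".join(seq[k] for k in codon_sites) not in stops:
            continue
        site = next(k for k in codon_sites if k in mutated)
        alternatives = [b for b in BASES if b != parent[site] and b != seq[site]]
        order = rng.permutation(len(alternatives))
        for b in (alternatives[i] for i in order):
            seq[site] = b
            if "".join(seq[k] for k in codon_sites) not in stops:
                break


def evolve(
    seq: str,
    n_substitutions: int,
    rng: np.random.Generator,
    avoid_stops: bool = True,
    sites: Sequence[int] | np.ndarray | None = None,
    genetic_code: int = 2,
) -> str:
    """Substitute exactly ``n_substitutions`` distinct sites of ``seq``.

    Each chosen site is changed to a different base, so the p-distance to
    the input is exactly ``100 * n / len(seq)``. When ``sites`` is not
    given they are drawn with an 8:1:1 third:second:first codon-position
    bias. With ``avoid_stops`` any codon turned into a stop has its
    mutated base redrawn (still different from the parent base, so the
    substitution count is preserved); since at most two of the three
    alternative bases at any position can yield a stop, a safe choice
    always exists.
    """
    if n_substitutions > len(seq):
        raise ValueError("more substitutions than sites")
    if sites is None:
        weights = _site_weights(len(seq))
        available = np.ones(len(seq), dtype=bool)
        sites = _draw_sites(rng, available, n_substitutions, weights)
    else:
        sites = np.asarray(sites, dtype=int)
        if sites.size != n_substitutions:
            raise ValueError("site list length does not match n_substitutions")
    out = list(seq)
    for s in sites:
        choices = [b for b in BASES if b != seq[s]]
        out[s] = choices[int(rng.integers(0, len(choices)))]
    if avoid_stops and n_substitutions:
        _fix_stops(out, seq, set(int(s) for s in sites), genetic_code, rng)
    return "".join(out)


def _member_sub_counts(
    n: int, within_subs: int, rng: np.random.Generator
) -> list[int]:
    """Per-member substitution counts so max pairwise == within_subs exactly.

    Member 0 is the founder itself (0 substitutions); the second and third
    members split the target so their pair realizes it; any further
    members stay within half the target so no pair exceeds it.
    """
    if n == 1:
        return [0]
    if n == 2:
        return [0, within_subs]
    hi, lo = math.ceil(within_subs / 2), math.floor(within_subs / 2)
    rest = [int(rng.integers(0, lo + 1)) for _ in range(n - 3)]
    return [0, hi, lo] + rest


def _radii_subs(specs: Sequence[HaplogroupSpec], n_sites: int) -> list[int]:
    """Founder radii (substitutions) so pair separations hit the targets.

    With separations = r_i + r_j the system is solved by
    r_i = t_i - t_min/2; every target is achieved exactly when the
    smallest target is shared by at least two groups.
    """
    if len(specs) == 1:
        return [0]
    t = [h.target_min_to_sibling for h in specs]
    t_min = min(t)
    return [int(round(n_sites * (ti - t_min / 2) / 100.0)) for ti in t]


def generate_dataset(cfg: SimulationConfig) -> tuple[Dataset, PlantedTruth]:
    """Generate a planted-structure barcode dataset plus its ground truth.

    Fully determined by ``cfg.seed``. Realized per-group minimum
    separations are compared against the configured targets and recorded
    in ``truth.target_report``; a deviation beyond 0.5 percentage points
    is logged as a warning. If ``cfg.anomalies`` requests anomalies they
    are injected before returning.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_sites
    weights = _site_weights(L)
    root = sample_ancestor(
        n_codons=cfg.n_codons, genetic_code=cfg.genetic_code, rng=rng
    )
    species_subs = int(round(L * cfg.species_radius_pct / 100.0))

    sequences: list[BarcodeSequence] = []
    records: list[SpecimenRecord] = []
    partition: dict[str, list[str]] = {}
    groups: dict[str, GroupTruth] = {}
    target_report: list[dict] = []
    counter = 0

    for sp in cfg.species:
        ancestor = evolve(
            root, species_subs, rng, avoid_stops=True, genetic_code=cfg.genetic_code
        )
        available = np.ones(L, dtype=bool)
        radii = _radii_subs(sp.haplogroups, L)
        founders: list[str] = []
        for g, (spec, r) in enumerate(zip(sp.haplogroups, radii)):
            founder_sites = _draw_sites(rng, available, r, weights)
            founders.append(
                evolve(
                    ancestor, r, rng, avoid_stops=True, sites=founder_sites,
                    genetic_code=cfg.genetic_code,
                )
            )
        for g, (spec, founder) in enumerate(zip(sp.haplogroups, founders)):
            label = f"{sp.name} Group {g + 1}"
            within_subs = int(round(L * spec.target_within_max / 100.0))
            msubs = _member_sub_counts(spec.n_specimens, within_subs, rng)
            locality = sp.localities[g % len(sp.localities)]
            member_subs: dict[str, int] = {}
            for m in msubs:
                counter += 1
                sid = f"s{counter:04d}"
                member_sites = _draw_sites(rng, available, m, weights)
                nt = evolve(
                    founder, m, rng, avoid_stops=True, sites=member_sites,
                    genetic_code=cfg.genetic_code,
                )
                sequences.append(BarcodeSequence(sid, nt, source="synthetic"))
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        morphospecies=sp.name,
                        locality=locality,
                        catalogue=f"T{counter:05d}",
                    )
                )
                member_subs[sid] = m
            partition[label] = list(member_subs)
            groups[label] = GroupTruth(
                species=sp.name, index=g + 1, radius_subs=radii[g],
                member_subs=member_subs,
            )
        if len(sp.haplogroups) > 1:
            for g, spec in enumerate(sp.haplogroups):
                realized = 100.0 * (
                    radii[g] + min(radii[:g] + radii[g + 1 :])
                ) / L
                dev = realized - spec.target_min_to_sibling
                target_report.append(
                    {
                        "group": f"{sp.name} Group {g + 1}",
                        "target_min_to_sibling": spec.target_min_to_sibling,
                        "realized_min_to_sibling": realized,
                    }
                )
                if abs(dev) > 0.5:
                    logger.warning(
                        "%s Group %d: realized separation %.2f%% deviates "
                        "from target %.2f%% by more than 0.5 points",
                        sp.name, g + 1, realized, spec.target_min_to_sibling,
                    )

    dataset = Dataset(sequences=sequences, specimens=records)
    truth = PlantedTruth(
        partition=partition, groups=groups, n_sites=L, seed=cfg.seed,
        target_report=target_report,
    )
    if (
        cfg.anomalies.n_stop_codon_seqs
        or cfg.anomalies.n_contaminants
        or cfg.anomalies.n_short_seqs
    ):
        dataset, truth = inject_anomalies(dataset, truth, cfg.anomalies, rng, cfg)
    return dataset, truth


def inject_anomalies(
    dataset: Dataset,
    truth: PlantedTruth,
    spec: AnomalySpec,
    rng: np.random.Generator,
    cfg: SimulationConfig | None = None,
) -> tuple[Dataset, PlantedTruth]:
    """Corrupt designated specimens the way real barcode projects fail.

    Stop-codon sequences get one internal in-frame stop (pseudogene-like);
    contaminants are replaced by a near-copy (two substitutions, well
    under 0.6% divergence) of a random specimen from a DIFFERENT
    morphospecies while keeping their original label; short sequences are
    truncated below the resolved-length filter. Anomalous specimens are
    moved from the planted partition to the anomaly roster — the partition
    always describes what a clean analysis should recover.
    """
    total = spec.n_stop_codon_seqs + spec.n_contaminants + spec.n_short_seqs
    if total > len(dataset):
        raise ValueError("more anomalies requested than specimens available")
    genetic_code = cfg.genetic_code if cfg else 2
    stops = sorted(_stop_set(genetic_code))
    morpho = dataset.morphospecies_of()
    seq_by_id = {s.specimen_id: s for s in dataset.sequences}

    eligible = sorted(truth.clean_ids - truth.anomalous_ids)
    # a flaggable contaminant needs surviving conspecifics, so contaminant
    # victims are restricted to morphospecies with >= 2 clean specimens
    sp_counts: dict[str, int] = {}
    for sid in eligible:
        sp_counts[morpho[sid]] = sp_counts.get(morpho[sid], 0) + 1
    victims: list[str] = []
    if spec.n_contaminants:
        contam_pool = [s for s in eligible if sp_counts[morpho[s]] >= 3]
        if len(contam_pool) < spec.n_contaminants:
            raise ValueError("not enough specimens with conspecifics for contaminants")
        victims += [
            str(v)
            for v in rng.choice(contam_pool, size=spec.n_contaminants, replace=False)
        ]
    contam_species = {morpho[v] for v in victims}
    rest = [
        s for s in eligible
        if s not in victims and morpho[s] not in contam_species
    ]
    n_rest = spec.n_stop_codon_seqs + spec.n_short_seqs
    if n_rest > len(rest):
        raise ValueError("more anomalies requested than specimens available")
    victims += [str(v) for v in rng.choice(rest, size=n_rest, replace=False)]
    new_truth = PlantedTruth(
        partition={k: list(v) for k, v in truth.partition.items()},
        groups=truth.groups,
        n_sites=truth.n_sites,
        seed=truth.seed,
        anomalies={k: list(v) for k, v in truth.anomalies.items()},
        target_report=list(truth.target_report),
    )

    def retire(sid: str, kind: str) -> None:
        new_truth.anomalies[kind].append(sid)
        for label, members in list(new_truth.partition.items()):
            if sid in members:
                members.remove(sid)
                if not members:
                    del new_truth.partition[label]

    k = 0
    for _ in range(spec.n_contaminants):
        sid = victims[k]; k += 1
        donors = [
            d for d in sorted(truth.clean_ids)
            if morpho[d] != morpho[sid] and d not in victims
        ]
        if not donors:
            raise ValueError("contaminant injection needs a second morphospecies")
        donor = donors[int(rng.integers(0, len(donors)))]
        nt = evolve(
            seq_by_id[donor].nucleotides, 2, rng, avoid_stops=True,
            genetic_code=genetic_code,
        )
        seq_by_id[sid] = BarcodeSequence(sid, nt, source="synthetic")
        retire(sid, "contaminant")

    for _ in range(spec.n_stop_codon_seqs):
        sid = victims[k]; k += 1
        nt = list(seq_by_id[sid].nucleotides)
        codon_idx = int(rng.integers(1, len(nt) // 3 - 1))
        stop = stops[int(rng.integers(0, len(stops)))]
        nt[3 * codon_idx : 3 * codon_idx + 3] = list(stop)
        seq_by_id[sid] = BarcodeSequence(sid, "".join(nt), source="synthetic")
        retire(sid, "stop_codon")

    for _ in range(spec.n_short_seqs):
        sid = victims[k]; k += 1
        nt = seq_by_id[sid].nucleotides[:498]
        seq_by_id[sid] = BarcodeSequence(sid, nt, source="synthetic")
        retire(sid, "short")

    out = Dataset(
        sequences=[seq_by_id[s.specimen_id] for s in dataset.sequences],
        specimens=list(dataset.specimens),
    )
    return out, new_truth


def study_like_config(seed: int = 0, anomalies: bool = True) -> SimulationConfig:
    """Default simulation: the structure of a cryptic-species-rich survey.

    Mirrors, at reduced scale, the kinds of morphospecies a COI survey of
    a speciose goby genus contains: several single-haplogroup species,
    two-group splits in the 3.5–4.7% range, two four-group complexes with
    deep (4.5–8.7%) splits, an eight-group complex whose separations span
    2.4–19.9%, a complex with one pair of groups right at the 2% boundary,
    and (optionally) two pseudogene-like sequences, one cross-species
    contaminant and one too-short sequence.
    """
    H = HaplogroupSpec
    species = [
        SpeciesSpec(
            "Trimma sp. A", ("Moorea", "Fiji", "Palau", "Raja Ampat"),
            (H(4, 1.1, 7.9), H(2, 0.0, 8.7), H(10, 0.2, 6.2), H(5, 1.3, 6.2)),
        ),
        SpeciesSpec(
            "Trimma sp. B",
            ("Thailand", "Fiji", "New Caledonia", "Brunei", "Japan", "Taiwan",
             "Rabaul", "Great Barrier Reef"),
            (H(7, 0.9, 16.5), H(4, 0.0, 7.9), H(1, 0.0, 7.9), H(3, 0.0, 11.6),
             H(4, 0.3, 2.4), H(3, 0.3, 2.4), H(4, 0.2, 7.1), H(2, 0.2, 7.1)),
        ),
        SpeciesSpec(
            "Trimma sp. C", ("Raja Ampat", "Palau", "Rabaul"),
            (H(2, 0.2, 4.8), H(3, 0.3, 4.8), H(1, 0.0, 2.0), H(2, 0.2, 2.0)),
        ),
        SpeciesSpec(
            "Trimma sp. D", ("Raja Ampat", "Cendrawasih", "Palawan", "Rabaul"),
            (H(4, 0.2, 4.5), H(2, 0.4, 4.5), H(2, 0.3, 5.1), H(3, 0.0, 8.4)),
        ),
        SpeciesSpec(
            "Trimma sp. E", ("Raja Ampat", "Great Barrier Reef"),
            (H(4, 0.2, 3.5), H(6, 0.2, 3.5)),
        ),
        SpeciesSpec(
            "Trimma sp. F", ("Japan", "Palau"),
            (H(5, 0.4, 4.7), H(2, 0.0, 4.7)),
        ),
        SpeciesSpec("Trimma sp. G", ("Palau",), (H(8, 0.5),)),
        SpeciesSpec("Trimma sp. H", ("Raja Ampat",), (H(6, 1.1),)),
        SpeciesSpec("Trimma sp. I", ("Rabaul",), (H(3, 0.0),)),
        SpeciesSpec("Trimma RW sp. 24", ("Timor",), (H(14, 0.7),)),
        SpeciesSpec("Trimma RW sp. 97", ("Vanuatu",), (H(1, 0.0),)),
        SpeciesSpec("Trimma sp. L", ("Fiji",), (H(5, 0.9),)),
    ]
    anomaly_spec = (
        AnomalySpec(n_stop_codon_seqs=2, n_contaminants=1, n_short_seqs=1)
        if anomalies
        else AnomalySpec()
    )
    return SimulationConfig(seed=seed, species=tuple(species), anomalies=anomaly_spec)


EIGHT_GROUP_COMPLEX = SpeciesSpec(
    "Trimma sp. X",
    ("Thailand", "Fiji", "New Caledonia", "Brunei", "Japan", "Taiwan",
     "Rabaul", "Great Barrier Reef"),
    (
        HaplogroupSpec(7, 0.9, 16.5), HaplogroupSpec(4, 0.0, 7.9),
        HaplogroupSpec(1, 0.0, 7.9), HaplogroupSpec(3, 0.0, 11.6),
        HaplogroupSpec(4, 0.3, 2.4), HaplogroupSpec(3, 0.3, 2.4),
        HaplogroupSpec(4, 0.2, 7.1), HaplogroupSpec(2, 0.2, 7.1),
    ),
)


def random_survey_config(
    seed: int,
    min_separation: float = 3.0,
    max_within: float = 1.5,
    include_eight_group_complex: bool = False,
) -> SimulationConfig:
    """Random species/haplogroup layout for recovery experiments.

    Every species gets 1-4 haplogroups of 1-6 specimens. Two groups of
    each multi-group species share the smallest separation target (drawn
    in [``min_separation``, 10]; the rest up to 20%), so all planted
    minimum separations are realized exactly; within-group targets stay
    at or below ``max_within``. Optionally appends the deep eight-group
    complex whose separations span 2.4-19.9%.
    """
    rng = np.random.default_rng(seed)
    pool = ["Palau", "Raja Ampat", "Rabaul", "Fiji", "Japan", "Taiwan",
            "Timor", "Moorea", "Brunei", "New Caledonia"]
    species: list[SpeciesSpec] = []
    for s in range(int(rng.integers(3, 7))):
        k = int(rng.integers(1, 5))
        if k == 1:
            targets = [0.0]
        else:
            t_min = round(float(rng.uniform(min_separation, 10.0)), 1)
            targets = [t_min, t_min] + [
                round(float(rng.uniform(t_min, 20.0)), 1) for _ in range(k - 2)
            ]
        withins = [round(float(rng.uniform(0.0, max_within)), 1) for _ in range(k)]
        ns = [int(rng.integers(1, 7)) for _ in range(k)]
        locs = tuple(
            pool[i] for i in rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        )
        species.append(
            SpeciesSpec(
                f"Species {seed}-{s + 1}",
                locs,
                tuple(
                    HaplogroupSpec(n, w, t) for n, w, t in zip(ns, withins, targets)
                ),
            )
        )
    if include_eight_group_complex:
        species.append(EIGHT_GROUP_COMPLEX)
    return SimulationConfig(seed=seed, species=tuple(species))
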