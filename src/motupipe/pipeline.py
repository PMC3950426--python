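"""End-to-end orchestration: QC -> align -> distances -> MOTUs -> tree -> census."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from motupipe import census as census_mod
from motupipe.alignment import AlignedMatrix
from motupipe.delimit import DelimitationConfig, MOTUPartition, threshold_motus
from motupipe.distances import DistanceMatrix
from motupipe.io_metadata import (
    Dataset,
    join_dataset,
    read_fasta,
    read_specimen_table,
    write_group_table,
)
from motupipe.phenogram import CondensedTree, condense, neighbor_joining, to_newick
from motupipe.qc import QCConfig, QCReport, run_qc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = 2.0
    min_sites: int = 500
    genetic_code: int = 2
    conspecific_radius: float = 2.0
    outlier_floor: float = 10.0
    minmax_tables: bool = False
    known_richness: float = 110.0


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    config: dict
    input_checksums: dict[str, str]
    seed: int | None
    n_read: int = 0
    n_excluded: int = 0
    n_analyzed: int = 0
    n_haplogroups: int = 0

    def validate(self) -> None:
        if self.n_read != self.n_excluded + self.n_analyzed:
            raise ValueError("manifest counts do not reconcile")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    qc_report: QCReport
    aligned: AlignedMatrix | None
    distances: DistanceMatrix | None
    partition: MOTUPartition | None
    tree: object | None
    condensed: CondensedTree | None
    global_table: census_mod.GroupSummaryTable | None
    species_tables: dict[str, census_mod.GroupSummaryTable]
    census: census_mod.CensusReport | None
    extrapolation: census_mod.RichnessExtrapolation | None
    records: list = field(default_factory=list)

    def report_json(self) -> str:
        payload: dict = {"manifest": json.loads(self.manifest.to_json())}
        if self.census:
            payload["census"] = json.loads(self.census.to_json())
        if self.extrapolation:
            payload["richness"] = {
                "known_morphospecies_estimate": self.extrapolation.known_morphospecies_estimate,
                "inflation_ratio": self.extrapolation.inflation_ratio,
                "projected_species": self.extrapolation.projected_species,
                "projected_species_rounded": self.extrapolation.projected_species_rounded,
            }
        if self.partition:
            payload["partition"] = {
                label: members for label, members in self.partition.groups.items()
            }
        payload["qc"] = {
            "excluded": self.qc_report.excluded_ids,
            "retained": self.qc_report.retained_ids,
        }
        if self.condensed:
            payload["non_monophyletic_groups"] = self.condensed.non_monophyletic
        return json.dumps(payload, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def run_pipeline(
    fasta: str | Path | None = None,
    metadata: str | Path | None = None,
    dataset: Dataset | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the whole analysis and (optionally) write every artefact.

    Accepts either file paths (FASTA + TSV metadata) or an in-memory
    :class:`Dataset`. Stages: QC (frames, stop codons, alignment, length,
    contamination) -> p-distance matrix -> threshold MOTUs -> NJ
    phenogram with condensed rendering -> per-species and global
    between-group tables -> census and richness extrapolation.
    """
    config = config or PipelineConfig()
    checksums: dict[str, str] = {}
    if dataset is None:
        if fasta is None or metadata is None:
            raise ValueError("either a dataset or fasta+metadata paths are required")
        for p in (fasta, metadata):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        checksums = {str(fasta): _sha256(fasta), str(metadata): _sha256(metadata)}
        dataset = join_dataset(read_fasta(fasta), read_specimen_table(metadata))

    from motupipe import __version__

    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        input_checksums=checksums,
        seed=seed,
        n_read=len(dataset),
    )

    qc_cfg = QCConfig(
        min_sites=config.min_sites,
        genetic_code=config.genetic_code,
        conspecific_radius=config.conspecific_radius,
        outlier_floor=config.outlier_floor,
    )
    qc_report, aligned, distances_all, oriented = run_qc(dataset, qc_cfg)
    retained = [
        sid for sid in (aligned.ids if aligned else []) if sid in set(qc_report.retained_ids)
    ]
    manifest.n_excluded = len(dataset) - len(retained)
    manifest.n_analyzed = len(retained)

    partition = tree = condensed = global_table = census = extrapolation = None
    species_tables: dict[str, census_mod.GroupSummaryTable] = {}
    D = None
    records = [r for r in dataset.specimens if r.specimen_id in set(retained)]
    if distances_all is not None and len(retained) >= 2:
        D = distances_all.subset(retained)
        partition = threshold_motus(
            D, DelimitationConfig(threshold=config.threshold), records
        )
        manifest.n_haplogroups = partition.n_groups
        census = census_mod.haplogroup_census(partition, records)
        extrapolation = census_mod.richness_extrapolation(
            config.known_richness, census
        )
        mode = "min-max" if config.minmax_tables else "min"
        if partition.n_groups >= 2:
            global_table = census_mod.between_group_table(
                partition, D, mode=mode, records=records
            )
        morpho = {r.specimen_id: r.morphospecies for r in records}
        by_species: dict[str, dict[str, list[str]]] = {}
        for label, members in partition.groups.items():
            by_species.setdefault(morpho[members[0]], {})[label] = members
        for sp, groups in by_species.items():
            if len(groups) < 2:
                continue
            members = [m for g in groups.values() for m in g]
            sub = MOTUPartition(groups=groups, threshold=partition.threshold)
            species_tables[sp] = census_mod.between_group_table(
                sub, D.subset(members), mode=mode, records=records
            )
        if len(retained) >= 3:
            tree = neighbor_joining(D)
            condensed = condense(tree, partition, D=D, records=records)

    manifest.validate()
    result = PipelineResult(
        manifest=manifest,
        qc_report=qc_report,
        aligned=aligned,
        distances=D,
        partition=partition,
        tree=tree,
        condensed=condensed,
        global_table=global_table,
        species_tables=species_tables,
        census=census,
        extrapolation=extrapolation,
        records=records,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.write_tsv(out / "qc_report.tsv")
    (out / "qc_report.json").write_text(result.qc_report.to_json() + "\n")
    if result.aligned is not None:
        result.aligned.write_fasta(out / "aligned.fasta")
    if result.distances is not None:
        result.distances.write_tsv(out / "distances.tsv")
        result.distances.write_phylip(out / "distances.phy")
    if result.partition is not None:
        result.partition.write_tsv(out / "partition.tsv", result.records)
    if result.tree is not None:
        (out / "phenogram.nwk").write_text(to_newick(result.tree) + "\n")
    if result.condensed is not None:
        (out / "phenogram_condensed.nwk").write_text(
            result.condensed.to_newick() + "\n"
        )
    if result.global_table is not None:
        write_group_table(result.global_table, out / "groups_global.tsv")
    tables_dir = out / "groups"
    if result.species_tables:
        tables_dir.mkdir(exist_ok=True)
        for sp, table in result.species_tables.items():
            write_group_table(table, tables_dir / f"{_slug(sp)}.tsv")
    if result.census is not None:
        (out / "census.json").write_text(result.census.to_json() + "\n")
    (out / "manifest.json").write_text(result.manifest.to_json() + "\n")
    (out / "report.json").write_text(result.report_json() + "\n")
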