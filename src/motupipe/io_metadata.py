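"""Reading, writing and joining barcode sequences and specimen metadata.

Sequences travel as FASTA (the first whitespace-delimited token of a header
is the specimen id, mirroring GenBank/BOLD exports); specimen metadata as a
tab-separated table with a header row, the convention used by BOLD specimen
exports. Group summary tables are written as TSV in the upper-triangular
layout used for between-group distance tables in barcoding studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes plus the gap character used after alignment.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Mandatory columns of the specimen-metadata table.
MANDATORY_COLUMNS = ("specimen_id", "morphospecies", "locality")

#: Optional columns, filled with empty values when absent.
OPTIONAL_COLUMNS = ("catalogue", "is_type_locality")


@dataclass(frozen=True)
class BarcodeSequence:
    """One specimen's COI barcode nucleotide sequence.

    Parameters
    ----------
    specimen_id:
        Unique specimen identifier (joins 1:1 to a :class:`SpecimenRecord`).
    nucleotides:
        Uppercase IUPAC DNA, possibly containing ``N`` and, after
        alignment, ``-`` gap characters.
    source:
        ``"fasta"`` for sequences read from file, ``"synthetic"`` for
        simulated ones.
    """

    specimen_id: str
    nucleotides: str
    source: str = "fasta"

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")
        bad = set(self.nucleotides) - IUPAC_DNA
        if bad:
            pos = next(
                i for i, c in enumerate(self.nucleotides) if c in bad
            )
            raise ValueError(
                f"illegal character {self.nucleotides[pos]!r} at position "
                f"{pos} in sequence {self.specimen_id!r}"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class SpecimenRecord:
    """Identity and taxonomy of one vouchered specimen.

    ``morphospecies`` is the morphology-based label, either a binomial or
    an informal code of the form ``"<Genus> RW sp. <n>"`` used for known
    but undescribed species.
    """

    specimen_id: str
    morphospecies: str
    locality: str = ""
    catalogue: str = ""
    is_type_locality: bool = False

    def __post_init__(self) -> None:
        if not self.morphospecies or not str(self.morphospecies).strip():
            raise ValueError(
                f"blank morphospecies for specimen {self.specimen_id!r}"
            )


@dataclass
class Dataset:
    """Joined collection of sequences and specimen records.

    Both sides carry exactly the same specimen ids, with no duplicates.
    """

    sequences: list[BarcodeSequence]
    specimens: list[SpecimenRecord]

    def __post_init__(self) -> None:
        seq_ids = [s.specimen_id for s in self.sequences]
        rec_ids = [r.specimen_id for r in self.specimens]
        if len(set(seq_ids)) != len(seq_ids):
            raise ValueError("duplicate specimen ids among sequences")
        if len(set(rec_ids)) != len(rec_ids):
            raise ValueError("duplicate specimen ids among records")
        if set(seq_ids) != set(rec_ids):
            raise ValueError("sequence and record id sets differ")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.specimen_id for s in self.sequences]

    def sequence(self, specimen_id: str) -> BarcodeSequence:
        return next(s for s in self.sequences if s.specimen_id == specimen_id)

    def record(self, specimen_id: str) -> SpecimenRecord:
        return next(r for r in self.specimens if r.specimen_id == specimen_id)

    def morphospecies_of(self) -> dict[str, str]:
        """Mapping specimen id -> morphospecies label."""
        return {r.specimen_id: r.morphospecies for r in self.specimens}

    def subset(self, keep_ids: Iterable[str]) -> "Dataset":
        keep = set(keep_ids)
        return Dataset(
            sequences=[s for s in self.sequences if s.specimen_id in keep],
            specimens=[r for r in self.specimens if r.specimen_id in keep],
        )


def read_fasta(path: str | Path, source: str = "fasta") -> list[BarcodeSequence]:
    """Read barcode sequences from a FASTA file.

    The first whitespace-delimited token of each header is taken as the
    specimen id; the remainder of the header is ignored. Sequences are
    uppercased. Raises on an empty file, on duplicate ids, and on
    characters outside the IUPAC alphabet.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seqs: list[BarcodeSequence] = []
    seen: set[str] = set()
    for rec in records:
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate specimen id {sid!r} in {path}")
        seen.add(sid)
        seqs.append(
            BarcodeSequence(
                specimen_id=sid, nucleotides=str(rec.seq).upper(), source=source
            )
        )
    return seqs


def write_fasta(seqs: Iterable[BarcodeSequence], path: str | Path) -> None:
    """Write sequences to FASTA (id-only headers)."""
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.specimen_id, description="")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    return s in {"1", "true", "yes", "y"}


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read a tab-separated specimen-metadata table.

    The header must contain at least ``specimen_id``, ``morphospecies``
    and ``locality``; optional columns (``catalogue``,
    ``is_type_locality``) are filled with empty values when absent.
    Missing individual cells in optional/locality columns become empty
    strings with a logged warning; a blank morphospecies is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"specimen table {path} lacks mandatory column {col!r}")
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        locality = row.get("locality", "")
        if not locality:
            logger.warning(
                "specimen %s has no locality; stored as empty", row["specimen_id"]
            )
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                morphospecies=row["morphospecies"],
                locality=locality,
                catalogue=row.get("catalogue", ""),
                is_type_locality=_parse_bool(row.get("is_type_locality", False)),
            )
        )
    return records


def write_specimen_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write specimen records as a TSV with the standard column set."""
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "catalogue": r.catalogue,
                "morphospecies": r.morphospecies,
                "locality": r.locality,
                "is_type_locality": str(r.is_type_locality).lower(),
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def join_dataset(
    seqs: Sequence[BarcodeSequence], records: Sequence[SpecimenRecord]
) -> Dataset:
    """Join sequences to specimen records on specimen id.

    Ids present on only one side are dropped with a logged warning; zero
    overlap is an error. The result preserves the sequence input order.
    """
    seq_ids = {s.specimen_id for s in seqs}
    rec_ids = {r.specimen_id for r in records}
    common = seq_ids & rec_ids
    if not common:
        raise ValueError("no specimen ids shared between sequences and metadata")
    dropped = (seq_ids | rec_ids) - common
    if dropped:
        logger.warning(
            "dropping %d specimen(s) present on only one side: %s",
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    rec_by_id = {r.specimen_id: r for r in records}
    kept_seqs = [s for s in seqs if s.specimen_id in common]
    kept_recs = [rec_by_id[s.specimen_id] for s in kept_seqs]
    return Dataset(sequences=kept_seqs, specimens=kept_recs)


def format_distance_cell(
    min_value: float | None, max_value: float | None = None
) -> str:
    """Render one between-group distance cell, e.g. ``"1.2"`` or ``"1.2/1.6"``."""
    from motupipe.distances import round_report

    if min_value is None:
        return "-"
    cell = f"{round_report(min_value):.1f}"
    if max_value is not None:
        cell += f"/{round_report(max_value):.1f}"
    return cell


def write_group_table(table, path: str | Path) -> None:
    """Write a :class:`~motupipe.census.GroupSummaryTable` as TSV.

    One row per haplogroup with its locality summary, specimen count and
    maximum within-group variation (``n/a`` for singletons), followed by
    the upper triangle of between-group minimum distances (or ``min/max``
    pairs when the table was built in min-max mode). The diagonal is
    rendered ``0`` and the lower triangle ``-``, the layout conventional
    for barcode distance tables.
    """
    from motupipe.distances import round_report

    k = len(table.labels)
    header = ["group", "locality", "n", "variation"] + [
        table.labels[j] for j in range(1, k)
    ]
    lines = ["\t".join(header)]
    for i in range(k):
        var = table.variations[i]
        var_cell = "n/a" if var is None else f"{round_report(var):.1f}"
        cells = [table.labels[i], table.localities[i], str(table.ns[i]), var_cell]
        for j in range(1, k):
            if j < i:
                cells.append("-")
            elif j == i:
                cells.append("0")
            else:
                mx = table.max_between[i][j] if table.max_between is not None else None
                cells.append(format_distance_cell(table.min_between[i][j], mx))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
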