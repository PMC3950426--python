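"""Pre-analysis quality control of COI barcodes.

COI is protein-coding, so a healthy barcode translates without internal
stop codons in some reading frame; in-frame stops betray nuclear
pseudogene copies (NUMTs) or sequencing artefacts. Beyond the reading
frame, sequences must carry enough resolved sites to yield meaningful
p-distances, and cross-contaminated samples — sequences that nest inside a
different morphospecies while sitting far from every conspecific — are
flagged from the distance matrix itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from motupipe.io_metadata import BarcodeSequence, Dataset, SpecimenRecord

logger = logging.getLogger(__name__)

#: NCBI translation table for vertebrate mitochondria.
VERTEBRATE_MITO = 2

_UNAMBIGUOUS = frozenset("ACGT")


def _stop_codons(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def _codons(seq: str, frame: int) -> list[str]:
    """Complete codons of ``seq`` read from offset ``frame``."""
    core = seq[frame:]
    return [core[i : i + 3] for i in range(0, len(core) - len(core) % 3, 3)]


def _count_stops(seq: str, frame: int, genetic_code: int) -> int:
    """Unambiguous in-frame stop codons (ambiguity-containing codons never count)."""
    stops = _stop_codons(genetic_code)
    return sum(
        1
        for codon in _codons(seq, frame)
        if set(codon) <= _UNAMBIGUOUS and codon in stops
    )


def detect_reading_frame(
    seq: BarcodeSequence | str, genetic_code: int = VERTEBRATE_MITO
) -> tuple[int, int]:
    """Find the reading frame of a coding sequence on the given strand.

    Returns ``(frame, n_stops)`` where ``frame`` in {0, 1, 2} is the
    offset minimizing the number of unambiguous in-frame stop codons and
    ``n_stops`` that minimum. Ties break to the smallest offset.
    """
    nt = seq.nucleotides if isinstance(seq, BarcodeSequence) else seq
    nt = nt.replace("-", "")
    counts = [_count_stops(nt, f, genetic_code) for f in (0, 1, 2)]
    frame = int(np.argmin(counts))
    return frame, counts[frame]


def stop_codon_check(
    seq: BarcodeSequence | str, frame: int, genetic_code: int = VERTEBRATE_MITO
) -> int:
    """Count internal unambiguous stop codons in the given frame.

    A stop that is the final complete codon is treated as a legitimate
    terminal stop and not counted; any earlier stop is.
    """
    nt = seq.nucleotides if isinstance(seq, BarcodeSequence) else seq
    nt = nt.replace("-", "")
    codons = _codons(nt, frame)
    stops = _stop_codons(genetic_code)
    n = 0
    for i, codon in enumerate(codons):
        if set(codon) <= _UNAMBIGUOUS and codon in stops:
            if i == len(codons) - 1:
                continue  # terminal stop
            n += 1
    return n


def length_filter(aligned_seq: str, min_sites: int = 500) -> bool:
    """True iff the sequence has strictly more than ``min_sites`` resolved sites.

    Resolved sites are characters that are neither gaps nor ``N``; partial
    ambiguity codes (R, Y, ...) still count as resolved here — they are
    handled pair-by-pair at distance time.
    """
    resolved = sum(1 for c in aligned_seq if c not in ("-", "N"))
    return resolved > min_sites


@dataclass(frozen=True)
class ContaminationEvidence:
    neighbour_id: str
    neighbour_distance: float
    neighbour_morphospecies: str
    min_conspecific_distance: float


def flag_contaminants(
    D,
    records: Sequence[SpecimenRecord],
    conspecific_radius: float = 2.0,
    outlier_floor: float = 10.0,
) -> dict[str, ContaminationEvidence]:
    """Flag specimens whose barcode nests inside a different morphospecies.

    A specimen is flagged when BOTH hold: (a) its nearest neighbour in the
    distance matrix belongs to a different morphospecies at a distance
    below ``conspecific_radius`` (percent), and (b) its minimum distance
    to any conspecific exceeds ``outlier_floor``. Specimens whose
    morphospecies has no other sampled member cannot satisfy (b) and are
    never flagged. Returns a mapping flagged id -> evidence.
    """
    morpho = {r.specimen_id: r.morphospecies for r in records}
    ids = [i for i in D.ids if i in morpho]
    if len({morpho[i] for i in ids}) < 2:
        logger.warning("single-morphospecies dataset: contamination check skipped")
        return {}
    flags: dict[str, ContaminationEvidence] = {}
    for i in ids:
        others = [j for j in ids if j != i]
        dists = np.array([D.get(i, j) for j in others])
        nn = others[int(np.argmin(dists))]
        d_nn = float(dists.min())
        if morpho[nn] == morpho[i] or d_nn >= conspecific_radius:
            continue
        consp = [D.get(i, j) for j in others if morpho[j] == morpho[i]]
        if not consp:
            continue
        d_consp = float(min(consp))
        if d_consp > outlier_floor:
            flags[i] = ContaminationEvidence(
                neighbour_id=nn,
                neighbour_distance=d_nn,
                neighbour_morphospecies=morpho[nn],
                min_conspecific_distance=d_consp,
            )
    return flags


@dataclass(frozen=True)
class QCConfig:
    min_sites: int = 500
    genetic_code: int = VERTEBRATE_MITO
    conspecific_radius: float = 2.0
    outlier_floor: float = 10.0
    #: try the reverse strand when every forward frame has at least this many stops
    rc_stop_trigger: int = 3


@dataclass
class SpecimenQC:
    """Per-specimen QC flags with human-readable reasons."""

    specimen_id: str
    frame: int
    n_stop_codons: int
    passes_length: bool
    contaminant_flag: bool = False
    contamination: ContaminationEvidence | None = None
    reverse_complemented: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return self.n_stop_codons > 0 or not self.passes_length or self.contaminant_flag


@dataclass
class QCReport:
    """QC outcome for a whole dataset."""

    per_specimen: dict[str, SpecimenQC]
    config: QCConfig

    @property
    def excluded_ids(self) -> list[str]:
        return [s for s, q in self.per_specimen.items() if q.excluded]

    @property
    def retained_ids(self) -> list[str]:
        return [s for s, q in self.per_specimen.items() if not q.excluded]

    def to_json(self) -> str:
        payload = {
            sid: {
                "frame": q.frame,
                "n_stop_codons": q.n_stop_codons,
                "passes_length": q.passes_length,
                "contaminant_flag": q.contaminant_flag,
                "reverse_complemented": q.reverse_complemented,
                "excluded": q.excluded,
                "reasons": q.reasons,
                "contamination": (
                    {
                        "neighbour_id": q.contamination.neighbour_id,
                        "neighbour_distance": q.contamination.neighbour_distance,
                        "neighbour_morphospecies": q.contamination.neighbour_morphospecies,
                        "min_conspecific_distance": q.contamination.min_conspecific_distance,
                    }
                    if q.contamination
                    else None
                ),
            }
            for sid, q in self.per_specimen.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write_tsv(self, path: str | Path) -> None:
        lines = [
            "specimen_id\tframe\tn_stop_codons\tpasses_length\t"
            "contaminant_flag\texcluded\treasons"
        ]
        for sid, q in self.per_specimen.items():
            lines.append(
                f"{sid}\t{q.frame}\t{q.n_stop_codons}\t{q.passes_length}\t"
                f"{q.contaminant_flag}\t{q.excluded}\t{'; '.join(q.reasons)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def orient_and_frame(
    seq: BarcodeSequence, cfg: QCConfig
) -> tuple[BarcodeSequence, int, int, bool]:
    """Detect the reading frame, trying the reverse strand if needed.

    When every forward frame carries ``cfg.rc_stop_trigger`` or more stops
    the reverse complement is tried; the orientation with fewer stops
    wins. Returns (possibly reverse-complemented sequence, frame,
    internal stop count, was_reverse_complemented).
    """
    frame, stops_all = detect_reading_frame(seq, cfg.genetic_code)
    internal = stop_codon_check(seq, frame, cfg.genetic_code)
    if stops_all >= cfg.rc_stop_trigger:
        rc_nt = str(Seq(seq.nucleotides.replace("-", "")).reverse_complement())
        rc_frame, rc_stops = detect_reading_frame(rc_nt, cfg.genetic_code)
        if rc_stops < stops_all:
            rc_seq = BarcodeSequence(seq.specimen_id, rc_nt, seq.source)
            return (
                rc_seq,
                rc_frame,
                stop_codon_check(rc_nt, rc_frame, cfg.genetic_code),
                True,
            )
    return seq, frame, internal, False


def run_qc(dataset: Dataset, cfg: QCConfig | None = None):
    """Run the full QC stage: frames, stop codons, alignment, length, contamination.

    Returns ``(report, aligned, distances, oriented)`` where ``aligned``
    is the trimmed alignment of all stop-free sequences, ``distances``
    the p-distance matrix over the length-passing subset (contaminants
    included, so their evidence is visible), and ``oriented`` the dataset
    with any strand flips applied. Downstream stages should subset both
    to ``report.retained_ids``.
    """
    from motupipe.alignment import align_translations, trim_to_core
    from motupipe.distances import build_matrix

    cfg = cfg or QCConfig()
    qcs: dict[str, SpecimenQC] = {}
    oriented_seqs: list[BarcodeSequence] = []
    frames: dict[str, int] = {}
    for seq in dataset.sequences:
        oseq, frame, n_stops, flipped = orient_and_frame(seq, cfg)
        oriented_seqs.append(oseq)
        frames[seq.specimen_id] = frame
        q = SpecimenQC(
            specimen_id=seq.specimen_id,
            frame=frame,
            n_stop_codons=n_stops,
            passes_length=True,
            reverse_complemented=flipped,
        )
        if flipped:
            q.reasons.append("sequence reverse-complemented to coding strand")
        if n_stops > 0:
            q.reasons.append(
                f"{n_stops} in-frame stop codon(s): likely pseudogene/artefact"
            )
        qcs[seq.specimen_id] = q

    oriented = Dataset(sequences=oriented_seqs, specimens=list(dataset.specimens))

    stop_free = [s for s in oriented_seqs if qcs[s.specimen_id].n_stop_codons == 0]
    aligned = None
    distances = None
    if len(stop_free) >= 2:
        aligned = trim_to_core(align_translations(stop_free, frames=frames))
        for sid, row in zip(aligned.ids, aligned.rows):
            if not length_filter(row, cfg.min_sites):
                qcs[sid].passes_length = False
                resolved = sum(1 for c in row if c not in ("-", "N"))
                qcs[sid].reasons.append(
                    f"only {resolved} resolved aligned sites "
                    f"(needs > {cfg.min_sites})"
                )
        # stop-excluded sequences: evaluate length on the raw sequence
        for sid, q in qcs.items():
            if q.n_stop_codons > 0:
                raw = oriented.sequence(sid).nucleotides
                q.passes_length = length_filter(raw, cfg.min_sites)

        survivors = [
            sid for sid in aligned.ids if qcs[sid].passes_length
        ]
        if len(survivors) >= 2:
            distances = build_matrix(aligned.subset(survivors))
            flags = flag_contaminants(
                distances,
                dataset.specimens,
                conspecific_radius=cfg.conspecific_radius,
                outlier_floor=cfg.outlier_floor,
            )
            for sid, ev in flags.items():
                qcs[sid].contaminant_flag = True
                qcs[sid].contamination = ev
                qcs[sid].reasons.append(
                    f"nearest neighbour {ev.neighbour_id} "
                    f"({ev.neighbour_morphospecies}) at "
                    f"{ev.neighbour_distance:.2f}% but nearest conspecific at "
                    f"{ev.min_conspecific_distance:.2f}%: likely contamination"
                )
    return QCReport(per_specimen=qcs, config=cfg), aligned, distances, oriented
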