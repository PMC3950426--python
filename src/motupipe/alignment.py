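"""Translation-guided alignment of COI barcodes into common coordinates.

5' COI barcodes are protein-coding and essentially indel-free, so a full
profile-HMM is unnecessary to recover a common coordinate system: each
sequence is translated in its detected reading frame, its amino-acid
string is anchored to the longest stop-free sequence by pairwise protein
alignment, and the resulting codon-level offsets (and, rarely, codon-width
gaps) are applied back to the nucleotides. This is an approximation of
the HMM-based aligner used by barcoding platforms, adequate because the
marker carries virtually no length variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from motupipe.io_metadata import BarcodeSequence

GAP_CODON = "---"


@dataclass
class AlignedMatrix:
    """Site-by-specimen character matrix in common codon coordinates.

    ``positions`` holds the 1-based reference coordinate of every column
    (reference = the emitted alignment before any trimming), so trimming
    preserves provenance. ``frames`` records the reading-frame offset that
    was stripped from each input sequence.
    """

    ids: list[str]
    rows: list[str]
    frames: dict[str, int]
    positions: list[int]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows have unequal lengths")
        if self.rows and len(self.positions) != len(self.rows[0]):
            raise ValueError("positions/row length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def reference_span(self) -> tuple[int, int]:
        """1-based inclusive reference coordinates of the retained region."""
        return (self.positions[0], self.positions[-1]) if self.positions else (0, 0)

    def row(self, specimen_id: str) -> str:
        return self.rows[self.ids.index(specimen_id)]

    def subset(self, keep_ids: Iterable[str]) -> "AlignedMatrix":
        keep = set(keep_ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        return AlignedMatrix(
            ids=[self.ids[i] for i in idx],
            rows=[self.rows[i] for i in idx],
            frames={self.ids[i]: self.frames[self.ids[i]] for i in idx},
            positions=list(self.positions),
        )

    def write_fasta(self, path) -> None:
        from motupipe.io_metadata import BarcodeSequence, write_fasta

        write_fasta(
            [BarcodeSequence(sid, row) for sid, row in zip(self.ids, self.rows)],
            path,
        )


def _coding_block(nt: str, frame: int) -> str:
    core = nt[frame:]
    return core[: len(core) - len(core) % 3]


def _translate(coding: str, genetic_code: int) -> str:
    return str(Seq(coding).translate(table=genetic_code))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-8.0,
        extend_gap_score=-1.0,
    )
    # truncated barcodes are the norm: end gaps are free
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # older biopython spelling
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    return aligner


def align_translations(
    seqs: Sequence[BarcodeSequence],
    frames: Mapping[str, int] | None = None,
    genetic_code: int = 2,
    min_anchor_coverage: float = 0.5,
) -> AlignedMatrix:
    """Align QC-passed barcodes via their amino-acid translations.

    The anchor is the longest stop-free sequence (ties broken by id).
    Every other sequence's translation is globally aligned to the anchor's
    with free end gaps; amino-acid gaps become codon-width nucleotide
    gaps, so the reading frame survives alignment. Sequences whose
    translation matches the anchor identically over less than
    ``min_anchor_coverage`` of their own length (likely non-COI) raise an
    error listing the offending ids.
    """
    from motupipe.qc import detect_reading_frame, stop_codon_check

    if not seqs:
        raise ValueError("no sequences to align")
    if frames is None:
        frames = {
            s.specimen_id: detect_reading_frame(s, genetic_code)[0] for s in seqs
        }
    coding = {
        s.specimen_id: _coding_block(s.nucleotides.replace("-", ""), frames[s.specimen_id])
        for s in seqs
    }
    aa = {sid: _translate(c, genetic_code) for sid, c in coding.items()}
    stop_free = [
        s.specimen_id
        for s in seqs
        if stop_codon_check(coding[s.specimen_id], 0, genetic_code) == 0
    ]
    candidates = stop_free or [s.specimen_id for s in seqs]
    anchor_id = sorted(candidates, key=lambda sid: (-len(coding[sid]), sid))[0]
    anchor_aa = aa[anchor_id]
    n_anchor = len(anchor_aa)

    aligner = _make_aligner()
    # anchor aa index -> (seq id -> seq aa index); insertions keyed by the
    # anchor position they precede (n_anchor = after the end)
    mappings: dict[str, dict[int, int]] = {}
    insertions: dict[str, dict[int, list[int]]] = {}
    poor: list[str] = []
    for s in seqs:
        sid = s.specimen_id
        if sid == anchor_id:
            mappings[sid] = {i: i for i in range(n_anchor)}
            insertions[sid] = {}
            continue
        aln = aligner.align(anchor_aa, aa[sid])[0]
        mapping: dict[int, int] = {}
        ins: dict[int, list[int]] = {}
        identical = 0
        target_blocks, query_blocks = aln.aligned
        prev_q_end = 0
        for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
            if q0 > prev_q_end:
                ins.setdefault(t0, []).extend(range(prev_q_end, q0))
            for k in range(t1 - t0):
                mapping[t0 + k] = q0 + k
                if anchor_aa[t0 + k] == aa[sid][q0 + k]:
                    identical += 1
            prev_q_end = q1
        if prev_q_end < len(aa[sid]):
            ins.setdefault(n_anchor, []).extend(range(prev_q_end, len(aa[sid])))
        if len(aa[sid]) > 0 and identical / len(aa[sid]) < min_anchor_coverage:
            poor.append(sid)
        mappings[sid] = mapping
        insertions[sid] = ins
    if poor:
        raise ValueError(
            "sequences could not be anchored to the alignment (likely non-COI): "
            + ", ".join(sorted(poor))
        )

    ins_width = {
        p: max((len(insertions[sid].get(p, [])) for sid in mappings), default=0)
        for p in range(n_anchor + 1)
    }
    rows: dict[str, list[str]] = {sid: [] for sid in mappings}
    for p in range(n_anchor + 1):
        width = ins_width[p]
        for sid in mappings:
            own = insertions[sid].get(p, [])
            cells = [coding[sid][3 * q : 3 * q + 3] for q in own]
            cells += [GAP_CODON] * (width - len(own))
            rows[sid].extend(cells)
        if p < n_anchor:
            for sid in mappings:
                q = mappings[sid].get(p)
                rows[sid].append(
                    GAP_CODON if q is None else coding[sid][3 * q : 3 * q + 3]
                )

    ids = [s.specimen_id for s in seqs]
    out_rows = ["".join(rows[sid]) for sid in ids]
    n_cols = len(out_rows[0]) if out_rows else 0
    return AlignedMatrix(
        ids=ids,
        rows=out_rows,
        frames={sid: frames[sid] for sid in ids},
        positions=list(range(1, n_cols + 1)),
    )


def trim_to_core(matrix: AlignedMatrix, min_coverage: float = 0.5) -> AlignedMatrix:
    """Drop alignment columns with non-gap coverage below ``min_coverage``.

    Keeps a column iff the fraction of non-gap characters is at least
    ``min_coverage``, so ragged alignment ends do not count toward the
    resolved-length filter. Raises if nothing survives.
    """
    n = len(matrix.rows)
    if n == 0:
        raise ValueError("empty alignment")
    keep = [
        c
        for c in range(matrix.n_sites)
        if sum(1 for r in matrix.rows if r[c] != "-") / n >= min_coverage
    ]
    if not keep:
        raise ValueError("no alignment columns meet the coverage threshold")
    return AlignedMatrix(
        ids=list(matrix.ids),
        rows=["".join(r[c] for c in keep) for r in matrix.rows],
        frames=dict(matrix.frames),
        positions=[matrix.positions[c] for c in keep],
    )
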