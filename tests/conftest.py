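from __future__ import annotations

import numpy as np
import pytest

from motupipe.alignment import AlignedMatrix
from motupipe.distances import DistanceMatrix
from motupipe.io_metadata import BarcodeSequence, Dataset, SpecimenRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20140218)


def random_rows(rng, n=20, length=120, with_ambiguity=True) -> list[str]:
    """Random aligned rows sharing a backbone so distances vary widely."""
    alphabet = list("ACGT")
    backbone = rng.integers(0, 4, size=length)
    rows = []
    for _ in range(n):
        mut = rng.random(length) < rng.uniform(0.02, 0.6)
        row = np.where(mut, rng.integers(0, 4, size=length), backbone)
        chars = [alphabet[b] for b in row]
        if with_ambiguity:
            for k in np.flatnonzero(rng.random(length) < 0.02):
                chars[k] = "N" if rng.random() < 0.5 else "-"
        rows.append("".join(chars))
    return rows


def matrix_from_rows(rows: list[str]) -> DistanceMatrix:
    from motupipe.distances import build_matrix

    ids = [f"s{i}" for i in range(len(rows))]
    aligned = AlignedMatrix(
        ids=ids,
        rows=rows,
        frames={i: 0 for i in ids},
        positions=list(range(1, len(rows[0]) + 1)),
    )
    return build_matrix(aligned)


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Five specimens, two morphospecies, trivially clean sequences."""
    base = "ATGACAGCCCTAAGCCTACTAATTCGAGCCGAACTAAGCCAACCAGGC" * 5
    seqs = [
        BarcodeSequence("a1", base),
        BarcodeSequence("a2", base[:-3] + "GGA"),
        BarcodeSequence("b1", base.replace("CGA", "CGG")),
        BarcodeSequence("b2", base.replace("CGA", "CGT")),
        BarcodeSequence("b3", base),
    ]
    recs = [
        SpecimenRecord("a1", "Trimma alpha", "Palau"),
        SpecimenRecord("a2", "Trimma alpha", "Palau"),
        SpecimenRecord("b1", "Trimma beta", "Fiji"),
        SpecimenRecord("b2", "Trimma beta", "Fiji"),
        SpecimenRecord("b3", "Trimma beta", "Rabaul"),
    ]
    return Dataset(sequences=seqs, specimens=recs)
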