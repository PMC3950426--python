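"""Pairwise p-distances with pairwise deletion.

The p-distance between two aligned barcodes is the percentage of compared
sites at which they differ, where a site is compared only if both
sequences carry an unambiguous base (A, C, G or T) there — gaps and
ambiguity codes are deleted pair by pair. No substitution-model
correction is applied: at barcode depths the uncorrected proportion is
the conventional currency and keeps thresholds comparable across studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from motupipe.alignment import AlignedMatrix

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _encode(row: str) -> np.ndarray:
    return _CODE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances in percent.

    ``values[i, j]`` is the unrounded p-distance between specimens
    ``ids[i]`` and ``ids[j]``; ``n_sites[i, j]`` the number of sites the
    pair was compared over.
    """

    ids: list[str]
    values: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < 0).any() or (self.values > 100).any():
            raise ValueError("p-distances must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, keep_ids: Iterable[str]) -> "DistanceMatrix":
        keep = set(keep_ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        return DistanceMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            n_sites=self.n_sites[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format."""
        lines = [f"{len(self.ids)}"]
        for sid, row in zip(self.ids, self.values):
            cells = " ".join(f"{v:.6f}" for v in row)
            lines.append(f"{sid:<10s} {cells}")
        Path(path).write_text("\n".join(lines) + "\n")


def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """p-distance (percent) and compared-site count for one aligned pair.

    Sites where either sequence has a gap or any non-ACGT character are
    excluded (pairwise deletion). Raises when no site is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows have different lengths")
    a, b = _encode(row_a), _encode(row_b)
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("zero comparable sites between the pair")
    mismatches = int(((a != b) & mask).sum())
    return 100.0 * mismatches / n, n


def build_matrix(matrix: AlignedMatrix) -> DistanceMatrix:
    """All-pairs p-distance matrix over an alignment.

    Specimen order is preserved. A pair with zero comparable sites is an
    error naming both specimens.
    """
    if len(matrix.rows) < 2:
        raise ValueError("need at least 2 sequences to build a distance matrix")
    enc = np.stack([_encode(r) for r in matrix.rows])
    valid = enc < 4
    n = len(matrix.ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sites, valid.sum(axis=1))
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"zero comparable sites between {matrix.ids[i]!r} "
                    f"and {matrix.ids[j]!r}"
                )
            mm = int(((enc[i] != enc[j]) & mask).sum())
            values[i, j] = values[j, i] = 100.0 * mm / m
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(ids=list(matrix.ids), values=values, n_sites=sites)


def round_report(value: float) -> float:
    """Round a percent value to 1 decimal, halves away from zero.

    Used only at the presentation layer; clustering and tables always
    consume unrounded distances so that boundary cases (e.g. a pair at
    exactly 2.0%) do not depend on display rounding.
    """
    return float(
        Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
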