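"""Core domain containers shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention).  Conversion
from 1-based inclusive conventions (VCF positions, coordinates quoted in
papers/browsers) happens exactly once, at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` in bp."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp shared under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_one_based_inclusive(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Convert a 1-based inclusive range (e.g. browser coordinates)."""
        return cls(chrom, start - 1, end)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced ATAC fragment with its cell barcode.

    ``count`` is the duplicate count reported by the fragment file; a
    duplicate-collapse is a QC concern, not an I/O one.
    """

    interval: GenomicInterval
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.count}")
        if not self.barcode:
            raise ValueError("barcode must be non-empty")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class LoopRecord:
    """A pair of Hi-C loop anchors; anchors are stored canonically ordered
    (anchor_a does not start after anchor_b)."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"loop score must be >= 0, got {self.score}")
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)

    @property
    def is_cis(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom


@dataclass
class CountMatrix:
    """Sparse nonnegative peaks x cells count matrix.

    ``obs`` carries per-cell metadata (one row per barcode, aligned with
    the matrix columns); typical columns are ``subset`` and ``donor``.
    """

    matrix: sp.csr_matrix
    peak_ids: list[str]
    barcodes: list[str]
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.peak_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.peak_ids)} peaks x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(self.obs) == 0:
            self.obs = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        elif list(self.obs.index) != list(self.barcodes):
            raise ValueError("obs index must equal barcodes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())
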