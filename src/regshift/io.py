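"""Readers and writers for the text formats the pipeline touches.

Supported formats: BED (3-6 columns), BEDPE (6+ columns), FASTA,
MatrixMarket coordinate integer, dense TSV matrices, fragment files
(chrom, start, end, barcode, count) and SNP tables (chrom, pos, rsid,
ref, alt, trait[, pvalue[, block]]).

Conventions
-----------
* BED/BEDPE/fragment coordinates are 0-based half-open and kept as-is.
* SNP positions are 1-based on input (VCF convention) and converted to
  0-based internally by consumers via ``pos - 1``.
* Ranges quoted 1-based inclusive (browser style) can be converted with
  ``parse_region(..., one_based_inclusive=True)``.
* All text formats are transparently gzip-compressed when the file name
  ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from regshift.core import CountMatrix, FragmentRecord, GenomicInterval, LoopRecord

_VALID_BASES = frozenset("ACGTN")
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)[-–](?P<end>[\d,]+)$")


class ParseError(ValueError):
    """Raised on malformed input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _open_text(source, mode: str = "rt") -> IO[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, mode)
        return open(path, mode)
    return source


def _iter_lines(source) -> Iterator[tuple[int, str]]:
    handle = _open_text(source)
    try:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line
    finally:
        if handle is not source:
            handle.close()


def _parse_int(text: str, what: str, line: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", line) from None


# ---------------------------------------------------------------------------
# regions / BED


def parse_region(text: str, one_based_inclusive: bool = False) -> GenomicInterval:
    """Parse ``chrom:start-end`` (commas and en-dashes tolerated).

    With ``one_based_inclusive=True`` the range is interpreted the way
    genome browsers and papers print it and converted to half-open.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ParseError(f"cannot parse region {text!r}")
    chrom = m.group("chrom")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if one_based_inclusive:
        return GenomicInterval.from_one_based_inclusive(chrom, start, end)
    return GenomicInterval(chrom, start, end)


def parse_bed(source) -> list[tuple[GenomicInterval, str | None, float | None]]:
    """Parse BED3-6. Returns ``(interval, name, score)`` tuples in input order."""
    out: list[tuple[GenomicInterval, str | None, float | None]] = []
    for lineno, line in _iter_lines(source):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"expected >=3 tab-separated fields, got {len(fields)}", lineno)
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        try:
            interval = GenomicInterval(fields[0], start, end)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(f"non-numeric score: {fields[4]!r}", lineno) from None
        out.append((interval, name, score))
    return out


def parse_bed_intervals(source) -> list[GenomicInterval]:
    """Like :func:`parse_bed` but drops the optional columns."""
    return [iv for iv, _, _ in parse_bed(source)]


def write_bed(records, dest) -> None:
    """Write intervals (or ``(interval, name, score)`` tuples) as BED."""
    handle = _open_text(dest, "wt")
    try:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, name, score = rec, None, None
            else:
                iv, name, score = (tuple(rec) + (None, None))[:3]
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None or score is not None:
                fields.append(name if name is not None else ".")
            if score is not None:
                fields.append(f"{score:g}")
            handle.write("\t".join(fields) + "\n")
    finally:
        if handle is not dest:
            handle.close()


# ---------------------------------------------------------------------------
# fragments


def parse_fragments(source) -> list[FragmentRecord]:
    """Parse a fragment file: chrom, start, end, barcode, count."""
    out: list[FragmentRecord] = []
    for lineno, line in _iter_lines(source):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"expected 5 fields, got {len(fields)}", lineno)
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        count = _parse_int(fields[4], "count", lineno)
        try:
            out.append(FragmentRecord(GenomicInterval(fields[0], start, end), fields[3], count))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return out


def write_fragments(records: Iterable[FragmentRecord], dest) -> None:
    handle = _open_text(dest, "wt")
    try:
        for rec in records:
            iv = rec.interval
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.barcode}\t{rec.count}\n")
    finally:
        if handle is not dest:
            handle.close()


def fragments_to_frame(records: Sequence[FragmentRecord]) -> pd.DataFrame:
    """Columnar view of a fragment list (one row per record)."""
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in records],
            "start": np.fromiter((r.interval.start for r in records), dtype=np.int64, count=len(records)),
            "end": np.fromiter((r.interval.end for r in records), dtype=np.int64, count=len(records)),
            "barcode": [r.barcode for r in records],
            "count": np.fromiter((r.count for r in records), dtype=np.int64, count=len(records)),
        }
    )


# ---------------------------------------------------------------------------
# BEDPE loops


def parse_bedpe(source) -> list[LoopRecord]:
    """Parse BEDPE loop calls; anchors are canonically ordered per record."""
    out: list[LoopRecord] = []
    for lineno, line in _iter_lines(source):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"expected >=6 fields, got {len(fields)}", lineno)
        try:
            a = GenomicInterval(
                fields[0], _parse_int(fields[1], "start1", lineno), _parse_int(fields[2], "end1", lineno)
            )
            b = GenomicInterval(
                fields[3], _parse_int(fields[4], "start2", lineno), _parse_int(fields[5], "end2", lineno)
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
        score = 0.0
        if len(fields) > 7 and fields[7] not in (".", ""):
            try:
                score = float(fields[7])
            except ValueError:
                raise ParseError(f"non-numeric score: {fields[7]!r}", lineno) from None
        out.append(LoopRecord(a, b, score))
    return out


def write_bedpe(records: Iterable[LoopRecord], dest) -> None:
    handle = _open_text(dest, "wt")
    try:
        for rec in records:
            a, b = rec.anchor_a, rec.anchor_b
            handle.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t.\t{rec.score:g}\n"
            )
    finally:
        if handle is not dest:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(source) -> dict[str, str]:
    """Parse FASTA into ``{name: sequence}``; alphabet restricted to ACGTN
    (case-folded to upper)."""
    handle = _open_text(source)
    try:
        sequences: dict[str, str] = {}
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c not in _VALID_BASES)
                raise ParseError(
                    f"invalid base {seq[pos]!r} at position {pos} of sequence {record.id!r}"
                )
            sequences[record.id] = seq
        return sequences
    finally:
        if handle is not source:
            handle.close()


def write_fasta(sequences: dict[str, str], dest, width: int = 80) -> None:
    handle = _open_text(dest, "wt")
    try:
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
    finally:
        if handle is not dest:
            handle.close()


# ---------------------------------------------------------------------------
# count matrices


def parse_matrix_mtx(source, peak_ids=None, barcodes=None) -> CountMatrix:
    """Parse a MatrixMarket coordinate integer matrix (peaks x cells)."""
    handle = _open_text(source)
    try:
        try:
            mat = spio.mmread(handle)
        except ValueError as exc:
            raise ParseError(f"malformed MatrixMarket input: {exc}") from None
    finally:
        if handle is not source:
            handle.close()
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise ParseError("matrix entries must be nonnegative")
    n_peaks, n_cells = mat.shape
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(n_peaks)]
    if barcodes is None:
        barcodes = [f"cell_{i}" for i in range(n_cells)]
    return CountMatrix(mat, list(peak_ids), list(barcodes))


def write_matrix_mtx(cm: CountMatrix, dest) -> None:
    handle = _open_text(dest, "wb" if isinstance(dest, (str, Path)) else "wt")
    try:
        spio.mmwrite(handle, sp.coo_matrix(cm.matrix), field="integer")
    finally:
        if handle is not dest:
            handle.close()


def parse_matrix_tsv(source) -> CountMatrix:
    """Parse a dense TSV matrix: header row of barcodes, first column peak ids."""
    handle = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", index_col=0)
    finally:
        if handle is not source:
            handle.close()
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError("dense matrix contains non-numeric entries")
    if (values < 0).any():
        raise ParseError("matrix entries must be nonnegative")
    if not np.array_equal(values, np.round(values)):
        raise ParseError("matrix entries must be integers")
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_matrix_tsv(cm: CountMatrix, dest) -> None:
    df = pd.DataFrame(cm.dense(), index=cm.peak_ids, columns=cm.barcodes)
    handle = _open_text(dest, "wt")
    try:
        df.to_csv(handle, sep="\t")
    finally:
        if handle is not dest:
            handle.close()


# ---------------------------------------------------------------------------
# SNP tables

_SNP_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt", "trait"]


def parse_snp_table(source) -> pd.DataFrame:
    """Parse a TSV SNP table: chrom, pos (1-based), rsid, ref, alt, trait,
    with optional ``pvalue`` and ``block`` columns. Returns a DataFrame."""
    handle = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype={"chrom": str, "rsid": str})
    finally:
        if handle is not source:
            handle.close()
    missing = [c for c in _SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SNP table missing columns: {missing}")
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ParseError("SNP positions are 1-based and must be >= 1")
    for col in ("ref", "alt"):
        bad = ~df[col].isin(list("ACGT"))
        if bad.any():
            raise ParseError(f"invalid {col} allele: {df.loc[bad, col].iloc[0]!r}")
    if (df["ref"] == df["alt"]).any():
        raise ParseError("ref and alt alleles must differ")
    return df


def write_snp_table(df: pd.DataFrame, dest) -> None:
    handle = _open_text(dest, "wt")
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if handle is not dest:
            handle.close()
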