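"""Motif scanning: IUPAC degenerate consensus strings and log-odds PWMs.

Shared by peak classification (promoter M4 motif, CTCF motif fallback) and
allele-specific variant annotation (BLIMP1/PRDM1 creation next to STAT3).

Default motif set
-----------------
* ``m4`` -- the hyperconserved lymphocyte promoter motif ACTAYRnnnCCCR,
  a composite of RUNX (AACCACA), NF-Y (CCAAT) and ETS/IKZF1 (TCCCA)
  elements; used as the promoter classifier.
* ``stat3`` -- TTCCNGGAA.
* ``blimp1`` -- CTTTCT, the PRDM1 site created by the rs77291736-style
  C-to-T substitution.
* ``ctcf`` -- the 19-bp CTCF core consensus TGGCCACCAGGGGGCGCTA; a
  JASPAR-style position frequency matrix for the same factor is bundled
  as ``ctcf_pwm`` (log-odds vs uniform background, threshold at 80% of
  the maximum score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from regshift.core import GenomicInterval

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(sequence: str) -> str:
    """Reverse-complement an ACGTN (or degenerate IUPAC) sequence."""
    seq = sequence.upper()
    bad = set(seq) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A scannable motif: IUPAC consensus or log-odds PWM.

    ``matrix`` is 4 x L (rows A, C, G, T) of position log-odds versus the
    background; ``threshold`` is the minimum summed score for a PWM hit.
    """

    id: str
    kind: str  # "iupac" | "pwm"
    consensus: str | None = None
    matrix: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "iupac":
            if not self.consensus:
                raise ValueError(f"motif {self.id}: iupac motif needs a consensus")
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC_CODES)
            if bad:
                raise ValueError(
                    f"motif {self.id}: invalid IUPAC character(s) {sorted(bad)}"
                )
        elif self.kind == "pwm":
            if self.matrix is None or self.threshold is None:
                raise ValueError(f"motif {self.id}: pwm motif needs matrix and threshold")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape[0] != 4:
                raise ValueError(f"motif {self.id}: matrix must be 4 x L")
            if not np.isfinite(self.matrix).all():
                raise ValueError(f"motif {self.id}: matrix must be finite")
        else:
            raise ValueError(f"motif {self.id}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        if self.kind == "iupac":
            return len(self.consensus)
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        if self.kind != "pwm":
            raise ValueError("max_score is defined for PWM motifs only")
        return float(self.matrix.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    """A motif match in the scanned sequence's own coordinate frame."""

    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float = 1.0


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
    encoded = table[codes]
    if (encoded < 0).any():
        pos = int(np.argmax(encoded < 0))
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    return encoded


def _iupac_match_offsets(encoded: np.ndarray, consensus: str) -> np.ndarray:
    """Offsets where the degenerate consensus matches.

    A sequence N matches only a motif position that is itself N (an
    unknown base is not evidence for any specific-base requirement).
    """
    L = len(consensus)
    n = encoded.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    # allowed[b, j]: may sequence code b sit at motif position j?
    allowed = np.zeros((5, L), dtype=bool)
    for j, ch in enumerate(consensus):
        for base in IUPAC_CODES[ch]:
            allowed[_BASE_INDEX[base], j] = True
        allowed[4, j] = ch == "N"
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    ok = allowed[windows, np.arange(L)].all(axis=1)
    return np.flatnonzero(ok)


def scan_iupac(
    sequence: str,
    motif: Motif,
    both_strands: bool = True,
    seq_name: str = "seq",
) -> list[MotifHit]:
    """Find all (possibly overlapping) IUPAC-consensus matches.

    Minus-strand hits are found by scanning the reverse complement and
    mapping offsets back to the forward frame.
    """
    if motif.kind != "iupac":
        raise ValueError(f"motif {motif.id} is not an IUPAC motif")
    seq = sequence.upper()
    L = len(motif)
    if len(seq) < L:
        return []
    encoded = _encode(seq)
    hits = [
        MotifHit(motif.id, GenomicInterval(seq_name, int(i), int(i) + L), "+")
        for i in _iupac_match_offsets(encoded, motif.consensus)
    ]
    if both_strands:
        rc_encoded = _encode(reverse_complement(seq))
        n = len(seq)
        for i in _iupac_match_offsets(rc_encoded, motif.consensus):
            start = n - int(i) - L
            hits.append(MotifHit(motif.id, GenomicInterval(seq_name, start, start + L), "-"))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def _pwm_hit_offsets(encoded: np.ndarray, motif: Motif) -> tuple[np.ndarray, np.ndarray]:
    L = len(motif)
    n = encoded.size
    if n < L:
        return np.empty(0, dtype=np.int64), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = motif.matrix[safe, np.arange(L)].sum(axis=1)
    ok = (~has_n) & (scores >= motif.threshold)
    return np.flatnonzero(ok), scores[ok]


def scan_pwm(
    sequence: str,
    motif: Motif,
    both_strands: bool = True,
    seq_name: str = "seq",
) -> list[MotifHit]:
    """Find windows whose summed log-odds reaches the motif threshold.

    Windows containing N are skipped.
    """
    if motif.kind != "pwm":
        raise ValueError(f"motif {motif.id} is not a PWM motif")
    seq = sequence.upper()
    L = len(motif)
    if len(seq) < L:
        return []
    encoded = _encode(seq)
    offsets, scores = _pwm_hit_offsets(encoded, motif)
    hits = [
        MotifHit(motif.id, GenomicInterval(seq_name, int(i), int(i) + L), "+", float(s))
        for i, s in zip(offsets, scores)
    ]
    if both_strands:
        n = len(seq)
        rc_encoded = _encode(reverse_complement(seq))
        offsets, scores = _pwm_hit_offsets(rc_encoded, motif)
        for i, s in zip(offsets, scores):
            start = n - int(i) - L
            hits.append(
                MotifHit(motif.id, GenomicInterval(seq_name, start, start + L), "-", float(s))
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan(sequence: str, motif: Motif, both_strands: bool = True, seq_name: str = "seq") -> list[MotifHit]:
    """Dispatch on motif kind."""
    if motif.kind == "iupac":
        return scan_iupac(sequence, motif, both_strands, seq_name)
    return scan_pwm(sequence, motif, both_strands, seq_name)


# ---------------------------------------------------------------------------
# bundled motifs

# CTCF core position frequency matrix (19 positions, JASPAR-style counts).
_CTCF_PFM = np.array(
    [
        [87, 167, 281, 56, 8, 744, 40, 107, 851, 5, 333, 54, 12, 56, 104, 372, 82, 117, 402],
        [291, 145, 49, 800, 903, 13, 528, 433, 11, 0, 3, 12, 0, 8, 733, 13, 482, 322, 181],
        [76, 414, 449, 21, 0, 65, 334, 48, 32, 903, 566, 504, 890, 775, 5, 507, 307, 73, 266],
        [459, 187, 134, 36, 2, 91, 11, 324, 18, 3, 9, 341, 8, 71, 67, 17, 37, 396, 59],
    ],
    dtype=float,
)

CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"


def pfm_to_pwm(
    pfm: np.ndarray,
    motif_id: str,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
    threshold_fraction: float = 0.8,
) -> Motif:
    """Convert a position frequency matrix to a log2-odds PWM motif.

    Background defaults to uniform 0.25.  The hit threshold is set at
    ``threshold_fraction`` of the maximum achievable score.
    """
    pfm = np.asarray(pfm, dtype=float)
    if background is None:
        background = np.full(4, 0.25)
    probs = (pfm + pseudocount / 4) / (pfm.sum(axis=0) + pseudocount)
    matrix = np.log2(probs / background[:, None])
    max_score = float(matrix.max(axis=0).sum())
    return Motif(motif_id, "pwm", matrix=matrix, threshold=threshold_fraction * max_score)


def default_motifs() -> dict[str, Motif]:
    """The bundled motif set used throughout the pipeline."""
    return {
        "m4": Motif("m4", "iupac", consensus="ACTAYRNNNCCCR"),
        "stat3": Motif("stat3", "iupac", consensus="TTCCNGGAA"),
        "blimp1": Motif("blimp1", "iupac", consensus="CTTTCT"),
        "ctcf": Motif("ctcf", "iupac", consensus=CTCF_CONSENSUS),
        "ctcf_pwm": pfm_to_pwm(_CTCF_PFM, "ctcf_pwm"),
    }


# ---------------------------------------------------------------------------
# motif file loading


def load_iupac_motifs(source) -> dict[str, Motif]:
    """Load IUPAC motifs from a two-column TSV (id, consensus)."""
    from regshift.io import _iter_lines

    out: dict[str, Motif] = {}
    for lineno, line in _iter_lines(source):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 'id<TAB>consensus'")
        out[fields[0]] = Motif(fields[0], "iupac", consensus=fields[1])
    return out


def load_jaspar_pfms(source, threshold_fraction: float = 0.8) -> dict[str, Motif]:
    """Load JASPAR-format PFMs and convert to log-odds PWMs at load time."""
    from regshift.io import _open_text

    handle = _open_text(source)
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
    finally:
        if handle is not source:
            handle.close()
    out: dict[str, Motif] = {}
    for m in parsed:
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        motif_id = m.matrix_id or m.name
        out[motif_id] = pfm_to_pwm(pfm, motif_id, threshold_fraction=threshold_fraction)
    return out
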