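"""Peak compartmentalization: promoter / CTCF-distal / DRE.

The workflow separates promoter peaks from all non-promoter peaks first,
then splits the non-promoter peaks on CTCF evidence; what remains is the
distal-regulatory-element (DRE) compartment:

* **promoter** -- the peak overlaps a TSS window (default +/- 2 kb) or
  contains the hyperconserved M4 promoter motif;
* **ctcf_distal** -- otherwise, the peak overlaps a supplied CTCF ChIP
  interval, or (absent interval evidence) contains a CTCF motif hit;
* **dre** -- everything else.

Precedence is promoter > ctcf_distal > dre, so the three compartments
partition the peak set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from regshift.core import GenomicInterval
from regshift.motifs import Motif, scan

PROMOTER = "promoter"
CTCF_DISTAL = "ctcf_distal"
DRE = "dre"
UNASSIGNED = "unassigned"

COMPARTMENTS = (PROMOTER, CTCF_DISTAL, DRE)


@dataclass
class Peak:
    """An accessibility peak with its regulatory compartment label."""

    id: str
    interval: GenomicInterval
    compartment: str = UNASSIGNED
    evidence: set[str] = field(default_factory=set)


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` where ``a[i]`` and ``b[j]`` share >= 1 bp.

    Half-open arithmetic: ``[0, 10)`` and ``[10, 20)`` do not overlap.
    Output is sorted by ``(i, j)``.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(b):
        trees[iv.chrom].addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        pairs.extend((i, hit.data) for hit in tree.overlap(iv.start, iv.end))
    pairs.sort()
    return pairs


def peak_sequence(sequences: dict[str, str], interval: GenomicInterval) -> str | None:
    """Extract a peak's sequence from contig sequences; None if unavailable."""
    contig = sequences.get(interval.chrom)
    if contig is None or len(contig) < interval.end:
        return None
    return contig[interval.start : interval.end]


def classify_peaks(
    peaks: Sequence[Peak],
    tss: Sequence[GenomicInterval],
    sequences: dict[str, str] | None,
    m4: Motif,
    ctcf_evidence: Sequence[GenomicInterval] | Motif | None,
    tss_window_bp: int = 2000,
) -> list[Peak]:
    """Assign each peak to promoter, ctcf_distal or dre (in place).

    ``ctcf_evidence`` is preferably a list of CTCF ChIP peak intervals;
    a CTCF motif may be supplied instead for fully sequence-based runs.
    Sequence-based evidence (M4, CTCF motif) requires every peak's
    sequence to be retrievable from ``sequences``.
    """
    tss_windows = [
        GenomicInterval(t.chrom, max(0, t.start - tss_window_bp), t.end + tss_window_bp)
        for t in tss
    ]
    tss_hits = {i for i, _ in intersect([p.interval for p in peaks], tss_windows)}

    ctcf_overlap_hits: set[int] = set()
    ctcf_motif: Motif | None = None
    if isinstance(ctcf_evidence, Motif):
        ctcf_motif = ctcf_evidence
    elif ctcf_evidence is not None:
        ctcf_overlap_hits = {
            i for i, _ in intersect([p.interval for p in peaks], list(ctcf_evidence))
        }

    need_sequence = m4 is not None or ctcf_motif is not None
    missing: list[str] = []
    seqs: dict[int, str] = {}
    if need_sequence:
        for i, peak in enumerate(peaks):
            seq = peak_sequence(sequences or {}, peak.interval)
            if seq is None:
                missing.append(peak.id)
            else:
                seqs[i] = seq
        if missing:
            raise ValueError(
                f"no sequence retrievable for {len(missing)} peak(s): {missing[:10]}"
            )

    for i, peak in enumerate(peaks):
        evidence: set[str] = set()
        if i in tss_hits:
            evidence.add("tss_overlap")
        if m4 is not None and scan(seqs[i], m4):
            evidence.add("m4_hit")
        if evidence:
            peak.compartment = PROMOTER
            peak.evidence = evidence
            continue
        if i in ctcf_overlap_hits:
            evidence.add("ctcf_peak_overlap")
        elif ctcf_motif is not None and scan(seqs[i], ctcf_motif):
            evidence.add("ctcf_motif_hit")
        peak.compartment = CTCF_DISTAL if evidence else DRE
        peak.evidence = evidence
    return list(peaks)
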