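"""Trait-annotated SNPs: peak overlap and allele-specific motif deltas.

A regulatory SNP can create or destroy a transcription-factor binding
site: substituting the alternate allele into the reference sequence
context may add or remove motif matches whose footprint covers the SNP.
The canonical example modelled here is a C-to-T substitution turning the
context ``CCTTCT`` into a BLIMP1/PRDM1 site ``CTTTCT`` immediately next
to an (unchanged) STAT3 site -- only hits covering the SNP position count
toward the delta; adjacent intact hits are reported as context.

Traits are segregated into immune / psychological / other categories by
case-insensitive keyword matching, with immune taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from regshift.motifs import Motif, scan
from regshift.peaks import Peak

IMMUNE = "immune"
PSYCHOLOGICAL = "psychological"
OTHER = "other"

DEFAULT_IMMUNE_KEYWORDS = (
    "immune",
    "immun",
    "lymphocyte",
    "monocyte",
    "neutrophil",
    "eosinophil",
    "basophil",
    "leukocyte",
    "white blood cell",
    "nk cell",
    "natural killer",
    "t cell",
    "b cell",
    "cd56",
    "allerg",
    "asthma",
    "arthritis",
    "lupus",
    "celiac",
    "crohn",
    "colitis",
    "psoriasis",
    "multiple sclerosis",
    "inflammat",
)

DEFAULT_PSYCH_KEYWORDS = (
    "depress",
    "schizophren",
    "bipolar",
    "anxiety",
    "addiction",
    "autism",
    "adhd",
    "neurotic",
    "psychiatric",
    "psycholog",
    "mood",
    "alcohol dependence",
    "smoking",
    "insomnia",
    "intelligence",
    "educational attainment",
)


@dataclass(frozen=True)
class AlleleMotifDelta:
    """Per-(SNP, motif) record of covering-hit changes between alleles."""

    rsid: str
    motif_id: str
    status: str  # gained | lost | unchanged
    ref_hits: int
    alt_hits: int
    context_hits: int = 0  # window hits not covering the SNP (ref allele)
    containing_peak: str | None = None


def categorize_traits(
    snps: pd.DataFrame,
    immune_keywords: Sequence[str] = DEFAULT_IMMUNE_KEYWORDS,
    psych_keywords: Sequence[str] = DEFAULT_PSYCH_KEYWORDS,
) -> pd.DataFrame:
    """Assign each SNP a trait category by keyword substring match.

    Matching is case-insensitive; an immune keyword wins over a
    psychological one; traits matching neither list are ``other``.
    """
    if not immune_keywords or not psych_keywords:
        raise ValueError("keyword lists must be non-empty")
    immune = [k.lower() for k in immune_keywords]
    psych = [k.lower() for k in psych_keywords]

    def categorize(trait: str) -> str:
        t = str(trait).lower()
        if any(k in t for k in immune):
            return IMMUNE
        if any(k in t for k in psych):
            return PSYCHOLOGICAL
        return OTHER

    out = snps.copy()
    out["category"] = out["trait"].map(categorize)
    return out


def snps_in_peaks(snps: pd.DataFrame, peaks: Sequence[Peak]) -> dict[str, str | None]:
    """Map each rsid to its containing peak id (or None).

    A SNP at 1-based position p lies in half-open peak [s, e) iff
    s <= p-1 < e.  If several peaks contain it, the smallest wins; ties
    go to the leftmost.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out: dict[str, str | None] = {}
    for row in snps.itertuples(index=False):
        pos0 = int(row.pos) - 1
        candidates = [
            p
            for p in by_chrom.get(str(row.chrom), [])
            if p.interval.start <= pos0 < p.interval.end
        ]
        if candidates:
            best = min(candidates, key=lambda p: (len(p.interval), p.interval.start))
            out[str(row.rsid)] = best.id
        else:
            out[str(row.rsid)] = None
    return out


def _covering_hits(sequence: str, motif: Motif, offset: int) -> tuple[int, int]:
    """(covering, non-covering) hit counts around position ``offset``."""
    covering = 0
    context = 0
    for hit in scan(sequence, motif, both_strands=True):
        if hit.interval.start <= offset < hit.interval.end:
            covering += 1
        else:
            context += 1
    return covering, context


def allele_motif_delta(
    snp,
    sequences: Mapping[str, str],
    motifs: Mapping[str, Motif],
    window_bp: int = 30,
    containing_peak: str | None = None,
) -> list[AlleleMotifDelta]:
    """Score motif creation/disruption for one SNP.

    ``snp`` needs fields chrom, pos (1-based), rsid, ref, alt.  The
    +/- ``window_bp`` context around the SNP is extracted, the reference
    base is verified against ``ref``, the alternate allele is substituted,
    and every motif is scanned on both strands of both haplotypes.  Only
    hits whose footprint covers the SNP position count toward the delta.
    """
    chrom, pos, rsid = str(snp.chrom), int(snp.pos), str(snp.rsid)
    ref, alt = str(snp.ref).upper(), str(snp.alt).upper()
    contig = sequences.get(chrom)
    if contig is None:
        raise ValueError(f"{rsid}: no sequence for contig {chrom!r}")
    pos0 = pos - 1
    if not 0 <= pos0 < len(contig):
        raise ValueError(f"{rsid}: position {pos} outside contig {chrom!r}")
    if contig[pos0].upper() != ref:
        raise ValueError(
            f"{rsid}: reference base mismatch at {chrom}:{pos} "
            f"(genome has {contig[pos0]!r}, SNP table says {ref!r})"
        )
    longest = max(len(m) for m in motifs.values())
    if window_bp < longest:
        raise ValueError(
            f"window_bp {window_bp} is smaller than the longest motif ({longest})"
        )
    lo = max(0, pos0 - window_bp)
    hi = min(len(contig), pos0 + window_bp + 1)
    offset = pos0 - lo
    ref_seq = contig[lo:hi].upper()
    alt_seq = ref_seq[:offset] + alt + ref_seq[offset + 1 :]

    out: list[AlleleMotifDelta] = []
    for motif in motifs.values():
        ref_hits, context = _covering_hits(ref_seq, motif, offset)
        alt_hits, _ = _covering_hits(alt_seq, motif, offset)
        if alt_hits > ref_hits:
            status = "gained"
        elif alt_hits < ref_hits:
            status = "lost"
        else:
            status = "unchanged"
        out.append(
            AlleleMotifDelta(
                rsid=rsid,
                motif_id=motif.id,
                status=status,
                ref_hits=ref_hits,
                alt_hits=alt_hits,
                context_hits=context,
                containing_peak=containing_peak,
            )
        )
    return out


def allele_motif_deltas(
    snps: pd.DataFrame,
    sequences: Mapping[str, str],
    motifs: Mapping[str, Motif],
    peaks: Sequence[Peak] = (),
    window_bp: int = 30,
) -> pd.DataFrame:
    """Run :func:`allele_motif_delta` over a SNP table; tabular output."""
    peak_of = snps_in_peaks(snps, peaks) if len(peaks) else {}
    rows = []
    for snp in snps.itertuples(index=False):
        for delta in allele_motif_delta(
            snp, sequences, motifs, window_bp, containing_peak=peak_of.get(str(snp.rsid))
        ):
            rows.append(delta.__dict__)
    return pd.DataFrame(rows)


def best_snp_per_block(snps: pd.DataFrame) -> pd.DataFrame:
    """Collapse linkage blocks to their most significant SNP.

    Requires ``block`` and ``pvalue`` columns; within each block the row
    with the smallest p-value is kept (ties: first occurrence).
    """
    for col in ("block", "pvalue"):
        if col not in snps.columns:
            raise ValueError(f"SNP table needs a {col!r} column for block collapsing")
    idx = snps.groupby("block", sort=False)["pvalue"].idxmin()
    return snps.loc[sorted(idx)].reset_index(drop=True)
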