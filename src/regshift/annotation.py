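"""Minimal curated GRCh38 gene annotation for locus arithmetic.

Only the handful of genes the NK-cell analysis refers to are bundled
(transcription start sites from the Ensembl GRCh38 gene builds); for
anything larger, supply your own annotation as BED.
"""

from __future__ import annotations

from regshift.core import GenomicInterval
from regshift.io import parse_region

#: gene -> (chrom, 0-based TSS position, strand), GRCh38
GRCH38_TSS: dict[str, tuple[str, int, str]] = {
    # NCAM1 encodes CD56; + strand, gene start = TSS
    "NCAM1": ("chr11", 112961247, "+"),
    # KIR2DL1 on the KIR cluster, chromosome 19
    "KIR2DL1": ("chr19", 54771247, "+"),
}

#: the NCAM1 distal regulatory element as printed (1-based inclusive)
NCAM1_DRE_REGION = "chr11:112,879,032-112,879,132"
#: matched inaccessible control region used in reporter assays
NCAM1_CONTROL_REGION = "chr11:112,942,615-112,942,714"


def ncam1_dre_interval() -> GenomicInterval:
    """The NCAM1 DRE converted to half-open coordinates (length 101 bp)."""
    return parse_region(NCAM1_DRE_REGION, one_based_inclusive=True)


def distance_to_tss_kb(interval: GenomicInterval, gene: str) -> float:
    """Distance from an interval's midpoint to a bundled gene TSS, in kb."""
    chrom, tss, _ = GRCH38_TSS[gene]
    if interval.chrom != chrom:
        raise ValueError(f"{gene} is on {chrom}, interval is on {interval.chrom}")
    return abs(tss - interval.midpoint) / 1000.0
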