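"""Distance-constrained co-accessibility and loop-support annotation.

Single-cell accessibility is too sparse for per-cell correlation, so
cells are pooled into metacells and each peak's profile is the fraction
of pool members with a nonzero count.  Co-accessibility between two
same-chromosome peaks within a distance window is then the Pearson
correlation of their pooled profiles.

This is a deliberate simplification of graphical-model co-accessibility
(cicero-style): plain distance-constrained correlation has no tunable
regularisation path, and candidate links are meant to be validated
orthogonally against Hi-C loops (:func:`annotate_links`) rather than
trusted on their own.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regshift.core import CountMatrix, GenomicInterval, LoopRecord
from regshift.peaks import DRE, PROMOTER, Peak

DEFAULT_MAX_DIST_BP = 500_000
#: figure presets for the score cutoff
CUTOFF_PRESETS = {"default": 0.05, "locus": 0.05, "cluster": 0.25}


def binarize_and_pool(
    matrix: CountMatrix,
    pool_size: int,
    seed: int | np.random.Generator = 0,
    labels: Sequence[int] | None = None,
) -> np.ndarray:
    """Pool cells into metacells of ``pool_size``; entries are the
    fraction of pool members with count > 0.

    Cells are partitioned at random under ``seed`` unless explicit pool
    ``labels`` (one int per cell) are given.  A trailing remainder that
    cannot fill a pool is dropped.  Returns peaks x n_pools.
    """
    n_peaks, n_cells = matrix.shape
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size > n_cells:
        raise ValueError(f"pool_size {pool_size} exceeds {n_cells} cells")
    binary = (matrix.matrix > 0).astype(np.float64)
    if labels is not None:
        labels = np.asarray(labels)
        pools = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = rng.permutation(n_cells)
        n_pools = n_cells // pool_size
        pools = [order[k * pool_size : (k + 1) * pool_size] for k in range(n_pools)]
    pooled = np.empty((n_peaks, len(pools)))
    dense = np.asarray(binary.todense())
    for k, members in enumerate(pools):
        pooled[:, k] = dense[:, members].mean(axis=1)
    return pooled


def coaccessibility(
    pooled: np.ndarray,
    peaks: Sequence[Peak],
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Score all same-chromosome peak pairs within ``max_dist_bp``.

    The score is the Pearson correlation of pooled profiles; pairs with
    a zero-variance profile on either side get score 0 and are flagged
    (``zero_variance``).  Returns a DataFrame with columns ``peak_a``,
    ``peak_b`` (a precedes b by coordinate), ``score``, ``distance_bp``,
    ``passes_cutoff`` and ``zero_variance``.
    """
    if pooled.shape[0] != len(peaks):
        raise ValueError("pooled matrix rows must match the peak list")
    centered = pooled - pooled.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_var = norms == 0
    unit = centered / np.where(zero_var, 1.0, norms)[:, None]

    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.interval.chrom, []).append(i)

    rows: list[dict] = []
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda i: peaks[i].interval.start)
        mids = np.array([peaks[i].interval.midpoint for i in idx])
        for a_pos, i in enumerate(idx):
            hi = int(np.searchsorted(mids, mids[a_pos] + max_dist_bp, side="right"))
            partners = idx[a_pos + 1 : hi]
            if not partners:
                continue
            scores = unit[partners] @ unit[i]
            for j, score in zip(partners, scores):
                zv = bool(zero_var[i] or zero_var[j])
                s = 0.0 if zv else float(np.clip(score, -1.0, 1.0))
                rows.append(
                    {
                        "peak_a": peaks[i].id,
                        "peak_b": peaks[j].id,
                        "score": s,
                        "distance_bp": int(
                            abs(peaks[j].interval.midpoint - peaks[i].interval.midpoint)
                        ),
                        "passes_cutoff": s > cutoff,
                        "zero_variance": zv,
                    }
                )
    return pd.DataFrame(
        rows, columns=["peak_a", "peak_b", "score", "distance_bp", "passes_cutoff", "zero_variance"]
    )


def _near(peak: GenomicInterval, anchor: GenomicInterval, tol: int) -> bool:
    if peak.chrom != anchor.chrom:
        return False
    return peak.start < anchor.end + tol and anchor.start - tol < peak.end


def annotate_links(
    pairs: pd.DataFrame,
    peak_compartments: Mapping[str, str],
    peak_intervals: Mapping[str, GenomicInterval],
    loops: Sequence[LoopRecord],
    anchor_tolerance_bp: int = 10_000,
) -> pd.DataFrame:
    """Annotate scored pairs with DRE-promoter status and Hi-C loop support.

    ``loop_supported`` requires the two peaks to fall within
    ``anchor_tolerance_bp`` of the two anchors of the *same* loop, in
    either orientation.
    """
    out = pairs.copy()
    d2p = []
    supported = []
    for _, row in out.iterrows():
        ca = peak_compartments.get(row["peak_a"], "unassigned")
        cb = peak_compartments.get(row["peak_b"], "unassigned")
        d2p.append({ca, cb} == {DRE, PROMOTER})
        iva = peak_intervals[row["peak_a"]]
        ivb = peak_intervals[row["peak_b"]]
        hit = False
        for loop in loops:
            if (
                _near(iva, loop.anchor_a, anchor_tolerance_bp)
                and _near(ivb, loop.anchor_b, anchor_tolerance_bp)
            ) or (
                _near(iva, loop.anchor_b, anchor_tolerance_bp)
                and _near(ivb, loop.anchor_a, anchor_tolerance_bp)
            ):
                hit = True
                break
        supported.append(hit)
    out["dre_to_promoter"] = d2p
    out["loop_supported"] = supported
    return out
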