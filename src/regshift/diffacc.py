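"""Compartment-stratified differential accessibility.

Two modes are provided on donor-level pseudobulk counts:

* **raw** -- log2(count + pseudocount) per replicate, two-sample t-test
  across donors, fold change = difference of means of logs.  No
  between-sample normalization is applied, so a genuine global shift in
  accessibility (e.g. a broad loss at distal regulatory elements) is
  reported as such.
* **centered** -- identical, except counts are first divided by
  median-of-ratios size factors.  This comparator assumes the average
  fold change between samples is zero; when most peaks truly shift, the
  assumption fails and fold changes are redistributed: the shifted
  compartment is attenuated toward zero and unshifted compartments pick
  up a spurious opposite-signed bias.

The per-compartment summary (:func:`compartment_shift`) is the pipeline's
headline output: mean/sd of log2 fold change per compartment with a
one-sample test against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regshift.core import CountMatrix

RAW = "raw"
CENTERED = "centered"


@dataclass
class PseudobulkTable:
    """Peaks x groups summed counts with a group -> subset mapping.

    ``counts`` is indexed by peak id; columns are group labels (one per
    subset x donor).  ``subset_of`` maps each column to its subset.
    """

    counts: pd.DataFrame
    subset_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pseudobulk counts must be nonnegative")
        unknown = [c for c in self.counts.columns if c not in self.subset_of]
        if self.subset_of and unknown:
            raise ValueError(f"groups without a subset label: {unknown}")

    def columns_for(self, subset: str) -> list[str]:
        return [g for g in self.counts.columns if self.subset_of.get(g) == subset]


def pseudobulk(matrix: CountMatrix, cell_groups: Mapping[str, str]) -> PseudobulkTable:
    """Sum single-cell counts into per-group columns.

    ``cell_groups`` maps barcode -> group label (typically
    ``subset:donor``).  Every barcode in the matrix must be assigned.
    Total count mass is conserved.
    """
    unassigned = [bc for bc in matrix.barcodes if bc not in cell_groups]
    if unassigned:
        raise ValueError(
            f"{len(unassigned)} barcode(s) have no group assignment: {unassigned[:5]}"
        )
    groups = sorted({cell_groups[bc] for bc in matrix.barcodes})
    group_index = {g: k for k, g in enumerate(groups)}
    col_group = np.array([group_index[cell_groups[bc]] for bc in matrix.barcodes])
    # cells x groups indicator, so peaks x cells @ cells x groups sums per group
    indicator = sp.csr_matrix(
        (np.ones(len(col_group)), (np.arange(len(col_group)), col_group)),
        shape=(len(col_group), len(groups)),
    )
    summed = np.asarray((matrix.matrix @ indicator).todense())
    counts = pd.DataFrame(summed.astype(np.int64), index=matrix.peak_ids, columns=groups)
    subset_of = {}
    if "subset" in matrix.obs.columns:
        for bc in matrix.barcodes:
            subset_of[cell_groups[bc]] = str(matrix.obs.loc[bc, "subset"])
    return PseudobulkTable(counts, subset_of)


def size_factors_median_of_ratios(table: PseudobulkTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each peak nonzero in every group, the ratio of its count to its
    per-peak geometric mean is taken; a group's factor is the median of
    those ratios.  Requires at least one all-nonzero peak.
    """
    counts = table.counts if isinstance(table, PseudobulkTable) else table
    values = counts.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no peak has nonzero counts in all groups")
    used = values[usable]
    geomean = np.exp(np.log(used).mean(axis=1))
    factors = np.median(used / geomean[:, None], axis=0)
    factors /= np.exp(np.log(factors).mean())  # rescale to geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def diff_test(
    table: PseudobulkTable,
    subset_a: str,
    subset_b: str,
    mode: str = RAW,
    pseudocount: float = 1.0,
    min_mean: float = 5.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-peak differential accessibility, subset_b versus subset_a.

    Returns a DataFrame indexed by peak id with columns ``log2fc``
    (mean of log2-transformed replicate values, b minus a), ``t_stat``,
    ``p_value``, ``q_value`` (Benjamini-Hochberg over tested peaks) and
    ``mode``.  Peaks whose mean raw count is below ``min_mean`` in both
    subsets are excluded.  The default is the pooled-variance Student's
    t-test, which is well calibrated at the typical 3-donors-per-subset
    design; pass ``equal_var=False`` for Welch's unequal-variance variant.
    """
    if mode not in (RAW, CENTERED):
        raise ValueError(f"mode must be '{RAW}' or '{CENTERED}', got {mode!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    cols_a = table.columns_for(subset_a)
    cols_b = table.columns_for(subset_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >=2 replicates per subset, got {len(cols_a)} for {subset_a!r} "
            f"and {len(cols_b)} for {subset_b!r}"
        )
    raw_a = table.counts[cols_a].to_numpy(dtype=float)
    raw_b = table.counts[cols_b].to_numpy(dtype=float)
    keep = (raw_a.mean(axis=1) >= min_mean) | (raw_b.mean(axis=1) >= min_mean)

    if mode == CENTERED:
        factors = size_factors_median_of_ratios(table)
        norm_a = raw_a / factors[cols_a].to_numpy()
        norm_b = raw_b / factors[cols_b].to_numpy()
    else:
        norm_a, norm_b = raw_a, raw_b

    log_a = np.log2(norm_a[keep] + pseudocount)
    log_b = np.log2(norm_b[keep] + pseudocount)
    log2fc = log_b.mean(axis=1) - log_a.mean(axis=1)

    with warnings.catch_warnings():
        # near-identical replicate values trip scipy's precision-loss
        # warning; the degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(log_b, log_a, axis=1, equal_var=equal_var)
    # both groups constant and equal: no evidence of difference
    degenerate = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0) & (log2fc == 0)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)
    p_value = np.clip(p_value, np.finfo(float).tiny, 1.0)
    q_value = multipletests(p_value, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "mode": mode,
        },
        index=pd.Index(np.asarray(table.counts.index)[keep], name="peak_id"),
    )


def compartment_shift(
    results: pd.DataFrame, classes: Mapping[str, str]
) -> pd.DataFrame:
    """Summarise per-peak fold changes by compartment.

    Returns one row per (non-empty) compartment: ``mean_log2fc``, ``sd``,
    ``n_peaks`` and a one-sample t-test p-value for mean != 0.
    """
    compartments = pd.Series(
        [classes.get(p, "unassigned") for p in results.index], index=results.index
    )
    rows = []
    for compartment, group in results.groupby(compartments):
        fc = group["log2fc"].to_numpy()
        if fc.size == 0:
            continue
        if fc.size > 1 and fc.std(ddof=1) > 0:
            _, p = stats.ttest_1samp(fc, 0.0)
        else:
            p = 1.0 if fc.size and fc[0] == 0 else np.nan
        rows.append(
            {
                "compartment": compartment,
                "mean_log2fc": fc.mean(),
                "sd": fc.std(ddof=1) if fc.size > 1 else 0.0,
                "n_peaks": fc.size,
                "one_sample_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("compartment")
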