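# Methods

This note documents the models, parameter choices and numerical
conventions behind `regshift`, and what the synthetic-data experiments
do and do not demonstrate about real data.

## Coordinates

All internal coordinates are 0-based half-open (BED convention).
Conversion from 1-based inclusive ranges (browser/publication style,
`parse_region(..., one_based_inclusive=True)`) and from 1-based SNP
positions (VCF convention, `pos − 1`) happens exactly once, at parse
time. Chromosome names are matched strictly; no silent `chr`-prefix
reconciliation is attempted. The NCAM1 DRE printed as
chr11:112,879,032–112,879,132 is 101 bp under 1-based inclusive
arithmetic; the companion control region (112,942,615–112,942,714) is
100 bp though described as 101 bp — the discrepancy is recorded here and
left unresolved, and the control region is not used in any computation.
The bundled GRCh38 TSS lookup (`annotation.py`) carries only the genes
the analysis names; the NCAM1 entry (112,961,247, + strand) puts the DRE
midpoint 82.2 kb upstream, matching the quoted 82 kb.

## Per-cell QC

Metrics are computed per barcode after collapsing duplicate
(chrom, start, end, barcode) tuples.

- **TSS enrichment**: both fragment ends are assigned to the nearest TSS;
  the metric is the mean end coverage across the ±1000 bp window divided
  by the mean over the outermost 100 bp on each side. A uniform-coverage
  cell scores ≈ 1. Nearest-TSS assignment is exact when TSS windows do
  not overlap (true of the synthetic genome, where TSSs are ≥ 3 kb
  apart) and a mild approximation otherwise. A cell with window signal
  but zero flank ends gets +inf (passes); zero window signal gives 0
  (fails).
- **Nucleosome signal**: (# fragments 147–294 bp) / (# fragments
  < 147 bp); zero denominator → +inf sentinel, which fails the filter.
- **Blacklist ratio**: fraction of the cell's fragments overlapping any
  blacklist interval by ≥ 1 bp.
- Thresholds (keep iff TSS enrichment > 2, nucleosome signal < 4,
  blacklist ratio < 0.05, unique fragments > 200) are read as strict
  inequalities, so a cell with exactly 200 unique fragments is removed.
  A contig-/peak-width filter ("peaks under 3 kb") exists as a
  configurable option but is off by default: the intent of that rule is
  ambiguous and silently guessing would be worse than documenting it.

## Peak compartments

Precedence promoter > ctcf_distal > dre makes the three compartments a
partition. Promoter = TSS ± 2 kb overlap OR ≥ 1 M4 consensus hit
(`ACTAYRnnnCCCR`); M4 alone under-calls promoters that lack the
hyperconserved motif, hence the window. CTCF evidence prefers supplied
ChIP intervals (≥ 1 bp overlap) and falls back to the bundled 19-column
CTCF position-weight matrix (log2-odds against a uniform background,
pseudocount 0.8, hit threshold at 80% of the maximum score) for fully
sequence-based runs. Overlap is ≥ 1 bp with no reciprocal-fraction
requirement.

## Motif scanning

IUPAC consensus scanning reports all (overlapping) hits on both strands;
minus-strand hits are found on the reverse complement and mapped back.
An `N` in the sequence matches only a motif position that is itself `N`
— an unknown base is never treated as evidence for a specific-base
requirement. PWM scanning sums per-position log-odds and skips windows
containing `N`. The BLIMP1/PRDM1 site is encoded as the fixed consensus
`CTTTCT` (the created-allele form); STAT3 as `TTCCNGGAA`. Scanning is
case-insensitive.

## Differential accessibility

Counts are summed to donor-level pseudobulk columns (subset × donor).
Per peak, replicate values are `log2(count + 1)` (pseudocount 1,
configurable); in `centered` mode counts are first divided by
median-of-ratios size factors computed over all columns of the table and
rescaled to geometric mean 1 (the median is taken in ratio space).
`log2FC` is the difference of replicate means on the log scale, matching
the t-test's scale. The default test is the pooled-variance Student's
t-test: with three donors per subset and a shared noise model it is well
calibrated (empirical type-I error ≈ 0.05 at α = 0.05 over ≥ 2000 null
peaks), whereas Welch's variant is mildly conservative (≈ 0.035) at this
replicate count; Welch remains available (`equal_var=False`). Peaks with
mean raw pseudobulk count < 5 in both subsets are excluded before
testing; BH q-values are computed over tested peaks, with raw p-values
reported alongside. Degenerate peaks (zero variance in both groups,
equal means) get t = 0, p = 1.

The compartment-shift summary reports mean, SD and a one-sample t-test
of mean ≠ 0 per compartment. The masking effect has a simple closed
form: if a fraction f > 0.5 of all peaks shifts by δ and the rest are
static, the median ratio sits inside the shifted block, the size factors
absorb ≈ δ, and centered fold changes are displaced by ≈ −δ — the
shifted compartment is driven toward 0 and static compartments toward
−δ. At the default study scale (1400 of 2600 peaks shifted by −1) the
centered DRE mean is ≈ 0 and the promoter mean is inflated from +0.2 to
≈ +0.88.

## Co-accessibility

Cells are pooled into metacells (random partition under a seed, default
pool size 10, remainder dropped); a pooled entry is the fraction of pool
members with a nonzero count. For every same-chromosome pair with
midpoint distance ≤ 500 kb the score is the Pearson correlation of
pooled profiles; zero-variance profiles score 0 with a flag rather than
NaN. This deliberately replaces graphical-lasso co-accessibility
(cicero-style) with plain distance-constrained correlation: regularised
models are sensitive to algorithm settings, and candidate links are
meant to be validated orthogonally against Hi-C loops rather than
trusted on their own. Score cutoffs 0.05 (locus browsing) and 0.25
(cluster-scale) mirror common practice. Loop support requires both peaks
of a pair to lie within 10 kb (Hi-C bin scale) of the two anchors of the
same loop, in either orientation.

Pooling preserves the expected pairwise correlation (pool means of
i.i.d. cells correlate like the cells themselves), so a pair planted at
binarized correlation ρ scores ≈ ρ at either resolution; with 200
metacells the null correlation SD is ≈ 1/√200 ≈ 0.07, which is why the
0.25 cutoff passes < 1% of null pairs.

## Variant motif deltas

For each SNP a ±30 bp window (configurable; must exceed the longest
motif) is extracted, the reference base is verified against the genome,
and both haplotypes are scanned with every motif on both strands. Only
hits whose footprint covers the SNP position count toward
gained/lost/unchanged; adjacent intact hits are reported as context —
this is what distinguishes a created BLIMP1 site from the neighbouring
untouched STAT3 site. Deltas are antisymmetric under ref/alt swap and
invariant to window size beyond motif length. Indels are out of scope.
Trait categorisation is case-insensitive substring matching against
user-overridable immune and psychological keyword lists, immune taking
precedence; linkage blocks can be collapsed to their best-p SNP when the
table carries `block` and `pvalue` columns (LD computation itself is out
of scope — no genotype data).

## Synthetic data

The generator emulates the study conditions on three 1–3 Mb contigs:
peaks of 400 bp on a 3 kb grid, classes shuffled over slots; default
composition 500 promoter / 100 CTCF / 2000 DRE peaks, three subsets
(bright, dim57neg, dim57pos) × 600 cells × 3 donors.

- **Sequences**: i.i.d. uniform ACGT background. Promoter peaks carry an
  exact random instantiation of M4 (TSS at the peak midpoint); CTCF
  peaks carry the CTCF core consensus (also emitted as ChIP-like
  intervals); DRE peaks are rejection-resampled (cap 1000 attempts)
  until free of M4 and CTCF evidence, so classification against ground
  truth is exact by construction. One designated DRE carries a STAT3
  instance followed by `CCTTCT`, with the recorded C→T SNP creating
  exactly one covering BLIMP1 hit.
- **Counts**: negative binomial with dispersion 0.5 (a standard ATAC
  overdispersion level; the count-noise model is this package's choice),
  lognormal per-peak rates scaled to 5000 expected fragments per cell.
  Dim subsets multiply shifted-DRE rates by 2^(−1) (70% of DREs) and all
  promoter rates by 2^(+0.2); depth is deliberately not rebalanced, so
  the global shift is real. Per-cell depth is held constant so that
  binarized peaks are independent under the null — real data have
  per-cell depth variation that induces weak positive cross-peak
  correlation, which this generator intentionally omits.
- **Co-accessible pairs**: adjacent DRE pairs driven by a shared latent
  Bernoulli activity Z (P = 0.5) with emission probabilities
  q1,0 = (1 ± √ρ)/2, giving binarized correlation exactly ρ in closed
  form; pair peaks are excluded from the accessibility shift so the two
  plantings do not interact.
- **Fragments**: good cells draw ~Poisson(600) fragments, 60% with
  midpoints Normal(TSS, 80 bp), lengths a 75/25 mixture of
  sub-nucleosomal (Normal(75, 15), clipped < 147) and mono-nucleosomal
  (Normal(200, 25)); low-quality cells draw 20–149 fragments uniformly
  placed, nucleosome-scale lengths (no sub-nucleosomal mode → infinite
  nucleosome signal) and 15% inside blacklist intervals. The two quality
  modes are separated by construction on all four metrics, so perfect QC
  recovery demonstrates correctness of the filter logic, not the
  difficulty of real-data QC, where the modes overlap.
- **SNPs**: half inside peaks; traits drawn from fixed immune /
  psychological / other phrase lists that the default categoriser
  separates cleanly; the designated SNP always carries an immune trait
  and the best p-value in its linkage block.

Every stochastic draw flows from `numpy.random.default_rng([seed,
stage])`, so all outputs are byte-identical under a fixed seed.

## Problem sizes and tolerances

The validation suite runs the masking and null-calibration experiments
at the full default scale (2600 peaks, 1800 cells, 3 donors per subset),
QC recovery at 500 cells, co-accessibility at 360 peaks × 2001 cells
pooled to 200 metacells, and the oracle comparisons at 200-element /
1000-sequence sizes. Parameter-recovery assertions use ±0.1 absolute
tolerance on log2 fold changes and correlations (sampling error at these
sizes is several-fold smaller); oracle comparisons are exact.

## Known limitations

- The synthetic genome has uniform base composition, non-overlapping
  TSS windows, and motif-clean DREs; real peaks overlap annotation
  messily and motif hits occur in background.
- Co-accessibility is plain correlation: it does not deconvolve
  indirect correlation chains the way a graphical model would.
- The centered comparator implements median-of-ratios normalization
  only; it is not a reimplementation of any specific DE tool's full
  shrinkage/testing stack.
- Allele deltas handle single-nucleotide substitutions only.
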