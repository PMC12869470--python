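"""Synthetic snATAC-seq data with planted ground truth.

Generates every input the pipeline consumes -- contig sequences, peaks,
TSSs, CTCF sites, a blacklist, fragment files, per-subset count
matrices, SNP tables and Hi-C-style loops -- for three NK-cell-like
subsets (CD56bright, CD56dim CD57-, CD56dim CD57+) on a few desk-scale
contigs.  Planted structure:

* promoter-class peaks each carry at least one exact instantiation of
  the M4 promoter consensus, with a TSS at the peak midpoint;
* CTCF-class peaks carry the CTCF core consensus (also emitted as
  ChIP-like ``ctcf_sites`` intervals);
* DRE-class peaks are rejection-resampled until free of both motifs;
* in the dim subsets a configured fraction of DREs lose accessibility
  (negative log2 shift) while promoters gain mildly -- total depth is
  NOT rebalanced afterwards, so the global shift is real;
* designated co-accessible DRE pairs share a latent per-cell activity
  giving a closed-form binarized correlation;
* one designated DRE carries a STAT3 site next to the reference context
  ``CCTTCT`` whose C-to-T SNP creates a BLIMP1 site (``CTTTCT``);
* a configured fraction of barcodes in the fragment file are
  low-quality: few fragments, uniform positions, nucleosome-scale
  lengths, elevated blacklist overlap.

All stages are deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from regshift.core import CountMatrix, GenomicInterval, LoopRecord
from regshift.motifs import IUPAC_CODES, Motif, default_motifs, scan
from regshift.peaks import CTCF_DISTAL, DRE, PROMOTER, Peak

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_RESAMPLE = 1000

# fragment-model constants (good cells)
_TSS_TARGET_FRAC = 0.6
_TSS_OFFSET_SD = 80.0
_SUB_FRAC = 0.75
_SUB_LEN_MEAN, _SUB_LEN_SD = 75.0, 15.0
_MONO_LEN_MEAN, _MONO_LEN_SD = 200.0, 25.0
# low-quality cells
_LOWQ_BLACKLIST_FRAC = 0.15
_LOWQ_LEN_MEAN, _LOWQ_LEN_SD = 230.0, 30.0


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget -- the requested
    motif/background combination is inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the conditions
    the pipeline's validation scenarios use."""

    seed: int = 0
    subsets: tuple[str, ...] = ("bright", "dim57neg", "dim57pos")
    n_cells_per_subset: int = 600
    n_donors: int = 3
    n_promoter_peaks: int = 500
    n_ctcf_peaks: int = 100
    n_dre_peaks: int = 2000
    dre_shift_log2: float = -1.0
    promoter_shift_log2: float = 0.2
    frac_dre_shifted: float = 0.7
    mean_depth_per_cell: float = 5000.0
    dispersion: float = 0.5
    n_coaccess_pairs: int = 20
    coaccess_rho: float = 0.6
    frac_lowq_cells: float = 0.2
    n_qc_cells: int = 500
    fragments_per_cell: float = 600.0
    n_snps: int = 50
    frac_snps_in_peaks: float = 0.5
    peak_width_bp: int = 400
    peak_spacing_bp: int = 3000
    n_contigs: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_cells_per_subset",
            "n_donors",
            "n_promoter_peaks",
            "n_ctcf_peaks",
            "n_dre_peaks",
            "n_coaccess_pairs",
            "n_snps",
            "n_qc_cells",
            "n_contigs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_dre_shifted", "frac_lowq_cells", "frac_snps_in_peaks"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not abs(self.coaccess_rho) < 1:
            raise ValueError("|coaccess_rho| must be < 1")
        if self.mean_depth_per_cell <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth_per_cell and dispersion must be > 0")
        if self.peak_width_bp <= 0 or self.peak_spacing_bp <= self.peak_width_bp:
            raise ValueError("need peak_spacing_bp > peak_width_bp > 0")

    @property
    def n_peaks(self) -> int:
        return self.n_promoter_peaks + self.n_ctcf_peaks + self.n_dre_peaks


@dataclass(frozen=True)
class DesignatedSNP:
    """The planted motif-creating SNP (1-based position; C -> T)."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    peak_id: str


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline without re-simulation."""

    peak_class_by_id: dict[str, str] = field(default_factory=dict)
    shifted_dre_ids: set[str] = field(default_factory=set)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    snp_effects: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    lowq_barcodes: set[str] = field(default_factory=set)
    designated_snp: DesignatedSNP | None = None


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    peaks: list[Peak]
    tss: list[GenomicInterval]
    ctcf_sites: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    ground_truth: GroundTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _instantiate_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[ch])) for ch in consensus)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate contigs, classified peaks, TSSs, CTCF sites and blacklist."""
    rng = _rng(config, 1)
    motifs = default_motifs()
    m4, ctcf_iupac, ctcf_pwm = motifs["m4"], motifs["ctcf"], motifs["ctcf_pwm"]
    stat3, blimp1 = motifs["stat3"], motifs["blimp1"]

    n_peaks = config.n_peaks
    if n_peaks == 0:
        raise ValueError("no peaks requested")
    width, spacing = config.peak_width_bp, config.peak_spacing_bp
    margin = 10_000
    blacklist_block = 30_000

    # slot layout: round-robin over contigs, fixed spacing within a contig
    contig_of_slot = np.arange(n_peaks) % config.n_contigs
    pos_on_contig = np.arange(n_peaks) // config.n_contigs
    contig_names = [f"chrS{i + 1}" for i in range(config.n_contigs)]
    n_on_contig = np.bincount(contig_of_slot, minlength=config.n_contigs)
    contig_len = {
        contig_names[i]: margin + int(n_on_contig[i]) * spacing + blacklist_block
        for i in range(config.n_contigs)
    }

    # class labels, shuffled over slots
    labels = np.array(
        [PROMOTER] * config.n_promoter_peaks
        + [CTCF_DISTAL] * config.n_ctcf_peaks
        + [DRE] * config.n_dre_peaks
    )
    rng.shuffle(labels)

    raw = {name: _random_bases(rng, length) for name, length in contig_len.items()}

    peaks: list[Peak] = []
    tss: list[GenomicInterval] = []
    ctcf_sites: list[GenomicInterval] = []
    gt = GroundTruth()

    dre_slots = [int(s) for s in np.flatnonzero(labels == DRE)]
    designated_slot = dre_slots[0] if dre_slots else None

    for slot in range(n_peaks):
        chrom = contig_names[contig_of_slot[slot]]
        start = margin + int(pos_on_contig[slot]) * spacing
        interval = GenomicInterval(chrom, start, start + width)
        peak_id = f"peak_{slot:05d}"
        label = str(labels[slot])
        seq_arr = raw[chrom]

        if label == PROMOTER:
            instance = _instantiate_iupac(m4.consensus, rng)
            offset = int(rng.integers(0, width - len(instance) + 1))
            seq_arr[start + offset : start + offset + len(instance)] = np.frombuffer(
                instance.encode(), dtype=np.uint8
            )
            tss.append(GenomicInterval(chrom, interval.midpoint, interval.midpoint + 1))
        elif label == CTCF_DISTAL:
            site = ctcf_iupac.consensus  # exact core consensus
            for attempt in range(_MAX_RESAMPLE):
                candidate = _random_bases(rng, width)
                offset = int(rng.integers(0, width - len(site) + 1))
                candidate[offset : offset + len(site)] = np.frombuffer(
                    site.encode(), dtype=np.uint8
                )
                if not scan(_decode(candidate), m4):
                    break
            else:
                raise GenerationError(f"could not build a clean CTCF peak ({peak_id})")
            seq_arr[start : start + width] = candidate
            ctcf_sites.append(
                GenomicInterval(chrom, start + offset, start + offset + len(site))
            )
        elif slot == designated_slot:
            snp_offset = _plant_designated_dre(
                seq_arr, start, width, rng, m4, ctcf_iupac, ctcf_pwm, stat3, blimp1
            )
            rsid = "rsS00001"
            gt.designated_snp = DesignatedSNP(
                chrom=chrom,
                pos=start + snp_offset + 1,
                rsid=rsid,
                ref="C",
                alt="T",
                peak_id=peak_id,
            )
            gt.snp_effects[rsid] = ("blimp1", None)
        else:
            for attempt in range(_MAX_RESAMPLE):
                candidate = _random_bases(rng, width)
                text = _decode(candidate)
                if not scan(text, m4) and not scan(text, ctcf_iupac) and not scan(text, ctcf_pwm):
                    break
            else:
                raise GenerationError(f"could not build a motif-free DRE ({peak_id})")
            seq_arr[start : start + width] = candidate

        peaks.append(Peak(peak_id, interval))
        gt.peak_class_by_id[peak_id] = label

    # co-accessible pairs: contig-adjacent DRE slot pairs, excluding the
    # designated SNP-carrying DRE
    used: set[int] = set()
    for slot in dre_slots:
        if len(gt.planted_pairs) >= config.n_coaccess_pairs:
            break
        partner = slot + config.n_contigs
        if (
            slot in used
            or partner in used
            or slot == designated_slot
            or partner == designated_slot
            or partner >= n_peaks
            or labels[partner] != DRE
        ):
            continue
        gt.planted_pairs.append(
            (f"peak_{slot:05d}", f"peak_{partner:05d}", config.coaccess_rho)
        )
        used.update((slot, partner))
    if len(gt.planted_pairs) < config.n_coaccess_pairs:
        raise GenerationError(
            f"only {len(gt.planted_pairs)} adjacent DRE pairs available for "
            f"{config.n_coaccess_pairs} requested co-accessible pairs"
        )

    # shifted DREs: sampled from DREs not used as pair members (the
    # SNP-carrying DRE may shift; its role is sequence-level only)
    eligible = [s for s in dre_slots if s not in used]
    n_shifted = round(config.frac_dre_shifted * config.n_dre_peaks)
    if n_shifted > len(eligible):
        raise GenerationError(
            "not enough unconstrained DREs to plant the requested shifted fraction"
        )
    shifted = rng.choice(len(eligible), size=n_shifted, replace=False)
    gt.shifted_dre_ids = {f"peak_{eligible[i]:05d}" for i in shifted}

    # blacklist: two 5 kb intervals in the peak-free tail of each contig
    blacklist: list[GenomicInterval] = []
    for name in contig_names:
        tail = contig_len[name] - blacklist_block
        blacklist.append(GenomicInterval(name, tail + 5_000, tail + 10_000))
        blacklist.append(GenomicInterval(name, tail + 15_000, tail + 20_000))

    sequences = {name: _decode(arr) for name, arr in raw.items()}
    return SimulatedGenome(sequences, peaks, tss, ctcf_sites, blacklist, gt)


def _plant_designated_dre(
    seq_arr: np.ndarray,
    start: int,
    width: int,
    rng: np.random.Generator,
    m4: Motif,
    ctcf_iupac: Motif,
    ctcf_pwm: Motif,
    stat3: Motif,
    blimp1: Motif,
) -> int:
    """Build the SNP-carrying DRE: STAT3 site then ref context CCTTCT.

    Returns the SNP offset within the peak.  The reference haplotype has
    zero BLIMP1 hits covering the SNP; substituting T yields exactly one;
    the adjacent STAT3 hit never covers the SNP.
    """
    stat3_instance = "TTCCAGGAA"
    context = "CCTTCT"
    offset = width // 2 - len(stat3_instance)
    snp_offset = offset + len(stat3_instance) + 1  # the C that mutates to T
    insert = stat3_instance + context
    for attempt in range(_MAX_RESAMPLE):
        candidate = _random_bases(rng, width)
        candidate[offset : offset + len(insert)] = np.frombuffer(
            insert.encode(), dtype=np.uint8
        )
        text = _decode(candidate)
        if scan(text, m4) or scan(text, ctcf_iupac) or scan(text, ctcf_pwm):
            continue
        alt_arr = candidate.copy()
        alt_arr[snp_offset] = ord("T")
        alt_text = _decode(alt_arr)

        def covering(seq: str, motif: Motif) -> int:
            return sum(
                1
                for h in scan(seq, motif)
                if h.interval.start <= snp_offset < h.interval.end
            )

        if (
            covering(text, blimp1) == 0
            and covering(alt_text, blimp1) == 1
            and covering(text, stat3) == 0
            and covering(alt_text, stat3) == 0
            and len(scan(text, stat3)) >= 1
        ):
            seq_arr[start : start + width] = candidate
            return snp_offset
    raise GenerationError("could not build the designated SNP-carrying DRE")


# ---------------------------------------------------------------------------
# fragments


def simulate_fragments(
    config: SimulationConfig, genome: SimulatedGenome
) -> tuple[pd.DataFrame, set[str]]:
    """Generate a fragment table for QC, with planted low-quality cells.

    Good cells concentrate fragment midpoints near TSSs with
    sub-nucleosomal-dominant lengths; low-quality cells have < 200
    fragments, uniform positions, mono-nucleosomal lengths and elevated
    blacklist overlap.  Returns (fragment DataFrame, low-quality barcode
    set); the set is also recorded in ``genome.ground_truth``.
    """
    rng = _rng(config, 2)
    n_cells = config.n_qc_cells
    n_lowq = round(config.frac_lowq_cells * n_cells)
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]
    lowq_idx = rng.choice(n_cells, size=n_lowq, replace=False)
    lowq = {barcodes[i] for i in lowq_idx}
    is_lowq = np.zeros(n_cells, dtype=bool)
    is_lowq[lowq_idx] = True

    contigs = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in contigs], dtype=np.int64)
    contig_probs = lengths / lengths.sum()
    tss_chrom = np.array([t.chrom for t in genome.tss])
    tss_pos = np.array([t.midpoint for t in genome.tss], dtype=np.int64)
    blacklist = genome.blacklist

    frames: list[pd.DataFrame] = []
    for i, barcode in enumerate(barcodes):
        if is_lowq[i]:
            n = int(rng.integers(20, 150))
            frag_len = np.clip(
                rng.normal(_LOWQ_LEN_MEAN, _LOWQ_LEN_SD, n), 148, 294
            ).astype(np.int64)
            in_bl = rng.random(n) < _LOWQ_BLACKLIST_FRAC
            chrom_idx = rng.choice(len(contigs), size=n, p=contig_probs)
            mids = (rng.random(n) * (lengths[chrom_idx] - 600) + 300).astype(np.int64)
            chrom_arr = np.array(contigs, dtype=object)[chrom_idx]
            bl_pick = rng.integers(0, len(blacklist), size=n)
            for k in np.flatnonzero(in_bl):
                iv = blacklist[bl_pick[k]]
                chrom_arr[k] = iv.chrom
                mids[k] = int(rng.integers(iv.start + 150, iv.end - 150))
        else:
            n = int(rng.poisson(config.fragments_per_cell))
            sub = rng.random(n) < _SUB_FRAC
            frag_len = np.where(
                sub,
                np.clip(rng.normal(_SUB_LEN_MEAN, _SUB_LEN_SD, n), 20, 146),
                np.clip(rng.normal(_MONO_LEN_MEAN, _MONO_LEN_SD, n), 147, 294),
            ).astype(np.int64)
            targeted = rng.random(n) < _TSS_TARGET_FRAC
            chrom_idx = rng.choice(len(contigs), size=n, p=contig_probs)
            mids = (rng.random(n) * (lengths[chrom_idx] - 600) + 300).astype(np.int64)
            chrom_arr = np.array(contigs, dtype=object)[chrom_idx]
            if targeted.any() and tss_pos.size:
                pick = rng.integers(0, tss_pos.size, size=int(targeted.sum()))
                offsets = rng.normal(0, _TSS_OFFSET_SD, size=pick.size).astype(np.int64)
                mids[targeted] = tss_pos[pick] + offsets
                chrom_arr[targeted] = tss_chrom[pick]
        starts = mids - frag_len // 2
        # keep fragments inside contig bounds without changing their length
        max_start = np.array([len(genome.sequences[c]) for c in chrom_arr]) - frag_len
        starts = np.clip(starts, 0, np.maximum(max_start, 0))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom_arr,
                    "start": starts,
                    "end": starts + frag_len,
                    "barcode": barcode,
                    "count": 1,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    genome.ground_truth.lowq_barcodes = lowq
    return df, lowq


# ---------------------------------------------------------------------------
# counts


def _pair_bernoulli_probs(rho: float) -> tuple[float, float]:
    """Closed-form Bernoulli emission probabilities for a shared latent
    activity (P(Z)=0.5) so that corr(X_a, X_b) = rho (|rho| on the
    magnitude; sign via swapped emissions)."""
    root = float(np.sqrt(abs(rho)))
    return (1 + root) / 2, (1 - root) / 2


def simulate_counts(
    config: SimulationConfig, genome: SimulatedGenome
) -> CountMatrix:
    """Negative-binomial peak x cell counts for all subsets.

    Per-peak base rates are lognormal and scaled so a cell's expected
    total is ``mean_depth_per_cell``.  In dim subsets, shifted-DRE rates
    are multiplied by ``2**dre_shift_log2`` and promoter rates by
    ``2**promoter_shift_log2``; depth is not rebalanced afterwards.
    Planted co-accessible pairs are driven by a shared per-cell latent
    activity instead.  Cells carry ``subset`` and ``donor`` metadata.
    """
    rng = _rng(config, 3)
    gt = genome.ground_truth
    peaks = genome.peaks
    n_peaks = len(peaks)
    peak_ids = [p.id for p in peaks]
    peak_index = {pid: i for i, pid in enumerate(peak_ids)}

    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_peaks)
    rates = config.mean_depth_per_cell * base / base.sum()

    shifted_idx = np.array([peak_index[p] for p in gt.shifted_dre_ids], dtype=int)
    promoter_idx = np.array(
        [i for i, p in enumerate(peak_ids) if gt.peak_class_by_id[p] == PROMOTER],
        dtype=int,
    )
    pair_idx = sorted(
        {peak_index[a] for a, _, _ in gt.planted_pairs}
        | {peak_index[b] for _, b, _ in gt.planted_pairs}
    )

    q1, q0 = _pair_bernoulli_probs(config.coaccess_rho)
    nb_n = 1.0 / config.dispersion

    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    subset_col: list[str] = []
    donor_col: list[str] = []
    for subset in config.subsets:
        n_cells = config.n_cells_per_subset
        subset_rates = rates.copy()
        if subset != config.subsets[0]:  # dim subsets shift; reference does not
            if shifted_idx.size:
                subset_rates[shifted_idx] *= 2.0 ** config.dre_shift_log2
            if promoter_idx.size:
                subset_rates[promoter_idx] *= 2.0 ** config.promoter_shift_log2
        mean = np.broadcast_to(subset_rates[:, None], (n_peaks, n_cells))
        p = nb_n / (nb_n + mean)
        counts = rng.negative_binomial(nb_n, p).astype(np.int64)

        # planted co-accessible pairs share a latent per-cell activity
        for a, b, rho in gt.planted_pairs:
            z = rng.random(n_cells) < 0.5
            for which, idx in enumerate((peak_index[a], peak_index[b])):
                hi, lo = (q1, q0)
                if rho < 0 and which == 1:
                    hi, lo = lo, hi
                prob = np.where(z, hi, lo)
                active = rng.random(n_cells) < prob
                counts[idx] = np.where(active, 1 + rng.poisson(1.0, n_cells), 0)

        blocks.append(sp.csr_matrix(counts))
        for k in range(n_cells):
            donor = k * config.n_donors // n_cells
            barcodes.append(f"{subset}-d{donor}-{k:05d}")
            subset_col.append(subset)
            donor_col.append(f"d{donor}")

    matrix = sp.hstack(blocks, format="csr")
    obs = pd.DataFrame(
        {"subset": subset_col, "donor": donor_col},
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(matrix, peak_ids, barcodes, obs)


def cell_groups(matrix: CountMatrix) -> dict[str, str]:
    """Barcode -> ``subset:donor`` pseudobulk group labels."""
    return {
        bc: f"{matrix.obs.loc[bc, 'subset']}:{matrix.obs.loc[bc, 'donor']}"
        for bc in matrix.barcodes
    }


# ---------------------------------------------------------------------------
# SNPs


_IMMUNE_TRAITS = (
    "lymphocyte count",
    "monocyte count",
    "eosinophil percentage",
    "rheumatoid arthritis",
    "asthma",
    "inflammatory bowel disease",
)
_PSYCH_TRAITS = (
    "depression",
    "schizophrenia",
    "anxiety disorder",
    "addiction",
    "bipolar disorder",
)
_OTHER_TRAITS = (
    "height",
    "body mass index",
    "coffee consumption",
    "hair color",
    "heel bone mineral density",
)


def simulate_snps(config: SimulationConfig, genome: SimulatedGenome) -> pd.DataFrame:
    """Trait-annotated SNP table (1-based positions, ref verified against
    the genome).  The designated motif-creating SNP is always emitted
    first, with an immune trait and the best p-value in its block."""
    rng = _rng(config, 4)
    gt = genome.ground_truth
    rows: list[dict] = []

    designated = gt.designated_snp
    if designated is not None:
        rows.append(
            {
                "chrom": designated.chrom,
                "pos": designated.pos,
                "rsid": designated.rsid,
                "ref": designated.ref,
                "alt": designated.alt,
                "trait": "lymphocyte count",
                "pvalue": 1e-160,
            }
        )

    n_total = config.n_snps
    n_in_peaks = round(config.frac_snps_in_peaks * n_total)
    n_needed_in = max(0, n_in_peaks - len(rows))
    n_needed_out = n_total - n_in_peaks

    contigs = list(genome.sequences)
    peak_list = genome.peaks

    def peak_positions(n: int) -> list[tuple[str, int]]:
        out = []
        picks = rng.integers(0, len(peak_list), size=n)
        offs = rng.integers(0, config.peak_width_bp, size=n)
        for p, o in zip(picks, offs):
            iv = peak_list[p].interval
            out.append((iv.chrom, iv.start + int(o)))
        return out

    def gap_positions(n: int) -> list[tuple[str, int]]:
        out = []
        while len(out) < n:
            chrom = contigs[int(rng.integers(0, len(contigs)))]
            pos0 = int(rng.integers(100, len(genome.sequences[chrom]) - 100))
            inside = any(
                p.interval.chrom == chrom and p.interval.start <= pos0 < p.interval.end
                for p in peak_list
            )
            if not inside:
                out.append((chrom, pos0))
        return out

    positions = peak_positions(n_needed_in) + gap_positions(n_needed_out)
    for k, (chrom, pos0) in enumerate(positions):
        ref = genome.sequences[chrom][pos0]
        if ref == "N":
            ref = "A"
        alt = str(rng.choice(sorted(set("ACGT") - {ref})))
        category = rng.choice(3, p=[0.4, 0.3, 0.3])
        trait = str(
            rng.choice(
                [_IMMUNE_TRAITS, _PSYCH_TRAITS, _OTHER_TRAITS][category]
            )
        )
        rows.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "rsid": f"rsS{k + 2:05d}",
                "ref": ref,
                "alt": alt,
                "trait": trait,
                "pvalue": float(10 ** rng.uniform(-50, -5)),
            }
        )

    df = pd.DataFrame(rows)
    df["block"] = df["chrom"].astype(str) + ":" + (df["pos"] // 50_000).astype(str)
    return df


# ---------------------------------------------------------------------------
# loops


def simulate_loops(
    config: SimulationConfig,
    genome: SimulatedGenome,
    anchor_halfwidth_bp: int = 2_500,
    n_decoys: int = 5,
) -> list[LoopRecord]:
    """Hi-C-style loops whose anchors coincide with the planted
    co-accessible pairs, plus decoy loops between random other peaks."""
    rng = _rng(config, 5)
    peak_of = {p.id: p.interval for p in genome.peaks}
    loops: list[LoopRecord] = []

    def anchor(iv: GenomicInterval) -> GenomicInterval:
        mid = iv.midpoint
        return GenomicInterval(iv.chrom, max(0, mid - anchor_halfwidth_bp), mid + anchor_halfwidth_bp)

    paired_ids: set[str] = set()
    for a, b, _ in genome.ground_truth.planted_pairs:
        loops.append(LoopRecord(anchor(peak_of[a]), anchor(peak_of[b]), score=1.0))
        paired_ids.update((a, b))

    others = [p for p in genome.peaks if p.id not in paired_ids]
    by_chrom: dict[str, list[Peak]] = {}
    for p in others:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for _ in range(n_decoys):
        chrom = list(by_chrom)[int(rng.integers(0, len(by_chrom)))]
        pool = by_chrom[chrom]
        if len(pool) < 2:
            continue
        i, j = rng.choice(len(pool), size=2, replace=False)
        loops.append(
            LoopRecord(anchor(pool[i].interval), anchor(pool[j].interval), score=0.5)
        )
    return loops
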