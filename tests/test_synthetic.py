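"""The generator's planted structure and determinism contract."""

import numpy as np
import pytest

from conftest import iupac_regex_hits
from regshift.motifs import default_motifs
from regshift.peaks import CTCF_DISTAL, DRE, PROMOTER
from regshift.synthetic import (
    GenerationError,
    SimulationConfig,
    simulate_counts,
    simulate_fragments,
    simulate_genome,
)

MOTIFS = default_motifs()


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(coaccess_rho=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(frac_dre_shifted=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(peak_width_bp=0)


class TestGenome:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(
            seed=5, n_promoter_peaks=20, n_ctcf_peaks=5, n_dre_peaks=40, n_coaccess_pairs=2
        )
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert a.sequences == b.sequences
        assert [(p.id, p.interval) for p in a.peaks] == [(p.id, p.interval) for p in b.peaks]
        assert a.ground_truth.shifted_dre_ids == b.ground_truth.shifted_dre_ids
        assert a.ground_truth.planted_pairs == b.ground_truth.planted_pairs

    def test_promoter_peaks_contain_m4(self, small_genome):
        truth = small_genome.ground_truth.peak_class_by_id
        for p in small_genome.peaks:
            seq = small_genome.sequences[p.interval.chrom][p.interval.start : p.interval.end]
            hits = iupac_regex_hits(seq, MOTIFS["m4"].consensus)
            if truth[p.id] == PROMOTER:
                assert hits, f"{p.id} lacks an M4 instance"
            elif truth[p.id] == DRE:
                assert not hits, f"{p.id} should be M4-free"

    def test_ctcf_peaks_carry_consensus_dres_do_not(self, small_genome):
        truth = small_genome.ground_truth.peak_class_by_id
        for p in small_genome.peaks:
            seq = small_genome.sequences[p.interval.chrom][p.interval.start : p.interval.end]
            hits = iupac_regex_hits(seq, MOTIFS["ctcf"].consensus)
            if truth[p.id] == CTCF_DISTAL:
                assert hits
            elif truth[p.id] == DRE:
                assert not hits

    def test_designated_snp_creates_blimp1_in_alt_only(self, small_genome):
        snp = small_genome.ground_truth.designated_snp
        seq = small_genome.sequences[snp.chrom]
        p0 = snp.pos - 1
        assert seq[p0] == "C" and snp.ref == "C" and snp.alt == "T"
        window = seq[p0 - 30 : p0 + 31]
        alt_window = window[:30] + "T" + window[31:]
        assert "CTTTCT" not in window
        assert "CTTTCT" in alt_window
        assert iupac_regex_hits(window, "TTCCNGGAA")  # STAT3 next door

    def test_counts_align_with_peak_order(self, small_genome, small_counts):
        assert small_counts.peak_ids == [p.id for p in small_genome.peaks]

    def test_infeasible_pair_demand_raises(self):
        cfg = SimulationConfig(
            seed=0, n_promoter_peaks=5, n_ctcf_peaks=0, n_dre_peaks=4, n_coaccess_pairs=50
        )
        with pytest.raises(GenerationError):
            simulate_genome(cfg)


class TestFragments:
    def test_lowq_fraction_and_fragment_floor(self, small_config, small_genome, small_fragments):
        frags, lowq = small_fragments
        assert len(lowq) == round(small_config.frac_lowq_cells * small_config.n_qc_cells)
        per_cell = frags.drop_duplicates(["chrom", "start", "end", "barcode"]).groupby("barcode").size()
        for bc in lowq:
            assert per_cell[bc] < 200  # below the "more than 200" QC floor
        good = set(per_cell.index) - lowq
        assert all(per_cell[bc] > 200 for bc in good)

    def test_no_lowq_cells_all_pass_qc(self, small_genome):
        from regshift.qc import compute_cell_qc, filter_cells

        cfg = SimulationConfig(
            seed=3, n_promoter_peaks=60, n_ctcf_peaks=15, n_dre_peaks=200,
            n_qc_cells=40, frac_lowq_cells=0.0, n_coaccess_pairs=5,
        )
        genome = simulate_genome(cfg)
        frags, lowq = simulate_fragments(cfg, genome)
        assert lowq == set()
        qc = compute_cell_qc(frags, genome.tss, genome.blacklist)
        kept, _ = filter_cells(qc)
        assert len(kept) == 40

    def test_fragments_within_contigs(self, small_genome, small_fragments):
        frags, _ = small_fragments
        lengths = small_genome.contig_lengths
        assert (frags["start"] >= 0).all()
        max_end = frags.groupby("chrom")["end"].max()
        assert all(end <= lengths[chrom] for chrom, end in max_end.items())


class TestCounts:
    def test_null_config_has_equal_subset_means(self):
        cfg = SimulationConfig(
            seed=8, n_promoter_peaks=40, n_ctcf_peaks=10, n_dre_peaks=150,
            n_cells_per_subset=400, dre_shift_log2=0.0, promoter_shift_log2=0.0,
            n_coaccess_pairs=0,
        )
        genome = simulate_genome(cfg)
        cm = simulate_counts(cfg, genome)
        dense = cm.dense()
        subsets = cm.obs["subset"].to_numpy()
        means = {s: dense[:, subsets == s].mean() for s in cfg.subsets}
        ratios = [means[s] / means[cfg.subsets[0]] for s in cfg.subsets[1:]]
        assert np.allclose(ratios, 1.0, atol=0.05)

    def test_full_shift_recovered_from_raw_matrix(self):
        """dre_shift_log2=-1 on every DRE: dim/bright mean ratio is -1 in log2."""
        cfg = SimulationConfig(
            seed=9, n_promoter_peaks=40, n_ctcf_peaks=10, n_dre_peaks=150,
            n_cells_per_subset=500, frac_dre_shifted=1.0, n_coaccess_pairs=0,
        )
        genome = simulate_genome(cfg)
        cm = simulate_counts(cfg, genome)
        dense = cm.dense()
        subsets = cm.obs["subset"].to_numpy()
        dre_rows = np.array(
            [genome.ground_truth.peak_class_by_id[p] == DRE for p in cm.peak_ids]
        )
        bright = dense[np.ix_(dre_rows, subsets == "bright")].mean(axis=1)
        dim = dense[np.ix_(dre_rows, subsets == "dim57neg")].mean(axis=1)
        ratio = np.log2(dim.mean() / bright.mean())
        assert ratio == pytest.approx(-1.0, abs=0.1)

    def test_planted_pair_binarized_correlation(self):
        cfg = SimulationConfig(
            seed=10, n_promoter_peaks=40, n_ctcf_peaks=10, n_dre_peaks=150,
            n_cells_per_subset=500, n_coaccess_pairs=5,
            dre_shift_log2=0.0, promoter_shift_log2=0.0,
        )
        genome = simulate_genome(cfg)
        cm = simulate_counts(cfg, genome)
        binary = (cm.dense() > 0).astype(float)
        index = {p: i for i, p in enumerate(cm.peak_ids)}
        for a, b, rho in genome.ground_truth.planted_pairs:
            r = np.corrcoef(binary[index[a]], binary[index[b]])[0, 1]
            assert r == pytest.approx(rho, abs=0.1)

    def test_counts_nonnegative_integers(self, small_counts):
        data = small_counts.matrix.data
        assert (data >= 0).all() and np.array_equal(data, data.astype(np.int64))


class TestSnps:
    def test_planted_peak_fraction(self, small_config, small_genome, small_snps):
        assert len(small_snps) == small_config.n_snps
        refs = [
            small_genome.sequences[row.chrom][row.pos - 1]
            for row in small_snps.itertuples()
        ]
        assert refs == list(small_snps["ref"])  # ref always matches the genome

    def test_designated_snp_has_best_p_in_block(self, small_genome, small_snps):
        designated = small_genome.ground_truth.designated_snp
        row = small_snps[small_snps.rsid == designated.rsid].iloc[0]
        block = small_snps[small_snps.block == row.block]
        assert row.pvalue == block.pvalue.min()
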