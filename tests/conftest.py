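"""Shared fixtures: one small simulated study reused across test modules."""

from __future__ import annotations

import re

import pytest

from regshift.motifs import IUPAC_CODES, reverse_complement
from regshift.synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_fragments,
    simulate_genome,
    simulate_loops,
    simulate_snps,
)


def iupac_regex_hits(sequence: str, consensus: str) -> list[tuple[int, str]]:
    """Independent brute-force oracle: expand IUPAC degeneracies into a
    regex character class per position, test every offset on both strands
    via lookahead, and map minus-strand matches back."""
    seq = sequence.upper()
    pattern = "".join(
        "[" + "".join(sorted(IUPAC_CODES[ch])) + "]" if ch != "N" else "[ACGTN]"
        for ch in consensus.upper()
    )
    hits = [(m.start(1), "+") for m in re.finditer(f"(?=({pattern}))", seq)]
    L = len(consensus)
    rc = reverse_complement(seq)
    hits += [
        (len(seq) - m.start(1) - L, "-") for m in re.finditer(f"(?=({pattern}))", rc)
    ]
    return sorted(hits)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_promoter_peaks=60,
        n_ctcf_peaks=15,
        n_dre_peaks=200,
        n_cells_per_subset=240,
        n_qc_cells=120,
        n_coaccess_pairs=5,
        n_snps=30,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_genome):
    return simulate_counts(small_config, small_genome)


@pytest.fixture(scope="session")
def small_fragments(small_config, small_genome):
    return simulate_fragments(small_config, small_genome)


@pytest.fixture(scope="session")
def small_snps(small_config, small_genome):
    return simulate_snps(small_config, small_genome)


@pytest.fixture(scope="session")
def small_loops(small_config, small_genome):
    return simulate_loops(small_config, small_genome)
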