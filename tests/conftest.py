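"""Shared fixtures: small seeded genomes, signatures, and helper oracles."""

import numpy as np
import pytest

import apobecsig as a
from apobecsig.synthetic_data import ContextSiteIndex


@pytest.fixture(scope="session")
def refs():
    return a.synthetic_reference_signatures()


@pytest.fixture(scope="session")
def small_genome():
    """50 kb single nuclear contig + 4 kb chrM, GC 0.42."""
    return a.generate_genome(1, [50_000], 0.42, seed=101, mito_length=4_000)


@pytest.fixture(scope="session")
def big_genome():
    """300 kb across two nuclear contigs, enough sites for dense planting."""
    return a.generate_genome(2, [200_000, 100_000], 0.42, seed=202, mito_length=5_000)


@pytest.fixture(scope="session")
def big_index(big_genome):
    return ContextSiteIndex(big_genome)


def brute_window_census(seq: str, p0: int, flank: int = 20):
    """Independent per-position census of one enrichment window.

    Counts cytosines on both strands and pyrimidine-strand TCW contexts
    over the window, skipping the mutated base and its two neighbors
    (whose contexts overlap the mutation), with motif contexts read from
    flanks that may extend past the window edge.  Returns (tcw, c).
    """
    lo, hi = max(0, p0 - flank), min(len(seq), p0 + flank + 1)
    con_tcw = con_c = 0
    for j in range(lo, hi):
        if abs(j - p0) <= 1:
            continue
        base = seq[j]
        if base not in "CG":
            continue
        con_c += 1
        if 1 <= j < len(seq) - 1:
            prev, nxt = seq[j - 1], seq[j + 1]
            if base == "C" and prev == "T" and nxt in "AT":
                con_tcw += 1
            if base == "G" and nxt == "A" and prev in "AT":
                con_tcw += 1
    return con_tcw, con_c


def is_tcw_site(seq: str, p0: int) -> bool:
    if not 1 <= p0 < len(seq) - 1:
        return False
    prev, base, nxt = seq[p0 - 1], seq[p0], seq[p0 + 1]
    return (base == "C" and prev == "T" and nxt in "AT") or (
        base == "G" and nxt == "A" and prev in "AT"
    )
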