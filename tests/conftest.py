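"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's regex/bitmask machinery:
site matching is a position-by-position IUPAC set scan, digestion is
string splitting, and subset optimization is unpruned enumeration.
"""

from __future__ import annotations

import itertools

import pytest

from radopt.digest import GENOMIC, SequenceRegion, SizeWindow, classify_fragments, digest, size_select
from radopt.enzymes import (
    IUPAC_SETS,
    RestrictionEnzyme,
    iupac_reverse_complement,
    load_default_catalog,
)
from radopt.simulate import SimulationConfig, simulate_genome

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Position-by-position IUPAC matcher over both strands (no regex)."""
    seq = sequence.upper()
    cuts = set()

    def scan(site: str, cut_from_start: int) -> None:
        L = len(site)
        for i in range(len(seq) - L + 1):
            if all(seq[i + j] in IUPAC_SETS[site[j]] for j in range(L)):
                cuts.add(i + cut_from_start)

    scan(enzyme.recognition, enzyme.cut_offset)
    # a palindromic site occurs identically on both strands at the same
    # offset; only non-palindromic sites contribute a second scan whose
    # bottom-strand cut maps to s + L - offset on the top strand
    if iupac_reverse_complement(enzyme.recognition) != enzyme.recognition:
        scan(
            iupac_reverse_complement(enzyme.recognition),
            len(enzyme.recognition) - enzyme.cut_offset,
        )
    return sorted(cuts)


def oracle_digest_lengths(sequence: str, enzymes) -> list[int]:
    """Fragment lengths by splitting the string at every oracle cut."""
    cuts = sorted({c for e in enzymes for c in oracle_cut_sites(sequence, e)})
    boundaries = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    boundaries = sorted(set(boundaries))
    return [b - a for a, b in zip(boundaries[:-1], boundaries[1:])]


def oracle_second_round(fragments, residues, enzymes, max_combo_size):
    """Unpruned exhaustive subset search, recomputing incidence by scanning."""
    cut = {
        e.name: {
            i
            for i, seq in enumerate(residues)
            if any(0 < c < len(seq) for c in oracle_cut_sites(seq, e))
        }
        for e in enzymes
    }
    org = {i for i, f in enumerate(fragments) if f.region_class != GENOMIC}
    gen = {i for i, f in enumerate(fragments) if f.region_class == GENOMIC}
    best = None
    names = sorted(cut)
    for k in range(1, max_combo_size + 1):
        for combo in itertools.combinations(names, k):
            hit = set().union(*(cut[n] for n in combo))
            key = (
                not org <= hit,  # incomplete last
                -len(org & hit),  # among incomplete, cover more organellar
                -(len(gen) - len(gen & hit)),
                len(combo),
                combo,
            )
            if best is None or key < best[0]:
                best = (key, combo, org <= hit, len(gen) - len(gen & hit))
    return best  # (key, combo, complete, genomic_intact)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic study: 2 x 120 kb chromosomes, 40 kb chloroplast."""
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chromosome_length=120_000,
        n_planted_fragments=20,
        chloroplast_length=40_000,
        n_chloroplast_fragments=4,
        rrna_unit_length=8_000,
        n_rrna_fragments=2,
        n_polymorphisms=40,
        reads_per_sample=500,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def selected_fragments(small_truth, small_config, catalog):
    """Size-selected, classified non-terminal fragments of the synthetic genome."""
    pair = [catalog[n] for n in small_config.planted_enzymes]
    frags = [f for f in digest(small_truth.regions, pair) if not f.is_terminal]
    frags = classify_fragments(frags, small_truth.regions)
    return size_select(frags, small_config.window)
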