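"""Shared fixtures: simulated datasets reused across test modules.

The expensive end-to-end simulations (hundreds of loci) are built once
per session and shared between the module tests and the acceptance
tests; all are seeded, so every run sees identical data.
"""

from __future__ import annotations

import pytest

from tescar.synthetic_genomes import (
    SimConfig,
    generate_cds_pairs,
    generate_mite_genome,
    simulate,
)


@pytest.fixture(scope="session")
def small_pair():
    """A compact genome pair carrying every event class."""
    cfg = SimConfig(
        genome_length=600_000,
        n_genes=15,
        n_te_insertions=10,
        n_te_excisions=8,
        n_shared_tes=4,
        n_ltr_elements=5,
        seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def gradient_run():
    """200 excisions with the default repair gradient (A=5, L=1 kb),
    classified through the full locus-pairing pipeline."""
    from tescar.pipeline import call_polymorphisms

    cfg = SimConfig(
        genome_length=6_500_000,
        n_genes=60,
        n_te_insertions=0,
        n_te_excisions=200,
        n_shared_tes=0,
        gradient_amplitude=5.0,
        gradient_scale=1000.0,
        seed=17,
    )
    pair = simulate(cfg)
    records = call_polymorphisms(
        pair.genome_a, pair.genome_b, pair.features_a, pair.features_b, flank=12_000
    )
    return pair, records


@pytest.fixture(scope="session")
def classify_500_run():
    """500 mixed insertion/excision events under default noise."""
    from tescar.pipeline import call_polymorphisms

    cfg = SimConfig(
        genome_length=12_000_000,
        n_genes=120,
        n_te_insertions=250,
        n_te_excisions=250,
        n_shared_tes=10,
        seed=23,
    )
    pair = simulate(cfg)
    records = call_polymorphisms(
        pair.genome_a, pair.genome_b, pair.features_a, pair.features_b, flank=3000
    )
    return pair, records


@pytest.fixture(scope="session")
def ltr_run():
    """192 LTR retroelements with 5x TSD mutation burden."""
    from tescar.ltr_tsd import annotate_elements, filter_family_outliers, find_ltr_pairs

    cfg = SimConfig(
        genome_length=6_000_000,
        n_genes=40,
        n_te_insertions=0,
        n_te_excisions=0,
        n_shared_tes=0,
        n_ltr_elements=192,
        tsd_rate_multiplier=5.0,
        seed=9,
    )
    pair = simulate(cfg)
    elements = annotate_elements(
        find_ltr_pairs(pair.genome_a, pair.ltr_consensus), pair.genome_a
    )
    kept = filter_family_outliers(elements)
    return pair, elements, kept


@pytest.fixture(scope="session")
def mite_run():
    """50 planted MITEs and the accepted de novo candidates."""
    from tescar.discovery import discover_mites

    genome, planted = generate_mite_genome(seed=5)
    accepted = discover_mites(genome)
    return genome, planted, accepted


@pytest.fixture(scope="session")
def cds_run():
    """400 CDS pairs with a 1.3x mutation excess in the terminal fifths."""
    from tescar.pipeline import cds_bin_analysis

    cds_a, cds_b = generate_cds_pairs(400, seed=8, terminal_boost=1.3)
    return cds_bin_analysis(cds_a, cds_b)
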