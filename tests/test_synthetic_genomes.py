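"""Simulator contracts: determinism, conservation, planted-event structure."""

import numpy as np
import pytest

from tescar.io_formats import read_fasta, read_gff3, revcomp
from tescar.synthetic_genomes import (
    SimConfig,
    diverge,
    generate_ancestor,
    generate_cds_pairs,
    generate_mite_genome,
    read_truth,
    simulate,
    write_outputs,
    write_truth,
)


def test_invalid_configs_name_the_field():
    with pytest.raises(ValueError, match="background_sub_rate"):
        SimConfig(background_sub_rate=1.5)
    with pytest.raises(ValueError, match="gradient_amplitude"):
        SimConfig(gradient_amplitude=0.5)
    with pytest.raises(ValueError, match="excision_type_mix"):
        SimConfig(excision_type_mix={"perfect": 0.5, "deletion": 0.2, "filler": 0.2})
    with pytest.raises(ValueError, match="superfamily_tsd_lengths"):
        SimConfig(superfamily_tsd_lengths={"DTT": 0})
    with pytest.raises(ValueError, match="genome_length"):
        generate_ancestor(SimConfig(genome_length=100_000, n_genes=50))


def test_excess_excisions_rejected():
    cfg = SimConfig(genome_length=400_000, n_genes=5, n_te_excisions=3, n_shared_tes=0, seed=1)
    anc = generate_ancestor(cfg)
    bad = SimConfig(genome_length=400_000, n_genes=5, n_te_excisions=10, n_shared_tes=0, seed=1)
    with pytest.raises(ValueError, match="exceeds"):
        diverge(anc, bad)


def test_no_genes_still_valid(tmp_path):
    cfg = SimConfig(
        genome_length=200_000, n_genes=0, n_te_insertions=3,
        n_te_excisions=2, n_shared_tes=1, seed=4,
    )
    pair = simulate(cfg)
    assert not any(f.type == "gene" for f in pair.features_a)
    paths = write_outputs(pair, tmp_path)
    fasta = read_fasta(paths["fasta_A"])
    assert len(next(iter(fasta.values()))) == pair.truth.genome_a_length
    assert read_gff3(paths["gff_A"])  # TE + centromere features parse back


def test_same_seed_byte_identical(tmp_path, small_pair):
    cfg = small_pair.truth.config
    again = simulate(cfg)
    assert again.genome_a == small_pair.genome_a
    assert again.genome_b == small_pair.genome_b
    assert again.truth.events == small_pair.truth.events
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    write_outputs(small_pair, d1)
    write_outputs(again, d2)
    for p1, p2 in zip(sorted(d1.iterdir()), sorted(d2.iterdir())):
        assert p1.read_bytes() == p2.read_bytes()


def test_length_conservation_exact(small_pair):
    """Genome length = ancestor + insertions - deletions, from the truth table."""
    tr = small_pair.truth
    for lineage, glen, net in (
        ("A", tr.genome_a_length, tr.net_background_indel_a),
        ("B", tr.genome_b_length, tr.net_background_indel_b),
    ):
        delta = net
        for ev in tr.events:
            if ev.event_class == "insertion" and ev.species_with_te == lineage:
                delta += ev.te_length + ev.tsd_length
            elif ev.event_class.startswith("excision") and ev.species_with_te != lineage:
                delta -= (
                    ev.te_length + ev.deletion_left + ev.deletion_right - ev.filler_length
                )
            elif ev.event_class == "ltr_insertion" and lineage == "A":
                delta += ev.te_length + ev.tsd_length
        assert tr.ancestor_length + delta == glen


def test_event_counts_match_request(small_pair):
    tr = small_pair.truth
    cfg = tr.config
    n_exc = sum(1 for e in tr.events if e.event_class.startswith("excision"))
    n_ins = sum(1 for e in tr.events if e.event_class == "insertion")
    assert n_exc == cfg.n_te_excisions
    assert n_ins == cfg.n_te_insertions
    assert len(tr.by_class("ltr_insertion")) == cfg.n_ltr_elements


def test_planted_structure(small_pair):
    """Insertions carry exact TSDs; perfect excisions leave both TSD units."""
    ga, gb = small_pair.genome_a, small_pair.genome_b
    for ev in small_pair.truth.events:
        if ev.event_class == "insertion":
            g = ga if ev.species_with_te == "A" else gb
            p = ev.anchor_a if ev.species_with_te == "A" else ev.anchor_b
            k = ev.tsd_length
            assert g[p - k : p] == ev.tsd_seq
            assert g[p + ev.te_length : p + ev.te_length + k] == ev.tsd_seq
        elif ev.event_class == "excision_perfect":
            g = gb if ev.species_with_te == "A" else ga
            p = ev.anchor_b if ev.species_with_te == "A" else ev.anchor_a
            k = ev.tsd_length
            left, right = g[p - k : p], g[p : p + k]
            # both TSD units adjacent, up to lineage-specific substitutions
            mism = sum(1 for x, y in zip(left, right) if x != y)
            assert mism <= 2


def test_te_features_match_truth(small_pair):
    feature_ids = {
        f.attr("ID")
        for f in small_pair.features_a + small_pair.features_b
        if f.type not in ("gene", "centromere")
    }
    for ev in small_pair.truth.events:
        assert ev.event_id in feature_ids


def test_truth_round_trip(tmp_path, small_pair):
    path = tmp_path / "truth.tsv"
    write_truth(small_pair.truth, path)
    back = read_truth(path)
    assert back.events == small_pair.truth.events
    assert back.config == small_pair.truth.config
    assert back.genome_a_length == small_pair.truth.genome_a_length


def test_truth_empty_and_counts(tmp_path):
    cfg = SimConfig(genome_length=150_000, n_genes=0, n_te_insertions=0,
                    n_te_excisions=0, n_shared_tes=0, seed=2)
    pair = simulate(cfg)
    path = tmp_path / "truth.tsv"
    write_truth(pair.truth, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 1  # header only
    assert read_truth(path).events == []


def test_near_gene_insertion_bias():
    """With 10:1 bias, >= 70% of planted DNA TEs lie within 5 kb of a gene."""
    cfg = SimConfig(
        genome_length=1_600_000, n_genes=50, n_te_insertions=20,
        n_te_excisions=0, n_shared_tes=20, near_gene_bias=10.0, seed=31,
    )
    pair = simulate(cfg)
    genes = [(f.start, f.end) for f in pair.features_a if f.type == "gene"]
    tes = [
        f for f in pair.features_a if f.type in ("DTT", "DTH", "DTM", "DTA", "DTC")
    ]
    near = sum(
        1
        for te in tes
        if any(te.start < ge + 5000 and te.end > gs - 5000 for gs, ge in genes)
    )
    assert near / len(tes) >= 0.70


def test_gradient_off_means_flat_flanks():
    """With A=1 the flank substitution density equals background everywhere."""
    cfg = SimConfig(
        genome_length=3_200_000, n_genes=30, n_te_insertions=0,
        n_te_excisions=100, n_shared_tes=0, gradient_amplitude=1.0, seed=19,
    )
    from tescar.pipeline import call_polymorphisms, excision_profile

    pair = simulate(cfg)
    records = call_polymorphisms(
        pair.genome_a, pair.genome_b, pair.features_a, pair.features_b, flank=3000
    )
    prof = excision_profile(records, min_aligned=3000)
    centers, dens, mask = prof.windowed("substitution")
    near = dens[mask & (np.abs(centers) < 3000)]
    expected = 2 * cfg.background_sub_rate  # both lineages contribute
    se = np.sqrt(expected / (prof.n_alignments * 400))
    assert abs(near.mean() - expected) < 3 * se


def test_cds_pairs_translatable():
    cds_a, cds_b = generate_cds_pairs(5, seed=3, codon_range=(200, 300))
    from Bio.Seq import Seq

    for cds in list(cds_a.values()) + list(cds_b.values()):
        assert len(cds) % 3 == 0
        prot = str(Seq(cds).translate())
        assert "*" not in prot[:-1]
        assert prot[0] == "M"


def test_mite_genome_structure():
    genome, planted = generate_mite_genome(seed=1, genome_length=100_000,
                                           n_families=2, copies_per_family=3)
    assert len(planted) == 6
    for rec in planted:
        copy = genome[rec["start"] : rec["end"]]
        tir = copy[: rec["tir_length"]]
        tail = copy[-rec["tir_length"] :]
        mism = sum(1 for x, y in zip(revcomp(tir), tail) if x != y)
        # TIR pair is an inverted repeat up to per-copy divergence
        assert mism <= max(3, 0.25 * rec["tir_length"])
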