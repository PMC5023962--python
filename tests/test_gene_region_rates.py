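"""TE distribution near genes, promoter conservation, CDS synonymous bins."""

import numpy as np
import pytest

from tescar.gene_region_rates import (
    align_backtranslate,
    bidirectional_best_hits,
    bin_synonymous_rates,
    chromosome_bin,
    conservation_difference,
    count_restricted_synonymous,
    te_coverage_near_genes,
)
from tescar.io_formats import FeatureRecord


def _gene(start, end, gid="g1", strand="+"):
    return FeatureRecord("chr", "t", "gene", start, end, strand, attributes={"ID": gid})


def _te(start, end, tid="t1"):
    return FeatureRecord("chr", "t", "DTT", start, end, "+", attributes={"ID": tid})


class TestTeCoverage:
    def test_no_tes_gives_zero_vector(self):
        cov = te_coverage_near_genes([_gene(10_000, 15_000)], [])
        assert cov["tss_coverage"].sum() == 0
        assert cov["tes_coverage"].sum() == 0

    def test_single_te_in_upstream_window(self):
        genes = [_gene(10_000, 15_000)]
        tes = [_te(8000, 8300)]
        cov = te_coverage_near_genes(genes, tes)
        assert cov["tss_coverage"].sum() == 300
        covered = cov["tss_offsets"][cov["tss_coverage"] > 0]
        assert covered.min() == -2000 and covered.max() == -1701

    def test_reverse_strand_genes_ignored(self):
        genes = [_gene(10_000, 15_000, strand="-")]
        cov = te_coverage_near_genes(genes, [_te(8000, 8300)])
        assert cov["tss_coverage"].sum() == 0

    def test_short_gene_interior_not_counted(self):
        genes = [_gene(10_000, 12_000)]  # < 4 kb
        tes = [_te(10_500, 10_600)]
        cov = te_coverage_near_genes(genes, tes)
        assert cov["tss_coverage"].sum() == 0

    def test_near_gene_bias_visible_in_simulation(self, small_pair):
        genes = [f for f in small_pair.features_a if f.type == "gene"]
        tes = [
            f for f in small_pair.features_a
            if f.type in ("DTT", "DTH", "DTM", "DTA", "DTC")
        ]
        cov = te_coverage_near_genes(genes, tes)
        upstream = cov["tss_coverage"][:5000]
        assert upstream.sum() > 0


class TestChromosomeBins:
    def test_telomere_is_bin_one(self):
        assert chromosome_bin(0, 500, 1000) == 1
        assert chromosome_bin(999, 500, 1000) == 1

    def test_centromere_is_bin_three(self):
        assert chromosome_bin(499, 500, 1000) == 3
        assert chromosome_bin(501, 500, 1000) == 3

    def test_invalid_centromere(self):
        with pytest.raises(ValueError):
            chromosome_bin(10, 0, 1000)


def test_conservation_difference_formula():
    """Mean identities 98.22 vs 98.62 correspond to a 28.99% divergence excess."""
    assert conservation_difference(98.22, 98.62) == pytest.approx(28.99, abs=0.005)
    assert conservation_difference(99.0, 99.0) == 0.0
    assert np.isnan(conservation_difference(99.0, 100.0))


class TestBidirectionalBestHits:
    def test_identical_singletons_pair(self):
        seq = "ATG" + "GCT" * 200 + "TAA"
        assert bidirectional_best_hits({"a": seq}, {"b": seq}) == [("a", "b")]

    def test_equal_scoring_partners_excluded(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 900)])
        pairs = bidirectional_best_hits({"a": seq}, {"b1": seq, "b2": seq})
        assert pairs == []

    def test_simulated_orthologs_recovered(self):
        from tescar.synthetic_genomes import generate_cds_pairs

        cds_a, cds_b = generate_cds_pairs(100, seed=12, codon_range=(300, 500))
        pairs = bidirectional_best_hits(cds_a, cds_b)
        correct = sum(1 for a, b in pairs if a.split("_")[0] == b.split("_")[0])
        assert correct >= 95


class TestBacktranslate:
    def test_identical_cds_fully_paired(self):
        cds = "ATG" + "GCTGGGCCC" * 60 + "TAA"
        cols = align_backtranslate(cds, cds)
        paired = [(x, y) for x, y in cols if x and y]
        assert len(paired) == len(cds) // 3 - 1  # stop trimmed
        assert all(x == y for x, y in paired)

    def test_codon_insertion_is_single_gap(self):
        base = "ATG" + "GCTGGGCCCAAG" * 30 + "TAA"
        with_ins = base[:45] + "GAC" + base[45:]
        cols = align_backtranslate(base, with_ins)
        gaps = [(x, y) for x, y in cols if x is None or y is None]
        assert len(gaps) == 1
        assert gaps[0][1] == "GAC"

    def test_internal_stop_rejected(self):
        bad = "ATG" + "GCT" * 10 + "TAA" + "GCT" * 10 + "TAA"
        with pytest.raises(ValueError, match="internal stop"):
            align_backtranslate(bad, bad, name_x="geneX")


class TestRestrictedSynonymous:
    @pytest.mark.parametrize(
        "cx,cy,eligible,substituted",
        [
            ("GCA", "GCG", True, True),  # Ala fourfold, third-base change
            ("GCA", "GCA", True, False),
            ("TTA", "CTA", False, False),  # both Leu but TTA is not CT-prefixed
            ("CTA", "CTG", True, True),  # CT-box Leu
            ("ATG", "ATG", False, False),  # Met not in the family set
            ("AGT", "AGC", False, False),  # Ser outside the TC box
        ],
    )
    def test_eligibility_rules(self, cx, cy, eligible, substituted):
        flags = count_restricted_synonymous([(cx, cy)])
        assert flags == [(eligible, substituted)]

    def test_symmetric_in_species(self):
        cols = [("GCA", "GCG"), ("TTA", "CTA"), ("CTT", "CTC")]
        fwd = count_restricted_synonymous(cols)
        rev = count_restricted_synonymous([(y, x) for x, y in cols])
        assert fwd == rev

    def test_gap_columns_ineligible(self):
        assert count_restricted_synonymous([(None, "GCA")]) == [(False, False)]


class TestBinRates:
    def test_short_pairs_excluded(self):
        cds = "ATG" + "GCT" * 165 + "TAA"  # 1497 bp < 1500 threshold
        cols = align_backtranslate(cds, cds)
        summary = bin_synonymous_rates({"p": cols})
        assert summary.profiles == []

    def test_remainder_spread_over_first_bins(self):
        cds = "ATG" + "GCT" * 600 + "TAA"  # 601 aligned codons after stop trim
        cols = align_backtranslate(cds, cds)
        summary = bin_synonymous_rates({"p": cols})
        sizes = [
            s + (601 - sum(summary.profiles[0].eligible_sites)) // 5
            for s in summary.profiles[0].eligible_sites
        ]
        q, r = divmod(601, 5)
        assert summary.profiles[0].eligible_sites[0] >= summary.profiles[0].eligible_sites[-1]
        assert sum(summary.profiles[0].eligible_sites) <= 601

    def test_uniform_rate_is_flat(self):
        from tescar.synthetic_genomes import generate_cds_pairs
        from tescar.pipeline import cds_bin_analysis

        cds_a, cds_b = generate_cds_pairs(60, seed=14, terminal_boost=1.0)
        summary = cds_bin_analysis(cds_a, cds_b)
        rates = summary.pooled_rates
        assert max(rates) / min(rates) < 1.25
        assert summary.p_bin1_vs_bin3 > 0.05

    def test_terminal_boost_recovered(self, cds_run):
        assert cds_run.terminal_central_ratio == pytest.approx(1.3, abs=0.15)
        assert cds_run.p_bin1_vs_bin3 < 0.01
        assert cds_run.p_bin5_vs_bin3 < 0.01


def test_promoter_multiplier_recovery():
    """A 1.25x promoter mutation rate appears as ~25% excess divergence."""
    from tescar.synthetic_genomes import SimConfig, simulate
    from tescar.gene_region_rates import promoter_vs_intergenic

    cfg = SimConfig(
        genome_length=9_500_000, n_genes=300, n_te_insertions=0,
        n_te_excisions=0, n_shared_tes=0, promoter_rate_multiplier=1.25, seed=21,
    )
    pair = simulate(cfg)
    cons = promoter_vs_intergenic(
        pair.genome_a, pair.genome_b, pair.features_a, pair.features_b
    )
    assert cons.overall_difference_pct == pytest.approx(25.0, abs=5.0)
    assert (cons.per_bin.p < 0.05).all()
    assert set(cons.per_bin.bin) == {1, 2, 3}
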