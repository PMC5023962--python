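"""Pipeline orchestration: genomes + annotations -> calls, profiles, reports.

The driving loop takes two genome sequences with TE annotations, finds
each annotated TE's orthologous locus in the partner genome (by
mapping flanking 1-kb segments with the k-mer seeded mapper), aligns
the locus pair, classifies the polymorphism, and feeds the classified
loci to the downstream analyses (flank profiles, gradient fit,
promoter/CDS rates, SNP-based excision prediction, LTR/TSD dating).

``run_pipeline`` executes the stages in dependency order on a
simulated genome pair and writes deterministic TSV reports: rerunning
with the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

import tescar
from tescar.align_core import LocusAlignment, chain_align
from tescar.discovery import discover_mites, find_high_snp_segments
from tescar.flank_profiles import build_profile, collect_flanks, fit_gradient
from tescar.gene_region_rates import (
    align_backtranslate,
    bidirectional_best_hits,
    bin_synonymous_rates,
    promoter_vs_intergenic,
)
from tescar.io_formats import FeatureRecord
from tescar.ltr_tsd import annotate_elements, compare_tsd_vs_ltr, filter_family_outliers, find_ltr_pairs
from tescar.orthology import GenomeIndex, map_segment
from tescar.polymorphisms import TeAnnotation, classify_polymorphism, calls_to_rows
from tescar.synthetic_genomes import (
    DEFAULT_TSD_LENGTHS,
    SimConfig,
    simulate,
    write_outputs,
)

DNA_SUPERFAMILIES = ("DTT", "DTH", "DTM", "DTA", "DTC")


@dataclass
class CallRecord:
    """One classified (or unresolvable) TE locus."""

    te_id: str
    carrier: str  # "A" | "B"
    call: Optional[object]  # PolymorphismCall, None if the locus could not be paired
    aln: Optional[LocusAlignment]
    locus_carrier: Optional[tuple[int, int]] = None
    locus_other: Optional[tuple[int, int]] = None
    anchor_carrier_genome: int = -1
    anchor_other_genome: int = -1


def locate_partner_locus(
    te_start: int,
    te_end: int,
    genome_carrier: str,
    index_other: GenomeIndex,
    flank: int,
    seg_len: int = 1000,
) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    """Map the TE's outer flank segments to find the orthologous interval.

    Returns ((carrier locus), (partner locus)) or None when either
    flank cannot be placed in the partner genome.
    """
    flank_l = min(flank, te_start)
    flank_r = min(flank, len(genome_carrier) - te_end)
    if flank_l < seg_len or flank_r < seg_len:
        return None
    a0, a1 = te_start - flank_l, te_end + flank_r

    def _map_flank(seg_start: int, insets=(0, 2000)) -> Optional[tuple[int, int]]:
        for inset in insets:
            s = seg_start + inset
            seg = genome_carrier[s : s + seg_len]
            if len(seg) < seg_len:
                continue
            hit = map_segment(seg, index_other)
            if hit is not None:
                return hit.start - inset, inset
        return None

    left = _map_flank(a0)
    right = _map_flank(a1 - seg_len, insets=(0, -2000))
    if left is None or right is None:
        return None
    b0 = max(0, left[0])
    b1 = min(len(index_other.genome), right[0] + seg_len)
    span_a = a1 - a0
    if not (0 < b1 - b0 < span_a + 20_000) or b1 - b0 < span_a // 4:
        return None
    return (a0, a1), (b0, b1)


def call_polymorphisms(
    genome_a: str,
    genome_b: str,
    features_a: list[FeatureRecord],
    features_b: list[FeatureRecord],
    flank: int = 12_000,
    tsd_lengths: Optional[dict[str, int]] = None,
    superfamilies: tuple[str, ...] = DNA_SUPERFAMILIES,
    indices: Optional[dict[str, GenomeIndex]] = None,
) -> list[CallRecord]:
    """Classify every annotated DNA-TE locus that is polymorphic.

    TEs annotated in both genomes at orthologous positions raise the
    classifier's "not polymorphic" error internally and are skipped.
    In each returned record the carrier genome is row A of the locus
    alignment.
    """
    tsd_lengths = tsd_lengths or DEFAULT_TSD_LENGTHS
    indices = indices or {"A": GenomeIndex(genome_a), "B": GenomeIndex(genome_b)}
    records: list[CallRecord] = []
    genomes = {"A": genome_a, "B": genome_b}
    for carrier, feats in (("A", features_a), ("B", features_b)):
        other = "B" if carrier == "A" else "A"
        g_car = genomes[carrier]
        for f in feats:
            if f.type not in superfamilies:
                continue
            te_id = f.attr("ID", f"{f.type}_{f.start}")
            pairing = locate_partner_locus(
                f.start, f.end, g_car, indices[other], flank
            )
            if pairing is None:
                records.append(CallRecord(te_id, carrier, None, None))
                continue
            (a0, a1), (b0, b1) = pairing
            aln = chain_align(
                g_car[a0:a1],
                genomes[other][b0:b1],
                seq_a_id=f"{te_id}:{carrier}",
                seq_b_id=f"{te_id}:{other}",
            )
            ann = TeAnnotation(
                te_id=te_id,
                superfamily=f.type,
                tsd_length=tsd_lengths[f.type],
                start=f.start - a0,
                end=f.end - a0,
                carrier="a",
            )
            try:
                call = classify_polymorphism(
                    aln, ann, locus_id=te_id, species_a=carrier, species_b=other
                )
            except ValueError:
                continue  # TE present in both genomes: not polymorphic
            records.append(
                CallRecord(
                    te_id=te_id,
                    carrier=carrier,
                    call=call,
                    aln=aln,
                    locus_carrier=(a0, a1),
                    locus_other=(b0, b1),
                    anchor_carrier_genome=a0 + call.anchor_carrier,
                    anchor_other_genome=b0 + call.anchor_noncarrier,
                )
            )
    return records


def classified_records(records: list[CallRecord]) -> list[CallRecord]:
    return [r for r in records if r.call is not None]


def excision_profile(records: list[CallRecord], min_aligned: int = 7000, **kwargs):
    pairs = [
        (r.call, r.aln)
        for r in classified_records(records)
        if r.call.call_class.startswith("excision")
    ]
    return build_profile(collect_flanks(pairs, min_aligned), "excision", **kwargs)


def insertion_profile(records: list[CallRecord], min_aligned: int = 7000, **kwargs):
    pairs = [
        (r.call, r.aln)
        for r in classified_records(records)
        if r.call.call_class == "insertion"
    ]
    return build_profile(collect_flanks(pairs, min_aligned), "insertion", **kwargs)


def extract_cds_sets(
    genome_a: str, genome_b: str, features_a, features_b
) -> tuple[dict[str, str], dict[str, str]]:
    """CDS sequences per genome from gene annotations (intronless genes)."""
    cds_a = {
        f.attr("ID"): genome_a[f.start : f.end]
        for f in features_a
        if f.type == "gene"
    }
    cds_b = {
        f.attr("ID"): genome_b[f.start : f.end]
        for f in features_b
        if f.type == "gene"
    }
    return cds_a, cds_b


def cds_bin_analysis(cds_a: dict[str, str], cds_b: dict[str, str], n_bins: int = 5):
    """Bidirectional best hits -> codon alignments -> binned synonymous rates."""
    pairs = bidirectional_best_hits(cds_a, cds_b)
    alignments = {}
    for aid, bid in pairs:
        try:
            alignments[f"{aid}|{bid}"] = align_backtranslate(
                cds_a[aid], cds_b[bid], aid, bid
            )
        except ValueError:
            continue  # internal stop codon: annotation artefact, skip pair
    return bin_synonymous_rates(alignments, n_bins=n_bins)


_STAGES = (
    "simulate",
    "classify",
    "profile",
    "ltr",
    "gene_rates",
    "discovery",
    "report",
)


def run_pipeline(
    config: Optional[dict] = None,
    outdir: str | Path = "tescar_out",
    seed: int = 0,
    stages: tuple[str, ...] = _STAGES,
) -> dict:
    """Run the full demo pipeline on a simulated genome pair.

    ``config`` may carry a ``sim`` section with :class:`SimConfig`
    overrides and a ``classify`` section (``flank``).  All outputs are
    plain TSV with fixed float formatting, so identical seeds give
    byte-identical reports.
    """
    config = config or {}
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.get("sim", {}))
    sim_kwargs.setdefault("seed", seed)
    sim_cfg = SimConfig(**sim_kwargs)
    results: dict = {"config": sim_cfg}

    def _write(df: pd.DataFrame, name: str):
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    pair = simulate(sim_cfg)
    results["pair"] = pair
    if "simulate" in stages:
        write_outputs(pair, outdir / "genomes")

    records = []
    if "classify" in stages:
        flank = int(config.get("classify", {}).get("flank", 12_000))
        records = call_polymorphisms(
            pair.genome_a, pair.genome_b, pair.features_a, pair.features_b, flank=flank
        )
        results["records"] = records
        rows = calls_to_rows([r.call for r in classified_records(records)])
        for row, rec in zip(rows, classified_records(records)):
            row["carrier"] = rec.carrier
            row["anchor_carrier_genome"] = rec.anchor_carrier_genome
            row["anchor_other_genome"] = rec.anchor_other_genome
        _write(pd.DataFrame(rows), "calls.tsv")

    if "profile" in stages and records:
        prof = excision_profile(records)
        results["excision_profile"] = prof
        if prof.n_alignments:
            for kind, name in (("substitution", "profile_substitutions.tsv"),
                               ("indel", "profile_indels.tsv")):
                centers, dens, mask = prof.windowed(kind)
                _write(
                    pd.DataFrame(
                        {"offset": centers, "density": dens, "usable": mask.astype(int)}
                    ),
                    name,
                )
            try:
                fit = fit_gradient(prof)
                results["gradient_fit"] = fit
                _write(
                    pd.DataFrame(
                        [{
                            "amplitude_observed": fit.amplitude,
                            "amplitude_excised_lineage": fit.amplitude_excised_lineage,
                            "scale_bp": fit.scale,
                            "baseline": fit.baseline,
                            "rmsd": fit.residual,
                        }]
                    ),
                    "gradient_fit.tsv",
                )
            except ValueError:
                pass  # too few excisions in a small demo run

    if "ltr" in stages and pair.ltr_consensus:
        elements = find_ltr_pairs(pair.genome_a, pair.ltr_consensus)
        annotate_elements(elements, pair.genome_a)
        kept = filter_family_outliers(elements)
        results["ltr_elements"] = kept
        _write(
            pd.DataFrame(
                [
                    {
                        "element_id": e.element_id,
                        "family": e.family,
                        "left_start": e.left[0],
                        "left_end": e.left[1],
                        "right_start": e.right[0],
                        "right_end": e.right[1],
                        "ltr_identity": e.ltr_identity,
                        "ltr_mismatches": e.ltr_mismatches,
                        "tsd_5prime": e.tsd_5prime,
                        "tsd_3prime": e.tsd_3prime,
                        "tsd_mismatches": e.tsd_mismatches,
                    }
                    for e in kept
                ]
            ),
            "ltr_elements.tsv",
        )
        if len([e for e in kept if not e.unreliable]) >= 10:
            comp = compare_tsd_vs_ltr(kept)
            results["tsd_ltr"] = comp
            _write(
                pd.DataFrame([comp.__dict__]),
                "tsd_ltr.tsv",
            )

    if "gene_rates" in stages:
        cons = promoter_vs_intergenic(
            pair.genome_a, pair.genome_b, pair.features_a, pair.features_b
        )
        results["promoter_conservation"] = cons
        _write(cons.per_bin, "promoter_bins.tsv")
        _write(cons.table, "promoter_loci.tsv")
        cds_a, cds_b = extract_cds_sets(
            pair.genome_a, pair.genome_b, pair.features_a, pair.features_b
        )
        if cds_a:
            summary = cds_bin_analysis(cds_a, cds_b)
            results["cds_bins"] = summary
            _write(
                pd.DataFrame(
                    {
                        "bin": range(1, len(summary.pooled_rates) + 1),
                        "substitutions": summary.pooled_substitutions,
                        "eligible_sites": summary.pooled_sites,
                        "rate_per_kb": summary.pooled_rates,
                    }
                ),
                "cds_bins.tsv",
            )

    if "discovery" in stages and records:
        alns = [r.aln for r in classified_records(records)]
        segs = find_high_snp_segments(alns, sim_cfg.background_sub_rate)
        results["high_snp_segments"] = segs
        _write(
            pd.DataFrame(
                [
                    {
                        "locus_id": s.locus_id,
                        "start": s.start,
                        "end": s.end,
                        "density": s.snp_density,
                        "class": s.classification,
                    }
                    for s in segs
                ]
            ),
            "high_snp_segments.tsv",
        )
        mites = discover_mites(pair.genome_a[: min(len(pair.genome_a), 300_000)])
        results["tir_candidates"] = mites
        _write(
            pd.DataFrame(
                [
                    {
                        "start": c.start,
                        "end": c.end,
                        "stem_length": c.stem_length,
                        "stem_identity": c.stem_identity,
                        "copies": c.copy_count,
                    }
                    for c in mites
                ]
            ),
            "tir_candidates.tsv",
        )

    if "report" in stages:
        log = {
            "tescar_version": tescar.__version__,
            "seed": seed,
            "stages": list(stages),
            "sim_config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sim_cfg.__dict__.items()
            },
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return results
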