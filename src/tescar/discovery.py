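"""Excision-site prediction from SNP accumulations and de novo TIR discovery.

Error-prone repair concentrates substitutions around excision sites,
so windows whose SNP density far exceeds the genome background are
promising places to look for excision scars.  ``find_high_snp_segments``
formalizes this as >= ``threshold_fold`` x background in a sliding
window; ``excision_enrichment`` then contrasts how often event
categories (excisions, insertions, repeat slippage, plain InDels)
occur in high-SNP versus control loci with a chi-square test.

Small DNA transposons are discovered de novo from their terminal
inverted repeats (TIRs): overlapping 1-kb windows are locally aligned
against their own reverse complement; stems of >= 15 bp at >= 70%
identity nominate candidate elements, which are accepted when the
genome contains multiple further copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from tescar.align_core import (
    AlignScores,
    DEFAULT_SCORES,
    LocusAlignment,
    extract_events,
    local_align,
)
from tescar.io_formats import revcomp
from tescar.orthology import GenomeIndex
from tescar.stats import Contingency2x2, chi2_2x2


@dataclass
class SnpSegment:
    locus_id: str
    start: int  # alignment-column window bounds
    end: int
    snp_density: float
    classification: str  # "high_snp" | "control"

    def __post_init__(self):
        if self.snp_density < 0:
            raise ValueError("density must be >= 0")


def find_high_snp_segments(
    alignments: Iterable[LocusAlignment],
    background_rate: float,
    threshold_fold: float = 4.0,
    window: int = 500,
    step: int = 250,
) -> list[SnpSegment]:
    """Windows whose substitution density reaches ``threshold_fold`` x background.

    Density is substitutions per alignment column within the window.
    Overlapping qualifying windows of one locus are merged into one
    segment reporting the peak density.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    out: list[SnpSegment] = []
    threshold = threshold_fold * background_rate
    for aln in alignments:
        n = len(aln)
        if n < window:
            continue
        subs = np.zeros(n)
        for ev in extract_events(aln):
            if ev.kind == "substitution":
                subs[ev.position] += 1
        current: Optional[list] = None
        for start in range(0, n - window + 1, step):
            dens = subs[start : start + window].sum() / window
            if dens >= threshold:
                if current is not None and start <= current[1]:
                    current[1] = start + window
                    current[2] = max(current[2], dens)
                else:
                    if current is not None:
                        out.append(
                            SnpSegment(aln.seq_a_id, current[0], current[1], current[2], "high_snp")
                        )
                    current = [start, start + window, dens]
        if current is not None:
            out.append(SnpSegment(aln.seq_a_id, current[0], current[1], current[2], "high_snp"))
    return out


def select_control_loci(
    alignments: Iterable[LocusAlignment], background_rate: float, tolerance: float = 0.5
) -> list[LocusAlignment]:
    """Loci whose overall substitution density is within ``tolerance``
    of the genome background (the low-SNP control set)."""
    controls = []
    for aln in alignments:
        n_sub = sum(1 for ev in extract_events(aln) if ev.kind == "substitution")
        dens = n_sub / len(aln) if len(aln) else 0.0
        if abs(dens - background_rate) <= tolerance * background_rate:
            controls.append(aln)
    return controls


@dataclass
class EnrichmentResult:
    category: str
    n_high: int
    n_control: int
    high_total: int
    control_total: int
    chi2: float
    p: float


def excision_enrichment(
    high_ids: list[str],
    control_ids: list[str],
    events_by_locus: dict[str, Iterable[str]],
    categories: tuple[str, ...] = ("excision", "insertion", "repeat_slippage", "indel"),
) -> list[EnrichmentResult]:
    """Per-category 2x2 test: does the high-SNP set contain more loci
    with at least one event of the category than the control set?

    A zero-margin table yields p = NaN rather than an error.
    """
    if not high_ids or not control_ids:
        raise ValueError("both locus sets must be non-empty")
    results = []
    for cat in categories:
        n_high = sum(1 for lid in high_ids if cat in set(events_by_locus.get(lid, ())))
        n_ctrl = sum(1 for lid in control_ids if cat in set(events_by_locus.get(lid, ())))
        table = Contingency2x2(
            n_high, len(high_ids) - n_high, n_ctrl, len(control_ids) - n_ctrl
        )
        try:
            chi2, p = chi2_2x2(table)
        except ValueError:
            chi2, p = float("nan"), float("nan")
        results.append(
            EnrichmentResult(cat, n_high, n_ctrl, len(high_ids), len(control_ids), chi2, p)
        )
    return results


def detect_repeat_slippage(
    aln: LocusAlignment, max_unit: int = 6
) -> list[tuple]:
    """InDel events explained by micro/minisatellite copy-number change.

    An InDel whose inserted/deleted segment consists of >= 2 copies of
    a 1-6 bp unit that also matches the adjacent sequence is
    reclassified as replication slippage.  Returns (event, unit) pairs.
    """
    out = []
    for ev in extract_events(aln):
        if ev.kind != "indel":
            continue
        cols = slice(ev.position, ev.position + ev.length)
        gap_in_a = aln.aligned_a[cols.start] == "-"
        row = aln.aligned_b if gap_in_a else aln.aligned_a
        seg = row[cols].replace("-", "")
        if len(seg) < 2:
            continue
        for unit_len in range(1, max_unit + 1):
            if len(seg) % unit_len or len(seg) // unit_len < 2:
                continue
            unit = seg[:unit_len]
            if seg != unit * (len(seg) // unit_len):
                continue
            before = row[max(0, cols.start - unit_len) : cols.start].replace("-", "")
            after = row[cols.stop : cols.stop + 2 * unit_len].replace("-", "")[:unit_len]
            if before == unit or after == unit:
                out.append((ev, unit))
                break
    return out


@dataclass
class TirCandidate:
    """A putative small DNA transposon bounded by inverted repeats."""

    start: int
    end: int
    arm_left: tuple[int, int]
    arm_right: tuple[int, int]
    stem_length: int
    stem_identity: float
    window_origin: int
    copy_count: int = 0
    accepted: bool = False

    def __post_init__(self):
        if self.stem_length < 15 or self.stem_identity < 70.0:
            raise ValueError("TIR stem must be >= 15 bp at >= 70% identity")
        if self.arm_left[1] > self.arm_right[0]:
            raise ValueError("arms must not overlap")


def scan_inverted_repeats(
    genome: str,
    window: int = 1000,
    overlap: int = 500,
    min_stem: int = 15,
    min_identity: float = 70.0,
    scores: AlignScores = DEFAULT_SCORES,
) -> list[TirCandidate]:
    """Find TIR pairs by aligning each window against its reverse complement.

    Duplicate candidates arising from overlapping windows are merged.
    """
    if len(genome) < window:
        raise ValueError("genome shorter than the scan window")
    step = window - overlap
    candidates: list[TirCandidate] = []
    seen: list[tuple[int, int]] = []
    for wstart in range(0, len(genome) - window + 1, step):
        w = genome[wstart : wstart + window]
        aln = local_align(w, revcomp(w), scores)
        if len(aln) == 0:
            continue
        stem = aln.aligned_bases
        if stem < min_stem or aln.percent_identity < min_identity:
            continue
        a1 = (aln.start_a, aln.start_a + len(aln.aligned_a.replace("-", "")))
        rc_len = len(aln.aligned_b.replace("-", ""))
        a2 = (window - aln.start_b - rc_len, window - aln.start_b)
        left, right = (a1, a2) if a1[0] <= a2[0] else (a2, a1)
        if left[1] > right[0]:
            continue  # self-overlapping palindrome, not a TIR pair
        cand_start = wstart + left[0]
        cand_end = wstart + right[1]
        if any(abs(cand_start - s) <= 5 and abs(cand_end - e) <= 5 for s, e in seen):
            continue
        seen.append((cand_start, cand_end))
        candidates.append(
            TirCandidate(
                start=cand_start,
                end=cand_end,
                arm_left=(wstart + left[0], wstart + left[1]),
                arm_right=(wstart + right[0], wstart + right[1]),
                stem_length=stem,
                stem_identity=aln.percent_identity,
                window_origin=wstart,
            )
        )
    return candidates


def validate_copy_number(
    candidate: TirCandidate,
    genome: str,
    index: Optional[GenomeIndex] = None,
    min_hits: int = 3,
    min_len: int = 50,
    min_identity: float = 80.0,
    scores: AlignScores = DEFAULT_SCORES,
) -> bool:
    """Accept a candidate if the genome holds ``min_hits`` further copies.

    Hits must align >= ``min_len`` bases at >= ``min_identity``;
    the candidate's own locus is excluded.
    """
    if candidate.end - candidate.start < min_len:
        candidate.accepted = False
        return False
    index = index or GenomeIndex(genome)
    seq = genome[candidate.start : candidate.end]
    gpos, qpos = index.seed_positions(seq, step=2)
    hits = 0
    if gpos.size:
        diag = gpos - qpos
        order = np.argsort(diag, kind="stable")
        ds = diag[order]
        breaks = np.flatnonzero(np.diff(ds) > 100)
        for cl in np.split(ds, breaks + 1):
            if cl.size < 2:
                continue
            d0 = int(np.median(cl))
            hit_start = d0
            hit_end = d0 + len(seq)
            if hit_start < candidate.end and hit_end > candidate.start:
                continue  # self hit
            target = genome[max(0, d0 - 50) : min(len(genome), d0 + len(seq) + 50)]
            aln = local_align(seq, target, scores)
            if len(aln) and aln.aligned_bases >= min_len and aln.percent_identity >= min_identity:
                hits += 1
    candidate.copy_count = hits
    candidate.accepted = hits >= min_hits
    return candidate.accepted


def discover_mites(
    genome: str,
    window: int = 1000,
    overlap: int = 500,
    min_stem: int = 15,
    min_identity: float = 70.0,
    min_hits: int = 3,
    scores: AlignScores = DEFAULT_SCORES,
) -> list[TirCandidate]:
    """TIR scan followed by copy-number validation; returns accepted candidates."""
    index = GenomeIndex(genome)
    candidates = scan_inverted_repeats(genome, window, overlap, min_stem, min_identity, scores)
    return [
        c for c in candidates if validate_copy_number(c, genome, index, min_hits=min_hits)
    ]
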