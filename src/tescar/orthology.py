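"""Orthology verification by 1-kb segment mapping and reciprocal best loci.

Long query sequences rarely map as a single alignment between two
genomes — TE insertions and low-complexity tracts fragment them — so a
locus is instead split into 1,000-bp segments, each segment is mapped
independently (k-mer seeding + local alignment), and the locus whose
partner region collects the majority of mapped segments is called the
ortholog.  Reciprocity (each locus identifying the other) is required
for a pass.

Low-complexity segments (dinucleotide entropy < 1 bit) are treated as
unmappable, emulating the default filtering of word-seeded search
tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from tescar.align_core import AlignScores, DEFAULT_SCORES, LocusAlignment, local_align

_CODE = np.full(256, 0, dtype=np.uint64)
for i, c in enumerate(b"ACGT"):
    _CODE[c] = i


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of overlapping dinucleotide frequencies."""
    if len(seq) < 2:
        return 0.0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE[arr[:-1]] * 4 + _CODE[arr[1:]]
    counts = np.bincount(codes.astype(np.int64), minlength=16)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


class GenomeIndex:
    """Sorted k-mer index of one genome for seed-and-extend mapping."""

    def __init__(self, genome: str, k: int = 16):
        if k > 31:
            raise ValueError("k must be <= 31")
        self.genome = genome.upper()
        self.k = k
        arr = np.frombuffer(self.genome.encode(), dtype=np.uint8)
        self._kmers, self._positions = self._encode_sorted(arr, k)

    @staticmethod
    def _encode(arr: np.ndarray, k: int) -> np.ndarray:
        n = arr.size - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64)
        codes = _CODE[arr]
        out = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            out |= codes[j : n + j] << np.uint64(2 * (k - 1 - j))
        return out

    @classmethod
    def _encode_sorted(cls, arr: np.ndarray, k: int):
        kmers = cls._encode(arr, k)
        order = np.argsort(kmers, kind="stable")
        return kmers[order], order.astype(np.int64)

    def seed_positions(self, query: str, step: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Genome positions and query offsets of exact k-mer matches."""
        qarr = np.frombuffer(query.upper().encode(), dtype=np.uint8)
        qk = self._encode(qarr, self.k)[::step]
        qoff = np.arange(0, qk.size * step, step, dtype=np.int64)
        lo = np.searchsorted(self._kmers, qk, side="left")
        hi = np.searchsorted(self._kmers, qk, side="right")
        counts = hi - lo
        keep = counts > 0
        reps = counts[keep]
        idx = np.concatenate(
            [np.arange(l, h) for l, h in zip(lo[keep], hi[keep])]
        ) if keep.any() else np.empty(0, dtype=np.int64)
        gpos = self._positions[idx]
        qpos = np.repeat(qoff[keep], reps)
        return gpos, qpos


@dataclass
class SegmentHit:
    """Best genome placement of one query segment."""

    start: int
    end: int
    score: float
    aligned_bases: int
    identity: float
    alignment: LocusAlignment


def _candidate_windows(
    gpos: np.ndarray, qpos: np.ndarray, seg_len: int, bucket: int = 500, top: int = 2,
    min_votes: int = 3,
) -> list[tuple[int, int]]:
    """Diagonal-vote candidate windows, best first, ties leftmost."""
    if gpos.size == 0:
        return []
    diag = gpos - qpos
    buckets = diag // bucket
    uniq, counts = np.unique(buckets, return_counts=True)
    # merge adjacent buckets' votes so hits straddling a boundary count together
    merged = {}
    for u, c in zip(uniq, counts):
        merged[u] = merged.get(u, 0) + c
        merged[u + 1] = merged.get(u + 1, 0) + c
    ranked = sorted(merged.items(), key=lambda t: (-t[1], t[0]))
    out = []
    for b, votes in ranked[: top * 2]:
        if votes < min_votes:
            continue
        sel = (buckets == b) | (buckets == b - 1)
        if not sel.any():
            continue
        d0 = int(np.median(diag[sel]))
        start = max(0, d0 - 100)
        out.append((start, start + seg_len + 200))
        if len(out) >= top:
            break
    return out


def map_segment(
    segment: str,
    index: GenomeIndex,
    min_aligned: int = 600,
    scores: AlignScores = DEFAULT_SCORES,
    entropy_threshold: float = 1.0,
) -> Optional[SegmentHit]:
    """Best placement of ``segment`` in the indexed genome, or None.

    Low-complexity segments are masked; hits must align at least
    ``min_aligned`` bases.  Among equal-scoring placements the leftmost
    wins.
    """
    if dinucleotide_entropy(segment) < entropy_threshold:
        return None
    gpos, qpos = index.seed_positions(segment, step=4)
    windows = _candidate_windows(gpos, qpos, len(segment))
    best: Optional[SegmentHit] = None
    for wstart, wend in windows:
        target = index.genome[wstart : min(wend, len(index.genome))]
        if not target:
            continue
        aln = local_align(segment, target, scores)
        if len(aln) == 0 or aln.aligned_bases < min_aligned:
            continue
        hit = SegmentHit(
            start=wstart + aln.start_b,
            end=wstart + aln.start_b + len(aln.aligned_b.replace("-", "")),
            score=aln.score,
            aligned_bases=aln.aligned_bases,
            identity=aln.percent_identity,
            alignment=aln,
        )
        if best is None or hit.score > best.score or (
            hit.score == best.score and hit.start < best.start
        ):
            best = hit
    return best


def segment_locus(seq: str, segment_length: int = 1000) -> list[str]:
    """Consecutive non-overlapping full-length segments; the final
    short remainder is dropped (it could not satisfy the 600-bp
    aligned-length requirement downstream)."""
    if not seq:
        raise ValueError("empty locus sequence")
    return [
        seq[i : i + segment_length]
        for i in range(0, len(seq) - segment_length + 1, segment_length)
    ]


@dataclass
class OrthologyReport:
    locus_id: str
    n_segments: int
    n_mappable: int
    n_mapped_own: int
    n_mapped_other: int
    reciprocal: bool
    score: float
    verdict: str  # "pass" | "fail"


def _majority_region(hits: list[SegmentHit], span: int = 50_000) -> Optional[tuple[int, int]]:
    """Genomic window (width ``span``) collecting the most segment hits."""
    if not hits:
        return None
    starts = sorted(h.start for h in hits)
    best_count, best_start = 0, starts[0]
    for s in starts:
        count = sum(1 for x in starts if s <= x < s + span)
        if count > best_count:
            best_count, best_start = count, s
    return best_start, best_start + span


def verify_orthology(
    locus_a: tuple[int, int],
    locus_b: tuple[int, int],
    genome_a: str,
    genome_b: str,
    index_a: Optional[GenomeIndex] = None,
    index_b: Optional[GenomeIndex] = None,
    locus_id: str = "locus",
    segment_length: int = 1000,
    majority: float = 0.5,
) -> OrthologyReport:
    """Check that two loci are each other's orthologous region.

    Splits locus A into segments, maps them to genome B (and B's
    segments to genome A); the verdict is ``pass`` when more than
    ``majority`` of the segments that map anywhere land inside the
    partner locus, in both directions, and the majority regions
    reciprocally identify each other.
    """
    sa, ea = locus_a
    sb, eb = locus_b
    if not (0 <= sa < ea <= len(genome_a)):
        raise ValueError(f"locus {locus_id}: interval {locus_a} outside genome A")
    if not (0 <= sb < eb <= len(genome_b)):
        raise ValueError(f"locus {locus_id}: interval {locus_b} outside genome B")
    index_a = index_a or GenomeIndex(genome_a)
    index_b = index_b or GenomeIndex(genome_b)

    def _direction(seq: str, own_index, own_locus, other_index, other_locus):
        segs = segment_locus(seq, segment_length)
        hits_other, mapped_own, mappable = [], 0, 0
        in_partner = 0
        for seg in segs:
            own_hit = map_segment(seg, own_index)
            other_hit = map_segment(seg, other_index)
            if own_hit is None and other_hit is None:
                continue
            mappable += 1
            if own_hit is not None and own_locus[0] - 2000 <= own_hit.start < own_locus[1] + 2000:
                mapped_own += 1
            if other_hit is not None:
                hits_other.append(other_hit)
                if other_locus[0] - 2000 <= other_hit.start < other_locus[1] + 2000:
                    in_partner += 1
        return segs, mappable, mapped_own, in_partner, hits_other

    seq_a = genome_a[sa:ea]
    seq_b = genome_b[sb:eb]
    segs_a, mappable_a, own_a, in_b, hits_ab = _direction(
        seq_a, index_a, locus_a, index_b, locus_b
    )
    segs_b, mappable_b, own_b, in_a, hits_ba = _direction(
        seq_b, index_b, locus_b, index_a, locus_a
    )

    frac_ab = in_b / mappable_a if mappable_a else 0.0
    frac_ba = in_a / mappable_b if mappable_b else 0.0
    region_in_b = _majority_region(hits_ab, span=max(50_000, 2 * len(seq_a)))
    region_in_a = _majority_region(hits_ba, span=max(50_000, 2 * len(seq_b)))
    reciprocal = bool(
        region_in_b
        and region_in_a
        and region_in_b[0] < eb + 2000
        and region_in_b[1] > sb - 2000
        and region_in_a[0] < ea + 2000
        and region_in_a[1] > sa - 2000
    )
    score = min(frac_ab, frac_ba)
    verdict = "pass" if (frac_ab > majority and frac_ba > majority and reciprocal) else "fail"
    return OrthologyReport(
        locus_id=locus_id,
        n_segments=len(segs_a) + len(segs_b),
        n_mappable=mappable_a + mappable_b,
        n_mapped_own=own_a + own_b,
        n_mapped_other=in_b + in_a,
        reciprocal=reciprocal,
        score=score,
        verdict=verdict,
    )
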