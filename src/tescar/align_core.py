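"""Pairwise alignment engines and mutation-event extraction.

Small sequence pairs are aligned with exact affine-gap dynamic
programming (Needleman-Wunsch / Smith-Waterman via Biopython's
PairwiseAligner).  Long loci are aligned by anchor-and-chain: unique
shared k-mers are chained colinearly and the gaps between anchors are
closed with exact DP, which gives full-DP results on the nearly
identical sequences this package compares.

Mutation events are read off the gapped alignment: one substitution
per mismatching base-base column (N matches anything), and one InDel
event per maximal gap run in either row regardless of its length.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_GAP = ord("-")

# Largest DP matrix (cells) solved exactly with traceback; pairs up to
# ~5 kb x 5 kb stay within this, larger pairs go through anchor-chain.
MAX_DP_CELLS = 26_000_000


@dataclass(frozen=True)
class AlignScores:
    """blastn-like default scoring: +2/-3, affine gaps -10 open, -0.5 extend.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


DEFAULT_SCORES = AlignScores()


@lru_cache(maxsize=8)
def _matrix(match: float, mismatch: float):
    # N scores 0 against everything so unknown bases are never penalized
    letters = "ACGTN"
    m = substitution_matrices.Array(letters, dims=2)
    for x in letters:
        for y in letters:
            if "N" in (x, y):
                m[x, y] = 0.0
            else:
                m[x, y] = match if x == y else mismatch
    return m


@lru_cache(maxsize=16)
def _aligner(mode: str, scores: AlignScores) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix(scores.match, scores.mismatch)
    al.open_gap_score = scores.gap_open
    al.extend_gap_score = scores.gap_extend
    return al


@dataclass
class MutationEvent:
    """A substitution (length 1) or an InDel run counted as one event."""

    kind: str  # "substitution" | "indel"
    position: int  # alignment column, later reassigned to a signed offset
    length: int = 1

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind not in ("substitution", "indel"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class LocusAlignment:
    """A gapped pairwise alignment with coordinate maps into both sequences.

    ``start_a``/``start_b`` anchor the alignment in the source
    sequences (non-zero for local alignments).  ``col_to_a[i]`` is the
    0-based source coordinate of the base in row A at column i; gap
    columns carry the coordinate of the preceding base (-1 before the
    first).
    """

    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    start_a: int = 0
    start_b: int = 0
    score: float = 0.0

    _arr_a: np.ndarray = field(default=None, repr=False, compare=False)
    _arr_b: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        self._arr_a = np.frombuffer(self.aligned_a.encode(), dtype=np.uint8)
        self._arr_b = np.frombuffer(self.aligned_b.encode(), dtype=np.uint8)
        if len(self.aligned_a) and np.any((self._arr_a == _GAP) & (self._arr_b == _GAP)):
            raise ValueError("column gapped in both rows")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def col_to_a(self) -> np.ndarray:
        return np.cumsum(self._arr_a != _GAP) - 1 + self.start_a

    @property
    def col_to_b(self) -> np.ndarray:
        return np.cumsum(self._arr_b != _GAP) - 1 + self.start_b

    @property
    def base_both_mask(self) -> np.ndarray:
        return (self._arr_a != _GAP) & (self._arr_b != _GAP)

    @property
    def aligned_bases(self) -> int:
        return int(self.base_both_mask.sum())

    @property
    def matches(self) -> int:
        """Base-base columns that agree; N matches anything."""
        both = self.base_both_mask
        is_n = (self._arr_a == ord("N")) | (self._arr_b == ord("N"))
        return int((both & ((self._arr_a == self._arr_b) | is_n)).sum())

    @property
    def percent_identity(self) -> float:
        n = self.aligned_bases
        if n == 0:
            return 0.0
        return 100.0 * self.matches / n

    def column_of_a(self, coord: int) -> int:
        """Alignment column holding base ``coord`` of sequence A."""
        cols = np.flatnonzero(self._arr_a != _GAP)
        idx = coord - self.start_a
        if idx < 0 or idx >= cols.size:
            raise IndexError(f"coordinate {coord} outside row A")
        return int(cols[idx])

    def column_of_b(self, coord: int) -> int:
        cols = np.flatnonzero(self._arr_b != _GAP)
        idx = coord - self.start_b
        if idx < 0 or idx >= cols.size:
            raise IndexError(f"coordinate {coord} outside row B")
        return int(cols[idx])


def score_alignment(aligned_a: str, aligned_b: str, scores: AlignScores = DEFAULT_SCORES) -> float:
    """Affine-gap score of an existing gapped alignment."""
    a = np.frombuffer(aligned_a.encode(), dtype=np.uint8)
    b = np.frombuffer(aligned_b.encode(), dtype=np.uint8)
    both = (a != _GAP) & (b != _GAP)
    is_n = (a == ord("N")) | (b == ord("N"))
    n_neutral = int((both & is_n).sum())
    matches = int((both & (a == b) & ~is_n).sum())
    mismatches = int(both.sum()) - matches - n_neutral
    total = scores.match * matches + scores.mismatch * mismatches

    for gaps in ((a == _GAP), (b == _GAP)):
        padded = np.concatenate([[False], gaps, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            total += scores.gap_open + (e - s - 1) * scores.gap_extend
    return float(total)


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for {name}")
    return seq.upper()


def _from_biopython(aln, a_id: str, b_id: str) -> LocusAlignment:
    ga, gb = str(aln[0]), str(aln[1])
    blocks = aln.aligned
    if len(blocks[0]):
        start_a = int(blocks[0][0][0])
        start_b = int(blocks[1][0][0])
    else:
        start_a = start_b = 0
    return LocusAlignment(
        seq_a_id=a_id,
        seq_b_id=b_id,
        aligned_a=ga,
        aligned_b=gb,
        start_a=start_a,
        start_b=start_b,
        score=float(aln.score),
    )


def global_align(
    a: str,
    b: str,
    scores: AlignScores = DEFAULT_SCORES,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
) -> LocusAlignment:
    """Optimal affine-gap global alignment (anchor-chained above ~5 kb)."""
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    if len(a) * len(b) > MAX_DP_CELLS:
        return chain_align(a, b, scores, seq_a_id=seq_a_id, seq_b_id=seq_b_id)
    aligner = _aligner("global", scores)
    aln = aligner.align(a, b)[0]
    out = _from_biopython(aln, seq_a_id, seq_b_id)
    out.start_a = out.start_b = 0
    return out


def local_align(
    a: str,
    b: str,
    scores: AlignScores = DEFAULT_SCORES,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
) -> LocusAlignment:
    """Maximal-scoring local (Smith-Waterman) alignment.

    If no positive-scoring segment exists, an empty alignment is
    returned rather than raising.
    """
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    aligner = _aligner("local", scores)
    if aligner.score(a, b) <= 0:
        return LocusAlignment(seq_a_id, seq_b_id, "", "", score=0.0)
    return _from_biopython(aligner.align(a, b)[0], seq_a_id, seq_b_id)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _anchors(a: str, b: str, k: int) -> list[tuple[int, int]]:
    pa = _unique_kmer_positions(a, k)
    pb = _unique_kmer_positions(b, k)
    shared = [(pa[km], pb[km]) for km in pa.keys() & pb.keys()]
    shared.sort()
    if not shared:
        return []
    # longest chain with strictly increasing b (patience LIS)
    tails: list[int] = []
    back: list[int] = []
    tidx: list[int] = []
    for i, (_, y) in enumerate(shared):
        j = bisect.bisect_left(tails, y)
        if j == len(tails):
            tails.append(y)
            tidx.append(i)
        else:
            tails[j] = y
            tidx[j] = i
        back.append(tidx[j - 1] if j > 0 else -1)
    chain = []
    i = tidx[len(tails) - 1]
    while i >= 0:
        chain.append(shared[i])
        i = back[i]
    chain.reverse()
    # enforce non-overlap of k-mer footprints
    out = []
    last_a = last_b = -(10**9)
    for x, y in chain:
        if x >= last_a + k and y >= last_b + k:
            out.append((x, y))
            last_a, last_b = x, y
    return out


def _edlib_global(a: str, b: str) -> tuple[str, str]:
    import edlib

    res = edlib.align(a, b, task="path", mode="NW")
    ga_parts, gb_parts = [], []
    ia = ib = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            ga_parts.append(a[ia : ia + n])
            gb_parts.append(b[ib : ib + n])
            ia += n
            ib += n
        elif ch == "I":  # consumes query (a)
            ga_parts.append(a[ia : ia + n])
            gb_parts.append("-" * n)
            ia += n
        elif ch == "D":
            ga_parts.append("-" * n)
            gb_parts.append(b[ib : ib + n])
            ib += n
    return "".join(ga_parts), "".join(gb_parts)


def _align_segment(a: str, b: str, scores: AlignScores, k: int) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if len(a) * len(b) <= MAX_DP_CELLS:
        aligner = _aligner("global", scores)
        aln = aligner.align(a, b)[0]
        return str(aln[0]), str(aln[1])
    if k >= 12:
        anchors = _anchors(a, b, k)
        if anchors:
            return _assemble(a, b, anchors, scores, k)
        return _align_segment(a, b, scores, k - 4)
    # last resort for huge divergent segments: edit-distance path
    return _edlib_global(a, b)


def _assemble(
    a: str, b: str, anchors: list[tuple[int, int]], scores: AlignScores, k: int
) -> tuple[str, str]:
    ga_parts, gb_parts = [], []
    ca = cb = 0
    for x, y in anchors:
        sa, sb = _align_segment(a[ca:x], b[cb:y], scores, k)
        ga_parts.append(sa)
        gb_parts.append(sb)
        ga_parts.append(a[x : x + k])
        gb_parts.append(b[y : y + k])
        ca, cb = x + k, y + k
    sa, sb = _align_segment(a[ca:], b[cb:], scores, k)
    ga_parts.append(sa)
    gb_parts.append(sb)
    return "".join(ga_parts), "".join(gb_parts)


def chain_align(
    a: str,
    b: str,
    scores: AlignScores = DEFAULT_SCORES,
    k: int = 20,
    seq_a_id: str = "a",
    seq_b_id: str = "b",
) -> LocusAlignment:
    """Anchor-and-chain global alignment for long, similar sequences."""
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    anchors = _anchors(a, b, k)
    if anchors:
        ga, gb = _assemble(a, b, anchors, scores, k)
    else:
        ga, gb = _align_segment(a, b, scores, k - 4)
    return LocusAlignment(
        seq_a_id,
        seq_b_id,
        ga,
        gb,
        score=score_alignment(ga, gb, scores),
    )


def extract_events(aln: LocusAlignment) -> list[MutationEvent]:
    """Substitution and InDel events from a gapped alignment.

    Positions are alignment column indices; an InDel run of any length
    is a single event anchored at its first column.
    """
    a, b = aln._arr_a, aln._arr_b
    events: list[MutationEvent] = []
    if a.size == 0:
        return events
    both = (a != _GAP) & (b != _GAP)
    is_n = (a == ord("N")) | (b == ord("N"))
    sub_cols = np.flatnonzero(both & (a != b) & ~is_n)
    for col in sub_cols:
        events.append(MutationEvent("substitution", int(col), 1))
    for gaps in ((a == _GAP), (b == _GAP)):
        padded = np.concatenate([[False], gaps, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            events.append(MutationEvent("indel", int(s), int(e - s)))
    events.sort(key=lambda ev: (ev.position, ev.kind))
    return events


def windowed_density(
    events: Iterable[MutationEvent],
    region_length: int,
    window: int,
    step: int,
) -> list[tuple[float, float]]:
    """Sliding-window event density over [0, region_length).

    Each window fully contained in the region yields
    (window_center, events_per_bp); an InDel counts once at its anchor
    position.  A window longer than the region gives an empty series.
    """
    if step <= 0 or window < step:
        raise ValueError("require window >= step > 0")
    if window > region_length:
        return []
    positions = np.array([ev.position for ev in events], dtype=float)
    out = []
    for start in range(0, region_length - window + 1, step):
        n = int(((positions >= start) & (positions < start + window)).sum()) if positions.size else 0
        out.append((start + window / 2.0, n / window))
    return out


def write_alignments_tsv(alignments: Sequence[LocusAlignment], path) -> None:
    """Serialize alignments as a MAF-like TSV (one locus pair per row)."""
    with open(path, "w") as fh:
        fh.write("seq_a_id\tseq_b_id\tstart_a\tstart_b\tscore\taligned_a\taligned_b\n")
        for aln in alignments:
            fh.write(
                f"{aln.seq_a_id}\t{aln.seq_b_id}\t{aln.start_a}\t{aln.start_b}\t"
                f"{aln.score:g}\t{aln.aligned_a}\t{aln.aligned_b}\n"
            )


def read_alignments_tsv(path) -> list[LocusAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_a_id"):
            raise ValueError(f"unexpected alignment TSV header in {path}")
        for line in fh:
            sa, sb, st_a, st_b, score, ga, gb = line.rstrip("\n").split("\t")
            out.append(
                LocusAlignment(sa, sb, ga, gb, int(st_a), int(st_b), float(score))
            )
    return out
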