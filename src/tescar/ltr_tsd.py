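"""LTR retroelement identification, LTR-LTR divergence and TSD mutation burden.

The two long terminal repeats of a retroelement are identical at
insertion time, so the mismatches between them measure the element's
age.  The 5-bp target-site duplications created by the same insertion
are equally old; comparing the pooled mismatch rate of TSDs with that
of LTRs therefore isolates the extra mutation load that error-prone
repair deposited on the single-stranded target-site segments.

Elements are found consensus-driven: local-alignment hits of each
family's LTR consensus are paired when they lie on the same strand
less than 14 kb apart; overlapping candidates are resolved by summed
hit score.  Family outliers (LTR identity more than 2 SD below the
family mean, a signature of inter-element recombination) can be
removed before the rate comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from tescar.align_core import AlignScores, DEFAULT_SCORES, local_align
from tescar.orthology import GenomeIndex
from tescar.stats import Contingency2x2, chi2_2x2

MAX_ELEMENT_SPAN = 14_000
TSD_LENGTH = 5


@dataclass
class LTRElement:
    element_id: str
    family: str
    left: tuple[int, int]
    right: tuple[int, int]
    score: float = 0.0
    ltr_identity: float = float("nan")
    ltr_mismatches: int = 0
    ltr_aligned: int = 0
    tsd_5prime: str = ""
    tsd_3prime: str = ""
    tsd_mismatches: int = 0
    unreliable: bool = False

    def __post_init__(self):
        if self.left[1] > self.right[0]:
            raise ValueError("left LTR must end before right LTR starts")
        if self.right[1] - self.left[0] >= MAX_ELEMENT_SPAN:
            raise ValueError("element span exceeds the 14 kb candidate limit")

    @property
    def span(self) -> tuple[int, int]:
        return self.left[0], self.right[1]


def _consensus_hits(
    consensus: str,
    index: GenomeIndex,
    min_votes: int = 5,
    min_aligned_frac: float = 0.5,
    min_identity: float = 70.0,
    scores: AlignScores = DEFAULT_SCORES,
) -> list[dict]:
    """All confident placements of an LTR consensus in the genome."""
    gpos, qpos = index.seed_positions(consensus, step=4)
    if gpos.size == 0:
        return []
    diag = gpos - qpos
    order = np.argsort(diag, kind="stable")
    diag_sorted = diag[order]
    # cluster diagonals closer than 200 bp
    breaks = np.flatnonzero(np.diff(diag_sorted) > 200)
    clusters = np.split(diag_sorted, breaks + 1)
    hits = []
    seen_windows: list[tuple[int, int]] = []
    for cl in clusters:
        if cl.size < min_votes:
            continue
        d0 = int(np.median(cl))
        wstart = max(0, d0 - 100)
        wend = min(len(index.genome), d0 + len(consensus) + 100)
        if any(ws <= wstart < we for ws, we in seen_windows):
            continue
        seen_windows.append((wstart, wend))
        aln = local_align(consensus, index.genome[wstart:wend], scores)
        if len(aln) == 0:
            continue
        aligned = aln.aligned_bases
        if aligned < min_aligned_frac * len(consensus) or aln.percent_identity < min_identity:
            continue
        # extrapolate to the full consensus extent: local alignment trims
        # mutated terminal bases, which would shift the TSD windows
        cons_used = len(aln.aligned_a.replace("-", ""))
        start = wstart + aln.start_b - aln.start_a
        end = (
            wstart + aln.start_b + len(aln.aligned_b.replace("-", ""))
            + (len(consensus) - aln.start_a - cons_used)
        )
        hits.append(
            {
                "start": max(0, start),
                "end": min(len(index.genome), end),
                "score": aln.score,
                "identity": aln.percent_identity,
            }
        )
    hits.sort(key=lambda h: h["start"])
    return hits


def find_ltr_pairs(
    genome: str,
    consensus_set: dict[str, str],
    index: Optional[GenomeIndex] = None,
    max_span: int = MAX_ELEMENT_SPAN,
    scores: AlignScores = DEFAULT_SCORES,
) -> list[LTRElement]:
    """Candidate full-length elements: same-family hit pairs < 14 kb apart.

    Consensus sequences shorter than 100 bp are rejected.  Overlapping
    candidates are resolved in favour of the highest summed hit score.
    """
    for fam, seq in consensus_set.items():
        if len(seq) < 100:
            raise ValueError(f"LTR consensus {fam!r} shorter than 100 bp")
    index = index or GenomeIndex(genome)
    candidates = []
    for fam in sorted(consensus_set):
        hits = _consensus_hits(consensus_set[fam], index, scores=scores)
        for i, h1 in enumerate(hits):
            for h2 in hits[i + 1 :]:
                if h2["start"] <= h1["end"]:
                    continue
                if h2["end"] - h1["start"] >= max_span:
                    break
                candidates.append(
                    {
                        "family": fam,
                        "left": (h1["start"], h1["end"]),
                        "right": (h2["start"], h2["end"]),
                        "score": h1["score"] + h2["score"],
                    }
                )
    candidates.sort(key=lambda c: (-c["score"], c["left"][0]))
    accepted: list[LTRElement] = []
    taken: list[tuple[int, int]] = []
    for i, cand in enumerate(candidates):
        span = (cand["left"][0], cand["right"][1])
        if any(span[0] < e and span[1] > s for s, e in taken):
            continue
        taken.append(span)
        accepted.append(
            LTRElement(
                element_id=f"{cand['family']}_elem{len(accepted)+1:04d}",
                family=cand["family"],
                left=cand["left"],
                right=cand["right"],
                score=cand["score"],
            )
        )
    accepted.sort(key=lambda e: e.left[0])
    return accepted


def ltr_divergence(
    elem: LTRElement, genome: str, scores: AlignScores = DEFAULT_SCORES
) -> tuple[int, float]:
    """Mismatches and percent identity between the two LTRs of an element.

    The LTR copies are locally aligned; mismatches are counted over
    base-base columns.  Elements whose LTR alignment covers less than
    half of the shorter LTR are flagged ``unreliable``.
    """
    left = genome[elem.left[0] : elem.left[1]]
    right = genome[elem.right[0] : elem.right[1]]
    aln = local_align(left, right, scores)
    aligned = aln.aligned_bases if len(aln) else 0
    elem.ltr_aligned = aligned
    if aligned < 0.5 * min(len(left), len(right)):
        elem.unreliable = True
        elem.ltr_identity = float("nan")
        elem.ltr_mismatches = 0
        return 0, float("nan")
    elem.ltr_mismatches = aligned - aln.matches
    elem.ltr_identity = aln.percent_identity
    return elem.ltr_mismatches, elem.ltr_identity


def extract_tsds(elem: LTRElement, genome: str) -> None:
    """Fill in the 5-bp flanks of the element and their ungapped mismatches."""
    s, e = elem.span
    elem.tsd_5prime = genome[max(0, s - TSD_LENGTH) : s]
    elem.tsd_3prime = genome[e : e + TSD_LENGTH]
    if len(elem.tsd_5prime) == len(elem.tsd_3prime) == TSD_LENGTH:
        elem.tsd_mismatches = sum(
            1 for x, y in zip(elem.tsd_5prime, elem.tsd_3prime) if x != y
        )
    else:
        elem.unreliable = True


def annotate_elements(
    elements: list[LTRElement], genome: str, scores: AlignScores = DEFAULT_SCORES
) -> list[LTRElement]:
    for elem in elements:
        ltr_divergence(elem, genome, scores)
        extract_tsds(elem, genome)
    return elements


def filter_family_outliers(elements: list[LTRElement]) -> list[LTRElement]:
    """Drop elements with LTR identity > 2 SD below their family mean.

    Families with fewer than 3 reliable elements are retained
    unfiltered (with a warning): the SD would be meaningless.
    """
    by_family: dict[str, list[LTRElement]] = {}
    for e in elements:
        by_family.setdefault(e.family, []).append(e)
    kept: list[LTRElement] = []
    for fam in sorted(by_family):
        group = [e for e in by_family[fam] if not e.unreliable]
        unreliable = [e for e in by_family[fam] if e.unreliable]
        if len(group) < 3:
            warnings.warn(
                f"family {fam}: only {len(group)} reliable elements; 2-SD filter skipped"
            )
            kept.extend(group)
            continue
        ids = np.array([e.ltr_identity for e in group])
        cutoff = ids.mean() - 2.0 * ids.std()
        kept.extend(e for e in group if e.ltr_identity >= cutoff)
        del unreliable
    kept.sort(key=lambda e: e.left[0])
    return kept


@dataclass
class TsdLtrComparison:
    n_elements: int
    tsd_mismatches: int
    tsd_sites: int
    ltr_mismatches: int
    ltr_sites: int
    rate_tsd: float
    rate_ltr: float
    ratio: float  # NaN when undefined
    chi2: float
    p: float


def compare_tsd_vs_ltr(elements: list[LTRElement]) -> TsdLtrComparison:
    """Pooled substitution burden in TSDs versus LTRs with a chi-square test."""
    usable = [e for e in elements if not e.unreliable]
    if len(usable) < 10:
        raise ValueError(f"need >= 10 reliable elements, have {len(usable)}")
    tsd_mism = sum(e.tsd_mismatches for e in usable)
    tsd_sites = TSD_LENGTH * len(usable)
    ltr_mism = sum(e.ltr_mismatches for e in usable)
    ltr_sites = sum(e.ltr_aligned for e in usable)
    if ltr_sites == 0:
        raise ValueError("no aligned LTR sites")
    rate_tsd = tsd_mism / tsd_sites
    rate_ltr = ltr_mism / ltr_sites
    ratio = rate_tsd / rate_ltr if rate_ltr > 0 and tsd_mism > 0 else float("nan")
    try:
        chi2, p = chi2_2x2(
            Contingency2x2(tsd_mism, tsd_sites - tsd_mism, ltr_mism, ltr_sites - ltr_mism)
        )
    except ValueError:
        chi2, p = float("nan"), float("nan")
    return TsdLtrComparison(
        n_elements=len(usable),
        tsd_mismatches=tsd_mism,
        tsd_sites=tsd_sites,
        ltr_mismatches=ltr_mism,
        ltr_sites=ltr_sites,
        rate_tsd=rate_tsd,
        rate_ltr=rate_ltr,
        ratio=ratio,
        chi2=chi2,
        p=p,
    )
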