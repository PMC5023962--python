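"""Classification of TE presence/absence loci into insertions and excision types.

A DNA transposon that *inserted* in one lineage is flanked by the two
units of its target-site duplication (TSD) in the carrier, while the
other genome holds a single copy of the target site.  A transposon
that *excised* from one lineage leaves a scar instead: a perfect
excision retains both TSD units and nothing else; excisions with
deletions remove flanking sequence (with one breakpoint within 3 bp of
a TE end, which distinguishes them from random deletions); excisions
with fillers replace the TE with unrelated DNA captured during
double-strand-break repair.  Events matching none of these patterns
are reported as ``ambiguous`` — never an error.

The classifier works in sequence space rather than trusting exact gap
placement (which is ambiguous around direct repeats): it anchors on
clean flank alignment well outside the TE, extracts the non-carrier
junction sequence, and compares it by edit distance against the two
reconstructable patterns — "TE removed, both TSD units kept" (perfect
excision) and "TE plus one TSD unit removed" (insertion).  Loci
matching neither pattern are resolved into deletion/filler excisions
from the breakpoint offsets, or reported ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tescar.align_core import LocusAlignment, local_align

CLASSES = (
    "insertion",
    "excision_perfect",
    "excision_deletion",
    "excision_filler",
    "ambiguous",
)


@dataclass
class TeAnnotation:
    """A TE interval in the carrier row of a locus alignment.

    ``start``/``end`` are coordinates in the carrier sequence (the
    alignment row that contains the TE); ``carrier`` names that row.
    """

    te_id: str
    superfamily: str
    tsd_length: int
    start: int
    end: int
    carrier: str = "a"  # "a" | "b"


@dataclass
class PolymorphismCall:
    locus_id: str
    te_id: str
    superfamily: str
    species_with_te: str
    call_class: str
    anchor_column: int
    anchor_carrier: int = -1
    anchor_noncarrier: int = -1
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.call_class not in CLASSES:
            raise ValueError(f"unknown class {self.call_class!r}")


def detect_tsd(
    carrier_seq: str, te_interval: tuple[int, int], tsd_length: int
) -> Optional[tuple[str, str, int]]:
    """TSD copies flanking a TE, if they agree with at most 1 mismatch.

    Compares the ``tsd_length`` bases immediately before the TE start
    with those immediately after the TE end.  Returns
    (left_copy, right_copy, n_mismatches) or None (also when the TE
    sits too close to a sequence edge to have full flanks).
    """
    ts, te = te_interval
    k = tsd_length
    if ts - k < 0 or te + k > len(carrier_seq):
        return None
    left = carrier_seq[ts - k : ts]
    right = carrier_seq[te : te + k]
    mism = sum(1 for x, y in zip(left, right) if x != y)
    if mism <= 1:
        return left, right, mism
    return None


def _swap(aln: LocusAlignment) -> LocusAlignment:
    return LocusAlignment(
        seq_a_id=aln.seq_b_id,
        seq_b_id=aln.seq_a_id,
        aligned_a=aln.aligned_b,
        aligned_b=aln.aligned_a,
        start_a=aln.start_b,
        start_b=aln.start_a,
        score=aln.score,
    )


def _edit_distance(x: str, y: str) -> int:
    import edlib

    if not x or not y:
        return max(len(x), len(y))
    return edlib.align(x, y, mode="NW")["editDistance"]


def _prefix_break(query: str, template: str) -> int:
    """Leading query bases explained by the template (the flank side).

    Walks the two strings in register, tolerating the few-percent
    substitution noise of diverged flanks (budget 3 + 15% of length),
    then trims back to the last position whose 8-base context holds at
    least 5 matches — beyond a breakpoint, matches are random (~25%)
    and fail that bar almost immediately.
    """
    n = min(len(query), len(template))
    if n == 0:
        return 0
    q = np.frombuffer(query[:n].encode(), dtype=np.uint8)
    t = np.frombuffer(template[:n].encode(), dtype=np.uint8)
    u = q == t
    mism = np.cumsum(~u)
    ok = np.flatnonzero(mism <= 0.15 * np.arange(1, n + 1) + 3)
    if ok.size == 0:
        return 0
    p0 = min(int(ok[-1]) + 8, n)
    w = np.convolve(u[:p0].astype(int), np.ones(8, dtype=int), mode="full")[: p0]
    good = np.flatnonzero(u[:p0] & (w >= 5))
    return int(good[-1]) + 1 if good.size else 0


def _scar_geometry(junction_nc: str, carrier_zone: str) -> tuple[int, int, int]:
    """Breakpoints of the removed/replaced block.

    The non-carrier junction is modelled as
    ``zone-prefix + interstitial + zone-suffix``; returns
    (t0, t1, interstitial_length) where [t0, t1) is the carrier-zone
    span missing from (or replaced in) the non-carrier.
    """
    p = _prefix_break(junction_nc, carrier_zone)
    s = _prefix_break(junction_nc[::-1], carrier_zone[::-1])
    if p + s > len(junction_nc):  # overlapping explanations: split evenly
        excess = p + s - len(junction_nc)
        p -= excess // 2 + excess % 2
        s -= excess // 2
    t0 = p
    t1 = len(carrier_zone) - s
    return t0, t1, len(junction_nc) - p - s


def classify_polymorphism(
    aln: LocusAlignment,
    te: TeAnnotation,
    locus_id: str = "locus",
    species_a: str = "A",
    species_b: str = "B",
) -> PolymorphismCall:
    """Classify one TE presence/absence locus.

    ``aln`` must span the TE with flanking sequence on both sides; the
    TE may be present in only one row (otherwise the locus is not
    polymorphic and a ``ValueError`` is raised).
    """
    if te.carrier == "b":
        call = classify_polymorphism(
            _swap(aln),
            TeAnnotation(te.te_id, te.superfamily, te.tsd_length, te.start, te.end, "a"),
            locus_id=locus_id,
            species_a=species_b,
            species_b=species_a,
        )
        return call

    carrier_seq = aln.aligned_a.replace("-", "")
    noncar_seq = aln.aligned_b.replace("-", "")
    ts, tend = te.start, te.end
    te_len = tend - ts
    k = te.tsd_length

    c0 = aln.column_of_a(ts)
    c1 = aln.column_of_a(tend - 1) + 1

    arr_a, arr_b = aln._arr_a, aln._arr_b
    bb = (arr_a != ord("-")) & (arr_b != ord("-"))
    col_a, col_b = aln.col_to_a, aln.col_to_b

    # bases of the non-carrier row aligned within the TE span
    span_bases = int((arr_b[c0:c1] != ord("-")).sum())
    if span_bases > 0.5 * te_len:
        raise ValueError(
            f"{locus_id}: TE {te.te_id} present in both rows — not polymorphic"
        )

    base = dict(
        locus_id=locus_id,
        te_id=te.te_id,
        superfamily=te.superfamily,
        species_with_te=species_a,
        anchor_column=c0,
    )

    # reference anchors on clean flank alignment, well clear of the junction
    ref_gap = 40
    bb_cols = np.flatnonzero(bb)
    left_ref = bb_cols[(bb_cols < c0) & (col_a[bb_cols] <= ts - ref_gap)]
    right_ref = bb_cols[(bb_cols >= c1) & (col_a[bb_cols] >= tend + ref_gap - 1)]
    if left_ref.size == 0 or right_ref.size == 0:
        return PolymorphismCall(**base, call_class="ambiguous", details={"reason": "no_flank"})
    lcol, rcol = int(left_ref[-1]), int(right_ref[0])
    lc, ln = int(col_a[lcol]), int(col_b[lcol])
    rc, rn = int(col_a[rcol]), int(col_b[rcol])

    junction_nc = noncar_seq[ln + 1 : rn]  # non-carrier sequence across the junction
    left_flank = carrier_seq[lc + 1 : ts]  # ends with the 5' TSD unit
    right_flank = carrier_seq[tend : rc]  # starts with the 3' TSD unit
    p_perfect = left_flank + right_flank
    p_insert = left_flank + carrier_seq[tend + k : rc]  # TE plus one TSD unit gone

    d_perf = _edit_distance(junction_nc, p_perfect)
    d_ins = _edit_distance(junction_nc, p_insert)
    tol = max(3, int(0.12 * len(p_perfect)))

    tsd_hit = detect_tsd(carrier_seq, (ts, tend), k)
    anchors = dict(anchor_carrier=ts, anchor_noncarrier=ln + (ts - lc))
    details = {
        "d_perfect": d_perf,
        "d_insertion": d_ins,
        "tsd_mismatches": tsd_hit[2] if tsd_hit else None,
        "tsd_left": tsd_hit[0] if tsd_hit else None,
        "zone_col_start": lcol + 1,
        "zone_col_end": rcol,
    }

    if min(d_perf, d_ins) <= tol:
        if d_perf == d_ins:
            # equal edit distance: break the tie on junction length —
            # a partial extra TSD remnant argues for an excision scar,
            # an exact single-unit junction for an insertion
            gap_perf = abs(len(junction_nc) - len(p_perfect))
            gap_ins = abs(len(junction_nc) - len(p_insert))
            if gap_perf == gap_ins:
                # a TE sitting in a pre-existing direct repeat: a perfect
                # excision and an insertion leave the same junction
                return PolymorphismCall(
                    **base, call_class="ambiguous", **anchors,
                    details={**details, "reason": "insertion_or_excision_into_repeat"},
                )
            d_perf += 0 if gap_perf < gap_ins else 1
            d_ins += 0 if gap_ins < gap_perf else 1
        if d_perf < d_ins:
            return PolymorphismCall(
                **base, call_class="excision_perfect", **anchors, details=details
            )
        if tsd_hit is None:
            return PolymorphismCall(
                **base, call_class="ambiguous", **anchors,
                details={**details, "reason": "insertion_pattern_without_tsd"},
            )
        return PolymorphismCall(**base, call_class="insertion", **anchors, details=details)

    # breakpoints of the scar relative to the carrier zone
    t0, t1, n_between = _scar_geometry(junction_nc, carrier_seq[lc + 1 : rc])
    left_off = (lc + 1 + t0) - ts  # <0: breakpoint inside the left flank
    right_off = (lc + 1 + t1) - tend  # >0: breakpoint beyond the TE end
    details.update(
        left_offset=left_off, right_offset=right_off, interstitial_bases=n_between
    )

    if n_between >= 10:
        filler = junction_nc[t0 : len(junction_nc) - (len(carrier_seq[lc + 1 : rc]) - t1)]
        rel = local_align(filler, carrier_seq[ts:tend])
        covered = len(rel.aligned_a.replace("-", "")) if len(rel) else 0
        related = covered >= 0.7 * len(filler) and rel.percent_identity >= 70.0
        near_end = min(abs(left_off), abs(right_off)) <= 5
        if not related and near_end:
            return PolymorphismCall(
                **base, call_class="excision_filler", **anchors,
                details={**details, "filler_length": n_between,
                         "deletion_extent": max(0, -left_off) + max(0, right_off)},
            )
        return PolymorphismCall(
            **base, call_class="ambiguous", **anchors,
            details={**details,
                     "reason": "interstitial_related" if related else "breakpoint_far"},
        )

    # excision with deletion: one breakpoint within 3 bp of a TE end,
    # the other removing flanking sequence beyond the TSD
    if (abs(left_off) <= 5 and right_off >= k + 4) or (abs(right_off) <= 5 and -left_off >= k + 4):
        return PolymorphismCall(
            **base, call_class="excision_deletion", **anchors,
            details={**details, "deletion_extent": -left_off + right_off},
        )

    return PolymorphismCall(
        **base, call_class="ambiguous", **anchors,
        details={**details, "reason": "unmatched_pattern"},
    )


def calls_to_rows(calls: list[PolymorphismCall]) -> list[dict]:
    """Flatten calls for TSV output."""
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "te_id": c.te_id,
                "superfamily": c.superfamily,
                "species_with_te": c.species_with_te,
                "class": c.call_class,
                "anchor_column": c.anchor_column,
                "anchor_carrier": c.anchor_carrier,
                "anchor_noncarrier": c.anchor_noncarrier,
                "deletion_extent": c.details.get("deletion_extent", 0),
                "filler_length": c.details.get("filler_length", 0),
            }
        )
    return rows
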