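"""Gene-centred mutation rates: TE positions, promoter conservation, CDS bins.

Three analyses that connect transposon activity to gene evolution:

* the positional distribution of annotated TEs around transcription
  start/end points (DNA transposons cluster in the 2 kb up/downstream
  of grass genes);
* sequence conservation of 2-kb promoters versus the middles of long
  (>= 10 kb) intergenic gaps, stratified into three chromosome-arm
  bins because conservation drops toward the centromere;
* synonymous substitution rates along coding sequences, in five
  equal-size bins of the codon alignment, restricted to third
  positions of the eight 4-fold-degenerate codon families (Ala, Gly,
  Leu, Pro, Arg, Ser, Thr, Val — for the 6-fold amino acids only the
  CT/TC/CG-prefixed boxes, where any third base change is silent).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices, PairwiseAligner
from Bio.Seq import Seq

from tescar.align_core import chain_align, local_align
from tescar.io_formats import FeatureRecord
from tescar.stats import rank_sum_test

FOURFOLD_PREFIXES = {"GC", "GG", "CT", "CC", "CG", "TC", "AC", "GT"}


# --------------------------------------------------------------------------
# TE distribution around genes
# --------------------------------------------------------------------------

def te_coverage_near_genes(
    genes: list[FeatureRecord],
    tes: list[FeatureRecord],
    outside: int = 5000,
    inside: int = 2000,
    min_gene_length: int = 4000,
) -> dict[str, np.ndarray]:
    """Per-position counts of TE-covered bases around gene boundaries.

    Only forward-strand genes are used.  Around the transcription
    start, offsets run from ``-outside`` (upstream) to ``+inside``
    (into the gene; the inside part only for genes >= ``min_gene_length``);
    mirrored for the transcription end.
    """
    tss_cov = np.zeros(outside + inside, dtype=np.int64)  # offsets -outside..inside-1
    tes_cov = np.zeros(outside + inside, dtype=np.int64)  # offsets -inside..outside-1
    te_iv = sorted((t.start, t.end) for t in tes)
    starts = np.array([s for s, _ in te_iv], dtype=np.int64)
    ends = np.array([e for _, e in te_iv], dtype=np.int64)

    def _accumulate(cov: np.ndarray, lo: int, hi: int, origin: int):
        if hi <= lo or starts.size == 0:
            return
        i0 = int(np.searchsorted(ends, lo, side="right"))
        for s, e in zip(starts[i0:], ends[i0:]):
            if s >= hi:
                break
            a, b = max(s, lo), min(e, hi)
            if b > a:
                cov[a - origin : b - origin] += 1

    for g in genes:
        if g.strand != "+":
            continue
        inward = inside if g.length >= min_gene_length else 0
        _accumulate(tss_cov, g.start - outside, g.start + inward, g.start - outside)
        _accumulate(tes_cov, g.end - inward, g.end + outside, g.end - outside)
    return {
        "tss_offsets": np.arange(-outside, inside),
        "tss_coverage": tss_cov,
        "tes_offsets": np.arange(-inside, outside),
        "tes_coverage": tes_cov,
    }


# --------------------------------------------------------------------------
# Promoter vs intergenic conservation
# --------------------------------------------------------------------------

def chromosome_bin(position: int, centromere: int, chrom_length: int, n_bins: int = 3) -> int:
    """Arm bin 1 (distal/telomeric) .. n_bins (proximal/centromeric)."""
    if centromere <= 0 or centromere >= chrom_length:
        raise ValueError("centromere must lie inside the chromosome")
    if position < centromere:
        frac = 1.0 - position / centromere
    else:
        frac = (position - centromere) / (chrom_length - centromere)
    frac = min(max(frac, 0.0), 1.0)
    # frac: 0 at centromere, 1 at telomere -> bin 1 at telomere
    return min(n_bins, n_bins - int(frac * n_bins) if frac < 1.0 else 1)


def conservation_difference(identity_promoter: float, identity_intergenic: float) -> float:
    """Percent excess divergence of promoters over intergenic sequence.

    ``((100 - id_promoter) / (100 - id_intergenic) - 1) * 100``.
    """
    div_p = 100.0 - identity_promoter
    div_i = 100.0 - identity_intergenic
    if div_i <= 0:
        return float("nan")
    return (div_p / div_i - 1.0) * 100.0


@dataclass
class RegionConservation:
    """Per-bin promoter/intergenic identity distributions and tests."""

    table: pd.DataFrame  # columns: locus_id, region_class, bin, identity
    per_bin: pd.DataFrame  # bin, mean_promoter, mean_intergenic, difference_pct, p

    @property
    def overall_difference_pct(self) -> float:
        prom = self.table[self.table.region_class == "promoter"].identity.mean()
        inter = self.table[self.table.region_class == "intergenic"].identity.mean()
        return conservation_difference(prom, inter)


def promoter_vs_intergenic(
    genome_a: str,
    genome_b: str,
    features_a: list[FeatureRecord],
    features_b: list[FeatureRecord],
    centromere: Optional[int] = None,
    promoter_length: int = 2000,
    min_aligned: int = 600,
    min_intergenic_gap: int = 10_000,
    n_bins: int = 3,
) -> RegionConservation:
    """Compare promoter and intergenic conservation per chromosome-arm bin.

    Gene pairs are matched by annotation ID.  Promoters are the
    ``promoter_length`` bases upstream of the transcription start;
    intergenic loci are segments of the same length centred in gaps of
    at least ``min_intergenic_gap`` between consecutive genes (matched
    by their flanking gene IDs).  Alignments with at most
    ``min_aligned`` aligned bases are discarded.
    """
    genes_a = {f.attr("ID"): f for f in features_a if f.type == "gene"}
    genes_b = {f.attr("ID"): f for f in features_b if f.type == "gene"}
    shared = sorted(set(genes_a) & set(genes_b))
    cen = centromere
    if cen is None:
        cens = [f.start for f in features_a if f.type == "centromere"]
        cen = cens[0] if cens else len(genome_a) // 2

    def _identity(iv_a: tuple[int, int], iv_b: tuple[int, int]) -> Optional[float]:
        sa = genome_a[max(0, iv_a[0]) : iv_a[1]]
        sb = genome_b[max(0, iv_b[0]) : iv_b[1]]
        if len(sa) < min_aligned or len(sb) < min_aligned:
            return None
        aln = chain_align(sa, sb)
        if aln.aligned_bases <= min_aligned:
            return None
        return aln.percent_identity

    rows = []
    for gid in shared:
        ga, gb = genes_a[gid], genes_b[gid]
        ident = _identity(
            (ga.start - promoter_length, ga.start), (gb.start - promoter_length, gb.start)
        )
        if ident is None:
            continue
        rows.append(
            {
                "locus_id": f"prom_{gid}",
                "region_class": "promoter",
                "bin": chromosome_bin(ga.start, cen, len(genome_a), n_bins),
                "identity": ident,
            }
        )

    order_a = sorted(genes_a.values(), key=lambda f: f.start)
    for g1, g2 in zip(order_a, order_a[1:]):
        gap = g2.start - g1.end
        if gap < min_intergenic_gap:
            continue
        id1, id2 = g1.attr("ID"), g2.attr("ID")
        if id1 not in genes_b or id2 not in genes_b:
            continue
        mid_a = (g1.end + g2.start) // 2
        mid_b = (genes_b[id1].end + genes_b[id2].start) // 2
        half = promoter_length // 2
        ident = _identity((mid_a - half, mid_a + half), (mid_b - half, mid_b + half))
        if ident is None:
            continue
        rows.append(
            {
                "locus_id": f"inter_{id1}_{id2}",
                "region_class": "intergenic",
                "bin": chromosome_bin(mid_a, cen, len(genome_a), n_bins),
                "identity": ident,
            }
        )

    table = pd.DataFrame(rows, columns=["locus_id", "region_class", "bin", "identity"])
    summary = []
    for b in range(1, n_bins + 1):
        sub = table[table.bin == b]
        prom = sub[sub.region_class == "promoter"].identity.to_numpy()
        inter = sub[sub.region_class == "intergenic"].identity.to_numpy()
        if len(prom) >= 2 and len(inter) >= 2:
            _, p = rank_sum_test(prom, inter)
        else:
            p = float("nan")
        summary.append(
            {
                "bin": b,
                "n_promoter": len(prom),
                "n_intergenic": len(inter),
                "mean_promoter": prom.mean() if len(prom) else float("nan"),
                "mean_intergenic": inter.mean() if len(inter) else float("nan"),
                "difference_pct": conservation_difference(
                    prom.mean() if len(prom) else float("nan"),
                    inter.mean() if len(inter) else float("nan"),
                ),
                "p": p,
            }
        )
    return RegionConservation(table=table, per_bin=pd.DataFrame(summary))


# --------------------------------------------------------------------------
# CDS comparison
# --------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def bidirectional_best_hits(
    cds_a: dict[str, str], cds_b: dict[str, str], k: int = 12
) -> list[tuple[str, str]]:
    """Mutual best-match gene pairs between two CDS sets.

    Candidates are ranked by shared k-mer counts; when the two top
    candidates are close (within 10%) the tie is resolved by local
    alignment score, and exact ties exclude the gene.
    """
    kmap: dict[str, list[str]] = {}
    for bid, seq in cds_b.items():
        for km in _kmer_set(seq, k):
            kmap.setdefault(km, []).append(bid)

    def _best(seq: str, pool: dict[str, str], votes_of) -> Optional[str]:
        votes = votes_of(seq)
        if not votes:
            return None
        ranked = votes.most_common(2)
        if len(ranked) == 1 or ranked[0][1] > 1.1 * ranked[1][1]:
            return ranked[0][0]
        s1 = local_align(seq, pool[ranked[0][0]]).score
        s2 = local_align(seq, pool[ranked[1][0]]).score
        if s1 == s2:
            return None  # ambiguous homology
        return ranked[0][0] if s1 > s2 else ranked[1][0]

    def _votes_b(seq: str) -> Counter:
        c: Counter = Counter()
        for km in _kmer_set(seq, k):
            for bid in kmap.get(km, ()):  # noqa: B905
                c[bid] += 1
        return c

    amap: dict[str, list[str]] = {}
    for aid, seq in cds_a.items():
        for km in _kmer_set(seq, k):
            amap.setdefault(km, []).append(aid)

    def _votes_a(seq: str) -> Counter:
        c: Counter = Counter()
        for km in _kmer_set(seq, k):
            for aid in amap.get(km, ()):
                c[aid] += 1
        return c

    forward = {aid: _best(seq, cds_b, _votes_b) for aid, seq in cds_a.items()}
    backward = {bid: _best(seq, cds_a, _votes_a) for bid, seq in cds_b.items()}
    pairs = [
        (aid, bid)
        for aid, bid in forward.items()
        if bid is not None and backward.get(bid) == aid
    ]
    pairs.sort()
    return pairs


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _protein_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def align_backtranslate(
    cds_x: str, cds_y: str, name_x: str = "x", name_y: str = "y"
) -> list[tuple[Optional[str], Optional[str]]]:
    """Codon-level alignment via protein alignment and back-translation.

    Returns a list of aligned codon columns ``(codon_x, codon_y)``
    with ``None`` for a 3-bp gap.  CDS with internal stop codons are
    rejected (``ValueError`` naming the offending gene); terminal
    partial codons are trimmed.
    """
    codons = {}
    for name, cds in ((name_x, cds_x), (name_y, cds_y)):
        cds = cds[: 3 * (len(cds) // 3)].upper()
        prot = str(Seq(cds).translate())
        if "*" in prot[:-1]:
            raise ValueError(f"CDS {name} contains an internal stop codon")
        if prot.endswith("*"):
            cds, prot = cds[:-3], prot[:-1]
        codons[name] = ([cds[i : i + 3] for i in range(0, len(cds), 3)], prot)

    cx, px = codons[name_x]
    cy, py = codons[name_y]
    aligner = _protein_aligner()
    if aligner.score(px, py) <= 0:
        return []
    aln = aligner.align(px, py)[0]
    gx, gy = str(aln[0]), str(aln[1])
    blocks = aln.aligned
    ix = int(blocks[0][0][0])
    iy = int(blocks[1][0][0])
    out: list[tuple[Optional[str], Optional[str]]] = []
    for ax, ay in zip(gx, gy):
        codon_x = codon_y = None
        if ax != "-":
            codon_x = cx[ix]
            ix += 1
        if ay != "-":
            codon_y = cy[iy]
            iy += 1
        out.append((codon_x, codon_y))
    return out


def count_restricted_synonymous(
    codon_alignment: list[tuple[Optional[str], Optional[str]]],
) -> list[tuple[bool, bool]]:
    """Per-column (eligible, substituted) flags for restricted synonymous sites.

    A column is eligible when both codons are present, share one of the
    eight 4-fold-degenerate prefixes (GC/GG/CT/CC/CG/TC/AC/GT) — so
    both encode the same amino acid and any third-base change is
    synonymous — and contain no ambiguity characters.  ``substituted``
    flags a third-base difference at an eligible site.
    """
    flags = []
    for cx, cy in codon_alignment:
        if cx is None or cy is None or len(cx) != 3 or len(cy) != 3:
            flags.append((False, False))
            continue
        if cx[:2] != cy[:2] or cx[:2] not in FOURFOLD_PREFIXES:
            flags.append((False, False))
            continue
        if set(cx + cy) - set("ACGT"):
            flags.append((False, False))
            continue
        flags.append((True, cx[2] != cy[2]))
    return flags


@dataclass
class CdsBinProfile:
    gene_pair_id: str
    aligned_cds_length: int
    eligible_sites: list[int] = field(default_factory=list)
    substitutions: list[int] = field(default_factory=list)

    def rate_per_kb(self, b: int) -> float:
        """Synonymous substitutions per kb of codons at eligible sites in bin b."""
        if self.eligible_sites[b] == 0:
            return float("nan")
        return self.substitutions[b] / self.eligible_sites[b] * 1000.0 / 3.0


@dataclass
class CdsBinSummary:
    profiles: list[CdsBinProfile]
    pooled_substitutions: np.ndarray
    pooled_sites: np.ndarray
    pooled_rates: np.ndarray  # per-kb, length n_bins
    p_bin1_vs_bin3: float
    p_bin5_vs_bin3: float

    @property
    def terminal_central_ratio(self) -> float:
        """Pooled terminal-bin (1 and 5) rate over central-bin (3) rate."""
        term = self.pooled_substitutions[[0, -1]].sum() / self.pooled_sites[[0, -1]].sum()
        cent = self.pooled_substitutions[len(self.pooled_rates) // 2] / self.pooled_sites[
            len(self.pooled_rates) // 2
        ]
        return float(term / cent) if cent > 0 else float("nan")


def bin_synonymous_rates(
    pair_alignments: dict[str, list[tuple[Optional[str], Optional[str]]]],
    n_bins: int = 5,
    min_aligned: int = 1500,
) -> CdsBinSummary:
    """Split each codon alignment into ``n_bins`` contiguous bins and
    profile restricted synonymous substitutions.

    Pairs with <= ``min_aligned`` aligned CDS bases are excluded; a
    remainder of r columns widens the first r bins by one column each.
    """
    profiles = []
    pooled_subs = np.zeros(n_bins, dtype=np.int64)
    pooled_sites = np.zeros(n_bins, dtype=np.int64)
    per_pair_rates: list[list[float]] = []
    for pair_id, codon_aln in pair_alignments.items():
        cols = [(cx, cy) for cx, cy in codon_aln if cx is not None and cy is not None]
        aligned_len = 3 * len(cols)
        if aligned_len <= min_aligned:
            continue
        flags = count_restricted_synonymous(cols)
        q, r = divmod(len(cols), n_bins)
        sizes = [q + 1 if i < r else q for i in range(n_bins)]
        prof = CdsBinProfile(pair_id, aligned_len)
        start = 0
        rates = []
        for b, size in enumerate(sizes):
            chunk = flags[start : start + size]
            start += size
            sites = sum(1 for e, _ in chunk if e)
            subs = sum(1 for e, s in chunk if e and s)
            prof.eligible_sites.append(sites)
            prof.substitutions.append(subs)
            pooled_sites[b] += sites
            pooled_subs[b] += subs
            rates.append(prof.rate_per_kb(b))
        profiles.append(prof)
        per_pair_rates.append(rates)

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_rates = pooled_subs / pooled_sites * 1000.0 / 3.0
    rate_arr = np.array(per_pair_rates, dtype=float)
    mid = n_bins // 2

    def _test(col: int) -> float:
        if rate_arr.size == 0:
            return float("nan")
        x = rate_arr[:, col]
        y = rate_arr[:, mid]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            return float("nan")
        return rank_sum_test(x[ok], y[ok])[1]

    return CdsBinSummary(
        profiles=profiles,
        pooled_substitutions=pooled_subs,
        pooled_sites=pooled_sites,
        pooled_rates=pooled_rates,
        p_bin1_vs_bin3=_test(0),
        p_bin5_vs_bin3=_test(n_bins - 1),
    )
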