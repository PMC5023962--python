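"""Two-genome evolution simulator with a machine-readable truth table.

An ancestral genome is generated with protein-coding genes (treated as
intronless CDS on the forward strand), a library of DNA-transposon
families carrying terminal inverted repeats, and planted ancestral TE
copies flanked by exact target-site duplications (TSDs).  Two
descendant genomes then evolve independently:

* lineage-specific substitutions and InDels at background rates,
* new TE insertions (one lineage, exact TSD of the superfamily length),
* TE excisions (one lineage) leaving a perfect, deletion or filler
  footprint, with an exponentially decaying excess of substitutions
  and InDels in the flanks of the excised lineage — the phenomenological
  signature of error-prone double-strand-break repair,
* LTR retroelement insertions with initially identical LTR pairs and a
  5-bp TSD whose sites mutate at a configurable multiple of the LTR
  substitution rate.

Every planted event is recorded in a :class:`TruthTable` so analyses
can be validated by parameter recovery.  All randomness flows from a
single seed; identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from tescar.io_formats import FeatureRecord, write_fasta, write_gff3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_TSD_LENGTHS = {"DTT": 2, "DTH": 3, "DTM": 9, "DTA": 8, "DTC": 3, "RLG": 5}


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _rand_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _revcomp(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    return comp[arr][::-1]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy with substitutions at per-site probability ``rate``."""
    out = arr.copy()
    hits = np.flatnonzero(rng.random(out.size) < rate)
    if hits.size:
        cur = out[hits]
        base_idx = np.zeros(cur.size, dtype=np.int64)
        for bi, bb in enumerate(_BASES):
            base_idx[cur == bb] = bi
        shift = rng.integers(1, 4, hits.size)
        out[hits] = _BASES[(base_idx + shift) % 4]
    return out


@dataclass
class SimConfig:
    """Generating parameters; defaults emulate a pair of rice-like genomes.

    ``background_sub_rate`` is the per-lineage, per-site substitution
    probability; the expected pairwise divergence of the two emitted
    genomes is roughly twice this value.  The flank gradient gives the
    excised lineage a per-site rate of
    ``background_sub_rate * (1 + (A - 1) * exp(-d / L))`` at distance
    ``d`` from the excision point (``A`` = ``gradient_amplitude``,
    ``L`` = ``gradient_scale``), out to ``gradient_extent``; the InDel
    rate is scaled by the same fold factor.
    """

    genome_length: int = 1_500_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (1500, 4500)
    promoter_length: int = 2000
    background_sub_rate: float = 0.005
    background_indel_rate: float = 0.0005
    n_te_insertions: int = 25
    n_te_excisions: int = 15
    n_shared_tes: int = 5
    excision_type_mix: dict = field(
        default_factory=lambda: {"perfect": 0.5, "deletion": 0.3, "filler": 0.2}
    )
    gradient_amplitude: float = 5.0
    gradient_scale: float = 1000.0
    gradient_extent: int = 3000
    n_ltr_elements: int = 0
    ltr_length: int = 400
    ltr_internal_length: int = 2000
    ltr_divergence_range: tuple[float, float] = (0.002, 0.02)
    tsd_rate_multiplier: float = 5.0
    # full-length family members sit far apart in real genomes; keeping
    # them beyond the 14-kb pairing window mirrors the curated element
    # sets used for LTR/TSD dating
    ltr_min_separation: int = 12_000
    superfamily_tsd_lengths: dict = field(default_factory=lambda: dict(DEFAULT_TSD_LENGTHS))
    near_gene_bias: float = 10.0
    promoter_rate_multiplier: float = 1.0
    min_te_separation: int = 8000
    seed: int = 0

    def __post_init__(self):
        for name in ("background_sub_rate", "background_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {v}")
        if self.gradient_amplitude < 1.0:
            raise ValueError("SimConfig.gradient_amplitude must be >= 1")
        if self.gradient_scale <= 0:
            raise ValueError("SimConfig.gradient_scale must be > 0")
        mix_sum = sum(self.excision_type_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"SimConfig.excision_type_mix must sum to 1, sums to {mix_sum}")
        if any(v < 1 for v in self.superfamily_tsd_lengths.values()):
            raise ValueError("SimConfig.superfamily_tsd_lengths must all be >= 1")
        if self.n_genes < 0 or self.genome_length <= 0:
            raise ValueError("SimConfig.n_genes/genome_length must be non-negative/positive")


@dataclass
class TruthEvent:
    """Ground truth for one planted polymorphism or LTR element."""

    event_id: str
    event_class: str  # insertion | excision_perfect | excision_deletion | excision_filler | ltr_insertion
    superfamily: str
    family: str
    species_with_te: str  # lineage carrying the TE ("A" or "B"; LTR elements sit in "A")
    anchor_a: int  # TE 5' boundary (carrier) or junction point (non-carrier), genome A
    anchor_b: int
    te_length: int
    tsd_length: int
    tsd_seq: str
    deletion_left: int = 0
    deletion_right: int = 0
    filler_length: int = 0
    ltr_rate: float = 0.0


@dataclass
class TruthTable:
    events: list[TruthEvent]
    config: SimConfig
    ancestor_length: int = 0
    genome_a_length: int = 0
    genome_b_length: int = 0
    net_background_indel_a: int = 0
    net_background_indel_b: int = 0

    def by_class(self, event_class: str) -> list[TruthEvent]:
        return [e for e in self.events if e.event_class == event_class]


@dataclass
class Ancestor:
    seq: np.ndarray
    genes: list[dict]
    tes: list[dict]
    te_library: dict[str, dict]
    centromere: int

    @property
    def sequence(self) -> str:
        return _to_str(self.seq)


@dataclass
class DivergedPair:
    genome_a: str
    genome_b: str
    features_a: list[FeatureRecord]
    features_b: list[FeatureRecord]
    truth: TruthTable
    ltr_consensus: dict[str, str] = field(default_factory=dict)


class _Occupancy:
    """Sorted interval set for rejection-sampling placements."""

    def __init__(self):
        self.starts: list[int] = []
        self.ends: list[int] = []

    def add(self, start: int, end: int):
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)

    def is_free(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, end)
        if i < len(self.starts) and self.starts[i] < end:
            return False
        if i > 0 and self.ends[i - 1] > start:
            return False
        return True


def _random_cds(rng: np.random.Generator, length_nt: int) -> np.ndarray:
    """Random coding sequence: ATG + non-stop codons + TAA, length rounded to 3."""
    n_codons = max(3, length_nt // 3)
    codons = ["ATG"]
    bases = "ACGT"
    while len(codons) < n_codons - 1:
        c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return _to_arr("".join(codons))


def _place(
    rng: np.random.Generator,
    occ_hard: _Occupancy,
    occ_sep: _Occupancy,
    length: int,
    genome_length: int,
    margin: int,
    hard_margin: int,
    separation: int,
    gene_anchors: list[int],
    bias: float,
    max_tries: int = 2000,
) -> int:
    """Sample a free insertion point, biased toward gene boundaries.

    ``occ_hard`` holds features the insertion must clear by
    ``hard_margin`` (genes, existing elements); ``occ_sep`` holds
    features of the same kind that must stay ``separation`` away.
    """
    p_near = bias / (bias + 1.0) if gene_anchors else 0.0
    # the near/uniform decision is made once per feature so that the
    # bias weight governs where features end up, not merely where the
    # sampler first looks
    near_mode = bool(gene_anchors) and rng.random() < p_near
    for attempt in range(max_tries):
        if near_mode and attempt < max_tries // 2:
            anchor = gene_anchors[rng.integers(0, len(gene_anchors))]
            pos = int(anchor + rng.integers(-2000, 2001))
        else:
            pos = int(rng.integers(margin, max(margin + 1, genome_length - margin - length)))
        if pos < margin or pos + length > genome_length - margin:
            continue
        if occ_hard.is_free(pos - hard_margin, pos + length + hard_margin) and occ_sep.is_free(
            pos - separation, pos + length + separation
        ):
            return pos
    raise RuntimeError(
        "could not place feature; genome too small for the requested feature count"
    )


def _build_te_library(rng: np.random.Generator) -> dict[str, dict]:
    """Two families per DNA-transposon superfamily, each with proper TIRs."""
    sizes = {"DTT": (120, 500), "DTH": (120, 600), "DTM": (500, 1500),
             "DTA": (500, 1500), "DTC": (600, 1800)}
    library: dict[str, dict] = {}
    for sf, (lo, hi) in sizes.items():
        for fam_i in (1, 2):
            tir_len = int(rng.integers(15, 26))
            internal_len = int(rng.integers(lo, hi))
            tir = _rand_dna(rng, tir_len)
            internal = _rand_dna(rng, internal_len)
            seq = np.concatenate([tir, internal, _revcomp(tir)])
            library[f"{sf}_fam{fam_i}"] = {
                "superfamily": sf,
                "seq": seq,
                "tir_length": tir_len,
            }
    return library


def generate_ancestor(config: SimConfig) -> Ancestor:
    """Build the ancestral genome: genes, TE library, planted ancestral TEs."""
    mean_gene = sum(config.gene_length_range) / 2
    if config.n_genes and config.genome_length < 10 * config.n_genes * mean_gene:
        raise ValueError(
            "SimConfig.genome_length too small: require genome_length >= "
            "10 * n_genes * mean gene length"
        )
    rng = np.random.default_rng([0, config.seed])
    L = config.genome_length
    seq = _rand_dna(rng, L)

    # genes: non-overlapping forward-strand CDS with random intergenic gaps
    genes: list[dict] = []
    occ_hard = _Occupancy()
    occ_te = _Occupancy()
    if config.n_genes:
        lengths = [
            int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            for _ in range(config.n_genes)
        ]
        lengths = [3 * (l // 3) for l in lengths]
        free = L - sum(lengths)
        raw = rng.random(config.n_genes + 1) + 0.05
        gaps = (raw / raw.sum() * free).astype(int)
        pos = 0
        for i, glen in enumerate(lengths):
            pos += int(gaps[i])
            start = min(pos, L - glen - 1)
            cds = _random_cds(rng, glen)
            seq[start : start + cds.size] = cds
            genes.append({"id": f"gene{i+1:04d}", "start": start, "end": start + cds.size})
            occ_hard.add(start, start + cds.size)
            pos = start + glen

    te_library = _build_te_library(rng)
    fam_names = sorted(te_library)

    n_anc = config.n_te_excisions + config.n_shared_tes
    margin = min(13_000, max(1000, L // 10))
    gene_anchors = [g["start"] for g in genes] + [g["end"] for g in genes]
    insert_edits: list[tuple[int, np.ndarray, dict]] = []
    for i in range(n_anc):
        fam = fam_names[rng.integers(0, len(fam_names))]
        entry = te_library[fam]
        sf = entry["superfamily"]
        k = config.superfamily_tsd_lengths[sf]
        te_seq = entry["seq"]
        pos = _place(
            rng, occ_hard, occ_te, te_seq.size + k, L, margin, 400,
            config.min_te_separation, gene_anchors, config.near_gene_bias,
        )
        occ_hard.add(pos, pos + te_seq.size + k)
        occ_te.add(pos, pos + te_seq.size + k)
        insert_edits.append(
            (pos, te_seq, {"id": f"anc_te{i+1:04d}", "family": fam, "superfamily": sf, "tsd_len": k})
        )

    # splice in ancestral TEs (each as: target site + TE + duplicated site)
    insert_edits.sort(key=lambda t: t[0])
    pieces = []
    tes: list[dict] = []
    cursor = 0
    shift = 0
    for pos, te_seq, meta in insert_edits:
        k = meta["tsd_len"]
        tsd = seq[pos : pos + k]
        pieces.append(seq[cursor : pos + k])
        te_start = pos + k + shift
        pieces.append(te_seq)
        pieces.append(tsd)
        tes.append(
            dict(meta, start=te_start, end=te_start + te_seq.size, tsd_seq=_to_str(tsd))
        )
        shift += te_seq.size + k
        cursor = pos + k
    pieces.append(seq[cursor:])
    final = np.concatenate(pieces) if pieces else seq

    # shift gene coordinates past the insertions
    ins_points = [e[0] for e in insert_edits]
    ins_sizes = np.cumsum([e[1].size + e[2]["tsd_len"] for e in insert_edits]) if insert_edits else np.array([])

    def _map(x: int) -> int:
        i = bisect.bisect_right(ins_points, x)
        return x + (int(ins_sizes[i - 1]) if i else 0)

    for g in genes:
        g["start"], g["end"] = _map(g["start"]), _map(g["end"])

    return Ancestor(
        seq=final,
        genes=genes,
        tes=tes,
        te_library=te_library,
        centromere=final.size // 2,
    )


def _apply_edits(
    seq: np.ndarray, edits: list[tuple[int, int, np.ndarray]]
) -> tuple[np.ndarray, list[int], list[int], list[int]]:
    """Splice ``(start, end, replacement)`` edits; edits must not overlap.

    Returns the new sequence plus parallel arrays (edit starts, edit
    ends, cumulative length delta after each edit) for coordinate
    mapping.
    """
    edits = sorted(edits, key=lambda e: (e[0], e[1]))
    for (s1, e1, _), (s2, _, _) in zip(edits, edits[1:]):
        if s2 < e1:
            raise ValueError("overlapping edits")
    pieces = []
    cursor = 0
    starts, ends, deltas = [], [], []
    delta = 0
    for s, e, rep in edits:
        pieces.append(seq[cursor:s])
        if rep.size:
            pieces.append(rep)
        delta += rep.size - (e - s)
        starts.append(s)
        ends.append(e)
        deltas.append(delta)
        cursor = e
    pieces.append(seq[cursor:])
    return np.concatenate(pieces), starts, ends, deltas


def _coord_mapper(starts: list[int], ends: list[int], deltas: list[int]):
    """Ancestor coordinate -> descendant coordinate (edited spans map to edit start)."""

    def mapper(x: int) -> int:
        i = bisect.bisect_right(ends, x)
        base = deltas[i - 1] if i else 0
        if i < len(starts) and x > starts[i]:  # inside edit i
            return starts[i] + base
        return x + base

    return mapper


def _overlaps(edit, start, end) -> bool:
    s, e, _ = edit
    return s < end and e > start and not (s == e == start)


def diverge(ancestor: Ancestor, config: SimConfig) -> DivergedPair:
    """Evolve two descendant genomes from ``ancestor`` under ``config``."""
    if config.n_te_excisions > len(ancestor.tes):
        raise ValueError(
            f"n_te_excisions={config.n_te_excisions} exceeds the "
            f"{len(ancestor.tes)} TEs planted in the ancestor"
        )
    rng = np.random.default_rng([1, config.seed])
    L = ancestor.seq.size
    A = config.gradient_amplitude
    Ls = config.gradient_scale
    extent = config.gradient_extent

    # --- choose events -------------------------------------------------
    exc_idx = rng.choice(len(ancestor.tes), config.n_te_excisions, replace=False)
    exc_idx.sort()
    mix_names = sorted(config.excision_type_mix)
    mix_p = np.array([config.excision_type_mix[n] for n in mix_names])
    excisions = []
    for i in exc_idx:
        te = ancestor.tes[int(i)]
        excisions.append(
            {
                "te": te,
                "lineage": "AB"[rng.integers(0, 2)],
                "type": mix_names[rng.choice(len(mix_names), p=mix_p)],
            }
        )

    occ_hard = _Occupancy()
    occ_te = _Occupancy()
    for g in ancestor.genes:
        occ_hard.add(g["start"], g["end"])
    for te in ancestor.tes:
        occ_hard.add(te["start"], te["end"])
        occ_te.add(te["start"], te["end"])
    gene_anchors = [g["start"] for g in ancestor.genes] + [g["end"] for g in ancestor.genes]
    margin = min(13_000, max(1000, L // 10))
    fam_names = sorted(ancestor.te_library)

    insertions = []
    for i in range(config.n_te_insertions):
        fam = fam_names[rng.integers(0, len(fam_names))]
        entry = ancestor.te_library[fam]
        k = config.superfamily_tsd_lengths[entry["superfamily"]]
        pos = _place(
            rng, occ_hard, occ_te, entry["seq"].size + k, L, margin, 400,
            config.min_te_separation, gene_anchors, config.near_gene_bias,
        )
        occ_hard.add(pos, pos + entry["seq"].size + k)
        occ_te.add(pos, pos + entry["seq"].size + k)
        insertions.append(
            {
                "id": f"new_te{i+1:04d}",
                "family": fam,
                "superfamily": entry["superfamily"],
                "tsd_len": k,
                "pos": pos,
                "lineage": "AB"[rng.integers(0, 2)],
            }
        )

    # LTR retroelement families (consensus LTR + internal region)
    ltr_families = {}
    for fam_i in (1, 2, 3):
        ltr_families[f"RLG_fam{fam_i}"] = {
            "ltr": _rand_dna(rng, config.ltr_length),
            "internal": _rand_dna(rng, config.ltr_internal_length),
        }
    ltr_events = []
    occ_ltr = _Occupancy()
    for i in range(config.n_ltr_elements):
        fam = sorted(ltr_families)[rng.integers(0, len(ltr_families))]
        size = config.ltr_length * 2 + config.ltr_internal_length + 5
        pos = _place(
            rng, occ_hard, occ_ltr, size, L, margin, 1000,
            config.ltr_min_separation, [], 0.0,
        )
        occ_hard.add(pos, pos + size)
        occ_ltr.add(pos, pos + size)
        ltr_events.append(
            {
                "id": f"ltr{i+1:04d}",
                "family": fam,
                "pos": pos,
                "rate": float(rng.uniform(*config.ltr_divergence_range)),
            }
        )

    # --- per-lineage mutation and splicing -----------------------------
    genomes: dict[str, np.ndarray] = {}
    mappers: dict[str, object] = {}
    net_indel = {"A": 0, "B": 0}
    structural: dict[str, list] = {"A": [], "B": []}
    exc_details: dict[str, tuple] = {}
    ltr_records = []

    for lineage in ("A", "B"):
        # per-site substitution rate with promoter and excision-flank terms
        rate = np.full(L, config.background_sub_rate)
        if config.promoter_rate_multiplier != 1.0:
            for g in ancestor.genes:
                lo = max(0, g["start"] - config.promoter_length)
                rate[lo : g["start"]] *= config.promoter_rate_multiplier
        d = np.arange(extent, dtype=float)
        factor = 1.0 + (A - 1.0) * np.exp(-d / Ls)
        for exc in excisions:
            if exc["lineage"] != lineage:
                continue
            ts, te = exc["te"]["start"], exc["te"]["end"]
            lo = max(0, ts - extent)
            left = (config.background_sub_rate * factor[::-1])[extent - (ts - lo):]
            rate[lo:ts] = np.maximum(rate[lo:ts], left)
            hi = min(L, te + extent)
            rate[te:hi] = np.maximum(rate[te:hi], config.background_sub_rate * factor[: hi - te])

        seq = ancestor.seq.copy()
        sub_pos = np.flatnonzero(rng.random(L) < rate)
        if sub_pos.size:
            cur = seq[sub_pos]
            base_idx = np.zeros(cur.size, dtype=np.int64)
            for bi, bb in enumerate(_BASES):
                base_idx[cur == bb] = bi
            shift = rng.integers(1, 4, cur.size)
            seq[sub_pos] = _BASES[(base_idx + shift) % 4]

        # background InDels at the same fold-elevation as substitutions
        if config.background_sub_rate > 0:
            indel_rate = config.background_indel_rate * rate / config.background_sub_rate
        else:
            indel_rate = np.full(L, config.background_indel_rate)
        indel_pos = np.flatnonzero(rng.random(L) < indel_rate)
        indel_edits = []
        for p in indel_pos:
            length = int(min(rng.geometric(0.5), 50))
            if rng.random() < 0.5:
                indel_edits.append((int(p), int(p), _rand_dna(rng, length)))
            else:
                indel_edits.append((int(p), int(min(p + length, L)), np.empty(0, dtype=np.uint8)))

        # structural edits for this lineage
        struct_edits = []
        for exc in excisions:
            if exc["lineage"] != lineage:
                continue
            te = exc["te"]
            ts, tend = te["start"], te["end"]
            key = te["id"]
            if exc["type"] == "perfect":
                struct_edits.append((ts, tend, np.empty(0, dtype=np.uint8)))
                exc_details[key] = (0, 0, 0)
            elif exc["type"] == "deletion":
                near = int(rng.integers(0, 4))
                far = int(rng.integers(20, 301))
                if rng.random() < 0.5:
                    dl, dr = near, far
                else:
                    dl, dr = far, near
                struct_edits.append((ts - dl, tend + dr, np.empty(0, dtype=np.uint8)))
                exc_details[key] = (dl, dr, 0)
            else:  # filler
                dl = int(rng.integers(0, 4))
                dr = int(rng.integers(0, 4))
                filler = _rand_dna(rng, int(rng.integers(10, 301)))
                struct_edits.append((ts - dl, tend + dr, filler))
                exc_details[key] = (dl, dr, filler.size)
        for ins in insertions:
            if ins["lineage"] != lineage:
                continue
            entry = ancestor.te_library[ins["family"]]
            k = ins["tsd_len"]
            p = ins["pos"]
            tsd = seq[p : p + k].copy()
            ins["tsd_seq"] = _to_str(tsd)
            struct_edits.append((p + k, p + k, np.concatenate([entry["seq"], tsd])))
        if lineage == "A":
            for ev in ltr_events:
                fam = ltr_families[ev["family"]]
                r = ev["rate"]
                p = ev["pos"]
                site = seq[p : p + 5].copy()
                ev["tsd_site"] = site
                ltr1 = _mutate(fam["ltr"], r, rng)
                ltr2 = _mutate(fam["ltr"], r, rng)
                internal = _mutate(fam["internal"], r, rng)
                tsd1 = _mutate(site, config.tsd_rate_multiplier * r, rng)
                tsd2 = _mutate(site, config.tsd_rate_multiplier * r, rng)
                element = np.concatenate([ltr1, internal, ltr2, tsd2])
                struct_edits.append((p, p + 5, np.concatenate([tsd1, element])))
                ev["element_len"] = ltr1.size + internal.size + ltr2.size

        # structural edits win over colliding background InDels; InDels
        # overlapping an earlier InDel are dropped too
        kept_indels = []
        last_end = -1
        for ed in sorted(indel_edits, key=lambda t: (t[0], t[1])):
            s, e, rep = ed
            pad = 5
            if s < last_end:
                continue
            if any(_overlaps((s - pad, e + pad, rep), ss, ee) for ss, ee, _ in struct_edits):
                continue
            kept_indels.append(ed)
            last_end = max(e, s + 1)
        net_indel[lineage] = sum(r.size - (e - s) for s, e, r in kept_indels)
        structural[lineage] = struct_edits

        all_edits = struct_edits + kept_indels
        new_seq, starts, ends, deltas = _apply_edits(seq, all_edits)
        genomes[lineage] = new_seq
        mappers[lineage] = _coord_mapper(starts, ends, deltas)

    map_a, map_b = mappers["A"], mappers["B"]

    # --- truth table and annotations ----------------------------------
    events: list[TruthEvent] = []
    excised_ids = {exc["te"]["id"]: exc for exc in excisions}
    for exc in excisions:
        te = exc["te"]
        carrier = "B" if exc["lineage"] == "A" else "A"
        dl, dr, flen = exc_details[te["id"]]
        anchor_carrier = (map_a if carrier == "A" else map_b)(te["start"])
        anchor_excised = (map_a if exc["lineage"] == "A" else map_b)(te["start"])
        events.append(
            TruthEvent(
                event_id=te["id"],
                event_class=f"excision_{exc['type']}",
                superfamily=te["superfamily"],
                family=te["family"],
                species_with_te=carrier,
                anchor_a=anchor_carrier if carrier == "A" else anchor_excised,
                anchor_b=anchor_carrier if carrier == "B" else anchor_excised,
                te_length=te["end"] - te["start"],
                tsd_length=te["tsd_len"],
                tsd_seq=te["tsd_seq"],
                deletion_left=dl,
                deletion_right=dr,
                filler_length=flen,
            )
        )
    for ins in insertions:
        entry = ancestor.te_library[ins["family"]]
        carrier = ins["lineage"]
        # the edit splices (TE + TSD copy) before ancestor base pos+tsd_len
        after_insert = (map_a if carrier == "A" else map_b)(ins["pos"] + ins["tsd_len"])
        anchor_carrier = after_insert - (entry["seq"].size + ins["tsd_len"])
        other = "B" if carrier == "A" else "A"
        anchor_other = (map_a if other == "A" else map_b)(ins["pos"])
        events.append(
            TruthEvent(
                event_id=ins["id"],
                event_class="insertion",
                superfamily=ins["superfamily"],
                family=ins["family"],
                species_with_te=carrier,
                anchor_a=anchor_carrier if carrier == "A" else anchor_other,
                anchor_b=anchor_carrier if carrier == "B" else anchor_other,
                te_length=entry["seq"].size,
                tsd_length=ins["tsd_len"],
                tsd_seq=ins["tsd_seq"],
            )
        )
    for ev in ltr_events:
        start_a = map_a(ev["pos"])  # position of the 5' TSD copy
        events.append(
            TruthEvent(
                event_id=ev["id"],
                event_class="ltr_insertion",
                superfamily="RLG",
                family=ev["family"],
                species_with_te="A",
                anchor_a=start_a + 5,
                anchor_b=map_b(ev["pos"]),
                te_length=ev["element_len"],
                tsd_length=5,
                tsd_seq=_to_str(ev["tsd_site"]),
                ltr_rate=ev["rate"],
            )
        )
        ltr_records.append(ev)

    features: dict[str, list[FeatureRecord]] = {"A": [], "B": []}
    for lineage, mapper in (("A", map_a), ("B", map_b)):
        chrom = f"chr1_{lineage}"
        for g in ancestor.genes:
            features[lineage].append(
                FeatureRecord(
                    chrom, "tescar_sim", "gene", mapper(g["start"]), mapper(g["end"]),
                    "+", attributes={"ID": g["id"]},
                )
            )
        for te in ancestor.tes:
            exc = excised_ids.get(te["id"])
            if exc is not None and exc["lineage"] == lineage:
                continue  # excised from this lineage
            features[lineage].append(
                FeatureRecord(
                    chrom, "tescar_sim", te["superfamily"],
                    mapper(te["start"]), mapper(te["end"]), "+",
                    attributes={"ID": te["id"], "family": te["family"]},
                )
            )
        for ins in insertions:
            if ins["lineage"] != lineage:
                continue
            entry = ancestor.te_library[ins["family"]]
            start = mapper(ins["pos"] + ins["tsd_len"]) - (entry["seq"].size + ins["tsd_len"])
            features[lineage].append(
                FeatureRecord(
                    chrom, "tescar_sim", ins["superfamily"], start, start + entry["seq"].size,
                    "+", attributes={"ID": ins["id"], "family": ins["family"]},
                )
            )
        if lineage == "A":
            for ev in ltr_records:
                start = map_a(ev["pos"]) + 5
                features[lineage].append(
                    FeatureRecord(
                        chrom, "tescar_sim", "RLG", start, start + ev["element_len"], "+",
                        attributes={"ID": ev["id"], "family": ev["family"]},
                    )
                )
        cen = mapper(ancestor.centromere)
        features[lineage].append(
            FeatureRecord(chrom, "tescar_sim", "centromere", cen, cen + 1, ".",
                          attributes={"ID": f"cen_{lineage}"})
        )
        features[lineage].sort(key=lambda f: (f.start, f.end, f.type))

    truth = TruthTable(
        events=events,
        config=config,
        ancestor_length=L,
        genome_a_length=genomes["A"].size,
        genome_b_length=genomes["B"].size,
        net_background_indel_a=net_indel["A"],
        net_background_indel_b=net_indel["B"],
    )
    return DivergedPair(
        genome_a=_to_str(genomes["A"]),
        genome_b=_to_str(genomes["B"]),
        features_a=features["A"],
        features_b=features["B"],
        truth=truth,
        ltr_consensus={fam: _to_str(v["ltr"]) for fam, v in ltr_families.items()},
    )


def simulate(config: SimConfig) -> DivergedPair:
    """Convenience wrapper: ``generate_ancestor`` + ``diverge``."""
    return diverge(generate_ancestor(config), config)


_TRUTH_COLUMNS = [
    "event_id", "event_class", "superfamily", "family", "species_with_te",
    "anchor_a", "anchor_b", "te_length", "tsd_length", "tsd_seq",
    "deletion_left", "deletion_right", "filler_length", "ltr_rate",
]


def write_truth(truth: TruthTable, path) -> None:
    """Write the truth table as TSV; generating parameters go in # headers."""
    cfg = asdict(truth.config)
    meta = {
        "ancestor_length": truth.ancestor_length,
        "genome_a_length": truth.genome_a_length,
        "genome_b_length": truth.genome_b_length,
        "net_background_indel_a": truth.net_background_indel_a,
        "net_background_indel_b": truth.net_background_indel_b,
    }
    with open(path, "w") as fh:
        fh.write("#config\t" + json.dumps(cfg, sort_keys=True) + "\n")
        fh.write("#meta\t" + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for ev in truth.events:
            d = asdict(ev)
            fh.write("\t".join(str(d[c]) for c in _TRUTH_COLUMNS) + "\n")


def read_truth(path) -> TruthTable:
    cfg = meta = None
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#config\t"):
                cfg = json.loads(line.split("\t", 1)[1])
                for key in ("gene_length_range", "ltr_divergence_range"):
                    cfg[key] = tuple(cfg[key])
                continue
            if line.startswith("#meta\t"):
                meta = json.loads(line.split("\t", 1)[1])
                continue
            if line.startswith("event_id\t"):
                continue
            vals = line.split("\t")
            row = dict(zip(_TRUTH_COLUMNS, vals))
            events.append(
                TruthEvent(
                    event_id=row["event_id"],
                    event_class=row["event_class"],
                    superfamily=row["superfamily"],
                    family=row["family"],
                    species_with_te=row["species_with_te"],
                    anchor_a=int(row["anchor_a"]),
                    anchor_b=int(row["anchor_b"]),
                    te_length=int(row["te_length"]),
                    tsd_length=int(row["tsd_length"]),
                    tsd_seq=row["tsd_seq"],
                    deletion_left=int(row["deletion_left"]),
                    deletion_right=int(row["deletion_right"]),
                    filler_length=int(row["filler_length"]),
                    ltr_rate=float(row["ltr_rate"]),
                )
            )
    if cfg is None or meta is None:
        raise ValueError(f"missing #config/#meta headers in {path}")
    return TruthTable(events=events, config=SimConfig(**cfg), **meta)


def write_outputs(pair: DivergedPair, outdir) -> dict[str, Path]:
    """Write FASTA + GFF3 for both genomes, LTR consensus FASTA, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lineage, genome, feats in (
        ("A", pair.genome_a, pair.features_a),
        ("B", pair.genome_b, pair.features_b),
    ):
        fa = outdir / f"genome_{lineage}.fa"
        gff = outdir / f"genome_{lineage}.gff3"
        write_fasta({f"chr1_{lineage}": genome}, fa)
        write_gff3(feats, gff)
        paths[f"fasta_{lineage}"] = fa
        paths[f"gff_{lineage}"] = gff
    if pair.ltr_consensus:
        ltr_fa = outdir / "ltr_consensus.fa"
        write_fasta(pair.ltr_consensus, ltr_fa)
        paths["ltr_consensus"] = ltr_fa
    truth_path = outdir / "truth.tsv"
    write_truth(pair.truth, truth_path)
    paths["truth"] = truth_path
    return paths


def generate_cds_pairs(
    n_pairs: int,
    seed: int,
    codon_range: tuple[int, int] = (700, 1000),
    sub_rate: float = 0.01,
    terminal_boost: float = 1.0,
    terminal_frac: float = 0.2,
) -> tuple[dict[str, str], dict[str, str]]:
    """Orthologous CDS pairs with an optional terminal mutation excess.

    Each pair descends from a random ancestral CDS; each lineage gets
    substitutions at per-site probability ``sub_rate``, multiplied by
    ``terminal_boost`` in the first and last ``terminal_frac`` of the
    sequence.  Substitutions creating internal stop codons are repaired
    by switching the third codon base (nonsense changes do not survive
    in real orthologs).
    """
    rng = np.random.default_rng([2, seed])
    cds_a: dict[str, str] = {}
    cds_b: dict[str, str] = {}
    for i in range(n_pairs):
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        anc = _random_cds(rng, n_codons * 3)
        L = anc.size
        t = int(L * terminal_frac)
        rate = np.full(L, sub_rate)
        rate[:t] *= terminal_boost
        rate[L - t :] *= terminal_boost
        rate[:3] = 0.0
        rate[-3:] = 0.0  # keep start/stop codons intact
        pair = {}
        for lineage in ("a", "b"):
            seq = anc.copy()
            hits = np.flatnonzero(rng.random(L) < rate)
            if hits.size:
                cur = seq[hits]
                base_idx = np.zeros(cur.size, dtype=np.int64)
                for bi, bb in enumerate(_BASES):
                    base_idx[cur == bb] = bi
                shift = rng.integers(1, 4, hits.size)
                seq[hits] = _BASES[(base_idx + shift) % 4]
            # repair nonsense codons
            s = _to_str(seq)
            codons = [s[j : j + 3] for j in range(0, L, 3)]
            for ci in range(1, len(codons) - 1):
                if codons[ci] in _STOPS:
                    codons[ci] = codons[ci][:2] + "C"
            pair[lineage] = "".join(codons)
        name = f"gene{i+1:05d}"
        cds_a[name + "_a"] = pair["a"]
        cds_b[name + "_b"] = pair["b"]
    return cds_a, cds_b


def generate_mite_genome(
    seed: int,
    genome_length: int = 300_000,
    n_families: int = 5,
    copies_per_family: int = 10,
    tir_range: tuple[int, int] = (18, 25),
    internal_range: tuple[int, int] = (80, 300),
    copy_divergence: float = 0.02,
) -> tuple[str, list[dict]]:
    """A single genome with planted MITE families for TIR-scan validation.

    Returns (genome, planted) where each planted record has the copy
    interval, family name and TIR length.  Copies within a family
    diverge from the family consensus by ``copy_divergence``
    substitutions per site.
    """
    rng = np.random.default_rng([3, seed])
    seq = _rand_dna(rng, genome_length)
    families = []
    for f in range(n_families):
        tir = _rand_dna(rng, int(rng.integers(*tir_range)))
        internal = _rand_dna(rng, int(rng.integers(*internal_range)))
        families.append(
            {"name": f"MITE_fam{f+1}", "seq": np.concatenate([tir, internal, _revcomp(tir)]),
             "tir_length": tir.size}
        )
    occ = _Occupancy()
    edits = []
    planted = []
    for fam in families:
        for c in range(copies_per_family):
            copy = _mutate(fam["seq"], copy_divergence, rng)
            for _ in range(2000):
                pos = int(rng.integers(1000, genome_length - 1000 - copy.size))
                if occ.is_free(pos - 1000, pos + copy.size + 1000):
                    break
            else:
                raise RuntimeError("MITE placement failed; genome too small")
            occ.add(pos - 1000, pos + copy.size + 1000)
            edits.append((pos, pos, copy))
            planted.append(
                {"family": fam["name"], "pos": pos, "length": int(copy.size),
                 "tir_length": fam["tir_length"], "copy": f"{fam['name']}_c{c+1}"}
            )
    new_seq, starts, ends, deltas = _apply_edits(seq, edits)
    mapper = _coord_mapper(starts, ends, deltas)
    for rec in planted:
        # mapper(pos) gives the coordinate after the inserted copy
        start = mapper(rec.pop("pos")) - rec["length"]
        rec["start"] = start
        rec["end"] = start + rec["length"]
    return _to_str(new_seq), planted
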