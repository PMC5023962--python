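"""SNP-accumulation excision prediction and de novo TIR discovery."""

import numpy as np
import pytest

from tescar.align_core import LocusAlignment
from tescar.discovery import (
    detect_repeat_slippage,
    excision_enrichment,
    find_high_snp_segments,
    scan_inverted_repeats,
    select_control_loci,
    validate_copy_number,
)
from tescar.io_formats import revcomp


def _aln_with_subs(n, sub_positions, locus_id="L"):
    rng = np.random.default_rng(0)
    a = np.array(list("ACGT"))[rng.integers(0, 4, n)]
    b = a.copy()
    for p in sub_positions:
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
    return LocusAlignment(locus_id, locus_id + "_b", "".join(a), "".join(b))


class TestHighSnpSegments:
    def test_flat_background_no_windows(self):
        aln = _aln_with_subs(4000, range(0, 4000, 200))  # 0.005/bp
        assert find_high_snp_segments([aln], 0.005, threshold_fold=4) == []

    def test_threshold_zero_flags_everything(self):
        aln = _aln_with_subs(2000, [100])
        segs = find_high_snp_segments([aln], 0.005, threshold_fold=0)
        assert segs
        assert segs[0].start == 0 and segs[-1].end == 2000

    def test_planted_accumulation_flagged(self):
        hot = list(range(1000, 1250, 10))  # 25 substitutions in 250 bp
        aln = _aln_with_subs(4000, hot)
        segs = find_high_snp_segments([aln], 0.005, threshold_fold=4)
        assert len(segs) == 1
        assert segs[0].start <= 1000 < segs[0].end

    def test_invalid_background(self):
        with pytest.raises(ValueError):
            find_high_snp_segments([], 0.0)

    def test_control_selection(self):
        near = _aln_with_subs(4000, range(0, 4000, 200), "near")  # 0.005
        hot = _aln_with_subs(4000, range(0, 4000, 20), "hot")  # 0.05
        controls = select_control_loci([near, hot], 0.005)
        assert [a.seq_a_id for a in controls] == ["near"]

    def test_excision_sites_detected_with_high_power(self, gradient_run):
        """At A=5, at least 80% of excision loci show a high-SNP segment
        near the anchor."""
        from tescar.pipeline import classified_records

        _, records = gradient_run
        recs = [
            r for r in classified_records(records)
            if r.call.call_class.startswith("excision")
        ]
        cfg = gradient_run[0].truth.config
        hits = 0
        for r in recs:
            segs = find_high_snp_segments([r.aln], cfg.background_sub_rate)
            anchor_col = r.call.anchor_column
            if any(s.start - 500 <= anchor_col < s.end + 500 for s in segs):
                hits += 1
        assert hits / len(recs) >= 0.8


class TestEnrichment:
    def test_reported_counts_give_expected_p(self):
        high = [f"h{i}" for i in range(50)]
        ctrl = [f"c{i}" for i in range(50)]
        events = {}
        for i in range(16):
            events.setdefault(f"h{i}", []).append("excision")
        for i in range(2):
            events.setdefault(f"c{i}", []).append("excision")
        res = excision_enrichment(high, ctrl, events, categories=("excision",))[0]
        assert res.n_high == 16 and res.n_control == 2
        assert res.p == pytest.approx(0.0003, abs=0.0001)

    def test_equal_counts_give_p_one(self):
        high = ["h1", "h2"]
        ctrl = ["c1", "c2"]
        events = {"h1": ["indel"], "c1": ["indel"]}
        res = excision_enrichment(high, ctrl, events, categories=("indel",))[0]
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_swap_preserves_chi2(self):
        high = [f"h{i}" for i in range(30)]
        ctrl = [f"c{i}" for i in range(30)]
        events = {f"h{i}": ["excision"] for i in range(10)}
        events.update({f"c{i}": ["excision"] for i in range(3)})
        fwd = excision_enrichment(high, ctrl, events, categories=("excision",))[0]
        rev = excision_enrichment(ctrl, high, events, categories=("excision",))[0]
        assert fwd.chi2 == pytest.approx(rev.chi2)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            excision_enrichment([], ["c"], {})

    def test_zero_margin_gives_nan(self):
        res = excision_enrichment(["h"], ["c"], {}, categories=("excision",))[0]
        assert np.isnan(res.p)


class TestRepeatSlippage:
    def test_microsatellite_expansion_detected(self):
        # (AT)6 in one row, (AT)8 in the other
        a = "GGCC" + "AT" * 6 + "----" + "CCGGTT"
        b = "GGCC" + "AT" * 6 + "ATAT" + "CCGGTT"
        aln = LocusAlignment("a", "b", a, b)
        slips = detect_repeat_slippage(aln)
        assert len(slips) == 1
        assert slips[0][1] == "AT"

    def test_random_insertion_not_slippage(self):
        a = "GGCCAATTGG" + "----" + "CCGGTT"
        b = "GGCCAATTGG" + "CTGA" + "CCGGTT"
        aln = LocusAlignment("a", "b", a, b)
        assert detect_repeat_slippage(aln) == []

    def test_identical_rows_no_events(self):
        aln = LocusAlignment("a", "b", "ACGTACGT", "ACGTACGT")
        assert detect_repeat_slippage(aln) == []


class TestTirScan:
    def _genome_with_mite(self, seed=3, tir_len=20, internal=150):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))

        def rand(n):
            return "".join(bases[rng.integers(0, 4, n)])

        tir = rand(tir_len)
        mite = tir + rand(internal) + revcomp(tir)
        pos = 2000
        genome = rand(pos) + mite + rand(3000)
        return genome, pos, len(mite), tir_len

    def test_planted_tir_found_with_exact_arms(self):
        genome, pos, mite_len, tir_len = self._genome_with_mite()
        cands = scan_inverted_repeats(genome)
        match = [c for c in cands if abs(c.start - pos) <= 3]
        assert match
        c = match[0]
        assert abs(c.arm_left[0] - pos) <= 2
        assert abs(c.arm_right[1] - (pos + mite_len)) <= 2
        assert c.stem_length >= tir_len - 2

    def test_stem_thresholds_enforced(self):
        from tescar.discovery import TirCandidate

        with pytest.raises(ValueError, match="15 bp"):
            TirCandidate(0, 100, (0, 14), (86, 100), 14, 95.0, 0)
        with pytest.raises(ValueError, match="70%"):
            TirCandidate(0, 100, (0, 20), (80, 100), 20, 60.0, 0)
        genome, _, _, _ = self._genome_with_mite()
        for c in scan_inverted_repeats(genome):
            assert c.stem_length >= 15 and c.stem_identity >= 70.0

    def test_genome_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            scan_inverted_repeats("ACGT" * 100)

    def test_single_copy_candidate_rejected(self):
        genome, pos, mite_len, _ = self._genome_with_mite()
        cands = [c for c in scan_inverted_repeats(genome) if abs(c.start - pos) <= 3]
        assert cands
        assert validate_copy_number(cands[0], genome) is False
        assert cands[0].copy_count == 0

    def test_multicopy_family_accepted(self, mite_run):
        genome, planted, accepted = mite_run
        assert accepted  # families planted at 10 copies pass validation
        assert all(c.copy_count >= 3 for c in accepted)

    def test_recall_and_precision_on_planted_mites(self, mite_run):
        genome, planted, accepted = mite_run

        def overlaps(c, p):
            return c.start < p["end"] and c.end > p["start"]

        tp = sum(1 for p in planted if any(overlaps(c, p) for c in accepted))
        fp = sum(1 for c in accepted if not any(overlaps(c, p) for p in planted))
        assert tp / len(planted) >= 0.9
        assert (len(accepted) - fp) / len(accepted) >= 0.8
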