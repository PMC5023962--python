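"""Alignment engines against a brute-force affine-gap DP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tescar.align_core import (
    AlignScores,
    DEFAULT_SCORES,
    LocusAlignment,
    MutationEvent,
    chain_align,
    extract_events,
    global_align,
    local_align,
    read_alignments_tsv,
    score_alignment,
    windowed_density,
    write_alignments_tsv,
)

NEG_INF = -1e18


def gotoh_global_score(a: str, b: str, s: AlignScores = DEFAULT_SCORES) -> float:
    """Quadratic-space affine-gap global alignment score (independent oracle).

    Convention: a gap of length L costs open + (L - 1) * extend.
    """
    n, m = len(a), len(b)
    sub = np.where(
        np.frombuffer(a.encode(), np.uint8)[:, None]
        == np.frombuffer(b.encode(), np.uint8)[None, :],
        s.match,
        s.mismatch,
    )
    M = np.full(m + 1, NEG_INF)
    X = np.full(m + 1, NEG_INF)  # gap in b (consuming a)
    Y = np.full(m + 1, NEG_INF)  # gap in a (consuming b)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = s.gap_open + (j - 1) * s.gap_extend
    for i in range(1, n + 1):
        prev_M, prev_X, prev_Y = M.copy(), X.copy(), Y.copy()
        M[:] = NEG_INF
        X[0] = s.gap_open + (i - 1) * s.gap_extend
        Y[0] = NEG_INF
        X[1:] = np.maximum(
            np.maximum(prev_M[1:] + s.gap_open, prev_X[1:] + s.gap_extend),
            prev_Y[1:] + s.gap_open,
        )
        for j in range(1, m + 1):
            M[j] = max(prev_M[j - 1], prev_X[j - 1], prev_Y[j - 1]) + sub[i - 1, j - 1]
            Y[j] = max(M[j - 1] + s.gap_open, Y[j - 1] + s.gap_extend, X[j - 1] + s.gap_open)
    return float(max(M[m], X[m], Y[m]))


def gotoh_local_score(a: str, b: str, s: AlignScores = DEFAULT_SCORES) -> float:
    n, m = len(a), len(b)
    sub = np.where(
        np.frombuffer(a.encode(), np.uint8)[:, None]
        == np.frombuffer(b.encode(), np.uint8)[None, :],
        s.match,
        s.mismatch,
    )
    M = np.zeros(m + 1)
    X = np.full(m + 1, NEG_INF)
    Y = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        prev_M, prev_X, prev_Y = M.copy(), X.copy(), Y.copy()
        M[:] = 0.0
        X[:] = NEG_INF
        Y[:] = NEG_INF
        X[1:] = np.maximum(
            np.maximum(prev_M[1:] + s.gap_open, prev_X[1:] + s.gap_extend),
            prev_Y[1:] + s.gap_open,
        )
        for j in range(1, m + 1):
            M[j] = max(0.0, max(prev_M[j - 1], prev_X[j - 1], prev_Y[j - 1]) + sub[i - 1, j - 1])
            Y[j] = max(M[j - 1] + s.gap_open, Y[j - 1] + s.gap_extend, X[j - 1] + s.gap_open)
            best = max(best, M[j])
    return best


def random_pair(rng, n, divergence=0.05, indels=2):
    bases = np.array(list("ACGT"))
    a = "".join(bases[rng.integers(0, 4, n)])
    b = list(a)
    for i in rng.choice(n, max(1, int(n * divergence)), replace=False):
        b[i] = "ACGT"[("ACGT".index(b[i]) + int(rng.integers(1, 4))) % 4]
    b = "".join(b)
    for _ in range(indels):
        p = int(rng.integers(0, len(b)))
        if rng.random() < 0.5:
            b = b[:p] + "".join(bases[rng.integers(0, 4, int(rng.integers(1, 6)))]) + b[p:]
        else:
            b = b[:p] + b[p + int(rng.integers(1, 6)) :]
    return a, b


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.percent_identity == 100.0
        assert extract_events(aln) == []

    def test_single_substitution(self):
        aln = global_align("ACGT", "AGGT")
        events = extract_events(aln)
        assert aln.percent_identity == 75.0
        assert len(events) == 1 and events[0].kind == "substitution"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_score_matches_dp_oracle(self):
        """Engine scores equal the quadratic-space DP oracle on seeded pairs."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = random_pair(rng, 200)
            aln = global_align(a, b)
            assert aln.score == pytest.approx(gotoh_global_score(a, b))
            # the reported traceback realizes the optimal score
            assert score_alignment(aln.aligned_a, aln.aligned_b) == pytest.approx(aln.score)

    def test_score_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = random_pair(rng, 300)
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_self_alignment_identity(self, x):
        aln = global_align(x, x)
        assert aln.percent_identity == 100.0
        assert extract_events(aln) == []

    def test_substitutions_plus_matches_conserved(self):
        rng = np.random.default_rng(6)
        a, b = random_pair(rng, 400)
        aln = global_align(a, b)
        n_sub = sum(1 for ev in extract_events(aln) if ev.kind == "substitution")
        assert n_sub + aln.matches == aln.aligned_bases


class TestLocalAlign:
    def test_identical_full_length(self):
        aln = local_align("ACGTACGTAC", "ACGTACGTAC")
        assert aln.aligned_bases == 10
        assert aln.percent_identity == 100.0

    def test_disjoint_alphabets_empty(self):
        aln = local_align("AAAA", "CCCC")
        assert len(aln) == 0
        assert aln.score == 0.0

    def test_scores_match_dp_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            a, b = random_pair(rng, 120, divergence=0.2, indels=1)
            assert local_align(a, b).score == pytest.approx(gotoh_local_score(a, b))


class TestChainAlign:
    def test_matches_full_dp_on_medium_pairs(self):
        """Anchor-and-chain reproduces the exact DP score on <= 5 kb pairs."""
        rng = np.random.default_rng(13)
        for n in (1500, 3000):
            a, b = random_pair(rng, n, divergence=0.02, indels=4)
            assert chain_align(a, b).score == pytest.approx(global_align(a, b).score)

    def test_long_insertion_single_event(self):
        rng = np.random.default_rng(14)
        a, _ = random_pair(rng, 4000, divergence=0.0, indels=0)
        ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        b = a[:2000] + ins + a[2000:]
        aln = chain_align(a, b)
        indels = [ev for ev in extract_events(aln) if ev.kind == "indel"]
        assert len(indels) == 1
        assert indels[0].length == 500


class TestEvents:
    def test_multibase_gap_is_one_event(self):
        aln = LocusAlignment("a", "b", "ACGTACGTAC", "ACG-----AC")
        events = extract_events(aln)
        assert [ (e.kind, e.length) for e in events ] == [("indel", 5)]

    def test_n_not_counted_as_mismatch(self):
        aln = LocusAlignment("a", "b", "ACGT", "ANGT")
        assert extract_events(aln) == []
        assert aln.percent_identity == 100.0

    def test_hand_enumerated_mixture(self):
        # 3 substitutions and 2 separate gap runs -> 5 events
        aln = LocusAlignment("a", "b", "ACGTAAACGTACGTAA", "ATGTAA--GTCC-TAT")
        events = extract_events(aln)
        assert len(events) == 5
        kinds = sorted(ev.kind for ev in events)
        assert kinds == ["indel", "indel", "substitution", "substitution", "substitution"]

    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError, match="both rows"):
            LocusAlignment("a", "b", "A-C", "A-C")

    def test_event_validation(self):
        with pytest.raises(ValueError):
            MutationEvent("substitution", 0, 0)
        with pytest.raises(ValueError):
            MutationEvent("weird", 0, 1)


class TestWindowedDensity:
    def test_no_events_all_zero(self):
        series = windowed_density([], 1000, 400, 40)
        assert len(series) == 16
        assert all(d == 0.0 for _, d in series)

    def test_single_event_localized(self):
        events = [MutationEvent("substitution", 200)]
        series = windowed_density(events, 1000, 400, 40)
        for center, dens in series:
            covers = center - 200 <= 200 < center + 200
            assert dens == pytest.approx(1 / 400 if covers else 0.0)

    def test_uniform_density_recovered(self):
        events = [MutationEvent("substitution", p) for p in range(0, 2000, 100)]
        series = windowed_density(events, 2000, 400, 40)
        for _, dens in series:
            assert dens == pytest.approx(0.01, abs=0.003)

    def test_window_larger_than_region(self):
        assert windowed_density([], 100, 400, 40) == []

    def test_bad_window(self):
        with pytest.raises(ValueError):
            windowed_density([], 100, 10, 20)


def test_alignment_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    a, b = random_pair(rng, 150)
    aln = global_align(a, b, seq_a_id="locus:A", seq_b_id="locus:B")
    path = tmp_path / "aln.tsv"
    write_alignments_tsv([aln], path)
    back = read_alignments_tsv(path)[0]
    assert back.aligned_a == aln.aligned_a
    assert back.aligned_b == aln.aligned_b
    assert back.seq_a_id == "locus:A"
    assert back.score == aln.score
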