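"""Affine-gap global alignment, indel calling and identity tracks.

The optimality oracle is independent of the implementation: a top-down
three-state recursion written here (and, for short pairs, literal
enumeration of every alignment scored from its gapped strings).
"""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from creloc.alnte import (
    AlignmentParams,
    call_indels,
    global_align,
    windowed_identity,
)
from creloc.synthio import sim_insertion_pair

P = AlignmentParams()


def score_gapped_rows(row_a, row_b, params=P):
    """Score an explicit alignment: gap runs cost open + L*extend; N is
    neutral."""
    score = 0.0
    for row in (row_a, row_b):
        for gap_run in "".join("-" if c == "-" else "x" for c in row).split("x"):
            if gap_run:
                score += params.gap_open + len(gap_run) * params.gap_extend
    for x, y in zip(row_a, row_b):
        if "-" in (x, y) or "N" in (x, y):
            continue
        score += params.match if x == y else params.mismatch
    return score


def enumerate_alignments(a, b):
    """Every global alignment of a and b as gapped row pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def optimal_score_recursive(a, b, params=P):
    """Independent affine-gap optimum via top-down recursion over the
    three column states."""
    open_cost = params.gap_open + params.gap_extend
    ext = params.gap_extend

    def sub(x, y):
        if "N" in (x, y):
            return 0.0
        return params.match if x == y else params.mismatch

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub(a[i], b[j]) + best(i + 1, j + 1, "m"))
        if i < len(a):  # gap in B
            cost = ext if state == "gb" else open_cost
            options.append(cost + best(i + 1, j, "gb"))
        if j < len(b):  # gap in A
            cost = ext if state == "ga" else open_cost
            options.append(cost + best(i, j + 1, "ga"))
        return max(options)

    return best(0, 0, "m")


def test_identity_alignment():
    aln = global_align("ACGTACGT", "ACGTACGT")
    assert aln.score == 8.0
    assert "-" not in aln.aligned_a + aln.aligned_b


def test_single_deletion_scoring_convention():
    """AAAA vs AA: 2 matches + one gap of length 2 = 2 - 5 - 2 = -5."""
    aln = global_align("AAAA", "AA")
    assert aln.score == -5.0
    calls = call_indels(aln)
    assert calls == [type(calls[0])("deletion", 0, 2)]


def test_empty_and_illegal_inputs_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACGT")
    with pytest.raises(ValueError):
        global_align("ACGT", "ACXT")


def test_n_is_mismatch_neutral():
    assert global_align("ANA", "ATA").score == 2.0
    assert global_align("ANA", "ANA").score == 2.0


def test_score_matches_enumeration_oracle_short_pairs(rng):
    """Optimal score equals the maximum over literally every alignment for
    random pairs up to 7 bp."""
    bases = np.array(list("ACGT"))
    for _ in range(40):
        a = "".join(rng.choice(bases, size=rng.integers(1, 8)))
        b = "".join(rng.choice(bases, size=rng.integers(1, 8)))
        brute = max(
            score_gapped_rows(ra, rb) for ra, rb in enumerate_alignments(a, b)
        )
        assert global_align(a, b).score == brute


def test_score_matches_recursive_oracle_up_to_12bp(rng):
    """Optimal score equals the independent three-state recursion on 200
    random pairs up to 12 bp."""
    bases = np.array(list("ACGT"))
    for _ in range(200):
        a = "".join(rng.choice(bases, size=rng.integers(1, 13)))
        b = "".join(rng.choice(bases, size=rng.integers(1, 13)))
        aln = global_align(a, b)
        assert aln.score == optimal_score_recursive(a, b)
        # the emitted rows really achieve the reported score
        assert score_gapped_rows(aln.aligned_a, aln.aligned_b) == aln.score


def test_oracles_agree_with_each_other(rng):
    """Consistency of the two independent oracles on short pairs."""
    bases = np.array(list("ACGT"))
    for _ in range(15):
        a = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        b = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        brute = max(
            score_gapped_rows(ra, rb) for ra, rb in enumerate_alignments(a, b)
        )
        assert brute == optimal_score_recursive(a, b)


def test_score_symmetric_under_exchange(rng):
    bases = np.array(list("ACGT"))
    for _ in range(20):
        a = "".join(rng.choice(bases, size=30))
        b = "".join(rng.choice(bases, size=rng.integers(20, 40)))
        f = global_align(a, b)
        r = global_align(b, a)
        assert f.score == r.score
        fi = [(c.kind, c.length) for c in call_indels(f)]
        ri = [(c.kind, c.length) for c in call_indels(r)]
        swap = {"insertion": "deletion", "deletion": "insertion"}
        assert sorted(fi) == sorted((swap[k], l) for k, l in ri)


def test_planted_insertions_recovered_exactly():
    """Planted insertions (with >= 20 bp flanks) come back at the recorded
    left-aligned position and exact length."""
    for seed in range(30):
        a, b, truth = sim_insertion_pair(
            base_len=1200, insertions=[(400, 163), (900, 57)], seed=seed
        )
        calls = call_indels(global_align(a, b))
        got = [(c.position, c.length) for c in calls if c.kind == "insertion"]
        assert got == truth.insertions
        assert all(c.kind == "insertion" for c in calls)


def test_min_len_suppresses_short_indels():
    aln = global_align("ACGTACGTACGTACGTAAAA", "ACGTACGTCGTACGTAAAA")
    assert call_indels(aln, min_len=5) == []
    assert len(call_indels(aln, min_len=1)) == 1


def test_windowed_identity_identical_and_threshold():
    aln = global_align("ACGTACGTAC" * 5, "ACGTACGTAC" * 5)
    identities, windows, above = windowed_identity(aln, window_bp=10)
    assert all(i == 1.0 for i in identities)
    assert above[0].start == 0 and above[-1].end == 50


def test_windowed_identity_gap_columns_count_as_mismatch():
    # B missing 4 of A's 10 bases -> identity 0.6 in that window
    a = "ACGTACGTAC"
    b = "ACGTAC"
    aln = global_align(a, b)
    identities, _, above = windowed_identity(aln, window_bp=10, threshold=0.75)
    assert identities[0] == pytest.approx(0.6)
    assert above == []
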