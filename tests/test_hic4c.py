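"""Virtual 4C profiles, distance-decay expectation, Fisher contact tests.

The p-value oracle is an exact-integer hypergeometric enumeration written
here from first principles (math.comb), independent of the scipy routine
used by the implementation.
"""

from math import comb

import numpy as np
import pytest

from creloc.hic4c import ContactMatrix, contact_test, expected_by_distance
from creloc.hic4c import test_cre_promoter as cre_promoter_test
from creloc.hic4c import virtual_profile
from creloc.intervals import GenomicInterval
from creloc.synthio import sim_contacts


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by enumerating every table with the same margins
    and summing those no more probable than the observed one (exact
    integer arithmetic; tiny float fuzz only in the final comparison)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[a]
    tail = sum(w for w in weights.values() if w <= obs * (1 + 1e-12))
    return tail / total


def decay_matrix(n=10, scale=100):
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i != j:
                counts[i, j] = scale // abs(i - j)
    return ContactMatrix("scaf", 5000, counts)


def test_matrix_validation():
    with pytest.raises(ValueError):
        ContactMatrix("s", 5000, np.array([[0, 1], [2, 0]]))
    with pytest.raises(ValueError):
        ContactMatrix("s", 0, np.zeros((3, 3)))


def test_virtual_profile_symmetry_and_planted_max():
    m, _ = sim_contacts(n_bins=50, seed=0)
    pa, _ = virtual_profile(m, 7)
    pb, _ = virtual_profile(m, 30)
    assert pa[30] == pb[7]
    flat = np.ones((20, 20), dtype=int)
    np.fill_diagonal(flat, 0)
    flat[5, 15] = flat[15, 5] = 40
    prof, anchor = virtual_profile(ContactMatrix("s", 5000, flat), 5)
    off = np.delete(prof, anchor)
    assert prof[15] == off.max() == 40
    with pytest.raises(ValueError):
        virtual_profile(m, 50)


def test_expected_by_distance_exact_construction():
    """counts(i,j) = 100/|i-j| -> mean(d) = median(d) = 100//d; pair counts
    n_bins - d."""
    model = expected_by_distance(decay_matrix(10))
    for d in range(1, 10):
        n_pairs, total, mean, median = model.at(d)
        assert n_pairs == 10 - d
        assert mean == median == 100 // d
        assert total == (10 - d) * (100 // d)


def test_expected_by_distance_poisson_sampling():
    """Simulated decay matrix: mean(d) within 3 SE of scale/d for d <= 50."""
    m, _ = sim_contacts(n_bins=500, scale=100.0, alpha=1.0, seed=1)
    model = expected_by_distance(m)
    for d in range(1, 51):
        n_pairs, _, mean, _ = model.at(d)
        se = np.sqrt((100 / d) / n_pairs)
        assert abs(mean - 100 / d) <= 3.5 * se


def test_contact_test_observed_equals_expected():
    t = contact_test(decay_matrix(10), 0, 3)
    # o = 33, e = round(mean) = 33
    assert t.observed == round(t.expected)
    assert t.odds_ratio == 1.0
    assert t.p_value == 1.0


def test_contact_test_strong_enrichment_table():
    """Spec-shaped table [[30,170],[5,195]]: p below 1e-4, OR > 1, matching
    the enumeration oracle."""
    counts = np.zeros((41, 41), dtype=np.int64)
    # distance-1 pairs: 40 of them; put 30 counts on pair (0,1), spread 170
    # over the rest so the mean is 5 -> e = round(200/40) = 5
    counts[0, 1] = counts[1, 0] = 30
    rest = np.full(39, 170 // 39)
    rest[: 170 - rest.sum()] += 1
    for k, v in enumerate(rest, start=1):
        counts[k, k + 1] = counts[k + 1, k] = v
    m = ContactMatrix("s", 5000, counts)
    t = contact_test(m, 0, 1)
    assert t.total == 200
    oracle_p = fisher_two_sided_oracle(
        [[t.observed, t.total - t.observed],
         [round(t.expected), t.total - round(t.expected)]]
    )
    assert t.p_value == pytest.approx(oracle_p, rel=1e-6)
    assert t.p_value < 1e-4
    assert t.odds_ratio > 1


def test_contact_test_matches_oracle_on_random_tables(rng):
    """Implementation p equals brute-force hypergeometric enumeration on
    random observed/expected tables with total <= 500."""
    for _ in range(200):
        total = int(rng.integers(2, 501))
        o = int(rng.integers(0, total + 1))
        e = int(rng.integers(0, total + 1))
        from scipy import stats

        _, p_impl = stats.fisher_exact(
            [[o, total - o], [e, total - e]], alternative="two-sided"
        )
        p_oracle = fisher_two_sided_oracle([[o, total - o], [e, total - e]])
        assert p_impl == pytest.approx(p_oracle, rel=1e-6, abs=1e-12)


def test_contact_test_two_sided_monotonicity():
    """For fixed e and T, p is non-increasing as o moves away from e."""
    from scipy import stats

    T, e = 300, 40
    ps_up = [
        stats.fisher_exact([[o, T - o], [e, T - e]])[1] for o in range(e, 101)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(ps_up, ps_up[1:]))
    ps_down = [
        stats.fisher_exact([[o, T - o], [e, T - e]])[1]
        for o in range(e, -1, -1)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(ps_down, ps_down[1:]))


def test_zero_information_distance_raises():
    counts = np.zeros((5, 5), dtype=np.int64)
    counts[0, 1] = counts[1, 0] = 3
    m = ContactMatrix("s", 5000, counts)
    with pytest.raises(ValueError):
        contact_test(m, 0, 3)


def test_cre_promoter_midpoint_bin_mapping():
    m, _ = sim_contacts(n_bins=100, bin_size=5000, seed=3)
    # interval inside one bin behaves exactly like contact_test on bins
    cre = GenomicInterval("scaf", 51_000, 54_000)  # midpoint 52500 -> bin 10
    prom = GenomicInterval("scaf", 251_000, 254_000)  # -> bin 50
    direct = contact_test(m, 10, 50)
    via = cre_promoter_test(m, cre, prom)
    assert (via.anchor, via.target) == (10, 50)
    assert via.p_value == direct.p_value
    # interval spanning two bins: the midpoint decides
    wide = GenomicInterval("scaf", 48_000, 58_000)  # midpoint 53000 -> bin 10
    assert m.bin_of(wide) == 10


def test_planted_loop_detected_single_seed():
    m, _ = sim_contacts(n_bins=200, loops=[(50, 80, 10.0)], seed=4)
    t = contact_test(m, 50, 80)
    assert t.p_value < 0.05
    assert t.odds_ratio > 1
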