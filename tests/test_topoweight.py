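"""Sliding windows, window filters, and topology weighting."""

import numpy as np
import pytest

from creloc.intervals import GenomicInterval
from creloc.synthio import sim_haplotypes
from creloc.topology import (
    ZeroComparableSitesError,
    enumerate_topologies,
    quartet_topology_id,
    tree_from_newick,
)
from creloc.topoweight import (
    MISSING,
    HaplotypeMatrix,
    WindowSpec,
    high_weight_intervals,
    make_windows,
    nj_tree,
    pairwise_distances,
    weight_exact,
    weight_mc,
    weighting_profile,
)


def toy_matrix(n_samples=8, n_sites=130, seed=0):
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i}" for i in range(n_samples)]
    group_of = {s: "G" + str(i % 4) for i, s in enumerate(sample_ids)}
    alleles = rng.integers(0, 4, size=(n_samples, n_sites)).astype(np.int8)
    return HaplotypeMatrix(sample_ids, group_of, np.arange(n_sites), alleles)


def test_window_arithmetic_130_sites():
    """130 sites, size 50, step 20 -> five windows, fixed boundaries."""
    wins = make_windows(toy_matrix(), WindowSpec())
    assert [(w.start, w.end) for w in wins] == [
        (0, 50), (20, 70), (40, 90), (60, 110), (80, 130)
    ]


def test_no_window_fits_49_sites():
    assert make_windows(toy_matrix(n_sites=49), WindowSpec()) == []


def test_all_missing_group_fails_filter():
    m = toy_matrix()
    members = [i for i, s in enumerate(m.sample_ids) if m.group_of[s] == "G2"]
    m.alleles[members, :] = MISSING
    assert all(not w.passes for w in make_windows(m, WindowSpec()))


def test_genotyping_filter_counts_sites_per_group():
    """A window passes iff >= min_sites sites have every group covered at
    min_genotyped_frac."""
    m = toy_matrix(n_samples=4, n_sites=50)  # one sample per group
    # knock out one group's sample at 41 of 50 sites -> only 9 usable sites
    m.alleles[0, :41] = MISSING
    assert [w.passes for w in make_windows(m, WindowSpec())] == [False]
    m2 = toy_matrix(n_samples=4, n_sites=50)
    m2.alleles[0, :40] = MISSING  # 10 usable sites: exactly min_sites
    assert [w.passes for w in make_windows(m2, WindowSpec())] == [True]


def test_pairwise_distance_missing_excluded_and_error():
    a = np.array([[0, 1, 2, 3], [0, 1, 0, MISSING]], dtype=np.int8)
    D = pairwise_distances(a)
    assert D[0, 1] == pytest.approx(1 / 3)  # 3 comparable sites, 1 diff
    b = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
    with pytest.raises(ZeroComparableSitesError):
        pairwise_distances(b)


def test_weight_exact_monophyletic_groups():
    """Groups monophyletic in the tree put weight 1 on the concordant
    topology."""
    tree = tree_from_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
    gof = {f"{g}{i}": g.upper() for g in "abcd" for i in (1, 2)}
    ts = enumerate_topologies(list("ABCD"))
    tw = weight_exact(tree, gof, ts)
    assert tw.weight(quartet_topology_id(("A", "B"), ("C", "D"))) == 1.0
    assert tw.weights.sum() == 1.0


def test_weight_exact_mixed_tree_half_half():
    """Two sampling combinations split evenly between AC|BD and AD|BC."""
    tree = tree_from_newick("(((a1,c1),b1),(a2,d1));")
    gof = dict(a1="A", a2="A", b1="B", c1="C", d1="D")
    ts = enumerate_topologies(list("ABCD"))
    tw = weight_exact(tree, gof, ts)
    assert tw.weight(quartet_topology_id(("A", "C"), ("B", "D"))) == 0.5
    assert tw.weight(quartet_topology_id(("A", "D"), ("B", "C"))) == 0.5
    assert tw.weight(quartet_topology_id(("A", "B"), ("C", "D"))) == 0.0


def test_weight_exact_generic_path_matches_quartet_path():
    """The generic (>4 groups) induced-subtree path agrees with the
    vectorized quartet path when restricted to 4 of 5 groups."""
    m, _ = sim_haplotypes(n_groups=5, n_per_group=2, n_sites=300,
                          block=None, seed=9)
    tree = nj_tree(m.window_slice(0, 100))
    ts5 = enumerate_topologies(list("ABCDE"))
    tw5 = weight_exact(tree, m.group_of, ts5)
    assert tw5.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(tw5.weights >= 0)


def test_weight_mc_within_binomial_ci_of_exact():
    """MC weighting at 1000 iterations within 3 sigma of the exact oracle."""
    tree = tree_from_newick("(((a1,c1),b1),(a2,d1));")
    gof = dict(a1="A", a2="A", b1="B", c1="C", d1="D")
    ts = enumerate_topologies(list("ABCD"))
    exact = weight_exact(tree, gof, ts)
    mc = weight_mc(tree, gof, ts, n_iter=1000, seed=11)
    assert np.all(np.abs(mc.weights - exact.weights) <= 3 * np.sqrt(0.25 / 1000))
    assert mc.weights.sum() == 1.0


def test_weight_mc_deterministic_and_monophyletic():
    tree = tree_from_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
    gof = {f"{g}{i}": g.upper() for g in "abcd" for i in (1, 2)}
    ts = enumerate_topologies(list("ABCD"))
    w1 = weight_mc(tree, gof, ts, seed=5)
    w2 = weight_mc(tree, gof, ts, seed=5)
    assert np.array_equal(w1.weights, w2.weights)
    assert w1.weight(quartet_topology_id(("A", "B"), ("C", "D"))) == 1.0


def test_weights_permutation_equivariant():
    """Relabelling groups permutes the weight vector accordingly."""
    m, _ = sim_haplotypes(seed=21)
    tree = nj_tree(m.window_slice(0, 50))
    ts = enumerate_topologies(list("ABCD"))
    base = weight_exact(tree, m.group_of, ts)
    # swap groups B and C
    swap = {"A": "A", "B": "C", "C": "B", "D": "D"}
    gof2 = {s: swap[g] for s, g in m.group_of.items()}
    swapped = weight_exact(tree, gof2, ts)
    for p1, p2 in ((("A", "B"), ("C", "D")), (("A", "C"), ("B", "D")),
                   (("A", "D"), ("B", "C"))):
        tid = quartet_topology_id(p1, p2)
        tid_sw = quartet_topology_id(
            (swap[p1[0]], swap[p1[1]]), (swap[p2[0]], swap[p2[1]])
        )
        assert base.weight(tid) == swapped.weight(tid_sw)


def test_profile_recovers_planted_block_single_seed():
    m, truth = sim_haplotypes(seed=0)
    prof = weighting_profile(m)
    assert np.allclose(prof.weights.sum(axis=1), 1.0)
    ivs = high_weight_intervals(prof, truth.concordant_topology)
    assert len(ivs) == 1
    assert ivs[0].overlaps(truth.association_interval)
    # boundaries within one window step of the truth
    assert abs(ivs[0].start - truth.association_interval.start) <= 50
    assert abs(ivs[0].end - truth.association_interval.end) <= 50


def test_high_weight_intervals_degenerate_all_ones():
    """All-weights-1 profile yields a single interval spanning everything."""
    m, truth = sim_haplotypes(seed=3)
    prof = weighting_profile(m)
    prof.weights[:] = 0.0
    prof.weights[:, prof.topology_set.index(truth.concordant_topology)] = 1.0
    ivs = high_weight_intervals(prof, truth.concordant_topology)
    assert len(ivs) == 1
    assert ivs[0].start == prof.windows[0].start
    assert ivs[0].end == prof.windows[-1].end
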