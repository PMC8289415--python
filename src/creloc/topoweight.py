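"""Sliding-window topology weighting.

Localises genomic intervals where haplotypes cluster by phenotype rather
than by species.  Windows of a fixed number of SNPs (default 50, step 20)
are turned into neighbor-joining trees on normalized Hamming distances;
each tree is then reduced to a weighting over all possible unrooted group
topologies by sampling one tip per group, either exhaustively or by Monte
Carlo subsampling (default 1000 iterations).  Maximal runs of windows in
which a chosen hypothesis topology carries high weight become association
intervals.

A window enters the analysis only if it contains at least ``min_sites``
sites at which every group has at least ``min_genotyped_frac`` of its
samples genotyped (defaults 10 and 0.5).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, merge_intervals
from .topology import (
    Tree,
    TopologySet,
    ZeroComparableSitesError,
    nj,
    quartet_topology_id,
)

MISSING = -1
_ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": MISSING, "-": MISSING}
_CODE_ALLELE = {0: "A", 1: "C", 2: "G", 3: "T", MISSING: "N"}


class CombinationCapError(RuntimeError):
    """Exhaustive weighting would enumerate too many tip combinations;
    use :func:`weight_mc` instead."""


@dataclass
class HaplotypeMatrix:
    """Phased alleles for samples at strictly increasing site positions.

    ``alleles`` is samples x sites, int8-coded (A,C,G,T -> 0..3; missing -> -1).
    """

    sample_ids: list[str]
    group_of: dict[str, str]
    positions: np.ndarray
    alleles: np.ndarray
    scaffold: str = "sim"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("alleles shape does not match samples x sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        missing = set(self.sample_ids) - set(self.group_of)
        if missing:
            raise ValueError(f"samples without group: {sorted(missing)}")

    @classmethod
    def from_strings(
        cls,
        sample_ids: list[str],
        group_of: dict[str, str],
        positions: list[int],
        rows: list[str],
        scaffold: str = "sim",
    ) -> "HaplotypeMatrix":
        alleles = np.array(
            [[_ALLELE_CODE[ch] for ch in row] for row in rows], dtype=np.int8
        )
        return cls(sample_ids, group_of, np.asarray(positions), alleles, scaffold)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, sid in enumerate(self.sample_ids):
            out.setdefault(self.group_of[sid], []).append(i)
        return out

    def window_slice(self, start: int, end: int) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.sample_ids,
            self.group_of,
            self.positions[start:end],
            self.alleles[:, start:end],
            self.scaffold,
        )


@dataclass(frozen=True)
class WindowSpec:
    size_snps: int = 50
    step_snps: int = 20
    min_sites: int = 10
    min_genotyped_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step_snps <= self.size_snps:
            raise ValueError("need 0 < step <= size")
        if not 0 < self.min_genotyped_frac <= 1:
            raise ValueError("min_genotyped_frac must be in (0, 1]")
        if self.min_sites > self.size_snps:
            raise ValueError("min_sites cannot exceed window size")


@dataclass
class Window:
    start: int  # site index, inclusive
    end: int  # site index, exclusive
    passes: bool


def make_windows(matrix: HaplotypeMatrix, spec: WindowSpec) -> list[Window]:
    """Fixed-size SNP-index windows; partial trailing windows are unused.

    A window passes the genotyping filter iff >= ``min_sites`` of its sites
    have, in every group, >= ``min_genotyped_frac`` of samples non-missing.
    """
    genotyped = matrix.alleles != MISSING  # samples x sites
    group_ok = np.ones(matrix.n_sites, dtype=bool)
    for members in matrix.groups.values():
        frac = genotyped[members].mean(axis=0)
        group_ok &= frac >= spec.min_genotyped_frac
    windows = []
    start = 0
    while start + spec.size_snps <= matrix.n_sites:
        end = start + spec.size_snps
        passes = int(group_ok[start:end].sum()) >= spec.min_sites
        windows.append(Window(start, end, passes))
        start += spec.step_snps
    return windows


def pairwise_distances(alleles: np.ndarray) -> np.ndarray:
    """Normalized Hamming distances with pairwise deletion of missing sites.

    Raises :class:`ZeroComparableSitesError` if any pair shares no site.
    """
    present = alleles != MISSING
    a = alleles[:, None, :]
    b = alleles[None, :, :]
    both = present[:, None, :] & present[None, :, :]
    comparable = both.sum(axis=2)
    if np.any(comparable == 0):
        i, j = np.argwhere(comparable == 0)[0]
        raise ZeroComparableSitesError(
            f"samples {i} and {j} share no genotyped site"
        )
    diffs = ((a != b) & both).sum(axis=2)
    return diffs / comparable


def nj_tree(matrix: HaplotypeMatrix) -> Tree:
    """Neighbor-joining tree for a (window slice of a) haplotype matrix."""
    if len(matrix.sample_ids) < 4:
        raise ValueError("need at least 4 samples for a window tree")
    D = pairwise_distances(matrix.alleles)
    return nj(D, matrix.sample_ids)


@dataclass
class TopologyWeights:
    """Weighting over a TopologySet for one tree/window."""

    weights: np.ndarray
    topology_set: TopologySet
    method: str
    window: GenomicInterval | None = None
    n_iter: int | None = None
    seed: int | None = None

    def weight(self, topology_id: str) -> float:
        return float(self.weights[self.topology_set.index(topology_id)])


def _group_picks(tree: Tree, group_of: dict[str, str]) -> dict[str, list[str]]:
    picks: dict[str, list[str]] = {}
    for label in tree.leaf_labels:
        picks.setdefault(group_of[label], []).append(label)
    if len(picks) < 3:
        raise ValueError("need at least 3 groups with leaves in the tree")
    return picks


def _quartet_machinery(
    tree: Tree, groups: list[str], topology_set: TopologySet
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, list[str]]:
    """Precompute what the vectorized 4-group path needs: the topological
    leaf-distance matrix, per-group leaf-index arrays and the map from
    four-point-condition argmin to topology index."""
    Dt, order = tree.leaf_distances(unit_lengths=True)
    idx_of = {lab: i for i, lab in enumerate(order)}
    g = groups
    split_ids = [
        quartet_topology_id((g[0], g[1]), (g[2], g[3])),
        quartet_topology_id((g[0], g[2]), (g[1], g[3])),
        quartet_topology_id((g[0], g[3]), (g[1], g[2])),
    ]
    split_to_topo = np.array([topology_set.index(s) for s in split_ids])
    return Dt, idx_of, split_to_topo, order


def _quartet_split_index(
    Dt: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorized four-point condition: 0 -> ab|cd, 1 -> ac|bd, 2 -> ad|bc.

    On a binary tree with unit branch lengths the true split's distance sum
    is strictly smallest, so argmin is unambiguous.
    """
    s0 = Dt[a, b] + Dt[c, d]
    s1 = Dt[a, c] + Dt[b, d]
    s2 = Dt[a, d] + Dt[b, c]
    return np.argmin(np.stack([s0, s1, s2]), axis=0)


def weight_exact(
    tree: Tree,
    group_of: dict[str, str],
    topology_set: TopologySet,
    cap: int = 10**6,
) -> TopologyWeights:
    """Exhaustive topology weighting: enumerate every one-tip-per-group
    combination and count the induced topologies (exact count ratio)."""
    picks = _group_picks(tree, group_of)
    groups = sorted(picks)
    if tuple(groups) != topology_set.group_labels:
        raise ValueError("tree groups do not match topology set labels")
    total = math.prod(len(v) for v in picks.values())
    if total > cap:
        raise CombinationCapError(
            f"{total} combinations exceed cap {cap}; use weight_mc"
        )
    counts = np.zeros(len(topology_set), dtype=np.int64)
    if len(groups) == 3:
        counts[0] = total
    elif len(groups) == 4:
        Dt, idx_of, split_to_topo, _ = _quartet_machinery(
            tree, groups, topology_set
        )
        arrs = [
            np.array([idx_of[lab] for lab in picks[g]]) for g in groups
        ]
        a, b, c, d = (x.ravel() for x in np.meshgrid(*arrs, indexing="ij"))
        split = _quartet_split_index(Dt, a, b, c, d)
        np.add.at(counts, split_to_topo[split], 1)
    else:
        for combo in itertools.product(*(picks[g] for g in groups)):
            tid = tree.induced_topology_id(
                {lab: g for lab, g in zip(combo, groups)}
            )
            counts[topology_set.index(tid)] += 1
    return TopologyWeights(counts / total, topology_set, "exact")


def weight_mc(
    tree: Tree,
    group_of: dict[str, str],
    topology_set: TopologySet,
    n_iter: int = 1000,
    seed: int | None = None,
) -> TopologyWeights:
    """Monte-Carlo topology weighting: uniform independent one-tip-per-group
    subsamples; weight = count / n_iter."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    picks = _group_picks(tree, group_of)
    groups = sorted(picks)
    if tuple(groups) != topology_set.group_labels:
        raise ValueError("tree groups do not match topology set labels")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(topology_set), dtype=np.int64)
    if len(groups) == 3:
        counts[0] = n_iter
    elif len(groups) == 4:
        Dt, idx_of, split_to_topo, _ = _quartet_machinery(
            tree, groups, topology_set
        )
        cols = []
        for g in groups:
            members = np.array([idx_of[lab] for lab in picks[g]])
            cols.append(members[rng.integers(0, len(members), size=n_iter)])
        split = _quartet_split_index(Dt, *cols)
        np.add.at(counts, split_to_topo[split], 1)
    else:
        for _ in range(n_iter):
            combo = {
                picks[g][rng.integers(0, len(picks[g]))]: g for g in groups
            }
            tid = tree.induced_topology_id(combo)
            counts[topology_set.index(tid)] += 1
    return TopologyWeights(
        counts / n_iter, topology_set, "montecarlo", n_iter=n_iter, seed=seed
    )


@dataclass
class WeightingProfile:
    """Per-window topology weightings over the passing windows of a scan."""

    topology_set: TopologySet
    windows: list[GenomicInterval] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def track(self, topology_id: str) -> np.ndarray:
        return self.weights[:, self.topology_set.index(topology_id)]


def weighting_profile(
    matrix: HaplotypeMatrix,
    spec: WindowSpec | None = None,
    topology_set: TopologySet | None = None,
    method: str = "exact",
    n_iter: int = 1000,
    seed: int | None = None,
    cap: int = 10**6,
) -> WeightingProfile:
    """Sliding-window scan: NJ tree and topology weighting per passing window.

    Window positions are reported as the bp span of their site positions,
    half-open ``[first_site, last_site + 1)``.
    """
    if spec is None:
        spec = WindowSpec()
    if topology_set is None:
        from .topology import enumerate_topologies

        topology_set = enumerate_topologies(
            sorted(set(matrix.group_of[s] for s in matrix.sample_ids))
        )
    windows: list[GenomicInterval] = []
    rows = []
    rng = np.random.default_rng(seed)
    for win in make_windows(matrix, spec):
        if not win.passes:
            continue
        sub = matrix.window_slice(win.start, win.end)
        tree = nj_tree(sub)
        if method == "exact":
            tw = weight_exact(tree, matrix.group_of, topology_set, cap=cap)
        elif method == "mc":
            tw = weight_mc(
                tree,
                matrix.group_of,
                topology_set,
                n_iter=n_iter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        windows.append(
            GenomicInterval(
                matrix.scaffold,
                int(sub.positions[0]),
                int(sub.positions[-1]) + 1,
            )
        )
        rows.append(tw.weights)
    weights = np.array(rows) if rows else np.empty((0, len(topology_set)))
    return WeightingProfile(topology_set, windows, weights)


def high_weight_intervals(
    profile: WeightingProfile,
    topology_id: str,
    threshold: float = 0.75,
    min_windows: int = 2,
) -> list[GenomicInterval]:
    """Maximal runs of >= ``min_windows`` consecutive windows whose weight
    for the hypothesis topology is >= ``threshold``, merged in bp space.
    Each interval is scored with the run's mean weight."""
    track = profile.track(topology_id)
    out: list[GenomicInterval] = []
    run: list[int] = []
    for i, w in enumerate(list(track) + [-1.0]):  # sentinel flushes last run
        if w >= threshold:
            run.append(i)
            continue
        if len(run) >= min_windows:
            members = [profile.windows[j] for j in run]
            score = float(np.mean([track[j] for j in run]))
            merged = merge_intervals(members, gap=0)
            # windows in a run overlap or abut in bp space; merge to one span
            out.append(
                GenomicInterval(
                    members[0].scaffold,
                    merged[0].start,
                    merged[-1].end,
                    score,
                )
            )
        run = []
    return out
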