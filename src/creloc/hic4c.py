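"""Virtual 4C profiles and contact-enrichment testing.

A symmetric binned Hi-C contact matrix (5 kb bins by default) is reduced to
an empirical distance-decay expectation: for each bin separation d >= 1,
the mean, median and total of counts over all pairs at that distance.  The
enrichment of one anchor/target pair is then assessed with a two-sided
Fisher's exact test on the 2x2 table

    [[observed,          total_at_d - observed],
     [round(expected),   total_at_d - round(expected)]]

which contrasts the pair's observed contacts with those expected from the
background model at the same genomic distance.  Feature intervals in bp are
mapped to the bin containing their midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval


@dataclass
class ContactMatrix:
    """Symmetric nonnegative integer contact counts over equal-size bins."""

    scaffold: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, interval: GenomicInterval) -> int:
        """Bin containing the interval midpoint (the centred-window rule)."""
        mid = (interval.start + interval.end) // 2
        b = mid // self.bin_size
        if not 0 <= b < self.n_bins:
            raise ValueError(f"interval midpoint falls outside the matrix: {mid}")
        return int(b)


@dataclass
class ExpectedModel:
    """Per-distance statistics over all unordered bin pairs (d = 0 excluded)."""

    n_bins: int
    n_pairs: np.ndarray  # index d-1
    totals: np.ndarray
    means: np.ndarray
    medians: np.ndarray

    def at(self, d: int) -> tuple[int, float, float, float]:
        if not 1 <= d <= self.n_bins - 1:
            raise ValueError(f"distance {d} out of range")
        i = d - 1
        return (
            int(self.n_pairs[i]),
            float(self.totals[i]),
            float(self.means[i]),
            float(self.medians[i]),
        )


@dataclass
class ContactTest:
    anchor: int
    target: int
    distance: int
    observed: int
    expected: float  # per-distance mean (unrounded)
    expected_median: float
    total: int  # total counts at this distance
    odds_ratio: float
    p_value: float


def virtual_profile(matrix: ContactMatrix, anchor: int) -> tuple[np.ndarray, int]:
    """Virtual 4C track: the matrix row at the anchor bin.  The anchor bin
    itself (self-contact) is included in the returned row; its index is
    returned alongside so callers can mask it."""
    if not 0 <= anchor < matrix.n_bins:
        raise ValueError(f"anchor bin {anchor} out of range")
    return matrix.counts[anchor].copy(), anchor


def expected_by_distance(matrix: ContactMatrix) -> ExpectedModel:
    """Empirical distance-decay background over all pairs at each separation."""
    n = matrix.n_bins
    n_pairs = np.empty(n - 1, dtype=np.int64)
    totals = np.empty(n - 1)
    means = np.empty(n - 1)
    medians = np.empty(n - 1)
    for d in range(1, n):
        diag = np.diagonal(matrix.counts, offset=d)
        n_pairs[d - 1] = len(diag)
        totals[d - 1] = diag.sum()
        means[d - 1] = diag.mean()
        medians[d - 1] = np.median(diag)
    return ExpectedModel(n, n_pairs, totals, means, medians)


def contact_test(
    matrix: ContactMatrix,
    anchor: int,
    target: int,
    model: ExpectedModel | None = None,
) -> ContactTest:
    """Two-sided Fisher's exact test of one pair against the distance-decay
    expectation at its separation."""
    if anchor == target:
        raise ValueError("anchor and target must differ")
    for b in (anchor, target):
        if not 0 <= b < matrix.n_bins:
            raise ValueError(f"bin {b} out of range")
    if model is None:
        model = expected_by_distance(matrix)
    d = abs(anchor - target)
    _, total, mean, median = model.at(d)
    total = int(total)
    if total == 0:
        raise ValueError(f"no counts at distance {d}: test is uninformative")
    o = int(matrix.counts[anchor, target])
    e = int(round(mean))
    table = np.array([[o, total - o], [e, total - e]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cells = table.astype(float)
    if np.any(cells == 0):
        cells = cells + 0.5  # Haldane correction
    odds_ratio = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    return ContactTest(
        anchor, target, d, o, mean, median, total, float(odds_ratio), float(p)
    )


def test_cre_promoter(
    matrix: ContactMatrix,
    cre: GenomicInterval,
    promoter: GenomicInterval,
    model: ExpectedModel | None = None,
) -> ContactTest:
    """Contact enrichment between bins centred on a candidate CRE and a
    promoter (bp intervals mapped by midpoint)."""
    return contact_test(
        matrix, matrix.bin_of(cre), matrix.bin_of(promoter), model=model
    )
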