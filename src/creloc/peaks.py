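"""Accessibility peak calling and the integration step that nominates
candidate CREs.

The caller is deliberately transparent: smooth the per-base coverage with a
centred moving average, threshold at global mean + k.sigma (with a floor on
sigma so flat tracks never fire), keep maximal super-threshold runs of a
minimum width, and merge runs separated by small gaps.  Candidate CREs are
the peaks that overlap a high-association interval from the topology
weighting scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, intersect, merge_intervals, sort_intervals

__all__ = [
    "CoverageTrack",
    "PeakParams",
    "call_peaks",
    "intersect",
    "merge_intervals",
    "nominate_cres",
]


@dataclass
class CoverageTrack:
    """Per-base coverage over [0, L) on one scaffold."""

    scaffold: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("coverage track must be a nonempty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("coverage must be nonnegative")


@dataclass(frozen=True)
class PeakParams:
    smooth_bp: int = 75
    k_sigma: float = 3.0
    sigma_floor: float = 1.0
    min_width_bp: int = 100
    merge_gap_bp: int = 50

    def __post_init__(self) -> None:
        for name in ("smooth_bp", "k_sigma", "sigma_floor", "min_width_bp", "merge_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with shrinking edge windows."""
    kernel = np.ones(width)
    sums = np.convolve(values, kernel, mode="same")
    norms = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / norms


def call_peaks(
    track: CoverageTrack, params: PeakParams | None = None
) -> list[GenomicInterval]:
    """Global-threshold peak calling; returns sorted, non-overlapping
    intervals scored by their mean smoothed coverage."""
    if params is None:
        params = PeakParams()
    smoothed = moving_average(track.values, params.smooth_bp)
    threshold = smoothed.mean() + params.k_sigma * max(
        smoothed.std(), params.sigma_floor
    )
    above = smoothed > threshold
    runs: list[GenomicInterval] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= params.min_width_bp:
                runs.append(GenomicInterval(track.scaffold, start, i))
            start = None
    merged = merge_intervals(runs, gap=params.merge_gap_bp)
    return [
        GenomicInterval(
            iv.scaffold,
            iv.start,
            iv.end,
            float(smoothed[iv.start : iv.end].mean()),
        )
        for iv in merged
    ]


def nominate_cres(
    assoc: list[GenomicInterval], peaks: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Peaks with >= 1 bp overlap with any association interval, each
    annotated with the best (highest) overlapping association score."""
    out = []
    for peak in sort_intervals(peaks):
        scores = [
            iv.score
            for iv in assoc
            if peak.overlaps(iv) and iv.score is not None
        ]
        hit = any(peak.overlaps(iv) for iv in assoc)
        if hit:
            out.append(
                GenomicInterval(
                    peak.scaffold,
                    peak.start,
                    peak.end,
                    max(scores) if scores else peak.score,
                )
            )
    return out
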