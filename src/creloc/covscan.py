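"""Windowed, normalized read-depth profiling and phenotype-concordant
coverage-drop detection.

Per-base depth tracks (pre-filtered upstream, e.g. at mapping quality 30)
are reduced to window medians (50 bp tiles by default), normalized by each
individual's scaffold-wide mean depth, and averaged per group.  A drop call
is a run of windows in which one set of groups sits at low normalized depth
while every other group stays near 1; the call is flagged concordant when
the low set coincides exactly with one phenotype class — the signature of a
structural variant explained by phenotype rather than geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval


@dataclass
class DepthProfile:
    """Per-base depth for one individual on one scaffold."""

    sample_id: str
    scaffold: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValueError("depth must be a nonempty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("depths must be nonnegative")

    @property
    def scaffold_mean(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class CovScanParams:
    window_bp: int = 50
    mapq_note: int = 30  # provenance only: depth tracks arrive pre-filtered
    carrier_max: float = 0.75
    control_min: float = 0.90
    min_windows: int = 3

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not 0 <= self.carrier_max < self.control_min:
            raise ValueError("need 0 <= carrier_max < control_min")


@dataclass
class GroupProfile:
    """Mean of normalized window medians across a group's individuals."""

    group: str
    values: np.ndarray
    windows: list[tuple[int, int]]


@dataclass
class DropCall:
    interval: GenomicInterval
    group_means: dict[str, float]
    carrier_groups: frozenset[str]
    concordant: bool
    contrast: float  # min control mean - max carrier mean inside the call


def window_tiling(length: int, window_bp: int = 50) -> list[tuple[int, int]]:
    """Non-overlapping tiling; a trailing partial window is kept iff it
    covers at least half a window."""
    tiles = []
    start = 0
    while start + window_bp <= length:
        tiles.append((start, start + window_bp))
        start += window_bp
    if length - start >= window_bp / 2 and length > start:
        tiles.append((start, length))
    return tiles


def window_medians(
    profile: DepthProfile, window_bp: int = 50
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Median depth per tile (even counts: mean of the two central values)."""
    if len(profile.depth) < window_bp:
        raise ValueError("profile shorter than one window")
    tiles = window_tiling(len(profile.depth), window_bp)
    medians = np.array([np.median(profile.depth[s:e]) for s, e in tiles])
    return medians, tiles


def normalize(medians: np.ndarray, scaffold_mean: float) -> np.ndarray:
    """Divide window medians by the individual's scaffold-wide mean depth."""
    if scaffold_mean <= 0:
        raise ValueError("scaffold mean depth must be > 0")
    return np.asarray(medians, dtype=float) / scaffold_mean


def normalized_profile(
    profile: DepthProfile, window_bp: int = 50
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    medians, tiles = window_medians(profile, window_bp)
    return normalize(medians, profile.scaffold_mean), tiles


def group_mean(
    normalized: dict[str, np.ndarray],
    group_of: dict[str, str],
    windows: list[tuple[int, int]],
) -> list[GroupProfile]:
    """Arithmetic mean of normalized window medians per group."""
    lengths = {len(v) for v in normalized.values()}
    if len(lengths) != 1 or lengths.pop() != len(windows):
        raise ValueError("profiles are not on identical windows")
    by_group: dict[str, list[np.ndarray]] = {}
    for sample, values in normalized.items():
        by_group.setdefault(group_of[sample], []).append(values)
    return [
        GroupProfile(g, np.mean(vals, axis=0), windows)
        for g, vals in sorted(by_group.items())
    ]


def detect_drops(
    group_profiles: list[GroupProfile],
    phenotype_of_group: dict[str, str],
    params: CovScanParams | None = None,
    scaffold: str = "scaffold",
) -> list[DropCall]:
    """Coverage-drop calls from group profiles.

    A window is a candidate when the groups split cleanly: a nonempty proper
    subset sits at mean <= ``carrier_max`` while every remaining group sits
    at mean >= ``control_min``.  Maximal runs of >= ``min_windows`` candidate
    windows sharing the same carrier set become calls; a call is concordant
    iff its carrier set equals one phenotype class exactly.
    """
    if params is None:
        params = CovScanParams()
    if not group_profiles:
        return []
    windows = group_profiles[0].windows
    for gp in group_profiles:
        if gp.windows != windows:
            raise ValueError("group profiles are on mismatched windows")
    groups = [gp.group for gp in group_profiles]
    values = np.vstack([gp.values for gp in group_profiles])
    phenotype_classes = {
        frozenset(g for g in groups if phenotype_of_group[g] == ph)
        for ph in set(phenotype_of_group[g] for g in groups)
    }

    n_win = values.shape[1]
    carrier_sets: list[frozenset[str] | None] = []
    for j in range(n_win):
        low = frozenset(
            g for i, g in enumerate(groups) if values[i, j] <= params.carrier_max
        )
        high = {
            g for i, g in enumerate(groups) if values[i, j] >= params.control_min
        }
        if low and len(low) < len(groups) and low | high == set(groups):
            carrier_sets.append(low)
        else:
            carrier_sets.append(None)

    calls: list[DropCall] = []
    j = 0
    while j < n_win:
        cset = carrier_sets[j]
        if cset is None:
            j += 1
            continue
        k = j
        while k < n_win and carrier_sets[k] == cset:
            k += 1
        if k - j >= params.min_windows:
            start_bp = windows[j][0]
            end_bp = windows[k - 1][1]
            means = {
                g: float(values[i, j:k].mean()) for i, g in enumerate(groups)
            }
            carriers = cset
            controls = set(groups) - carriers
            contrast = min(means[g] for g in controls) - max(
                means[g] for g in carriers
            )
            calls.append(
                DropCall(
                    GenomicInterval(scaffold, start_bp, end_bp, contrast),
                    means,
                    carriers,
                    carriers in phenotype_classes,
                    contrast,
                )
            )
        j = k
    return calls
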