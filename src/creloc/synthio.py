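"""Truth-tagged synthetic inputs for every analysis stage.

Each generator emulates the statistical structure one downstream detector
assumes, and records the planted features in a :class:`SimTruth` so
recovery can be checked without external data:

* haplotypes — multi-population alignments in which sites inside an
  association block evolve down a *phenotype* group tree while the
  background evolves down a *species* tree (fixed trees, not a coalescent:
  the analysis consumes only topologies, and fixed trees make truth exact);
* depth — negative-binomial per-base depth with a multiplicative drop over
  an insertion footprint in carrier individuals;
* contacts — Poisson counts with power-law distance decay plus planted
  enriched loops;
* track — boxcar accessibility peaks on a noisy background;
* insertion pair — a random sequence and a copy with planted insertions;
* trace — a noisy sinusoid with a known spatial period.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .covscan import DepthProfile
from .hic4c import ContactMatrix
from .intervals import GenomicInterval
from .peaks import CoverageTrack
from .ridges import IntensityTrace
from .topoweight import MISSING, HaplotypeMatrix
from .topology import tree_from_newick

# Fixed group-tree branch lengths (substitution-rate units, scaled by theta).
# Internal branches dominate pendant ones so that each 50-SNP window carries
# an unambiguous topology signal well below substitution saturation.
T_INTERNAL = 1.0
T_GROUP = 0.2
T_INDIVIDUAL = 0.02


@dataclass
class SimTruth:
    """Ground truth planted by a generator (what nature provides the study)."""

    seed: int | None = None
    association_interval: GenomicInterval | None = None
    concordant_topology: str | None = None
    species_topology: str | None = None
    insertion_site: int | None = None
    insertion_length: int | None = None
    carrier_ids: list[str] = field(default_factory=list)
    loop_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    peak_intervals: list[GenomicInterval] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    ridge_period: float | None = None

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, GenomicInterval):
                return {
                    "scaffold": obj.scaffold,
                    "start": obj.start,
                    "end": obj.end,
                    "score": obj.score,
                }
            raise TypeError(type(obj))

        return json.dumps(asdict(self), default=default, indent=2)


def _group_labels(n_groups: int) -> list[str]:
    if n_groups > 26:
        raise ValueError("at most 26 groups supported")
    return [chr(ord("A") + i) for i in range(n_groups)]


def _caterpillar_newick(order: list[str]) -> str:
    out = f"({order[0]},{order[1]})"
    for label in order[2:]:
        out = f"({out},{label})"
    return out + ";"


def _phenotype_order(groups: list[str]) -> list[str]:
    # swap the 2nd and 3rd clades so the phenotype partition crosses the
    # species partition (A with C instead of A with B)
    order = list(groups)
    if len(order) >= 3:
        order[1], order[2] = order[2], order[1]
    return order


def phenotype_of_groups(groups: list[str]) -> dict[str, str]:
    """The phenotype labelling implied by the phenotype tree: the first
    clade of the phenotype caterpillar carries the trait."""
    order = _phenotype_order(groups)
    carriers = set(order[:2])
    return {g: ("yellow" if g in carriers else "melanic") for g in groups}


def _mutate(states: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric substitution: with probability p, jump to one of the other
    three nucleotides uniformly."""
    out = states.copy()
    hit = rng.random(len(states)) < p
    if np.any(hit):
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _evolve_sites(
    order: list[str],
    n_per_group: int,
    n_sites: int,
    theta: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve ``n_sites`` independent sites down a caterpillar group tree,
    then hang ``n_per_group`` individuals off each group node.  Returns
    per-sample allele arrays keyed by sample id '<group>_<k>'."""

    def p_sub(branch: float) -> float:
        return 0.75 * (1.0 - np.exp(-theta * branch))

    root = rng.integers(0, 4, size=n_sites).astype(np.int8)
    # walk down the caterpillar spine: at each step one group splits off
    group_states: dict[str, np.ndarray] = {}
    spine = root
    remaining = list(order)
    while len(remaining) > 2:
        label = remaining.pop()  # last-joined clade splits off first
        group_states[label] = _mutate(spine, p_sub(T_GROUP), rng)
        spine = _mutate(spine, p_sub(T_INTERNAL), rng)
    for label in remaining:
        group_states[label] = _mutate(spine, p_sub(T_GROUP), rng)

    samples: dict[str, np.ndarray] = {}
    for label in order:
        for k in range(n_per_group):
            samples[f"{label}_{k}"] = _mutate(
                group_states[label], p_sub(T_INDIVIDUAL), rng
            )
    return samples


def sim_haplotypes(
    n_groups: int = 4,
    n_per_group: int = 4,
    n_sites: int = 2000,
    block: GenomicInterval | None = GenomicInterval("sim", 800, 1200),
    theta_bg: float = 1.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[HaplotypeMatrix, SimTruth]:
    """Haplotype matrix with a phenotype-concordant genealogy inside
    ``block`` (site-index units) and a species-concordant background.

    ``block=None`` is the null simulation (background everywhere).
    """
    if n_groups < 3:
        raise ValueError("need at least 3 groups")
    if n_per_group < 1:
        raise ValueError("need at least 1 sample per group")
    if block is not None and not (0 <= block.start < block.end <= n_sites):
        raise ValueError("block outside the simulated site range")
    groups = _group_labels(n_groups)
    rng = np.random.default_rng(seed)

    species_order = groups
    phenotype_order = _phenotype_order(groups)
    bg = _evolve_sites(species_order, n_per_group, n_sites, theta_bg, rng)
    sample_ids = sorted(bg)
    alleles = np.vstack([bg[s] for s in sample_ids])
    if block is not None:
        fg = _evolve_sites(
            phenotype_order, n_per_group, len(block), theta_bg, rng
        )
        alleles[:, block.start : block.end] = np.vstack(
            [fg[s] for s in sample_ids]
        )
    if missing_rate > 0:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = MISSING

    group_of = {s: s.split("_")[0] for s in sample_ids}
    matrix = HaplotypeMatrix(
        sample_ids, group_of, np.arange(n_sites), alleles, scaffold="sim"
    )
    truth = SimTruth(
        seed=seed,
        association_interval=block,
        concordant_topology=tree_from_newick(
            _caterpillar_newick(phenotype_order)
        ).canonical_id(),
        species_topology=tree_from_newick(
            _caterpillar_newick(species_order)
        ).canonical_id(),
    )
    return matrix, truth


def _nb_counts(
    mean: np.ndarray | float,
    dispersion: float | None,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and shape ``dispersion``
    (variance mean + mean^2/dispersion); Poisson when dispersion is None."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if dispersion is None:
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(float)


def sim_depth(
    n_individuals: int = 20,
    length: int = 10_000,
    mean_depth: float = 30.0,
    carriers: list[str] | tuple[str, ...] = (),
    site: int = 5000,
    footprint: int = 300,
    drop_frac: float = 0.4,
    dispersion: float | None = 10.0,
    seed: int | None = None,
    scaffold: str = "scaffold",
) -> tuple[list[DepthProfile], SimTruth]:
    """Per-base depth profiles; carriers have their mean multiplied by
    ``drop_frac`` over ``[site, site + footprint)``.

    Sample ids are 'ind00', 'ind01', ...; ``carriers`` must be a subset.
    """
    if not 0 <= drop_frac < 1:
        raise ValueError("need 0 <= drop_frac < 1")
    if footprint <= 0:
        raise ValueError("footprint must be positive")
    if site + footprint > length:
        raise ValueError("footprint extends past the simulated scaffold")
    ids = [f"ind{i:02d}" for i in range(n_individuals)]
    unknown = set(carriers) - set(ids)
    if unknown:
        raise ValueError(f"unknown carrier ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    profiles = []
    for sid in ids:
        mean = np.full(length, mean_depth)
        if sid in carriers:
            mean[site : site + footprint] *= drop_frac
        profiles.append(
            DepthProfile(sid, scaffold, _nb_counts(mean, dispersion, length, rng))
        )
    truth = SimTruth(
        seed=seed,
        insertion_site=site,
        insertion_length=footprint,
        carrier_ids=list(carriers),
        association_interval=GenomicInterval(scaffold, site, site + footprint),
    )
    return profiles, truth


def sim_contacts(
    n_bins: int = 200,
    bin_size: int = 5000,
    scale: float = 100.0,
    alpha: float = 1.0,
    loops: list[tuple[int, int, float]] | tuple = (),
    seed: int | None = None,
    scaffold: str = "scaffold",
) -> tuple[ContactMatrix, SimTruth]:
    """Symmetric Poisson contact matrix with mean ``scale * |i-j|^-alpha``
    off the diagonal, multiplied by each planted loop's enrichment factor."""
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    for i, j, factor in loops:
        if not (0 <= i < n_bins and 0 <= j < n_bins and i != j):
            raise ValueError(f"loop bins ({i}, {j}) out of range")
        if factor <= 1:
            raise ValueError("loop enrichment factor must exceed 1")
    rng = np.random.default_rng(seed)
    i_idx, j_idx = np.triu_indices(n_bins, k=1)
    mean = scale * (j_idx - i_idx).astype(float) ** (-alpha)
    for i, j, factor in loops:
        a, b = min(i, j), max(i, j)
        mean[(i_idx == a) & (j_idx == b)] *= factor
    upper = rng.poisson(mean)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    counts[i_idx, j_idx] = upper
    counts[j_idx, i_idx] = upper
    truth = SimTruth(seed=seed, loop_pairs=[tuple(l) for l in loops])
    return ContactMatrix(scaffold, bin_size, counts), truth


def sim_track(
    length: int = 20_000,
    background: float = 10.0,
    peaks: list[tuple[GenomicInterval, float]] | tuple = (),
    noise: str = "nb",
    dispersion: float = 10.0,
    seed: int | None = None,
    scaffold: str = "scaffold",
) -> tuple[CoverageTrack, SimTruth]:
    """Coverage track: boxcar peaks of given heights on a noisy background.

    ``noise``: 'nb' (negative binomial, default), 'poisson', or 'none'.
    """
    mean = np.full(length, background, dtype=float)
    for interval, height in peaks:
        if interval.end > length:
            raise ValueError("peak interval outside the track")
        mean[interval.start : interval.end] += height
    rng = np.random.default_rng(seed)
    if noise == "none":
        values = mean
    elif noise == "poisson":
        values = _nb_counts(mean, None, length, rng)
    elif noise == "nb":
        values = _nb_counts(mean, dispersion, length, rng)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    truth = SimTruth(
        seed=seed, peak_intervals=[interval for interval, _ in peaks]
    )
    return CoverageTrack(scaffold, values), truth


def sim_insertion_pair(
    base_len: int = 2000,
    insertions: list[tuple[int, int]] | tuple = ((700, 690), (1500, 163)),
    seed: int | None = None,
) -> tuple[str, str, SimTruth]:
    """A random sequence A and a copy B carrying planted insertions.

    ``insertions`` are (position on A, length) pairs; the default plants the
    two-element structure (a large ~690 bp element and a small ~163 bp one)
    typical of a TE-interrupted CRE haplotype.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq_a = "".join(rng.choice(bases, size=base_len))
    ins = sorted(insertions)
    for pos, ln in ins:
        if not 0 <= pos <= base_len:
            raise ValueError(f"insertion position {pos} outside sequence A")
        if ln < 1:
            raise ValueError("insertion length must be >= 1")
    parts = []
    recorded = []
    prev = 0
    for pos, ln in ins:
        insert = "".join(rng.choice(bases, size=ln))
        parts.append(seq_a[prev:pos])
        parts.append(insert)
        prev = pos
        # an insertion is only defined up to rotation against its flank;
        # record the canonical left-aligned position (the aligner's rule)
        canon_pos, canon_ins = pos, insert
        while canon_pos > 0 and seq_a[canon_pos - 1] == canon_ins[-1]:
            canon_ins = seq_a[canon_pos - 1] + canon_ins[:-1]
            canon_pos -= 1
        recorded.append((canon_pos, ln))
    parts.append(seq_a[prev:])
    seq_b = "".join(parts)
    truth = SimTruth(seed=seed, insertions=recorded)
    return seq_a, seq_b, truth


def sim_trace(
    period: float = 0.6,
    pixel: float = 0.01,
    n_px: int = 4096,
    noise_sd: float = 0.1,
    amplitude: float = 1.0,
    components: list[tuple[float, float]] | tuple = (),
    seed: int | None = None,
) -> tuple[IntensityTrace, SimTruth]:
    """Sinusoidal intensity trace of spatial ``period`` (µm) plus Gaussian
    noise; ``components`` adds further (period, amplitude) sinusoids."""
    if period <= 0 or pixel <= 0:
        raise ValueError("period and pixel must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(n_px) * pixel
    values = amplitude * np.sin(2 * np.pi * x / period)
    for extra_period, extra_amp in components:
        values = values + extra_amp * np.sin(2 * np.pi * x / extra_period)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_px)
    truth = SimTruth(seed=seed, ridge_period=period)
    return IntensityTrace(values, pixel), truth
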