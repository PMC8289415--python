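"""End-to-end synthetic locus: plant one CRE, run all evidence tiers.

This is the integration path the package exists for, on generated data: a
phenotype-association block localised by topology weighting, an
accessibility peak inside it, a phenotype-concordant coverage drop over
the peak, and a chromatin loop from the peak to a promoter bin.  A
candidate CRE passes when it is (1) an accessibility peak overlapping a
high-weight association interval, (2) overlapped by a concordant coverage
drop, and (3) significantly enriched for promoter contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import covscan, hic4c, peaks, synthio, topoweight
from .intervals import GenomicInterval

#: bp between consecutive SNPs when projecting site indices onto the locus
SNP_SPACING = 10


@dataclass
class LocusResult:
    truth_cre: GenomicInterval
    association_intervals: list[GenomicInterval]
    called_peaks: list[GenomicInterval]
    nominated: list[GenomicInterval]
    drop_calls: list[covscan.DropCall]
    contact_tests: dict[tuple[int, int], hic4c.ContactTest]
    passing: list[GenomicInterval] = field(default_factory=list)


def run_synthetic_locus(
    seed: int,
    locus_bp: int = 20_000,
    block_sites: tuple[int, int] = (800, 1200),
    cre_bp: tuple[int, int] = (9_000, 9_300),
    decoy_bp: tuple[int, int] = (2_000, 2_300),
    promoter_bp: tuple[int, int] = (15_000, 15_100),
    peak_height: float = 40.0,
    drop_frac: float = 0.4,
    loop_factor: float = 10.0,
    contact_scale: float = 1000.0,
    alpha: float = 0.05,
    null: bool = False,
) -> LocusResult:
    """Simulate one locus and run the three-tier CRE localisation.

    With ``null=True`` nothing is planted (no block, no peaks, no
    carriers, no loop): the detectors should report nothing.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    scaffold = "locus"
    cre = GenomicInterval(scaffold, *cre_bp)
    decoy = GenomicInterval(scaffold, *decoy_bp)
    promoter = GenomicInterval(scaffold, *promoter_bp)

    # tier 1: association from topology weighting (site index -> bp)
    block = None if null else GenomicInterval("sim", *block_sites)
    matrix, hap_truth = synthio.sim_haplotypes(block=block, seed=int(seeds[0]))
    matrix = topoweight.HaplotypeMatrix(
        matrix.sample_ids,
        matrix.group_of,
        matrix.positions * SNP_SPACING,
        matrix.alleles,
        scaffold,
    )
    profile = topoweight.weighting_profile(matrix)
    assoc = topoweight.high_weight_intervals(
        profile, hap_truth.concordant_topology
    )

    # accessibility track and peak calling
    planted_peaks = [] if null else [(cre, peak_height), (decoy, peak_height)]
    track, _ = synthio.sim_track(
        locus_bp, peaks=planted_peaks, seed=int(seeds[1]), scaffold=scaffold
    )
    called = peaks.call_peaks(track)
    nominated = peaks.nominate_cres(assoc, called)

    # tier 2: phenotype-concordant coverage drop
    groups = ["A", "B", "C", "D"]
    ids = [f"ind{i:02d}" for i in range(20)]
    group_of = {s: groups[i % 4] for i, s in enumerate(ids)}
    phenotype = synthio.phenotype_of_groups(groups)
    carriers = (
        []
        if null
        else [s for s in ids if phenotype[group_of[s]] == "yellow"]
    )
    profiles, _ = synthio.sim_depth(
        n_individuals=20,
        length=locus_bp,
        carriers=carriers,
        site=cre.start,
        footprint=len(cre),
        drop_frac=drop_frac,
        seed=int(seeds[2]),
        scaffold=scaffold,
    )
    tiles = None
    norm = {}
    for p in profiles:
        values, tiles = covscan.normalized_profile(p)
        norm[p.sample_id] = values
    drops = covscan.detect_drops(
        covscan.group_mean(norm, group_of, tiles), phenotype, scaffold=scaffold
    )

    # tier 3: promoter contact enrichment
    bin_size = 100
    n_bins = locus_bp // bin_size
    # contact depth chosen so the background at the CRE-promoter distance
    # is non-sparse (~17 counts/pair), the regime Fisher testing needs
    contact_matrix, _ = synthio.sim_contacts(
        n_bins=n_bins,
        bin_size=bin_size,
        scale=contact_scale,
        loops=(
            []
            if null
            else [
                (
                    ((cre.start + cre.end) // 2) // bin_size,
                    ((promoter.start + promoter.end) // 2) // bin_size,
                    loop_factor,
                )
            ]
        ),
        seed=int(seeds[3]),
        scaffold=scaffold,
    )
    model = hic4c.expected_by_distance(contact_matrix)
    tests = {}
    passing = []
    for cand in nominated:
        t = hic4c.test_cre_promoter(contact_matrix, cand, promoter, model=model)
        tests[(t.anchor, t.target)] = t
        concordant_drop = any(
            d.concordant and d.interval.overlaps(cand) for d in drops
        )
        if concordant_drop and t.p_value < alpha:
            passing.append(cand)

    return LocusResult(cre, assoc, called, nominated, drops, tests, passing)
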