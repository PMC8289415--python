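# Methods

This note documents the models implemented in `creloc`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Topology weighting (`topoweight`)

**Model.** Haplotypes are scanned in windows of a fixed number of SNPs
(`size_snps=50`, `step_snps=20`). Trailing SNPs beyond the last full
window are unused. A window enters the analysis only if at least
`min_sites=10` of its sites have, in *every* group, at least
`min_genotyped_frac=0.5` of samples non-missing. Each passing window is
turned into an unrooted tree and reduced to a weighting over all
unrooted group topologies — there are (2G−5)!! of them for G groups
(1, 3, 15, 105 for G = 3..6) — by counting, over one-tip-per-group
subsamples, which topology the induced subtree realises. `weight_exact`
enumerates all combinations (capped at 10⁶); `weight_mc` draws
`n_iter=1000` uniform independent subsamples. Weights are nonnegative
and sum to 1 exactly (count ratios).

**Tree building.** Window trees are neighbor-joining trees on
normalized Hamming distances with pairwise deletion of missing data (a
pair sharing no genotyped site is an error, not distance 0). NJ was
chosen over maximum likelihood deliberately: only the topology enters
the weighting, NJ is exact on additive matrices, dependency-free and
fast enough for hundred-window scans, and made deterministic by a tie
rule — equal Q criteria are resolved toward the lexicographically
smallest pair of representative leaf labels, and negative branch-length
estimates are clamped to zero without affecting topology. The induced
topology of a subsample is reconstructed from topological (unit-branch)
leaf distances: for four groups by the four-point condition (the true
split's distance sum is strictly smallest on a binary tree), for more
groups by NJ on the restricted distance matrix, which is exact because
those distances are additive on the induced subtree.

**Canonical topology identifiers** are sorted newick normal forms: root
at the smallest leaf label, sort children recursively by smallest
contained label. Identical shapes map to identical strings regardless of
input rotation.

**Association intervals.** `high_weight_intervals` reports maximal runs
of at least `min_windows=2` consecutive passing windows whose weight for
the hypothesis topology is ≥ `threshold=0.75`, merged in bp space and
scored by the run's mean weight. Threshold and run length are free
parameters — there is no published numeric criterion for what counts as
a "strong" association signal — and the defaults are validated only
against the synthetic benchmarks below.

## Coverage-drop scan (`covscan`)

Per-base depth (assumed pre-filtered upstream, e.g. at mapping quality
30 — recorded as `mapq_note` for provenance, never parsed here) is
tiled into non-overlapping 50 bp windows; a trailing partial window is
kept iff it covers at least half a window. Window summaries are medians
(even counts: mean of the two central values), divided by the
individual's scaffold-wide mean depth, then averaged per group. This
makes the scan invariant to each individual's sequencing depth.

A window is a drop candidate when the groups split cleanly: some
nonempty proper subset has mean ≤ `carrier_max=0.75` while every other
group has mean ≥ `control_min=0.90`; windows where any group sits in
the intermediate zone are not candidates. Runs of ≥ `min_windows=3`
candidates sharing one carrier set become calls, flagged *concordant*
iff the carrier set coincides exactly with a phenotype class. The three
thresholds are invented (the original identification of such drops is
visual); they are exposed, documented, and validated against simulation
only. The scan is symmetric: it does not matter which phenotype is
labelled carrier.

## Virtual 4C and contact enrichment (`hic4c`)

The background model is empirical: for each bin separation d ≥ 1, the
mean, median, total and pair count of contacts over all pairs at that
distance (d = 0 never enters). A pair (anchor, target) at distance d
with observed count o is tested with a two-sided Fisher's exact test on

    [[o, T − o], [e, T − e]],   e = round(mean at d),  T = total at d.

This table was chosen because it literally encodes "observed contacts
relative to those expected from the background"; it is one of several
defensible constructions (an alternative would pool all distances). Two
properties follow and are documented rather than hidden:

* the per-distance reading is implemented; the pooled alternative is
  not (no published detail selects between them);
* the test is **conservative**: Fisher's null treats both rows as
  random (variance of o − e about 2e), while under a distance-decay
  null only o varies (variance e), so the empirical type-I error at
  α = 0.05 is well below 0.05 (measured ≈ 0.000–0.007 over 1000 pairs).
  Enrichment calls are therefore trustworthy but the test needs a
  non-sparse background (rough guide: e of order 10 or more at the
  focal distance) to have power; the odds ratio (with Haldane 0.5
  correction on zero cells) and the per-distance median are reported
  alongside for diagnostics.

Feature intervals in bp map to the bin containing their midpoint (the
"window centred on the feature" rule).

## Peak calling and CRE nomination (`peaks`)

The caller is intentionally minimal and fully parameterised: centred
moving average (`smooth_bp=75`), global threshold mean + k·max(σ,
`sigma_floor=1`) with `k_sigma=3`, maximal super-threshold runs of at
least `min_width_bp=100`, merged across gaps ≤ `merge_gap_bp=50`. The
σ floor keeps constant tracks peak-free. A global threshold assumes
peaks occupy a small fraction of the track; tracks dominated by signal
would need a local background model, which is out of scope. Candidate
CREs are peaks overlapping (≥ 1 bp) any association interval, annotated
with the best overlapping association score. All intervals are 0-based
half-open BED throughout.

## Alignment and indel calling (`alnte`)

Global pairwise alignment under affine gap costs, scored as match +1,
mismatch −1, and gap of length L costing open + L·extend with open −5
and extend −1 (stated explicitly because the other convention — open
charged on the first base — also exists; the dynamic programme is
configured to match this one). N is mismatch-neutral (score 0 against
anything). The three-state dynamic programme is Biopython's
`PairwiseAligner`; this module pins the scoring convention and makes
indel placement reproducible by left-aligning every maximal gap run
(shifted to the smallest sequence-A coordinate among equal-scoring
placements). Indel calls report maximal gap runs with A coordinates; an
insertion adjacent to sequence that matches its own boundary is only
defined up to rotation, so the left-aligned representative is the
canonical position on both the generator and caller side. Windowed
identity counts gap columns as mismatches. Quadratic time and memory
are accepted: the intended inputs are Sanger-scale consensi (1–3 kb).

## Ridge spacing (`ridges`)

Traces are linearly detrended, tapered with a Hann window, Fourier
transformed; the spacing is 1/f\* for the strongest frequency inside
the band (default 0.1–5 µm, bracketing crossrib ≈ 0.6 µm and microrib
≈ 0.2 µm structures; the band minimum must respect Nyquist,
min_spacing ≥ 2·pixel). The peak is refined by quadratic interpolation
over the three surrounding bins (offset clamped to ±½ bin). Detrend,
taper and interpolation are standard spectral practice, not taken from
any published setting. Flat traces (no band power above a numerical
floor) raise an error; batch summaries exclude and count them.
Simulations show recovery within 2% down to SNR ≈ 3 given ≥ 10 periods
per trace.

## Synthetic data (`synthio`)

Each generator emulates exactly the structure its downstream detector
assumes; fixed seeds give bit-identical outputs, and every planted
feature is recorded in a `SimTruth`.

* **Haplotypes** evolve i.i.d. sites down *fixed* group trees
  (caterpillar topologies), not a coalescent: the analysis consumes
  only topologies, and fixed trees make the ground truth exact. Sites
  inside the association block use a phenotype-ordered caterpillar
  (first and third group clades together), the background the species
  order. Branch lengths (internal 1.0, group pendant 0.2, individual
  0.02, scaled by `theta_bg=1.0`, Jukes–Cantor-style symmetric
  substitution) were set so that a 50-SNP window carries an unambiguous
  topology signal well below substitution saturation and comfortably
  more than 10 segregating sites; within-group diversity is kept low so
  groups are near-monophyletic per window. Missingness is injected
  uniformly at `missing_rate=0` by default.
* **Depth** is negative-binomial per base (mean 30, dispersion 10 —
  variance mean + mean²/dispersion; Poisson in the dispersion→∞ limit)
  over 10 kb for 20 individuals; carriers have the mean multiplied by
  `drop_frac=0.4` over a 300 bp footprint. No breakpoint/soft-clip
  structure is modelled — depth is the only signal, as in the scan.
* **Contacts** are independent Poisson counts with mean
  scale·|i−j|^−α (scale 100, α 1, 5 kb bins), symmetrised, with planted
  loop pairs multiplied by an enrichment factor > 1.
* **Tracks** are boxcar peaks on a negative-binomial background;
  **sequence pairs** plant random-content insertions into a random
  sequence (truth stores left-aligned positions); **traces** are
  sinusoids plus Gaussian noise.

What passing the synthetic benchmarks does *not* show: robustness to
recombination and incomplete lineage sorting within windows (fixed
trees have neither), to mapping artefacts and GC-dependent depth bias,
to Hi-C matrix non-independence (real counts are not independent
Poisson draws), to replicate structure in accessibility data, or to
repeat-induced alignment ambiguity. Those belong to the upstream tools
this package deliberately consumes outputs from.

## The end-to-end locus (`pipeline`)

`run_synthetic_locus` plants one CRE on a 20 kb locus: an association
block at sites 800–1200 (SNPs spaced 10 bp, so bp 8000–12000), an
accessibility peak at 9000–9300 plus a decoy peak outside the block, a
40% carrier coverage drop over the peak, and a 10× contact loop from
the peak's bin to a promoter bin (100 bp bins). A candidate passes when
it is a nominated peak (tier 1), overlapped by a concordant drop (tier
2), and significantly enriched for promoter contact at α = 0.05 (tier
3). The contact matrix is simulated at scale 1000 so the background at
the CRE–promoter distance is ≈ 17 counts per pair: enrichment testing
with the conservative Fisher construction needs a non-sparse expected
count, and binned Hi-C at the distances being tested is not
count-starved in practice.

## Problem sizes and determinism

Recovery and false-positive rates are computed over 100 seeds per
condition (association, coverage, loop, end-to-end), 1000 pairs for the
type-I measurement, 100–200 random pairs for alignment optimality, and
10–20 traces per scale type for batch spacing — sizes at which each
rate's sampling error is a few percent and a full run of
`scripts/acceptance.py` takes about a minute. All randomness flows from
one master seed through named substreams, so identical seeds reproduce
identical JSON output.

## Known limitations

* Topology weighting assumes phased haplotypes; unphased heterozygotes
  from VCF are randomly phased under the run seed, which is adequate
  for weighting but not for haplotype-scale inference.
* The coverage scan cannot distinguish insertions from deletions (both
  depress mapped depth); resolving them requires sequence-level
  evidence, which is what the alignment module provides.
* The Fisher contact test's conservatism (above) means borderline
  loops in sparse matrices will be missed; calibrated alternatives
  (e.g. a Poisson test against the fitted expectation) would trade the
  exactness of the stated construction for power.
* The peak caller has no replicate or local-background model.
* Ridge-spacing estimation assumes a dominant stationary period per
  trace; strongly chirped or mixed traces return only the dominant
  component.
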