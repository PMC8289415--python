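"""Readers and writers for the plain-text formats the pipeline consumes.

Haplotypes travel as a TSV (rows = samples, columns = site positions) or a
phased biallelic VCF (split into two pseudo-haplotypes per sample;
unphased heterozygotes are resolved by seeded random assignment).  Depth
and coverage tracks are bedGraph; contact matrices are sparse
upper-triangle TSV triplets with a small header; sequences are FASTA;
intensity traces are CSV (long format with a trace_id column, or one
column per file).  All interval output is BED, 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .covscan import DepthProfile
from .hic4c import ContactMatrix
from .intervals import GenomicInterval
from .peaks import CoverageTrack
from .ridges import IntensityTrace
from .topoweight import _CODE_ALLELE, _ALLELE_CODE, HaplotypeMatrix, WeightingProfile


# -- haplotypes -------------------------------------------------------------


def write_haplotype_tsv(matrix: HaplotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, matrix.positions)) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            row = "".join(_CODE_ALLELE[int(a)] for a in matrix.alleles[i])
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def read_haplotype_tsv(
    path: str | Path, group_of: dict[str, str], scaffold: str = "sim"
) -> HaplotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        positions = [int(p) for p in header[1:]]
        sample_ids, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            sample_ids.append(fields[0])
            rows.append("".join(fields[1:]))
    return HaplotypeMatrix.from_strings(
        sample_ids, group_of, positions, rows, scaffold
    )


def read_groups_tsv(
    path: str | Path,
) -> tuple[dict[str, str], dict[str, str]]:
    """Sample metadata TSV: sample_id <tab> group [<tab> phenotype].

    Returns (group_of_sample, phenotype_of_group)."""
    group_of: dict[str, str] = {}
    phenotype_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            group_of[fields[0]] = fields[1]
            if len(fields) > 2:
                phenotype_of[fields[1]] = fields[2]
    return group_of, phenotype_of


def read_vcf(
    path: str | Path,
    group_of_sample: dict[str, str],
    seed: int | None = None,
    scaffold: str | None = None,
) -> HaplotypeMatrix:
    """Biallelic SNPs from a VCF as two pseudo-haplotypes per sample.

    Phased genotypes keep their phase; unphased heterozygotes are assigned
    to haplotypes uniformly at random under ``seed``.  Non-SNP and
    multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    rng = np.random.default_rng(seed)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom = None
    for var in vcf:
        if scaffold is not None and var.CHROM != scaffold:
            continue
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            continue
        ref_code = _ALLELE_CODE[var.REF.upper()]
        alt_code = _ALLELE_CODE[var.ALT[0].upper()]
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], bool(gt[2])
            if not phased and {a, b} == {0, 1} and rng.random() < 0.5:
                a, b = b, a
            for k, allele in enumerate((a, b)):
                if allele < 0:
                    col[2 * i + k] = _ALLELE_CODE["N"]
                else:
                    col[2 * i + k] = alt_code if allele else ref_code
        positions.append(var.POS - 1)  # to 0-based
        columns.append(col)
    if not positions:
        raise ValueError("no biallelic SNPs found in VCF")
    sample_ids = [f"{s}_{k}" for s in samples for k in (0, 1)]
    group_of = {
        f"{s}_{k}": group_of_sample[s] for s in samples for k in (0, 1)
    }
    alleles = np.column_stack(columns)
    return HaplotypeMatrix(
        sample_ids, group_of, np.asarray(positions), alleles, chrom or "vcf"
    )


# -- bedGraph / depth tracks ------------------------------------------------


def write_bedgraph(
    scaffold: str, values: np.ndarray, path: str | Path
) -> None:
    """Per-base values as run-length-compressed bedGraph."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start]:
                fh.write(f"{scaffold}\t{start}\t{i}\t{values[start]:g}\n")
                start = i


def read_bedgraph(path: str | Path) -> tuple[str, np.ndarray]:
    """bedGraph (or 3-column pos0/pos1/value TSV) to a per-base array."""
    rows = []
    scaffold = "track"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) == 4:
                scaffold = fields[0]
                rows.append((int(fields[1]), int(fields[2]), float(fields[3])))
            else:
                rows.append((int(fields[0]), int(fields[1]), float(fields[2])))
    if not rows:
        raise ValueError(f"empty track file: {path}")
    length = max(e for _, e, _ in rows)
    values = np.zeros(length)
    for s, e, v in rows:
        values[s:e] = v
    return scaffold, values


def read_depth_profile(path: str | Path, sample_id: str) -> DepthProfile:
    scaffold, values = read_bedgraph(path)
    return DepthProfile(sample_id, scaffold, values)


def read_coverage_track(path: str | Path) -> CoverageTrack:
    scaffold, values = read_bedgraph(path)
    return CoverageTrack(scaffold, values)


# -- contact matrices -------------------------------------------------------


def write_contact_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#scaffold={matrix.scaffold}\tbin_size={matrix.bin_size}"
            f"\tn_bins={matrix.n_bins}\n"
        )
        fh.write("bin_i\tbin_j\tcount\n")
        for i in range(matrix.n_bins):
            for j in range(i, matrix.n_bins):
                c = int(matrix.counts[i, j])
                if c:
                    fh.write(f"{i}\t{j}\t{c}\n")


def read_contact_tsv(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("contact TSV must start with a #scaffold header")
        meta = dict(
            item.split("=") for item in header.lstrip("#").split() if "=" in item
        )
        scaffold = meta.get("scaffold", "scaffold")
        bin_size = int(meta.get("bin_size", 5000))
        n_bins = int(meta["n_bins"])
        counts = np.zeros((n_bins, n_bins), dtype=np.int64)
        for line in fh:
            if line.startswith("bin_i") or not line.strip():
                continue
            i, j, c = line.split()
            counts[int(i), int(j)] = int(c)
            counts[int(j), int(i)] = int(c)
    return ContactMatrix(scaffold, bin_size, counts)


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- intensity traces -------------------------------------------------------


def read_traces_csv(
    path: str | Path, pixel: float
) -> list[tuple[str, IntensityTrace]]:
    """CSV intensity traces: either long format with columns
    (trace_id[, scale_type], intensity) or a single intensity column."""
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        rows = [r for r in reader if r and any(f.strip() for f in r)]
    if "intensity" not in cols:
        raise ValueError("traces CSV needs an 'intensity' column")
    if "trace_id" in cols:
        grouped: dict[str, list[float]] = {}
        types: dict[str, str] = {}
        for r in rows:
            tid = r[cols["trace_id"]]
            grouped.setdefault(tid, []).append(float(r[cols["intensity"]]))
            if "scale_type" in cols:
                types[tid] = r[cols["scale_type"]]
        return [
            (types.get(tid, tid), IntensityTrace(np.array(vals), pixel))
            for tid, vals in grouped.items()
        ]
    values = np.array([float(r[cols["intensity"]]) for r in rows])
    return [("trace", IntensityTrace(values, pixel))]


def write_trace_csv(
    trace: IntensityTrace, path: str | Path, trace_id: str = "trace"
) -> None:
    with open(path, "w") as fh:
        fh.write("trace_id,intensity\n")
        for v in trace.values:
            fh.write(f"{trace_id},{v:g}\n")


# -- BED and weights --------------------------------------------------------


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            if iv.score is None:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.scaffold}\t{iv.start}\t{iv.end}"
                    f"\tfeature{k}\t{iv.score:g}\n"
                )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            score = float(fields[4]) if len(fields) >= 5 else None
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), score)
            )
    return out


def write_weights_tsv(profile: WeightingProfile, path: str | Path) -> None:
    ids = profile.topology_set.topology_ids
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\t" + "\t".join(ids) + "\n")
        for win, row in zip(profile.windows, profile.weights):
            fh.write(
                f"{win.scaffold}\t{win.start}\t{win.end}\t"
                + "\t".join(f"{w:.6g}" for w in row)
                + "\n"
            )
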