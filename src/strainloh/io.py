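"""Plain-text readers and writers for the pipeline's tables and intervals.

All files are tab-separated with a single ``#``-prefixed header line; sample
identifiers travel in a ``#sample=`` comment where relevant.  Floats are
written with fixed precision so identical runs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breeding import DiploidGenome
from .classify import ConfoundVerdict
from .cnv import CNVSegment
from .haplotypes import HaplotypeSegment, LOHCall
from .readout import AlleleCountTable, CoverageProfile


def write_probes(probes, path) -> None:
    """ProbeSet as TSV: chrom, pos and, when present, log2_ratio."""
    cols = ["chrom", "pos"] + (["log2_ratio"] if "log2_ratio" in probes.probes else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in probes.probes[cols].itertuples(index=False):
            vals = [str(v) if not isinstance(v, float) else f"{v:.6f}" for v in row]
            fh.write("\t".join(vals) + "\n")


def write_coverage(profile: CoverageProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#sample={profile.sample_id}\n")
        fh.write("#chrom\tstart\tend\tcount\n")
        for row in profile.bins.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.count}\n")


def read_coverage(path) -> CoverageProfile:
    sample = "sample"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#sample="):
            sample = first.strip().split("=", 1)[1]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "count"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "count": np.int64},
    )
    return CoverageProfile(sample, df)


def write_allele_counts(table: AlleleCountTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#sample={table.sample_id}\n")
        fh.write("#chrom\tpos\tref_count\talt_count\n")
        for row in table.rows.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.ref_count}\t{row.alt_count}\n")


def read_allele_counts(path) -> AlleleCountTable:
    sample = "sample"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#sample="):
            sample = first.strip().split("=", 1)[1]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "pos", "ref_count", "alt_count"],
        dtype={"chrom": str, "pos": np.int64, "ref_count": np.int64, "alt_count": np.int64},
    )
    return AlleleCountTable(sample, df)


def write_allele_counts_vcf(table: AlleleCountTable, path) -> None:
    """Minimal VCF-dialect export with AD-style depths (REF,ALT) per site."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{table.sample_id}\n")
        for row in table.rows.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\tN\t<ALT>\t.\t.\t.\tAD\t"
                f"{row.ref_count},{row.alt_count}\n"
            )


def write_mosaics(genome: DiploidGenome, path) -> None:
    """Export both haplotype mosaics as BED: chrom, start, end, strain, copy."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tstrain\tcopy\n")
        for chrom in genome.layout.chromosomes:
            for copy_name, mosaic in zip(("A", "B"), genome.copies[chrom]):
                for s, e, strain in mosaic.blocks:
                    fh.write(f"{chrom}\t{s}\t{e}\t{strain}\t{copy_name}\n")


def write_haplotype_segments(segments: list[HaplotypeSegment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tstate\tn_snps\tmean_vaf\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{s.n_snps}\t{s.mean_vaf:.6f}\n")


def read_haplotype_segments(path) -> list[HaplotypeSegment]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, state, n_snps, mean_vaf = line.rstrip("\n").split("\t")
            out.append(
                HaplotypeSegment(chrom, int(start), int(end), state, int(n_snps),
                                 float(mean_vaf))
            )
    return out


def write_loh_calls(calls: list[LOHCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tmechanism\tretained\tcoverage_ratio\tn_snps\tmean_vaf\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.mechanism}\t{c.retained}\t"
                f"{c.coverage_ratio:.6f}\t{c.n_snps}\t{c.mean_vaf:.6f}\n"
            )


def read_loh_calls(path) -> list[LOHCall]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                LOHCall(f[0], int(f[1]), int(f[2]), f[3], f[4], float(f[5]),
                        int(f[6]), float(f[7]))
            )
    return out


def write_cnv_seg(segments: list[CNVSegment], path, sample_id: str = "sample") -> None:
    """SEG-dialect: sample, chrom, start, end, n_bins, mean log2 ratio, call."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#sample\tchrom\tstart\tend\tn_bins\tlog2_ratio\tcall\n")
        for s in segments:
            fh.write(
                f"{sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_bins}\t"
                f"{s.log2_ratio:.6f}\t{s.call}\n"
            )


def read_cnv_seg(path) -> tuple[str, list[CNVSegment]]:
    sample = "sample"
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            sample = f[0]
            out.append(CNVSegment(f[1], int(f[2]), int(f[3]), float(f[5]), int(f[4]), f[6]))
    return sample, out


def write_verdicts(verdicts: list[ConfoundVerdict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#tumor_id\tchrom\tstart\tend\tclassification\tmatches_registry\t"
            "identical_breakpoints\tlinked_driver_loh\tdistance_to_driver\n"
        )
        for v in verdicts:
            dist = "NA" if v.distance_to_driver is None else str(v.distance_to_driver)
            fh.write(
                f"{v.call.tumor_id}\t{v.call.chrom}\t{v.call.start}\t{v.call.end}\t"
                f"{v.classification}\t{int(v.matches_registry)}\t"
                f"{int(v.identical_breakpoints)}\t{int(v.linked_driver_loh)}\t{dist}\n"
            )
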