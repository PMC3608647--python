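"""Readers and writers for the standard interchange formats.

FASTA, SAM and VCF are 1-based; BED (mask, BED12 gene models) and the
refFlat-style table are 0-based half-open, matching UCSC conventions.
SAM and VCF I/O is delegated to :mod:`pysam`; FASTA reading to
:mod:`pyfaidx`.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from pyfaidx import Fasta

from .model import (
    AlignedRead,
    AlleleCatalog,
    AlleleCatalogEntry,
    CallSet,
    Gene,
    MaskInterval,
    ReferenceModel,
    SequenceRead,
    TruthSet,
    TruthVariant,
    VariantCall,
)

SAM_DUPLICATE_FLAG = 0x400
SAM_REVERSE_FLAG = 0x10

FILTER_DESCRIPTIONS = {
    "snp_cluster": "Two or more variants within the cluster window",
    "masked": "Site overlaps the accessibility mask",
}


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(contigs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fasta = Fasta(str(path), as_raw=True, rebuild=True)
    try:
        return {name: str(fasta[name][:]) for name in fasta.keys()}
    finally:
        fasta.close()


# ---------------------------------------------------------------------------
# Gene models: refFlat-style TSV and BED12

def write_refflat(genes: Sequence[Gene], path: str | os.PathLike) -> None:
    """refFlat columns: geneName name chrom strand txStart txEnd cdsStart
    cdsEnd exonCount exonStarts exonEnds (starts 0-based, ends exclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s - 1) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        g.contig,
                        g.strand,
                        str(g.tx_start - 1),
                        str(g.tx_end),
                        str(g.tx_start - 1),
                        str(g.tx_end),
                        str(len(g.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def read_refflat(path: str | os.PathLike) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = tuple((s + 1, e) for s, e in zip(starts, ends))
            genes.append(Gene(gene_id=f[0], contig=f[2], strand=f[3], exons=exons))
    return genes


def write_bed12(genes: Sequence[Gene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            chrom_start = g.tx_start - 1
            block_sizes = ",".join(str(e - s + 1) for s, e in g.exons) + ","
            block_starts = ",".join(str(s - 1 - chrom_start) for s, _ in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        str(chrom_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(chrom_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        block_sizes,
                        block_starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED3 mask

def write_mask_bed(mask: Sequence[MaskInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in mask:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_mask_bed(path: str | os.PathLike) -> list[MaskInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            if start >= end:
                raise ValueError(f"{path}: empty/inverted interval at line {lineno}")
            intervals.append(MaskInterval(fields[0], start, end))
    return intervals


# ---------------------------------------------------------------------------
# SAM

def _sam_header(contigs: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in contigs.items()],
        }
    )


def write_sam(
    reads: Iterable[AlignedRead],
    contigs: dict[str, str],
    path: str | os.PathLike,
) -> None:
    """Write coordinate-sorted SAM with @SQ lines; duplicate flag 0x400."""
    header = _sam_header(contigs)
    order = {name: i for i, name in enumerate(contigs)}
    sorted_reads = sorted(reads, key=lambda r: (order[r.contig], r.start, r.read_id))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sorted_reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = (SAM_REVERSE_FLAG if r.strand == "-" else 0) | (
                SAM_DUPLICATE_FLAG if r.duplicate else 0
            )
            seg.reference_name = r.contig
            seg.reference_start = r.start - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(r.bases))]
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(r.quals)
            out.write(seg)


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start + 1,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    bases=seg.query_sequence,
                    quals=pysam.qualities_to_qualitystring(seg.query_qualities),
                    duplicate=seg.is_duplicate,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# FASTQ (pre-alignment dedup input)

def write_fastq(reads: Iterable[SequenceRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")


def read_fastq(path: str | os.PathLike) -> list[SequenceRead]:
    reads = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            reads.append(SequenceRead(entry.name, entry.sequence, entry.quality))
    return reads


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(contigs: dict[str, str], with_filters: bool = False) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in contigs.items():
        header.contigs.add(name, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.info.add("AF", "A", "Float", "Alternative allele fraction")
    header.info.add("RESCUE", 1, "String", "Orthogonal-evidence rescue status")
    if with_filters:
        for name, desc in FILTER_DESCRIPTIONS.items():
            header.filters.add(name, None, None, desc)
    header.add_sample("SAMPLE")
    return header


def write_truth_vcf(
    truth: TruthSet, contigs: dict[str, str], path: str | os.PathLike
) -> None:
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in truth:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.samples["SAMPLE"]["GT"] = (0, 1) if v.zygosity == "het" else (1, 1)
            out.write(rec)


def read_truth_vcf(path: str | os.PathLike) -> TruthSet:
    variants = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            gt = rec.samples[0]["GT"]
            zygosity = "hom_alt" if gt == (1, 1) else "het"
            variants.append(
                TruthVariant(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    zygosity=zygosity,
                )
            )
    return TruthSet(variants)


def write_calls_vcf(
    calls: CallSet,
    contigs: dict[str, str],
    path: str | os.PathLike,
    rescue_status: dict[tuple[str, int], str] | None = None,
    drop_filtered: bool = False,
) -> None:
    """Calls as VCF with GT/DP format fields and AF info.

    Filtered records carry FILTER tags ``snp_cluster``/``masked`` unless
    ``drop_filtered`` is set, in which case they are omitted.
    """
    header = _vcf_header(contigs, with_filters=True)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            if drop_filtered and not c.passes:
                continue
            rec = out.new_record(
                contig=c.contig,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref_allele, c.alt_allele),
            )
            rec.info["AF"] = (c.alt_fraction,)
            if rescue_status and c.site in rescue_status:
                rec.info["RESCUE"] = rescue_status[c.site]
            rec.samples["SAMPLE"]["GT"] = (0, 1) if c.genotype == "het" else (1, 1)
            rec.samples["SAMPLE"]["DP"] = c.depth
            if c.passes:
                rec.filter.add("PASS")
            else:
                for label in sorted(c.filters):
                    rec.filter.add(label)
            out.write(rec)


def read_calls_vcf(path: str | os.PathLike) -> CallSet:
    calls = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            gt = rec.samples[0]["GT"]
            depth = rec.samples[0].get("DP") or 0
            af = rec.info.get("AF")
            if af is None:
                af = 1.0 if gt == (1, 1) else 0.5
            elif isinstance(af, tuple):
                af = af[0]
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            calls.append(
                VariantCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    genotype="hom_alt" if gt == (1, 1) else "het",
                    depth=depth,
                    alt_fraction=float(af),
                    filters=filters,
                )
            )
    return CallSet(calls)


def write_catalog_vcf(
    catalog: AlleleCatalog, contigs: dict[str, str], path: str | os.PathLike
) -> None:
    header = pysam.VariantHeader()
    for name, seq in contigs.items():
        header.contigs.add(name, length=len(seq))
    entries = sorted(catalog, key=lambda e: (e.contig, e.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for e in entries:
            alleles = sorted(e.alleles)
            out.write(
                out.new_record(
                    contig=e.contig, start=e.pos - 1, stop=e.pos, alleles=tuple(alleles)
                )
            )


def read_catalog_vcf(path: str | os.PathLike) -> AlleleCatalog:
    entries = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            entries.append(
                AlleleCatalogEntry(
                    contig=rec.contig,
                    pos=rec.pos,
                    alleles=frozenset(rec.alleles),
                )
            )
    return AlleleCatalog(entries)


def reference_from_files(fasta_path: str | os.PathLike, refflat_path: str | os.PathLike) -> ReferenceModel:
    return ReferenceModel(contigs=read_fasta(fasta_path), genes=read_refflat(refflat_path))
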