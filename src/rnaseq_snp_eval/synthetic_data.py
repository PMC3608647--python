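"""Synthetic reference, truth variants, RNA-seq and DNA-evidence alignments.

Everything the evaluation pipeline consumes can be generated here from a
single seeded configuration, so no external data are required.  Reads are
confined to single exons, which keeps every alignment ungapped and the pileup
exact without a splice-aware aligner.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import formats
from .model import (
    BASES,
    AlignedRead,
    AlleleCatalog,
    AlleleCatalogEntry,
    Gene,
    MaskInterval,
    ReferenceModel,
    TruthSet,
    TruthVariant,
)


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment.

    ``read_length`` defaults to 40 bp single-end reads.  Probabilities are
    validated to [0, 1]; every exon is generated at least ``read_length`` long
    so reads always fit within one exon.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 50_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 8)
    read_length: int = 40
    n_reads: int = 10_000
    error_rate: float = 0.005
    pcr_duplicate_rate: float = 0.0
    duplicate_error_mode: str = "with_errors"  # exact | with_errors | mixed
    het_fraction: float = 0.6
    variants_per_kb: float = 2.0
    expression_dispersion: float = 1.0
    mask_fraction: float = 0.0
    mask_error_multiplier: float = 1.0
    evidence_depth: float = 20.0
    base_quality: int = 30

    min_exon_length: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("error_rate", "pcr_duplicate_rate", "het_fraction", "mask_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.duplicate_error_mode not in ("exact", "with_errors", "mixed"):
            raise ValueError(f"invalid duplicate_error_mode {self.duplicate_error_mode!r}")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("exons_per_gene must be a (lo, hi) range with 1 <= lo <= hi")
        if self.variants_per_kb < 0 or self.evidence_depth < 0:
            raise ValueError("rates and depths must be non-negative")
        if self.mask_error_multiplier < 1.0:
            raise ValueError("mask_error_multiplier must be >= 1")
        self.min_exon_length = self.read_length

    @property
    def quality_char(self) -> str:
        return chr(self.base_quality + 33)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per simulation stage."""
    # crc32, not hash(): str hashing is salted per process
    tag = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# Reference and gene models

def build_reference(config: SimConfig) -> ReferenceModel:
    """Random contigs populated with non-overlapping multi-exon gene models.

    Deterministic for a fixed seed.  Raises if the contigs are too short to
    host the requested genes.
    """
    rng = _rng(config, "reference")
    contigs = {
        f"chr{i + 1}": "".join(rng.choice(list(BASES), size=config.contig_length))
        for i in range(config.n_contigs)
    }

    exon_lo, exon_hi = config.exons_per_gene
    min_len, max_len = config.min_exon_length, max(config.min_exon_length, 3 * config.read_length)
    genes: list[Gene] = []
    cursors = {name: 1 for name in contigs}
    contig_names = list(contigs)
    for g in range(config.n_genes):
        contig = contig_names[g % len(contig_names)]
        n_exons = int(rng.integers(exon_lo, exon_hi + 1))
        exons = []
        cursor = cursors[contig] + int(rng.integers(50, 200))
        for _ in range(n_exons):
            length = int(rng.integers(min_len, max_len + 1))
            exons.append((cursor, cursor + length - 1))
            cursor += length + int(rng.integers(20, 200))  # intron gap
        if exons[-1][1] > config.contig_length:
            raise ValueError(
                f"contig {contig} (length {config.contig_length} bp) too short to host "
                f"gene {g + 1} of {config.n_genes}; increase contig_length or reduce "
                "n_genes/exons_per_gene"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene{g + 1}", contig, strand, tuple(exons)))
        cursors[contig] = exons[-1][1] + 1
    return ReferenceModel(contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# Truth variants

def plant_truth_variants(ref: ReferenceModel, config: SimConfig) -> TruthSet:
    """Plant biallelic SNVs over the exonic footprint at ``variants_per_kb``.

    Each exonic base independently hosts a variant with probability
    ``variants_per_kb / 1000``; zygosity is het with probability
    ``het_fraction``, hom_alt otherwise.
    """
    p = config.variants_per_kb / 1000.0
    if p > 1.0:
        raise ValueError(
            f"variants_per_kb={config.variants_per_kb} implies a per-base probability "
            f"{p:.2f} > 1; variants cannot be placed that densely"
        )
    rng = _rng(config, "truth")
    variants = []
    for contig, start, end in ref.exonic_intervals():
        length = end - start + 1
        hits = rng.random(length) < p
        for offset in np.flatnonzero(hits):
            pos = start + int(offset)
            ref_base = ref.base_at(contig, pos)
            alt = str(rng.choice([b for b in BASES if b != ref_base]))
            zygosity = "het" if rng.random() < config.het_fraction else "hom_alt"
            variants.append(TruthVariant(contig, pos, ref_base, alt, zygosity))
    return TruthSet(variants)


def catalog_from_truth(
    truth: TruthSet, extra_entries: Sequence[AlleleCatalogEntry] = ()
) -> AlleleCatalog:
    """Allele catalog (dbSNP stand-in) listing ref+alt at every truth site."""
    entries = [
        AlleleCatalogEntry(v.contig, v.pos, frozenset({v.ref_allele, v.alt_allele}))
        for v in truth
    ]
    return AlleleCatalog(list(entries) + list(extra_entries))


# ---------------------------------------------------------------------------
# Mask intervals

def generate_mask(ref: ReferenceModel, config: SimConfig) -> list[MaskInterval]:
    """Mask ~``mask_fraction`` of each exon with one random sub-interval."""
    if config.mask_fraction == 0:
        return []
    rng = _rng(config, "mask")
    intervals = []
    for contig, start, end in ref.exonic_intervals():
        exon_len = end - start + 1
        target = config.mask_fraction * exon_len
        length = int(math.floor(target))
        if rng.random() < target - length:
            length += 1
        if length == 0:
            continue
        length = min(length, exon_len)
        offset = int(rng.integers(0, exon_len - length + 1))
        bed_start = (start - 1) + offset
        intervals.append(MaskInterval(contig, bed_start, bed_start + length))
    return sorted(intervals, key=lambda iv: (iv.contig, iv.start))


def _mask_lookup(mask: Sequence[MaskInterval]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in mask:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    return by_contig


def _pos_masked(by_contig: dict[str, list[tuple[int, int]]], contig: str, pos: int) -> bool:
    return any(s <= pos - 1 < e for s, e in by_contig.get(contig, ()))


# ---------------------------------------------------------------------------
# Read simulation

def _fragment_sequence(
    ref: ReferenceModel,
    truth: TruthSet,
    contig: str,
    start: int,
    length: int,
    rng: np.random.Generator,
) -> str:
    """True (pre-error) fragment sequence: het alleles drawn with p=1/2,
    hom_alt sites always alt."""
    bases = list(ref.contigs[contig][start - 1 : start - 1 + length])
    for i in range(length):
        v = truth.get(contig, start + i)
        if v is None:
            continue
        if v.zygosity == "hom_alt" or rng.random() < 0.5:
            bases[i] = v.alt_allele
    return "".join(bases)


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    error_rate: float,
    per_base_rates: np.ndarray | None = None,
) -> str:
    rates = per_base_rates if per_base_rates is not None else np.full(len(seq), error_rate)
    hits = rng.random(len(seq)) < rates
    if not hits.any():
        return seq
    bases = list(seq)
    for i in np.flatnonzero(hits):
        bases[i] = str(rng.choice([b for b in BASES if b != bases[i]]))
    return "".join(bases)


def simulate_rna_alignments(
    ref: ReferenceModel,
    truth: TruthSet,
    config: SimConfig,
    mask: Sequence[MaskInterval] = (),
) -> list[AlignedRead]:
    """Expression-weighted, single-exon, ungapped RNA-seq alignments.

    Genes are sampled proportionally to gamma-distributed expression weights;
    read starts are uniform over valid within-exon positions.  With
    probability ``pcr_duplicate_rate`` a fragment is emitted as k >= 2 copies
    sharing (contig, start, end, strand); copies carry independent errors in
    ``with_errors`` mode, identical bases in ``exact`` mode, and a coin flip
    per copy in ``mixed`` mode.  If a mask is supplied and
    ``mask_error_multiplier`` > 1, bases inside masked intervals err at the
    boosted rate (simulating non-unique regions that attract mismatches).
    """
    if not ref.genes or config.n_reads == 0:
        return []
    rng = _rng(config, "rna")
    weights = rng.gamma(shape=config.expression_dispersion, scale=1.0, size=len(ref.genes))
    weights = np.maximum(weights, 1e-9)
    weights /= weights.sum()

    # per-gene exon start-position tables
    gene_tables = []
    for gene in ref.genes:
        starts_per_exon = [
            (s, e - config.read_length + 1) for s, e in gene.exons
        ]  # inclusive range of valid read starts
        counts = np.array([hi - lo + 1 for lo, hi in starts_per_exon], dtype=float)
        gene_tables.append((starts_per_exon, counts / counts.sum()))

    masked = _mask_lookup(mask)
    boost = config.mask_error_multiplier

    reads: list[AlignedRead] = []
    quals = config.quality_char * config.read_length
    gene_idx = rng.choice(len(ref.genes), size=config.n_reads, p=weights)
    for frag_no, gi in enumerate(gene_idx):
        gene = ref.genes[gi]
        starts_per_exon, exon_p = gene_tables[gi]
        ei = int(rng.choice(len(starts_per_exon), p=exon_p))
        lo, hi = starts_per_exon[ei]
        start = int(rng.integers(lo, hi + 1))
        end = start + config.read_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        true_seq = _fragment_sequence(ref, truth, gene.contig, start, config.read_length, rng)

        per_base = None
        if masked and boost > 1.0:
            per_base = np.array(
                [
                    min(1.0, config.error_rate * boost)
                    if _pos_masked(masked, gene.contig, start + i)
                    else config.error_rate
                    for i in range(config.read_length)
                ]
            )

        n_copies = 1
        if config.pcr_duplicate_rate > 0 and rng.random() < config.pcr_duplicate_rate:
            n_copies = 2 + int(rng.poisson(0.5))

        first_bases = None
        for copy in range(n_copies):
            if copy == 0:
                bases = _apply_errors(true_seq, rng, config.error_rate, per_base)
                first_bases = bases
            elif config.duplicate_error_mode == "exact":
                bases = first_bases
            elif config.duplicate_error_mode == "with_errors":
                bases = _apply_errors(true_seq, rng, config.error_rate, per_base)
            else:  # mixed
                if rng.random() < 0.5:
                    bases = first_bases
                else:
                    bases = _apply_errors(true_seq, rng, config.error_rate, per_base)
            reads.append(
                AlignedRead(
                    read_id=f"rna_{frag_no}_{copy}",
                    contig=gene.contig,
                    start=start,
                    end=end,
                    strand=strand,
                    bases=bases,
                    quals=quals,
                )
            )
    return reads


def simulate_evidence_alignments(
    ref: ReferenceModel, truth: TruthSet, config: SimConfig
) -> list[AlignedRead]:
    """Uniform-depth DNA-style alignments over all contigs at
    ``evidence_depth``; allele sampling at truth sites as in the RNA
    simulator."""
    if config.evidence_depth <= 0:
        return []
    rng = _rng(config, "evidence")
    reads: list[AlignedRead] = []
    quals = config.quality_char * config.read_length
    for contig, seq in ref.contigs.items():
        max_start = len(seq) - config.read_length + 1
        if max_start < 1:
            continue
        n = int(round(config.evidence_depth * len(seq) / config.read_length))
        starts = rng.integers(1, max_start + 1, size=n)
        for i, start in enumerate(sorted(int(s) for s in starts)):
            true_seq = _fragment_sequence(ref, truth, contig, start, config.read_length, rng)
            bases = _apply_errors(true_seq, rng, config.error_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                AlignedRead(
                    read_id=f"dna_{contig}_{i}",
                    contig=contig,
                    start=start,
                    end=start + config.read_length - 1,
                    strand=strand,
                    bases=bases,
                    quals=quals,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Fixture emission

def emit_fixture_files(
    ref: ReferenceModel,
    truth: TruthSet,
    rna: Sequence[AlignedRead],
    evidence: Sequence[AlignedRead],
    mask: Sequence[MaskInterval],
    outdir: str | Path,
    catalog: AlleleCatalog | None = None,
) -> dict[str, Path]:
    """Write every fixture in its standard format; returns the file manifest.

    Reading the files back with :mod:`rnaseq_snp_eval.formats` reproduces the
    in-memory objects exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "reference_fasta": outdir / "reference.fa",
        "genes_refflat": outdir / "genes.refflat.tsv",
        "genes_bed12": outdir / "genes.bed12",
        "truth_vcf": outdir / "truth.vcf",
        "rna_sam": outdir / "rna.sam",
        "evidence_sam": outdir / "evidence.sam",
        "mask_bed": outdir / "mask.bed",
    }
    try:
        formats.write_fasta(ref.contigs, manifest["reference_fasta"])
        formats.write_refflat(ref.genes, manifest["genes_refflat"])
        formats.write_bed12(ref.genes, manifest["genes_bed12"])
        formats.write_truth_vcf(truth, ref.contigs, manifest["truth_vcf"])
        formats.write_sam(rna, ref.contigs, manifest["rna_sam"])
        formats.write_sam(evidence, ref.contigs, manifest["evidence_sam"])
        formats.write_mask_bed(mask, manifest["mask_bed"])
        if catalog is not None:
            manifest["catalog_vcf"] = outdir / "catalog.vcf"
            formats.write_catalog_vcf(catalog, ref.contigs, manifest["catalog_vcf"])
    except OSError as exc:
        raise OSError(f"failed writing fixture {exc.filename or outdir}: {exc}") from exc
    return manifest


def simulate_all(
    config: SimConfig,
) -> tuple[ReferenceModel, TruthSet, list[AlignedRead], list[AlignedRead], list[MaskInterval], AlleleCatalog]:
    """Run every stage of the simulator from one config."""
    ref = build_reference(config)
    truth = plant_truth_variants(ref, config)
    mask = generate_mask(ref, config)
    rna = simulate_rna_alignments(ref, truth, config, mask=mask)
    evidence = simulate_evidence_alignments(ref, truth, config)
    catalog = catalog_from_truth(truth)
    return ref, truth, rna, evidence, mask, catalog
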