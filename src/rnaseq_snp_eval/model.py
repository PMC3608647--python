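"""Core domain types shared across the pipeline.

Coordinate conventions, stated once and enforced by the readers/writers in
:mod:`rnaseq_snp_eval.formats`:

* FASTA / SAM / VCF records use 1-based inclusive coordinates.
* BED intervals use 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Gene:
    """A gene model: ordered, non-overlapping exons on one contig.

    Exons are 1-based closed intervals ``(start, end)``.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            if end < start:
                raise ValueError(f"gene {self.gene_id}: exon end < start")
            prev_end = end

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


@dataclass
class ReferenceModel:
    """Contig sequences plus the gene models that define the transcriptome
    footprint."""

    contigs: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene.contig not in self.contigs:
                raise ValueError(f"gene {gene.gene_id} on unknown contig {gene.contig}")
            if gene.tx_end > len(self.contigs[gene.contig]):
                raise ValueError(f"gene {gene.gene_id} extends past contig end")

    def base_at(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def exonic_intervals(self) -> list[tuple[str, int, int]]:
        """All exon intervals as (contig, start, end), 1-based closed."""
        return [(g.contig, s, e) for g in self.genes for s, e in g.exons]

    def exonic_footprint_bp(self) -> int:
        return sum(g.exonic_length for g in self.genes)


@dataclass(frozen=True)
class TruthVariant:
    """A planted biallelic SNV with a known diploid genotype."""

    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: str  # "het" | "hom_alt"

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom_alt"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("alt allele must differ from ref")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("biallelic SNVs only")

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)


class TruthSet:
    """Indexed collection of truth variants (at most one per site)."""

    def __init__(self, variants: Iterable[TruthVariant] = ()) -> None:
        self.variants: list[TruthVariant] = sorted(
            variants, key=lambda v: (v.contig, v.pos)
        )
        self._by_site: dict[tuple[str, int], TruthVariant] = {}
        for v in self.variants:
            if v.site in self._by_site:
                raise ValueError(f"two truth variants at {v.site}")
            self._by_site[v.site] = v

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[TruthVariant]:
        return iter(self.variants)

    def get(self, contig: str, pos: int) -> TruthVariant | None:
        return self._by_site.get((contig, pos))

    def subset(self, keep: Iterable[TruthVariant]) -> "TruthSet":
        return TruthSet(keep)


@dataclass(frozen=True)
class MaskInterval:
    """Accessibility-mask interval, 0-based half-open (BED convention)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"mask interval start must be < end, got {self}")

    def contains_pos(self, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside this interval."""
        return self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class SequenceRead:
    """An unaligned read (the input of pre-alignment deduplication)."""

    read_id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped, mapped single-end read in genome coordinates."""

    read_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"
    bases: str
    quals: str
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.end - self.start + 1 != len(self.bases):
            raise ValueError("ungapped alignment: end - start + 1 must equal read length")
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def coordinate_key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)

    def base_at(self, pos: int) -> str:
        """Read base aligned to the 1-based reference position ``pos``."""
        return self.bases[pos - self.start]

    def qual_at(self, pos: int) -> int:
        return ord(self.quals[pos - self.start]) - 33

    def with_duplicate(self, flag: bool) -> "AlignedRead":
        return replace(self, duplicate=flag)


@dataclass(frozen=True)
class VariantCall:
    """One called SNV with its genotype and supporting depth."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # "het" | "hom_alt"
    depth: int
    alt_fraction: float
    filters: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "hom_alt"):
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if not 0 < self.alt_fraction <= 1:
            raise ValueError("alt_fraction must be in (0, 1]")

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    @property
    def passes(self) -> bool:
        return not self.filters

    def with_filter(self, label: str) -> "VariantCall":
        return replace(self, filters=self.filters | {label})


class CallSet:
    """An ordered collection of variant calls, sorted by coordinate."""

    def __init__(self, calls: Iterable[VariantCall] = ()) -> None:
        self.calls: list[VariantCall] = sorted(calls, key=lambda c: (c.contig, c.pos))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def passing(self) -> "CallSet":
        return CallSet(c for c in self.calls if c.passes)

    def get(self, contig: str, pos: int) -> VariantCall | None:
        for c in self.calls:
            if c.contig == contig and c.pos == pos:
                return c
        return None


@dataclass(frozen=True)
class AlleleCatalogEntry:
    """A known-polymorphic site with its allele set (the dbSNP stand-in)."""

    contig: str
    pos: int
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError("catalog entry needs at least two alleles")


class AlleleCatalog:
    def __init__(self, entries: Iterable[AlleleCatalogEntry] = ()) -> None:
        self._by_site = {(e.contig, e.pos): e for e in entries}

    def __len__(self) -> int:
        return len(self._by_site)

    def __iter__(self) -> Iterator[AlleleCatalogEntry]:
        return iter(self._by_site.values())

    def get(self, contig: str, pos: int) -> AlleleCatalogEntry | None:
        return self._by_site.get((contig, pos))


@dataclass
class StratumMetrics:
    """Concordance counts and ratios for one depth bin x zygosity stratum.

    ``tp`` counts true-positive *calls* (binned by call depth) and pairs with
    ``fp`` in specificity; ``tp_expected`` counts truth sites detected with the
    correct genotype (binned by truth-site depth) and pairs with ``fn`` in
    sensitivity.  The two TP counts can differ because catalog-rescued calls
    contribute to specificity only.
    """

    depth_bin: tuple[float, float]  # half-open [lo, hi)
    zygosity: str  # "het" | "hom_alt" | "all"
    tp: int = 0
    fp: int = 0
    tp_expected: int = 0
    fn: int = 0

    @property
    def specificity(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)

    @property
    def sensitivity(self) -> float | None:
        if self.tp_expected + self.fn == 0:
            return None
        return self.tp_expected / (self.tp_expected + self.fn)
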