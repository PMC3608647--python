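"""A minimal, fully specified pileup genotype caller.

This is a threshold caller, not a likelihood caller: it exists so the
pipeline is end-to-end testable with exactly documented behaviour.  Its
parameters can be tightened or loosened to emulate permissive vs
conservative external callers; external VCF call sets can also be
substituted at the pipeline boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .model import BASES, AlignedRead, CallSet, ReferenceModel, VariantCall


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts over unflagged, quality-passing read bases."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    base_counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the stand-in caller.

    ``min_depth`` defaults to 3: sites below 3x coverage are never called
    (and, symmetrically, never expected by the evaluator).
    """

    min_depth: int = 3
    min_base_quality: int = 0
    het_band: tuple[float, float] = (0.2, 0.8)
    hom_threshold: float = 0.8
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not 0 < lo < hi < 1:
            raise ValueError("het_band must satisfy 0 < low < high < 1")
        if self.hom_threshold < hi:
            raise ValueError("hom_threshold must be >= het_band upper bound")


def build_pileup(
    alignments: Sequence[AlignedRead],
    ref: ReferenceModel,
    min_base_quality: int = 0,
) -> list[PileupColumn]:
    """One column per covered position; zero-depth columns omitted.

    Duplicate-flagged reads contribute nothing; bases below
    ``min_base_quality`` are excluded from the counts.
    """
    counts: dict[tuple[str, int], Counter] = {}
    for read in alignments:
        if read.duplicate:
            continue
        if read.contig not in ref.contigs:
            raise ValueError(
                f"read {read.read_id} aligned to contig {read.contig!r} absent from the reference"
            )
        for pos in range(read.start, read.end + 1):
            if read.qual_at(pos) < min_base_quality:
                continue
            base = read.base_at(pos)
            if base not in BASES:
                continue
            counts.setdefault((read.contig, pos), Counter())[base] += 1
    columns = []
    for (contig, pos), counter in sorted(counts.items()):
        if sum(counter.values()) == 0:
            continue
        columns.append(
            PileupColumn(
                contig=contig,
                pos=pos,
                ref_base=ref.base_at(contig, pos),
                base_counts=dict(counter),
            )
        )
    return columns


def call_site(column: PileupColumn, params: CallerParams) -> VariantCall | None:
    """Genotype one pileup column; ``None`` means no-call.

    The alt allele is the most frequent non-reference base (ties broken
    alphabetically).  het requires the alt fraction inside ``het_band``;
    hom_alt requires it above ``hom_threshold``; ref/ref is never emitted.
    """
    if column.depth < params.min_depth:
        return None
    non_ref = {b: n for b, n in column.base_counts.items() if b != column.ref_base and n > 0}
    if not non_ref:
        return None
    alt = min(non_ref, key=lambda b: (-non_ref[b], b))
    alt_count = non_ref[alt]
    if alt_count < params.min_alt_reads:
        return None
    alt_fraction = alt_count / column.depth
    lo, hi = params.het_band
    if lo <= alt_fraction <= hi:
        genotype = "het"
    elif alt_fraction > params.hom_threshold:
        genotype = "hom_alt"
    else:
        return None
    return VariantCall(
        contig=column.contig,
        pos=column.pos,
        ref_allele=column.ref_base,
        alt_allele=alt,
        genotype=genotype,
        depth=column.depth,
        alt_fraction=alt_fraction,
    )


def call_variants(
    alignments: Sequence[AlignedRead],
    ref: ReferenceModel,
    params: CallerParams = CallerParams(),
) -> CallSet:
    """Map :func:`call_site` over the pileup.  Deterministic."""
    columns = build_pileup(alignments, ref, min_base_quality=params.min_base_quality)
    calls = [c for col in columns if (c := call_site(col, params)) is not None]
    return CallSet(calls)
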