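"""Orthogonal-evidence rescue of putative false positives.

A false-positive call is re-examined against DNA-evidence alignments at the
same site: a het call is rescued when the alternative allele occurs in
20-80% (inclusive) of the evidence reads; a hom_alt call when it occurs in
strictly more than 90%.  Sites with fewer than ``min_evidence_depth``
evidence reads are reported unassessable — below a handful of reads the
20-80% band is nearly unfalsifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import AlignedRead, VariantCall

RESCUED = "yes"
NOT_RESCUED = "no"
UNASSESSABLE = "unassessable"

DEFAULT_HET_BAND = (0.20, 0.80)
DEFAULT_HOM_MIN = 0.90
DEFAULT_MIN_EVIDENCE_DEPTH = 4


@dataclass(frozen=True)
class RescueResult:
    call: VariantCall
    status: str  # yes | no | unassessable
    evidence_depth: int
    alt_fraction: float | None

    @property
    def rescued(self) -> bool:
        return self.status == RESCUED


def evidence_allele_fraction(
    call: VariantCall, evidence: Sequence[AlignedRead]
) -> tuple[int, int]:
    """(alt reads, total reads) among unflagged evidence reads at the site."""
    depth = alt = 0
    for read in evidence:
        if read.duplicate or read.contig != call.contig:
            continue
        if not read.start <= call.pos <= read.end:
            continue
        depth += 1
        if read.base_at(call.pos) == call.alt_allele:
            alt += 1
    return alt, depth


def rescue_false_positives(
    fp_calls: Iterable[VariantCall],
    evidence: Sequence[AlignedRead],
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    hom_min: float = DEFAULT_HOM_MIN,
    min_evidence_depth: int = DEFAULT_MIN_EVIDENCE_DEPTH,
) -> list[RescueResult]:
    """Flag each FP call rescued / not rescued / unassessable.

    het rescued iff alt fraction in [het_band lo, het_band hi] (endpoints
    inclusive); hom_alt rescued iff alt fraction > hom_min (strict, so 18/20
    = 0.90 is NOT rescued).
    """
    lo, hi = het_band
    results = []
    for call in fp_calls:
        alt, depth = evidence_allele_fraction(call, evidence)
        if depth < min_evidence_depth:
            results.append(RescueResult(call, UNASSESSABLE, depth, None))
            continue
        fraction = alt / depth
        if call.genotype == "het":
            ok = lo <= fraction <= hi
        else:
            ok = fraction > hom_min
        results.append(RescueResult(call, RESCUED if ok else NOT_RESCUED, depth, fraction))
    return results


def rescued_fraction(results: Sequence[RescueResult]) -> float | None:
    """Fraction of all FP calls that were rescued (the reported summary
    quantity); None when there were no FP calls."""
    if not results:
        return None
    return sum(r.rescued for r in results) / len(results)
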