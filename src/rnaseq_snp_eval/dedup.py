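"""Duplicate-read handling.

Two semantics are implemented side by side:

* **pre-alignment** (:func:`collapse_identical`) — duplicates are reads with
  an exactly identical base string; one copy per distinct string is kept.
* **post-alignment** (:func:`mark_positional_duplicates`) — duplicates are
  reads mapping to the same (contig, start, end, strand); one copy per
  coordinate group is retained, the rest flagged (SAM flag 0x400) so both
  behaviours stay auditable.  Downstream stages skip flagged reads.

Strand is part of the positional key, following standard duplicate-marking
practice.  Within a coordinate group the retained copy is the one with the
highest total base quality, ties broken by first occurrence, preserving the
most reliable evidence.
"""

from __future__ import annotations

from typing import Sequence, TypeVar

from .model import AlignedRead, SequenceRead

R = TypeVar("R", SequenceRead, AlignedRead)


def collapse_identical(reads: Sequence[R]) -> list[R]:
    """Keep exactly one read per distinct base string (first occurrence)."""
    seen: set[str] = set()
    out: list[R] = []
    for read in reads:
        if read.bases in seen:
            continue
        seen.add(read.bases)
        out.append(read)
    return out


def _qual_sum(read: AlignedRead) -> int:
    return sum(ord(q) - 33 for q in read.quals)


def mark_positional_duplicates(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Flag all but one read in each (contig, start, end, strand) group.

    Returns a new list in the original order; exactly one read per group is
    unflagged.  Reads already flagged on input are re-evaluated from scratch.
    """
    best: dict[tuple[str, int, int, str], int] = {}
    for idx, read in enumerate(alignments):
        key = read.coordinate_key
        if key not in best or _qual_sum(read) > _qual_sum(alignments[best[key]]):
            best[key] = idx
    keep = set(best.values())
    return [read.with_duplicate(idx not in keep) for idx, read in enumerate(alignments)]


def drop_duplicates(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    """The in-memory pipeline view: flagged reads removed."""
    return [r for r in alignments if not r.duplicate]


def apply_dedup(alignments: Sequence[AlignedRead], mode: str) -> list[AlignedRead]:
    """Run one duplicate strategy over aligned reads.

    ``pre`` collapses exact-sequence duplicates (what pre-alignment
    deduplication of the raw reads would have produced, since alignment here
    is deterministic in the read), ``post`` marks positional duplicates and
    drops them, ``none`` is the identity.
    """
    if mode == "pre":
        return collapse_identical(list(alignments))
    if mode == "post":
        return drop_duplicates(mark_positional_duplicates(alignments))
    if mode == "none":
        return list(alignments)
    raise ValueError(f"unknown dedup mode {mode!r}; expected pre|post|none")
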