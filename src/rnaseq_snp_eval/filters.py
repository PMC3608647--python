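"""Post-call site filters applied before evaluation.

Cluster convention: two calls cluster when |pos difference| < window (both
fit inside some window-bp stretch), and *all* members of a cluster are
removed, not thinned.  Cross-contig positions never cluster.  Filtered
calls are tagged, not deleted, so VCF output can either drop them or carry
FILTER labels ``snp_cluster`` / ``masked``.
"""

from __future__ import annotations

from typing import Sequence

from .model import CallSet, MaskInterval

CLUSTER_FILTER = "snp_cluster"
MASK_FILTER = "masked"


def filter_clusters(calls: CallSet, window: int = 3) -> CallSet:
    """Tag every call that has another call on the same contig within
    ``window`` bp (exclusive): calls at pos 100 and 102 both go, 100 and 103
    both stay with the default window of 3."""
    ordered = list(calls)  # CallSet iterates in (contig, pos) order
    tagged = []
    for i, call in enumerate(ordered):
        clustered = False
        for j in (i - 1, i + 1):
            if 0 <= j < len(ordered):
                other = ordered[j]
                if other.contig == call.contig and abs(other.pos - call.pos) < window:
                    clustered = True
                    break
        tagged.append(call.with_filter(CLUSTER_FILTER) if clustered else call)
    return CallSet(tagged)


def filter_masked(calls: CallSet, mask: Sequence[MaskInterval]) -> CallSet:
    """Tag calls whose 1-based position falls inside a mask interval
    (interval start <= pos-1 < end)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in mask:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    tagged = []
    for call in calls:
        hit = any(s <= call.pos - 1 < e for s, e in by_contig.get(call.contig, ()))
        tagged.append(call.with_filter(MASK_FILTER) if hit else call)
    return CallSet(tagged)


def apply_filters(
    calls: CallSet, mask: Sequence[MaskInterval] = (), window: int = 3
) -> CallSet:
    """Cluster filter then mask filter (the two commute)."""
    return filter_masked(filter_clusters(calls, window=window), mask)
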