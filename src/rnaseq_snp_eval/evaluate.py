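"""Concordance of a call set against a truth genotype set.

Definitions (the study's usage — note "specificity" here is what is
elsewhere called precision/PPV):

* expected call — a truth site covered by >= ``min_depth`` (default 3)
  unflagged reads;
* TP call — a call at a truth site with matching genotype (zygosity + alt
  allele), or at a catalog site whose allele set contains both the call's
  ref and alt alleles;
* FP call — any other passing call;
* FN — an expected truth site with no call, or a call with the wrong
  genotype;
* specificity = TP/(TP+FP) over calls; sensitivity = TP/(TP+FN) over
  expected truth sites.

Depth stratification uses post-dedup pipeline depth for both calls (the
call's own depth) and truth sites (pileup depth), keeping the two
denominators consistent.  A catalog-only TP counts toward specificity but
never toward sensitivity.  Undefined ratios are reported as missing, never
0 or 1.
"""

from __future__ import annotations

import bisect
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .model import (
    AlignedRead,
    AlleleCatalog,
    CallSet,
    StratumMetrics,
    TruthSet,
    TruthVariant,
    VariantCall,
)

DEFAULT_BIN_EDGES = (3, 4, 5, 6, 8, 10, 15, 20)


def truth_site_depth(
    truth: TruthSet, alignments: Sequence[AlignedRead]
) -> dict[tuple[str, int], int]:
    """Unflagged-read depth at every truth site (0 when uncovered)."""
    depths = {v.site: 0 for v in truth}
    if not depths:
        return depths
    by_contig: dict[str, list[int]] = {}
    for contig, pos in depths:
        by_contig.setdefault(contig, []).append(pos)
    for positions in by_contig.values():
        positions.sort()
    for read in alignments:
        if read.duplicate:
            continue
        positions = by_contig.get(read.contig)
        if not positions:
            continue
        lo = bisect.bisect_left(positions, read.start)
        hi = bisect.bisect_right(positions, read.end)
        for pos in positions[lo:hi]:
            depths[(read.contig, pos)] += 1
    return depths


def expected_call_set(
    truth: TruthSet,
    depths: Mapping[tuple[str, int], int],
    min_depth: int = 3,
) -> TruthSet:
    """Truth sites with depth >= ``min_depth`` — the detectable subset."""
    return TruthSet(v for v in truth if depths.get(v.site, 0) >= min_depth)


def _genotype_matches(call: VariantCall, variant: TruthVariant) -> bool:
    return call.alt_allele == variant.alt_allele and call.genotype == variant.zygosity


def classify_calls(
    calls: CallSet,
    truth: TruthSet,
    catalog: AlleleCatalog | None = None,
) -> dict[tuple[str, int], str]:
    """Label each passing call TP or FP."""
    labels = {}
    for call in calls.passing():
        variant = truth.get(call.contig, call.pos)
        if variant is not None:
            labels[call.site] = "TP" if _genotype_matches(call, variant) else "FP"
            continue
        entry = catalog.get(call.contig, call.pos) if catalog else None
        if entry is not None and {call.ref_allele, call.alt_allele} <= entry.alleles:
            labels[call.site] = "TP"
        else:
            labels[call.site] = "FP"
    return labels


def classify_truth(
    expected: TruthSet, calls: CallSet
) -> dict[tuple[str, int], str]:
    """Label each expected truth site TP (detected with correct genotype)
    or FN."""
    call_by_site = {c.site: c for c in calls.passing()}
    labels = {}
    for variant in expected:
        call = call_by_site.get(variant.site)
        if call is not None and _genotype_matches(call, variant):
            labels[variant.site] = "TP"
        else:
            labels[variant.site] = "FN"
    return labels


def make_bins(edges: Sequence[float] = DEFAULT_BIN_EDGES) -> list[tuple[float, float]]:
    """Half-open depth bins from ascending edges; last bin extends to inf."""
    if list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must be strictly ascending")
    edges = list(edges)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)] + [(edges[-1], float("inf"))]


def _bin_of(depth: float, bins: Sequence[tuple[float, float]], cumulative: bool) -> list[int]:
    if cumulative:
        return [i for i, (lo, _) in enumerate(bins) if depth >= lo]
    return [i for i, (lo, hi) in enumerate(bins) if lo <= depth < hi]


def compute_metrics(
    call_labels: Mapping[tuple[str, int], str],
    truth_labels: Mapping[tuple[str, int], str],
    calls: CallSet,
    truth: TruthSet,
    depths: Mapping[tuple[str, int], int],
    bins: Sequence[tuple[float, float]] | None = None,
    zygosity_split: bool = True,
    cumulative: bool = False,
) -> list[StratumMetrics]:
    """Per depth-bin (and optionally per-zygosity) TP/FP/FN with the two
    ratios.

    Calls are binned by call depth; truth sites by truth-site pileup depth.
    ``cumulative=True`` bins each item into every bin whose lower edge it
    reaches (">= d" curves); the default bins exactly.  Overlapping bins are
    rejected in exact mode.
    """
    if bins is None:
        bins = make_bins()
    if not cumulative:
        for i, (lo, hi) in enumerate(bins):
            for lo2, hi2 in bins[i + 1 :]:
                if lo < hi2 and lo2 < hi:
                    raise ValueError(f"overlapping depth bins {(lo, hi)} and {(lo2, hi2)}")

    zygosities = ("het", "hom_alt", "all") if zygosity_split else ("all",)
    table = {
        (i, z): StratumMetrics(depth_bin=bins[i], zygosity=z)
        for i in range(len(bins))
        for z in zygosities
    }

    call_by_site = {c.site: c for c in calls.passing()}
    for site, label in call_labels.items():
        call = call_by_site[site]
        for i in _bin_of(call.depth, bins, cumulative):
            for z in ("all", call.genotype) if zygosity_split else ("all",):
                m = table[(i, z)]
                if label == "TP":
                    m.tp += 1
                else:
                    m.fp += 1

    truth_by_site = {v.site: v for v in truth}
    for site, label in truth_labels.items():
        variant = truth_by_site[site]
        depth = depths.get(site, 0)
        for i in _bin_of(depth, bins, cumulative):
            for z in ("all", variant.zygosity) if zygosity_split else ("all",):
                m = table[(i, z)]
                if label == "TP":
                    m.tp_expected += 1
                else:
                    m.fn += 1

    return [table[(i, z)] for i in range(len(bins)) for z in zygosities]


def callset_overlap(a: CallSet, b: CallSet) -> tuple[float, float]:
    """(|a∩b|/|a|, |a∩b|/|b|) keyed on (contig, pos, alt allele, genotype)."""
    key = lambda c: (c.contig, c.pos, c.alt_allele, c.genotype)
    set_a = {key(c) for c in a.passing()}
    set_b = {key(c) for c in b.passing()}
    inter = len(set_a & set_b)
    frac_a = inter / len(set_a) if set_a else 0.0
    frac_b = inter / len(set_b) if set_b else 0.0
    return frac_a, frac_b


def evaluate_callset(
    calls: CallSet,
    truth: TruthSet,
    alignments: Sequence[AlignedRead],
    catalog: AlleleCatalog | None = None,
    min_depth: int = 3,
    bins: Sequence[tuple[float, float]] | None = None,
    zygosity_split: bool = True,
    cumulative: bool = False,
) -> tuple[list[StratumMetrics], dict]:
    """Full evaluation: depths, expected set, labels, stratified metrics.

    Returns the strata plus a summary dict with pooled counts and the two
    pooled ratios.
    """
    depths = truth_site_depth(truth, alignments)
    expected = expected_call_set(truth, depths, min_depth=min_depth)
    call_labels = classify_calls(calls, truth, catalog)
    truth_labels = classify_truth(expected, calls)
    strata = compute_metrics(
        call_labels,
        truth_labels,
        calls,
        truth,
        depths,
        bins=bins,
        zygosity_split=zygosity_split,
        cumulative=cumulative,
    )
    counts = Counter(call_labels.values())
    truth_counts = Counter(truth_labels.values())
    tp, fp = counts["TP"], counts["FP"]
    tp_exp, fn = truth_counts["TP"], truth_counts["FN"]
    summary = {
        "n_calls": len(calls.passing()),
        "n_expected": len(expected),
        "tp": tp,
        "fp": fp,
        "tp_expected": tp_exp,
        "fn": fn,
        "specificity": tp / (tp + fp) if tp + fp else None,
        "sensitivity": tp_exp / (tp_exp + fn) if tp_exp + fn else None,
    }
    return strata, summary


def metrics_to_rows(strata: Iterable[StratumMetrics]) -> list[dict]:
    """Tidy rows (one per bin x zygosity) for TSV/DataFrame output."""
    rows = []
    for m in strata:
        rows.append(
            {
                "depth_lo": m.depth_bin[0],
                "depth_hi": m.depth_bin[1],
                "zygosity": m.zygosity,
                "tp": m.tp,
                "fp": m.fp,
                "tp_expected": m.tp_expected,
                "fn": m.fn,
                "specificity": m.specificity,
                "sensitivity": m.sensitivity,
            }
        )
    return rows
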