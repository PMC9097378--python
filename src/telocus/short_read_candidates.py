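"""Short-read TE expression-candidate calling.

Three filters are applied to every annotated TE locus and their union forms
the expression-candidate pool:

1. unique-read counting (intersection-nonempty semantics) with a strict
   read-count threshold;
2. multi-mapping-inclusive coverage: total overlapping reads and mean
   per-base depth over covered bases;
3. dangler evidence: uniquely mapped reads whose paired mate aligned to the
   canonical TE library, clustered within a window of a locus boundary,
   combined with an internal-read requirement.

Candidates are then classified as trackable (any unique-read support) and
full-length (genomic span > 90% of the canonical element length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_model import ShortReadAlignment, TELocus, locus_interval_tree


@dataclass
class CandidateCall:
    """Per-locus evidence record across the three filters."""

    locus_id: str
    unique_count: int
    total_count: int
    covered_bases: int
    mean_depth: float
    dangler_left: int
    dangler_right: int
    internal_reads: int
    passed_filter1: bool
    passed_filter2: bool
    passed_filter3: bool
    is_candidate: bool
    trackable: bool
    integrity: float
    is_full_length: bool


def count_unique_overlaps(
    alignments: Iterable[ShortReadAlignment],
    te_loci: Sequence[TELocus],
) -> dict[str, int]:
    """Count unique-mapping reads per locus, intersection-nonempty style.

    A unique alignment contributes to a locus iff it overlaps that locus
    and no other TE locus (ambiguous assignments are dropped); each
    alignment is counted at most once.
    """
    trees = locus_interval_tree(te_loci)
    counts = {locus.id: 0 for locus in te_loci}
    for aln in alignments:
        if not aln.is_unique:
            continue
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        hits = {iv.data.id for iv in tree.overlap(aln.start, aln.end)}
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return counts


def filter_unique(counts: Mapping[str, int], min_reads: int = 10) -> dict[str, bool]:
    """Pass iff unique_count strictly exceeds ``min_reads``."""
    return {locus_id: c > min_reads for locus_id, c in counts.items()}


def compute_coverage_stats(
    alignments: Iterable[ShortReadAlignment],
    te_loci: Sequence[TELocus],
) -> dict[str, tuple[int, int, float]]:
    """Per-locus (total_count, covered_bases, mean_depth).

    Every reported alignment (unique or multi) overlapping a locus counts
    once at that locus; depth averages only over covered bases.
    """
    trees = locus_interval_tree(te_loci)
    depth = {locus.id: np.zeros(locus.length, dtype=np.int64) for locus in te_loci}
    total = {locus.id: 0 for locus in te_loci}
    for aln in alignments:
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(aln.start, aln.end):
            locus = iv.data
            total[locus.id] += 1
            lo = max(aln.start, locus.start) - locus.start
            hi = min(aln.end, locus.end) - locus.start
            depth[locus.id][lo:hi] += 1
    out = {}
    for locus in te_loci:
        d = depth[locus.id]
        covered = int((d > 0).sum())
        mean_depth = float(d[d > 0].mean()) if covered else 0.0
        out[locus.id] = (total[locus.id], covered, mean_depth)
    return out


def filter_coverage(
    stats: Mapping[str, tuple[int, int, float]],
    min_reads: int = 10,
    min_depth: float = 5.0,
) -> dict[str, bool]:
    """Pass iff total_count > min_reads and mean_depth > min_depth (both strict)."""
    return {
        locus_id: (total > min_reads and depth > min_depth)
        for locus_id, (total, _covered, depth) in stats.items()
    }


def find_danglers(
    genome_alignments: Iterable[ShortReadAlignment],
    te_library_hits: set[str],
    te_loci: Sequence[TELocus],
    window: int = 1000,
    exclude_tails: bool = True,
) -> dict[str, tuple[int, int, int]]:
    """Per-locus (dangler_left, dangler_right, internal_reads).

    A dangler is a uniquely mapped genome alignment whose mate aligned to
    the canonical TE library. It is assigned to a locus side when it lies
    entirely within ``window`` bp of that boundary, outside the locus, and
    is oriented toward it (+ strand left of the locus, - strand right of
    it). With ``exclude_tails`` alignments crossing a locus boundary are
    discarded. Internal reads (unique or multi) lie wholly inside the
    locus.
    """
    trees = locus_interval_tree(te_loci)
    result = {locus.id: [0, 0, 0] for locus in te_loci}
    for aln in genome_alignments:
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        # boundary-crossing reads: overlap a locus but stick out of it
        crossing = any(
            not (iv.begin <= aln.start and aln.end <= iv.end)
            for iv in tree.overlap(aln.start, aln.end)
        )
        if exclude_tails and crossing:
            continue
        for iv in tree.overlap(aln.start, aln.end):
            locus = iv.data
            if locus.start <= aln.start and aln.end <= locus.end:
                result[locus.id][2] += 1
        if not (aln.is_unique and aln.read_id in te_library_hits):
            continue
        # candidate flanking placements within the window on either side
        for iv in tree.overlap(aln.start - window, aln.end + window):
            locus = iv.data
            if aln.end <= locus.start and locus.start - aln.start <= window:
                if aln.strand == "+":
                    result[locus.id][0] += 1
            elif aln.start >= locus.end and aln.end - locus.end <= window:
                if aln.strand == "-":
                    result[locus.id][1] += 1
    return {locus_id: tuple(v) for locus_id, v in result.items()}


def filter_danglers(
    counts: Mapping[str, tuple[int, int, int]],
    min_reads: int = 10,
    side_mode: str = "any",
) -> dict[str, bool]:
    """Dangler filter: side condition per mode plus strict internal-read bound."""
    if side_mode not in ("any", "both"):
        raise ValueError(f"side_mode must be 'any' or 'both', got {side_mode!r}")
    out = {}
    for locus_id, (left, right, internal) in counts.items():
        if side_mode == "any":
            side_ok = max(left, right) > min_reads
        else:
            side_ok = min(left, right) > min_reads
        out[locus_id] = side_ok and internal > min_reads
    return out


def assemble_candidates(
    unique_counts: Mapping[str, int],
    coverage_stats: Mapping[str, tuple[int, int, float]],
    dangler_counts: Mapping[str, tuple[int, int, int]],
    te_loci: Sequence[TELocus],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, CandidateCall]:
    """Union the three filters into the expression-candidate pool.

    Returns a CandidateCall for every annotated locus; candidates are those
    passing at least one filter.
    """
    f1 = filter_unique(unique_counts, config.min_reads)
    f2 = filter_coverage(coverage_stats, config.min_reads, config.min_depth)
    f3 = filter_danglers(dangler_counts, config.min_reads, config.dangler_side_mode)
    calls = {}
    for locus in te_loci:
        uc = unique_counts.get(locus.id, 0)
        total, covered, depth = coverage_stats.get(locus.id, (0, 0, 0.0))
        left, right, internal = dangler_counts.get(locus.id, (0, 0, 0))
        p1 = f1.get(locus.id, False)
        p2 = f2.get(locus.id, False)
        p3 = f3.get(locus.id, False)
        integrity = locus.integrity
        calls[locus.id] = CandidateCall(
            locus_id=locus.id,
            unique_count=uc,
            total_count=total,
            covered_bases=covered,
            mean_depth=depth,
            dangler_left=left,
            dangler_right=right,
            internal_reads=internal,
            passed_filter1=p1,
            passed_filter2=p2,
            passed_filter3=p3,
            is_candidate=p1 or p2 or p3,
            trackable=uc > 0,
            integrity=integrity,
            is_full_length=integrity > config.integrity_threshold,
        )
    return calls


def calls_to_dataframe(calls: Mapping[str, CandidateCall]):
    """One row per CandidateCall, ready for TSV export."""
    import pandas as pd

    return pd.DataFrame([vars(c) for c in calls.values()]).set_index("locus_id")


def exclusion_summary(calls: Mapping[str, CandidateCall]) -> dict[str, int]:
    """Partition all annotated loci into candidates / below-threshold / zero-evidence."""
    candidates = below = zero = 0
    for call in calls.values():
        if call.is_candidate:
            candidates += 1
        elif call.unique_count or call.total_count or call.dangler_left or call.dangler_right:
            below += 1
        else:
            zero += 1
    return {
        "candidates": candidates,
        "below_threshold": below,
        "zero_evidence": zero,
        "total": len(calls),
    }
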