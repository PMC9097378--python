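"""Genomic-location classification of TE candidates and location-bias tests.

Each locus receives one hierarchical assignment (region -> co-localised
gene activity -> location -> integrity -> trackability); observed
candidate distributions are compared against all annotated loci with
chi-square goodness-of-fit tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_model import (
    LOCATION_PRIORITY,
    CompartmentMap,
    ShortReadAlignment,
    TELocus,
    locus_interval_tree,
)
from .short_read_candidates import CandidateCall

logger = logging.getLogger(__name__)


@dataclass
class CompartmentAssignment:
    """A locus's single hierarchical placement."""

    locus_id: str
    region: str  # genic | intergenic
    location: str  # exon | intron | N-flank | C-flank | none
    gene_id: Optional[str] = None
    gene_expressed: Optional[bool] = None
    integrity_class: Optional[str] = None  # full-length | fragmented
    trackable_class: Optional[str] = None  # trackable | un-trackable


@dataclass
class LocationBiasTest:
    """Chi-square goodness-of-fit of observed candidate counts vs expected proportions."""

    categories: list[str]
    observed: list[int]
    expected_proportions: list[float]
    statistic: float
    df: int
    p_value: float
    significant: bool


def assign_location(locus: TELocus, compartment_map: CompartmentMap) -> CompartmentAssignment:
    """Assign a locus to one region/location/gene.

    Any overlap with a genic label makes the locus genic. Among genes, the
    one with the largest total overlap wins (ties by gene id for
    determinism); within that gene the location is the highest-priority
    overlapped label (exon > intron > N-flank > C-flank).
    """
    overlaps = compartment_map.overlaps(locus.chrom, locus.start, locus.end)
    if not overlaps:
        return CompartmentAssignment(locus_id=locus.id, region="intergenic", location="none")
    per_gene: dict[str, dict[str, int]] = {}
    for label, gene_id, ov in overlaps:
        per_gene.setdefault(gene_id, {})
        per_gene[gene_id][label] = per_gene[gene_id].get(label, 0) + ov
    # largest total overlap wins; ties go to the gene with the lower start
    best_gene = min(
        per_gene,
        key=lambda g: (
            -sum(per_gene[g].values()),
            compartment_map.gene_starts.get(g, 0),
            g,
        ),
    )
    labels = per_gene[best_gene]
    for label in LOCATION_PRIORITY:
        if label in labels:
            return CompartmentAssignment(
                locus_id=locus.id, region="genic", location=label, gene_id=best_gene
            )
    raise AssertionError("unreachable: overlap with no known label")


def enumerate_colocalisations(
    locus: TELocus, compartment_map: CompartmentMap
) -> list[CompartmentAssignment]:
    """One assignment per overlapping gene (for DETE-DEG pairing).

    Unlike :func:`assign_location`, which yields a single label per locus,
    this enumerates every gene whose unit or flanks the locus intersects,
    each with its highest-priority location label.
    """
    overlaps = compartment_map.overlaps(locus.chrom, locus.start, locus.end)
    per_gene: dict[str, set[str]] = {}
    for label, gene_id, _ov in overlaps:
        per_gene.setdefault(gene_id, set()).add(label)
    out = []
    for gene_id in sorted(per_gene):
        for label in LOCATION_PRIORITY:
            if label in per_gene[gene_id]:
                out.append(
                    CompartmentAssignment(
                        locus_id=locus.id, region="genic", location=label, gene_id=gene_id
                    )
                )
                break
    return out


def gene_expression_status(
    expression: pd.DataFrame,
    fpkm_threshold: float = 1.0,
    tpm_threshold: Optional[float] = None,
) -> dict[str, bool]:
    """Expressed-gene flags from an abundance table.

    ``expression`` has columns gene and fpkm (plus tpm in long-read mode).
    Expressed means fpkm strictly above the threshold; when
    ``tpm_threshold`` is given, the long-read conjunction applies: both the
    TPM and FPKM bounds must hold.
    """
    out = {}
    for row in expression.itertuples(index=False):
        ok = float(row.fpkm) > fpkm_threshold
        if tpm_threshold is not None:
            ok = ok and float(row.tpm) > tpm_threshold
        out[str(row.gene)] = ok
    return out


def annotate_assignments(
    assignments: Iterable[CompartmentAssignment],
    calls: Mapping[str, CandidateCall],
    expressed: Mapping[str, bool],
) -> list[CompartmentAssignment]:
    """Fill gene-expression, integrity and trackability layers in place."""
    out = []
    for a in assignments:
        if a.gene_id is not None:
            if a.gene_id not in expressed:
                logger.info("gene %s missing from expression table; treated as not expressed", a.gene_id)
            a.gene_expressed = expressed.get(a.gene_id, False)
        call = calls.get(a.locus_id)
        if call is not None:
            a.integrity_class = "full-length" if call.is_full_length else "fragmented"
            a.trackable_class = "trackable" if call.trackable else "un-trackable"
        out.append(a)
    return out


def hierarchical_summary(assignments: Sequence[CompartmentAssignment]) -> pd.DataFrame:
    """Nested counts: region -> gene activity -> location -> integrity -> trackability.

    Tidy output with one row per populated leaf; counts at any level sum to
    their parent.
    """
    rows = []
    for a in assignments:
        if a.gene_expressed is None:
            activity = "n/a"
        else:
            activity = "expressed" if a.gene_expressed else "non-expressed"
        rows.append(
            {
                "region": a.region,
                "gene_activity": activity if a.region == "genic" else "n/a",
                "location": a.location,
                "integrity": a.integrity_class or "n/a",
                "trackability": a.trackable_class or "n/a",
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["region", "gene_activity", "location", "integrity", "trackability"])
        .size()
        .rename("count")
        .reset_index()
    )


def chisq_location_bias(
    observed: Mapping[str, int],
    expected_proportions: Mapping[str, float],
    alpha: float = 0.01,
) -> LocationBiasTest:
    """Goodness-of-fit X^2 = sum (O_i - N p_i)^2 / (N p_i), df = k - 1."""
    categories = list(observed)
    if len(categories) < 2:
        raise ValueError("need at least two categories")
    obs = np.array([observed[c] for c in categories], dtype=float)
    props = np.array([expected_proportions[c] for c in categories], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        props = props / props.sum()
    n = obs.sum()
    expected = n * props
    if np.any(expected == 0):
        zero = [c for c, e in zip(categories, expected) if e == 0]
        raise ValueError(
            f"expected count of zero for categories {zero}; merge categories before testing"
        )
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(categories) - 1
    p = float(stats.chi2.sf(x2, df))
    return LocationBiasTest(
        categories=categories,
        observed=[int(o) for o in obs],
        expected_proportions=list(props),
        statistic=x2,
        df=df,
        p_value=p,
        significant=p < alpha,
    )


def expected_proportions_from_loci(
    assignments: Sequence[CompartmentAssignment],
    key,
) -> dict[str, float]:
    """Category proportions over a background locus set (e.g. all annotated loci)."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[key(a)] = counts.get(key(a), 0) + 1
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def family_summary(
    calls: Mapping[str, CandidateCall],
    te_loci: Sequence[TELocus],
) -> pd.DataFrame:
    """Per-family candidate counts, {trackable, un-trackable} x {fragmented, full-length}.

    Families with zero candidates are omitted; row sums equal per-family
    candidate totals.
    """
    fam = {locus.id: locus.family for locus in te_loci}
    rows = []
    for call in calls.values():
        if not call.is_candidate:
            continue
        rows.append(
            {
                "family": fam[call.locus_id],
                "trackability": "trackable" if call.trackable else "un-trackable",
                "integrity": "full-length" if call.is_full_length else "fragmented",
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["trackable_fragmented", "trackable_full_length",
                     "untrackable_fragmented", "untrackable_full_length"]
        )
    df = pd.DataFrame(rows)
    tab = df.pivot_table(
        index="family", columns=["trackability", "integrity"], aggfunc="size", fill_value=0
    )
    tab.columns = [
        f"{'trackable' if t == 'trackable' else 'untrackable'}_{i.replace('-', '_')}"
        for t, i in tab.columns
    ]
    for col in ("trackable_fragmented", "trackable_full_length",
                "untrackable_fragmented", "untrackable_full_length"):
        if col not in tab.columns:
            tab[col] = 0
    return tab[["trackable_fragmented", "trackable_full_length",
                "untrackable_fragmented", "untrackable_full_length"]].sort_index()


CANDIDATE_CLASSES = (
    "full-length_trackable",
    "full-length_un-trackable",
    "fragmented_trackable",
    "fragmented_un-trackable",
)


def read_class_sharing(
    alignments: Iterable[ShortReadAlignment],
    calls: Mapping[str, CandidateCall],
    te_loci: Sequence[TELocus],
) -> pd.DataFrame:
    """Per-read membership over the four candidate classes.

    Each read id maps to the set of classes of the candidate loci it
    aligns to; returns the intersection-size table over all non-empty class
    combinations (up to 15).
    """
    class_of = {}
    for call in calls.values():
        if call.is_candidate:
            integ = "full-length" if call.is_full_length else "fragmented"
            track = "trackable" if call.trackable else "un-trackable"
            class_of[call.locus_id] = f"{integ}_{track}"
    trees = locus_interval_tree([l for l in te_loci if l.id in class_of])
    membership: dict[str, set[str]] = {}
    for aln in alignments:
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(aln.start, aln.end):
            membership.setdefault(aln.read_id, set()).add(class_of[iv.data.id])
    combo_counts: dict[str, int] = {}
    for classes in membership.values():
        key = "+".join(sorted(classes))
        combo_counts[key] = combo_counts.get(key, 0) + 1
    df = pd.DataFrame(
        [{"classes": k, "n_classes": k.count("+") + 1, "reads": v} for k, v in combo_counts.items()]
    )
    if not df.empty:
        df = df.sort_values(["n_classes", "classes"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Summary arithmetic shared by figures/tables
# ---------------------------------------------------------------------------

def fraction_percent(part: int, whole: int, ndigits: int = 2) -> float:
    """Percentage part/whole rounded to ``ndigits`` — the summary arithmetic
    used for trackable/genic/concordance proportions."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, ndigits)
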