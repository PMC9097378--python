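"""Long-read (cDNA) evidence at TE loci.

Classifies sense-overlapping long reads by transcription start relative to
the TE boundary (de novo vs read-through), the genic origin of read-through
transcription, alignment-end geometry (internal/external/clipped), breadth
of coverage over the superfamily-specific autonomy feature, and per-read
full-length transcript evidence for potentially autonomous loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_model import CompartmentMap, TELocus

logger = logging.getLogger(__name__)


@dataclass
class LongReadRecord:
    """One long-read alignment with clip geometry and spliced blocks."""

    read_id: str
    read_length: int
    chrom: str
    aln_start: int
    aln_end: int
    strand: str
    blocks: list[tuple[int, int]]
    mapped_bases: int
    clip5: int  # soft-clip at the read's 5' end (read orientation)
    clip3: int
    is_multi: bool = False

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        if self.mapped_bases + self.clip5 + self.clip3 > self.read_length:
            raise ValueError(f"read {self.read_id}: mapped+clipped bases exceed read length")

    def five_prime_position(self) -> int:
        """Biological 5' alignment position (strand-aware)."""
        return self.aln_start if self.strand == "+" else self.aln_end - 1


@dataclass
class LocusTranscriptionProfile:
    locus_id: str
    n_sense_reads: int
    start_category: Optional[str]  # All_within | All_upstream | Mix
    origin_category: Optional[str]  # exonic | intronic | no_gene
    breadth: Optional[float]
    full_length_read_ids: list[str] = field(default_factory=list)


@dataclass
class EndClassification:
    read_id: str
    locus_id: str
    end5: str  # internal | external | clipped
    end3: str


def read_long_alignments(path) -> Iterator[LongReadRecord]:
    """Stream long-read alignments from SAM/BAM (spliced, possibly secondary)."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples or []
            # soft clips in alignment orientation
            left_clip = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
            right_clip = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
            if rec.is_reverse:
                clip5, clip3 = right_clip, left_clip
            else:
                clip5, clip3 = left_clip, right_clip
            mapped = sum(l for op, l in cigar if op in (0, 7, 8))  # M/=/X ops
            length = rec.infer_read_length() or (mapped + left_clip + right_clip)
            is_multi = rec.is_secondary or (rec.has_tag("NH") and int(rec.get_tag("NH")) > 1)
            yield LongReadRecord(
                read_id=rec.query_name,
                read_length=length,
                chrom=rec.reference_name,
                aln_start=rec.reference_start,
                aln_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                blocks=[(s, e) for s, e in rec.get_blocks()],
                mapped_bases=mapped,
                clip5=clip5,
                clip3=clip3,
                is_multi=is_multi,
            )


def sense_overlap_reads(
    long_reads: Iterable[LongReadRecord], locus: TELocus
) -> list[LongReadRecord]:
    """Reads on the locus strand whose blocks overlap the locus by >= 1 bp."""
    out = []
    for read in long_reads:
        if read.chrom != locus.chrom or read.strand != locus.strand:
            continue
        if any(min(e, locus.end) > max(s, locus.start) for s, e in read.blocks):
            out.append(read)
    return out


def _initiates_upstream(read: LongReadRecord, locus: TELocus) -> bool:
    """True when the read's biological 5' start lies upstream of the locus's
    5' boundary in locus orientation."""
    p = read.five_prime_position()
    if locus.strand == "+":
        return p < locus.start
    return p >= locus.end


def start_category(sense_reads: Sequence[LongReadRecord], locus: TELocus) -> str:
    """All_within / All_upstream / Mix by strand-aware read start positions.

    A read initiates "within" unless its 5' start lies upstream of the
    locus's 5' boundary (starts downstream of the 3' boundary count as
    within-class internal starts).
    """
    if not sense_reads:
        raise ValueError("start_category requires >= 1 sense read")
    upstream = [_initiates_upstream(r, locus) for r in sense_reads]
    if all(upstream):
        return "All_upstream"
    if not any(upstream):
        return "All_within"
    return "Mix"


ORIGIN_PRIORITY = ("exonic", "intronic", "no_gene")


def origin_category(
    sense_reads: Sequence[LongReadRecord],
    locus: TELocus,
    compartment_map: CompartmentMap,
) -> Optional[str]:
    """Genic origin of read-through transcription at a locus.

    Each upstream-initiating read's 5' start is tested against the
    compartment map (exon -> exonic, intron -> intronic, else no_gene); the
    locus label is the majority, ties resolved exonic > intronic > no_gene.
    None when no read initiates upstream.
    """
    votes = {"exonic": 0, "intronic": 0, "no_gene": 0}
    n = 0
    for read in sense_reads:
        if not _initiates_upstream(read, locus):
            continue
        n += 1
        labels = {lab for lab, _g in compartment_map.labels_at(read.chrom, read.five_prime_position())}
        if "exon" in labels:
            votes["exonic"] += 1
        elif "intron" in labels:
            votes["intronic"] += 1
        else:
            votes["no_gene"] += 1
    if n == 0:
        return None
    best = max(votes.values())
    for cat in ORIGIN_PRIORITY:
        if votes[cat] == best:
            return cat
    raise AssertionError("unreachable")


def breadth_of_coverage(
    sense_reads: Iterable[LongReadRecord], feature: tuple[int, int]
) -> float:
    """|union of (read blocks intersect feature)| / |feature|."""
    fs, fe = feature
    if fe <= fs:
        raise ValueError("feature interval must be non-empty")
    covered = np.zeros(fe - fs, dtype=bool)
    for read in sense_reads:
        for s, e in read.blocks:
            lo, hi = max(s, fs), min(e, fe)
            if lo < hi:
                covered[lo - fs:hi - fs] = True
    return float(covered.mean())


def classify_ends(
    read: LongReadRecord, locus: TELocus, clip_min: int = 20
) -> EndClassification:
    """Label each read end internal / external / clipped relative to the locus.

    An end is clipped when its soft-clip is >= clip_min; otherwise external
    when the alignment extends beyond the corresponding locus boundary, and
    internal when it falls inside. Ends follow read orientation: on the -
    strand the 5' end is the rightmost aligned coordinate.
    """
    if read.strand == "+":
        pos5, pos3 = read.aln_start, read.aln_end
        out5, out3 = pos5 < locus.start, pos3 > locus.end
    else:
        pos5, pos3 = read.aln_end, read.aln_start
        out5, out3 = pos5 > locus.end, pos3 < locus.start
    end5 = "clipped" if read.clip5 >= clip_min else ("external" if out5 else "internal")
    end3 = "clipped" if read.clip3 >= clip_min else ("external" if out3 else "internal")
    return EndClassification(read_id=read.read_id, locus_id=locus.id, end5=end5, end3=end3)


def full_length_evidence(
    read: LongReadRecord,
    locus: TELocus,
    mapped_fraction_threshold: float = 0.9,
) -> bool:
    """Does a single read evidence a full-length (autonomy-competent) transcript?

    Requires the read to be at least as long as the locus's autonomy
    feature (INT for LTR-TEs, transposase ORF for TIR-TEs, the whole
    element for LINEs) and to have mapped bases >= the threshold fraction
    of its read length.
    """
    feature = locus.autonomy_feature()
    if feature is None:
        return False
    feature_length = feature[1] - feature[0]
    if read.read_length < feature_length:
        return False
    return read.mapped_bases / read.read_length >= mapped_fraction_threshold


def profile_locus(
    long_reads: Iterable[LongReadRecord],
    locus: TELocus,
    compartment_map: Optional[CompartmentMap] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> LocusTranscriptionProfile:
    """Full long-read transcription profile of one locus."""
    sense = sense_overlap_reads(long_reads, locus)
    feature = locus.autonomy_feature()
    breadth = None
    if feature is not None:
        breadth = breadth_of_coverage(sense, feature)
    elif sense:
        logger.info("locus %s: required sub-feature missing, breadth skipped", locus.id)
    cat = start_category(sense, locus) if sense else None
    origin = None
    if compartment_map is not None and sense:
        origin = origin_category(sense, locus, compartment_map)
    full = [
        r.read_id for r in sense
        if full_length_evidence(r, locus, config.mapped_fraction_threshold)
    ]
    return LocusTranscriptionProfile(
        locus_id=locus.id,
        n_sense_reads=len(sense),
        start_category=cat,
        origin_category=origin,
        breadth=breadth,
        full_length_read_ids=full,
    )


def select_autonomous_candidates(
    loci: Sequence[TELocus],
    profiles: dict[str, LocusTranscriptionProfile],
    breadth_threshold: float = 0.9,
) -> list[LocusTranscriptionProfile]:
    """Structurally intact loci whose autonomy feature has breadth above threshold.

    Each selected locus is reported with its full-length read ids, possibly
    empty: broad coverage without a qualifying contiguous read is exactly
    the "transcribed but no autonomous transcript" pattern.
    """
    out = []
    for locus in loci:
        if not locus.structurally_intact:
            continue
        prof = profiles.get(locus.id)
        if prof is None or prof.breadth is None:
            continue
        if prof.breadth > breadth_threshold:
            out.append(prof)
    return out
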