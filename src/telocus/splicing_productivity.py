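"""Alternative splicing of long-read isoforms and transcript productivity.

Isoforms are compared against their gene's reference transcript to detect
four alternative-splicing feature types — alternative 3' splicing (Alt3),
alternative 5' splicing (Alt5), intron retention (IR) and exon skipping
(ES). Features are annotated with transposable-element overlap, and each
isoform is classified by coding productivity: PRO (productive), PTC
(premature termination codon, by the 50-nt last-junction convention), NGO
(no start codon) or NST (start but no stop). For PTC isoforms carrying a
TE-overlapping retained intron, the premature stop is localised relative
to the TE's projection into transcript coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_model import TELocus, locus_interval_tree

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_BASES = frozenset("ACGTN")


@dataclass
class IsoformModel:
    """A transcript isoform: ordered exon blocks plus its spliced sequence."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    sequence: str  # spliced, transcript orientation (5'->3')

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        prev = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"isoform {self.id}: empty block [{s},{e})")
            if prev is not None and s < prev:
                raise ValueError(f"isoform {self.id}: overlapping blocks")
            prev = e
        if len(self.sequence) != sum(e - s for s, e in self.blocks):
            raise ValueError(f"isoform {self.id}: sequence length != total block length")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]

    @property
    def junctions(self) -> list[int]:
        """Transcript coordinates of exon-exon junctions (5'->3')."""
        lengths = [e - s for s, e in self.blocks]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, acc = [], 0
        for length in lengths[:-1]:
            acc += length
            out.append(acc)
        return out

    def to_transcript_coord(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position inside an exon block to a transcript offset."""
        acc = 0
        blocks = self.blocks if self.strand == "+" else self.blocks[::-1]
        for s, e in blocks:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return acc + (genomic_pos - s)
                return acc + (e - 1 - genomic_pos)
            acc += e - s
        return None

    def project_interval(self, start: int, end: int) -> Optional[tuple[int, int]]:
        """Project a genomic interval (clipped to exonic bases) into transcript
        coordinates; None when the interval has no exonic overlap."""
        positions = []
        for s, e in self.blocks:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                positions.extend(
                    (self.to_transcript_coord(lo), self.to_transcript_coord(hi - 1))
                )
        if not positions:
            return None
        return min(positions), max(positions) + 1


def make_isoform(
    isoform_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    blocks: Sequence[tuple[int, int]],
    genome: Mapping[str, str],
) -> IsoformModel:
    """Build an isoform, deriving the spliced sequence from the genome."""
    blocks = sorted(blocks)
    seq = "".join(str(genome[chrom][s:e]) for s, e in blocks).upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return IsoformModel(
        id=isoform_id, gene_id=gene_id, chrom=chrom, strand=strand,
        blocks=list(blocks), sequence=seq,
    )


@dataclass
class ASFeature:
    """One alternative-splicing feature with its genomic footprint."""

    type: str  # Alt3 | Alt5 | IR | ES
    chrom: str
    start: int
    end: int
    isoform_ids: list[str] = field(default_factory=list)
    te_overlaps: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class ProductivityCall:
    isoform_id: str
    klass: str  # PRO | PTC | NGO | NST
    start_pos: Optional[int] = None  # transcript coordinate of ATG
    stop_pos: Optional[int] = None  # transcript coordinate of stop codon start
    stop_vs_te: str = "n/a"  # within | before | after | n/a
    distance_bp: Optional[int] = None


def detect_as_features(
    isoform: IsoformModel, reference: IsoformModel
) -> list[ASFeature]:
    """Alternative-splicing features of an isoform versus its reference.

    IR: a reference intron fully exonic in the isoform. ES: a reference
    exon absent from the isoform while an isoform intron spans it.
    Alt3/Alt5: a junction sharing one edge with a reference junction but
    shifted at the other; the delta interval is the feature, typed by which
    edge moved in transcript orientation (3' acceptor vs 5' donor).
    """
    if isoform.chrom != reference.chrom or isoform.strand != reference.strand:
        raise ValueError("isoform and reference must share chromosome and strand")
    features: list[ASFeature] = []
    chrom = isoform.chrom
    iso_introns = isoform.introns
    ref_introns = reference.introns

    def exonic_in(model: IsoformModel, start: int, end: int) -> bool:
        covered = 0
        for s, e in model.blocks:
            covered += max(0, min(e, end) - max(s, start))
        return covered == end - start

    for rs, re_ in ref_introns:
        if exonic_in(isoform, rs, re_):
            features.append(ASFeature("IR", chrom, rs, re_, [isoform.id]))

    es_introns: set[tuple[int, int]] = set()
    for xs, xe in reference.blocks:
        overlaps_exon = any(min(e, xe) > max(s, xs) for s, e in isoform.blocks)
        spanning = [iv for iv in iso_introns if iv[0] <= xs and xe <= iv[1]]
        if not overlaps_exon and spanning:
            features.append(ASFeature("ES", chrom, xs, xe, [isoform.id]))
            es_introns.update(spanning)

    for is_, ie in iso_introns:
        if (is_, ie) in es_introns:
            continue  # an exon-skipping junction, not a shifted splice site
        for rs, re_ in ref_introns:
            if min(ie, re_) <= max(is_, rs):
                continue
            if is_ == rs and ie != re_:
                # genomic end edge shifted: acceptor on +, donor on -
                ftype = "Alt3" if isoform.strand == "+" else "Alt5"
                features.append(
                    ASFeature(ftype, chrom, min(ie, re_), max(ie, re_), [isoform.id])
                )
            elif ie == re_ and is_ != rs:
                ftype = "Alt5" if isoform.strand == "+" else "Alt3"
                features.append(
                    ASFeature(ftype, chrom, min(is_, rs), max(is_, rs), [isoform.id])
                )
    return features


def annotate_te_overlap(
    features: Iterable[ASFeature], te_loci: Sequence[TELocus]
) -> list[ASFeature]:
    """Record every >=1 bp TE intersection on each feature."""
    trees = locus_interval_tree(te_loci)
    out = []
    for feat in features:
        tree = trees.get(feat.chrom)
        feat.te_overlaps = []
        if tree is not None:
            for iv in sorted(tree.overlap(feat.start, feat.end)):
                ov = min(feat.end, iv.end) - max(feat.start, iv.begin)
                if ov > 0:
                    feat.te_overlaps.append((iv.data.id, ov))
        out.append(feat)
    return out


def classify_productivity(
    isoform: IsoformModel, config: AnalysisConfig = DEFAULT_CONFIG
) -> ProductivityCall:
    """Coding-productivity class of an isoform.

    Translation is assumed to start at the first ATG of the spliced
    sequence. No ATG -> NGO; no in-frame stop -> NST; an in-frame stop at
    least ``ptc_junction_rule_nt`` nt upstream of the final exon-exon
    junction -> PTC; otherwise PRO.
    """
    seq = isoform.sequence.upper()
    if set(seq) - VALID_BASES:
        raise ValueError(f"isoform {isoform.id}: sequence contains non-ACGTN characters")
    start = seq.find("ATG")
    if start == -1:
        return ProductivityCall(isoform_id=isoform.id, klass="NGO")
    stop = None
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos:pos + 3] in STOP_CODONS:
            stop = pos
            break
    if stop is None:
        return ProductivityCall(isoform_id=isoform.id, klass="NST", start_pos=start)
    junctions = isoform.junctions
    if junctions:
        last_junction = junctions[-1]
        if last_junction - (stop + 3) >= config.ptc_junction_rule_nt:
            return ProductivityCall(
                isoform_id=isoform.id, klass="PTC", start_pos=start, stop_pos=stop
            )
    return ProductivityCall(
        isoform_id=isoform.id, klass="PRO", start_pos=start, stop_pos=stop
    )


def locate_stop_vs_te(
    call: ProductivityCall,
    isoform: IsoformModel,
    ir_feature: ASFeature,
    te_locus: TELocus,
) -> ProductivityCall:
    """Place a PTC isoform's premature stop relative to a TE inside a
    retained intron.

    The TE's exonic footprint within the IR feature is projected into
    transcript coordinates and compared with the stop codon: "within" when
    the stop codon starts inside the projection, otherwise "before"
    (stop 5' of the TE) or "after", with the transcript-coordinate gap in
    ``distance_bp``.
    """
    if call.klass != "PTC" or call.stop_pos is None:
        raise ValueError("locate_stop_vs_te applies to PTC calls only")
    if ir_feature.type != "IR":
        raise ValueError("feature must be an intron-retention feature")
    te_start = max(ir_feature.start, te_locus.start)
    te_end = min(ir_feature.end, te_locus.end)
    if te_end <= te_start:
        raise ValueError("TE does not overlap the IR feature")
    proj = isoform.project_interval(te_start, te_end)
    if proj is None:
        raise ValueError("TE footprint is not exonic in the isoform")
    t_start, t_end = proj
    stop = call.stop_pos
    if t_start <= stop < t_end:
        call.stop_vs_te, call.distance_bp = "within", None
    elif stop < t_start:
        call.stop_vs_te, call.distance_bp = "before", t_start - stop
    else:
        call.stop_vs_te, call.distance_bp = "after", stop - t_end + 1
    return call
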