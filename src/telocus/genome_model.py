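"""Core genomic data model: annotations, alignments, genome compartments.

All coordinates are 0-based half-open internally; GFF3 (1-based closed) and
SAM (1-based) are converted at the I/O boundary. BED input needs no
conversion.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam
from intervaltree import IntervalTree

SUPERFAMILIES = ("Copia", "Gypsy", "LINE", "hAT", "MULE", "Harbinger", "CACTA", "other")
LTR_SUPERFAMILIES = frozenset({"Copia", "Gypsy"})
TIR_SUPERFAMILIES = frozenset({"hAT", "MULE", "Harbinger", "CACTA"})
SUB_FEATURE_TYPES = ("LTR5", "LTR3", "INT", "ORF")

MAPQ_UNIQUE_FALLBACK = 10  # unique-count tools default-filter at MAPQ 10


@dataclass
class TELocus:
    """An annotated transposable-element interval.

    ``sub_features`` maps feature type (LTR5/LTR3/INT/ORF) to a 0-based
    half-open interval on the same chromosome, contained in the locus.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    superfamily: str
    canonical_length: int
    sub_features: dict[str, tuple[int, int]] = field(default_factory=dict)
    structurally_intact: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TE locus {self.id}: start must be < end")
        if self.canonical_length <= 0:
            raise ValueError(f"TE locus {self.id}: canonical_length must be > 0")
        for name, (s, e) in self.sub_features.items():
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"TE locus {self.id}: sub-feature {name} [{s},{e}) outside locus bounds"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def integrity(self) -> float:
        """Genomic span as a fraction of the canonical element length."""
        return self.length / self.canonical_length

    @property
    def is_ltr_te(self) -> bool:
        return self.superfamily in LTR_SUPERFAMILIES

    @property
    def is_tir_te(self) -> bool:
        return self.superfamily in TIR_SUPERFAMILIES

    def autonomy_feature(self) -> Optional[tuple[int, int]]:
        """Interval whose transcription is required for autonomy.

        INT domain for LTR retrotransposons, transposase ORF for DNA (TIR)
        transposons, the whole locus for LINEs. None when the required
        sub-feature is absent from the annotation.
        """
        if self.is_ltr_te:
            return self.sub_features.get("INT")
        if self.is_tir_te:
            return self.sub_features.get("ORF")
        if self.superfamily == "LINE":
            return (self.start, self.end)
        return self.sub_features.get("ORF") or self.sub_features.get("INT")


@dataclass
class GeneModel:
    """A gene unit: exons and introns bounded by transcription start/stop."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"Gene {self.id}: start must be < end")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"Gene {self.id}: exon [{s},{e}) outside gene bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"Gene {self.id}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]


@dataclass
class ShortReadAlignment:
    """One reported alignment of one mate of a paired-end short read."""

    read_id: str
    mate_index: int
    chrom: str
    start: int
    end: int
    strand: str
    is_unique: bool
    n_hits: int
    mate_maps_to_te_library: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"Alignment {self.read_id}/{self.mate_index}: start must be < end")


#: Compartment labels in assignment-priority order (highest first).
LOCATION_PRIORITY = ("exon", "intron", "N-flank", "C-flank")


class CompartmentMap:
    """Per-chromosome interval index of genomic compartments.

    Every base maps to >=1 of {exon, intron, N-flank, C-flank} (each tagged
    with its owning gene) or, when covered by none, is intergenic.
    Overlapping genes may stack labels; downstream assignment resolves by
    priority.
    """

    def __init__(self, chrom_lengths: dict[str, int], flank_width: int = 2000) -> None:
        self.chrom_lengths = dict(chrom_lengths)
        self.flank_width = flank_width
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}
        self.gene_starts: dict[str, int] = {}

    def add_label(self, chrom: str, start: int, end: int, label: str, gene_id: str) -> None:
        if start < end:
            self._trees[chrom].addi(start, end, (label, gene_id))

    def overlaps(self, chrom: str, start: int, end: int) -> list[tuple[str, str, int]]:
        """All (label, gene_id, overlap_bp) records intersecting [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start, end):
            label, gene_id = iv.data
            ov = min(end, iv.end) - max(start, iv.begin)
            if ov > 0:
                out.append((label, gene_id, ov))
        return out

    def labels_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """(label, gene_id) pairs covering a single position."""
        return [(lab, gid) for lab, gid, _ in self.overlaps(chrom, pos, pos + 1)]


def build_compartments(
    genes: Iterable[GeneModel],
    chrom_lengths: dict[str, int],
    flank_width: int = 2000,
) -> CompartmentMap:
    """Compartmentalise the genome around gene units.

    The gene unit [start, end) is tiled by its exons and introns. The
    N-flank covers ``flank_width`` bp upstream of the transcription start
    and the C-flank the same downstream of the stop, strand-aware and
    truncated at chromosome bounds.
    """
    cmap = CompartmentMap(chrom_lengths, flank_width)
    for gene in genes:
        clen = chrom_lengths[gene.chrom]
        cmap.gene_starts[gene.id] = gene.start
        for s, e in gene.exons:
            cmap.add_label(gene.chrom, s, e, "exon", gene.id)
        for s, e in gene.introns:
            cmap.add_label(gene.chrom, s, e, "intron", gene.id)
        left = (max(0, gene.start - flank_width), gene.start)
        right = (gene.end, min(clen, gene.end + flank_width))
        if gene.strand == "+":
            n_flank, c_flank = left, right
        else:
            n_flank, c_flank = right, left
        cmap.add_label(gene.chrom, n_flank[0], n_flank[1], "N-flank", gene.id)
        cmap.add_label(gene.chrom, c_flank[0], c_flank[1], "C-flank", gene.id)
    return cmap


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_gene_annotation(path) -> list[GeneModel]:
    """Read gene models from GFF3.

    Multi-transcript genes are collapsed to the exon chain of their primary
    (longest) transcript. Coordinates are converted from 1-based closed to
    0-based half-open.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 at line {lineno} (expected 9 columns)")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric coordinates at line {lineno}") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: gene without ID at line {lineno}")
                genes[gid] = {"chrom": chrom, "start": start0, "end": end0,
                              "strand": strand, "transcripts": []}
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attr.get("ID"), attr.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}: transcript without ID/Parent at line {lineno}")
                transcripts[tid] = {"gene": parent, "start": start0, "end": end0, "exons": []}
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}: exon without Parent at line {lineno}")
                for tid in parent.split(","):
                    if tid in transcripts:
                        transcripts[tid]["exons"].append((start0, end0))
                    elif tid in genes:
                        # exon attached directly to a gene: treat the gene as
                        # a single implicit transcript
                        tkey = tid + ".implicit"
                        transcripts.setdefault(
                            tkey, {"gene": tid, "start": genes[tid]["start"],
                                   "end": genes[tid]["end"], "exons": []}
                        )["exons"].append((start0, end0))
                    else:
                        raise ValueError(f"{path}: exon with unknown Parent {tid!r} at line {lineno}")
    for trec in transcripts.values():
        genes[trec["gene"]].setdefault("transcripts", []).append(trec)
    out = []
    for gid, grec in genes.items():
        trs = grec["transcripts"]
        if trs:
            primary = max(trs, key=lambda t: t["end"] - t["start"])
            exons = sorted(primary["exons"])
        else:
            exons = [(grec["start"], grec["end"])]
        out.append(
            GeneModel(id=gid, chrom=grec["chrom"], start=grec["start"],
                      end=grec["end"], strand=grec["strand"], exons=exons)
        )
    return out


def read_te_annotation(
    path,
    canonical_lengths,
    sub_features=None,
) -> list[TELocus]:
    """Read TE loci from BED6 with a companion family table.

    Parameters
    ----------
    path
        BED6 file: chrom, start, end, name, score, strand. ``name`` is
        ``locus_id|family`` or just the family (locus ids are then derived
        from coordinates); a score of ``1`` flags a structurally intact
        locus.
    canonical_lengths
        TSV path or DataFrame with columns family, superfamily,
        canonical_length.
    sub_features
        Optional TSV path or DataFrame with columns locus_id, feature
        (LTR5/LTR3/INT/ORF), start, end (0-based half-open).
    """
    if not isinstance(canonical_lengths, pd.DataFrame):
        canonical_lengths = pd.read_csv(canonical_lengths, sep="\t")
    fam_table = canonical_lengths.set_index("family")

    sub_map: dict[str, dict[str, tuple[int, int]]] = {}
    if sub_features is not None:
        if not isinstance(sub_features, pd.DataFrame):
            sub_features = pd.read_csv(sub_features, sep="\t")
        for row in sub_features.itertuples(index=False):
            sub_map.setdefault(str(row.locus_id), {})[str(row.feature)] = (
                int(row.start), int(row.end)
            )

    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "score": str, "strand": str},
    )
    unknown = set()
    loci = []
    for row in bed.itertuples(index=False):
        name = row.name
        if "|" in name:
            locus_id, family = name.split("|", 1)
        else:
            family = name
            locus_id = f"{family}_{row.chrom}_{row.start}-{row.end}"
        if family not in fam_table.index:
            unknown.add(family)
            continue
        frec = fam_table.loc[family]
        loci.append(
            TELocus(
                id=locus_id, chrom=row.chrom, start=int(row.start), end=int(row.end),
                strand=row.strand, family=family, superfamily=str(frec["superfamily"]),
                canonical_length=int(frec["canonical_length"]),
                sub_features=sub_map.get(locus_id, {}),
                structurally_intact=str(row.score) == "1",
            )
        )
    if unknown:
        raise ValueError(
            "TE annotation families missing from canonical-length table: "
            + ", ".join(sorted(unknown))
        )
    return loci


def read_alignments(path, require_index: bool = False) -> Iterator[ShortReadAlignment]:
    """Stream mapped short-read alignments from SAM/BAM.

    Uniqueness resolves from the NH tag (NH==1) when present, otherwise
    MAPQ >= 10. Unmapped records are skipped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, require_index=require_index) as af:
        for rec in af.fetch(until_eof=not require_index):
            if rec.is_unmapped:
                continue
            if rec.has_tag("NH"):
                n_hits = int(rec.get_tag("NH"))
                is_unique = n_hits == 1
            else:
                is_unique = rec.mapping_quality >= MAPQ_UNIQUE_FALLBACK
                n_hits = 1 if is_unique else 2
            yield ShortReadAlignment(
                read_id=rec.query_name,
                mate_index=2 if rec.is_read2 else 1,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                is_unique=is_unique,
                n_hits=n_hits,
            )


def locus_interval_tree(loci: Iterable[TELocus]) -> dict[str, IntervalTree]:
    """Index TE loci by chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, locus)
    return trees
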