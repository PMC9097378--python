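"""Synthetic genomes, annotations, alignments and count matrices.

Every dataset comes with a truth manifest sufficient to predict each
pipeline stage's output, so the whole analysis is testable without any
external download. Alignments are authored directly (no aligner in the
loop): read multiplicity, mate structure, soft-clips and spliced blocks
are planted, which isolates the pipeline's logic from aligner behaviour.

Everything is deterministic under a fixed (plan, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_model import GeneModel, ShortReadAlignment, TELocus
from .longread_transcription import LongReadRecord

BASES = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

COMPARTMENTS = ("exon", "intron", "N-flank", "C-flank", "intergenic")

#: archetype -> log2 fold-change at (1h, 3h, 6h, 12h)
DE_ARCHETYPES: dict[str, tuple[float, float, float, float]] = {
    "up-back": (1.5, 2.5, 1.0, 0.0),
    "up": (0.8, 1.6, 2.2, 2.6),
    "down": (-0.8, -1.6, -2.2, -2.6),
    "flat": (0.0, 0.0, 0.0, 0.0),
}


@dataclass
class FamilyPlan:
    """Placement plan for one TE family."""

    name: str
    superfamily: str
    canonical_length: int
    ltr_length: int = 0  # >0 only for LTR superfamilies
    orf_length: int = 0  # >0 only for TIR superfamilies
    ltr_divergence: float = 0.02  # planted per-site divergence between the LTRs
    #: compartment -> (n_fragmented, n_full_length)
    quotas: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return sum(f + fl for f, fl in self.quotas.values())


@dataclass
class SimulationPlan:
    n_chromosomes: int = 2
    chromosome_length: int = 250_000
    n_genes: int = 24
    exons_per_gene: int = 3
    exon_length: int = 400
    intron_length: int = 3000
    flank_width: int = 2000
    families: list[FamilyPlan] = field(default_factory=list)
    short_read_length: int = 100
    long_read_min: int = 500
    long_read_max: int = 6000
    nb_dispersion: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.families:
            self.families = default_families()
        for fam in self.families:
            if any(f < 0 or fl < 0 for f, fl in fam.quotas.values()):
                raise ValueError(f"family {fam.name}: negative quota")


def default_families() -> list[FamilyPlan]:
    """A small mixed-superfamily TE complement."""
    return [
        FamilyPlan(
            name="Copia-S1", superfamily="Copia", canonical_length=2000,
            ltr_length=300, ltr_divergence=0.02,
            quotas={"intron": (4, 3), "intergenic": (4, 2), "N-flank": (2, 0)},
        ),
        FamilyPlan(
            name="Gypsy-S1", superfamily="Gypsy", canonical_length=2400,
            ltr_length=350, ltr_divergence=0.05,
            quotas={"intron": (3, 2), "intergenic": (5, 2), "C-flank": (2, 0)},
        ),
        FamilyPlan(
            name="LINE-S1", superfamily="LINE", canonical_length=1800,
            quotas={"intron": (4, 1), "exon": (1, 0), "intergenic": (4, 1)},
        ),
        FamilyPlan(
            name="hAT-S1", superfamily="hAT", canonical_length=1500, orf_length=900,
            quotas={"intron": (3, 2), "intergenic": (3, 1)},
        ),
    ]


@dataclass
class TruthManifest:
    """Planted ground truth keyed to locus/gene/read ids."""

    seed: int
    locus_compartment: dict[str, str] = field(default_factory=dict)
    locus_family: dict[str, str] = field(default_factory=dict)
    locus_integrity: dict[str, float] = field(default_factory=dict)
    locus_full_length: dict[str, bool] = field(default_factory=dict)
    locus_intact: dict[str, bool] = field(default_factory=dict)
    locus_ltr_divergence: dict[str, float] = field(default_factory=dict)
    locus_host_gene: dict[str, Optional[str]] = field(default_factory=dict)
    # short-read plan
    locus_unique_reads: dict[str, int] = field(default_factory=dict)
    locus_multi_reads: dict[str, int] = field(default_factory=dict)
    locus_danglers: dict[str, tuple[int, int]] = field(default_factory=dict)
    expressed_loci: list[str] = field(default_factory=list)
    # long-read plan
    locus_start_category: dict[str, str] = field(default_factory=dict)
    locus_origin_category: dict[str, str] = field(default_factory=dict)
    full_length_reads: dict[str, list[str]] = field(default_factory=dict)
    # counts plan
    feature_archetype: dict[str, str] = field(default_factory=dict)
    gene_expressed: dict[str, bool] = field(default_factory=dict)
    pair_concordant: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    genes: list[GeneModel]
    te_loci: list[TELocus]
    canonical_seqs: dict[str, str]
    manifest: TruthManifest
    plan: SimulationPlan

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate_sequence(
    seq: str, divergence: float, rng: np.random.Generator, ts_tv: float = 2.0
) -> str:
    """Introduce substitutions at the given per-site rate with a
    transition:transversion ratio (default 2:1)."""
    out = list(seq)
    p_ts = ts_tv / (ts_tv + 1.0)
    for i in range(len(out)):
        if rng.random() < divergence:
            base = out[i]
            if rng.random() < p_ts:
                out[i] = TRANSITION[base]
            else:
                out[i] = TRANSVERSIONS[base][rng.integers(0, 2)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def generate_reference(plan: SimulationPlan, seed: int) -> SyntheticReference:
    """Genome + gene/TE annotations with quota-controlled TE placement.

    Genes are laid out on a regular grid, alternating strand, leaving
    intergenic space beyond the flanks. TE loci are carved into the
    compartment their quota names; structurally intact LTR/TIR loci get
    LTR5/INT/LTR3 or ORF sub-features, with the 3' LTR mutated away from
    the 5' LTR at the planted divergence.
    """
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed)

    gene_span = plan.exons_per_gene * plan.exon_length + (plan.exons_per_gene - 1) * plan.intron_length
    slot = gene_span + 2 * plan.flank_width + 6000  # flanks + intergenic gap
    genes: list[GeneModel] = []
    chrom_names = [f"chr{i + 1}" for i in range(plan.n_chromosomes)]
    genome_arrays = {c: list(_random_seq(rng, plan.chromosome_length)) for c in chrom_names}

    per_chrom = int(np.ceil(plan.n_genes / plan.n_chromosomes))
    gi = 0
    for chrom in chrom_names:
        for k in range(per_chrom):
            if gi >= plan.n_genes:
                break
            start = plan.flank_width + 1000 + k * slot
            if start + gene_span + plan.flank_width + 1000 > plan.chromosome_length:
                raise ValueError("infeasible plan: genes do not fit on the chromosome")
            exons = []
            pos = start
            for _ in range(plan.exons_per_gene):
                exons.append((pos, pos + plan.exon_length))
                pos += plan.exon_length + plan.intron_length
            end = exons[-1][1]
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(GeneModel(id=f"gene{gi + 1}", chrom=chrom, start=start,
                                   end=end, strand=strand, exons=exons))
            gi += 1

    # canonical sequences per family
    canonical: dict[str, str] = {}
    for fam in plan.families:
        canonical[fam.name] = _random_seq(rng, fam.canonical_length)

    # available placement slots per compartment
    slots: dict[str, list[tuple[str, int, int, Optional[GeneModel]]]] = {c: [] for c in COMPARTMENTS}
    for gene in genes:
        for s, e in gene.exons:
            slots["exon"].append((gene.chrom, s, e, gene))
        for s, e in gene.introns:
            slots["intron"].append((gene.chrom, s, e, gene))
        left = (gene.start - plan.flank_width, gene.start)
        right = (gene.end, gene.end + plan.flank_width)
        nf, cf = (left, right) if gene.strand == "+" else (right, left)
        slots["N-flank"].append((gene.chrom, nf[0], nf[1], gene))
        slots["C-flank"].append((gene.chrom, cf[0], cf[1], gene))
    # intergenic: gaps between gene-flank envelopes
    for chrom in chrom_names:
        envelopes = sorted(
            (g.start - plan.flank_width, g.end + plan.flank_width)
            for g in genes if g.chrom == chrom
        )
        prev = 0
        for s, e in envelopes + [(plan.chromosome_length, plan.chromosome_length)]:
            if s - prev > 200:
                slots["intergenic"].append((chrom, prev + 100, s - 100, None))
            prev = max(prev, e)

    cursor = {c: 0 for c in COMPARTMENTS}
    offset_in_slot = {c: {} for c in COMPARTMENTS}
    te_loci: list[TELocus] = []

    def place(compartment: str, length: int) -> tuple[str, int, Optional[GeneModel]]:
        pool = slots[compartment]
        tried = 0
        while tried < len(pool):
            idx = cursor[compartment] % len(pool)
            chrom, s, e, gene = pool[idx]
            used = offset_in_slot[compartment].get(idx, s)
            if used + length + 50 <= e:
                offset_in_slot[compartment][idx] = used + length + 50
                cursor[compartment] += 1
                return chrom, used, gene
            cursor[compartment] += 1
            tried += 1
        raise ValueError(f"infeasible plan: no room for a {length} bp TE in {compartment}")

    def max_room(compartment: str) -> int:
        pool = slots[compartment]
        best = 0
        for idx, (_c, s, e, _g) in enumerate(pool):
            used = offset_in_slot[compartment].get(idx, s)
            best = max(best, e - used - 50)
        return best

    locus_counter = 0
    for fam in plan.families:
        for compartment, (n_frag, n_full) in fam.quotas.items():
            for is_full in [False] * n_frag + [True] * n_full:
                locus_counter += 1
                locus_id = f"{fam.name}_L{locus_counter:03d}"
                if is_full:
                    length = fam.canonical_length
                else:
                    length = int(fam.canonical_length * rng.uniform(0.2, 0.6))
                    # fragments shrink to the roomiest remaining slot
                    room = max_room(compartment)
                    if room < 100:
                        raise ValueError(
                            f"infeasible plan: no room for a TE in {compartment}"
                        )
                    length = min(length, room)
                chrom, start, gene = place(compartment, length)
                end = start + length
                strand = "+" if rng.random() < 0.5 else "-"
                sub = {}
                intact = False
                divergence = None
                if is_full and fam.ltr_length > 0:
                    intact = True
                    divergence = fam.ltr_divergence
                    ltr5 = canonical[fam.name][: fam.ltr_length]
                    internal = canonical[fam.name][fam.ltr_length: fam.canonical_length - fam.ltr_length]
                    ltr3 = mutate_sequence(ltr5, divergence, rng)
                    seq = ltr5 + internal + ltr3
                    genome_arrays[chrom][start:end] = list(seq)
                    sub = {
                        "LTR5": (start, start + fam.ltr_length),
                        "INT": (start + fam.ltr_length, end - fam.ltr_length),
                        "LTR3": (end - fam.ltr_length, end),
                    }
                elif is_full and fam.orf_length > 0:
                    intact = True
                    orf_start = start + (length - fam.orf_length) // 2
                    sub = {"ORF": (orf_start, orf_start + fam.orf_length)}
                    genome_arrays[chrom][start:end] = list(canonical[fam.name][:length])
                else:
                    frag = canonical[fam.name][:length]
                    genome_arrays[chrom][start:end] = list(mutate_sequence(frag, 0.05, rng))
                locus = TELocus(
                    id=locus_id, chrom=chrom, start=start, end=end, strand=strand,
                    family=fam.name, superfamily=fam.superfamily,
                    canonical_length=fam.canonical_length,
                    sub_features=sub, structurally_intact=intact,
                )
                te_loci.append(locus)
                manifest.locus_compartment[locus_id] = compartment
                manifest.locus_family[locus_id] = fam.name
                manifest.locus_integrity[locus_id] = locus.integrity
                manifest.locus_full_length[locus_id] = locus.integrity > 0.9
                manifest.locus_intact[locus_id] = intact
                manifest.locus_host_gene[locus_id] = gene.id if gene is not None else None
                if divergence is not None:
                    manifest.locus_ltr_divergence[locus_id] = divergence

    genome = {c: "".join(arr) for c, arr in genome_arrays.items()}
    return SyntheticReference(
        genome=genome, genes=genes, te_loci=te_loci,
        canonical_seqs=canonical, manifest=manifest, plan=plan,
    )


# ---------------------------------------------------------------------------
# Annotation / sequence writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n")
            tid = f"{g.id}.t1"
            fh.write(f"{g.chrom}\tsynth\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n")


def write_te_bed(
    te_loci: Sequence[TELocus], bed_path, families_path=None, sub_features_path=None
) -> None:
    with open(bed_path, "w") as fh:
        for t in te_loci:
            score = "1" if t.structurally_intact else "0"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}|{t.family}\t{score}\t{t.strand}\n")
    if families_path is not None:
        rows = {}
        for t in te_loci:
            rows[t.family] = (t.superfamily, t.canonical_length)
        with open(families_path, "w") as fh:
            fh.write("family\tsuperfamily\tcanonical_length\n")
            for fam in sorted(rows):
                sf, cl = rows[fam]
                fh.write(f"{fam}\t{sf}\t{cl}\n")
    if sub_features_path is not None:
        with open(sub_features_path, "w") as fh:
            fh.write("locus_id\tfeature\tstart\tend\n")
            for t in te_loci:
                for name, (s, e) in sorted(t.sub_features.items()):
                    fh.write(f"{t.id}\t{name}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Short-read alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class ShortReadPlan:
    """Planted per-locus short-read evidence.

    ``multi_groups`` lists sets of locus ids that share multi-mapping
    reads; each group's loci receive the same reads (one reported
    alignment per locus, NH = group size x reads).
    """

    unique_reads: dict[str, int] = field(default_factory=dict)
    multi_reads: dict[str, int] = field(default_factory=dict)  # per locus via its group
    multi_groups: list[list[str]] = field(default_factory=list)
    internal_multi: dict[str, int] = field(default_factory=dict)  # NH>1, one placement emitted
    danglers: dict[str, tuple[int, int]] = field(default_factory=dict)  # (left, right)
    boundary_reads: dict[str, int] = field(default_factory=dict)  # straddling locus start


@dataclass
class ShortReadDataset:
    alignments: list[ShortReadAlignment]
    te_library_hits: set[str]

    def write_sam(self, path, chrom_lengths: Mapping[str, int]) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            refs = {c: i for i, c in enumerate(chrom_lengths)}
            for aln in self.alignments:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = aln.read_id
                rec.reference_id = refs[aln.chrom]
                rec.reference_start = aln.start
                length = aln.end - aln.start
                rec.cigarstring = f"{length}M"
                rec.query_sequence = "A" * length
                rec.query_qualities = pysam.qualitystring_to_array("I" * length)
                rec.mapping_quality = 60 if aln.is_unique else 1
                rec.flag = (64 if aln.mate_index == 1 else 128) | 1
                if aln.strand == "-":
                    rec.flag |= 16
                rec.set_tag("NH", aln.n_hits)
                out.write(rec)


def default_short_read_plan(reference: SyntheticReference, rng: np.random.Generator) -> ShortReadPlan:
    """Plant expression on a deterministic subset of loci.

    Every third locus is "expressed" with 15-40 unique reads; one
    full-length family group shares multi-reads; a couple of loci get
    dangler support only.
    """
    plan = ShortReadPlan()
    loci = reference.te_loci
    for i, locus in enumerate(loci):
        if i % 3 == 0:
            plan.unique_reads[locus.id] = int(rng.integers(15, 41))
    # multi-mapping group: intact loci of the first LTR family
    fam = reference.plan.families[0].name
    group = [l.id for l in loci if l.family == fam and l.structurally_intact]
    if len(group) >= 2:
        plan.multi_groups.append(group)
        # enough shared reads that mean depth clears the coverage filter
        n = int(rng.integers(130, 170))
        for lid in group:
            plan.multi_reads[lid] = n
    # dangler-only loci: first two loci with no unique reads planted
    dangler_only = [
        l.id for l in loci if l.id not in plan.unique_reads and l.id not in group
    ][:2]
    for lid in dangler_only:
        plan.danglers[lid] = (int(rng.integers(12, 20)), int(rng.integers(12, 20)))
        plan.internal_multi[lid] = 15  # internal support for filter 3
    return plan


def simulate_short_read_alignments(
    reference: SyntheticReference,
    plan: Optional[ShortReadPlan],
    seed: int,
) -> ShortReadDataset:
    """Author paired-end alignment records per the planted evidence."""
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = default_short_read_plan(reference, rng)
    rl = reference.plan.short_read_length
    alignments: list[ShortReadAlignment] = []
    te_hits: set[str] = set()
    loci = {l.id: l for l in reference.te_loci}
    counter = 0

    def spread_starts(locus: TELocus, n: int) -> np.ndarray:
        span = max(1, locus.length - rl)
        return locus.start + (np.arange(n) * max(1, span // max(n, 1))) % span

    for lid, n in sorted(plan.unique_reads.items()):
        locus = loci[lid]
        for s in spread_starts(locus, n):
            counter += 1
            alignments.append(ShortReadAlignment(
                read_id=f"u{counter}", mate_index=1, chrom=locus.chrom,
                start=int(s), end=int(s) + min(rl, locus.length), strand="+",
                is_unique=True, n_hits=1,
            ))
    for group in plan.multi_groups:
        n = plan.multi_reads[group[0]]
        n_hits = len(group)
        for j in range(n):
            counter += 1
            rid = f"m{counter}"
            for lid in group:
                locus = loci[lid]
                span = max(1, locus.length - rl)
                s = locus.start + (j * max(1, span // max(n, 1))) % span
                alignments.append(ShortReadAlignment(
                    read_id=rid, mate_index=1, chrom=locus.chrom,
                    start=int(s), end=int(s) + min(rl, locus.length), strand="+",
                    is_unique=n_hits == 1, n_hits=n_hits,
                ))
    for lid, n in sorted(plan.internal_multi.items()):
        locus = loci[lid]
        for s in spread_starts(locus, n):
            counter += 1
            alignments.append(ShortReadAlignment(
                read_id=f"im{counter}", mate_index=1, chrom=locus.chrom,
                start=int(s), end=int(s) + min(rl, locus.length), strand="+",
                is_unique=False, n_hits=2,
            ))
    for lid, (n_left, n_right) in sorted(plan.danglers.items()):
        locus = loci[lid]
        for j in range(n_left):
            counter += 1
            rid = f"d{counter}"
            end = locus.start - 10 - (j % 5)
            alignments.append(ShortReadAlignment(
                read_id=rid, mate_index=1, chrom=locus.chrom,
                start=end - rl, end=end, strand="+", is_unique=True, n_hits=1,
            ))
            te_hits.add(rid)
        for j in range(n_right):
            counter += 1
            rid = f"d{counter}"
            start = locus.end + 10 + (j % 5)
            alignments.append(ShortReadAlignment(
                read_id=rid, mate_index=1, chrom=locus.chrom,
                start=start, end=start + rl, strand="-", is_unique=True, n_hits=1,
            ))
            te_hits.add(rid)
    for lid, n in sorted(plan.boundary_reads.items()):
        locus = loci[lid]
        for _ in range(n):
            counter += 1
            alignments.append(ShortReadAlignment(
                read_id=f"b{counter}", mate_index=1, chrom=locus.chrom,
                start=locus.start - rl // 2, end=locus.start + rl // 2,
                strand="+", is_unique=True, n_hits=1,
            ))
    # record the plan in the manifest
    m = reference.manifest
    m.locus_unique_reads = dict(plan.unique_reads)
    m.locus_multi_reads = dict(plan.multi_reads)
    for lid, n in plan.internal_multi.items():
        m.locus_multi_reads[lid] = m.locus_multi_reads.get(lid, 0) + n
    m.locus_danglers = dict(plan.danglers)
    m.expressed_loci = sorted(
        set(plan.unique_reads) | set(plan.multi_reads)
        | set(plan.internal_multi) | set(plan.danglers)
    )
    return ShortReadDataset(alignments=alignments, te_library_hits=te_hits)


# ---------------------------------------------------------------------------
# Long-read alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class LongReadSpec:
    """Planted long-read structure at one locus."""

    locus_id: str
    n_within: int = 0
    n_upstream: int = 0
    upstream_offset: int = 500  # bp upstream of the locus 5' boundary
    clip3: int = 0
    full_length: bool = False  # emit one read spanning the autonomy feature


@dataclass
class LongReadDataset:
    reads: list[LongReadRecord]

    def write_sam(self, path, chrom_lengths: Mapping[str, int]) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            refs = {c: i for i, c in enumerate(chrom_lengths)}
            for read in self.reads:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read.read_id
                rec.reference_id = refs[read.chrom]
                rec.reference_start = read.aln_start
                cig = []
                clip_left = read.clip5 if read.strand == "+" else read.clip3
                clip_right = read.clip3 if read.strand == "+" else read.clip5
                if clip_left:
                    cig.append((4, clip_left))
                prev_end = None
                for s, e in read.blocks:
                    if prev_end is not None and s > prev_end:
                        cig.append((3, s - prev_end))
                    cig.append((0, e - s))
                    prev_end = e
                if clip_right:
                    cig.append((4, clip_right))
                rec.cigartuples = cig
                qlen = sum(l for op, l in cig if op in (0, 4))
                rec.query_sequence = "A" * qlen
                rec.mapping_quality = 1 if read.is_multi else 60
                rec.flag = 16 if read.strand == "-" else 0
                rec.set_tag("NH", 2 if read.is_multi else 1)
                out.write(rec)


def simulate_long_read_alignments(
    reference: SyntheticReference,
    specs: Sequence[LongReadSpec],
    seed: int,
) -> LongReadDataset:
    """Author long-read alignments with planted starts, clips and blocks."""
    rng = np.random.default_rng(seed)
    loci = {l.id: l for l in reference.te_loci}
    reads: list[LongReadRecord] = []
    counter = 0
    m = reference.manifest
    for spec in specs:
        locus = loci[spec.locus_id]
        strand = locus.strand
        full_ids: list[str] = []

        def emit(start: int, end: int, clip3: int = 0, read_id: Optional[str] = None) -> LongReadRecord:
            nonlocal counter
            counter += 1
            rid = read_id or f"ont{counter}"
            mapped = end - start
            rec = LongReadRecord(
                read_id=rid, read_length=mapped + clip3, chrom=locus.chrom,
                aln_start=start, aln_end=end, strand=strand,
                blocks=[(start, end)], mapped_bases=mapped,
                clip5=0, clip3=clip3,
            )
            reads.append(rec)
            return rec

        for j in range(spec.n_within):
            offset = 20 + 15 * j
            if strand == "+":
                start = locus.start + min(offset, max(0, locus.length - 100))
                end = min(locus.end, start + int(rng.integers(300, max(400, locus.length))))
            else:
                end = locus.end - min(offset, max(0, locus.length - 100))
                start = max(locus.start, end - int(rng.integers(300, max(400, locus.length))))
            if end <= start:
                start, end = locus.start, locus.end
            emit(start, end, clip3=spec.clip3)
        for j in range(spec.n_upstream):
            if strand == "+":
                start = locus.start - spec.upstream_offset - 10 * j
                end = min(locus.end, start + spec.upstream_offset + int(locus.length * 0.6))
            else:
                end = locus.end + spec.upstream_offset + 10 * j
                start = max(locus.start, end - spec.upstream_offset - int(locus.length * 0.6))
            emit(start, end, clip3=spec.clip3)
        if spec.full_length:
            feature = locus.autonomy_feature()
            if feature is None:
                raise ValueError(f"locus {spec.locus_id} has no autonomy feature")
            fs, fe = feature
            rec = emit(fs, fe)
            full_ids.append(rec.read_id)
        # manifest labels
        if spec.n_within or spec.n_upstream:
            if spec.n_within and spec.n_upstream:
                m.locus_start_category[locus.id] = "Mix"
            elif spec.n_within:
                m.locus_start_category[locus.id] = "All_within"
            else:
                m.locus_start_category[locus.id] = "All_upstream"
        if full_ids:
            m.full_length_reads[locus.id] = full_ids
    return LongReadDataset(reads=reads)


# ---------------------------------------------------------------------------
# Count-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class CountPlan:
    """Planted archetypes for a time-course count matrix."""

    feature_archetype: dict[str, str]
    baseline_mean: float = 200.0
    treatment: str = "treated"
    baseline: str = "mock"


def simulate_counts(
    plan: CountPlan,
    seed: int,
    n_replicates: int = 3,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for a 4-timepoint, replicated contrast.

    Returns (counts, design); design columns: sample, condition, timepoint,
    replicate. Each feature's treatment mean at timepoint t is
    baseline_mean * 2**lfc(t) per its archetype.
    """
    rng = np.random.default_rng(seed)
    timepoints = ("1h", "3h", "6h", "12h")
    features = sorted(plan.feature_archetype)
    design_rows = []
    columns: dict[str, np.ndarray] = {}

    def nb(mean: np.ndarray) -> np.ndarray:
        n = 1.0 / dispersion
        p = n / (n + mean)
        return rng.negative_binomial(n, p)

    base_means = plan.baseline_mean * np.exp(rng.normal(0.0, 0.4, size=len(features)))
    arch_lfc = np.array(
        [DE_ARCHETYPES[plan.feature_archetype[f]] for f in features], dtype=float
    )
    for ti, tp in enumerate(timepoints):
        for rep in range(1, n_replicates + 1):
            s = f"{plan.baseline}_{tp}_r{rep}"
            design_rows.append({"sample": s, "condition": plan.baseline,
                                "timepoint": tp, "replicate": rep})
            columns[s] = nb(base_means)
        for rep in range(1, n_replicates + 1):
            s = f"{plan.treatment}_{tp}_r{rep}"
            design_rows.append({"sample": s, "condition": plan.treatment,
                                "timepoint": tp, "replicate": rep})
            columns[s] = nb(base_means * np.power(2.0, arch_lfc[:, ti]))
    counts = pd.DataFrame(columns, index=features)
    design = pd.DataFrame(design_rows)
    return counts, design


def concordance_count_plan(
    n_pairs: int,
    planted_concordance: float,
    rng: np.random.Generator,
    archetypes: Sequence[str] = ("up-back", "up", "down"),
    n_background: Optional[int] = None,
) -> tuple[CountPlan, dict[str, bool]]:
    """Co-localised TE-gene pairs sharing archetypes at a planted rate.

    Returns a CountPlan over features te{i}/gene{i} and the per-pair truth
    (shared archetype or not). ``n_background`` flat features (default
    4 x n_pairs) emulate the non-responsive bulk of the transcriptome so
    that median-of-ratios normalisation stays anchored.
    """
    feature_archetype: dict[str, str] = {}
    truth: dict[str, bool] = {}
    if n_background is None:
        n_background = 4 * n_pairs
    for j in range(n_background):
        feature_archetype[f"bg{j + 1}"] = "flat"
    for i in range(n_pairs):
        arch = archetypes[int(rng.integers(0, len(archetypes)))]
        te_id, gene_id = f"te{i + 1}", f"gene{i + 1}"
        feature_archetype[gene_id] = arch
        if rng.random() < planted_concordance:
            feature_archetype[te_id] = arch
            truth[te_id] = True
        else:
            others = [a for a in archetypes if a != arch]
            feature_archetype[te_id] = others[int(rng.integers(0, len(others)))]
            truth[te_id] = False
    return CountPlan(feature_archetype=feature_archetype), truth
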