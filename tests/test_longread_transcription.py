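"""Long-read start/origin/end classification, breadth, and autonomy evidence."""

import numpy as np
import pytest

from telocus import (
    GeneModel,
    LongReadRecord,
    TELocus,
    breadth_of_coverage,
    build_compartments,
    classify_ends,
    full_length_evidence,
    origin_category,
    profile_locus,
    select_autonomous_candidates,
    sense_overlap_reads,
    start_category,
)
from telocus.longread_transcription import read_long_alignments
from telocus.synthetic_data import (
    LongReadSpec,
    SimulationPlan,
    generate_reference,
    simulate_long_read_alignments,
)


def ltr_locus(start=10_000, end=14_000, strand="+", intact=True):
    return TELocus(
        id="L", chrom="chr1", start=start, end=end, strand=strand,
        family="Copia-X", superfamily="Copia", canonical_length=end - start,
        sub_features={
            "LTR5": (start, start + 500),
            "INT": (start + 500, end - 500),
            "LTR3": (end - 500, end),
        },
        structurally_intact=intact,
    )


def read(
    rid="r1", start=10_500, end=12_000, strand="+", clip5=0, clip3=0,
    blocks=None, read_length=None, mapped=None, chrom="chr1",
):
    blocks = blocks or [(start, end)]
    mapped = mapped if mapped is not None else sum(e - s for s, e in blocks)
    return LongReadRecord(
        read_id=rid, read_length=read_length or (mapped + clip5 + clip3),
        chrom=chrom, aln_start=start, aln_end=end, strand=strand,
        blocks=blocks, mapped_bases=mapped, clip5=clip5, clip3=clip3,
    )


def mirror_locus(locus, L):
    flipped = {"+": "-", "-": "+"}[locus.strand]
    subs = {k: (L - e, L - s) for k, (s, e) in locus.sub_features.items()}
    return TELocus(id=locus.id, chrom=locus.chrom, start=L - locus.end,
                   end=L - locus.start, strand=flipped, family=locus.family,
                   superfamily=locus.superfamily,
                   canonical_length=locus.canonical_length, sub_features=subs,
                   structurally_intact=locus.structurally_intact)


def mirror_read(r, L):
    flipped = {"+": "-", "-": "+"}[r.strand]
    return LongReadRecord(
        read_id=r.read_id, read_length=r.read_length, chrom=r.chrom,
        aln_start=L - r.aln_end, aln_end=L - r.aln_start, strand=flipped,
        blocks=[(L - e, L - s) for s, e in r.blocks],
        mapped_bases=r.mapped_bases, clip5=r.clip5, clip3=r.clip3,
    )


class TestSenseOverlap:
    def test_antisense_read_excluded(self):
        locus = ltr_locus()
        assert sense_overlap_reads([read(strand="-")], locus) == []

    def test_one_base_overlap_included(self):
        locus = ltr_locus()
        r = read(start=9_000, end=10_001)
        assert sense_overlap_reads([r], locus) == [r]

    def test_spliced_read_with_no_block_overlap_excluded(self):
        locus = ltr_locus()
        r = read(start=8_000, end=16_000, blocks=[(8_000, 9_000), (15_000, 16_000)])
        assert sense_overlap_reads([r], locus) == []


class TestStartCategory:
    def test_all_within(self):
        locus = ltr_locus()
        reads = [read(start=10_100 + i * 50, end=12_000) for i in range(3)]
        assert start_category(reads, locus) == "All_within"

    def test_all_upstream(self):
        locus = ltr_locus()
        reads = [read(start=9_000 - i * 100, end=11_000) for i in range(3)]
        assert start_category(reads, locus) == "All_upstream"

    def test_mix(self):
        locus = ltr_locus()
        reads = [read(start=9_000, end=11_000), read(start=10_500, end=12_000)]
        assert start_category(reads, locus) == "Mix"

    def test_minus_strand_upstream_is_rightward(self):
        locus = ltr_locus(strand="-")
        r = read(start=12_000, end=15_000, strand="-")  # 5' end at 14999 >= end
        assert start_category([r], locus) == "All_upstream"

    def test_requires_reads(self):
        with pytest.raises(ValueError):
            start_category([], ltr_locus())


@pytest.fixture(scope="module")
def cmap():
    gene = GeneModel(id="g", chrom="chr1", start=2_000, end=8_000, strand="+",
                     exons=[(2_000, 3_000), (6_000, 8_000)])
    return build_compartments([gene], {"chr1": 50_000}, flank_width=2000)


class TestOriginCategory:
    def test_exonic_origin(self, cmap):
        locus = ltr_locus()
        r = read(start=2_500, end=11_000)
        assert origin_category([r], locus, cmap) == "exonic"

    def test_intronic_origin(self, cmap):
        locus = ltr_locus()
        r = read(start=4_000, end=11_000)
        assert origin_category([r], locus, cmap) == "intronic"

    def test_intergenic_origin(self, cmap):
        locus = ltr_locus(start=30_000, end=34_000)
        r = read(start=25_000, end=31_000)
        assert origin_category([r], locus, cmap) == "no_gene"

    def test_majority_with_deterministic_tie(self, cmap):
        locus = ltr_locus()
        reads = [read(rid="a", start=2_500, end=11_000),
                 read(rid="b", start=4_000, end=11_000)]
        assert origin_category(reads, locus, cmap) == "exonic"  # tie -> exonic

    def test_none_when_no_upstream_reads(self, cmap):
        locus = ltr_locus()
        assert origin_category([read()], locus, cmap) is None


class TestBreadth:
    def test_full_span(self):
        assert breadth_of_coverage([read(start=10_500, end=13_500)],
                                   (10_500, 13_500)) == 1.0

    def test_union_of_disjoint_halves(self):
        reads = [read(rid="a", start=10_500, end=12_000),
                 read(rid="b", start=12_000, end=13_500)]
        assert breadth_of_coverage(reads, (10_500, 13_500)) == 1.0

    def test_partial_fraction(self):
        assert breadth_of_coverage([read(start=0, end=450)], (0, 1000)) == 0.45

    def test_matches_bitmap_oracle_on_random_blocks(self, rng):
        feature = (1_000, 3_000)
        reads = []
        bitmap = np.zeros(2_000, dtype=bool)
        for i in range(60):
            s = int(rng.integers(500, 3_400))
            e = s + int(rng.integers(30, 600))
            blocks = [(s, e)]
            if rng.random() < 0.4:
                gap = int(rng.integers(20, 100))
                blocks = [(s, s + 50), (s + 50 + gap, e + gap)]
            reads.append(read(rid=f"r{i}", start=blocks[0][0], end=blocks[-1][1],
                              blocks=blocks))
            for bs, be in blocks:
                lo, hi = max(bs, 1_000), min(be, 3_000)
                if lo < hi:
                    bitmap[lo - 1_000:hi - 1_000] = True
        assert breadth_of_coverage(reads, feature) == pytest.approx(bitmap.mean())


class TestEndClassification:
    def test_fully_internal_unclipped(self):
        locus = ltr_locus()
        e = classify_ends(read(start=10_500, end=12_000), locus, clip_min=20)
        assert (e.end5, e.end3) == ("internal", "internal")

    def test_external_three_prime(self):
        locus = ltr_locus()
        e = classify_ends(read(start=12_000, end=14_500), locus, clip_min=20)
        assert (e.end5, e.end3) == ("internal", "external")

    def test_clip_dominates_position(self):
        locus = ltr_locus()
        e = classify_ends(read(start=10_500, end=12_000, clip3=150), locus, clip_min=20)
        assert e.end3 == "clipped"

    def test_minus_strand_ends_follow_read_orientation(self):
        locus = ltr_locus(strand="-")
        # minus-strand read: biological 5' end is the rightmost coordinate
        e = classify_ends(read(start=9_500, end=12_000, strand="-"), locus, clip_min=20)
        assert (e.end5, e.end3) == ("internal", "external")


class TestFullLengthEvidence:
    def test_long_well_mapped_read_qualifies(self):
        locus = ltr_locus(start=0, end=5_084, strand="+")
        locus.sub_features["INT"] = (500, 4_584)  # 4084 bp INT
        r = read(start=400, end=4_600, read_length=4_200, mapped=4_000)
        assert r.mapped_bases / r.read_length >= 0.95
        assert full_length_evidence(r, locus)

    def test_short_read_fails_length_gate(self):
        locus = ltr_locus(start=0, end=5_084)
        locus.sub_features["INT"] = (500, 4_584)
        r = read(start=500, end=3_400, read_length=2_900, mapped=2_900)
        assert not full_length_evidence(r, locus)

    def test_poorly_mapped_read_fails_fraction_gate(self):
        locus = ltr_locus(start=0, end=5_084)
        locus.sub_features["INT"] = (500, 4_584)
        r = read(start=500, end=3_000, read_length=5_000, mapped=2_500)
        assert not full_length_evidence(r, locus)

    def test_line_uses_whole_element(self):
        locus = TELocus(id="l", chrom="chr1", start=0, end=1_800, strand="+",
                        family="LINE-X", superfamily="LINE", canonical_length=1_800)
        r = read(start=0, end=1_800)
        assert full_length_evidence(r, locus)


class TestAutonomousSelection:
    def test_breadth_below_threshold_not_selected(self):
        locus = ltr_locus()
        reads = [read(start=10_500, end=13_050)]  # 2550 of 3000 bp INT = 0.85
        prof = profile_locus(reads, locus)
        assert prof.breadth == pytest.approx(0.85)
        assert select_autonomous_candidates([locus], {locus.id: prof}, 0.9) == []

    def test_selected_with_zero_full_length_reads(self):
        locus = ltr_locus()
        reads = [read(rid="a", start=10_500, end=12_200),
                 read(rid="b", start=12_100, end=13_500)]
        prof = profile_locus(reads, locus)
        selected = select_autonomous_candidates([locus], {locus.id: prof}, 0.9)
        assert len(selected) == 1
        assert selected[0].full_length_read_ids == []

    def test_non_intact_locus_never_selected(self):
        locus = ltr_locus(intact=False)
        prof = profile_locus([read(start=10_500, end=13_500)], locus)
        assert select_autonomous_candidates([locus], {locus.id: prof}, 0.9) == []


class TestStrandReflection:
    def test_labels_invariant_under_mirroring(self, rng):
        """Mirroring all coordinates and strands preserves every category."""
        L = 50_000
        for strand in "+-":
            locus = ltr_locus(strand=strand)
            reads = [
                read(rid="a", start=9_200, end=11_500, strand=strand),
                read(rid="b", start=10_600, end=13_000, strand=strand, clip3=150),
                read(rid="c", start=12_200, end=14_600, strand=strand),
            ]
            sense = sense_overlap_reads(reads, locus)
            cat = start_category(sense, locus)
            ends = [classify_ends(r, locus, 20) for r in sense]
            breadth = breadth_of_coverage(sense, locus.sub_features["INT"])

            m_locus = mirror_locus(locus, L)
            m_reads = [mirror_read(r, L) for r in reads]
            m_sense = sense_overlap_reads(m_reads, m_locus)
            assert {r.read_id for r in m_sense} == {r.read_id for r in sense}
            assert start_category(m_sense, m_locus) == cat
            m_ends = {e.read_id: e for e in
                      (classify_ends(r, m_locus, 20) for r in m_sense)}
            for e in ends:
                assert (m_ends[e.read_id].end5, m_ends[e.read_id].end3) == (e.end5, e.end3)
            assert breadth_of_coverage(m_sense, m_locus.sub_features["INT"]) == breadth


class TestSyntheticRoundTrip:
    def test_planted_categories_and_sam_round_trip(self, tmp_path, reference, compartments):
        intact = [l for l in reference.te_loci if l.structurally_intact]
        specs = [
            LongReadSpec(locus_id=intact[0].id, n_within=4, full_length=True),
            LongReadSpec(locus_id=intact[1].id, n_upstream=3, upstream_offset=400),
            LongReadSpec(locus_id=intact[2].id, n_within=2, n_upstream=2, clip3=150),
        ]
        ds = simulate_long_read_alignments(reference, specs, seed=3)
        m = reference.manifest
        for spec in specs:
            locus = next(l for l in reference.te_loci if l.id == spec.locus_id)
            prof = profile_locus(ds.reads, locus, compartments)
            assert prof.start_category == m.locus_start_category[locus.id]
            if spec.full_length:
                for rid in m.full_length_reads[locus.id]:
                    assert rid in prof.full_length_read_ids
            if spec.clip3 >= 20:
                clipped = [classify_ends(r, locus, 20) for r in
                           sense_overlap_reads(ds.reads, locus) if r.clip3 >= 20]
                assert clipped and all(e.end3 == "clipped" for e in clipped)
        sam = tmp_path / "long.sam"
        ds.write_sam(sam, reference.chrom_lengths)
        back = list(read_long_alignments(sam))
        assert len(back) == len(ds.reads)
        orig = {r.read_id: r for r in ds.reads}
        for r in back:
            o = orig[r.read_id]
            assert (r.aln_start, r.aln_end, r.strand, r.blocks) == (
                o.aln_start, o.aln_end, o.strand, o.blocks
            )
            assert (r.clip5, r.clip3, r.mapped_bases) == (o.clip5, o.clip3, o.mapped_bases)
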