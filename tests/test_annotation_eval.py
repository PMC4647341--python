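"""Intron extraction/validation, splice-motif matrices and transfrag calling."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandtag import annotation_eval as ae
from strandtag import synthetic_data as sd
from strandtag import tag_counting as tc
from strandtag.io_formats import (
    AlignmentRecord,
    Feature,
    GenomeAnnotation,
    GenomicInterval,
)


def _transcript(tid, scaffold, strand, exons):
    feats = [
        Feature(f"{tid}.g", "gene",
                GenomicInterval(scaffold, exons[0][0], exons[-1][1], strand)),
        Feature(tid, "mRNA",
                GenomicInterval(scaffold, exons[0][0], exons[-1][1], strand),
                f"{tid}.g"),
    ]
    for i, (a, b) in enumerate(exons):
        feats.append(
            Feature(f"{tid}.e{i}", "exon", GenomicInterval(scaffold, a, b, strand), tid)
        )
    return feats


def _spliced_rec(scaffold, pos, cigar, reverse=False, first=True, name="q"):
    return AlignmentRecord(
        query_name=name, paired=True, first_in_pair=first, mapped=True,
        mate_mapped=False, reverse=reverse, mate_reverse=False,
        scaffold=scaffold, position=pos, cigar=cigar,
    )


class TestExtractIntrons:
    def test_plus_strand_coordinates_and_sites(self):
        ann = GenomeAnnotation(_transcript("t1", "s", "+", [(0, 100), (200, 300)]))
        (intron,) = ae.extract_introns(ann)
        assert (intron.start, intron.end) == (100, 200)
        assert intron.donor == 100 and intron.acceptor == 199
        assert intron.is_first and intron.is_last

    def test_minus_strand_sites_and_ordinals(self):
        ann = GenomeAnnotation(
            _transcript("t1", "s", "-", [(0, 100), (200, 300), (400, 500)])
        )
        introns = ae.extract_introns(ann)
        assert len(introns) == 2
        first = next(i for i in introns if i.is_first)
        # transcription starts at the right: first intron is the rightmost gap
        assert (first.start, first.end) == (300, 400)
        assert first.donor == 399 and first.acceptor == 300

    def test_isoforms_share_one_intron_record(self):
        feats = _transcript("t1", "s", "+", [(0, 100), (200, 300)])
        feats += [
            Feature("t2", "mRNA", GenomicInterval("s", 0, 400, "+"), "t1.g"),
            Feature("t2.e0", "exon", GenomicInterval("s", 0, 100, "+"), "t2"),
            Feature("t2.e1", "exon", GenomicInterval("s", 200, 400, "+"), "t2"),
        ]
        (intron,) = ae.extract_introns(GenomeAnnotation(feats))
        assert {t for t, _, _ in intron.contexts} == {"t1", "t2"}

    def test_overlapping_exons_are_hard_error(self):
        ann = GenomeAnnotation(_transcript("t1", "s", "+", [(0, 150), (100, 300)]))
        with pytest.raises(ValueError, match="overlap"):
            ae.extract_introns(ann)

    def test_synthetic_truth_introns_recovered(self, clean_dataset):
        _, truth, _, _ = clean_dataset
        introns = ae.extract_introns(truth.true_annotation)
        planted = {
            (g.scaffold, g.strand, a, b)
            for g in truth.genes.values()
            for a, b in g.introns
        }
        assert {i.key for i in introns} == planted


class TestExtractJunctions:
    def test_gap_coordinates_from_cigar(self):
        rec = _spliced_rec("s", 0, [("M", 50), ("N", 100), ("M", 30)])
        table = ae.extract_junctions([rec])
        assert table.counts == {("s", "+", 50, 150): 1}

    def test_strand_follows_fragment_rule(self):
        r1_rev = _spliced_rec("s", 0, [("M", 10), ("N", 5), ("M", 10)], reverse=True)
        r2_fwd = _spliced_rec("s", 0, [("M", 10), ("N", 5), ("M", 10)], first=False)
        assert set(ae.extract_junctions([r1_rev]).counts) == {("s", "-", 10, 15)}
        assert set(ae.extract_junctions([r2_fwd]).counts) == {("s", "-", 10, 15)}

    def test_unspliced_reads_yield_nothing(self):
        rec = _spliced_rec("s", 0, [("M", 80)])
        assert ae.extract_junctions([rec]).counts == {}

    def test_short_overhang_skipped_and_tallied(self):
        rec = _spliced_rec("s", 0, [("M", 2), ("N", 50), ("M", 40)])
        table = ae.extract_junctions([rec], min_overhang=5)
        assert table.counts == {} and table.skipped_no_flank == 1

    def test_merge_sums_counts(self):
        a = ae.extract_junctions([_spliced_rec("s", 0, [("M", 10), ("N", 5), ("M", 10)])])
        b = ae.extract_junctions([_spliced_rec("s", 0, [("M", 10), ("N", 5), ("M", 10)])])
        assert a.merge(b).counts[("s", "+", 10, 15)] == 2


class TestValidateIntrons:
    def _one_intron(self):
        ann = GenomeAnnotation(_transcript("t1", "s", "+", [(0, 100), (200, 300)]))
        return ae.extract_introns(ann)

    def test_threshold_classes(self):
        introns = self._one_intron()
        for n, at1, at10 in ((0, False, False), (1, True, False),
                             (9, True, False), (10, True, True)):
            table = ae.JunctionTable({("s", "+", 100, 200): n} if n else {})
            v = ae.validate_introns(introns, table)
            (rec,) = v.records
            assert rec.validated_at_1 is at1 and rec.validated_at_10 is at10
            assert rec.support_class == ("full" if n else "none")

    def test_end_only_classes(self):
        introns = self._one_intron()
        donor_only = ae.JunctionTable({("s", "+", 100, 250): 3})
        acceptor_only = ae.JunctionTable({("s", "+", 50, 200): 3})
        assert ae.validate_introns(introns, donor_only).records[0].support_class == "5p_only"
        assert ae.validate_introns(introns, acceptor_only).records[0].support_class == "3p_only"

    def test_strand_mismatch_gives_no_support(self):
        introns = self._one_intron()
        wrong = ae.JunctionTable({("s", "-", 100, 200): 20})
        assert ae.validate_introns(introns, wrong).records[0].support_class == "none"

    def test_validated_at_10_subset_of_at_1(self, clean_dataset):
        _, truth, polya, ribozero = clean_dataset
        introns = ae.extract_introns(truth.published_annotation)
        junctions = ae.extract_junctions(polya).merge(ae.extract_junctions(ribozero))
        v = ae.validate_introns(introns, junctions)
        for rec in v.records:
            if rec.validated_at_10:
                assert rec.validated_at_1
        c = v.counts()
        assert c["validated_at_10"] <= c["validated_at_1"] <= c["unique_introns"]

    def test_classes_match_planted_misannotations(self, clean_dataset):
        _, truth, polya, ribozero = clean_dataset
        introns = ae.extract_introns(truth.published_annotation)
        junctions = ae.extract_junctions(polya).merge(ae.extract_junctions(ribozero))
        v = ae.validate_introns(introns, junctions)
        observed = {r.intron.key: r.support_class for r in v.records}
        assert observed == truth.intron_classes

    def test_positional_bias_of_planted_errors(self, clean_dataset):
        _, truth, polya, ribozero = clean_dataset
        introns = ae.extract_introns(truth.published_annotation)
        junctions = ae.extract_junctions(polya).merge(ae.extract_junctions(ribozero))
        bias = ae.positional_bias(ae.validate_introns(introns, junctions))
        by_class = bias.set_index("class")
        # a mis-annotated gene 5' end perturbs the first intron's donor,
        # leaving acceptor-only (3'-only) support on a first intron
        assert by_class.loc["3p_only", "first_fraction"] == 1.0
        assert by_class.loc["5p_only", "last_fraction"] == 1.0

    def test_positional_bias_empty_class_is_nan(self):
        v = ae.validate_introns(self._one_intron(), ae.JunctionTable({}))
        bias = ae.positional_bias(v).set_index("class")
        assert math.isnan(bias.loc["3p_only", "first_fraction"])


class TestBoundaryMotifs:
    def _single_intron_setup(self, strand):
        # exon(0,20) intron(20,50) exon(50,70) on the + reference
        up = "ACGTACGTACGTACGTACGT"           # 20 exonic bases
        intron = "GTAAGT" + "C" * 18 + "TTTTAG"  # donor GTAAGT ... acceptor AG
        down = "TTGCATTGCATTGCATTGCA"
        ref = up + intron + down
        if strand == "-":
            ref = ae._revcomp(ref)
            exons = [(0, 20), (50, 70)]
        else:
            exons = [(0, 20), (50, 70)]
        ann = GenomeAnnotation(_transcript("t1", "s", strand, exons))
        return {"s": ref}, ae.extract_introns(ann)

    @pytest.mark.parametrize("strand", "+-")
    def test_planted_consensus_recovered(self, strand):
        seqs, introns = self._single_intron_setup(strand)
        m5, m3 = ae.boundary_motifs(introns, seqs, window=(4, 6))
        # 5' window: 4 exonic then 6 intronic bases = GTAAGT
        assert m5.consensus()[4:] == "GTAAGT"
        # 3' window: 6 intronic then 4 exonic; last two intronic bases are AG
        assert m3.consensus()[4:6] == "AG"
        # a single sequence is fully determined: 2 bits everywhere
        assert np.allclose(m5.bits.to_numpy(), 2.0)

    def test_information_content_closed_form(self):
        assert ae._information_content(np.array([0.25, 0.25, 0.25, 0.25])) == pytest.approx(0.0)
        assert ae._information_content(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(2.0)
        expected = 2 + 0.7 * math.log2(0.7) + 0.3 * math.log2(0.3)
        assert ae._information_content(np.array([0.7, 0.3, 0.0, 0.0])) == pytest.approx(expected)
        assert expected == pytest.approx(1.1187, abs=5e-4)

    def test_edge_window_skipped(self):
        ann = GenomeAnnotation(_transcript("t1", "s", "+", [(0, 5), (30, 40)]))
        introns = ae.extract_introns(ann)
        m5, _ = ae.boundary_motifs(introns, {"s": "A" * 40}, window=(10, 10))
        assert m5.skipped == 1 and m5.n_sequences == 0

    @settings(max_examples=20, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_bits_bounded_and_order_invariant(self, rnd):
        cfg = sd.SynthConfig(seed=rnd.randrange(1000))
        sequences, truth = sd.generate_genome(cfg)
        introns = ae.extract_introns(truth.true_annotation)
        shuffled = list(introns)
        rnd.shuffle(shuffled)
        m5a, m3a = ae.boundary_motifs(introns, sequences)
        m5b, m3b = ae.boundary_motifs(shuffled, sequences)
        for m in (m5a, m3a):
            assert ((m.bits >= -1e-12) & (m.bits <= 2 + 1e-12)).all()
        assert np.allclose(m5a.frequencies, m5b.frequencies)
        assert np.allclose(m3a.frequencies, m3b.frequencies)

    def test_planted_donor_is_information_rich(self, clean_dataset):
        sequences, truth, _, _ = clean_dataset
        introns = ae.extract_introns(truth.true_annotation)
        m5, m3 = ae.boundary_motifs(introns, sequences)
        # GT / AG are forced: the first two intronic and last two intronic
        # positions carry the full 2 bits
        assert m5.bits.loc[0] == pytest.approx(2.0)
        assert m5.bits.loc[1] == pytest.approx(2.0)
        assert m3.bits.loc[-2] == pytest.approx(2.0)
        assert m3.bits.loc[-1] == pytest.approx(2.0)
        assert "GTAAGT" in m5.consensus()


class TestTransfrags:
    def _tags(self, spans, strand="+", scaffold="s"):
        return [
            tc.Tag(f"f{i}", scaffold, [span], strand, True)
            for i, span in enumerate(spans)
        ]

    def test_min_frags_threshold_boundary(self):
        spans = [(0, 100)] * 100
        assert len(ae.call_transfrags(self._tags(spans), min_frags=100)) == 1
        assert len(ae.call_transfrags(self._tags(spans[:99]), min_frags=100)) == 0

    def test_gap_splits_islands(self):
        spans = [(0, 100)] * 3 + [(151, 250)] * 3
        tfs = ae.call_transfrags(self._tags(spans), min_frags=3, max_gap=50)
        assert [(t.start, t.end) for t in tfs] == [(0, 100), (151, 250)]
        joined = ae.call_transfrags(self._tags(spans), min_frags=3, max_gap=51)
        assert [(t.start, t.end) for t in joined] == [(0, 250)]

    def test_strands_kept_separate(self):
        tags = self._tags([(0, 100)] * 3) + self._tags([(0, 100)] * 3, strand="-")
        tfs = ae.call_transfrags(tags, min_frags=3)
        assert sorted(t.strand for t in tfs) == ["+", "-"]

    def test_count_monotone_in_min_frags(self, clean_dataset):
        _, truth, _, ribozero = clean_dataset
        tags = tc.assemble_tags(ribozero)
        previous = None
        for mf in (1, 10, 50, 100):
            n = len(ae.call_transfrags(tags, min_frags=mf))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_novel_requires_same_strand_overlap(self):
        ann = GenomeAnnotation(_transcript("t1", "s", "+", [(0, 100), (200, 300)]))
        tfs = [
            ae.Transfrag("s", "+", 50, 150, 10),   # overlaps gene span, same strand
            ae.Transfrag("s", "-", 50, 150, 10),   # opposite strand: novel
            ae.Transfrag("s", "+", 400, 500, 10),  # beyond gene: novel
        ]
        novel = ae.novel_features(tfs, ann)
        assert [(t.strand, t.start) for t in novel] == [("-", 50), ("+", 400)]

    def test_polya_minus_genes_expressed_only_in_ribozero(self, clean_dataset):
        _, truth, polya, ribozero = clean_dataset
        ann = truth.true_annotation
        pa = ae.call_transfrags(tc.assemble_tags(polya), min_frags=20)
        rz = ae.call_transfrags(tc.assemble_tags(ribozero), min_frags=20)

        def covered(tfs, gid):
            g = truth.genes[gid]
            a, b = g.span
            return any(
                t.scaffold == g.scaffold and t.strand == g.strand
                and t.start < b and a < t.end
                for t in tfs
            )

        hit_rz = sum(covered(rz, gid) for gid in truth.polya_minus_ids)
        hit_pa = sum(covered(pa, gid) for gid in truth.polya_minus_ids)
        assert hit_rz > hit_pa
        assert hit_pa == 0
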