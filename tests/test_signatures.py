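import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svlr.models import AlignmentRecord, parse_cigar, cigar_query_length
from svlr.signatures import (INTER_FEATURES, INTRA_FEATURES,
                             base_distribution, extract_inter_signatures,
                             extract_intra_signatures)


def _record(cigar, ref_start=0, contig="chr1", strand="+", name="r1",
            primary=True, mapq=60, seq=None):
    cig = parse_cigar(cigar)
    read_len = cigar_query_length(cig)
    if seq is None:
        seq = "ACGT" * (read_len // 4 + 1)
        seq = seq[:read_len]
    from svlr.models import cigar_reference_span
    return AlignmentRecord(
        read_name=name, contig=contig, ref_start=ref_start,
        ref_end=ref_start + cigar_reference_span(cig), mapq=mapq,
        strand=strand, is_primary=primary, is_supplementary=not primary,
        cigar=cig, edit_distance=5, read_sequence=seq, read_length=read_len)


class TestIntraExtraction:
    def test_simple_deletion_gap(self):
        sigs = extract_intra_signatures(_record("100M50D100M", ref_start=1000),
                                        min_size=30)
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.t, sig.s, sig.e, sig.length) == ("DEL", 1100, 1150, 50)

    def test_below_min_size_is_dropped(self):
        assert extract_intra_signatures(_record("100M20I100M"), min_size=30) == []

    def test_mixed_gaps_hand_walk(self):
        sigs = extract_intra_signatures(_record("50S100M40I60M200D100M"),
                                        min_size=30)
        assert [(s.t, s.s, s.e, s.length) for s in sigs] == [
            ("INS", 100, 140, 40), ("DEL", 160, 360, 200)]

    def test_nearby_same_type_gaps_merge(self):
        # two 25 bp deletions 100 bp apart merge into one spanning signature
        sigs = extract_intra_signatures(_record("100M25D100M25D100M"),
                                        min_size=30)
        assert len(sigs) == 1
        assert (sigs[0].t, sigs[0].s, sigs[0].e) == ("DEL", 100, 250)

    def test_feature_vector_well_formed(self):
        sigs = extract_intra_signatures(_record("50S100M40I60M200D100M"))
        for sig in sigs:
            assert sig.features.shape == (len(INTRA_FEATURES),)
            assert np.all(np.isfinite(sig.features))
            freqs = sig.features[15:23]
            assert np.all((0 <= freqs) & (freqs <= 1))

    def test_missing_sequence_never_crashes(self):
        rec = _record("100M50D100M")
        rec.read_sequence = None
        sigs = extract_intra_signatures(rec)
        assert len(sigs) == 1
        assert np.all(np.isfinite(sigs[0].features))


class TestBaseDistribution:
    @pytest.mark.parametrize("seq,expect", [
        ("AAAAA", [1.0, 0, 0, 0, 1.0]),
        ("ACGTACGT", [0.25, 0.25, 0.25, 0.25, 0.0]),
        ("AAAAACCCCCGGGG", [5 / 14, 5 / 14, 4 / 14, 0.0, 10 / 14]),
    ])
    def test_examples(self, seq, expect):
        np.testing.assert_allclose(base_distribution(seq), expect)

    def test_empty_and_n_handling(self):
        assert np.all(base_distribution("") == 0)
        out = base_distribution("NNNNACGT")
        assert out[:4].sum() == pytest.approx(0.5)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_frequencies_are_proper(self, seq):
        out = base_distribution(seq)
        assert np.all((0 <= out) & (out <= 1))
        assert out[:4].sum() <= 1 + 1e-12


def _split_pair(primary_cigar, primary_pos, supp_cigar, supp_pos,
                supp_strand="+", supp_contig="chr1"):
    p = _record(primary_cigar, ref_start=primary_pos, name="read")
    s = _record(supp_cigar, ref_start=supp_pos, contig=supp_contig,
                strand=supp_strand, name="read", primary=False)
    return [p, s]


class TestInterExtraction:
    def test_deletion_from_split_gap(self):
        # primary read[0,1000) -> chr1:[10000,11000)+; suppl read[1050,2000)
        # -> chr1:[13000,13950)+ : read gap 50 << ref gap 2000 -> DEL 1950
        recs = _split_pair("1000M1000S", 10_000, "1050S950M", 13_000)
        sigs = extract_inter_signatures(recs)
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.t, sig.s, sig.e, sig.length) == ("DEL", 11_000, 12_950, 1950)
        assert sig.features.shape == (len(INTER_FEATURES),)

    def test_insertion_from_split_gap(self):
        # read gap 1000 >> ref gap 0 -> INS of 1000 at the junction
        recs = _split_pair("1000M2000S", 10_000, "2000S1000M", 11_000)
        sigs = extract_inter_signatures(recs)
        assert [(s.t, s.s, s.length) for s in sigs] == [("INS", 11_000, 1000)]

    def test_opposite_strands_give_inversion(self):
        recs = _split_pair("1000M1000S", 10_000, "500S1000M500S", 11_000,
                           supp_strand="-")
        sigs = extract_inter_signatures(recs)
        assert len(sigs) == 1 and sigs[0].t == "INV"

    def test_different_contigs_give_translocation(self):
        recs = _split_pair("1000M1000S", 10_000, "1000S1000M", 50_000,
                           supp_contig="chr5")
        sigs = extract_inter_signatures(recs)
        assert len(sigs) == 1
        sig = sigs[0]
        assert (sig.t, sig.c, sig.c2) == ("TRA", "chr1", "chr5")
        assert (sig.s, sig.p2) == (11_000, 50_000)

    def test_reference_backtrack_gives_duplication(self):
        # supplementary restarts 600 bp before the primary's end
        recs = _split_pair("1000M1000S", 10_000, "1000S1000M", 10_400)
        sigs = extract_inter_signatures(recs)
        assert [(s.t, s.s, s.e) for s in sigs] == [("DUP", 10_400, 11_000)]

    def test_single_segment_read_yields_nothing(self):
        assert extract_inter_signatures([_record("1000M")]) == []

    def test_order_invariance(self):
        recs = _split_pair("1000M1000S", 10_000, "1050S950M", 13_000)
        a = extract_inter_signatures(recs)
        b = extract_inter_signatures(recs[::-1])
        assert [(s.t, s.s, s.e) for s in a] == [(s.t, s.s, s.e) for s in b]

    def test_sa_tag_fallback_matches_supplementary_records(self):
        from svlr.models import SAEntry
        recs = _split_pair("1000M1000S", 10_000, "1050S950M", 13_000)
        with_sa = [recs[0]]
        with_sa[0].sa_entries = [SAEntry(contig="chr1", pos=13_000, strand="+",
                                         cigar=parse_cigar("1050S950M"),
                                         mapq=60, nm=2)]
        a = extract_inter_signatures(recs)
        b = extract_inter_signatures(with_sa)
        assert [(s.t, s.s, s.e) for s in a] == [(s.t, s.s, s.e) for s in b]
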