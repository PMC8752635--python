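"""Triplet classification, spectra, context counters and genome adjustment."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from tlsmut import spectra
from tlsmut.spectra import (
    CHANNELS,
    GenomeRef,
    MutationRecord,
    SpectraError,
    TripletSpectrum,
    build_triplet_spectrum,
    classify_sbs,
    collapse_triplet,
    count_ncc_nac,
    count_t_ins_after_gg,
    cross_genome_adjust,
    deletion_size_histogram,
    read_mutations,
    read_spectra,
    triplet_frequencies,
    write_mutations,
    write_spectra,
)


def _oracle_classify(ref: str, alt: str, five: str, three: str) -> str:
    """Independent channel-name oracle using Bio.Seq reverse complement."""
    if ref in "AG":
        ref, alt = str(Seq(ref).reverse_complement()), str(Seq(alt).reverse_complement())
        five, three = (
            str(Seq(three).reverse_complement()),
            str(Seq(five).reverse_complement()),
        )
    return f"{five}[{ref}>{alt}]{three}"


# ---------------------------------------------------------------------------
# I/O


class TestReadMutations:
    def test_tsv_classes(self, tmp_path):
        p = tmp_path / "muts.tsv"
        p.write_text(
            "sample\tchrom\tpos\tref\talt\n"
            "s1\tchr1\t10\tC\tT\n"
            "s1\tchr1\t10\tC\tCT\n"
            "s1\tchr1\t10\tCA\tC\n"
        )
        recs = read_mutations(p)
        assert [r.mut_class for r in recs] == ["SBS", "INS", "DEL"]

    def test_ref_equals_alt_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "muts.tsv"
        p.write_text("sample\tchrom\tpos\tref\talt\ns1\tchr1\t10\tC\tC\n")
        with pytest.raises(SpectraError, match=":2:"):
            read_mutations(p)

    def test_roundtrip(self, tmp_path):
        recs = [
            MutationRecord("s1", "chr1", 10, "C", "T"),
            MutationRecord("s2", "chr1", 42, "A", "AGG"),
        ]
        p = tmp_path / "m.tsv"
        write_mutations(recs, p)
        assert read_mutations(p) == recs

    def test_vcf(self, tmp_path):
        p = tmp_path / "s1.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\t.\tC\tT\t.\t.\t.\n"
            "chr1\t20\t.\tG\tGA\t.\t.\t.\n"
        )
        recs = read_mutations(p)
        assert [(r.sample_id, r.pos, r.mut_class) for r in recs] == [
            ("s1", 10, "SBS"),
            ("s1", 20, "INS"),
        ]


# ---------------------------------------------------------------------------
# Classification


class TestClassifySBS:
    def test_pyrimidine_strand_direct(self):
        g = GenomeRef({"c": "AACGA"})
        cls = classify_sbs(MutationRecord("s", "c", 3, "C", "T"), g)
        assert cls.name == "A[C>T]G"

    def test_purine_mapped_to_reverse_complement(self):
        g = GenomeRef({"c": "ATGAA"})
        cls = classify_sbs(MutationRecord("s", "c", 3, "G", "A"), g)
        assert cls.name == "T[C>T]A"

    def test_contig_edge_errors(self):
        g = GenomeRef({"c": "CCCC"})
        with pytest.raises(SpectraError, match="edge"):
            classify_sbs(MutationRecord("s", "c", 1, "C", "T"), g)
        with pytest.raises(SpectraError, match="edge"):
            classify_sbs(MutationRecord("s", "c", 4, "C", "T"), g)

    def test_n_in_context_errors(self):
        g = GenomeRef({"c": "ANCGA"})
        with pytest.raises(SpectraError, match="N in"):
            classify_sbs(MutationRecord("s", "c", 3, "C", "T"), g)

    def test_ref_mismatch_errors(self):
        g = GenomeRef({"c": "AACGA"})
        with pytest.raises(SpectraError, match="record ref"):
            classify_sbs(MutationRecord("s", "c", 3, "T", "A"), g)

    @pytest.mark.parametrize("channel", CHANNELS)
    def test_strand_involution_all_channels(self, channel):
        """Classifying a mutation and its reverse complement yields the same channel."""
        five, ref, alt, three = channel[0], channel[2], channel[4], channel[6]
        fwd = GenomeRef({"c": f"A{five}{ref}{three}A"})
        cls_f = classify_sbs(MutationRecord("s", "c", 3, ref, alt), fwd)
        rc_seq = str(Seq(f"A{five}{ref}{three}A").reverse_complement())
        rc_ref = str(Seq(ref).reverse_complement())
        rc_alt = str(Seq(alt).reverse_complement())
        rev = GenomeRef({"c": rc_seq})
        cls_r = classify_sbs(MutationRecord("s", "c", 3, rc_ref, rc_alt), rev)
        assert cls_f == cls_r
        assert cls_f.name == channel


class TestTripletSpectrum:
    def test_empty_is_zero_vector(self, toy_genome):
        s = build_triplet_spectrum([], toy_genome)
        assert s.total == 0

    def test_single_channel_accumulation(self):
        g = GenomeRef({"c": "AACGA"})
        muts = [MutationRecord("s", "c", 3, "C", "T")] * 3
        s = build_triplet_spectrum(muts, g)
        assert s.counts[spectra.CHANNEL_INDEX["A[C>T]G"]] == 3
        assert s.total == 3

    def test_matches_independent_enumeration(self, toy_genome, rng):
        """20 random SBS on a 200 bp genome: channel counts equal an oracle tally."""
        seq = toy_genome.sequences["chr1"]
        muts = []
        expected = {}
        while len(muts) < 20:
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            muts.append(MutationRecord("s", "chr1", pos, ref, alt))
            name = _oracle_classify(ref, alt, seq[pos - 2], seq[pos])
            expected[name] = expected.get(name, 0) + 1
        s = build_triplet_spectrum(muts, toy_genome)
        for i, channel in enumerate(CHANNELS):
            assert s.counts[i] == expected.get(channel, 0)
        assert s.total == 20

    def test_edge_records_skipped_with_warning(self, caplog):
        g = GenomeRef({"c": "CACGA"})
        muts = [
            MutationRecord("s", "c", 1, "C", "T"),  # edge: skipped
            MutationRecord("s", "c", 3, "C", "T"),
        ]
        with caplog.at_level("WARNING"):
            s = build_triplet_spectrum(muts, g)
        assert s.total == 1
        assert "skipping" in caplog.text

    def test_spectra_tsv_roundtrip(self, tmp_path):
        s = TripletSpectrum(np.arange(96, dtype=float), label="a")
        p = tmp_path / "spec.tsv"
        write_spectra([s], p)
        back = read_spectra(p)
        assert back[0].label == "a"
        np.testing.assert_array_equal(back[0].counts, s.counts)


# ---------------------------------------------------------------------------
# Context counters


class TestContextCounters:
    def test_ncc_nac_zero_without_c_to_a(self):
        g = GenomeRef({"c": "AGCCA"})
        assert count_ncc_nac([MutationRecord("s", "c", 3, "C", "T")], g) == 0

    def test_ncc_nac_direct_strand(self):
        g = GenomeRef({"c": "AGCCA"})
        assert count_ncc_nac([MutationRecord("s", "c", 3, "C", "A")], g) == 1

    def test_ncc_nac_opposite_strand(self):
        # triplet GGC: its G>T reads as G[C>A]C on the pyrimidine strand
        g = GenomeRef({"c": "AGGCA"})
        assert count_ncc_nac([MutationRecord("s", "c", 3, "G", "T")], g) == 1

    def test_ncc_nac_equals_spectrum_channels(self, toy_genome, rng):
        """Counter agrees with the sum of the four N[C>A]C spectrum channels."""
        seq = toy_genome.sequences["chr1"]
        muts = []
        while len(muts) < 200:
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            muts.append(MutationRecord("s", "chr1", pos, ref, alt))
        s = build_triplet_spectrum(muts, toy_genome)
        channel_sum = sum(
            s.counts[spectra.CHANNEL_INDEX[f"{n}[C>A]C"]] for n in "ACGT"
        )
        assert count_ncc_nac(muts, toy_genome) == channel_sum

    def test_t_insertion_after_gg(self):
        g = GenomeRef({"c": "AGGTA"})
        ins = MutationRecord("s", "c", 3, "G", "GT")
        assert count_t_ins_after_gg([ins], g) == 1

    def test_t_insertion_wrong_context(self):
        g = GenomeRef({"c": "AAATA"})
        ins = MutationRecord("s", "c", 3, "A", "AT")
        assert count_t_ins_after_gg([ins], g) == 0

    def test_a_insertion_before_cc_counts(self):
        # opposite strand: A inserted immediately 5' of CC
        g = GenomeRef({"c": "ATCCA"})
        ins = MutationRecord("s", "c", 2, "T", "TA")
        assert count_t_ins_after_gg([ins], g) == 1

    def test_deletion_histogram_binning(self):
        muts = [
            MutationRecord("s", "c", 1, "AT", "A"),
            MutationRecord("s", "c", 5, "CG", "C"),
            MutationRecord("s", "c", 9, "TAC", "T"),
            MutationRecord("s", "c", 13, "GACGTA", "G"),
        ]
        assert deletion_size_histogram(muts) == {"1": 2, "2": 1, "3+": 1}

    def test_deletion_histogram_random_tally(self, rng):
        sizes = rng.integers(1, 11, size=100)
        muts = [
            MutationRecord("s", "c", int(i + 1), "A" + "C" * int(sz), "A")
            for i, sz in enumerate(sizes)
        ]
        hist = deletion_size_histogram(muts)
        assert hist["1"] == int((sizes == 1).sum())
        assert hist["2"] == int((sizes == 2).sum())
        assert hist["3+"] == int((sizes >= 3).sum())
        assert sum(hist.values()) == 100


# ---------------------------------------------------------------------------
# Triplet frequencies and adjustment


class TestTripletFrequencies:
    def test_hand_enumeration_acgt(self):
        # ACGT has 3-mers ACG and CGT; CGT collapses to ACG
        freq = triplet_frequencies(GenomeRef({"c": "ACGT"}))
        assert freq["ACG"] == 2
        assert sum(freq.values()) == 2

    def test_all_n_errors(self):
        with pytest.raises(SpectraError):
            triplet_frequencies(GenomeRef({"c": "NNNNNN"}))

    def test_short_genome_errors(self):
        with pytest.raises(SpectraError):
            triplet_frequencies(GenomeRef({"c": "AC"}))

    def test_additive_over_concatenation(self, toy_genome):
        seq = toy_genome.sequences["chr1"]
        single = triplet_frequencies(toy_genome)
        double = triplet_frequencies(GenomeRef({"a": seq, "b": seq}))
        for t, c in single.items():
            assert double[t] == 2 * c


class TestCrossGenomeAdjust:
    def test_identity_when_src_equals_dst(self, toy_genome, rng):
        freq = triplet_frequencies(toy_genome)
        s = TripletSpectrum(rng.integers(0, 20, size=96).astype(float))
        out = cross_genome_adjust(s, freq, freq)
        np.testing.assert_allclose(out.counts, s.counts)

    def test_uniform_rescaling_invariance(self, toy_genome, rng):
        freq = triplet_frequencies(toy_genome)
        doubled = {t: 2 * c for t, c in freq.items()}
        s = TripletSpectrum(rng.integers(0, 20, size=96).astype(float))
        out = cross_genome_adjust(s, freq, doubled)
        np.testing.assert_allclose(out.counts, s.counts)

    def test_two_channel_arithmetic(self):
        # spectrum with counts 10 in A[C>A]A and 10 in A[C>A]C;
        # dst doubles the ACA triplet only -> reweighted 20:10, renormalised to 20 total
        counts = np.zeros(96)
        i, j = spectra.CHANNEL_INDEX["A[C>A]A"], spectra.CHANNEL_INDEX["A[C>A]C"]
        counts[i] = counts[j] = 10
        src = {t: 1 for t in spectra.PYRIMIDINE_TRIPLETS}
        dst = dict(src)
        dst["ACA"] = 2
        out = cross_genome_adjust(TripletSpectrum(counts), src, dst)
        assert out.total == pytest.approx(20)
        assert out.counts[i] == pytest.approx(20 * 2 / 3)
        assert out.counts[j] == pytest.approx(20 * 1 / 3)

    def test_zero_source_frequency_errors(self):
        s = TripletSpectrum(np.ones(96))
        src = {t: 1 for t in spectra.PYRIMIDINE_TRIPLETS}
        bad = dict(src)
        bad["ACA"] = 0
        with pytest.raises(SpectraError):
            cross_genome_adjust(s, bad, src)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=3))
def test_collapse_triplet_involution(triplet):
    """Collapsing is idempotent and strand-symmetric."""
    collapsed = collapse_triplet(triplet)
    assert collapsed[1] in "CT"
    assert collapse_triplet(collapsed) == collapsed
    assert collapse_triplet(str(Seq(triplet).reverse_complement())) == collapsed
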