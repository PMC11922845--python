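"""Sequence-level machinery: ORF search, site counting, SNP classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from coniferdiv import codon
from coniferdiv.codon import (
    SnpEffect,
    classify_snp,
    count_sites,
    find_longest_orf,
    reverse_complement,
    translate_codon,
)

SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


def brute_force_sites(codon_str):
    """Independent oracle: enumerate all 9 single-base mutants of a codon."""
    aa = translate_codon(codon_str)
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon_str[pos]:
                continue
            mutant = codon_str[:pos] + b + codon_str[pos + 1:]
            if translate_codon(mutant) == aa:
                syn += 1
    return 3.0 - syn / 3.0, syn / 3.0  # (La, Ls)


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq,start,end,strand",
        [
            ("ATGAAATAG", 0, 9, "+"),
            ("GATGAAATAGC", 1, 10, "+"),
            ("ATGAAACCCGGG", 0, 12, "+"),  # 3'-truncated, no stop
        ],
    )
    def test_simple_orfs(self, seq, start, end, strand):
        orf = find_longest_orf(seq, "t", min_len=9)
        assert (orf.start, orf.end, orf.strand) == (start, end, strand)

    def test_reverse_strand_orf(self):
        # no forward ORF in the flanks; the reverse-complement ORF must win
        seq = "CCCC" + reverse_complement("ATGAAAGAAGATTAG") + "CCCC"
        orf = find_longest_orf(seq, "t", min_len=9)
        assert orf.strand == "-"
        assert orf.coding_sequence(seq) == "ATGAAAGAAGATTAG"

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            find_longest_orf("")

    def test_no_orf_returns_none(self):
        assert find_longest_orf("CCCCCCCCCCCC") is None
        assert find_longest_orf("ATGTAG", min_len=30) is None  # below minimum

    def test_forward_strand_wins_ties(self):
        # same-length ORF on both strands; forward strand preferred
        fwd = "ATGAAATAG"
        seq = fwd + "CC" + reverse_complement(fwd)
        orf = find_longest_orf(seq, min_len=9)
        assert orf.strand == "+" and orf.start == 0

    @pytest.mark.parametrize("left,right", [(0, 0), (3, 7), (11, 2), (25, 25)])
    def test_strand_involution(self, left, right):
        # C/A-only construction guarantees the designed ORF is unique
        seq = "C" * left + "ATG" + "AAA" * 15 + "TAG" + "C" * right
        orf = find_longest_orf(seq, min_len=9)
        mirrored = find_longest_orf(reverse_complement(seq), min_len=9)
        n = len(seq)
        assert (mirrored.start, mirrored.end) == (n - orf.end, n - orf.start)
        assert {orf.strand, mirrored.strand} == {"+", "-"}
        assert mirrored.coding_sequence(reverse_complement(seq)) == \
            orf.coding_sequence(seq)


class TestCountSites:
    @pytest.mark.parametrize(
        "c,la,ls",
        [("GGG", 2.0, 1.0), ("ATG", 3.0, 0.0), ("TTT", 8 / 3, 1 / 3)],
    )
    def test_reference_codons(self, c, la, ls):
        sc = count_sites(c)
        assert sc.La == pytest.approx(la, abs=1e-12)
        assert sc.Ls == pytest.approx(ls, abs=1e-12)

    def test_oracle_equivalence_all_sense_codons(self):
        for c in SENSE_CODONS:
            la, ls = brute_force_sites(c)
            sc = count_sites(c)
            assert sc.La == pytest.approx(la, abs=1e-12), c
            assert sc.Ls == pytest.approx(ls, abs=1e-12), c

    def test_terminal_stop_and_n_codons_excluded(self):
        base = count_sites("ATGGGG")
        assert count_sites("ATGGGGTAA").n_codons == base.n_codons == 2
        withn = count_sites("ATGNNNGGG")
        assert withn.n_codons == 2
        assert withn.La + withn.Ls == pytest.approx(6.0)

    def test_length_error(self):
        with pytest.raises(ValueError):
            count_sites("ATGA")

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, codons):
        sc = count_sites("".join(codons))
        assert sc.La + sc.Ls == pytest.approx(3 * len(codons), abs=1e-9)
        assert sc.La >= 0 and sc.Ls >= 0


class TestClassifySnp:
    ORF = codon.OrfInterval("t", 0, 9, "+", 0)

    def test_synonymous(self):
        eff = classify_snp(self.ORF, "GGGAAATAG", 2, "G", "A")
        assert eff.category == "synonymous"
        assert (eff.ref_codon, eff.alt_codon) == ("GGG", "GGA")

    def test_nonsynonymous(self):
        eff = classify_snp(self.ORF, "TTTAAATAG", 0, "T", "C")
        assert eff.category == "nonsynonymous"

    def test_stop_gain_is_nonsynonymous(self):
        # TAC (Tyr) -> TAA (stop)
        eff = classify_snp(self.ORF, "TACAAATAG", 2, "C", "A")
        assert eff.category == "nonsynonymous"

    def test_noncoding_outside_orf(self):
        orf = codon.OrfInterval("t", 3, 12, "+", 0)
        eff = classify_snp(orf, "CCCATGAAATAGCC", 1, "C", "T")
        assert eff == SnpEffect("noncoding", None, None, None)

    def test_ref_mismatch_names_transcript_and_position(self):
        with pytest.raises(codon.RefMismatchError, match="t:1"):
            classify_snp(self.ORF, "GGGAAATAG", 1, "A", "T")

    def test_reverse_strand_classification(self):
        fwd = "ATGGGGAAATAG"
        seq = reverse_complement(fwd)
        orf = find_longest_orf(seq, "t", min_len=9)
        assert orf.strand == "-"
        # third position of the GGG codon on the coding strand corresponds to
        # transcript base complement; a G->A coding change is synonymous
        pos = orf.end - 1 - 5  # coding offset 5 = GGG third position
        ref = seq[pos]
        alt = reverse_complement("A")
        eff = classify_snp(orf, seq, pos, ref, alt)
        assert eff.category == "synonymous"

    def test_consistency_with_site_counts(self, rng):
        """Exhaustive classification of a codon's 9 mutants reproduces its
        synonymous-site contribution from count_sites."""
        for c in rng.choice(SENSE_CODONS, size=25):
            seq = c + "TAA"
            orf = codon.OrfInterval("t", 0, 3, "+", 0)
            syn = 0
            for pos in range(3):
                for b in "ACGT":
                    if b == seq[pos]:
                        continue
                    eff = classify_snp(orf, seq, pos, seq[pos], b)
                    syn += eff.category == "synonymous"
            assert syn / 3.0 == pytest.approx(count_sites(c).Ls, abs=1e-12)
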