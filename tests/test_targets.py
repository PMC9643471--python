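"""Sensitive-site counting against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from schwannoma.targets import (
    AmbiguousBaseError,
    CodingSequence,
    GeneTargetProfile,
    IndelLengthDistribution,
    NoOrfError,
    bozic_indel_approximation,
    count_deletion_sensitive,
    count_substitution_sensitive,
    deletion_profile,
    expected_indel_sensitive,
    extract_longest_orf,
    profile_gene,
    read_sequences,
)

from conftest import random_orf_bases
from oracles import (
    brute_deletion_sensitive,
    brute_longest_orf,
    brute_substitution_multiplicity,
)

bases_strategy = st.text(alphabet="ACGT", min_size=12, max_size=120)


class TestOrfExtraction:
    def test_whole_input_is_the_orf(self):
        orf = extract_longest_orf("ATGGCCGCCTAA")
        assert orf.bases == "ATGGCCGCCTAA"
        assert orf.frame_origin == 0
        assert orf.has_terminal_stop
        assert len(orf.codons) == 4

    def test_longer_offset_frame_wins(self, rng):
        # frame 0: short ORF; frame 1: long ORF
        short = "ATG" + "GCC" * 3 + "TAA"
        long_body = random_orf_bases(rng, 30)
        seq = short + "C" + long_body  # shifts the long ORF to frame 1
        orf = extract_longest_orf(seq)
        assert orf.frame_origin == len(short) + 1
        assert orf.bases == long_body

    def test_no_atg_raises(self):
        with pytest.raises(NoOrfError):
            extract_longest_orf("GCCGCCGCCGCC")

    def test_ambiguity_code_rejected_with_position(self):
        with pytest.raises(AmbiguousBaseError) as err:
            extract_longest_orf("ATGNCCTAA")
        assert err.value.position == 3

    @given(bases_strategy)
    def test_matches_exhaustive_scan(self, bases):
        expected = brute_longest_orf(bases)
        if expected is None:
            with pytest.raises(NoOrfError):
                extract_longest_orf(bases)
        else:
            start, length, has_stop = expected
            orf = extract_longest_orf(bases)
            assert (orf.frame_origin, len(orf.bases), orf.has_terminal_stop) == (
                start,
                length,
                has_stop,
            )


class TestSubstitutionCounting:
    def test_inert_codons_count_zero(self):
        orf = CodingSequence("x", "ATG" + "GCC" * 5 + "TAA", has_terminal_stop=True)
        raw, l = count_substitution_sensitive(orf)
        assert raw == 0 and l == 0.0

    def test_tac_reaches_two_stops(self):
        # brute-force all 9 variants of TAC: TAA and TAG are reachable
        variants = {
            "TAC"[:i] + alt + "TAC"[i + 1 :]
            for i in range(3)
            for alt in "ACGT"
            if alt != "TAC"[i]
        }
        assert len(variants & {"TAA", "TAG", "TGA"}) == 2
        orf = CodingSequence("x", "ATGTACTAA", has_terminal_stop=True)
        raw, l = count_substitution_sensitive(orf)
        assert raw == 2
        assert l == pytest.approx(2 / 3)

    def test_too_short_orf_errors(self):
        orf = CodingSequence("x", "ATGTAA", has_terminal_stop=True)
        with pytest.raises(ValueError):
            count_substitution_sensitive(orf)

    def test_appending_near_stop_codon_never_decreases_raw(self, rng):
        for _ in range(5):
            body = random_orf_bases(rng, int(rng.integers(3, 20)))[:-3]  # drop stop
            base_orf = CodingSequence("x", body + "TAA", has_terminal_stop=True)
            grown = CodingSequence("x", body + "TAC" + "TAA", has_terminal_stop=True)
            assert (
                count_substitution_sensitive(grown)[0]
                >= count_substitution_sensitive(base_orf)[0]
            )

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(25):
            bases = random_orf_bases(rng, int(rng.integers(2, 60)))
            orf = CodingSequence("r", bases, has_terminal_stop=True)
            raw, _ = count_substitution_sensitive(orf)
            assert raw == brute_substitution_multiplicity(bases, orf.coding_length)


class TestDeletionCounting:
    def test_in_frame_deletion_of_inert_codons_is_insensitive(self):
        orf = CodingSequence("x", "ATG" + "GCC" * 8 + "TAA", has_terminal_stop=True)
        for k in (3, 6):
            assert count_deletion_sensitive(orf, k) == 0

    def test_k_out_of_range_errors(self):
        orf = CodingSequence("x", "ATGGCCTAA", has_terminal_stop=True)
        with pytest.raises(ValueError):
            count_deletion_sensitive(orf, 0)
        with pytest.raises(ValueError):
            count_deletion_sensitive(orf, len(orf.bases) - 2)

    def test_toy_orf_matches_exhaustive_simulation(self):
        bases = "ATGTATGACGCCTAA"
        orf = CodingSequence("toy", bases, has_terminal_stop=True)
        for k in range(1, 7):
            assert count_deletion_sensitive(orf, k) == brute_deletion_sensitive(
                bases, orf.coding_length, k
            )

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(15):
            bases = random_orf_bases(rng, int(rng.integers(2, 40)))
            orf = CodingSequence("r", bases, has_terminal_stop=True)
            for k in (1, 2, 3, 4, 5):
                if k > len(bases) - 3:
                    continue
                assert count_deletion_sensitive(orf, k) == brute_deletion_sensitive(
                    bases, orf.coding_length, k
                )


class TestIndelAverage:
    def test_zero_profile_gives_zero(self):
        orf = CodingSequence("x", "ATG" + "GCC" * 8 + "TAA", has_terminal_stop=True)
        dist = IndelLengthDistribution()
        assert expected_indel_sensitive(orf, dist, m_profile={k: 0 for k in range(1, 41)}) == 0.0

    def test_constant_profile_halved_by_insertions(self):
        # symmetric f: insertions carry half the total weight but contribute 0
        dist = IndelLengthDistribution()
        orf = CodingSequence("x", "ATGGCCGCCTAA", has_terminal_stop=True)
        m = expected_indel_sensitive(orf, dist, m_profile={k: 7 for k in range(1, 41)})
        assert m == pytest.approx(3.5, rel=1e-9)

    def test_agrees_with_independent_summation(self, rng):
        bases = random_orf_bases(rng, 20)  # 60-bp coding body
        orf = CodingSequence("x", bases, has_terminal_stop=True)
        dist = IndelLengthDistribution(q=0.53)
        profile = deletion_profile(orf, dist)
        # independent evaluation of the length-weighted average
        q = 0.53
        num = sum(profile[k] * q ** k for k in profile)
        den = sum(q ** abs(k) for k in range(-dist.k_max, dist.k_max + 1) if k != 0)
        assert expected_indel_sensitive(orf, dist) == pytest.approx(num / den, rel=1e-12)

    def test_invariant_under_weight_rescaling(self):
        # the normalisation constant of f(k) cancels: doubling all weights is a no-op
        dist = IndelLengthDistribution(q=0.53)
        profile = {1: 4, 2: 1, 3: 6}
        orf = CodingSequence("x", "ATGGCCGCCTAA", has_terminal_stop=True)
        m = expected_indel_sensitive(orf, dist, m_profile=profile)
        num = sum(2.0 * v * 0.53 ** k for k, v in profile.items())
        den = 2.0 * dist.total_weight
        assert m == pytest.approx(num / den, rel=1e-12)

    def test_q_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            IndelLengthDistribution(q=1.0)

    @given(st.floats(min_value=0.0, max_value=1e4))
    def test_bozic_approximation_is_linear(self, l):
        assert bozic_indel_approximation(l) == pytest.approx(0.74 * l)

    def test_bozic_rejects_negative(self):
        with pytest.raises(ValueError):
            bozic_indel_approximation(-1.0)


class TestProfile:
    def test_n_equals_l_plus_m(self, rng):
        bases = random_orf_bases(rng, 30)
        profile = profile_gene(bases, cds_mode="annotated")
        assert profile.n_gene == profile.l_gene + profile.m_gene

    def test_empty_sensitivity_orf(self):
        profile = profile_gene("ATG" + "GCC" * 10 + "TAA", cds_mode="annotated")
        assert profile.n_gene == 0.0

    def test_printed_smarcb1_arithmetic(self):
        # the printed per-gene counts compose to the printed total
        profile = GeneTargetProfile("SMARCB1", 143, 143 / 3, m_gene=37.0)
        assert round(profile.n_gene) == 85

    def test_weighted_m_cannot_exceed_max_term(self, rng):
        bases = random_orf_bases(rng, 25)
        profile = profile_gene(bases, cds_mode="annotated")
        if profile.m_profile:
            assert profile.m_gene <= max(profile.m_profile.values())


class TestIo:
    def test_fasta_roundtrip(self, tmp_path):
        fasta = tmp_path / "genes.fa"
        fasta.write_text(">g1\nATGTACGCCTAA\n>g2\nATGGCCGCCGCCTAA\n")
        seqs = read_sequences(fasta, "fasta")
        assert [s.identifier for s in seqs] == ["g1", "g2"]
        p1 = profile_gene(seqs[0], cds_mode="longest-orf")
        assert p1.raw_substitution_multiplicity == 2

    def test_genbank_cds_extraction(self, tmp_path):
        gb = tmp_path / "gene.gb"
        gb.write_text(
            "LOCUS       TEST                      18 bp    DNA     linear   UNA 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             join(4..9,13..18)\n"
            '                     /gene="toy"\n'
            "ORIGIN\n"
            "        1 cccatgtacg ggccgtaa\n"
            "//\n"
        )
        seqs = read_sequences(gb, "genbank")
        assert len(seqs) == 1
        assert seqs[0].identifier == "toy"
        assert seqs[0].bases == "ATGTACCCGTAA"  # join of 4..9 and 13..18
        assert seqs[0].has_terminal_stop
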