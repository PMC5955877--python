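import numpy as np
import pytest

from erenorm.screen import (
    PrimerPair,
    RepeatFamily,
    ScreenError,
    conservation_rate,
    count_expressed_targets,
    find_amplicons,
    read_alignment_fasta,
    revcomp,
    screen_assay,
)
from erenorm.simulate import generate_transcriptome

PAIR = PrimerPair("a1", "GGTTGGAATGGGTGTGTCAC", "TGGCTTACAGGTTCAGAGGT")


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def cassette_transcript(rng, spacer=80, left=200, right=200, antisense=False):
    cassette = PAIR.forward + rand_seq(rng, spacer) + revcomp(PAIR.reverse)
    if antisense:
        cassette = revcomp(cassette)
    return rand_seq(rng, left) + cassette + rand_seq(rng, right), left, len(cassette)


class TestConservation:
    def test_identical_copies_100_percent(self):
        fam = RepeatFamily("f", "ACGT" * 25, ("ACGT" * 25,) * 3)
        assert conservation_rate(fam) == 100.0

    def test_three_mismatches_in_100_columns(self):
        consensus = "A" * 100
        copy = "T" * 3 + "A" * 97
        assert conservation_rate(RepeatFamily("f", consensus, (copy,))) == pytest.approx(97.0)

    def test_mean_across_copies_and_pass_at_threshold(self):
        consensus = "A" * 100
        fam = RepeatFamily("f", consensus, ("A" * 100, "C" * 6 + "A" * 94))
        rate = conservation_rate(fam)
        assert rate == pytest.approx(97.0)
        result = screen_assay(fam, PAIR, {"tx": "ACGT" * 200}, conservation_threshold=97.0)
        assert result.conservation_pass

    def test_gap_columns_in_consensus_ignored(self):
        fam = RepeatFamily("f", "AC--GT", ("ACTTGT",))
        assert conservation_rate(fam) == 100.0

    def test_all_gap_consensus_rejected(self):
        with pytest.raises(ScreenError):
            conservation_rate(RepeatFamily("f", "----", ("ACGT",)))

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ScreenError):
            RepeatFamily("f", "ACGT", ("ACG",))


class TestFindAmplicons:
    def test_constructed_cassette_found_exactly_once(self, rng):
        seq, left, clen = cassette_transcript(rng)
        hits = find_amplicons(seq, PAIR, 0)
        assert len(hits) == 1
        (amp,) = hits
        assert (amp.start, amp.end, amp.orientation) == (left, left + clen, "+")
        assert amp.length == len(PAIR.forward) + 80 + len(PAIR.reverse)

    def test_cap_exceeded_no_amplicon(self, rng):
        seq, left, _ = cassette_transcript(rng)
        # plant cap+1 internal mismatches in the forward site
        s = list(seq)
        for off in (2, 5, 8, 11):
            s[left + off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[left + off]]
        mutated = "".join(s)
        assert find_amplicons(mutated, PAIR, 3) == []
        assert len(find_amplicons(mutated, PAIR, 4)) == 1

    def test_three_prime_mismatch_blocks_even_below_cap(self, rng):
        seq, left, _ = cassette_transcript(rng)
        s = list(seq)
        pos = left + len(PAIR.forward) - 1  # forward primer 3' terminus
        s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
        assert find_amplicons("".join(s), PAIR, 3) == []

    def test_antisense_cassette_reported_opposite_orientation(self, rng):
        seq, left, clen = cassette_transcript(rng, antisense=True)
        hits = find_amplicons(seq, PAIR, 0)
        assert len(hits) == 1
        assert hits[0].orientation == "-"
        assert (hits[0].start, hits[0].end) == (left, left + clen)

    def test_length_window_enforced(self, rng):
        seq, _, clen = cassette_transcript(rng, spacer=80)
        assert find_amplicons(seq, PAIR, 0, amplicon_range=(50, clen - 1)) == []
        assert len(find_amplicons(seq, PAIR, 0, amplicon_range=(clen, clen))) == 1

    def test_primer_longer_than_transcript_empty(self):
        assert find_amplicons("ACGTACGT", PAIR, 3) == []

    def test_strand_symmetry(self, rng):
        """Reverse-complementing the transcript flips orientations but keeps
        the amplicon count."""
        seq, _, _ = cassette_transcript(rng)
        fwd_hits = find_amplicons(seq, PAIR, 1)
        rc_hits = find_amplicons(revcomp(seq), PAIR, 1)
        assert len(fwd_hits) == len(rc_hits)
        assert sorted(a.length for a in fwd_hits) == sorted(a.length for a in rc_hits)

    def test_pair_total_semantics_stricter(self, rng):
        seq, left, _ = cassette_transcript(rng)
        s = list(seq)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        s[left + 2] = flip[s[left + 2]]          # 1 mismatch forward
        rev_start = left + len(PAIR.forward) + 80
        s[rev_start + 3] = flip[s[rev_start + 3]]  # 1 mismatch reverse
        mutated = "".join(s)
        assert len(find_amplicons(mutated, PAIR, 1, pair_total=False)) == 1
        assert find_amplicons(mutated, PAIR, 1, pair_total=True) == []
        assert len(find_amplicons(mutated, PAIR, 2, pair_total=True)) == 1


class TestCounting:
    def test_embedded_in_5_of_10(self, rng):
        transcripts = {}
        for i in range(10):
            if i < 5:
                seq, _, _ = cassette_transcript(rng)
            else:
                seq = rand_seq(rng, 500)
            transcripts[f"tx{i}"] = seq
        for cap in (0, 2, 3):
            counts = count_expressed_targets(transcripts, PAIR, caps=(cap,))
            assert counts[cap] == 5

    def test_monotone_in_cap(self):
        transcripts, _ = generate_transcriptome(
            60, PAIR, insertion_prob=0.6, per_base_mutation_rate=0.02, seed=9
        )
        counts = count_expressed_targets(transcripts, PAIR, caps=(0, 1, 2, 3, 4))
        vals = [counts[c] for c in (0, 1, 2, 3, 4)]
        assert vals == sorted(vals)

    def test_absent_pair_counts_zero(self, rng):
        transcripts = {f"tx{i}": rand_seq(rng, 400) for i in range(20)}
        counts = count_expressed_targets(transcripts, PAIR, caps=(3, 2))
        assert counts == {3: 0, 2: 0}

    def test_ground_truth_exactness_zero_mutation(self):
        transcripts, records = generate_transcriptome(
            200, PAIR, insertion_prob=0.5, per_base_mutation_rate=0.0, seed=4
        )
        counts = count_expressed_targets(transcripts, PAIR, caps=(0, 3))
        assert counts[0] == counts[3] == len(records)

    def test_ground_truth_exactness_sub_cap_mutation(self):
        """With mutated cassettes, predicted transcripts at cap c are exactly
        the insertions with per-primer mismatches <= c and intact 3' ends."""
        for seed in range(10):
            transcripts, records = generate_transcriptome(
                80, PAIR, insertion_prob=0.7, per_base_mutation_rate=0.03,
                antisense_prob=0.4, seed=seed,
            )
            for cap in (2, 3):
                counts = count_expressed_targets(transcripts, PAIR, caps=(cap,))
                expected = sum(
                    1
                    for r in records
                    if max(r.mismatch_forward, r.mismatch_reverse) <= cap
                    and r.three_prime_intact
                )
                assert counts[cap] == expected

    def test_antisense_insertions_detected_with_orientation(self):
        transcripts, records = generate_transcriptome(
            30, PAIR, insertion_prob=1.0, antisense_prob=1.0, seed=2
        )
        assert all(r.orientation == "-" for r in records)
        for tid in transcripts:
            hits = find_amplicons(transcripts[tid], PAIR, 0)
            assert len(hits) == 1 and hits[0].orientation == "-"


class TestScreenAssay:
    def test_gates_combined(self):
        transcripts, _ = generate_transcriptome(
            80, PAIR, insertion_prob=0.8, seed=1
        )
        fam = RepeatFamily("f", "A" * 100, ("A" * 100, "C" * 4 + "A" * 96))
        result = screen_assay(fam, PAIR, transcripts, min_hits=30)
        assert result.conservation_rate == pytest.approx(98.0)
        assert result.conservation_pass and result.adequacy_pass
        assert result.n_targets[2] <= result.n_targets[3]

    def test_conservation_below_threshold_fails(self):
        fam = RepeatFamily("f", "A" * 200, ("C" * 7 + "A" * 193,))
        result = screen_assay(fam, PAIR, {"tx": "ACGT" * 100})
        assert result.conservation_rate == pytest.approx(96.5)
        assert not result.conservation_pass

    def test_no_upper_adequacy_gate(self):
        transcripts, records = generate_transcriptome(
            120, PAIR, insertion_prob=1.0, seed=6
        )
        result = screen_assay(
            RepeatFamily("f", "A" * 50, ("A" * 50,)), PAIR, transcripts
        )
        assert result.n_targets[3] == len(records) == 120
        assert result.adequacy_pass


class TestPrimerValidation:
    def test_non_acgt_rejected(self):
        with pytest.raises(ScreenError):
            PrimerPair("x", "ACGTNACGTACGTACGTA", "ACGTACGTACGTACGT")

    def test_length_bounds(self):
        with pytest.raises(ScreenError):
            PrimerPair("x", "ACGT", "ACGTACGTACGTACGT")

    def test_lowercase_accepted_and_upcased(self):
        pair = PrimerPair("x", "ggttggaatgggtgtgtcac", "tggcttacaggttcagaggt")
        assert pair.forward == "GGTTGGAATGGGTGTGTCAC"


def test_alignment_fasta_reader(tmp_path):
    path = tmp_path / "fam.fa"
    path.write_text(">cons\nAC-GT\n>copy1\nACTGT\n>copy2\nACCGT\n")
    fam = read_alignment_fasta(path)
    assert fam.family_id == "cons"
    assert len(fam.copies) == 2
    assert conservation_rate(fam) == 100.0
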