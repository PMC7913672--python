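import numpy as np
import pytest

from noseq import (
    ReferenceAmplicon,
    StructuredRead,
    SubstitutionMatrix,
    ValidationError,
    align_all,
    build_index,
    extend_and_score,
    seed_matches,
)
from noseq.align import AlignedRead, Rejection

from conftest import DNA_53MER, fully_deaminated, make_read

MATRIX = SubstitutionMatrix.default()
PLUS_ONE = {("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
            ("G", "A"), ("A", "G"), ("T", "C")}


def brute_force_align(insert: str, reference: ReferenceAmplicon,
                      matrix: SubstitutionMatrix = MATRIX) -> tuple[bool, int | None]:
    """Independent oracle: score every ungapped placement directly.

    Accepts iff some placement has score == read length, starts at
    reference position 1, and spans the whole reference.
    """
    ref = reference.sequence
    n, l = len(ref), len(insert)
    best = None
    for start in range(n - l + 1):
        score = sum(matrix.score(b, r) if b in "ACGT" else -1
                    for b, r in zip(insert, ref[start:start + l]))
        if score == l and start == 0 and l == n:
            return True, score
    return False, None


class TestSubstitutionMatrix:
    def test_plus_one_entries_exactly(self):
        for rb in "ACGT":
            for fb in "ACGT":
                expected = 1 if (rb, fb) in PLUS_ONE else -1
                assert MATRIX.score(rb, fb) == expected

    def test_asymmetry_is_load_bearing(self):
        # read T over reference C is a deamination signal; the transpose is not
        assert MATRIX.score("T", "C") == 1
        assert MATRIX.score("C", "T") == -1

    def test_table_round_trip(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        MATRIX.to_table(path)
        assert (SubstitutionMatrix.from_table(path).scores == MATRIX.scores).all()

    def test_non_unit_entries_rejected(self):
        with pytest.raises(ValidationError):
            SubstitutionMatrix(np.zeros((4, 4)))


class TestKmerIndex:
    def test_53mer_has_43_start_positions(self, ref53):
        index = build_index(ref53, k=11)
        starts = [p for _, positions in index.entries for p in positions]
        assert len(starts) == 53 - 11 + 1 == 43
        assert sorted(starts) == list(range(1, 44))

    def test_single_entry_reference(self):
        ref = ReferenceAmplicon("x", "ACGT")
        index = build_index(ref, k=4)
        assert index.entries == (("ACGT", (1,)),)

    def test_entries_alphabetically_ordered(self, ref53):
        kmers = [kmer for kmer, _ in build_index(ref53, k=11).entries]
        assert kmers == sorted(kmers)

    @pytest.mark.parametrize("k", [0, -3, 54])
    def test_invalid_k_rejected(self, ref53, k):
        with pytest.raises(ValidationError):
            build_index(ref53, k=k)


class TestSeedMatches:
    def test_identity_segment_seeds(self, ref53):
        index = build_index(ref53, k=11)
        read = DNA_53MER[10:30]
        seeds = seed_matches(read, index, MATRIX)
        assert (1, 11) in seeds

    def test_deaminated_homopolymer_seeds(self):
        # G onto A scores +1 at all 11 positions -> a valid seed
        ref = ReferenceAmplicon("polyA", "A" * 11)
        seeds = seed_matches("G" * 11, build_index(ref, k=11), MATRIX)
        assert seeds == [(1, 1)]

    def test_incompatible_homopolymer_does_not_seed(self):
        ref = ReferenceAmplicon("polyC", "C" * 11)
        assert seed_matches("A" * 11, build_index(ref, k=11), MATRIX) == []


class TestExtendAndScore:
    def test_fully_deaminated_53mer_scores_53(self, ref53):
        read = make_read(fully_deaminated(DNA_53MER))
        result = extend_and_score(read, (1, 1), ref53)
        assert isinstance(result, AlignedRead)
        assert result.score == 53 == len(read.insert)
        assert result.reference_start == 1

    def test_reference_verbatim_scores_length(self, ref53):
        result = extend_and_score(make_read(DNA_53MER), (1, 1), ref53)
        assert isinstance(result, AlignedRead)
        assert result.score == 53

    def test_single_minus_one_pairing_rejects(self, ref53):
        # a C over the reference T at position 2 is not a deamination product
        read = list(DNA_53MER)
        assert read[1] == "T"
        read[1] = "C"
        result = extend_and_score(make_read("".join(read)), (1, 1), ref53)
        assert isinstance(result, Rejection)
        assert result.reason == "score"

    def test_off_anchor_placement_rejected(self, ref53):
        result = extend_and_score(make_read(DNA_53MER[10:]), (1, 11), ref53)
        assert isinstance(result, Rejection)
        assert result.reason == "anchor"

    def test_extension_beyond_reference_is_coverage(self, ref53):
        result = extend_and_score(make_read(DNA_53MER + "AAAA"), (1, 1), ref53)
        assert isinstance(result, Rejection)
        assert result.reason == "coverage"


class TestAlignAll:
    def test_untouched_reads_all_align(self, ref53):
        reads = [make_read(DNA_53MER, f"r{i}") for i in range(10)]
        result = align_all(reads, ref53)
        assert result.n_reads == 10
        assert result.stats["input"] == result.stats["accepted"] == 10

    def test_truncated_reads_rejected_for_coverage(self, ref53):
        reads = [make_read(DNA_53MER[:30], "trunc"), make_read(DNA_53MER, "full")]
        result = align_all(reads, ref53)
        assert result.n_reads == 1
        (rej,) = result.rejections
        assert rej.reason == "coverage"

    def test_reads_with_n_discarded(self, ref53):
        read = make_read("N" + DNA_53MER[1:], "withN")
        result = align_all([read], ref53)
        assert result.n_reads == 0
        assert result.rejections[0].reason == "N"

    def test_funnel_conserves_reads(self, ref53):
        reads = [
            make_read(DNA_53MER, "ok"),
            make_read(fully_deaminated(DNA_53MER), "deam"),
            make_read(DNA_53MER[:20], "trunc"),
            make_read("C" * 53, "junk"),
            make_read("NN" + DNA_53MER[2:], "withN"),
        ]
        result = align_all(reads, ref53)
        s = result.stats
        total = (s["accepted"] + s["rejected_score"] + s["rejected_anchor"]
                 + s["rejected_coverage"] + s["rejected_no_seed"])
        assert total == s["input"] == 5
        assert s["input"] >= s["seeded"] >= s["score_ok"] >= s["accepted"]

    def test_monotone_degeneracy(self, ref53):
        """Extra A->G or C->T conversions never break an accepted read."""
        rng = np.random.default_rng(7)
        base = fully_deaminated(DNA_53MER)  # start from an accepted read
        assert align_all([make_read(DNA_53MER)], ref53).n_reads == 1
        for _ in range(50):
            read = list(DNA_53MER)
            for i in rng.choice(53, size=rng.integers(1, 53), replace=False):
                if read[i] == "A":
                    read[i] = "G"
                elif read[i] == "C":
                    read[i] = "T"
            assert align_all([make_read("".join(read))], ref53).n_reads == 1

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Seed-and-extend equals exhaustive placement scoring."""
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            length = int(rng.integers(20, 41))
            ref = ReferenceAmplicon("r", "".join(bases[rng.integers(0, 4, length)]))
            for _ in range(25):
                insert = _mutate(ref.sequence, rng)
                read = make_read(insert)
                mine = align_all([read], ref, k=min(11, len(insert), length))
                accepted, score = brute_force_align(insert, ref)
                assert (mine.n_reads == 1) == accepted
                if accepted:
                    assert mine.reads[0].score == score


def _mutate(sequence: str, rng: np.random.Generator) -> str:
    """Random deamination-like and adversarial edits for oracle comparison."""
    seq = list(sequence)
    for i in range(len(seq)):
        u = rng.random()
        if seq[i] == "A" and u < 0.4:
            seq[i] = "G"
        elif seq[i] == "C" and u < 0.4:
            seq[i] = "T"
        elif u < 0.08:  # sprinkle incompatible errors
            seq[i] = "ACGT"[rng.integers(0, 4)]
    # occasionally truncate or shift
    u = rng.random()
    if u < 0.15:
        seq = seq[: rng.integers(5, len(seq)) ]
    elif u < 0.25:
        seq = seq[rng.integers(1, 5) :]
    return "".join(seq)
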