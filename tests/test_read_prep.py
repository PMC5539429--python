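"""Read preparation: Hamming scan, tag extraction, FASTQ accounting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnseq_ci.read_prep import (
    DEFAULT_TN_SEQUENCE as TN,
    PrepAccounting,
    ReadPrepParams,
    _scan_batch,
    extract_tag,
    find_transposon,
    hamming,
    process_fastq,
)
from tnseq_ci.reference import revcomp

P = ReadPrepParams()


def mutate(seq: str, positions, rng=None) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def rand_dna(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("NNNN", "ACGT", 4),
         ("NN", "NN", 2)],
    )
    def test_distance(self, a, b, d):
        assert hamming(a, b) == d

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming("ACG", "ACGT")


def brute_force_find(read: str, params: ReadPrepParams):
    """Oracle: exhaustive scan, leftmost offset of minimal distance."""
    tn = params.tn_sequence
    best, best_d = None, None
    for o in range(len(read) - len(tn) + 1):
        d = hamming(read[o : o + len(tn)], tn)
        if best_d is None or d < best_d:
            best, best_d = o, d
    if best_d is None or best_d > params.max_mismatches:
        return None
    return best


class TestFindTransposon:
    def test_perfect_match_at_zero(self):
        read = TN + "ACGTACGTACGTACGTACGT"
        assert find_transposon(read, P) == 0

    def test_four_mismatches_rejected(self):
        read = mutate(TN, [0, 8, 16, 24]) + "ACGTACGTACGTACGTA"
        assert find_transposon(read, P) is None

    def test_three_mismatches_accepted(self):
        read = mutate(TN, [0, 8, 16]) + "ACGTACGTACGTACGTA"
        assert find_transposon(read, P) == 0

    def test_leftmost_minimal_wins(self):
        # a 2-mismatch match at offset 4 beats a later 3-mismatch match
        rng = random.Random(0)
        read = rand_dna(4, rng) + mutate(TN, [3, 17]) + rand_dna(10, rng)
        assert find_transposon(read, P) == 4
        assert brute_force_find(read, P) == 4

    def test_short_read_returns_none(self):
        assert find_transposon("ACGT", P) is None

    def test_revcomp_input(self):
        read = TN + "ACGTACGTACGTACGTACGT"
        params = ReadPrepParams(revcomp_input=True)
        assert find_transposon(revcomp(read), params) == 0

    def test_anchor0_restricts_offsets(self):
        read = "ACGT" + TN + "ACGTACGTACGTACGTA"
        assert find_transposon(read, ReadPrepParams(anchor0=True)) is None
        assert find_transposon(read, P) == 4

    def test_exact_mode_is_substring_search(self):
        rng = random.Random(1)
        params = ReadPrepParams(max_mismatches=0)
        for _ in range(200):
            read = rand_dna(8, rng) + TN + rand_dna(20, rng)
            assert find_transposon(read, params) == read.index(TN)

    def test_oracle_equivalence_random_reads(self):
        rng = random.Random(7)
        for _ in range(2000):
            kind = rng.randrange(3)
            if kind == 0:
                read = rand_dna(60, rng)
            else:
                n_err = rng.randrange(0, 4) if kind == 1 else rng.randrange(4, 7)
                offset = rng.randrange(0, 60 - 32 + 1)
                body = mutate(TN, rng.sample(range(32), n_err))
                read = rand_dna(offset, rng) + body + rand_dna(60 - 32 - offset, rng)
            assert find_transposon(read, P) == brute_force_find(read, P)

    def test_vectorized_scan_matches_scalar(self):
        rng = random.Random(13)
        reads = []
        for _ in range(500):
            length = rng.choice([20, 31, 32, 40, 60])
            reads.append(rand_dna(length, rng))
            reads.append(
                rand_dna(5, rng)[: rng.randrange(6)]
                + mutate(TN, rng.sample(range(32), rng.randrange(5)))
            )
        offsets, _ = _scan_batch(reads, P)
        for read, off in zip(reads, offsets):
            expected = find_transposon(read, P)
            assert (None if off < 0 else int(off)) == expected


@given(read=st.text(alphabet="ACGTN", min_size=1, max_size=80))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_find_transposon_equals_oracle_property(read):
    """Scanning matches the exhaustive minimal-distance oracle on arbitrary
    reads, including N-containing and sub-transposon-length ones."""
    assert find_transposon(read, P) == brute_force_find(read, P)


@given(
    a=st.text(alphabet="ACGTN", min_size=1, max_size=50),
    b=st.text(alphabet="ACGTN", min_size=1, max_size=50),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hamming_symmetry_and_bounds(a, b):
    if len(a) != len(b):
        with pytest.raises(ValueError):
            hamming(a, b)
        return
    d = hamming(a, b)
    assert d == hamming(b, a)
    assert 0 <= d <= len(a)
    if "N" not in a and "N" not in b and a == b:
        assert d == 0


class TestExtractTag:
    def test_bases_after_match(self):
        read = TN + "ACGTACGTACGTACGTACGTACGTACGT"
        assert extract_tag(read, 0, P) == "ACGTACGTACGTACGTA"

    def test_too_short(self):
        read = TN + "ACGTACGT"  # only 8 bases remain
        assert extract_tag(read, 0, P) is None

    def test_n_returned_verbatim(self):
        read = TN + "NNNNNNNNNNNNNNNNN"
        assert extract_tag(read, 0, P) == "N" * 17


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")


class TestProcessFastq:
    def test_three_way_accounting(self, tmp_path):
        reads = [
            TN + "A" * 20,                      # used
            mutate(TN, [0, 8, 16, 24]) + "A" * 20,  # no transposon
            TN + "ACGT",                        # too short for a tag
        ]
        fq = tmp_path / "t.fastq"
        write_fastq(fq, reads)
        tags, acct = process_fastq(fq)
        assert (acct.reads_used, acct.reads_no_tn, acct.reads_too_short) == (1, 1, 1)
        assert acct.total_reads == 3
        assert tags == {"A" * 17: 1}

    def test_empty_file(self, tmp_path):
        fq = tmp_path / "e.fastq"
        fq.write_text("")
        tags, acct = process_fastq(fq)
        assert acct == PrepAccounting(0, 0, 0, 0) and not tags

    def test_accounting_conservation_noisy_reads(self, tmp_path):
        rng = random.Random(3)
        reads = []
        for _ in range(3000):
            body = mutate(TN, [p for p in range(32) if rng.random() < 0.03])
            reads.append(body + rand_dna(rng.choice([5, 17, 28]), rng))
        fq = tmp_path / "n.fastq"
        write_fastq(fq, reads)
        tags, acct = process_fastq(fq, batch_size=512)
        assert acct.total_reads == 3000
        assert acct.total_reads == acct.reads_no_tn + acct.reads_too_short + acct.reads_used
        assert sum(tags.values()) == acct.reads_used

    def test_revcomp_mode(self, tmp_path):
        read = TN + "ACGTACGTACGTACGTA" + "GGGGGGGGGGG"
        fq = tmp_path / "rc.fastq"
        write_fastq(fq, [revcomp(read)])
        tags, acct = process_fastq(fq, ReadPrepParams(revcomp_input=True))
        assert acct.reads_used == 1
        assert tags == {"ACGTACGTACGTACGTA": 1}

    def test_truncated_record_rejected(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r0\nACGT\n+\n")  # missing quality line
        with pytest.raises(ValueError):
            process_fastq(fq)
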