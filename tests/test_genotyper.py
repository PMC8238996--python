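"""FASTQ junction scanning, VAF arithmetic and the three-way call."""

import gzip
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from alugrep.allele_model import junction_queries
from alugrep.genotyper import (
    CALL_DETECTED,
    CALL_INSUFFICIENT,
    CALL_NO_INSERTION,
    CALL_SUSPECTED,
    ClassificationPolicy,
    FastqParseError,
    JunctionCounts,
    classify_call,
    compute_vaf,
    count_read_matches,
    genotype_sample,
    reverse_complement,
    scan_fastq,
)

from conftest import random_seq, write_fastq


def brute_force_matches(read: str, query: str, max_mismatch: int) -> int:
    """Independent oracle: test every offset with an explicit Hamming count."""
    read, query = read.upper(), query.upper()
    if not query or len(query) > len(read):
        return 0
    hits = 0
    for offset in range(len(read) - len(query) + 1):
        dist = 0
        for r, q in zip(read[offset: offset + len(query)], query):
            if r != q or r not in "ACGT" or q not in "ACGT":
                dist += 1
        if dist <= max_mismatch:
            hits += 1
    return hits


class TestCountReadMatches:
    def test_verbatim_single_occurrence(self):
        read = "TTTT" + "ACGTACGTAC" + "GGGG"
        assert count_read_matches(read, "ACGTACGTAC", 0) == 1

    def test_one_substitution_needs_mismatch_allowance(self):
        query = "ACGTACGTACGT"
        mutated = "ACGTACTTACGT"  # one substitution
        read = "GGGG" + mutated + "CCCC"
        assert count_read_matches(read, query, 0) == 0
        assert count_read_matches(read, query, 1) == 1

    def test_query_longer_than_read_returns_zero(self):
        assert count_read_matches("ACGT", "ACGTACGT", 1) == 0

    def test_n_positions_never_match(self):
        read = "TTTTACGNACGTTTTT"
        assert count_read_matches(read, "ACGNACGT", 0) == 0
        # the N costs one mismatch on each side
        assert count_read_matches(read, "ACGAACGT", 1) == 1

    def test_invalid_mismatch_budget(self):
        with pytest.raises(ValueError):
            count_read_matches("ACGT", "AC", 3)

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, max_mismatch):
        rng = random.Random(1234 + max_mismatch)
        for _ in range(400):
            read = random_seq(rng, rng.randint(30, 100))
            if rng.random() < 0.3:
                query = random_seq(rng, rng.randint(8, 26))
            else:
                # plant the query with a few substitutions to hit near-misses
                query = random_seq(rng, rng.randint(8, 26))
                pos = rng.randrange(0, len(read) - len(query) + 1)
                planted = list(query)
                for _ in range(rng.randint(0, 2)):
                    j = rng.randrange(len(planted))
                    planted[j] = rng.choice("ACGT")
                read = read[:pos] + "".join(planted) + read[pos + len(query):]
            assert count_read_matches(read, query, max_mismatch) == \
                brute_force_matches(read, query, max_mismatch)

    def test_monotone_in_mismatch_budget(self):
        rng = random.Random(99)
        for _ in range(200):
            read = random_seq(rng, 80)
            query = random_seq(rng, 20)
            c0 = count_read_matches(read, query, 0)
            c1 = count_read_matches(read, query, 1)
            c2 = count_read_matches(read, query, 2)
            assert c0 <= c1 <= c2


class TestScanFastq:
    @pytest.fixture()
    def queries(self, demo_event):
        return junction_queries(demo_event)

    def embed(self, core, rng, read_len=80):
        pad = read_len - len(core)
        left = random_seq(rng, rng.randint(0, pad))
        return left + core + random_seq(rng, pad - len(left))

    def test_three_record_file(self, tmp_path, demo_event, queries):
        rng = random.Random(3)
        mut_q = next(q for q in queries if q.kind == "mutant_5prime").sequence
        wt_q = next(q for q in queries if q.kind == "wildtype").sequence
        path = write_fastq(tmp_path / "t.fastq", [
            ("m", self.embed(mut_q, rng)),
            ("w", self.embed(wt_q, rng)),
            ("n", random_seq(rng, 80)),
        ])
        counts = scan_fastq([path], queries)
        assert (counts.mutant_reads, counts.wildtype_reads) == (1, 1)
        assert counts.total_reads_scanned == 3

    def test_strand_symmetry(self, tmp_path, queries):
        rng = random.Random(4)
        mut_q = next(q for q in queries if q.kind == "mutant_5prime").sequence
        wt_q = next(q for q in queries if q.kind == "wildtype").sequence
        reads = [
            ("m", self.embed(mut_q, rng)),
            ("w", self.embed(wt_q, rng)),
            ("n", random_seq(rng, 80)),
        ]
        fwd = write_fastq(tmp_path / "fwd.fastq", reads)
        rev = write_fastq(
            tmp_path / "rev.fastq",
            [(n, reverse_complement(s)) for n, s in reads],
        )
        a = scan_fastq([fwd], queries, search_revcomp=True)
        b = scan_fastq([rev], queries, search_revcomp=True)
        assert (a.mutant_reads, a.wildtype_reads) == (b.mutant_reads, b.wildtype_reads)

    def test_forward_only_mode_misses_reverse_reads(self, tmp_path, queries):
        rng = random.Random(5)
        mut_q = next(q for q in queries if q.kind == "mutant_5prime").sequence
        rev = write_fastq(
            tmp_path / "r.fastq",
            [("m", reverse_complement(self.embed(mut_q, rng)))],
        )
        assert scan_fastq([rev], queries, search_revcomp=False).mutant_reads == 0
        assert scan_fastq([rev], queries, search_revcomp=True).mutant_reads == 1

    def test_gzip_input(self, tmp_path, queries):
        rng = random.Random(6)
        mut_q = next(q for q in queries if q.kind == "mutant_5prime").sequence
        path = tmp_path / "t.fastq.gz"
        with gzip.open(path, "wt") as fh:
            seq = self.embed(mut_q, rng)
            fh.write(f"@m\n{seq}\n+\n{'I' * len(seq)}\n")
        assert scan_fastq([path], queries).mutant_reads == 1

    def test_malformed_record_reports_file_and_index(self, tmp_path, queries):
        path = tmp_path / "bad.fastq"
        path.write_text("@ok\nACGT\n+\nIIII\n@bad\nACGTACGT\n+\nIII\n")
        with pytest.raises(FastqParseError) as err:
            scan_fastq([path], queries)
        assert "bad.fastq" in str(err.value)
        assert err.value.record_index == 1

    def test_missing_file_raises(self, tmp_path, queries):
        with pytest.raises(OSError):
            scan_fastq([tmp_path / "absent.fastq"], queries)

    def test_requires_both_query_categories(self, tmp_path, queries):
        path = write_fastq(tmp_path / "t.fastq", [("r", "ACGT" * 20)])
        mutant_only = [q for q in queries if q.is_mutant]
        with pytest.raises(ValueError):
            scan_fastq([path], mutant_only)

    def test_scan_matches_naive_rescan_on_simulated_het(self, het_sample, demo_event):
        queries = junction_queries(demo_event)
        counts = scan_fastq([het_sample["fastq"]], queries)
        # independent whole-file rescan with the brute-force matcher
        mut = wt = total = 0
        lines = het_sample["fastq"].read_text().splitlines()
        for i in range(0, len(lines), 4):
            seq = lines[i + 1]
            rc = reverse_complement(seq)
            total += 1
            mut_qs = [q.sequence for q in queries if q.is_mutant]
            wt_qs = [q.sequence for q in queries if not q.is_mutant]
            if any(brute_force_matches(s, q, 0) for s in (seq, rc) for q in mut_qs):
                mut += 1
            if any(brute_force_matches(s, q, 0) for s in (seq, rc) for q in wt_qs):
                wt += 1
        assert (counts.mutant_reads, counts.wildtype_reads, counts.total_reads_scanned) \
            == (mut, wt, total)


class TestVafAndClassification:
    def test_worked_example(self):
        counts = JunctionCounts(mutant_reads=10, wildtype_reads=41)
        vaf = compute_vaf(counts)
        assert vaf == pytest.approx(10 / 51)
        assert round(100 * vaf, 1) == 19.6
        assert classify_call(vaf) == CALL_SUSPECTED

    def test_zero_mutant(self):
        assert compute_vaf(JunctionCounts(mutant_reads=0, wildtype_reads=50)) == 0.0

    def test_symmetric_counts(self):
        assert compute_vaf(JunctionCounts(mutant_reads=5, wildtype_reads=5)) == 0.5

    def test_undefined_when_no_junction_reads(self):
        assert compute_vaf(JunctionCounts()) is None
        assert classify_call(None) == CALL_INSUFFICIENT

    @pytest.mark.parametrize("vaf,expected", [
        (0.05, CALL_NO_INSERTION),
        (0.0999, CALL_NO_INSERTION),
        (0.1, CALL_SUSPECTED),
        (0.196, CALL_SUSPECTED),
        (0.2999, CALL_SUSPECTED),
        (0.3, CALL_DETECTED),
        (0.447, CALL_DETECTED),
        (1.0, CALL_DETECTED),
        (0.0, CALL_NO_INSERTION),
    ])
    def test_threshold_boundaries(self, vaf, expected):
        assert classify_call(vaf) == expected

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            ClassificationPolicy(0.3, 0.1)
        with pytest.raises(ValueError):
            ClassificationPolicy(0.0, 0.3)

    def test_out_of_range_vaf_rejected(self):
        with pytest.raises(ValueError):
            classify_call(1.5)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_classification_exhaustive_and_exclusive(self, vaf):
        call = classify_call(vaf)
        assert call in {CALL_NO_INSERTION, CALL_SUSPECTED, CALL_DETECTED}

    @given(
        wildtype=st.integers(1, 500),
        mutant_lo=st.integers(0, 200),
        delta=st.integers(1, 50),
    )
    def test_vaf_monotone_in_mutant_count(self, wildtype, mutant_lo, delta):
        lo = compute_vaf(JunctionCounts(mutant_reads=mutant_lo, wildtype_reads=wildtype))
        hi = compute_vaf(
            JunctionCounts(mutant_reads=mutant_lo + delta, wildtype_reads=wildtype)
        )
        assert 0.0 <= lo < hi <= 1.0

    def test_noise_floor_spurious_reads_stay_negative(self):
        # 1-2 stray junction-like reads against deep wildtype coverage must
        # not trigger a call
        for spurious in (1, 2):
            counts = JunctionCounts(mutant_reads=spurious, wildtype_reads=60)
            vaf = compute_vaf(counts)
            assert vaf < 0.1
            assert classify_call(vaf) == CALL_NO_INSERTION


class TestGenotypeSample:
    def test_simulated_het_detected(self, het_sample, demo_event):
        call = genotype_sample([het_sample["fastq"]], demo_event)
        assert call.call == CALL_DETECTED
        assert 0.3 <= call.vaf <= 0.7

    def test_simulated_wildtype_negative(self, wildtype_sample, demo_event):
        call = genotype_sample([wildtype_sample["fastq"]], demo_event)
        assert call.counts.mutant_reads == 0
        assert call.call == CALL_NO_INSERTION

    def test_empty_fastq_insufficient_data(self, tmp_path, demo_event):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        call = genotype_sample([path], demo_event)
        assert call.vaf is None
        assert call.call == CALL_INSUFFICIENT

    def test_multi_file_sample_pools_counts(self, het_sample, demo_event, tmp_path):
        single = genotype_sample([het_sample["fastq"]], demo_event)
        double = genotype_sample([het_sample["fastq"], het_sample["fastq"]], demo_event)
        assert double.counts.mutant_reads == 2 * single.counts.mutant_reads
        assert double.counts.total_reads_scanned == 2 * single.counts.total_reads_scanned
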