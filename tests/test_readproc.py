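import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecap.design import TargetGene, reverse_complement
from spikecap.readproc import (
    FilterConfig,
    FilterSummary,
    ReadRecord,
    find_best_match,
    filter_r1,
    filter_r2,
    normalize_read_id,
    r2_target_query,
    read_fastq,
    reconcile_pairs,
    write_fastq,
)


def brute_force_best(read, pattern, max_mismatch, both):
    """Independent O(n*m) oracle with explicit N semantics and tie-breaking."""
    queries = [("forward", pattern)]
    if both:
        queries.append(("reverse-complement", reverse_complement(pattern)))
    best = None
    for rank, (orient, q) in enumerate(queries):
        for pos in range(len(read) - len(q) + 1):
            mm = 0
            for rc, qc in zip(read[pos : pos + len(q)], q):
                if qc == "N":
                    continue
                if rc == "N" or rc != qc:
                    mm += 1
            if mm <= max_mismatch:
                key = (mm, pos, rank)
                if best is None or key < best:
                    best = key
    return best  # (mismatches, position, orientation rank) or None


def _hit_key(hit):
    if hit is None:
        return None
    return (hit.mismatches, hit.position, 0 if hit.orientation == "forward" else 1)


class TestFindBestMatch:
    def test_exact_containment(self):
        read = "T" * 30 + "AGGGTCAGTAAGCACCCGCG" + "A" * 20
        hit = find_best_match(read, "AGGGTCAGTAAGCACCCGCG", 0)
        assert hit.position == 30 and hit.mismatches == 0
        assert hit.orientation == "forward"

    def test_single_substitution_needs_budget(self):
        pattern = "AGGGTCAGTAAGCACCCGCG"
        read = "T" * 10 + pattern[:7] + "C" + pattern[8:] + "A" * 10
        assert pattern[7] != "C"
        hit = find_best_match(read, pattern, 1)
        assert hit.mismatches == 1 and hit.position == 10
        assert find_best_match(read, pattern, 0) is None

    def test_reverse_complement_orientation(self):
        pattern = "AAACCCGGGTTA"
        read = "G" * 5 + reverse_complement(pattern) + "G" * 5
        assert find_best_match(read, pattern, 0) is None
        hit = find_best_match(read, pattern, 0, both_orientations=True)
        assert hit.orientation == "reverse-complement" and hit.position == 5

    def test_pattern_longer_than_read(self):
        assert find_best_match("ACGT", "ACGTACGT", 2) is None

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            find_best_match("ACGT", "", 0)

    def test_n_in_read_counts_as_mismatch(self):
        assert find_best_match("ANGT", "ACGT", 0) is None
        assert find_best_match("ANGT", "ACGT", 1).mismatches == 1

    def test_n_in_pattern_matches_anything(self):
        assert find_best_match("ACGT", "ANGT", 0).mismatches == 0

    def test_forward_preferred_on_tie(self):
        # palindromic pattern: identical forward and RC matches everywhere
        read = "ACGTACGT"
        hit = find_best_match(read, "ACGT", 0, both_orientations=True)
        assert hit.orientation == "forward" and hit.position == 0

    def test_random_read_no_hit(self):
        rng = np.random.default_rng(5)
        read = "".join(rng.choice(list("ACGT"), 100))
        pattern = "AGGGTCAGTAAGCACCCGCG"
        assert _hit_key(find_best_match(read, pattern, 1, True)) == brute_force_best(
            read, pattern, 1, True
        )

    @settings(max_examples=300, deadline=None)
    @given(st.data())
    def test_oracle_equivalence(self, data):
        read = data.draw(st.text(alphabet="ACGTN", min_size=5, max_size=40))
        plen = data.draw(st.integers(1, len(read)))
        pattern = data.draw(st.text(alphabet="ACGTN", min_size=plen, max_size=plen))
        budget = data.draw(st.integers(0, 3))
        both = data.draw(st.booleans())
        got = find_best_match(read, pattern, budget, both)
        assert _hit_key(got) == brute_force_best(read, pattern, budget, both)


@pytest.fixture(scope="module")
def toy_target():
    return TargetGene("toy", "ACGTTGCAAGGCTTAACCGGTTAGCATG" * 3)


class TestFilterR1:
    def _reads(self, target, n_true, n_random, seed=0):
        rng = np.random.default_rng(seed)
        offset = 39
        reads = []
        for i in range(n_true):
            pad = "".join(rng.choice(list("ACGT"), offset))
            seq = pad + target.sequence[:50]
            reads.append(ReadRecord(f"t{i}", seq, "I" * len(seq)))
        for i in range(n_random):
            seq = "".join(rng.choice(list("ACGT"), offset + 50))
            reads.append(ReadRecord(f"r{i}", seq, "I" * len(seq)))
        return reads

    def test_true_reads_pass_random_fail(self, toy_target):
        cfg = FilterConfig(max_mismatch=1, r1_query_len=40)
        reads = self._reads(toy_target, 10, 5)
        summary = FilterSummary()
        passed = list(filter_r1(reads, toy_target, cfg, summary=summary))
        assert [r.read_id for r, _ in passed] == [f"t{i}" for i in range(10)]
        assert summary.reads_in == 15 and summary.reads_passed == 10

    def test_short_reads_skipped_and_counted(self, toy_target):
        cfg = FilterConfig(max_mismatch=0, r1_query_len=40)
        summary = FilterSummary()
        short = ReadRecord("s", "ACGT", "IIII")
        assert list(filter_r1([short], toy_target, cfg, summary=summary)) == []
        assert summary.reads_skipped_short == 1

    def test_hit_position_includes_offset(self, toy_target):
        cfg = FilterConfig(max_mismatch=0, r1_query_len=20)
        read = ReadRecord("x", "G" * 39 + toy_target.sequence[:30], "I" * 69)
        [(rec, hit)] = list(filter_r1([read], toy_target, cfg))
        assert hit.position == 39

    def test_budget_monotonicity(self, toy_target):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(60):
            base = "G" * 39 + toy_target.sequence[:45]
            arr = list(base)
            for _ in range(rng.integers(0, 5)):
                j = rng.integers(39, len(arr))
                arr[j] = rng.choice(list("ACGT"))
            reads.append(ReadRecord(f"m{i}", "".join(arr), "I" * len(arr)))
        previous = set()
        for budget in range(6):
            cfg = FilterConfig(max_mismatch=budget, r1_query_len=40)
            current = {r.read_id for r, _ in filter_r1(reads, toy_target, cfg)}
            assert previous <= current
            previous = current


class TestFilterR2(object):
    def test_true_r2_passes(self, design, target):
        cfg = FilterConfig(max_mismatch=1)
        end = design.anchor_interval[1]
        seq = (
            "A" * 10
            + design.feature_barcode
            + "C" * 9
            + reverse_complement(target.sequence[:end])
        )[:100]
        read = ReadRecord("r", seq, "I" * len(seq))
        [(rec, bc_hit, t_hit)] = list(filter_r2([read], target, design, cfg))
        assert bc_hit.mismatches == 0
        assert t_hit.mismatches == 0
        assert t_hit.orientation == "reverse-complement"

    def test_barcode_without_target_fails(self, design, target):
        cfg = FilterConfig(max_mismatch=1)
        rng = np.random.default_rng(1)
        seq = (
            "A" * 10
            + design.feature_barcode
            + "C" * 9
            + "".join(rng.choice(list("ACGT"), 66))
        )
        read = ReadRecord("r", seq, "I" * len(seq))
        assert list(filter_r2([read], target, design, cfg)) == []

    def test_target_without_barcode_fails(self, design, target):
        cfg = FilterConfig(max_mismatch=1)
        end = design.anchor_interval[1]
        seq = ("A" * 34 + reverse_complement(target.sequence[:end]))[:100]
        read = ReadRecord("r", seq, "I" * len(seq))
        assert list(filter_r2([read], target, design, cfg)) == []

    def test_barcode_only_mode_admits_nonspecific(self, design, target):
        cfg = FilterConfig(max_mismatch=1)
        rng = np.random.default_rng(2)
        seq = (
            "A" * 10
            + design.feature_barcode
            + "C" * 9
            + "".join(rng.choice(list("ACGT"), 66))
        )
        read = ReadRecord("r", seq, "I" * len(seq))
        out = list(filter_r2([read], target, design, cfg, require_target=False))
        assert len(out) == 1 and out[0][2] is None

    def test_r2_query_is_anchored_at_anchor_end(self, design, target):
        q = r2_target_query(target, design, 40)
        end = design.anchor_interval[1]
        assert q == target.sequence[end - 40 : end]


class TestReconcilePairs:
    def _rec(self, rid):
        return ReadRecord(rid, "ACGT", "IIII")

    def test_intersection(self):
        r1s = [self._rec(x) for x in "abc"]
        r2s = [self._rec(x) for x in "bcd"]
        pairs = list(reconcile_pairs({"a", "b", "c"}, {"b", "c", "d"}, r1s, r2s))
        assert {p.read_id for p in pairs} == {"b", "c"}
        for p in pairs:
            assert p.r1.read_id == p.r2.read_id == p.read_id

    def test_disjoint_sets_empty(self):
        r1s, r2s = [self._rec("a")], [self._rec("b")]
        assert list(reconcile_pairs({"a"}, {"b"}, r1s, r2s)) == []

    def test_duplicate_id_is_hard_error(self):
        r1s = [self._rec("a"), self._rec("a")]
        with pytest.raises(ValueError, match="duplicate read ID"):
            list(reconcile_pairs({"a"}, {"a"}, r1s, [self._rec("a")]))

    def test_pair_soundness_on_sim(self, clean_sim, design, target, anatomy):
        cfg = FilterConfig(max_mismatch=0, r1_insert_offset=anatomy.r1_insert_offset)
        r1_pass = [r.read_id for r, _ in filter_r1(clean_sim.r1, target, cfg)]
        r2_pass = [r.read_id for r, _, _ in filter_r2(clean_sim.r2, target, design, cfg)]
        pairs = list(reconcile_pairs(r1_pass, r2_pass, clean_sim.r1, clean_sim.r2))
        assert {p.read_id for p in pairs} == set(r1_pass) & set(r2_pass)
        assert len({p.read_id for p in pairs}) == len(pairs)


class TestFastqIO:
    def test_round_trip_and_id_normalization(self, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text(
            "@read1/1 comment here\nACGT\n+\nIIII\n@read2 xx\nGGTT\n+\nFFFF\n"
        )
        records = list(read_fastq(path))
        assert [r.read_id for r in records] == ["read1", "read2"]
        out = tmp_path / "y.fastq"
        assert write_fastq(records, out) == 2
        assert list(read_fastq(out)) == records

    def test_gzip_transparent(self, tmp_path):
        records = [ReadRecord("a", "ACGT", "IIII")]
        path = tmp_path / "z.fastq.gz"
        write_fastq(records, path)
        assert list(read_fastq(path)) == records

    def test_determinism(self, tmp_path, clean_sim):
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(clean_sim.r1, p1)
        write_fastq(clean_sim.r1, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_normalize_read_id(self):
        assert normalize_read_id("x/2") == "x"
        assert normalize_read_id("x y z") == "x"
        assert normalize_read_id("plain") == "plain"

    def test_mismatched_qual_length_rejected(self):
        with pytest.raises(ValueError):
            ReadRecord("a", "ACGT", "II")
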