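import numpy as np
import pytest

from durumir.io_formats import revcomp
from durumir.preprocess import UniqueReadTable
from durumir.hairpin_discovery import (
    AlignmentHit,
    MIN_LOOP,
    assign_category,
    coverage_metrics,
    discover,
    enumerate_locus_pairs,
    find_alignments,
    fold_hairpin,
    match_known,
    mircheck_like,
)
from durumir.synthdata import SimulationConfig, make_genome, reduced_design, simulate_study

PAIRABLE = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


class TestFindAlignments:
    def test_planted_read_one_perfect_hit(self):
        genome = make_genome(1, [2000], seed=1)
        read = genome["ctg01"][500:521]
        hits = find_alignments([read], genome, "perfect")
        assert hits == [AlignmentHit(read, "ctg01", 500, 521, "+", 0)]

    def test_reverse_complement_with_three_substitutions(self):
        genome = make_genome(1, [2000], seed=2)
        seg = list(genome["ctg01"][800:821])
        for p in (4, 10, 16):
            seg[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[p]]
        read = revcomp("".join(seg))
        hits = find_alignments([read], genome, "imperfect")
        assert AlignmentHit(read, "ctg01", 800, 821, "-", 3) in hits

    def test_one_mismatch_excluded_from_both_modes(self):
        genome = make_genome(1, [2000], seed=3)
        seg = list(genome["ctg01"][100:121])
        seg[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[10]]
        read = "".join(seg)
        perfect = [h for h in find_alignments([read], genome, "perfect") if h.start == 100]
        imperfect = [h for h in find_alignments([read], genome, "imperfect") if h.start == 100]
        assert perfect == [] and imperfect == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(13)
        genome = make_genome(1, [600], seed=13)
        contig = genome["ctg01"]
        reads = []
        for _ in range(30):
            off = int(rng.integers(0, 579))
            q = list(contig[off : off + 21])
            for p in rng.choice(21, size=int(rng.integers(0, 6)), replace=False):
                q[p] = str(rng.choice([b for b in "ACGT" if b != q[p]]))
            reads.append("".join(q))

        def brute(read, lo, hi):
            out = set()
            for q, strand in ((read, "+"), (revcomp(read), "-")):
                for off in range(len(contig) - 21 + 1):
                    mm = sum(a != b for a, b in zip(q, contig[off : off + 21]))
                    if lo <= mm <= hi:
                        out.add((off, strand, mm))
            return out

        for mode, lo, hi in (("perfect", 0, 0), ("imperfect", 2, 5)):
            hits = find_alignments(reads, genome, mode)
            by_read = {}
            for h in hits:
                by_read.setdefault(h.read_seq, set()).add((h.start, h.strand, h.mismatches))
            for r in reads:
                assert by_read.get(r, set()) == brute(r, lo, hi), (mode, r)


class TestLocusPairs:
    def _hit(self, read, start, end, strand, mm, contig="c"):
        return AlignmentHit(read, contig, start, end, strand, mm)

    def test_accepted_pair_arithmetic(self):
        p = self._hit("r", 100, 121, "+", 0)
        q = self._hit("r", 181, 202, "-", 3)
        pairs = enumerate_locus_pairs([p], [q], contig_lengths={"c": 10_000})
        assert len(pairs) == 1
        assert pairs[0].inner_gap == 60
        assert pairs[0].region == ("c", 80, 222)

    def test_gap_below_54_rejected(self):
        p = self._hit("r", 100, 121, "+", 0)
        q = self._hit("r", 161, 182, "-", 3)
        assert enumerate_locus_pairs([p], [q]) == []

    def test_same_strand_rejected(self):
        p = self._hit("r", 100, 121, "+", 0)
        q = self._hit("r", 181, 202, "+", 3)
        assert enumerate_locus_pairs([p], [q]) == []

    def test_different_reads_not_paired(self):
        p = self._hit("r1", 100, 121, "+", 0)
        q = self._hit("r2", 181, 202, "-", 3)
        assert enumerate_locus_pairs([p], [q]) == []

    def test_matches_brute_force_over_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            reads = [f"r{rng.integers(0, 5)}" for _ in range(n)]
            perfect, imperfect = [], []
            for r in reads:
                start = int(rng.integers(0, 2000))
                L = int(rng.integers(19, 27))
                strand = "+" if rng.random() < 0.5 else "-"
                h = self._hit(r, start, start + L, strand, 0)
                (perfect if rng.random() < 0.5 else imperfect).append(
                    h if rng.random() < 0.5 else self._hit(r, start, start + L, strand, int(rng.integers(2, 6)))
                )
            got = {
                (p.perfect.start, p.imperfect.start, p.region)
                for p in enumerate_locus_pairs(perfect, imperfect, contig_lengths={"c": 3000})
            }
            expected = set()
            for p in perfect:
                for q in imperfect:
                    if p.read_seq != q.read_seq or p.strand == q.strand:
                        continue
                    gap = max(p.start, q.start) - min(p.end, q.end)
                    if 54 <= gap <= 1000:
                        lo = max(min(p.start, q.start) - 20, 0)
                        hi = min(max(p.end, q.end) + 20, 3000)
                        expected.add((p.start, q.start, ("c", lo, hi)))
            assert got == expected


def oracle_max_pairs(seq):
    """Exhaustive enumeration of nested structures (min loop 3, WC + GU)."""
    s = seq.upper().replace("U", "T")

    def best(i, j):
        if j - i < MIN_LOOP + 1:
            return 0
        top = best(i, j - 1)
        for k in range(i, j - MIN_LOOP):
            if (s[k], s[j]) in PAIRABLE:
                left = best(i, k - 1) if k > i else 0
                top = max(top, left + 1 + best(k + 1, j - 1))
        return top

    return best(0, len(s) - 1)


class TestFold:
    def test_simple_hairpin(self):
        f = fold_hairpin("GGGAAACCC")
        assert f.structure == "(((...)))" and f.n_pairs == 3

    def test_no_complementarity(self):
        assert fold_hairpin("AAAAAA").n_pairs == 0

    def test_balanced_structure(self):
        f = fold_hairpin("GGCAUGCAUUCGAAAGCAUGCUAA")
        assert f.structure.count("(") == f.structure.count(")") == f.n_pairs

    def test_matches_exhaustive_oracle_up_to_14nt(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            n = int(rng.integers(4, 15))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert fold_hairpin(seq).n_pairs == oracle_max_pairs(seq), seq

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            fold_hairpin("ACGTNACGT")


class TestMircheck:
    def test_planted_hairpins_pass(self, study):
        for h in study.hairpins:
            fold = fold_hairpin(h.hairpin_sequence, (20, 20 + h.arm_length))
            ok, reasons = mircheck_like(fold, (20, 20 + h.arm_length))
            assert ok, (h.feature_id, reasons)

    def test_shuffled_sequences_fail(self, study):
        rng = np.random.default_rng(12)
        seq = list(study.hairpins[0].hairpin_sequence)
        fails = 0
        n = 200
        for _ in range(n):
            rng.shuffle(seq)
            fold = fold_hairpin("".join(seq), (20, 41))
            ok, _ = mircheck_like(fold, (20, 41))
            fails += not ok
        assert fails / n >= 0.95

    def test_unpairable_mature_fails_on_unpaired(self):
        seq = "A" * 120  # nothing can pair
        fold = fold_hairpin(seq, (20, 41))
        ok, reasons = mircheck_like(fold, (20, 41))
        assert not ok and "mature_unpaired" in reasons


class TestCoverageMetrics:
    def test_all_pass_example(self):
        reads = (
            [(5, 26, "+", 1)] * 0
            + [(10, 31, "+", 94)]  # 5' window
            + [(120, 141, "+", 3)]  # 3' window (region length 150)
            + [(60, 81, "+", 2)]  # loop
            + [(10, 31, "-", 1)]
        )
        m = coverage_metrics(150, reads)
        assert m.booleans == (True, True, True)
        assert m.strand_bias == pytest.approx(0.99)
        assert m.terminal_fraction == pytest.approx(0.95)
        assert m.loop_fraction == pytest.approx(0.02)

    def test_strand_bias_boundary(self):
        reads = [(0, 21, "+", 94), (0, 21, "-", 6)]
        m = coverage_metrics(150, reads)
        assert m.strand_bias == pytest.approx(0.94)
        assert m.booleans[0] is False

    def test_short_region_has_vacuous_loop_metric(self):
        reads = [(0, 21, "+", 10), (60, 81, "+", 10)]
        m = coverage_metrics(100, reads)
        assert m.loop_fraction == 0.0 and m.booleans[2]

    def test_boundary_tie_goes_to_terminal_window(self):
        # read straddling the window edge with an exact base split
        reads = [(38, 62, "+", 10)]  # 12 bases in window, 12 in loop
        m = coverage_metrics(200, reads)
        assert m.terminal_fraction == pytest.approx(1.0)
        assert m.loop_fraction == pytest.approx(1.0)  # still overlaps the loop

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError):
            coverage_metrics(150, [])


class TestCategories:
    def test_truth_table_bijection(self):
        expected = {
            (True, True, True): "A",
            (True, True, False): "B",
            (True, False, True): "C",
            (True, False, False): "D",
            (False, True, True): "E",
            (False, True, False): "F",
            (False, False, True): "G",
            (False, False, False): "H",
        }
        seen = set()
        for triple, cat in expected.items():
            got = assign_category(triple)
            assert got == cat
            seen.add(got)
        assert seen == set("ABCDEFGH")


class TestMatchKnown:
    def test_verbatim_match(self):
        hp = "AAAA" + "ACGTACGTACGTACGTACGTA" + "TTTT"
        assert match_known(hp, {"m": "ACGTACGTACGTACGTACGTA"}) == ["m"]

    def test_u_normalised(self):
        hp = "AAAACGTACGTTTT"
        assert match_known(hp, {"m": "ACGUACGU"}) == ["m"]

    def test_one_mismatch_is_novel(self):
        hp = "AAAAACGTACGTACGTACGTACGTATTTT"
        assert match_known(hp, {"m": "ACGTACGTACGTACGTACGTT"}) == []

    def test_star_arm_match_counts_as_known(self, study):
        h = study.hairpins[0]
        assert match_known(h.hairpin_sequence, {"star": h.star_sequence}) == ["star"]


class TestDiscover:
    def test_truth_categories_recovered(self, study, discovered):
        truth = {h.feature_id: h.truth_category for h in study.hairpins}
        assert len(discovered) == len(study.hairpins)
        for c in discovered:
            assert truth[c.name] == c.category

    def test_known_novel_split_matches_truth(self, study, discovered):
        for c in discovered:
            assert (c.status == "known") == (c.name in study.known_mature_names)
            assert (c.status == "known") == bool(c.known_matches)

    def test_invariant_to_read_order(self, study, preprocessed, discovered):
        df = preprocessed.table.df
        shuffled = UniqueReadTable(df.iloc[::-1])
        again = discover(shuffled, study.genome, study.mature_refs)
        assert [c.name for c in again] == [c.name for c in discovered]
        assert [c.category for c in again] == [c.category for c in discovered]

    def test_sorted_by_category_then_position(self, discovered):
        keys = [(c.category, c.identifier.contig_id, c.identifier.start) for c in discovered]
        assert keys == sorted(keys)

    def test_random_reads_yield_no_candidates(self):
        rng = np.random.default_rng(3)
        genome = make_genome(1, [20_000], seed=33)
        design = reduced_design(1)
        libs = design.library_ids
        reads = {}
        for _ in range(150):
            off = int(rng.integers(0, 19_979))
            reads["%s" % genome["ctg01"][off : off + 21]] = 10
        import pandas as pd

        df = pd.DataFrame(
            {lib: list(reads.values()) for lib in libs},
            index=pd.Index(list(reads), name="sequence"),
        )
        cands = discover(UniqueReadTable(df), genome, {})
        assert len(cands) <= 1  # negative control: at most stray leakage
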