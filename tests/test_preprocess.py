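import numpy as np
import pytest

from durumir.io_formats import revcomp
from durumir.preprocess import (
    FilterParams,
    UniqueReadTable,
    assemble_and_filter_breakdown,
    assemble_contigs,
    collapse_unique,
    filter_contaminants,
    filter_low_abundance,
    map_ungapped,
    partition_reads,
    trim_adapter,
)
from durumir.synthdata import make_genome, reduced_design

ADAPTER = "AGATCGGAAGAG"


class TestTrim:
    def test_adapter_suffix_removed(self):
        assert trim_adapter("ACGTACGTAGATCGGA", ADAPTER, 8) == ("ACGTACGT", True)

    def test_no_adapter(self):
        assert trim_adapter("ACGTACGTACGTACGT", ADAPTER, 8) == ("ACGTACGTACGTACGT", False)

    def test_read_equal_to_adapter_trims_to_empty(self):
        assert trim_adapter(ADAPTER, ADAPTER, 8) == ("", True)

    def test_short_overlap_not_trimmed(self):
        # 7-base adapter prefix at the 3' end is below the 8-base minimum
        assert trim_adapter("ACGTACGTACGT" + ADAPTER[:7], ADAPTER, 8)[1] is False


class TestPartition:
    def test_routing(self):
        per_lib = {
            "L1": [
                "A" * 21 + ADAPTER,          # trimmed 21-mer -> set1 and approach1
                "C" * 30 + ADAPTER[:10],     # trimmed 30-mer -> approach1 only
                "ACGT" * 9,                  # no adapter -> set2
                "A" * 10 + ADAPTER,          # too short after trim -> discarded
                "AN" + "A" * 19 + ADAPTER,   # contains N -> dropped
            ]
        }
        parts = partition_reads(per_lib, ADAPTER)
        assert parts.set1["L1"] == ["A" * 21]
        assert parts.approach1["L1"] == ["A" * 21, "C" * 30]
        assert parts.set2["L1"] == ["ACGT" * 9]
        assert parts.n_discarded["contains_N"] == 1
        assert parts.n_discarded["length_out_of_range"] == 1

    def test_five_prime_adapter_dropped(self):
        a5 = "GTTCAGAGTT"
        per_lib = {"L1": [a5 + "A" * 15 + ADAPTER]}
        parts = partition_reads(per_lib, ADAPTER, adapter5=a5)
        assert parts.set1["L1"] == [] and parts.n_discarded["adapter5"] == 1


class TestCollapse:
    def test_basic(self):
        design = reduced_design(1)
        libs = design.library_ids
        streams = {libs[0]: ["ACGT", "ACGT", "TTTT"], libs[1]: ["ACGT"]}
        t = collapse_unique(streams, design)
        assert t.df.loc["ACGT", libs[0]] == 2
        assert t.df.loc["ACGT", libs[1]] == 1
        assert t.df.loc["TTTT", libs[0]] == 1
        assert int(t.total_count.sum()) == 4

    def test_conservation_10k_reads(self):
        rng = np.random.default_rng(1)
        design = reduced_design(1)
        libs = design.library_ids
        streams = {
            lib: ["".join(rng.choice(list("ACGT"), 21)) for _ in range(1250)]
            for lib in libs
        }
        t = collapse_unique(streams, design)
        assert int(t.df.to_numpy().sum()) == 10_000
        for lib in libs:
            assert int(t.df[lib].sum()) == 1250

    def test_unknown_library_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            collapse_unique({"nope": ["ACGT"]}, reduced_design(1))


class TestLowAbundance:
    def test_boundary(self):
        design = reduced_design(1)
        libs = design.library_ids
        streams = {libs[0]: ["A" * 21] * 5 + ["C" * 21] * 6}
        t = filter_low_abundance(collapse_unique(streams, design), 5)
        assert t.sequences == ["C" * 21]

    def test_empty_table(self):
        t = collapse_unique({}, reduced_design(1))
        assert len(filter_low_abundance(t)) == 0


def brute_force_hits(query, refs, max_mm):
    """Independent O(n*m) Hamming scanner over both strands."""
    out = set()
    for name, ref in refs.items():
        for q, strand in ((query, "+"), (revcomp(query), "-")):
            for off in range(len(ref) - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, ref[off : off + len(q)]))
                if mm <= max_mm:
                    out.add((name, off, strand, mm))
    return out


class TestMapUngapped:
    def test_exact_substring(self):
        refs = {"r": "AAACCCGGGTTTACGTACGT"}
        hit, hits = map_ungapped("CCCGGG", refs, 0)
        assert hit and ("r", 3, "+", 0) in hits

    def test_three_mismatches_not_hit(self):
        ref = "A" * 30
        assert map_ungapped("AAATTTAAA" + "A" * 12, {"r": ref}, 2)[0] is False

    def test_matches_brute_force_on_random_panel(self):
        rng = np.random.default_rng(8)
        genome = make_genome(2, [400, 400], seed=8)
        queries = []
        for _ in range(60):
            contig = genome[rng.choice(list(genome))]
            off = int(rng.integers(0, len(contig) - 21))
            q = list(contig[off : off + 21])
            for p in rng.choice(21, size=int(rng.integers(0, 4)), replace=False):
                q[p] = str(rng.choice([b for b in "ACGT" if b != q[p]]))
            q = "".join(q)
            if rng.random() < 0.5:
                q = revcomp(q)
            queries.append(q)
        for q in queries:
            _, hits = map_ungapped(q, genome, 2)
            assert set(hits) == brute_force_hits(q, genome, 2)


class TestContaminantFilter:
    def test_truth_tagged_removal(self, study, preprocessed, config):
        # every contaminant-origin unique read is gone, planted reads retained
        kept = set(preprocessed.table.sequences)
        for seq, tag in study.read_class.items():
            if tag.startswith("contaminant|"):
                assert seq not in kept

    def test_exact_counts_on_constructed_fixture(self):
        rng = np.random.default_rng(5)
        design = reduced_design(1)
        lib = design.library_ids[0]
        contaminant_ref = "".join(rng.choice(list("ACGT"), 300))
        cont_reads = [contaminant_ref[i : i + 21] for i in range(0, 100)]
        clean_reads = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(100)]
        t = collapse_unique({lib: cont_reads + clean_reads}, design)
        filtered, tallies = filter_contaminants(
            t, {"rRNA_1": contaminant_ref}, {"rRNA_1": "rRNA"}
        )
        assert tallies["rRNA"] == 100
        assert len(filtered) == len(t) - 100


class TestAssembler:
    def test_tiled_transcript_recovered_and_fragment_filtered(self):
        rng = np.random.default_rng(6)
        transcript = "".join(rng.choice(list("ACGT"), 60))
        untrimmed = [transcript[i : i + 36] for i in range(0, 25, 4)]
        design = reduced_design(1)
        lib = design.library_ids[0]
        fragment = transcript[20:41]
        clean = "".join(rng.choice(list("ACGT"), 21))
        table = collapse_unique({lib: [fragment] * 10 + [clean] * 10}, design)
        filtered, contigs, removed = assemble_and_filter_breakdown(untrimmed, table)
        assert any(len(c) >= 50 for c in contigs)
        assert removed == 1
        assert filtered.sequences == [clean]

    def test_no_untrimmed_reads_table_unchanged(self):
        design = reduced_design(1)
        lib = design.library_ids[0]
        table = collapse_unique({lib: ["ACGT" * 5 + "A"]}, design)
        filtered, contigs, removed = assemble_and_filter_breakdown([], table)
        assert removed == 0 and len(filtered) == 1

    def test_contig_below_min_length_not_used(self):
        rng = np.random.default_rng(7)
        transcript = "".join(rng.choice(list("ACGT"), 49))
        design = reduced_design(1)
        lib = design.library_ids[0]
        fragment = transcript[10:31]
        table = collapse_unique({lib: [fragment] * 10}, design)
        # transcript itself yields a 49 nt contig: below the 50 bp floor
        filtered, contigs, removed = assemble_and_filter_breakdown([transcript], table)
        assert removed == 0 and len(filtered) == 1

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_contigs(["ACGT" * 10], k=16)


class TestCascade:
    def test_monotone_and_accounted(self, preprocessed):
        log = preprocessed.removal_log.set_index("stage")["unique_reads"]
        removed = log.drop(["input_unique", "output_unique"]).sum()
        assert log["input_unique"] - removed == log["output_unique"]
        assert (log >= 0).all()

    def test_recall_and_leakage_on_truth(self, study, preprocessed):
        """>=99% of clean planted read volume survives; <=1% contaminant leaks."""
        kept = preprocessed.table
        kept_seqs = set(kept.sequences)
        clean_total = clean_kept = cont_total = cont_kept = 0
        # reconstruct input volumes from the truth tags
        from durumir.preprocess import partition_reads
        per_lib = {
            lib: [seq for _r, seq, _q in recs] for lib, recs in study.reads.items()
        }
        parts = partition_reads(per_lib, "AGATCGGAAGAGCACACGTCT")
        from collections import Counter
        counts = Counter(s for reads in parts.set1.values() for s in reads)
        for seq, n in counts.items():
            tag = study.read_class.get(seq, "")
            if tag.startswith("hairpin|"):
                clean_total += n
                if seq in kept_seqs:
                    clean_kept += n
            elif tag.startswith("contaminant|"):
                cont_total += n
                if seq in kept_seqs:
                    cont_kept += n
        assert clean_total > 0 and cont_total > 0
        assert clean_kept / clean_total >= 0.99
        assert cont_kept / cont_total <= 0.01
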