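"""Read pre-processing: adapter trimming, partitioning, collapsing, filters.

The filter cascade mirrors a standard small-RNA clean-up: drop low-abundance
unique reads, remove reads mapping (ungapped, <=2 mismatches, either strand)
to contaminant references (rRNA-like, organellar, vector, repeat), and remove
likely mRNA breakdown products by assembling the untrimmed read set with a
minimal de Bruijn assembler (k=17) and filtering against contigs >= 50 bp.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import StudyDesign, revcomp

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
_ENC[ord("U")] = _ENC[ord("T")]


def encode_seq(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class FilterParams:
    """Thresholds of the pre-processing cascade."""

    len_min_a1: int = 15
    len_max_a1: int = 50
    len_min_a2: int = 19
    len_max_a2: int = 26
    low_abundance_max: int = 5
    contaminant_max_mismatch: int = 2
    assembly_k: int = 17
    contig_min_len: int = 50
    min_overlap: int = 8  # adapter detection

    def __post_init__(self):
        if not (self.len_min_a1 < self.len_max_a1 and self.len_min_a2 < self.len_max_a2):
            raise ValueError("length windows must satisfy min < max")


# ---------------------------------------------------------------------------
# Adapter trimming and partitioning
# ---------------------------------------------------------------------------

def trim_adapter(read: str, adapter3: str, min_overlap: int = 8) -> tuple[str, bool]:
    """Remove a 3' adapter; returns (sequence, trimmed flag).

    The leftmost read suffix of >= ``min_overlap`` bases that exactly matches
    a prefix of the adapter is removed. Reads without such a match are
    returned unchanged and flagged untrimmed.
    """
    if len(adapter3) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    for i in range(0, len(read) - min_overlap + 1):
        n = min(len(adapter3), len(read) - i)
        if read[i : i + n] == adapter3[:n]:
            return read[:i], True
    return read, False


@dataclass
class PartitionedReads:
    """Per-library read streams split by adapter/length status.

    ``set1`` holds trimmed reads in the hairpin-discovery window (19-26 nt);
    ``set2`` the untrimmed reads (no adapter found), used for breakdown-product
    assembly; ``approach1`` all trimmed reads in the wider 15-50 nt profiling
    window (a superset of set1); the remainder is discarded.
    """

    set1: dict[str, list[str]] = field(default_factory=dict)
    set2: dict[str, list[str]] = field(default_factory=dict)
    approach1: dict[str, list[str]] = field(default_factory=dict)
    n_discarded: Counter = field(default_factory=Counter)


def partition_reads(
    per_library: Mapping[str, Iterable[str]],
    adapter3: str,
    params: FilterParams | None = None,
    adapter5: str | None = None,
) -> PartitionedReads:
    """Trim and partition raw reads per library.

    Reads containing N are dropped (stand-in for quality filtering); reads
    still carrying a 5' adapter prefix after 3' trimming are dropped.
    """
    params = params or FilterParams()
    out = PartitionedReads()
    for lib, stream in per_library.items():
        s1, s2, a1 = [], [], []
        for read in stream:
            if "N" in read:
                out.n_discarded["contains_N"] += 1
                continue
            seq, trimmed = trim_adapter(read, adapter3, params.min_overlap)
            if adapter5 and seq.startswith(adapter5):
                out.n_discarded["adapter5"] += 1
                continue
            if not trimmed:
                s2.append(seq)
                continue
            if params.len_min_a2 <= len(seq) <= params.len_max_a2:
                s1.append(seq)
            if params.len_min_a1 <= len(seq) <= params.len_max_a1:
                a1.append(seq)
            else:
                out.n_discarded["length_out_of_range"] += 1
        out.set1[lib] = s1
        out.set2[lib] = s2
        out.approach1[lib] = a1
    return out


# ---------------------------------------------------------------------------
# Unique-read table
# ---------------------------------------------------------------------------

class UniqueReadTable:
    """Non-redundant unique-sequence x library count matrix."""

    def __init__(self, df: pd.DataFrame):
        self.df = df

    @property
    def sequences(self) -> list[str]:
        return list(self.df.index)

    @property
    def total_count(self) -> pd.Series:
        return self.df.sum(axis=1)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, keep) -> "UniqueReadTable":
        return UniqueReadTable(self.df.loc[keep])

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "total", self.total_count)
        out.to_csv(path, sep="\t", index_label="sequence")

    @staticmethod
    def from_tsv(path) -> "UniqueReadTable":
        df = pd.read_csv(path, sep="\t", index_col="sequence")
        return UniqueReadTable(df.drop(columns=["total"], errors="ignore").astype(int))


def collapse_unique(
    per_library: Mapping[str, Iterable[str]], design: StudyDesign
) -> UniqueReadTable:
    """Collapse per-library read streams into a unique-read count table."""
    lib_ids = design.library_ids
    unknown = [l for l in per_library if l not in lib_ids]
    if unknown:
        raise ValueError(f"unknown library ids: {unknown[:3]}")
    counters = {lib: Counter(per_library.get(lib, ())) for lib in lib_ids}
    seqs = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else set())
    data = {lib: [counters[lib].get(s, 0) for s in seqs] for lib in lib_ids}
    df = pd.DataFrame(data, index=pd.Index(seqs, name="sequence"), dtype=int)
    return UniqueReadTable(df)


def filter_low_abundance(table: UniqueReadTable, max_total: int = 5) -> UniqueReadTable:
    """Drop rows whose summed count over all libraries is <= ``max_total``."""
    return table.subset(table.total_count > max_total)


# ---------------------------------------------------------------------------
# Ungapped mapping (Hamming, both strands, exhaustive)
# ---------------------------------------------------------------------------

def _hits_on_array(query: np.ndarray, ref: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Offsets where ``query`` aligns to ``ref`` with <= max_mismatch mismatches."""
    L = len(query)
    if L > len(ref):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(ref, L)
    mism = (windows != query).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0]


def map_ungapped(
    query: str,
    references: Mapping[str, str] | Mapping[str, np.ndarray],
    max_mismatch: int = 2,
) -> tuple[bool, list[tuple[str, int, str, int]]]:
    """Exhaustive ungapped search of ``query`` against reference sequences.

    A hit is any offset on either strand where the full query aligns with
    Hamming distance <= ``max_mismatch``. Returns (any_hit, hits) with hits as
    (reference, offset, strand, mismatches) on forward coordinates.
    """
    q_fwd = encode_seq(query)
    q_rev = encode_seq(revcomp(query))
    hits: list[tuple[str, int, str, int]] = []
    for name in references:
        ref = references[name]
        arr = ref if isinstance(ref, np.ndarray) else encode_seq(ref)
        if len(q_fwd) > len(arr):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(q_fwd))
        for q, strand in ((q_fwd, "+"), (q_rev, "-")):
            mism = (windows != q).sum(axis=1)
            for off in np.nonzero(mism <= max_mismatch)[0]:
                hits.append((name, int(off), strand, int(mism[off])))
    return bool(hits), hits


def filter_contaminants(
    table: UniqueReadTable,
    contaminants: Mapping[str, str],
    classes: Mapping[str, str] | None = None,
    max_mismatch: int = 2,
) -> tuple[UniqueReadTable, Counter]:
    """Remove unique reads hitting any contaminant reference (<=2 mismatches).

    Returns the filtered table and per-class removal tallies.
    """
    if not contaminants:
        raise ValueError("contaminant reference set is empty")
    encoded = {n: encode_seq(s) for n, s in contaminants.items()}
    tallies: Counter = Counter()
    keep = []
    for seq in table.sequences:
        hit, hits = map_ungapped(seq, encoded, max_mismatch)
        if hit:
            cls = classes[hits[0][0]] if classes else "contaminant"
            tallies[cls] += 1
        keep.append(not hit)
    return table.subset(np.array(keep, dtype=bool)), tallies


# ---------------------------------------------------------------------------
# Minimal de Bruijn assembler (breakdown-product reference)
# ---------------------------------------------------------------------------

def assemble_contigs(reads: Iterable[str], k: int = 17) -> list[str]:
    """Unbranched-path contigs of the de Bruijn graph on k-mers of ``reads``.

    A deliberately minimal assembler: nodes are (k-1)-mers, edges are observed
    k-mers, and contigs are maximal non-branching paths. No bubble popping, no
    coverage cutoffs; the output only serves as a filter reference.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    kmers: set[str] = set()
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i : i + k]
            if "N" not in km:
                kmers.add(km)
    out_edges: dict[str, set[str]] = {}
    in_deg: Counter = Counter()
    for km in kmers:
        u, v = km[:-1], km[1:]
        out_edges.setdefault(u, set()).add(v)
        out_edges.setdefault(v, set())
        in_deg[v] += 1
        in_deg.setdefault(u, 0)

    def is_through(node: str) -> bool:
        return in_deg[node] == 1 and len(out_edges[node]) == 1

    contigs: list[str] = []
    visited_edges: set[tuple[str, str]] = set()
    for u in sorted(out_edges):
        if is_through(u):
            continue
        for v in sorted(out_edges[u]):
            if (u, v) in visited_edges:
                continue
            path = [u, v]
            visited_edges.add((u, v))
            while is_through(path[-1]):
                nxt = next(iter(out_edges[path[-1]]))
                if (path[-1], nxt) in visited_edges:
                    break
                visited_edges.add((path[-1], nxt))
                path.append(nxt)
            contigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles: every node is a through-node
    for u in sorted(out_edges):
        for v in sorted(out_edges[u]):
            if (u, v) in visited_edges:
                continue
            path = [u, v]
            visited_edges.add((u, v))
            while is_through(path[-1]):
                nxt = next(iter(out_edges[path[-1]]))
                if (path[-1], nxt) in visited_edges:
                    break
                visited_edges.add((path[-1], nxt))
                path.append(nxt)
            contigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    return sorted(contigs)


def assemble_and_filter_breakdown(
    set2_reads: Iterable[str],
    table: UniqueReadTable,
    k: int = 17,
    contig_min: int = 50,
    max_mismatch: int = 2,
) -> tuple[UniqueReadTable, list[str], int]:
    """Filter the unique-read table against de novo contigs of breakdown reads.

    The untrimmed read set plus the table's own sequences are assembled; table
    rows with an ungapped <=2-mismatch hit to a contig >= ``contig_min`` bp
    are removed. Returns (filtered table, contigs used, rows removed).
    """
    reads = list(set2_reads) + list(table.sequences)
    contigs = [c for c in assemble_contigs(reads, k) if len(c) >= contig_min]
    if not contigs:
        return table, [], 0
    refs = {f"contig{i}": encode_seq(c) for i, c in enumerate(contigs)}
    keep = []
    for seq in table.sequences:
        hit, _ = map_ungapped(seq, refs, max_mismatch)
        keep.append(not hit)
    keep = np.array(keep, dtype=bool)
    return table.subset(keep), contigs, int((~keep).sum())


# ---------------------------------------------------------------------------
# Cascade driver
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    table: UniqueReadTable  # 19-26 nt unique reads after the full cascade
    approach1_table: UniqueReadTable  # 15-50 nt unique reads (profiling input)
    library_totals: pd.Series  # trimmed 15-50 nt reads per library (RPM denominators)
    removal_log: pd.DataFrame
    contigs: list[str]


def run_preprocess(
    per_library_reads: Mapping[str, Iterable[str]],
    design: StudyDesign,
    adapter3: str,
    contaminants: Mapping[str, str],
    contaminant_classes: Mapping[str, str] | None = None,
    params: FilterParams | None = None,
) -> PreprocessResult:
    """Run the full pre-processing cascade in the fixed printed order.

    Stages for the 19-26 nt table: low abundance, rRNA, organellar,
    de-novo contigs, vector, repeat. Logged removals sum to input - output.
    """
    params = params or FilterParams()
    parts = partition_reads(per_library_reads, adapter3, params)
    table = collapse_unique(parts.set1, design)
    approach1 = collapse_unique(parts.approach1, design)
    totals = approach1.df.sum(axis=0)

    log_rows = [("input_unique", len(table))]
    t = filter_low_abundance(table, params.low_abundance_max)
    log_rows.append(("low_abundance", len(table) - len(t)))

    by_class: dict[str, dict[str, str]] = {}
    if contaminant_classes:
        for name, cls in contaminant_classes.items():
            by_class.setdefault(cls, {})[name] = contaminants[name]
    else:
        by_class["contaminant"] = dict(contaminants)

    contigs: list[str] = []
    stage_order = ["rRNA", "organellar", "__contigs__", "vector", "repeat"]
    for stage in stage_order:
        if stage == "__contigs__":
            set2_all = [r for lib in design.library_ids for r in parts.set2.get(lib, [])]
            t, contigs, removed = assemble_and_filter_breakdown(
                set2_all, t, params.assembly_k, params.contig_min_len,
                params.contaminant_max_mismatch,
            )
            log_rows.append(("breakdown_contigs", removed))
            continue
        refs = by_class.get(stage)
        if not refs:
            log_rows.append((stage, 0))
            continue
        before = len(t)
        t, _ = filter_contaminants(t, refs, None, params.contaminant_max_mismatch)
        log_rows.append((stage, before - len(t)))
    log_rows.append(("output_unique", len(t)))
    log = pd.DataFrame(log_rows, columns=["stage", "unique_reads"])
    return PreprocessResult(
        table=t, approach1_table=approach1, library_totals=totals,
        removal_log=log, contigs=contigs,
    )
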