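"""De novo pre-miRNA hairpin discovery from opposite-strand read alignments.

A candidate locus is nominated wherever one read has both a perfect genomic
alignment and an imperfect (2-5 mismatch) alignment on the opposite strand of
the same contig, with the facing interval edges separated by 54-1000 bp — the
footprint of a miRNA/miRNA* duplex whose star arm has drifted a few
substitutions from perfect complementarity. Each non-redundant region (+/-20
bp) is folded with a maximum-base-pairing dynamic program, gated by
plant-miRNA biogenesis checks on the duplex, scored with three Boolean
read-coverage metrics (strand bias >= 95%, terminal-50 bp concentration
>= 95%, loop reads <= 5%) and assigned one of eight categories A-H; category
A is the profile of a genuine miRNA. Candidates containing an exact match to
a known mature miRNA are labelled known, the rest novel.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HairpinIdentifier, format_hairpin_identifier, revcomp
from .preprocess import UniqueReadTable, encode_seq

CATEGORIES = "ABCDEFGH"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    """Ungapped alignment of a read, on forward-strand coordinates."""

    read_seq: str
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' | '-'
    mismatches: int


def find_alignments(
    reads: Iterable[str],
    genome: Mapping[str, str],
    mode: str = "perfect",
) -> list[AlignmentHit]:
    """Exhaustive ungapped alignment of reads to both genome strands.

    ``perfect`` returns every 0-mismatch occurrence; ``imperfect`` every
    occurrence with 2-5 mismatches (1-mismatch hits are deliberately outside
    both sets).
    """
    if mode == "perfect":
        lo, hi = 0, 0
    elif mode == "imperfect":
        lo, hi = 2, 5
    else:
        raise ValueError(f"unknown mode {mode!r}")
    encoded = {c: encode_seq(s) for c, s in genome.items()}
    by_len: dict[int, list[str]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r)
    hits: list[AlignmentHit] = []
    for contig in sorted(encoded):
        arr = encoded[contig]
        for L, group in sorted(by_len.items()):
            if L > len(arr) or L == 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            for read in group:
                for q, strand in ((encode_seq(read), "+"), (encode_seq(revcomp(read)), "-")):
                    mism = (windows != q).sum(axis=1)
                    sel = np.nonzero((mism >= lo) & (mism <= hi))[0]
                    for off in sel:
                        hits.append(
                            AlignmentHit(read, contig, int(off), int(off) + L, strand, int(mism[off]))
                        )
    return hits


# ---------------------------------------------------------------------------
# Locus pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusPair:
    """A perfect/imperfect opposite-strand alignment pair of one read."""

    perfect: AlignmentHit
    imperfect: AlignmentHit
    inner_gap: int
    region: tuple[str, int, int]  # contig, 0-based half-open


def enumerate_locus_pairs(
    perfect: Sequence[AlignmentHit],
    imperfect: Sequence[AlignmentHit],
    gap_min: int = 54,
    gap_max: int = 1000,
    contig_lengths: Mapping[str, int] | None = None,
    flank: int = 20,
) -> list[LocusPair]:
    """All same-read same-contig opposite-strand pairs separated by 54-1000 bp.

    The separation is the inner-edge gap between the two alignment intervals
    (the prospective loop plus spacer). Regions are the pair footprint
    extended by ``flank`` on both sides, clipped to the contig.
    """
    by_key: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in imperfect:
        by_key.setdefault((h.read_seq, h.contig_id), []).append(h)
    pairs: list[LocusPair] = []
    for p in perfect:
        for q in by_key.get((p.read_seq, p.contig_id), ()):
            if q.strand == p.strand:
                continue
            gap = max(p.start, q.start) - min(p.end, q.end)
            if not (gap_min <= gap <= gap_max):
                continue
            lo = min(p.start, q.start) - flank
            hi = max(p.end, q.end) + flank
            if contig_lengths is not None:
                hi = min(hi, contig_lengths[p.contig_id])
            lo = max(lo, 0)
            pairs.append(LocusPair(p, q, gap, (p.contig_id, lo, hi)))
    return pairs


def nonredundant_regions(pairs: Iterable[LocusPair]) -> list[tuple[str, int, int]]:
    """Distinct candidate regions, sorted by genomic position."""
    return sorted({p.region for p in pairs})


# ---------------------------------------------------------------------------
# Folding (maximum base pairing, Watson-Crick + G.U wobble, min loop 3)
# ---------------------------------------------------------------------------

# A=0 C=1 G=2 T/U=3
_CAN_PAIR = np.zeros((4, 4), dtype=bool)
for x, y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[x, y] = True

MIN_LOOP = 3


@dataclass
class FoldResult:
    """Nested maximum-pairing structure and duplex statistics.

    ``pairs[i]`` is the partner index of base i (or -1). The mature-arm
    fields are computed against the supplied mature interval: unpaired count,
    the largest asymmetric bulge inside the dominant helix run, whether that
    run pairs outside the mature arm (a genuine arm-to-arm duplex), and the
    fraction of the mature arm belonging to the dominant helix run.
    """

    structure: str
    n_pairs: int
    pairs: list[int]
    sequence: str = ""
    mature_unpaired: int = -1
    largest_bulge: int = -1
    arm_span_paired: bool = False
    dominant_stem_fraction: float = 0.0


# Combined DP score: SCALE * n_pairs + n_stacked_pairs. Maximising it gives
# the exact maximum pairing count (stacks < n/2 < SCALE) while breaking the
# massive degeneracy of max-pairing structures in favour of long helices —
# without a stacking preference the traceback of a planted stem-loop tends to
# scatter the duplex across equivalent-count structures.
_SCALE = 4096


def _fold_dp(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes)
    F = np.zeros((n, n), dtype=np.int64)  # best score of s[i..j]
    P = np.full((n, n), -1, dtype=np.int64)  # best score with (i,j) paired
    pair_ks: list[np.ndarray] = []
    for j in range(n):
        pair_ks.append(np.nonzero(_CAN_PAIR[codes[:j], codes[j]])[0])
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if _CAN_PAIR[codes[i], codes[j]]:
                interior = F[i + 1, j - 1]
                if P[i + 1, j - 1] >= 0:
                    interior = max(interior, P[i + 1, j - 1] + 1)
                P[i, j] = _SCALE + interior
            best = F[i, j - 1]
            ks = pair_ks[j]
            lo = bisect_left(ks, i)
            hi = bisect_right(ks, j - MIN_LOOP - 1)
            if hi > lo:
                kk = ks[lo:hi]
                left = np.where(kk > i, F[i, np.maximum(kk - 1, 0)], 0)
                tot = int((left + P[kk, j]).max())
                if tot > best:
                    best = tot
            F[i, j] = best
    return F, P


def _traceback(codes: np.ndarray, F: np.ndarray, P: np.ndarray) -> list[int]:
    n = len(codes)
    pairs = [-1] * n
    stack: list[tuple[int, int, str]] = [(0, n - 1, "F")]
    while stack:
        i, j, state = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if state == "P":
            pairs[i], pairs[j] = j, i
            # prefer helix continuation when it ties the interior optimum
            if P[i + 1, j - 1] >= 0 and P[i, j] == _SCALE + P[i + 1, j - 1] + 1:
                stack.append((i + 1, j - 1, "P"))
            else:
                stack.append((i + 1, j - 1, "F"))
            continue
        if F[i, j] == F[i, j - 1]:
            stack.append((i, j - 1, "F"))
            continue
        target = F[i, j]
        for k in range(i, j - MIN_LOOP):
            if P[k, j] < 0:
                continue
            left = F[i, k - 1] if k > i else 0
            if left + P[k, j] == target:
                if k > i:
                    stack.append((i, k - 1, "F"))
                stack.append((k, j, "P"))
                break
    return pairs


def _mature_stats(codes: np.ndarray, pairs: Sequence[int], mature: tuple[int, int]):
    """Duplex statistics of the mature arm.

    The mature/star duplex is located by an exhaustive antiparallel
    complementarity scan of the mature arm against every distal window of the
    sequence (Watson-Crick + G.U, no indels). A maximum-base-pairing
    structure is highly degenerate and routinely scatters the duplex over
    equal-count alternatives, so the gate measures complementarity directly;
    the bulge statistic is taken from the traceback structure's dominant
    mature helix run.
    """
    ms, me = mature
    arm = me - ms
    m = codes[ms:me]
    n = len(codes)

    def window_mask(t: int) -> np.ndarray | None:
        if t < 0 or t + arm > n:
            return None
        if t < me + MIN_LOOP and t + arm > ms - MIN_LOOP:
            return None  # window must be distal to the mature arm
        return _CAN_PAIR[m, codes[t : t + arm][::-1]]

    best_matches, best_t, best_mask = -1, None, None
    for t in range(0, n - arm + 1):
        mask = window_mask(t)
        if mask is None:
            continue
        matches = int(mask.sum())
        if matches > best_matches:
            best_matches, best_t, best_mask = matches, t, mask
    if best_t is None:
        return arm, 0, False, 0.0

    # composite duplex with one asymmetric bulge (register shift <= 4 nt),
    # accepted only when it recovers >= 3 extra pairs — a real bulged stem
    # regains a whole segment, whereas chance realignment gains one or two
    bulge = 0
    mask = best_mask
    matches = best_matches
    for delta in (-4, -3, -2, -1, 1, 2, 3, 4):
        mask2 = window_mask(best_t + delta)
        if mask2 is None:
            continue
        c1 = np.concatenate(([0], np.cumsum(best_mask)))
        c2 = np.concatenate(([0], np.cumsum(mask2)))
        split_scores = c1[:-1] + (c2[-1] - c2[:-1])
        s = int(split_scores.argmax())
        val = int(split_scores[s])
        if val >= best_matches + 3 and val > matches:
            matches = val
            bulge = abs(delta)
            mask = np.concatenate((best_mask[:s], mask2[s:]))
    unpaired = arm - matches

    # merge matched positions across gaps of up to 3 unpaired bases into runs
    runs: list[int] = []
    current = 0
    last = None
    for i in np.nonzero(mask)[0]:
        if last is not None and i - last <= 4:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 1
        last = int(i)
    if current:
        runs.append(current)
    frac = (max(runs) / arm) if runs else 0.0
    return unpaired, bulge, matches > 0, frac


def fold_hairpin(seq: str, mature_interval: tuple[int, int] | None = None) -> FoldResult:
    """Maximum base-pairing nested fold of a candidate hairpin sequence.

    Watson-Crick and G.U wobble pairs, minimum loop of 3 nt. When a mature
    interval (0-based half-open) is given, duplex statistics for the
    biogenesis checks are filled in.
    """
    s = seq.upper().replace("U", "T")
    if not (4 <= len(s) <= 1100):
        raise ValueError(f"sequence length {len(s)} outside the foldable 4-1100 nt range")
    codes = encode_seq(s)
    if (codes > 3).any():
        bad = s[int(np.nonzero(codes > 3)[0][0])]
        raise ValueError(f"non-ACGU character {bad!r} in sequence")
    F, P = _fold_dp(codes)
    pairs = _traceback(codes, F, P)
    structure = "".join(
        "(" if p > i else ")" if p != -1 else "." for i, p in enumerate(pairs)
    )
    fold = FoldResult(
        structure=structure, n_pairs=int(F[0, len(s) - 1]) // _SCALE, pairs=pairs, sequence=s
    )
    if mature_interval is not None:
        ms, me = mature_interval
        if not (0 <= ms < me <= len(s)):
            raise ValueError("mature interval outside sequence")
        (
            fold.mature_unpaired,
            fold.largest_bulge,
            fold.arm_span_paired,
            fold.dominant_stem_fraction,
        ) = _mature_stats(codes, pairs, mature_interval)
    return fold


@dataclass
class MircheckParams:
    """Thresholds of the plant-miRNA biogenesis gate."""

    max_mature_unpaired: int = 4
    max_bulge: int = 2
    min_dominant_stem_fraction: float = 0.6


def mircheck_like(
    fold: FoldResult,
    mature_interval: tuple[int, int] | None = None,
    params: MircheckParams | None = None,
) -> tuple[bool, list[str]]:
    """Biogenesis-plausibility gate on a folded candidate.

    Pass requires: <= 4 unpaired mature bases; no asymmetric bulge > 2 nt in
    the dominant helix; the dominant helix pairs outside the mature arm
    (a real miRNA/miRNA* arm-to-arm duplex); and >= 60% of the mature arm in
    a single helix run. Returns (passed, failure reasons).
    """
    params = params or MircheckParams()
    if fold.mature_unpaired < 0:
        if mature_interval is None or not fold.sequence:
            raise ValueError("fold lacks mature statistics; pass mature_interval to fold_hairpin")
        (
            fold.mature_unpaired,
            fold.largest_bulge,
            fold.arm_span_paired,
            fold.dominant_stem_fraction,
        ) = _mature_stats(encode_seq(fold.sequence), fold.pairs, mature_interval)
    reasons = []
    if fold.mature_unpaired > params.max_mature_unpaired:
        reasons.append("mature_unpaired")
    if fold.largest_bulge > params.max_bulge:
        reasons.append("bulge")
    if not fold.arm_span_paired:
        reasons.append("arm_span")
    if fold.dominant_stem_fraction < params.min_dominant_stem_fraction:
        reasons.append("dominant_stem")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Coverage metrics and categories
# ---------------------------------------------------------------------------

TERMINAL_WINDOW = 50


@dataclass
class CoverageMetrics:
    """The three Boolean read-coverage metrics of a hairpin region.

    ``strand_bias``: count-weighted fraction of reads on the majority strand.
    ``terminal_fraction``: the larger of the two terminal 50 bp windows'
    majority-assigned read fractions (ties at the window edge go to the
    terminal window). ``loop_fraction``: fraction of reads overlapping the
    loop region (everything strictly between the windows) by >= 1 nt; regions
    <= 100 bp have an empty loop and the loop metric holds vacuously.
    """

    strand_bias: float
    terminal_fraction: float
    loop_fraction: float
    n_reads: int

    @property
    def booleans(self) -> tuple[bool, bool, bool]:
        return (
            self.strand_bias >= 0.95,
            self.terminal_fraction >= 0.95,
            self.loop_fraction <= 0.05,
        )


def coverage_metrics(
    region_length: int,
    read_intervals: Sequence[tuple[int, int, str, int]],
) -> CoverageMetrics:
    """Coverage metrics from region-relative read placements.

    ``read_intervals`` holds (start, end, strand, count) with coordinates
    relative to the region start (clipping not required).
    """
    if not read_intervals:
        raise ValueError("no reads overlap the region")
    w = TERMINAL_WINDOW
    loop_lo, loop_hi = w, max(region_length - w, w)
    total = plus = w5 = w3 = loop_overlap = 0
    for start, end, strand, count in read_intervals:
        total += count
        if strand == "+":
            plus += count
        in5 = max(0, min(end, w) - max(start, 0))
        in3 = max(0, min(end, region_length) - max(start, loop_hi))
        inloop = max(0, min(end, loop_hi) - max(start, loop_lo))
        # majority-of-bases assignment; exact ties go to a terminal window
        if in5 >= in3 and in5 >= inloop:
            w5 += count
        elif in3 >= inloop:
            w3 += count
        if inloop > 0:
            loop_overlap += count
    return CoverageMetrics(
        strand_bias=max(plus, total - plus) / total,
        terminal_fraction=max(w5, w3) / total,
        loop_fraction=(loop_overlap / total) if loop_hi > loop_lo else 0.0,
        n_reads=total,
    )


def assign_category(booleans: tuple[bool, bool, bool]) -> str:
    """Map the (strand, terminal, loop) Boolean triple to category A-H."""
    table = {
        (True, True, True): "A",
        (True, True, False): "B",
        (True, False, True): "C",
        (True, False, False): "D",
        (False, True, True): "E",
        (False, True, False): "F",
        (False, False, True): "G",
        (False, False, False): "H",
    }
    return table[tuple(bool(b) for b in booleans)]


def match_known(
    hairpin_seq: str,
    mature_refs: Mapping[str, str],
    both_strands: bool = False,
) -> list[str]:
    """Reference matures occurring verbatim within the hairpin sequence."""
    seq = hairpin_seq.upper().replace("U", "T")
    rc = revcomp(seq) if both_strands else None
    out = []
    for name in sorted(mature_refs):
        ref = mature_refs[name].upper().replace("U", "T")
        if ref in seq or (rc is not None and ref in rc):
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryParams:
    gap_min: int = 54
    gap_max: int = 1000
    flank: int = 20
    mircheck: MircheckParams = field(default_factory=MircheckParams)
    match_both_strands: bool = False
    min_region_reads: int = 1


@dataclass
class HairpinCandidate:
    identifier: HairpinIdentifier
    strand: str
    sequence: str  # sense orientation
    fold: FoldResult
    metrics: CoverageMetrics
    category: str
    known_matches: list[str]
    status: str  # known | novel
    mature_interval: tuple[int, int]  # sense-hairpin coords, 0-based half-open

    @property
    def name(self) -> str:
        return format_hairpin_identifier(self.identifier)


def _overlapping_hits(
    hits: Sequence[AlignmentHit], contig: str, lo: int, hi: int
) -> list[AlignmentHit]:
    out = []
    for h in hits:
        if h.contig_id != contig:
            continue
        ov = min(h.end, hi) - max(h.start, lo)
        if ov * 2 >= (h.end - h.start):  # majority of the read inside the region
            out.append(h)
    return out


def discover(
    table: UniqueReadTable,
    genome: Mapping[str, str],
    mature_refs: Mapping[str, str],
    params: DiscoveryParams | None = None,
) -> list[HairpinCandidate]:
    """Full hairpin-discovery pass over a filtered unique-read table.

    Perfect alignments are found for every read; imperfect (2-5 mismatch)
    alignments only for reads that aligned perfectly somewhere, mirroring the
    two-stage nomination. Candidate regions are folded, gated, scored and
    classified; output is sorted by (category, contig, start) and independent
    of read input order.
    """
    params = params or DiscoveryParams()
    reads = sorted(table.sequences)
    counts = table.total_count
    perfect = find_alignments(reads, genome, "perfect")
    with_perfect = sorted({h.read_seq for h in perfect})
    imperfect = find_alignments(with_perfect, genome, "imperfect")
    contig_lengths = {c: len(s) for c, s in genome.items()}
    pairs = enumerate_locus_pairs(
        perfect, imperfect, params.gap_min, params.gap_max, contig_lengths, params.flank
    )
    regions = nonredundant_regions(pairs)

    candidates: list[HairpinCandidate] = []
    for contig, lo, hi in regions:
        over = _overlapping_hits(perfect, contig, lo, hi)
        if not over:
            continue
        strand_weight = {"+": 0, "-": 0}
        for h in over:
            strand_weight[h.strand] += int(counts[h.read_seq])
        total_reads = strand_weight["+"] + strand_weight["-"]
        if total_reads < params.min_region_reads:
            continue
        strand = "+" if strand_weight["+"] >= strand_weight["-"] else "-"
        # the mature arm is taken as the most abundant majority-strand read
        sense_hits = [h for h in over if h.strand == strand]
        if not sense_hits:
            continue
        mature_hit = max(sense_hits, key=lambda h: (int(counts[h.read_seq]), -h.start))
        region_seq = genome[contig][lo:hi]
        sense_seq = region_seq if strand == "+" else revcomp(region_seq)
        if strand == "+":
            m_lo, m_hi = mature_hit.start - lo, mature_hit.end - lo
        else:
            m_lo, m_hi = hi - mature_hit.end, hi - mature_hit.start
        m_lo, m_hi = max(m_lo, 0), min(m_hi, hi - lo)
        fold = fold_hairpin(sense_seq, (m_lo, m_hi))
        ok, _reasons = mircheck_like(fold, (m_lo, m_hi), params.mircheck)
        if not ok:
            continue
        metrics = coverage_metrics(
            hi - lo,
            [(h.start - lo, h.end - lo, h.strand, int(counts[h.read_seq])) for h in over],
        )
        category = assign_category(metrics.booleans)
        known = match_known(sense_seq, mature_refs, params.match_both_strands)
        ident = HairpinIdentifier(
            contig_id=contig, start=lo + 1, end=hi,
            mature_start=m_lo + 1, mature_length=m_hi - m_lo,
        )
        candidates.append(
            HairpinCandidate(
                identifier=ident, strand=strand, sequence=sense_seq, fold=fold,
                metrics=metrics, category=category, known_matches=known,
                status="known" if known else "novel", mature_interval=(m_lo, m_hi),
            )
        )
    candidates.sort(key=lambda c: (c.category, c.identifier.contig_id, c.identifier.start))
    return candidates


def quantify_candidates(
    candidates: Sequence[HairpinCandidate],
    table: UniqueReadTable,
    genome: Mapping[str, str],
    perfect_hits: Sequence[AlignmentHit] | None = None,
) -> pd.DataFrame:
    """Per-library read counts of each candidate hairpin.

    A unique read counts toward a candidate when the majority of its perfect
    alignment falls inside the candidate region.
    """
    if perfect_hits is None:
        perfect_hits = find_alignments(sorted(table.sequences), genome, "perfect")
    perfect = perfect_hits
    rows = []
    for c in candidates:
        lo, hi = c.identifier.start - 1, c.identifier.end
        over = _overlapping_hits(perfect, c.identifier.contig_id, lo, hi)
        seqs = sorted({h.read_seq for h in over})
        if seqs:
            row = table.df.loc[seqs].sum(axis=0)
        else:
            row = pd.Series(0, index=table.df.columns)
        rows.append(row)
    return pd.DataFrame(rows, index=[c.name for c in candidates]).astype(int)


def candidates_frame(candidates: Sequence[HairpinCandidate]) -> pd.DataFrame:
    """Tabular summary of discovered hairpins."""
    rows = []
    for c in candidates:
        b1, b2, b3 = c.metrics.booleans
        rows.append(
            dict(
                identifier=c.name,
                category=c.category,
                strand=c.strand,
                strand_bias=round(c.metrics.strand_bias, 4),
                terminal_fraction=round(c.metrics.terminal_fraction, 4),
                loop_fraction=round(c.metrics.loop_fraction, 4),
                metric_strand="Y" if b1 else "N",
                metric_terminal="Y" if b2 else "N",
                metric_loop="Y" if b3 else "N",
                n_reads=c.metrics.n_reads,
                n_pairs=c.fold.n_pairs,
                status=c.status,
                known_matches=",".join(c.known_matches),
            )
        )
    return pd.DataFrame(rows)
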