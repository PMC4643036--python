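"""Readers and writers for the formats the pipeline touches.

Covers 4-line FASTQ, FASTA, the tab/comma-separated study-design table, the
hairpin locus identifier codec (``contig:start-end[mature_start,mature_len]``,
1-based inclusive coordinates as printed in supplementary hairpin tables),
and BED6 export of hairpin loci.

Internally all interval arithmetic is 0-based half-open; the identifier codec
converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

TISSUES = ("flag_leaf", "head")
TREATMENTS = ("control", "water_deficit")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (returns DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, sequence, quality)`` from a 4-line FASTQ file.

    Sequences are uppercased; record order is preserved. A record whose
    quality string length differs from its sequence length raises
    :class:`ParseError` naming the offending line.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield header[1:].split()[0], seq.upper(), qual


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path) -> dict[str, str]:
    """Ordered mapping id -> uppercase sequence; duplicate ids are an error."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in out:
                raise ParseError(f"{path}: duplicate sequence id {name!r}")
            out[name] = seq.upper()
    return out


def read_fasta_with_descriptions(path) -> dict[str, tuple[str, str]]:
    """Like :func:`read_fasta` but keeps the full header line per record."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in out:
                raise ParseError(f"{path}: duplicate sequence id {name!r}")
            out[name] = (title, seq.upper())
    return out


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryRecord:
    """One sequencing library of the factorial design."""

    library_id: str
    genotype: str
    tolerance: int  # 1 = water-deficit tolerant, 0 = sensitive
    tissue: str  # flag_leaf | head
    treatment: str  # control | water_deficit
    replicate: int

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} (expected one of {TISSUES})")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r} (expected one of {TREATMENTS})")
        if self.tolerance not in (0, 1):
            raise ValueError(f"tolerance must be 0 or 1, got {self.tolerance!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


class StudyDesign:
    """The library -> factor mapping of a factorial small-RNA study.

    Validates that (genotype, tissue, treatment, replicate) is unique and
    that the tolerance class is constant within a genotype.
    """

    def __init__(self, records: Iterable[LibraryRecord]):
        self.records: list[LibraryRecord] = list(records)
        seen_ids: set[str] = set()
        seen_cells: set[tuple] = set()
        tol_by_geno: dict[str, int] = {}
        for r in self.records:
            if r.library_id in seen_ids:
                raise ValueError(f"duplicate library_id {r.library_id!r}")
            seen_ids.add(r.library_id)
            cell = (r.genotype, r.tissue, r.treatment, r.replicate)
            if cell in seen_cells:
                raise ValueError(f"duplicate design cell {cell}")
            seen_cells.add(cell)
            prev = tol_by_geno.setdefault(r.genotype, r.tolerance)
            if prev != r.tolerance:
                raise ValueError(
                    f"genotype {r.genotype!r} listed with inconsistent tolerance classes"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LibraryRecord]:
        return iter(self.records)

    @property
    def library_ids(self) -> list[str]:
        return [r.library_id for r in self.records]

    @property
    def genotypes(self) -> list[str]:
        out = []
        for r in self.records:
            if r.genotype not in out:
                out.append(r.genotype)
        return out

    def tolerance_of(self, genotype: str) -> int:
        for r in self.records:
            if r.genotype == genotype:
                return r.tolerance
        raise KeyError(genotype)

    def libraries(self, **factors) -> list[str]:
        """library_ids of records matching all given factor values."""
        out = []
        for r in self.records:
            if all(getattr(r, k) == v for k, v in factors.items()):
                out.append(r.library_id)
        return out

    def groups(self) -> dict[tuple[str, str, str], list[str]]:
        """Factor cells (genotype, tissue, treatment) -> library ids."""
        out: dict[tuple[str, str, str], list[str]] = {}
        for r in self.records:
            out.setdefault((r.genotype, r.tissue, r.treatment), []).append(r.library_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.library_id, r.genotype, r.tolerance, r.tissue, r.treatment, r.replicate)
                for r in self.records
            ],
            columns=["library_id", "genotype", "tolerance", "tissue", "treatment", "replicate"],
        )

    def to_table(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


DESIGN_COLUMNS = ("library_id", "genotype", "tolerance", "tissue", "treatment", "replicate")


def parse_design(path) -> StudyDesign:
    """Read a tab- or comma-separated design table with a header row."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: design table missing columns {missing}")
    records = [
        LibraryRecord(
            library_id=row.library_id,
            genotype=row.genotype,
            tolerance=int(row.tolerance),
            tissue=row.tissue,
            treatment=row.treatment,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    return StudyDesign(records)


# ---------------------------------------------------------------------------
# Hairpin identifier codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinIdentifier:
    """Genomic hairpin locus with the mature-arm placement inside it.

    ``start``/``end`` are 1-based inclusive positions on the contig;
    ``mature_start`` is the 1-based offset of the mature miRNA within the
    hairpin and ``mature_length`` its length in nt.
    """

    contig_id: str
    start: int
    end: int
    mature_start: int
    mature_length: int

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid hairpin interval {self.start}-{self.end}")
        hairpin_len = self.end - self.start + 1
        if not (1 <= self.mature_start <= hairpin_len):
            raise ValueError(f"mature_start {self.mature_start} outside hairpin of length {hairpin_len}")
        if self.mature_length < 1 or self.mature_start + self.mature_length - 1 > hairpin_len:
            raise ValueError(
                f"mature arm ({self.mature_start},{self.mature_length}) extends past hairpin of length {hairpin_len}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def format_hairpin_identifier(h: HairpinIdentifier) -> str:
    """Canonical string form, e.g. ``1AL_3896362:3010-3120[21,21]``."""
    return f"{h.contig_id}:{h.start}-{h.end}[{h.mature_start},{h.mature_length}]"


_ID_RE = re.compile(r"^(?P<contig>.+):(?P<start>\d+)[-–](?P<end>\d+)\[(?P<ms>\d+),(?P<ml>\d+)\]$")


def parse_hairpin_identifier(s: str) -> HairpinIdentifier:
    """Parse the canonical identifier; an en dash is accepted for the hyphen."""
    m = _ID_RE.match(s)
    if m is None:
        raise ParseError(f"malformed hairpin identifier {s!r}")
    try:
        return HairpinIdentifier(
            contig_id=m.group("contig"),
            start=int(m.group("start")),
            end=int(m.group("end")),
            mature_start=int(m.group("ms")),
            mature_length=int(m.group("ml")),
        )
    except ValueError as exc:
        raise ParseError(f"invalid hairpin identifier {s!r}: {exc}") from exc


CATEGORY_RANK = {c: 8 - i for i, c in enumerate("ABCDEFGH")}  # A=8 ... H=1


def write_bed6(path, loci: Iterable[tuple[HairpinIdentifier, str, str]]) -> None:
    """BED6 export of hairpin loci.

    ``loci`` yields (identifier, category, strand); coordinates convert to
    0-based half-open, the name field is the canonical identifier string and
    the score the category rank (A=8 .. H=1).
    """
    with open(path, "w") as fh:
        for ident, category, strand in loci:
            fh.write(
                f"{ident.contig_id}\t{ident.start - 1}\t{ident.end}\t"
                f"{format_hairpin_identifier(ident)}\t{CATEGORY_RANK[category]}\t{strand}\n"
            )
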