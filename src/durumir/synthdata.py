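"""Synthetic small-RNA study generator with full ground truth.

Emulates a factorial water-deficit study: a random genome standing in for
wheat survey-sequence contigs, planted pre-miRNA hairpins whose read coverage
realises one of the eight Boolean-metric categories (A-H), contaminant
references (rRNA-like, organellar-like, vector-like, repeat-like), mRNA
breakdown products, adapter-ligated reads, and negative-binomial counts with
planted genotype / tissue / treatment / tolerance-x-treatment effects.

Every downstream stage of the pipeline can be scored against the truth tables
this module writes. All randomness flows from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    HairpinIdentifier,
    LibraryRecord,
    StudyDesign,
    format_hairpin_identifier,
    revcomp,
    write_fasta,
    write_fastq,
)

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# Flank added on each side of the mature+loop+star insert; mirrors the +/-20 bp
# extension used when candidate loci are nominated, so planted truth loci and
# rediscovered loci coincide.
FLANK = 20

# Read-allocation recipes per truth category. Fractions of a locus's reads by
# class: mature-arm, window-straddling (terminal window but overlapping the
# loop), loop, star-arm, antisense. Margins are chosen so multinomial noise at
# a few hundred reads cannot flip a Boolean metric across its 95/95/5
# threshold.
CATEGORY_RECIPES: dict[str, dict[str, float]] = {
    #      mature  straddle loop   star   antisense
    "A": dict(mature=0.95, straddle=0.01, loop=0.00, star=0.03, antisense=0.01),
    "B": dict(mature=0.84, straddle=0.12, loop=0.00, star=0.02, antisense=0.02),
    "C": dict(mature=0.55, straddle=0.01, loop=0.01, star=0.41, antisense=0.02),
    "D": dict(mature=0.50, straddle=0.10, loop=0.05, star=0.33, antisense=0.02),
    "E": dict(mature=0.81, straddle=0.01, loop=0.00, star=0.03, antisense=0.15),
    "F": dict(mature=0.71, straddle=0.12, loop=0.00, star=0.02, antisense=0.15),
    "G": dict(mature=0.45, straddle=0.01, loop=0.01, star=0.38, antisense=0.15),
    "H": dict(mature=0.40, straddle=0.10, loop=0.05, star=0.30, antisense=0.15),
}

READ_CLASSES = ("mature", "straddle", "loop", "star", "antisense")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(n_contigs: int, lengths: list[int], seed: int) -> dict[str, str]:
    """i.i.d. uniform-ACGT contigs, deterministic given the seed."""
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have one entry per contig")
    if any(l < 200 for l in lengths):
        raise ValueError("contig lengths must be >= 200 nt")
    rng = np.random.default_rng(seed)
    return {f"ctg{i + 1:02d}": _random_seq(rng, l) for i, l in enumerate(lengths)}


# ---------------------------------------------------------------------------
# Hairpin planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedHairpin:
    """Ground truth for one planted pre-miRNA locus."""

    contig_id: str
    strand: str  # '+' or '-'
    arm_length: int
    loop_length: int
    star_mismatches: int
    truth_category: str
    mature_sequence: str
    star_sequence: str
    locus: HairpinIdentifier
    hairpin_sequence: str = ""  # sense orientation, flanks included

    @property
    def feature_id(self) -> str:
        return format_hairpin_identifier(self.locus)

    @property
    def region(self) -> tuple[int, int]:
        """0-based half-open genomic interval of the full hairpin region."""
        return self.locus.start - 1, self.locus.end

    def genomic_interval(self, sense_offset: int, length: int) -> tuple[int, int]:
        """Genomic interval of a sense-hairpin subinterval (strand aware)."""
        rs, re_ = self.region
        if self.strand == "+":
            return rs + sense_offset, rs + sense_offset + length
        return re_ - sense_offset - length, re_ - sense_offset


def plant_hairpin(
    genome: dict[str, str],
    contig_id: str,
    position: int,
    *,
    arm_length: int = 21,
    loop_length: int = 60,
    star_mismatches: int = 3,
    category: str = "A",
    strand: str = "+",
    rng: np.random.Generator,
    occupied: list[tuple[str, int, int]] | None = None,
    allow_edge_cases: bool = False,
) -> tuple[dict[str, str], PlantedHairpin]:
    """Insert a fold-back hairpin into the genome at ``position``.

    ``position`` is the 0-based genomic start of the full region including the
    20 nt flank. The star arm is the reverse complement of the mature arm with
    exactly ``star_mismatches`` substitutions placed >= 2 nt from both arm
    ends. The inner-edge separation of the arms equals ``loop_length``, which
    must fall in the 54-1000 bp window the pairing stage accepts.
    """
    if not allow_edge_cases:
        if not (2 <= star_mismatches <= 5):
            raise ValueError(
                "star_mismatches must be 2-5 for a rediscoverable hairpin "
                "(pass allow_edge_cases=True to override)"
            )
        if not (54 <= loop_length <= 1000):
            raise ValueError("loop_length outside the discoverable 54-1000 bp separation")
    if star_mismatches > max(arm_length - 4, 0):
        raise ValueError("too many star mismatches for the arm length")
    if category not in CATEGORY_RECIPES:
        raise ValueError(f"unknown truth category {category!r}")

    insert_len = 2 * arm_length + loop_length
    region_len = insert_len + 2 * FLANK
    contig = genome[contig_id]
    if position < 0 or position + region_len > len(contig):
        raise ValueError("hairpin region outside contig")
    if occupied is not None:
        for c, s, e in occupied:
            if c == contig_id and position < e and s < position + region_len:
                raise ValueError(
                    f"hairpin region {contig_id}:{position}-{position + region_len} "
                    f"overlaps a previously planted locus {c}:{s}-{e}"
                )

    mature = _random_seq(rng, arm_length)
    star = list(revcomp(mature))
    if star_mismatches:
        pos_choices = rng.choice(
            np.arange(2, arm_length - 2), size=star_mismatches, replace=False
        )
        for p in sorted(int(x) for x in pos_choices):
            alt = [b for b in "ACGT" if b != star[p]]
            star[p] = alt[int(rng.integers(0, 3))]
    star_seq = "".join(star)

    loop_seq = contig[position + FLANK + arm_length : position + FLANK + arm_length + loop_length]
    insert = mature + loop_seq + star_seq
    genomic_insert = insert if strand == "+" else revcomp(insert)
    new_contig = (
        contig[: position + FLANK] + genomic_insert + contig[position + FLANK + insert_len :]
    )
    genome = dict(genome)
    genome[contig_id] = new_contig

    locus = HairpinIdentifier(
        contig_id=contig_id,
        start=position + 1,
        end=position + region_len,
        mature_start=FLANK + 1,
        mature_length=arm_length,
    )
    region_seq = new_contig[position : position + region_len]
    hairpin = PlantedHairpin(
        contig_id=contig_id,
        strand=strand,
        arm_length=arm_length,
        loop_length=loop_length,
        star_mismatches=star_mismatches,
        truth_category=category,
        mature_sequence=mature,
        star_sequence=star_seq,
        locus=locus,
        hairpin_sequence=region_seq if strand == "+" else revcomp(region_seq),
    )
    if occupied is not None:
        occupied.append((contig_id, position, position + region_len))
    return genome, hairpin


def _class_read_seqs(h: PlantedHairpin) -> dict[str, list[str]]:
    """Insert sequences (as sequenced, 5'->3') for each read class of a locus."""
    hp = h.hairpin_sequence
    arm, loop = h.arm_length, h.loop_length
    mature = hp[FLANK : FLANK + arm]
    star = hp[FLANK + arm + loop : FLANK + 2 * arm + loop]
    straddle = [hp[28:52], hp[32:56]]
    loop_reads = [hp[52:73], hp[58:79]]
    return {
        "mature": [mature],
        "star": [star],
        "straddle": straddle,
        "loop": loop_reads,
        "antisense": [revcomp(mature)],
    }


# ---------------------------------------------------------------------------
# Factorial count model
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Expected-count model of one feature across the factorial design.

    Means follow a log2-link factorial model; counts are negative binomial
    with the given dispersion (variance mu + dispersion * mu^2).
    """

    feature_id: str
    baseline_mean: float
    genotype_log2fc: dict[str, float] = field(default_factory=dict)
    tissue_log2fc: float = 0.0
    treatment_log2fc: float = 0.0
    interaction_log2fc: float = 0.0  # tolerance x treatment
    dispersion: float = 0.1

    def __post_init__(self):
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def mean_for(self, rec: LibraryRecord) -> float:
        log2mu = (
            np.log2(self.baseline_mean)
            + self.genotype_log2fc.get(rec.genotype, 0.0)
            + self.tissue_log2fc * (rec.tissue == "head")
            + self.treatment_log2fc * (rec.treatment == "water_deficit")
            + self.interaction_log2fc * rec.tolerance * (rec.treatment == "water_deficit")
        )
        return float(2.0**log2mu)


def nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial counts parametrised by mean and dispersion."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    design: StudyDesign, effects: list[EffectSpec], seed: int | np.random.Generator
) -> pd.DataFrame:
    """Feature x library negative-binomial count matrix from effect specs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for eff in effects:
        means = np.array([eff.mean_for(r) for r in design])
        rows.append(nb_draw(rng, means, eff.dispersion))
    return pd.DataFrame(
        np.array(rows, dtype=int),
        index=[e.feature_id for e in effects],
        columns=design.library_ids,
    )


# ---------------------------------------------------------------------------
# Design presets
# ---------------------------------------------------------------------------

_ABBR_TISSUE = {"flag_leaf": "FL", "head": "H"}
_ABBR_TREAT = {"control": "CG", "water_deficit": "WG"}


def _factorial_design(genotypes: list[tuple[str, int]], n_replicates: int) -> StudyDesign:
    records = []
    for geno, tol in genotypes:
        for tissue in ("flag_leaf", "head"):
            for treatment in ("control", "water_deficit"):
                for rep in range(1, n_replicates + 1):
                    lib = f"{geno}_{_ABBR_TISSUE[tissue]}_{_ABBR_TREAT[treatment]}_r{rep}"
                    records.append(
                        LibraryRecord(lib, geno, tol, tissue, treatment, rep)
                    )
    return StudyDesign(records)


def full_design() -> StudyDesign:
    """The study's 4 genotypes x 2 tissues x 2 treatments x 6 replicates (96)."""
    return _factorial_design(
        [("Tamaroi", 1), ("Yawa", 1), ("EGA_Bellaroi", 0), ("Tjilkuri", 0)], 6
    )


def reduced_design(n_replicates: int = 3) -> StudyDesign:
    """Fast test-scale design: 1 tolerant + 1 sensitive genotype, 3 replicates."""
    return _factorial_design([("Tamaroi", 1), ("EGA_Bellaroi", 0)], n_replicates)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Reads plus ground truth for one simulated study."""

    design: StudyDesign
    genome: dict[str, str]
    hairpins: list[PlantedHairpin]
    effects: dict[str, EffectSpec]
    contaminants: dict[str, str]  # id -> sequence; id carries class=<label>
    contaminant_classes: dict[str, str]  # id -> class label
    mature_refs: dict[str, str]
    known_mature_names: dict[str, str]  # planted feature_id -> reference name
    reads: dict[str, list[tuple[str, str, str]]]  # library -> FASTQ records
    truth_counts: pd.DataFrame  # hairpin feature x library (non-contaminant)
    read_class: dict[str, str]  # insert sequence -> truth tag

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(os.path.join(outdir, "genome.fasta"), self.genome)
        write_fasta(
            os.path.join(outdir, "contaminants.fasta"),
            {f"{n} class={self.contaminant_classes[n]}": s for n, s in self.contaminants.items()},
        )
        write_fasta(os.path.join(outdir, "mature_refs.fasta"), self.mature_refs)
        self.design.to_table(os.path.join(outdir, "design.tsv"))
        readdir = os.path.join(outdir, "reads")
        os.makedirs(readdir, exist_ok=True)
        for lib in self.design.library_ids:
            write_fastq(os.path.join(readdir, f"{lib}.fastq"), self.reads[lib])
        self.truth_counts.to_csv(os.path.join(outdir, "truth_counts.tsv"), sep="\t")
        truth_rows = [
            (
                h.feature_id,
                h.contig_id,
                h.strand,
                h.truth_category,
                h.arm_length,
                h.loop_length,
                h.star_mismatches,
                h.mature_sequence,
            )
            for h in self.hairpins
        ]
        pd.DataFrame(
            truth_rows,
            columns=[
                "feature_id", "contig", "strand", "category",
                "arm_length", "loop_length", "star_mismatches", "mature_sequence",
            ],
        ).to_csv(os.path.join(outdir, "truth_hairpins.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(self.read_class.items()), columns=["sequence", "truth_class"]
        ).to_csv(os.path.join(outdir, "truth_read_classes.tsv"), sep="\t", index=False)


def make_contaminants(rng: np.random.Generator, n_per_class: int = 2, length: int = 300):
    """Generated stand-ins for rRNA / organellar / vector / repeat references."""
    refs: dict[str, str] = {}
    classes: dict[str, str] = {}
    for cls in ("rRNA", "organellar", "vector", "repeat"):
        for i in range(n_per_class):
            name = f"{cls}_{i + 1}"
            refs[name] = _random_seq(rng, length)
            classes[name] = cls
    return refs, classes


def _sequenced_read(insert: str, adapter3: str, read_length: int) -> str:
    return (insert + adapter3)[:read_length]


def simulate_reads(
    design: StudyDesign,
    hairpins: list[PlantedHairpin],
    effects: dict[str, EffectSpec],
    contaminants: dict[str, str],
    adapter3: str,
    seed: int | np.random.Generator,
    *,
    read_length: int = 36,
    contaminant_fraction: float = 0.05,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame, dict[str, str]]:
    """Simulate adapter-ligated reads per library.

    Returns (reads per library, truth count table hairpin x library, insert
    sequence -> truth class). Per-category coverage signatures are realised by
    the :data:`CATEGORY_RECIPES` multinomial allocation; contaminant reads are
    mixed in at ``contaminant_fraction`` of the hairpin read volume.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [h.feature_id for h in hairpins if h.feature_id not in effects]
    if missing:
        raise ValueError(f"missing EffectSpec for hairpins: {missing[:3]}")

    class_seqs = {h.feature_id: _class_read_seqs(h) for h in hairpins}
    read_class: dict[str, str] = {}
    for h in hairpins:
        for cls, seqs in class_seqs[h.feature_id].items():
            for s in seqs:
                read_class.setdefault(s, f"hairpin|{h.feature_id}|{cls}")

    cont_pool: list[tuple[str, str]] = []  # (insert, class tag)
    for name in sorted(contaminants):
        ref = contaminants[name]
        for off in range(10, len(ref) - 21, 40):
            ins = ref[off : off + 21]
            cont_pool.append((ins, name))
            read_class.setdefault(ins, f"contaminant|{name}")

    reads: dict[str, list[tuple[str, str, str]]] = {}
    counts = pd.DataFrame(
        0, index=[h.feature_id for h in hairpins], columns=design.library_ids, dtype=int
    )
    for rec in design:
        lib_reads: list[tuple[str, str, str]] = []
        serial = 0
        n_hairpin_reads = 0
        for h in hairpins:
            eff = effects[h.feature_id]
            n = int(nb_draw(rng, eff.mean_for(rec), eff.dispersion))
            counts.loc[h.feature_id, rec.library_id] = n
            n_hairpin_reads += n
            recipe = CATEGORY_RECIPES[h.truth_category]
            probs = np.array([recipe[c] for c in READ_CLASSES])
            alloc = rng.multinomial(n, probs / probs.sum())
            for cls, n_cls in zip(READ_CLASSES, alloc):
                seqs = class_seqs[h.feature_id][cls]
                sub = rng.multinomial(n_cls, np.full(len(seqs), 1.0 / len(seqs)))
                for s, k in zip(seqs, sub):
                    for _ in range(int(k)):
                        read = _sequenced_read(s, adapter3, read_length)
                        lib_reads.append((f"{rec.library_id}_{serial}", read, "I" * len(read)))
                        serial += 1
        if cont_pool:
            n_cont = int(round(contaminant_fraction * n_hairpin_reads))
            alloc = rng.multinomial(n_cont, np.full(len(cont_pool), 1.0 / len(cont_pool)))
            for (ins, _name), k in zip(cont_pool, alloc):
                for _ in range(int(k)):
                    read = _sequenced_read(ins, adapter3, read_length)
                    lib_reads.append((f"{rec.library_id}_{serial}", read, "I" * len(read)))
                    serial += 1
        reads[rec.library_id] = lib_reads
    return reads, counts, read_class


# ---------------------------------------------------------------------------
# Whole-study construction
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults are the reduced test-scale design (2 genotypes x 2 tissues x
    2 treatments x 3 replicates); ``use_full_design`` switches to the study's
    96-library factorial.
    """

    n_contigs: int = 4
    contig_length: int = 25_000
    n_hairpins_per_category: dict[str, int] = field(
        default_factory=lambda: {"A": 8, "C": 2, "E": 2, "H": 2}
    )
    arm_length: int = 21
    loop_range: tuple[int, int] = (54, 90)
    star_mismatch_choices: tuple[int, ...] = (2, 3, 4)
    minus_strand_fraction: float = 0.5
    adapter3: str = "AGATCGGAAGAGCACACGTCT"
    read_length: int = 36
    baseline_mean: float = 80.0
    dispersion: float = 0.05
    interaction_fraction: float = 0.125
    interaction_log2fc: float = 2.0
    treatment_responsive_fraction: float = 0.25
    treatment_log2fc: float = 1.5
    tissue_log2fc: float = 1.0
    tissue_fraction: float = 0.25
    contaminant_fraction: float = 0.05
    known_mature_fraction: float = 0.5
    n_decoy_refs: int = 10
    n_breakdown_transcripts: int = 2
    breakdown_transcript_length: int = 150
    breakdown_fragment_mean: int = 8
    n_junk_reads: int = 30
    use_full_design: bool = False
    n_replicates: int = 3


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Build a complete synthetic study from one master seed."""
    ss = np.random.SeedSequence(seed)
    (g_seed, plant_seed, eff_seed, read_seed, extra_seed) = ss.spawn(5)
    genome = make_genome(
        config.n_contigs, [config.contig_length] * config.n_contigs, g_seed.generate_state(1)[0] % 2**31
    )
    plant_rng = np.random.default_rng(plant_seed)
    eff_rng = np.random.default_rng(eff_seed)
    extra_rng = np.random.default_rng(extra_seed)

    # -- plant hairpins on a grid of well-separated positions
    contig_ids = sorted(genome)
    hairpins: list[PlantedHairpin] = []
    occupied: list[tuple[str, int, int]] = []
    categories = [c for c, k in sorted(config.n_hairpins_per_category.items()) for _ in range(k)]
    n_total = len(categories)
    per_contig = -(-n_total // len(contig_ids))
    slots = []
    max_region = 2 * config.arm_length + config.loop_range[1] + 2 * FLANK
    for cid in contig_ids:
        usable = config.contig_length - max_region - 100
        step = usable // per_contig
        for j in range(per_contig):
            slots.append((cid, 50 + j * step))
    order = extra_rng.permutation(n_total)
    for idx, cat in zip(order, categories):
        cid, pos = slots[int(idx)]
        loop = int(plant_rng.integers(config.loop_range[0], config.loop_range[1] + 1))
        mism = int(plant_rng.choice(config.star_mismatch_choices))
        strand = "-" if plant_rng.random() < config.minus_strand_fraction else "+"
        genome, hp = plant_hairpin(
            genome, cid, pos,
            arm_length=config.arm_length, loop_length=loop, star_mismatches=mism,
            category=cat, strand=strand, rng=plant_rng, occupied=occupied,
        )
        hairpins.append(hp)
    hairpins.sort(key=lambda h: (h.contig_id, h.locus.start))

    # -- effect specs: planted interaction / treatment / tissue effects
    design = full_design() if config.use_full_design else reduced_design(config.n_replicates)
    effects: dict[str, EffectSpec] = {}
    for i, h in enumerate(hairpins):
        eff = EffectSpec(h.feature_id, config.baseline_mean, dispersion=config.dispersion)
        u = eff_rng.random()
        if u < config.interaction_fraction:
            sign = 1.0 if eff_rng.random() < 0.5 else -1.0
            eff = replace(eff, interaction_log2fc=sign * config.interaction_log2fc)
        elif u < config.interaction_fraction + config.treatment_responsive_fraction:
            sign = 1.0 if eff_rng.random() < 0.5 else -1.0
            eff = replace(eff, treatment_log2fc=sign * config.treatment_log2fc)
        if eff_rng.random() < config.tissue_fraction:
            sign = 1.0 if eff_rng.random() < 0.5 else -1.0
            eff = replace(eff, tissue_log2fc=sign * config.tissue_log2fc)
        effects[h.feature_id] = eff

    contaminants, cont_classes = make_contaminants(extra_rng)
    reads, truth_counts, read_class = simulate_reads(
        design, hairpins, effects, contaminants, config.adapter3,
        np.random.default_rng(read_seed),
        read_length=config.read_length, contaminant_fraction=config.contaminant_fraction,
    )

    # -- mature reference set: a known fraction of planted matures plus decoys
    mature_refs: dict[str, str] = {}
    known: dict[str, str] = {}
    for i, h in enumerate(hairpins):
        if extra_rng.random() < config.known_mature_fraction:
            name = f"pmiR{i + 1:03d}"
            mature_refs[name] = h.mature_sequence
            known[h.feature_id] = name
    for j in range(config.n_decoy_refs):
        mature_refs[f"decoy{j + 1:03d}"] = _random_seq(extra_rng, config.arm_length)

    # -- breakdown products of longer transcripts: untrimmed long fragments
    #    plus short trimmed fragments that the assembly filter should remove
    transcripts = [
        _random_seq(extra_rng, config.breakdown_transcript_length)
        for _ in range(config.n_breakdown_transcripts)
    ]
    frag_inserts: list[str] = []
    for t in transcripts:
        for off in range(0, len(t) - config.read_length, 4):
            frag_inserts.append(t[off : off + config.read_length + 6])  # > read length: stays untrimmed
        for off in range(5, len(t) - 21, 37):
            frag_inserts.append(t[off : off + 21])  # breakdown sRNA-sized fragment
    for ins in frag_inserts:
        tag = "breakdown_long" if len(ins) > config.read_length else "breakdown_short"
        read_class.setdefault(ins, tag)
    for rec in design:
        lib_reads = reads[rec.library_id]
        serial = len(lib_reads)
        for ins in frag_inserts:
            k = int(extra_rng.poisson(config.breakdown_fragment_mean))
            for _ in range(k):
                read = _sequenced_read(ins, config.adapter3, config.read_length)
                lib_reads.append((f"{rec.library_id}_{serial}", read, "I" * len(read)))
                serial += 1
        # junk singletons exercising the low-abundance filter
        for _ in range(config.n_junk_reads):
            ins = _random_seq(extra_rng, 21)
            read_class.setdefault(ins, "junk")
            read = _sequenced_read(ins, config.adapter3, config.read_length)
            lib_reads.append((f"{rec.library_id}_{serial}", read, "I" * len(read)))
            serial += 1

    return SimulatedStudy(
        design=design,
        genome=genome,
        hairpins=hairpins,
        effects=effects,
        contaminants=contaminants,
        contaminant_classes=cont_classes,
        mature_refs=mature_refs,
        known_mature_names=known,
        reads=reads,
        truth_counts=truth_counts,
        read_class=read_class,
    )
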