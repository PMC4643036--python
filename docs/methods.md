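# Methods

This note documents the models, rules and numerical choices behind
`durumir`, and what the synthetic-data validation does and does not
demonstrate.

## Study design and coordinates

A study is a factorial design of genotype × tissue (flag leaf, developing
head) × treatment (control, water deficit) × replicate. Each genotype
carries a binary tolerance class, constant within genotype. The reference
design is 4 genotypes × 2 × 2 × 6 = 96 libraries; the default test-scale
design is 2 genotypes (one tolerant, one sensitive) × 2 × 2 × 3 = 24
libraries, which keeps fixtures fast while preserving every factor.

All internal interval arithmetic is 0-based half-open. The hairpin
identifier string `contig:start-end[mature_start,mature_length]` uses
1-based inclusive coordinates, converting only at the codec boundary; an en
dash is accepted on input as an alias for the hyphen.

## Pre-processing cascade

Reads are 3′-adapter trimmed (leftmost exact match of ≥ 8 adapter bases;
shorter matches are treated as absent), and partitioned into: trimmed
19–26 nt reads (hairpin discovery), trimmed 15–50 nt reads (conserved
profiling), and untrimmed reads (no adapter ⇒ insert longer than the read).
Reads containing N are dropped — a declared stand-in for quality filtering,
since base-quality realism is out of scope — and reads still carrying a 5′
adapter prefix after 3′ trimming are discarded.

Unique-read tables are filtered in a fixed order: total count ≤ 5 across all
libraries; rRNA-like; organellar; de novo breakdown contigs; vector; repeat.
Contaminant mapping is an exhaustive ungapped Hamming search over both
strands with ≤ 2 mismatches and no indels — the same contract as a
two-mismatch end-to-end short-read aligner, with simpler semantics. The
breakdown filter assembles the untrimmed reads plus the table's own
sequences with a minimal de Bruijn assembler (k = 17, unbranched paths, no
bubble popping or coverage cutoffs) and removes table rows hitting any
contig ≥ 50 bp; the assembly exists only to produce this filter reference,
so path-level fidelity is irrelevant. Assembly runs before contaminant
filtering, matching the cascade order. Every stage's removals are logged and
sum to input − output.

## Conserved-miRNA profiling

Annotation aligns each unique read to each mature reference at the best
ungapped offset with overlap ≥ min(len_read, len_ref) − 2 and ≤ 2
mismatches over the overlap; the overlap slack accommodates the ± 2 nt
length variation of mature references. Reads tying several references count
toward all of them and are flagged.

RPM normalises by the library's total trimmed 15–50 nt reads. The candidate
rule (RPM strictly > 2 in ≥ ⌈half the libraries⌉) is evaluated on replicate
libraries; fold-change contrasts use the mean RPM of a factor cell's
replicates (the aggregation choice is ours; pooled counts would weight deep
libraries more). The call requires fold change > 1.5 and raw RPM ≥ 10 on one
side; zeros are floored at 0.01 RPM before ratios so direction is always
defined.

Pattern classifiers operate on called contrasts only. "Predominant"
expression is operationalised as unanimity of direction over called cells:
genotype groups I–IV require ≥ 1 called contrast per treatment with all
called contrasts in one treatment agreeing (I: tolerant under both
treatments; II: sensitive under both; III: tolerant under control, sensitive
under stress; IV: the reverse); anything else — including a treatment with
no callable contrast — is unclassified. Tissue predominance requires ≥ 6 of
the 8 genotype × treatment strata called in one direction (scaled
proportionally for smaller designs). Stress responsiveness requires ≥ 1
called stress-vs-control stratum, with uncalled strata recorded as 0 log₂FC
in the exported matrices.

## Hairpin discovery

A candidate locus is any same-read pairing of a perfect alignment with a
2–5-mismatch alignment on the opposite strand of the same contig, separated
by 54–1000 bp. The separation is the inner-edge gap between the two
alignment intervals — the prospective loop plus spacer; a centre-to-centre
reading would be geometrically meaningless for 19–26 nt arms. One-mismatch
alignments belong to neither set. Imperfect alignment is only run for reads
that aligned perfectly somewhere, reflecting the two-stage nomination. The
non-redundant set of pair footprints ± 20 bp forms the candidate regions.

Each region is folded by a maximum-base-pairing dynamic program
(Watson–Crick plus G·U wobble, minimum loop 3 nt). The DP maximises
(pairs, stacked pairs) lexicographically: the pair count is exactly the
Nussinov maximum, while the stacking tie-break makes the traceback realise
long helices instead of scattering pairs across equivalent-count structures.

The biogenesis gate evaluates the miRNA/miRNA\* duplex directly rather than
reading it off the traceback. Maximum base pairing is not an energy model:
its optimum is massively degenerate, and after a star-arm mismatch it often
pairs the remainder of the mature arm into loop or flank partners because
that gains *more* total pairs than the true stem — so duplex statistics
derived from any single optimal structure are unstable. Instead, the mature
arm is scanned against every distal window of the region (antiparallel
complementarity, WC + G·U, no indels), optionally allowing one register
shift of ≤ 4 nt when it recovers ≥ 3 extra pairs (a real asymmetric bulge
regains a whole helix segment, whereas chance realignment gains one or two).
The gate passes when: unpaired mature bases ≤ 4; the register shift (bulge)
≤ 2 nt; the duplex window is distal to the mature arm; and one merged helix
run (gaps ≤ 3 unpaired bases) covers ≥ 60 % of the mature arm. On planted
hairpins this gate passes essentially always; on shuffled sequences of the
same composition it rejects ≥ 95 %, with failures dominated by the unpaired
count. All four thresholds are configuration keys (`MircheckParams`).

Coverage metrics use the perfect alignments of all unique reads
majority-overlapping the region, count-weighted: strand bias is the
majority-strand fraction; the terminal metric assigns each read to the
5′ window [0, 50), the loop, or the 3′ window [L−50, L) by majority of
bases (exact ties go to the terminal window) and takes the larger window's
fraction; the loop metric is the fraction of reads overlapping the loop
region by ≥ 1 nt. The loop metric deliberately uses overlap rather than
majority assignment: under majority assignment, ≥ 95 % in one window would
force loop ≤ 5 % and two of the eight categories (Y Y N and N Y N) could
never occur, contradicting their observed non-emptiness; window-straddling
reads are exactly what distinguishes them. Regions ≤ 100 bp have an empty
loop and the loop metric holds vacuously. The three Booleans
(≥ 0.95, ≥ 0.95, ≤ 0.05) map to categories A = YYY … H = NNN.

The candidate's orientation is the majority read strand; the mature arm is
the most abundant majority-strand read. Known/novel status is an exact
substring match of a reference mature (U→T normalised) in the sense hairpin
sequence; matching the star arm also counts (arms are not distinguished),
and `match_both_strands` extends the search to the reverse complement.
Output is sorted by (category, contig, start) and is invariant to read input
order.

## Interaction testing

Hairpin counts (per-library sums of unique reads whose perfect alignment
majority-overlaps the candidate region) are transformed to
log₂((count + 0.5) / (total + 1) × 10⁶), with library totals taken from the
whole filtered read table so that feature-subset matrices are normalised
correctly. The linear model is
`intercept + tolerance + treatment + tissue + tolerance × treatment`,
fitted by OLS per feature; tissue enters as a main effect because all
libraries are analysed together (a per-tissue mode refits tissues
separately). The tolerance × treatment coefficient is the only contrast
tested.

Moderation follows the standard empirical-Bayes variance hierarchy: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior (d₀, s₀²) is estimated by
method of moments, inverting the trigamma function by geometric bisection
(tolerance 10⁻⁸, ≤ 100 iterations); excess variance ≤ 0 gives the d₀ = ∞
limit (s̃²_g = s₀², normal reference distribution). The implementation
reproduces Bioconductor limma's `lmFit`/`eBayes` to ~10⁻¹⁰ relative error in
the finite-d₀ regime (checked in the test suite via `Rscript`). No
mean–variance (voom-style) observation weights are used — a documented
simplification: hairpin-level counts in the simulated studies are moderate
and roughly equidispersed on the log scale. Benjamini–Hochberg at FDR 0.05
(configurable) defines significance.

The read-signature screen replacing manual coverage inspection passes a
flagged hairpin when strand bias ≥ 0.98, ≥ 90 % of reads fall in the mature
terminal window, and the modal 5′ end carries ≥ 50 % of the mature-window
reads (crisp Dicer-style processing); the score is the product of the three
fractions. It is deliberately stricter than category A.

## The synthetic generator

The generator emulates the study conditions, not sequencing physics.
Defaults: 4 contigs × 25 kb of i.i.d. uniform ACGT; 21 nt arms; loop
lengths uniform in 54–90 nt (the lower bound is the smallest separation the
pairing stage accepts); star arms with 2–4 substitutions placed ≥ 2 nt from
arm ends — 5 is a legal input but is not sampled by default, since a
5-mismatch duplex can exceed the gate's 4-unpaired tolerance and the
generator refuses to plant truth the pipeline is specified to reject; both
strands planted with equal probability; 36 nt reads with a 21 nt 3′ adapter;
constant base qualities.

Counts per locus and library are negative binomial with log₂-link factorial
means. Default baseline 80 reads/library and dispersion 0.05 — the
biological-replicate scale (CV ≈ 0.22) at which the > 1.5-fold calling rule
has a low false-call rate on null features; the interaction-statistics
simulations use dispersion 0.1 explicitly as a harder setting. Default
planted effects: 12.5 % of hairpins carry a ± 2 log₂ interaction, 25 % a
± 1.5 log₂ treatment response, 25 % a ± 1 log₂ tissue effect.

Reads at each locus are allocated by per-category recipes over five classes
— mature, star, window-straddling, loop, antisense — with margins (e.g.
category A: 95 % mature, 3 % star, 1 % antisense) chosen so multinomial
noise at a few hundred reads cannot flip a Boolean metric across its
95/95/5 threshold. The mature:star ratio is therefore category-dependent: a
uniform ratio like 10:1 would cap the terminal-window fraction at ~0.91 and
make every metric-2-positive category unplantable. Contaminants (rRNA-like,
organellar-like, vector-like, repeat-like generated sequences, truth-tagged)
are mixed at 5 % of hairpin read volume; two 150 nt transcripts provide
untrimmed fragments and short breakdown products for the assembly filter;
30 junk singletons per library exercise the low-abundance filter. All
randomness descends from one master seed; identical seeds give byte-identical
FASTQ and pipeline outputs.

What passing tests show — and what they do not: the validation demonstrates
correctness of the rules and statistics under the generative model (NB
counts, exact planted duplexes, substitution-only divergence, uniform base
composition). Real small-RNA data add RNA-editing and isomiR 5′/3′
heterogeneity, multi-mapping across homoeologous subgenomes, non-uniform
genome composition and repeat structure, adapter chemistry biases, and
quality artefacts; recovery rates measured here are upper bounds for such
data, and genome-scale (gigabase) alignment would need an indexed aligner
rather than the exhaustive scan used at these problem sizes.

## Numerical and degenerate-case choices

- Fold input is limited to 4–1100 nt; non-ACGU characters are errors.
- DP tie-breaks: a position is left unpaired when that already attains the
  optimum; otherwise the smallest admissible partner is taken; helix
  continuation is preferred inside a pair when it ties the interior optimum.
  This fixes one deterministic structure per sequence.
- Equal group means give direction "tie" and are never called.
- A zero library total is an error naming the library.
- A single feature cannot be moderated; the ordinary t is used with a
  warning.
- `estimate_prior` floors variances at 10⁻³⁰⁰ before logs; exact-fit rows
  (s² = 0) therefore do not crash the hierarchy but will dominate shrinkage —
  filter constant features upstream.
- Problem sizes in the tests and the acceptance script (100 kb genome, 40
  planted loci, 24–96 libraries, 2000-feature null panels) are the scale at
  which every property is measurable with tight Monte-Carlo error; they are
  the package's validation conditions, not limits of the implementation.

## Known limitations

- The fold model has no thermodynamics: no ΔG, no multiloop penalty, no
  pseudoknots. It is a plausibility gate, not a structure predictor.
- Known/novel status uses exact substring matching only; a 1-mismatch
  reference match is "novel".
- The tissue main effect assumes parallel tissue shifts; genuine
  tissue × treatment structure would need the per-tissue mode.
- The headline counts of a real field study (hundreds of millions of reads,
  thousands of candidate loci) are not reproducible at these problem sizes;
  the pipeline validates the *rules*, not the census.
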