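"""End-to-end orchestration of the small-RNA analysis stages.

``run_all`` drives the whole pipeline on a simulated study (or on inputs
written by an earlier ``simulate`` run) and writes deterministic TSV outputs:
identical seeds produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from . import conserved_profiling as cp
from . import hairpin_discovery as hd
from . import interaction_de as ide
from .io_formats import write_bed6, write_fasta
from .preprocess import FilterParams, PreprocessResult, run_preprocess
from .synthdata import SimulatedStudy, SimulationConfig, simulate_study

FLOAT_FMT = "%.6g"


@dataclass
class PipelineResult:
    study: SimulatedStudy
    preprocess: PreprocessResult
    rpm: pd.DataFrame
    conserved_candidates: list[str]
    genotype_groups: pd.Series
    tissue_predominance: pd.Series
    stress_responsive: list[str]
    hairpin_candidates: list[hd.HairpinCandidate]
    hairpin_counts: pd.DataFrame
    interaction: ide.InteractionFit | None
    flagged: list[str]
    strong: list[str]


def _to_tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)


def run_all(config: SimulationConfig, seed: int, outdir: str) -> PipelineResult:
    """Simulate a study and run every analysis stage, writing all outputs."""
    os.makedirs(outdir, exist_ok=True)
    study = simulate_study(config, seed)
    study.write(os.path.join(outdir, "inputs"))
    design = study.design

    # ---- pre-processing cascade
    per_lib = {lib: [seq for _rid, seq, _q in recs] for lib, recs in study.reads.items()}
    pre = run_preprocess(
        per_lib, design, config.adapter3, study.contaminants, study.contaminant_classes,
        FilterParams(),
    )
    pre.table.to_tsv(os.path.join(outdir, "unique_reads.tsv"))
    _to_tsv(pre.removal_log, os.path.join(outdir, "removal_log.tsv"), index=False)

    # ---- conserved profiling (Approach 1)
    annot, _multi = cp.annotate_conserved(pre.approach1_table, study.mature_refs)
    rpm = cp.compute_rpm(annot, pre.library_totals)
    _to_tsv(rpm, os.path.join(outdir, "rpm_matrix.tsv"), index_label="miRNA")
    conserved_candidates = cp.call_candidates(rpm)
    with open(os.path.join(outdir, "conserved_candidates.txt"), "w") as fh:
        fh.write("\n".join(conserved_candidates) + ("\n" if conserved_candidates else ""))

    geno = cp.genotype_comparisons(rpm, design)
    tiss = cp.tissue_comparisons(rpm, design)
    stress = cp.stress_comparisons(rpm, design)

    groups = pd.Series(
        {
            f: cp.classify_genotype_group({k: geno[k][f] for k in geno})
            for f in rpm.index
        },
        name="group",
    ).sort_index()
    tissue_pred = pd.Series(
        {
            f: cp.classify_tissue_predominance(
                {k: tiss[k][f] for k in tiss}, min_called=max(1, len(tiss) * 3 // 4)
            )
            for f in rpm.index
        },
        name="tissue_predominance",
    ).sort_index()
    flagged_stress, stress_mat = cp.call_stress_responsive(stress)
    _to_tsv(groups.to_frame(), os.path.join(outdir, "genotype_groups.tsv"), index_label="miRNA")
    _to_tsv(
        tissue_pred.to_frame(), os.path.join(outdir, "tissue_predominance.tsv"), index_label="miRNA"
    )
    _to_tsv(stress_mat, os.path.join(outdir, "stress_log2fc.tsv"), index_label="miRNA")
    _to_tsv(
        cp.log2fc_matrix(geno), os.path.join(outdir, "genotype_log2fc.tsv"), index_label="miRNA"
    )
    _to_tsv(
        cp.log2fc_matrix(tiss), os.path.join(outdir, "tissue_log2fc.tsv"), index_label="miRNA"
    )
    with open(os.path.join(outdir, "stress_responsive.txt"), "w") as fh:
        fh.write("\n".join(flagged_stress) + ("\n" if flagged_stress else ""))

    # ---- hairpin discovery (Approach 2)
    candidates = hd.discover(pre.table, study.genome, study.mature_refs)
    frame = hd.candidates_frame(candidates)
    _to_tsv(frame, os.path.join(outdir, "hairpin_candidates.tsv"), index=False)
    write_bed6(
        os.path.join(outdir, "hairpins.bed"),
        [(c.identifier, c.category, c.strand) for c in candidates],
    )
    write_fasta(
        os.path.join(outdir, "hairpins.fasta"), [(c.name, c.sequence) for c in candidates]
    )
    with open(os.path.join(outdir, "hairpins_structure.txt"), "w") as fh:
        for c in candidates:
            fh.write(f">{c.name}\n{c.sequence}\n{c.fold.structure}\n")

    perfect_hits = hd.find_alignments(sorted(pre.table.sequences), study.genome, "perfect")
    hp_counts = hd.quantify_candidates(candidates, pre.table, study.genome, perfect_hits)
    _to_tsv(hp_counts, os.path.join(outdir, "hairpin_counts.tsv"), index_label="hairpin")

    # ---- tolerance x treatment interaction on category-A hairpins
    interaction = None
    flagged: list[str] = []
    strong: list[str] = []
    if len(hp_counts) >= 2:
        interaction = ide.run_interaction(
            hp_counts, design, library_totals=pre.table.df.sum(axis=0)
        )
        _to_tsv(
            interaction.table, os.path.join(outdir, "interaction_fits.tsv"), index_label="hairpin"
        )
        cat_a = [c.name for c in candidates if c.category == "A"]
        flagged = ide.select_candidates(interaction, cat_a)
        by_name = {c.name: c for c in candidates}
        sig_rows = []
        for name in flagged:
            c = by_name[name]
            lo, hi = c.identifier.start - 1, c.identifier.end
            over = hd._overlapping_hits(perfect_hits, c.identifier.contig_id, lo, hi)
            intervals = [
                (h.start - lo, h.end - lo, h.strand, int(pre.table.total_count[h.read_seq]))
                for h in over
            ]
            # mature interval in region (genomic) coordinates
            m_lo, m_hi = c.mature_interval
            if c.strand == "-":
                m_lo, m_hi = (hi - lo) - m_hi, (hi - lo) - m_lo
            ok, score = ide.signature_check(intervals, hi - lo, (m_lo, m_hi))
            sig_rows.append((name, ok, score))
            if ok:
                strong.append(name)
        _to_tsv(
            pd.DataFrame(sig_rows, columns=["hairpin", "signature_pass", "score"]),
            os.path.join(outdir, "interaction_flagged.tsv"),
            index=False,
        )

    return PipelineResult(
        study=study,
        preprocess=pre,
        rpm=rpm,
        conserved_candidates=conserved_candidates,
        genotype_groups=groups,
        tissue_predominance=tissue_pred,
        stress_responsive=flagged_stress,
        hairpin_candidates=candidates,
        hairpin_counts=hp_counts,
        interaction=interaction,
        flagged=flagged,
        strong=strong,
    )
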