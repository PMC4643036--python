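"""Conserved-miRNA profiling against a mature reference set.

Unique reads are annotated to known mature miRNAs (best ungapped alignment,
up to two mismatches), counts are normalised to reads per million (RPM), and
differential abundance is called with explicit rules: a 0.01 RPM floor for
zeros, >= 10 RPM required in one side of a comparison, and a fold change
> 1.5. Pattern classifiers summarise genotype groups (I-IV), tissue
predominance, and water-deficit responsiveness across the factorial strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import StudyDesign
from .preprocess import UniqueReadTable


@dataclass
class DECriteria:
    """Thresholds for candidate and differential-abundance calls."""

    zero_floor: float = 0.01
    min_rpm: float = 10.0
    fc_threshold: float = 1.5
    candidate_min_rpm: float = 2.0
    candidate_min_fraction: float = 0.5
    annot_max_mismatch: int = 2

    def __post_init__(self):
        if not (0 < self.candidate_min_fraction <= 1):
            raise ValueError("candidate_min_fraction must be in (0, 1]")
        for fieldname in ("zero_floor", "min_rpm", "fc_threshold", "candidate_min_rpm"):
            if getattr(self, fieldname) <= 0:
                raise ValueError(f"{fieldname} must be strictly positive")


@dataclass
class DEComparisonResult:
    """One feature's fold change between two conditions.

    ``direction`` is 'a' when the first argument is the more abundant side,
    'b' otherwise; ``log2fc`` is signed (positive favours side a).
    """

    feature_id: str
    comparison: str
    rpm_a: float
    rpm_b: float
    fold_change: float
    log2fc: float
    direction: str  # 'a' | 'b' | 'tie'
    called: bool
    reason: str  # passed | below_min_rpm | below_fc


# ---------------------------------------------------------------------------
# Annotation and normalisation
# ---------------------------------------------------------------------------

def _best_ungapped(read: str, ref: str, max_mismatch: int, min_overlap_slack: int = 2):
    """Best sliding-offset ungapped alignment of read vs reference.

    The overlap must be >= min(len(read), len(ref)) - 2 (mature references
    vary by a couple of nt in length); mismatches are counted over the
    overlap. Returns the minimum mismatch count or None if no admissible
    offset achieves <= max_mismatch.
    """
    lr, lf = len(read), len(ref)
    need = min(lr, lf) - min_overlap_slack
    best = None
    for shift in range(-(lr - need), lf - need + 1):
        a0 = max(0, -shift)
        b0 = max(0, shift)
        n = min(lr - a0, lf - b0)
        if n < need:
            continue
        mm = sum(1 for i in range(n) if read[a0 + i] != ref[b0 + i])
        if mm <= max_mismatch and (best is None or mm < best):
            best = mm
            if best == 0:
                break
    return best


def annotate_conserved(
    table: UniqueReadTable,
    mature_refs: Mapping[str, str],
    max_mismatch: int = 2,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Assign unique reads to mature references (<=2 mismatches, ungapped).

    Each read goes to all references tying for the minimum mismatch count;
    reads hitting more than one reference are flagged. Returns the per-miRNA
    per-library count matrix and the multi-assignment flags
    (read sequence -> assigned reference names).
    """
    if not mature_refs:
        raise ValueError("mature reference set is empty")
    refs = {n: s.upper().replace("U", "T") for n, s in mature_refs.items()}
    counts = pd.DataFrame(
        0.0, index=sorted(refs), columns=table.df.columns
    )
    multi: dict[str, list[str]] = {}
    for seq in table.sequences:
        scores = {}
        for name, ref in refs.items():
            mm = _best_ungapped(seq, ref, max_mismatch)
            if mm is not None:
                scores[name] = mm
        if not scores:
            continue
        best = min(scores.values())
        assigned = sorted(n for n, mm in scores.items() if mm == best)
        if len(assigned) > 1:
            multi[seq] = assigned
        for name in assigned:
            counts.loc[name] += table.df.loc[seq]
    counts = counts.astype(int)
    return counts.loc[counts.sum(axis=1) > 0], multi


def compute_rpm(counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """Reads-per-million normalisation: counts / library total x 1e6."""
    totals = library_totals.reindex(counts.columns)
    bad = totals[(totals <= 0) | totals.isna()]
    if len(bad):
        raise ValueError(f"non-positive library total for {list(bad.index)[:3]}")
    return counts / totals * 1e6


def call_candidates(rpm: pd.DataFrame, criteria: DECriteria | None = None) -> list[str]:
    """Features with RPM strictly above the candidate threshold in at least
    ceil(fraction x n_libraries) libraries."""
    criteria = criteria or DECriteria()
    need = math.ceil(criteria.candidate_min_fraction * rpm.shape[1])
    ok = (rpm > criteria.candidate_min_rpm).sum(axis=1) >= need
    return list(rpm.index[ok])


# ---------------------------------------------------------------------------
# Pairwise differential abundance
# ---------------------------------------------------------------------------

def pairwise_de(
    rpm_a: float,
    rpm_b: float,
    criteria: DECriteria | None = None,
    feature_id: str = "",
    comparison: str = "",
) -> DEComparisonResult:
    """Fold-change call between two group-mean RPM values.

    Zeros are floored to ``zero_floor`` before the ratio; the call requires
    fold change > ``fc_threshold`` and raw RPM >= ``min_rpm`` on at least one
    side.
    """
    criteria = criteria or DECriteria()
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("RPM values must be non-negative")
    a = rpm_a if rpm_a > 0 else criteria.zero_floor
    b = rpm_b if rpm_b > 0 else criteria.zero_floor
    fc = max(a, b) / min(a, b)
    if a == b:
        direction = "tie"
    else:
        direction = "a" if a > b else "b"
    log2fc = float(np.log2(a / b))
    if max(rpm_a, rpm_b) < criteria.min_rpm:
        called, reason = False, "below_min_rpm"
    elif fc <= criteria.fc_threshold:
        called, reason = False, "below_fc"
    else:
        called, reason = True, "passed"
    return DEComparisonResult(
        feature_id=feature_id, comparison=comparison, rpm_a=rpm_a, rpm_b=rpm_b,
        fold_change=float(fc), log2fc=log2fc, direction=direction,
        called=called, reason=reason,
    )


def group_mean_rpm(rpm: pd.DataFrame, design: StudyDesign, **factors) -> pd.Series:
    """Mean RPM over the replicate libraries of one factor cell."""
    libs = design.libraries(**factors)
    if not libs:
        raise ValueError(f"no libraries match {factors}")
    return rpm[libs].mean(axis=1)


# ---------------------------------------------------------------------------
# Stratified comparison runners
# ---------------------------------------------------------------------------

def genotype_comparisons(
    rpm: pd.DataFrame,
    design: StudyDesign,
    pairs: list[tuple[str, str]] | None = None,
    criteria: DECriteria | None = None,
) -> dict[tuple[str, str, str], dict[str, DEComparisonResult]]:
    """Tolerant-vs-sensitive genotype contrasts per (pair, treatment, tissue).

    ``pairs`` lists (tolerant, sensitive) genotype couples; by default every
    tolerant genotype is paired with the sensitive genotype of equal rank in
    design order. Side a is always the tolerant genotype.
    """
    criteria = criteria or DECriteria()
    if pairs is None:
        tol = [g for g in design.genotypes if design.tolerance_of(g) == 1]
        sen = [g for g in design.genotypes if design.tolerance_of(g) == 0]
        if len(tol) != len(sen):
            raise ValueError("cannot auto-pair genotypes; pass pairs explicitly")
        pairs = list(zip(tol, sen))
    out: dict[tuple[str, str, str], dict[str, DEComparisonResult]] = {}
    for tol_g, sen_g in pairs:
        label = f"{tol_g}-vs-{sen_g}"
        for treatment in ("control", "water_deficit"):
            for tissue in ("flag_leaf", "head"):
                a = group_mean_rpm(rpm, design, genotype=tol_g, treatment=treatment, tissue=tissue)
                b = group_mean_rpm(rpm, design, genotype=sen_g, treatment=treatment, tissue=tissue)
                stratum = {}
                for f in rpm.index:
                    stratum[f] = pairwise_de(
                        float(a[f]), float(b[f]), criteria, f,
                        f"{label}|{treatment}|{tissue}",
                    )
                out[(label, treatment, tissue)] = stratum
    return out


def tissue_comparisons(
    rpm: pd.DataFrame, design: StudyDesign, criteria: DECriteria | None = None
) -> dict[tuple[str, str], dict[str, DEComparisonResult]]:
    """Head-vs-flag-leaf contrasts per (genotype, treatment); side a = head."""
    criteria = criteria or DECriteria()
    out = {}
    for geno in design.genotypes:
        for treatment in ("control", "water_deficit"):
            a = group_mean_rpm(rpm, design, genotype=geno, treatment=treatment, tissue="head")
            b = group_mean_rpm(rpm, design, genotype=geno, treatment=treatment, tissue="flag_leaf")
            out[(geno, treatment)] = {
                f: pairwise_de(float(a[f]), float(b[f]), criteria, f, f"head-vs-flag_leaf|{geno}|{treatment}")
                for f in rpm.index
            }
    return out


def stress_comparisons(
    rpm: pd.DataFrame, design: StudyDesign, criteria: DECriteria | None = None
) -> dict[tuple[str, str], dict[str, DEComparisonResult]]:
    """Water-deficit-vs-control contrasts per (genotype, tissue); side a = stress."""
    criteria = criteria or DECriteria()
    out = {}
    for geno in design.genotypes:
        for tissue in ("flag_leaf", "head"):
            a = group_mean_rpm(rpm, design, genotype=geno, tissue=tissue, treatment="water_deficit")
            b = group_mean_rpm(rpm, design, genotype=geno, tissue=tissue, treatment="control")
            out[(geno, tissue)] = {
                f: pairwise_de(float(a[f]), float(b[f]), criteria, f, f"WG-vs-CG|{geno}|{tissue}")
                for f in rpm.index
            }
    return out


# ---------------------------------------------------------------------------
# Pattern classifiers
# ---------------------------------------------------------------------------

def _treatment_direction(results: list[DEComparisonResult]) -> str:
    """Summarise called directions: tolerant / sensitive / mixed / absent.

    Side a of genotype contrasts is the tolerant genotype, so direction 'a'
    is tolerant-favouring.
    """
    called = [r.direction for r in results if r.called and r.direction != "tie"]
    if not called:
        return "absent"
    if all(d == "a" for d in called):
        return "tolerant"
    if all(d == "b" for d in called):
        return "sensitive"
    return "mixed"


_GROUP_TABLE = {
    ("tolerant", "tolerant"): "I",
    ("sensitive", "sensitive"): "II",
    ("tolerant", "sensitive"): "III",
    ("sensitive", "tolerant"): "IV",
}


def classify_genotype_group(
    results_by_stratum: Mapping[tuple[str, str, str], DEComparisonResult]
) -> str:
    """Group I-IV pattern of one feature across genotype contrasts.

    Keys are (pair_label, treatment, tissue). A treatment counts as
    tolerant- or sensitive-favouring only when all its called comparisons
    agree and at least one comparison is called; any feature whose two
    treatment summaries are not a row of the I-IV truth table is
    'unclassified'.
    """
    per_treatment = {}
    for treatment in ("control", "water_deficit"):
        rs = [r for (pair, tr, ti), r in results_by_stratum.items() if tr == treatment]
        per_treatment[treatment] = _treatment_direction(rs)
    key = (per_treatment["control"], per_treatment["water_deficit"])
    return _GROUP_TABLE.get(key, "unclassified")


def classify_tissue_predominance(
    results_by_stratum: Mapping[tuple[str, str], DEComparisonResult],
    min_called: int = 6,
) -> str:
    """Tissue predominance across (genotype, treatment) strata; a = head.

    Requires >= ``min_called`` of the 8 strata called, all in one direction.
    """
    called = [r.direction for r in results_by_stratum.values() if r.called and r.direction != "tie"]
    if len(called) >= min_called and all(d == "a" for d in called):
        return "head_predominant"
    if len(called) >= min_called and all(d == "b" for d in called):
        return "leaf_predominant"
    return "none"


def call_stress_responsive(
    results_by_stratum: Mapping[tuple[str, str], dict[str, DEComparisonResult]],
) -> tuple[list[str], pd.DataFrame]:
    """Stress-responsive flags and the signed log2-FC matrix.

    A feature is flagged when called in at least one (genotype, tissue)
    stratum; log2 fold changes of uncalled strata are recorded as zero.
    """
    strata = sorted(results_by_stratum)
    features = sorted({f for d in results_by_stratum.values() for f in d})
    mat = pd.DataFrame(
        0.0, index=features, columns=[f"{g}|{t}" for g, t in strata]
    )
    flagged = []
    for f in features:
        any_called = False
        for (g, t) in strata:
            r = results_by_stratum[(g, t)].get(f)
            if r is not None and r.called:
                mat.loc[f, f"{g}|{t}"] = r.log2fc
                any_called = True
        if any_called:
            flagged.append(f)
    return flagged, mat


def log2fc_matrix(
    results_by_stratum: Mapping[tuple, dict[str, DEComparisonResult]],
    called_only: bool = True,
) -> pd.DataFrame:
    """Signed log2-FC matrix (features x strata) for heat-map style export."""
    strata = sorted(results_by_stratum)
    features = sorted({f for d in results_by_stratum.values() for f in d})
    cols = ["|".join(map(str, s)) for s in strata]
    mat = pd.DataFrame(0.0, index=features, columns=cols)
    for s, col in zip(strata, cols):
        for f, r in results_by_stratum[s].items():
            if r.called or not called_only:
                mat.loc[f, col] = r.log2fc
    return mat
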