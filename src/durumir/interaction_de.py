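"""Tolerance x treatment interaction testing on hairpin counts.

Each hairpin's log2-CPM profile across the factorial design is fitted with an
ordinary least-squares linear model (intercept + tolerance + treatment +
tissue + tolerance x treatment); residual variances are shrunk toward a
pooled prior by empirical-Bayes moderation (method-of-moments on the log
sample variances, the scaled-inverse-chi-square hierarchy familiar from
moderated t-statistics), and the interaction coefficient is tested with the
moderated t on augmented degrees of freedom. Benjamini-Hochberg controls the
FDR across hairpins. A deterministic coverage-signature check stands in for
manual read-profile inspection of the significant candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import StudyDesign

INTERACTION = "tolerance_x_treatment"
DESIGN_COLUMNS = ("intercept", "tolerance", "treatment", "tissue", INTERACTION)


def build_design_matrix(design: StudyDesign, include_tissue: bool = True) -> pd.DataFrame:
    """Library x covariate matrix with the tolerance x treatment product."""
    rows = []
    for r in design:
        treat = 1 if r.treatment == "water_deficit" else 0
        tissue = 1 if r.tissue == "head" else 0
        row = dict(intercept=1, tolerance=r.tolerance, treatment=treat)
        if include_tissue:
            row["tissue"] = tissue
        row[INTERACTION] = r.tolerance * treat
        rows.append(row)
    return pd.DataFrame(rows, index=design.library_ids)


def cpm_log2(
    counts: pd.DataFrame, prior_count: float = 0.5, library_totals: pd.Series | None = None
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count guarding zeros.

    ``library_totals`` defaults to the column sums of ``counts``; pass the
    library-wide read totals when the matrix covers only a feature subset.
    """
    totals = (
        library_totals.reindex(counts.columns).astype(float)
        if library_totals is not None
        else counts.sum(axis=0).astype(float)
    )
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for {bad[:3]}")
    return np.log2((counts + prior_count) / (totals + 2 * prior_count) * 1e6)


@dataclass
class LinearFit:
    coefficients: pd.DataFrame  # features x columns
    s2: pd.Series  # residual variances
    df_residual: int
    design_matrix: pd.DataFrame
    unscaled_var: pd.Series  # diag (X'X)^-1 per column


def fit_linear(logcpm: pd.DataFrame, X: pd.DataFrame) -> LinearFit:
    """Ordinary least squares of every feature row on the design matrix."""
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # name the aliased columns for the error message
        _, R = np.linalg.qr(Xm)
        aliased = [X.columns[i] for i in range(p) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    if n <= p:
        raise ValueError("more model columns than libraries")
    Y = logcpm[X.index].to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    beta = Y @ Xm @ XtX_inv.T
    resid = Y - beta @ Xm.T
    df = n - rank
    s2 = (resid**2).sum(axis=1) / df
    return LinearFit(
        coefficients=pd.DataFrame(beta, index=logcpm.index, columns=X.columns),
        s2=pd.Series(s2, index=logcpm.index),
        df_residual=df,
        design_matrix=X,
        unscaled_var=pd.Series(np.diag(XtX_inv), index=X.columns),
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by bisection (trigamma is decreasing on (0, inf))."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection suits the 1/x scale
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return float(np.sqrt(lo * hi))


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Models s2 as scaled F around a prior variance: on the log scale,
    e = log(s2) - digamma(df/2) + log(df/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    if len(s2) < 2:
        return 0.0, float(s2.mean())
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(float(evar))
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(emean))
    d0 = 2 * half_d0
    s0 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0


@dataclass
class InteractionFit:
    """Moderated interaction statistics for all features."""

    table: pd.DataFrame  # coef, s2, s2_post, t, p, padj, significant
    d0: float
    s0_squared: float
    df_residual: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.index[t["padj"] <= alpha])


def moderate(
    fit: LinearFit,
    term: str = INTERACTION,
    alpha: float = 0.05,
    prior: tuple[float, float] | None = None,
) -> InteractionFit:
    """Empirical-Bayes moderated t-test of one model term across features.

    Shrinks each residual variance toward the pooled prior:
    s2_post = (d0 s0^2 + df s2) / (d0 + df); the moderated t has d0 + df
    degrees of freedom. With a single feature no shrinkage is possible and
    the ordinary t is used.
    """
    s2 = fit.s2.to_numpy()
    df = fit.df_residual
    if prior is not None:
        d0, s0 = prior
    elif len(s2) < 2:
        warnings.warn("single feature: falling back to the ordinary t-test")
        d0, s0 = 0.0, float(s2.mean()) if len(s2) else 0.0
    else:
        d0, s0 = estimate_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    v = float(fit.unscaled_var[term])
    beta = fit.coefficients[term].to_numpy()
    se = np.sqrt(s2_post * v)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else p
    table = pd.DataFrame(
        {
            "coef": beta,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=fit.s2.index,
    )
    return InteractionFit(table=table, d0=float(d0), s0_squared=float(s0), df_residual=df)


def run_interaction(
    counts: pd.DataFrame,
    design: StudyDesign,
    prior_count: float = 0.5,
    include_tissue: bool = True,
    alpha: float = 0.05,
    library_totals: pd.Series | None = None,
) -> InteractionFit:
    """Counts -> log2 CPM -> OLS -> moderated interaction test."""
    X = build_design_matrix(design, include_tissue)
    logcpm = cpm_log2(counts, prior_count, library_totals)
    return moderate(fit_linear(logcpm, X), alpha=alpha)


def select_candidates(
    fit: InteractionFit,
    candidate_ids: Sequence[str],
    alpha: float = 0.05,
) -> list[str]:
    """Significant interaction features among the given candidates, by p."""
    t = fit.table.loc[[c for c in candidate_ids if c in fit.table.index]]
    sig = t[t["padj"] <= alpha].sort_values("p")
    return list(sig.index)


# ---------------------------------------------------------------------------
# Coverage-signature check (automated stand-in for manual inspection)
# ---------------------------------------------------------------------------

@dataclass
class SignatureParams:
    min_strand_bias: float = 0.98
    min_mature_window_fraction: float = 0.90
    min_modal_end_fraction: float = 0.50


def signature_check(
    read_intervals: Sequence[tuple[int, int, str, int]],
    region_length: int,
    mature_interval: tuple[int, int],
    params: SignatureParams | None = None,
) -> tuple[bool, float]:
    """Strict read-signature screen of a flagged hairpin.

    ``read_intervals`` are region-relative (start, end, strand, count). The
    mature window is the terminal 50 bp containing the mature arm. Pass
    requires near-perfect strand bias (>= 0.98), >= 90% of reads in the
    mature window, and a modal 5' end carrying >= 50% of the mature-window
    reads (the crisp processing of a genuine miRNA). The score is the product
    of the three fractions.
    """
    params = params or SignatureParams()
    if not read_intervals:
        raise ValueError("no reads to inspect")
    w = 50
    m_lo, _m_hi = mature_interval
    window = (0, w) if m_lo < region_length / 2 else (region_length - w, region_length)
    total = plus = in_window = 0
    ends: dict[tuple[int, str], int] = {}
    for start, end, strand, count in read_intervals:
        total += count
        if strand == "+":
            plus += count
        ov = min(end, window[1]) - max(start, window[0])
        if ov * 2 >= (end - start):
            in_window += count
            five_prime = start if strand == "+" else end
            ends[(five_prime, strand)] = ends.get((five_prime, strand), 0) + count
    strand_bias = max(plus, total - plus) / total
    window_frac = in_window / total
    modal_frac = max(ends.values()) / in_window if in_window else 0.0
    score = strand_bias * window_frac * modal_frac
    passed = (
        strand_bias >= params.min_strand_bias
        and window_frac >= params.min_mature_window_fraction
        and modal_frac >= params.min_modal_end_fraction
    )
    return passed, float(score)
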