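"""Methylation-expression integration over shared cell lines.

Couples each consensus DM CpG to its target gene's expression: batch
correction of the (GEO-style) expression panel, per-link Spearman rank
correlation between the probe's M-values and the gene's log2 expression
("M-E Spearman coefficient"), expression log2 fold changes, quadrant pattern
classification at |rho| >= 0.25, and the scatter highlight rule
(|meth log2FC| > 2, |expr log2FC| > 2, |rho| > 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MethylationMatrix, TransformConfig

__all__ = [
    "ExpressionMatrix",
    "PATTERNS",
    "correct_batch",
    "me_spearman",
    "expression_log2fc",
    "classify_pattern",
    "highlight_links",
    "assemble_links",
]

PATTERNS = ("hyper_down", "hypo_up", "hyper_up", "hypo_down", "unclassified")


@dataclass
class ExpressionMatrix:
    """log2 expression values (genes x samples) with a batch label per sample."""

    values: pd.DataFrame
    batch: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene symbols must be unique")
        if not self.batch.index.equals(self.values.columns):
            self.batch = self.batch.reindex(self.values.columns)
        if self.batch.isna().any():
            raise ValueError("every sample needs a batch label")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def correct_batch(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene location-scale batch adjustment.

    Each batch is centered to the gene's grand mean and its SD rescaled to
    the pooled within-batch SD, so post-correction batch means agree per gene
    (to numerical precision) while within-batch sample rankings are
    preserved.  A single batch returns the input unchanged; a single-sample
    batch is an error (its scale is undefined).
    """
    batches = expr.batch
    labels = batches.unique()
    if len(labels) == 1:
        return ExpressionMatrix(expr.values.copy(), batches.copy())
    counts = batches.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"single-sample batch(es) {bad}: scale undefined")

    x = expr.values.to_numpy(dtype=float)
    grand = x.mean(axis=1, keepdims=True)
    out = np.empty_like(x)
    # pooled within-batch SD per gene
    ss = np.zeros(x.shape[0])
    dof = 0
    cols_of = {b: np.flatnonzero((batches == b).to_numpy()) for b in labels}
    for b in labels:
        cols = cols_of[b]
        xb = x[:, cols]
        ss += xb.var(axis=1, ddof=1) * (len(cols) - 1)
        dof += len(cols) - 1
    pooled_sd = np.sqrt(ss / dof)
    for b in labels:
        cols = cols_of[b]
        xb = x[:, cols]
        mb = xb.mean(axis=1, keepdims=True)
        sb = xb.std(axis=1, ddof=1, keepdims=True)
        scale = np.where(sb > 0, pooled_sd[:, None] / np.where(sb > 0, sb, 1.0), 1.0)
        out[:, cols] = (xb - mb) * scale + grand
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        batches.copy(),
    )


def me_spearman(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    links: pd.DataFrame,
    samples: Sequence[str],
    config: TransformConfig | None = None,
) -> pd.Series:
    """Spearman rho per probe-gene link across shared samples.

    ``links`` needs columns ``probe_id`` and ``gene``.  The methylation side
    is the probe's M-value.  Ties get average ranks; links with missing
    values fall back to pairwise-complete computation.  Requires >= 3 shared
    samples.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples for Spearman")
    m = meth.m_values(config)[samples]
    e = expr.values[samples]

    mv = m.loc[links["probe_id"]].to_numpy(dtype=float)
    ev = e.loc[links["gene"]].to_numpy(dtype=float)

    rho = np.full(len(links), np.nan)
    clean = ~(np.isnan(mv).any(axis=1) | np.isnan(ev).any(axis=1))
    if clean.any():
        rm = stats.rankdata(mv[clean], axis=1)
        re = stats.rankdata(ev[clean], axis=1)
        rm = rm - rm.mean(axis=1, keepdims=True)
        re = re - re.mean(axis=1, keepdims=True)
        denom = np.sqrt((rm**2).sum(axis=1) * (re**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[clean] = np.where(denom > 0, (rm * re).sum(axis=1) / denom, np.nan)
    for i in np.flatnonzero(~clean):
        ok = ~(np.isnan(mv[i]) | np.isnan(ev[i]))
        if ok.sum() >= 3:
            rho[i] = stats.spearmanr(mv[i, ok], ev[i, ok]).statistic
    return pd.Series(rho, index=links.index, name="rho")


def expression_log2fc(
    expr: ExpressionMatrix, case: Sequence[str], control: Sequence[str]
) -> pd.Series:
    """Per-gene mean(case) - mean(control) on the log2 scale."""
    return (expr.values[list(case)].mean(axis=1)
            - expr.values[list(control)].mean(axis=1)).rename("expr_log2fc")


def classify_pattern(
    meth_log2fc, expr_log2fc, rho, rho_cutoff: float = 0.25
):
    """Quadrant pattern of a link: hyper/hypo x up/down, gated on |rho|.

    Links with |rho| < cutoff, or with either fold change exactly 0, are
    unclassified.  Vectorized; accepts scalars or aligned array-likes.
    """
    mfc = np.asarray(meth_log2fc, dtype=float)
    efc = np.asarray(expr_log2fc, dtype=float)
    r = np.asarray(rho, dtype=float)
    labels = np.where(
        (np.abs(r) < rho_cutoff) | (mfc == 0) | (efc == 0) | np.isnan(r),
        "unclassified",
        np.where(mfc > 0,
                 np.where(efc > 0, "hyper_up", "hyper_down"),
                 np.where(efc > 0, "hypo_up", "hypo_down")),
    )
    if np.isscalar(meth_log2fc):
        return str(labels)
    if isinstance(meth_log2fc, pd.Series):
        return pd.Series(labels, index=meth_log2fc.index, name="pattern")
    return labels


def highlight_links(
    links: pd.DataFrame,
    meth_cutoff: float = 2.0,
    expr_cutoff: float = 2.0,
    rho_cutoff: float = 0.75,
) -> pd.Series:
    """Scatter highlight rule: all three strict inequalities must hold."""
    return (
        (links["meth_log2fc"].abs() > meth_cutoff)
        & (links["expr_log2fc"].abs() > expr_cutoff)
        & (links["rho"].abs() > rho_cutoff)
    ).rename("highlight")


def assemble_links(
    consensus: pd.DataFrame,
    annot: pd.DataFrame,
    cell_results: pd.DataFrame,
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    samples: Sequence[str],
    case: Sequence[str],
    control: Sequence[str],
    rho_cutoff: float = 0.25,
    config: TransformConfig | None = None,
) -> pd.DataFrame:
    """Build the probe-gene link table for retained consensus probes.

    Keeps probes located in promoter / alternative-promoter / gene-body CGIs
    whose gene has expression data.  Methylation log2FC comes from the
    cell-line sample-set results (the fold change the scatter plots use);
    expression log2FC and rho are computed here.
    """
    from .diffmeth import REGION_CLASSES

    kept = consensus.index[consensus["retained"]]
    sub = annot.reindex(kept)
    sub = sub[sub["region_class"].isin(REGION_CLASSES) & sub["gene"].notna()]
    sub = sub[sub["gene"].isin(expr.genes)]
    links = pd.DataFrame({
        "probe_id": sub.index,
        "gene": sub["gene"].to_numpy(),
        "region_class": sub["region_class"].to_numpy(),
    }).reset_index(drop=True)
    if links.empty:
        return links.assign(meth_log2fc=[], expr_log2fc=[], rho=[], pattern=[],
                            highlight=[])
    links["meth_log2fc"] = cell_results["log2fc"].reindex(links["probe_id"]).to_numpy()
    efc = expression_log2fc(expr, case, control)
    links["expr_log2fc"] = efc.reindex(links["gene"]).to_numpy()
    links["rho"] = me_spearman(meth, expr, links, samples, config).to_numpy()
    links["pattern"] = classify_pattern(
        links["meth_log2fc"], links["expr_log2fc"], links["rho"], rho_cutoff
    ).to_numpy()
    links["highlight"] = highlight_links(links).to_numpy()
    return links
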