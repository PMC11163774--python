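"""Dependency-based prioritization and the tumor/cell-line consistency filter.

DepMap-style dependency scores (negative = the gene is essential for growth
in that cell line) are averaged per ARID1A status group; a gene with a
negative mutant-group mean and a non-negative wildtype mean is flagged as an
mt-specific dependency, the sign pattern that marks a putative synthetic-
lethal partner of ARID1A loss.  Candidate genes must additionally be in the
triple-GSEA consensus leading edge and show same-direction consensus DM
evidence in both the primary-tumor and the cell-line sample sets; the result
is the Table-2-shaped candidate report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import spearman_distance

__all__ = [
    "DependencyTable",
    "group_dependency_means",
    "consistency_filter",
    "build_candidate_table",
    "module_heatmap_order",
]


@dataclass
class DependencyTable:
    """Gene x cell-line dependency scores with per-line ARID1A status."""

    scores: pd.DataFrame
    status: pd.Series  # cell_line -> "mt" | "wt"
    source: str = "CRISPR"

    def __post_init__(self) -> None:
        if not set(self.status.dropna().unique()) <= {"mt", "wt"}:
            raise ValueError("cell-line status labels must be 'mt' or 'wt'")
        missing = [c for c in self.scores.columns if c not in self.status.index]
        if missing:
            raise ValueError(f"cell lines without status: {missing}")


def group_dependency_means(
    table: DependencyTable, genes: Iterable[str]
) -> pd.DataFrame:
    """Arithmetic mean dependency per status group for the requested genes.

    Genes absent from the table are reported with ``missing=True`` and NaN
    means (never silently zero).  ``mt_specific`` marks mt mean < 0 <= wt
    mean — the sign-based mt-specific negative-dependency flag.
    """
    genes = list(genes)
    mt_cols = [c for c in table.scores.columns if table.status[c] == "mt"]
    wt_cols = [c for c in table.scores.columns if table.status[c] == "wt"]
    rows = []
    for g in genes:
        if g in table.scores.index:
            mt = float(table.scores.loc[g, mt_cols].mean()) if mt_cols else np.nan
            wt = float(table.scores.loc[g, wt_cols].mean()) if wt_cols else np.nan
            rows.append((g, mt, wt, mt - wt, False))
        else:
            rows.append((g, np.nan, np.nan, np.nan, True))
    out = pd.DataFrame(
        rows, columns=["gene", "mt_mean", "wt_mean", "differential", "missing"]
    ).set_index("gene")
    out["mt_specific"] = (~out["missing"]) & (out["mt_mean"] < 0) & (out["wt_mean"] >= 0)
    return out


def consistency_filter(
    consensus: pd.DataFrame,
    annot: pd.DataFrame,
    tumor_set: str = "primary_tumor",
    cell_set: str = "cell_lines",
) -> list[str]:
    """Genes with same-direction consensus DM evidence in tumors AND cell lines.

    A gene passes iff at least one of its retained consensus probes is
    flagged DM in both named sample sets with equal direction.  Probes
    without a gene are ignored.  Sorted gene list.
    """
    kept = consensus[consensus["retained"]]
    for col in (f"dm_{tumor_set}", f"dm_{cell_set}"):
        if col not in kept.columns:
            raise KeyError(f"consensus table lacks {col!r}")
    both = (
        kept[f"dm_{tumor_set}"]
        & kept[f"dm_{cell_set}"]
        & (kept[f"dir_{tumor_set}"] == kept[f"dir_{cell_set}"])
        & (kept[f"dir_{tumor_set}"] != 0)
    )
    genes = annot.reindex(kept.index[both])["gene"].dropna()
    return sorted(set(genes))


def build_candidate_table(
    links: pd.DataFrame,
    consistent_genes: Iterable[str],
    leading_edge_genes: Iterable[str],
    dependency_means: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the Table-2-shaped candidate report.

    One row per gene passing both (a) consensus leading-edge membership and
    (b) the tumor/cell-line consistency filter.  Methylation fields come
    from the gene's representative link (largest |methylation log2FC|);
    genes lacking expression data get NaN expression fields, genes absent
    from the dependency table get NaN means.  Rows ordered by gene symbol.
    """
    candidates = sorted(set(consistent_genes) & set(leading_edge_genes))
    cols = ["gene", "meth_log2fc", "expr_log2fc", "rho", "region_class",
            "pattern", "mt_mean", "wt_mean", "mt_specific", "consistent"]
    if not candidates:
        return pd.DataFrame(columns=cols).set_index("gene")
    rows = []
    by_gene = links.set_index("gene", drop=False) if len(links) else links
    for g in candidates:
        rec = {"gene": g, "meth_log2fc": np.nan, "expr_log2fc": np.nan,
               "rho": np.nan, "region_class": pd.NA, "pattern": pd.NA,
               "mt_mean": np.nan, "wt_mean": np.nan, "mt_specific": False,
               "consistent": True}
        if len(links):
            sub = links[links["gene"] == g]
            if len(sub):
                best = sub.loc[sub["meth_log2fc"].abs().idxmax()]
                rec.update(
                    meth_log2fc=float(best["meth_log2fc"]),
                    expr_log2fc=float(best["expr_log2fc"]),
                    rho=float(best["rho"]),
                    region_class=best["region_class"],
                    pattern=best["pattern"],
                )
        if dependency_means is not None and g in dependency_means.index:
            d = dependency_means.loc[g]
            if not bool(d["missing"]):
                rec.update(mt_mean=float(d["mt_mean"]), wt_mean=float(d["wt_mean"]),
                           mt_specific=bool(d["mt_specific"]))
        rows.append(rec)
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def module_heatmap_order(
    candidate_genes: Sequence[str],
    collection,
    min_shared: int = 2,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Gene x gene-set membership matrix with clustered orderings.

    Restricted to sets sharing strictly more than ``min_shared`` candidate
    genes.  Rows (genes) and columns (sets) are ordered by hierarchical
    clustering with 1 - Spearman distance and Ward-style linkage; axes too
    short to cluster keep their sorted order.  Returns (membership,
    row_order, col_order).
    """
    from scipy.cluster import hierarchy

    genes = sorted(set(candidate_genes))
    sets = {}
    for name in sorted(collection.names()):
        shared = set(collection[name]) & set(genes)
        if len(shared) > min_shared:
            sets[name] = shared
    member = pd.DataFrame(
        [[int(g in sets[s]) for s in sets] for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=pd.Index(list(sets), name="set"),
        dtype=int,
    )

    def _order(frame: pd.DataFrame) -> list[str]:
        # cluster the columns of `frame`; constant columns make Spearman
        # undefined, so fall back to sorted order there too
        if frame.shape[1] < 3 or frame.shape[0] < 2:
            return list(frame.columns)
        std = frame.to_numpy().std(axis=0)
        if (std == 0).any():
            return list(frame.columns)
        z = hierarchy.linkage(spearman_distance(frame), method="ward")
        leaves = hierarchy.leaves_list(z)
        return [frame.columns[i] for i in leaves]

    col_order = _order(member)
    row_order = _order(member.T)
    return member, row_order, col_order
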