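"""Unsupervised clustering of samples on genome-wide beta-values, and
association of cluster membership with mutation/stage covariates.

Samples are clustered hierarchically (default Euclidean distance with Ward
linkage on genome-wide beta; a 1 - Spearman-correlation distance is
available for the gene/gene-set heatmap style of clustering).  Two-cluster
membership is then tested against binary covariates (ARID1A/PIK3CA, TP53,
stage...) with a two-sided Fisher exact test, and jointly with ordinary
least squares of the cluster indicator on a covariate design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .preprocess import MethylationMatrix

__all__ = [
    "ClusteringResult",
    "AssociationResult",
    "spearman_distance",
    "hierarchical_cluster",
    "fisher_association",
    "regress_cluster",
]


@dataclass
class ClusteringResult:
    """Linkage tree plus the k-cluster cut labels."""

    linkage: np.ndarray
    labels: pd.Series  # sample_id -> 1..k
    metric: str
    method: str
    k: int


@dataclass
class AssociationResult:
    """Association of a covariate with cluster membership."""

    covariate: str
    table: pd.DataFrame | None  # 2 x k contingency (Fisher) or None (OLS)
    p: float
    estimate: float | None = None
    stderr: float | None = None


def spearman_distance(values: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Spearman-rho distance between columns."""
    rho = stats.spearmanr(values.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def hierarchical_cluster(
    meth: MethylationMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "ward",
    k: int = 2,
) -> ClusteringResult:
    """Cluster samples (columns) and cut the tree into k groups.

    Ward linkage (the ward.D2-style criterion) requires the Euclidean or the
    1 - Spearman ("spearman") distance option; other metric/linkage
    combinations defined by scipy pass through.  Deterministic given the
    input and method.
    """
    values = meth.beta if isinstance(meth, MethylationMatrix) else meth
    if values.isna().to_numpy().any():
        raise ValueError("clustering requires complete data (no missing values)")
    n = values.shape[1]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if method == "ward" and metric not in ("euclidean", "spearman"):
        raise ValueError("ward linkage is defined for euclidean (or the "
                         "1 - Spearman dissimilarity), not " + repr(metric))
    if metric == "spearman":
        dist = spearman_distance(values)
    else:
        dist = pdist(values.to_numpy().T, metric=metric)
    z = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusteringResult(
        linkage=z,
        labels=pd.Series(labels, index=values.columns, name="cluster"),
        metric=metric,
        method=method,
        k=k,
    )


def fisher_association(labels: pd.Series, covariate: pd.Series) -> AssociationResult:
    """Two-sided Fisher exact test of a binary covariate vs 2 clusters.

    Missing covariate values are excluded pairwise.  The p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    cov = covariate.reindex(labels.index)
    ok = cov.notna()
    lab = labels[ok]
    cov = cov[ok]
    lab_levels = sorted(lab.unique())
    cov_levels = sorted(pd.unique(cov))
    if len(lab_levels) != 2:
        raise ValueError("Fisher association requires exactly 2 clusters")
    if len(cov_levels) > 2:
        raise ValueError("covariate must be binary")
    table = pd.crosstab(cov, lab).reindex(
        index=cov_levels, columns=lab_levels, fill_value=0)
    if table.shape != (2, 2):  # constant covariate: pad the missing level
        table = table.reindex(index=(list(table.index) + ["__absent__"])[:2], fill_value=0)
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return AssociationResult(covariate=str(covariate.name), table=table, p=float(p))


def regress_cluster(labels: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS of the cluster indicator on a numeric covariate design.

    Returns estimate, standard error and two-sided t-test p per covariate
    (plus the intercept row).  A rank-deficient design raises, naming the
    collinear columns.
    """
    import statsmodels.api as sm

    x = covariates.reindex(labels.index).astype(float)
    if x.isna().to_numpy().any():
        raise ValueError("covariate design contains missing values")
    y = labels.astype(float).to_numpy()
    design = sm.add_constant(x, has_constant="add")
    arr = design.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # greedy: columns that do not grow the rank of their predecessors
        bad = []
        cols = []
        for j, name in enumerate(design.columns):
            trial = arr[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(str(name))
            else:
                cols.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {"estimate": fit.params, "stderr": fit.bse, "p": fit.pvalues},
        index=design.columns,
    )
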