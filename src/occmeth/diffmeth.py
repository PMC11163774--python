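"""Per-sample-set differential methylation with empirical-Bayes moderation.

Each of the four sample sets (primary tumors, the cell-line panel, and the
two isogenic knockout pairs) is tested probe-by-probe on the M-value scale
with a two-group linear model whose residual variance is shrunk toward a
common prior, exactly in the spirit of microarray moderated t-statistics:

    s_tilde^2_g = (d0 * s0^2 + d_g * s^2_g) / (d0 + d_g)

with the prior (d0, s0^2) fitted by matching the first two moments of
log s^2_g to a scaled F / log-chi-square distribution (digamma / trigamma
matching).  The moderated t refers to a t distribution with d0 + d_g degrees
of freedom; p-values are Benjamini-Hochberg adjusted within each sample set.

A probe is called DM when it passes both an adjusted-p and an |M log2FC|
cutoff; probes called DM in at least two of the four sets with a consistent
direction form the unambiguous consensus used by all downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MethylationMatrix, TransformConfig

__all__ = [
    "SampleSetDefinition",
    "ModerationEstimate",
    "DMThresholds",
    "fit_variance_prior",
    "trigamma_inverse",
    "moderated_dm_test",
    "call_dm",
    "consensus_dm",
    "annotate_and_count",
]

REGION_CLASSES = ("promoter", "alt_promoter", "gene_body")


@dataclass(frozen=True)
class SampleSetDefinition:
    """One case/control comparison (mt or ko vs wt or parental)."""

    set_id: str
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]

    def __init__(self, set_id: str, case_ids: Sequence[str], control_ids: Sequence[str]):
        object.__setattr__(self, "set_id", set_id)
        object.__setattr__(self, "case_ids", tuple(case_ids))
        object.__setattr__(self, "control_ids", tuple(control_ids))
        if not self.case_ids or not self.control_ids:
            raise ValueError(f"sample set {set_id!r}: both sides must be non-empty")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError(f"sample set {set_id!r}: case and control overlap")


@dataclass(frozen=True)
class ModerationEstimate:
    """Fitted empirical-Bayes prior: d0 (prior df, may be inf) and s0^2."""

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if not (self.prior_df > 0 or self.prior_df == 0 or math.isinf(self.prior_df)):
            raise ValueError("prior_df must be >= 0 or inf")
        if self.prior_var <= 0 and self.prior_df != 0:
            raise ValueError("prior_var must be positive")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; no solution for y <= 0")
    if y > 1e7:  # trigamma(x) ~ 1/x^2 + ... for small x
        return 1.0 / math.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x for large x
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> ModerationEstimate:
    """Method-of-moments fit of (d0, s0^2) from per-probe sample variances.

    Works on z = log(s2): E[z] and Var[z] under the scaled-F model are
    expressed through digamma/trigamma of df/2 and d0/2; the excess variance
    of z beyond the chi-square sampling term identifies d0.  Non-positive
    excess means the variances are consistent with a single common value and
    d0 = inf (complete shrinkage to s0^2 = exp(mean z)).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    n = e.size
    emean = float(e.mean())
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return ModerationEstimate(prior_df=d0, prior_var=s02)


def moderated_dm_test(
    meth: MethylationMatrix,
    set_def: SampleSetDefinition,
    config: TransformConfig | None = None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[pd.DataFrame, ModerationEstimate]:
    """Two-group moderated t-test per probe on M-values.

    Forcing ``prior_df=0`` recovers the ordinary two-sample pooled t exactly;
    ``prior_df=inf`` uses s0^2 (given, or fitted as exp(mean log s2)) for
    every probe.  Probes with zero variance on both sides and d0 = 0 are
    flagged ``degenerate`` with undefined p.

    Returns (results, moderation).  Results columns: log2fc (case mean M -
    control mean M), t, p, adj_p, direction (+1/-1/0), s2, s2_post,
    degenerate, set_id.
    """
    case = [s for s in set_def.case_ids]
    ctrl = [s for s in set_def.control_ids]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(f"sample set {set_def.set_id!r}: need >= 2 samples per side")
    m = meth.m_values(config)
    a = m[case].to_numpy()
    b = m[ctrl].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    dg = n1 + n2 - 2

    diff = a.mean(axis=1) - b.mean(axis=1)
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / dg

    if prior_df is None:
        mod = fit_variance_prior(s2, dg)
    else:
        if prior_df == 0:
            mod = ModerationEstimate(0.0, prior_var if prior_var is not None else 1.0)
        elif math.isinf(prior_df):
            s02 = prior_var if prior_var is not None else float(np.exp(np.mean(np.log(s2[s2 > 0]))))
            mod = ModerationEstimate(math.inf, s02)
        else:
            s02 = prior_var if prior_var is not None else fit_variance_prior(s2, dg).prior_var
            mod = ModerationEstimate(float(prior_df), s02)

    d0 = mod.prior_df
    if d0 == 0:
        s2_post = s2
        df_total = float(dg)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, mod.prior_var)
        df_total = math.inf
    else:
        s2_post = (d0 * mod.prior_var + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, diff / np.where(degenerate, np.nan, se))
    df_arr = np.inf if math.isinf(df_total) else df_total
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df_arr))

    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    res = pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "p": p,
            "adj_p": adj,
            "direction": np.sign(diff).astype(int),
            "s2": s2,
            "s2_post": s2_post,
            "degenerate": degenerate,
            "set_id": set_def.set_id,
        },
        index=meth.probe_ids,
    )
    return res, mod


@dataclass(frozen=True)
class DMThresholds:
    """Dual volcano cutoffs for calling a probe DM."""

    adj_p: float = 0.05
    abs_log2fc: float = 1.0


def call_dm(results: pd.DataFrame, thresholds: DMThresholds | None = None) -> pd.DataFrame:
    """Flag probes passing both cutoffs; keep signed direction for flagged ones."""
    th = thresholds or DMThresholds()
    flag = (
        (results["adj_p"] <= th.adj_p).fillna(False)
        & (results["log2fc"].abs() >= th.abs_log2fc)
        & (results["direction"] != 0)
    )
    out = results[["log2fc", "adj_p", "direction", "set_id"]].copy()
    out["dm"] = flag.to_numpy()
    return out


def consensus_dm(
    per_set_calls: Mapping[str, pd.DataFrame], min_sets: int = 2
) -> pd.DataFrame:
    """The >=2-of-4 direction-consistent consensus over per-set DM calls.

    A probe is retained iff it is flagged in at least ``min_sets`` sets and
    every flagging set agrees in sign; probes flagged with conflicting signs
    are marked ambiguous and excluded.  Output is independent of the mapping
    order (sets are processed sorted by id).
    """
    if not per_set_calls:
        raise ValueError("need at least one sample set")
    set_ids = sorted(per_set_calls)
    probes = per_set_calls[set_ids[0]].index
    for sid in set_ids[1:]:
        probes = probes.union(per_set_calls[sid].index)
    probes = probes.sort_values()

    flags = np.zeros((len(probes), len(set_ids)), dtype=bool)
    dirs = np.zeros((len(probes), len(set_ids)), dtype=int)
    out = pd.DataFrame(index=probes)
    for j, sid in enumerate(set_ids):
        calls = per_set_calls[sid].reindex(probes)
        f = calls["dm"].fillna(False).to_numpy(dtype=bool)
        d = calls["direction"].fillna(0).to_numpy(dtype=int)
        flags[:, j] = f
        dirs[:, j] = np.where(f, d, 0)
        out[f"dm_{sid}"] = f
        out[f"dir_{sid}"] = dirs[:, j]

    n_dm = flags.sum(axis=1)
    any_pos = (dirs > 0).any(axis=1)
    any_neg = (dirs < 0).any(axis=1)
    ambiguous = any_pos & any_neg
    consensus_dir = np.where(ambiguous, 0, np.where(any_pos, 1, np.where(any_neg, -1, 0)))
    out["n_sets_dm"] = n_dm
    out["ambiguous"] = ambiguous
    out["consensus_direction"] = consensus_dir
    out["retained"] = (n_dm >= min_sets) & ~ambiguous
    return out


def annotate_and_count(
    consensus: pd.DataFrame, annot: pd.DataFrame
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[str]], int]:
    """Region x direction counts for retained consensus probes.

    ``annot`` carries probe_id(index), region_class and gene.  Probes whose
    region class is not a promoter / alternative-promoter / gene-body CGI are
    excluded.  Returns (counts, gene_lists, total_genes): counts has one row
    per region class with gained/lost probe counts and distinct gene counts;
    gene_lists maps (region, direction-label) to the sorted distinct genes;
    total_genes counts each gene once over all cells.
    """
    kept = consensus[consensus["retained"]]
    sub = annot.reindex(kept.index)
    region = sub["region_class"]
    gene = sub["gene"]
    direction = kept["consensus_direction"]

    counts = pd.DataFrame(
        0,
        index=pd.Index(REGION_CLASSES, name="region_class"),
        columns=["probes_gained", "probes_lost", "genes_gained", "genes_lost"],
    )
    gene_lists: dict[tuple[str, str], list[str]] = {}
    all_genes: set[str] = set()
    for rc in REGION_CLASSES:
        for label, sign in (("gained", 1), ("lost", -1)):
            sel = (region == rc) & (direction == sign)
            counts.loc[rc, f"probes_{label}"] = int(sel.sum())
            genes = sorted(set(gene[sel].dropna()))
            counts.loc[rc, f"genes_{label}"] = len(genes)
            gene_lists[(rc, label)] = genes
            all_genes.update(genes)
    return counts, gene_lists, len(all_genes)
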