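"""From-scratch pre-ranked gene-set enrichment analysis (GSEA).

The enrichment score is the signed extreme of a weighted Kolmogorov-Smirnov
running statistic walked down the ranked gene list: hits advance the sum by
|score|^p normalized over the set's total hit weight, misses retreat it by
1/(N - N_hits).  Significance comes from a gene-label permutation null (the
only null available for pre-ranked input): NES divides ES by the mean |null
ES| of the same sign, nominal p is the same-sign tail fraction with +1
smoothing, and FDR q compares the same-sign pooled null NES tail with the
observed NES tail, clipped to [0, 1].

The study design runs three pre-ranked GSEAs (methylation log2FC, expression
log2FC, M-E Spearman rho) over the same gene universe; a set counts as a
consensus hit only when significant under all three metrics, and the
consensus leading edge intersects, across metrics, the union of leading-edge
genes of that metric's significant sets.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "GseaResult",
    "GseaThresholds",
    "enrichment_score",
    "leading_edge",
    "preranked_gsea",
    "consensus_sets",
    "consensus_leading_edge",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class RankedList:
    """A deterministically ordered gene ranking for one metric.

    Ordering is descending by score with ties broken ascending by gene
    symbol, so reruns and permutation indices are reproducible.
    """

    metric: str
    scores: pd.Series

    @classmethod
    def from_scores(cls, metric: str, scores: Mapping[str, float] | pd.Series) -> "RankedList":
        s = pd.Series(dict(scores), dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
        if s.index.has_duplicates:
            raise ValueError("ranked genes must be unique")
        if s.isna().any():
            raise ValueError("ranked scores must not be missing")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(metric=metric, scores=s.loc[order])

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed); descriptions optional."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GseaResult:
    """Per-set enrichment summary for one ranking metric."""

    name: str
    metric: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]
    size: int
    n_perm: int
    seed: int
    warning: str | None = None

    def significant(self, fdr: float = 0.25, abs_nes: float = 2.0) -> bool:
        return self.q <= fdr and abs(self.nes) >= abs_nes


def _hit_weights(scores: np.ndarray, weight: float) -> np.ndarray:
    if weight == 0:
        return np.ones_like(scores)
    w = np.abs(scores) ** weight
    return w


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted KS running statistic over the full ranked list.

    Returns (ES, running profile, peak index).  ES is the profile value of
    largest magnitude (first occurrence on ties); the profile has one entry
    per ranked gene, evaluated after that gene is consumed.
    """
    members = set(gene_set)
    genes = ranked.genes
    hit = np.asarray(genes.isin(members))
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    if n_hit == n:
        raise ValueError("gene set covers the whole universe; misses undefined")
    w = _hit_weights(ranked.scores.to_numpy(), weight)
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores exactly zero: fall back to equal weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~hit) / (n - n_hit)
    running = p_hit - p_miss
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def leading_edge(
    ranked: RankedList, gene_set: Iterable[str], running: np.ndarray, peak: int
) -> list[str]:
    """Set members driving the enrichment: at/before a positive peak, at/after
    a negative one.  Returned in rank order."""
    members = set(gene_set)
    genes = ranked.genes
    if running[peak] >= 0:
        sel = genes[: peak + 1]
    else:
        sel = genes[peak:]
    return [g for g in sel if g in members]


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for permutation draws given sorted hit positions.

    pos: (n_perm, k) sorted ascending hit indices; w: matching |score|^p hit
    weights.  The extreme of the running statistic can only occur right after
    a hit (candidate maxima) or right before one (candidate minima), which is
    all this evaluates.
    """
    n_perm, k = pos.shape
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():  # all-zero weights: unweighted fallback, matching enrichment_score
        w = w.copy()
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / totals
    j = np.arange(k)
    miss_before = (pos - j) / (n - k)  # misses strictly before each hit
    at_hit = cum - miss_before
    before_hit = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - miss_before
    top = at_hit.max(axis=1)
    bottom = before_hit.min(axis=1)
    return np.where(top >= -bottom, top, bottom)


def _set_rng(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.blake2b(name.encode(), digest_size=4).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "big")])


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GseaResult]:
    """Run pre-ranked GSEA for every set in the collection.

    Sets are intersected with the ranked universe and size-filtered to
    [min_size, max_size].  Each set draws its own permutation stream from
    (seed, hash(set name)), so results are identical under reruns and
    independent of collection order.  n_perm < 100 records a warning on the
    results instead of failing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    warn = f"n_perm={n_perm} < 100: unstable p/FDR estimates" if n_perm < 100 else None

    genes = ranked.genes
    scores = ranked.scores.to_numpy()
    n = len(genes)
    w_all = _hit_weights(scores, weight)

    results: list[GseaResult] = []
    null_nes_pool: list[np.ndarray] = []
    for name in sorted(collection.names()):
        members = [g for g in dict.fromkeys(collection[name]) if g in genes]
        k = len(members)
        if k < min_size or k > max_size or k == n:
            continue
        es, running, peak = enrichment_score(ranked, members, weight)
        le = leading_edge(ranked, members, running, peak)

        rng = _set_rng(seed, name)
        u = rng.random((n_perm, n))
        pos = np.sort(np.argpartition(u, k, axis=1)[:, :k], axis=1)
        null_es = _es_from_positions(pos, w_all[pos], n)

        same = null_es >= 0 if es >= 0 else null_es < 0
        if same.any():
            norm = float(np.abs(null_es[same]).mean())
        else:  # no same-sign permutation ES at all: fall back to overall mean
            norm = float(np.abs(null_es).mean())
        norm = norm if norm > 0 else 1.0
        nes = es / norm
        null_nes = np.where(null_es >= 0,
                            null_es / max(float(np.abs(null_es[null_es >= 0]).mean()) if (null_es >= 0).any() else norm, 1e-12),
                            null_es / max(float(np.abs(null_es[null_es < 0]).mean()) if (null_es < 0).any() else norm, 1e-12))
        null_nes_pool.append(null_nes)

        n_same = int(same.sum())
        n_extreme = int((np.abs(null_es[same]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)

        results.append(GseaResult(
            name=name, metric=ranked.metric, es=es, nes=float(nes), p=float(p),
            q=np.nan, leading_edge=le, size=k, n_perm=n_perm, seed=seed,
            warning=warn,
        ))

    if not results:
        return results

    pooled = np.concatenate(null_nes_pool)
    obs = np.array([r.nes for r in results])
    for r in results:
        if r.nes >= 0:
            null_tail = (pooled >= r.nes).sum() / max((pooled >= 0).sum(), 1)
            obs_tail = (obs >= r.nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_tail = (pooled <= r.nes).sum() / max((pooled < 0).sum(), 1)
            obs_tail = (obs <= r.nes).sum() / max((obs < 0).sum(), 1)
        r.q = float(np.clip(null_tail / obs_tail, 0.0, 1.0)) if obs_tail > 0 else 0.0
    return results


@dataclass(frozen=True)
class GseaThresholds:
    """Significance filter used throughout the triple-consensus step."""

    fdr: float = 0.25
    abs_nes: float = 2.0


def consensus_sets(
    results_by_metric: Mapping[str, Sequence[GseaResult]],
    thresholds: GseaThresholds | None = None,
) -> pd.DataFrame:
    """Sets significant under every metric, with their NES sign pattern.

    Returns one row per consensus set, columns nes_<metric> / q_<metric>,
    sorted by set name; empty frame when the intersection is empty.
    """
    th = thresholds or GseaThresholds()
    metrics = sorted(results_by_metric)
    sig: dict[str, dict[str, GseaResult]] = {}
    for metric in metrics:
        sig[metric] = {r.name: r for r in results_by_metric[metric]
                       if r.significant(th.fdr, th.abs_nes)}
    common = set.intersection(*(set(s) for s in sig.values())) if metrics else set()
    rows = {}
    for name in sorted(common):
        row: dict[str, float] = {}
        for metric in metrics:
            row[f"nes_{metric}"] = sig[metric][name].nes
            row[f"q_{metric}"] = sig[metric][name].q
        rows[name] = row
    cols = [f"{pre}_{m}" for m in metrics for pre in ("nes", "q")]
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        out = pd.DataFrame(columns=cols)
    out.index.name = "set"
    return out


def consensus_leading_edge(
    results_by_metric: Mapping[str, Sequence[GseaResult]],
    thresholds: GseaThresholds | None = None,
) -> list[str]:
    """Genes leading-edge under every metric.

    Per metric: the union of leading-edge genes over that metric's
    significant sets; then the intersection across metrics.  Sorted output;
    invariant to metric processing order.
    """
    th = thresholds or GseaThresholds()
    per_metric: list[set[str]] = []
    for metric in sorted(results_by_metric):
        union: set[str] = set()
        for r in results_by_metric[metric]:
            if r.significant(th.fdr, th.abs_nes):
                union.update(r.leading_edge)
        per_metric.append(union)
    if not per_metric:
        return []
    return sorted(set.intersection(*per_metric))


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Lines with fewer than three fields raise a parse error naming the line;
    duplicate members within a set are collapsed with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"{path}: line {lineno}: duplicate genes in set {name!r} collapsed")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")
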