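"""Probe-level quality filtration, beta/M transforms and genome-wide summaries.

The Infinium array reports methylation as a beta-value (methylated intensity
fraction, in [0, 1]).  Differential testing is done on the M-value scale,
``M = log2((beta + a) / (1 - beta + a))``, which is approximately
variance-stabilized; ``a`` is a small offset keeping M finite when beta
touches 0 or 1.  This module houses the methylation matrix container, the
transform pair, multi-step probe filtration and the descriptive summaries
(per-group density bins, one-to-one |delta beta| fractions) used to
characterize genome-wide methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransformConfig",
    "MethylationMatrix",
    "FilterRules",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "density_summary",
    "delta_beta_fractions",
]

#: bin edges matching the printed density bins "0 < beta <= 0.2" ... "0.8 < beta <= 1"
DEFAULT_BETA_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class TransformConfig:
    """Configuration of the beta -> M logit2 transform.

    m_offset is the stabilizing constant ``a``.  It must be positive whenever
    any beta equals exactly 0 or 1; with pre-clipped simulated data the
    default 0 is exact.
    """

    m_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.m_offset < 0:
            raise ValueError(f"m_offset must be >= 0, got {self.m_offset}")


def beta_to_m(beta, config: TransformConfig | None = None):
    """logit2 transform of beta-values.

    M = log2((beta + a) / (1 - beta + a)).  Strictly increasing in beta on
    [0, 1] for any a >= 0; exactly invertible by :func:`m_to_beta`.
    Accepts scalars, arrays, Series or DataFrames.
    """
    cfg = config or TransformConfig()
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1) & ~np.isnan(arr)):
        raise ValueError("beta values must lie in [0, 1]")
    a = cfg.m_offset
    if a == 0 and np.any((arr == 0) | (arr == 1)):
        raise ValueError("beta of exactly 0 or 1 requires a positive m_offset")
    with np.errstate(divide="ignore"):
        m = np.log2((arr + a) / (1.0 - arr + a))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m, config: TransformConfig | None = None):
    """Inverse of :func:`beta_to_m`: beta = (2^M (1+a) - a) / (1 + 2^M)."""
    cfg = config or TransformConfig()
    a = cfg.m_offset
    arr = np.asarray(m, dtype=float)
    p = np.exp2(arr)
    beta = (p * (1.0 + a) - a) / (1.0 + p)
    beta = np.clip(beta, 0.0, 1.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


@dataclass
class MethylationMatrix:
    """Beta-values per CpG probe (rows) per sample (columns).

    ``detection_mask`` marks detection failures (True = failed); masked or
    missing entries are permitted before filtering only.
    """

    beta: pd.DataFrame
    detection_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("probe ids must be unique")
        if not self.beta.columns.is_unique:
            raise ValueError("sample ids must be unique")
        vals = self.beta.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] < 0) | (vals[present] > 1)):
            raise ValueError("beta values must lie in [0, 1] wherever present")
        if self.detection_mask is not None:
            if not (
                self.detection_mask.index.equals(self.beta.index)
                and self.detection_mask.columns.equals(self.beta.columns)
            ):
                raise ValueError("detection_mask must share the beta matrix axes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def m_values(self, config: TransformConfig | None = None) -> pd.DataFrame:
        return beta_to_m(self.beta, config)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        mask = None if self.detection_mask is None else self.detection_mask[list(sample_ids)]
        return MethylationMatrix(self.beta[list(sample_ids)], mask)

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        mask = None if self.detection_mask is None else self.detection_mask.loc[list(probe_ids)]
        return MethylationMatrix(self.beta.loc[list(probe_ids)], mask)


@dataclass
class FilterRules:
    """Ordered multi-step probe filtration thresholds.

    Rules are applied in declared order; a probe removed by an earlier rule is
    never counted again under a later one, so per-rule removal counts are
    reproducible.  Drop-lists are named probe-id collections (sex-chromosome,
    SNP-overlapping, cross-reactive probes, ...).
    """

    max_detection_failure_frac: float = 0.05
    max_missing_frac: float = 0.0
    drop_lists: Mapping[str, Iterable[str]] = field(default_factory=dict)


def filter_probes(
    meth: MethylationMatrix, rules: FilterRules | None = None
) -> tuple[MethylationMatrix, pd.Series]:
    """Apply multi-step quality filtration; return surviving matrix + report.

    The report is a Series of removal counts keyed by rule name, in
    application order: ``detection_failure``, ``missingness``, then each
    drop-list.  Raises if no probe survives.
    """
    rules = rules or FilterRules()
    beta = meth.beta
    mask = meth.detection_mask
    alive = pd.Series(True, index=beta.index)
    report: dict[str, int] = {}

    if mask is not None:
        fail_frac = mask.to_numpy(dtype=bool).mean(axis=1)
    else:
        fail_frac = np.zeros(len(beta))
    bad = pd.Series(fail_frac > rules.max_detection_failure_frac, index=beta.index)
    removed = bad & alive
    report["detection_failure"] = int(removed.sum())
    alive &= ~bad

    # masked entries count as missing for the missingness rule
    vals = beta.to_numpy(dtype=float).copy()
    if mask is not None:
        vals[mask.to_numpy(dtype=bool)] = np.nan
    miss_frac = pd.Series(np.isnan(vals).mean(axis=1), index=beta.index)
    bad = miss_frac > rules.max_missing_frac
    removed = bad & alive
    report["missingness"] = int(removed.sum())
    alive &= ~bad

    for name, probes in rules.drop_lists.items():
        bad = beta.index.isin(set(probes))
        removed = pd.Series(bad, index=beta.index) & alive
        report[name] = int(removed.sum())
        alive &= ~bad

    if not alive.any():
        raise ValueError("all probes removed by filtration rules")

    kept = beta.index[alive]
    out_beta = pd.DataFrame(vals, index=beta.index, columns=beta.columns).loc[kept]
    out_mask = None if mask is None else mask.loc[kept]
    return MethylationMatrix(out_beta, out_mask), pd.Series(report, name="removed")


def density_summary(
    meth: MethylationMatrix,
    groups: Mapping[str, Sequence[str]],
    bins: Sequence[float] = DEFAULT_BETA_BINS,
) -> pd.DataFrame:
    """Per-group beta density-bin fractions plus mean and SD.

    Bins are right-closed, matching the printed convention
    "0 < beta <= 0.2" / "0.8 < beta <= 1"; the lowest edge is included so a
    literal beta = 0 is not dropped.  Fractions are over all (probe, sample)
    values of the group and sum to 1.
    """
    edges = np.asarray(bins, dtype=float)
    rows = {}
    for name, samples in groups.items():
        vals = meth.beta[list(samples)].to_numpy(dtype=float).ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"group {name!r} has no beta values")
        idx = np.searchsorted(edges[1:-1], vals, side="left")
        counts = np.bincount(idx, minlength=len(edges) - 1)
        row = {
            f"({edges[i]:g},{edges[i + 1]:g}]": counts[i] / vals.size
            for i in range(len(edges) - 1)
        }
        row["mean"] = float(vals.mean())
        row["sd"] = float(vals.std(ddof=0))
        rows[name] = row
    return pd.DataFrame(rows).T


def delta_beta_fractions(
    meth: MethylationMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thresholds: Sequence[float] = (0.1, 0.4),
) -> pd.Series:
    """Fraction of probes whose group-mean beta difference exceeds each threshold.

    One-to-one CpG comparison: |mean_a - mean_b| > t, one fraction per t.
    Monotonically non-increasing in t.
    """
    a = meth.beta[list(group_a)].mean(axis=1).to_numpy()
    b = meth.beta[list(group_b)].mean(axis=1).to_numpy()
    d = np.abs(a - b)
    valid = ~np.isnan(d)
    if not valid.any():
        raise ValueError("no probes with complete group means")
    return pd.Series(
        {t: float((d[valid] > t).mean()) for t in thresholds}, name="fraction"
    )
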