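"""Statistics for the wet-lab validation arm.

Bisulfite sequencing PCR (BSP) clone calls are semi-quantified as the mean
over non-missing calls (methylated = 1, hemi-methylated = 0.5,
unmethylated = 0) per CpG and per region, then correlated with the array
beta-values over shared CpGs/samples (Spearman; exact permutation p for
small n).  RT-qPCR expression is quantified by the 2^-ddCt convention with a
single reference gene, and DNA-methyltransferase-inhibitor (DAC) induction
is tested with a two-sided Student t on replicate dCt values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BspRegion",
    "bsp_ratio",
    "bsp_array_correlation",
    "relative_expression",
    "dac_induction_test",
    "significance_stars",
]

_VALID_CALLS = (0.0, 0.5, 1.0)


@dataclass
class BspRegion:
    """Clone x CpG methylation calls for one sequenced region.

    Calls are 0 (unmethylated), 0.5 (hemi-methylated), 1 (methylated) or NaN
    (missed CpG).
    """

    region_id: str
    gene: str
    calls: pd.DataFrame  # clones (rows) x CpG positions (columns)

    def __post_init__(self) -> None:
        if self.calls.shape[0] < 1:
            raise ValueError("a BSP region needs at least one clone")
        vals = self.calls.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if not np.isin(present, _VALID_CALLS).all():
            raise ValueError("BSP calls must be 0, 0.5, 1 or missing")


def bsp_ratio(region: BspRegion) -> tuple[float, pd.Series]:
    """Methylation ratio for the region and per CpG.

    Ratio = sum of non-missing calls / number of non-missing calls; missing
    calls enter neither numerator nor denominator.
    """
    vals = region.calls.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    if present.sum() == 0:
        raise ValueError("no non-missing calls in region")
    overall = float(np.nansum(vals) / present.sum())
    per_cpg = region.calls.mean(axis=0, skipna=True).rename("ratio")
    return overall, per_cpg


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def bsp_array_correlation(
    bsp: Sequence[float], array_beta: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman correlation of BSP semi-quantification vs array beta.

    Two-sided p by exact permutation enumeration for n <= ``exact_max_n``,
    otherwise by the t approximation.  Requires >= 4 paired observations.
    """
    x = np.asarray(bsp, dtype=float)
    y = np.asarray(array_beta, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rho = _spearman(x, y)
    if math.isnan(rho):
        return rho, math.nan
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        ry0 = ry - ry.mean()
        rx = stats.rankdata(x)
        denom = math.sqrt(((rx - rx.mean()) ** 2).sum() * (ry0**2).sum())
        count = 0
        total = 0
        base = rx - rx.mean()
        for perm in itertools.permutations(range(n)):
            r = float((base[list(perm)] * ry0).sum() / denom)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, float(min(p, 1.0))


def relative_expression(
    records: pd.DataFrame, calibrator: str
) -> pd.Series:
    """2^-ddCt fold change per sample relative to a calibrator sample.

    ``records`` columns: sample, ct_target, ct_reference (replicates allowed;
    dCt is averaged over replicates per sample).  dCt = Ct_target -
    Ct_reference; ddCt = dCt_sample - dCt_calibrator; fold = 2^-ddCt.
    """
    req = {"sample", "ct_target", "ct_reference"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if (records[["ct_target", "ct_reference"]] <= 0).to_numpy().any():
        raise ValueError("Ct values must be positive")
    dct = (records["ct_target"] - records["ct_reference"]).groupby(
        records["sample"]).mean()
    if calibrator not in dct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in records")
    ddct = dct - dct[calibrator]
    return np.exp2(-ddct).rename("fold_change")


def dac_induction_test(
    records: pd.DataFrame, equal_var: bool = True
) -> tuple[float, float, float, str]:
    """Fold change DAC/control plus a two-sided t-test on replicate dCt.

    ``records`` columns: condition ("control"/"DAC"), ct_target,
    ct_reference.  Returns (fold, t, p, stars).  The default is the
    pooled-variance Student t; ``equal_var=False`` switches to Welch.  With
    zero variance on both sides the t statistic degenerates: p = 1 for equal
    means, p = 0 (below machine floor) otherwise.
    """
    req = {"condition", "ct_target", "ct_reference"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    dct = records["ct_target"] - records["ct_reference"]
    ctrl = dct[records["condition"] == "control"].to_numpy(dtype=float)
    dac = dct[records["condition"] == "DAC"].to_numpy(dtype=float)
    if len(ctrl) < 2 or len(dac) < 2:
        raise ValueError("need >= 2 replicates per condition")
    fold = float(np.exp2(-(dac.mean() - ctrl.mean())))
    if ctrl.var(ddof=1) == 0 and dac.var(ddof=1) == 0:
        if dac.mean() == ctrl.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if dac.mean() > ctrl.mean() else -math.inf, 0.0
    else:
        res = stats.ttest_ind(dac, ctrl, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
    return fold, t, p, significance_stars(p)


def significance_stars(p: float) -> str:
    """The figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
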