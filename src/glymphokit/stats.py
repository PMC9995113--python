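"""Group statistics and derived physiological quantities.

Small, pure helpers mirroring the study's statistical toolkit: brain water
content from wet/dry weights, the mean +/- 1.5 SD outlier-retention filter
used for interstitial-volume (TMA) cohorts, the Mann-Whitney U test (exact
for small groups), and Pearson/Spearman correlation with the regression line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    summaries: dict = field(default_factory=dict)
    effect_direction: str | None = None
    extras: dict = field(default_factory=dict)


def water_content(w_wet: float, w_dry: float) -> float:
    """Brain water content (ml H2O per g dry weight): (W_wet - W_dry) / W_dry."""
    if w_dry <= 0:
        raise ValueError("dry weight must be positive")
    if w_wet <= w_dry:
        raise ValueError("wet weight must exceed dry weight")
    return (w_wet - w_dry) / w_dry


def filter_within_sd(values, k: float = 1.5) -> np.ndarray:
    """Keep values within mean +/- k*SD of the full input (single pass).

    Mean and SD (population) are computed once from all values; no iteration.
    With SD = 0 all values are retained.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        return values.copy()
    return values[np.abs(values - mu) <= k * sd]


def mann_whitney(a, b, exact_below: int = 20) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups are smaller than ``exact_below``
    and tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) < exact_below and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = "a>b" if np.median(a) > np.median(b) else (
        "a<b" if np.median(a) < np.median(b) else "a~b")
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
        n=(a.size, b.size),
        summaries={
            "a": {"n": a.size, "mean": a.mean(), "sd": a.std(ddof=1) if a.size > 1 else 0.0,
                  "median": float(np.median(a))},
            "b": {"n": b.size, "mean": b.mean(), "sd": b.std(ddof=1) if b.size > 1 else 0.0,
                  "median": float(np.median(b))},
        },
        effect_direction=direction,
    )


def correlate(x, y, method: str = "pearson") -> ComparisonResult:
    """Pearson r or Spearman rho with p-value, plus the regression line.

    The slope/intercept support the "non-zero regression slope" criterion
    used alongside |r| > 0.5 and p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        import warnings

        warnings.warn("zero variance; correlation undefined")
        return ComparisonResult(np.nan, np.nan, method, (x.size,))
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    reg = sps.linregress(x, y)
    return ComparisonResult(
        statistic=float(r), p_value=float(p), method=method, n=(x.size,),
        extras={"slope": float(reg.slope), "intercept": float(reg.intercept),
                "significant": abs(r) > 0.5 and p < 0.05},
    )


def load_source_table(
    path, sheet_name=0, column_map: dict | None = None, header: int = 0
) -> pd.DataFrame:
    """Read a per-animal measurement sheet (CSV or XLSX) into a tidy frame.

    ``column_map`` renames the sheet's columns to the canonical
    (subject, genotype, region, measurement, value, units) layout; layouts
    differ between source files, so the mapping is configurable.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet_name, header=header)
    else:
        df = pd.read_csv(path, header=header)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def group_means(df: pd.DataFrame, value: str = "value",
                by=("genotype", "measurement")) -> pd.DataFrame:
    """Group mean/SD/n table from a tidy per-animal frame."""
    g = df.groupby(list(by))[value]
    return g.agg(["mean", "std", "count"]).reset_index()
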