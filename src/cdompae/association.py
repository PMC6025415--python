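"""Correlation and regression layer linking FRI components, water quality and PAEs.

Thin, well-tested wrappers around scipy.stats primitives:

* pairwise-complete Pearson correlation matrices in long format
  (var1, var2, n, r, r2, p) — both r and r² are always reported;
* simple OLS regression with an attached predictor, used to evaluate the
  fulvic-like FRI component as a proxy for DEP concentration;
* classical one-way ANOVA for seasonal comparisons.

Missing values are excluded pairwise; no multiple-testing correction is
applied by default (a Benjamini–Hochberg option exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "pearson_matrix",
    "RegressionResult",
    "regress_simple",
    "anova_oneway",
    "benjamini_hochberg",
]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up), NaNs passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def pearson_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None,
                   min_pairs: int = 3, adjust: str | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations in long format.

    Every unordered pair of ``columns`` (default: all numeric columns)
    yields one row with n, r, r² and the two-tailed p-value from the
    t-transform with n−2 degrees of freedom.  Zero-variance pairs produce
    NaN cells with a warning.  ``adjust="bh"`` appends BH-adjusted p-values.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for i, x_name in enumerate(columns):
        for y_name in columns[i + 1:]:
            pair = table[[x_name, y_name]].dropna()
            n = len(pair)
            if n < min_pairs:
                warnings.warn(f"pearson_matrix: only {n} complete pairs for "
                              f"({x_name}, {y_name})", stacklevel=2)
                r = p = math.nan
            else:
                x = pair[x_name].to_numpy(dtype=float)
                y = pair[y_name].to_numpy(dtype=float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    warnings.warn(f"pearson_matrix: zero variance in "
                                  f"({x_name}, {y_name})", stacklevel=2)
                    r = p = math.nan
                else:
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
            rows.append({"var1": x_name, "var2": y_name, "n": n,
                         "r": r, "r2": r * r, "p": p})
    out = pd.DataFrame(rows, columns=["var1", "var2", "n", "r", "r2", "p"])
    if adjust == "bh":
        out["p_adj"] = benjamini_hochberg(out["p"])
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return out


@dataclass
class RegressionResult:
    """Simple OLS fit y = slope·x + intercept."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def predict(self, x) -> np.ndarray:
        """Point prediction ŷ(x) from the fitted line."""
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def regress_simple(x, y) -> RegressionResult:
    """OLS regression of y on x with r² and a two-tailed slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValidationError("regress_simple needs at least 2 complete pairs")
    if np.ptp(x) == 0:
        raise ValidationError("predictor is constant; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r2=float(fit.rvalue) ** 2, p=float(fit.pvalue), n=int(x.size))


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F = MS_between / MS_within with its p-value.

    Degenerate input where every observation is identical returns
    (F=0, p=1) instead of the undefined 0/0 ratio.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValidationError("anova_oneway needs at least two groups")
    for a in arrays:
        if a.size < 2:
            raise ValidationError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not math.isfinite(f):  # identical group means with zero within-variance
        return 0.0, 1.0
    return float(f), float(p)
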