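"""Spearman rank correlation with exact small-sample p-values.

rho is the Pearson correlation of mid-ranks (average ranks for ties).
The two-sided p-value is computed by full permutation enumeration for
n <= 8 — exact under the null of exchangeability — and by the usual
t-approximation for larger n.  For tie-free data the exact null
distribution of rho depends only on n and is cached.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sstats

EXACT_P_MAX_N = 8
_FEATURES = ("cv", "coactivation", "t_ref")


def _rank_corr(xr: np.ndarray, yr: np.ndarray) -> float:
    sx, sy = xr.std(ddof=1), yr.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    return float(np.cov(xr, yr, ddof=1)[0, 1] / (sx * sy))


def _perm_rhos(xr: np.ndarray, y_vals: np.ndarray) -> np.ndarray:
    """rho for every permutation of y against fixed x ranks."""
    n = len(xr)
    perms = np.array(list(permutations(range(n))))
    yperm = np.asarray(y_vals)[perms]
    yr = sstats.rankdata(yperm, axis=1)
    xc = xr - xr.mean()
    yc = yr - yr.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    return num / den


@lru_cache(maxsize=8)
def _tie_free_null(n: int) -> np.ndarray:
    """Exact |rho| null distribution for n distinct ranks."""
    xr = np.arange(1.0, n + 1.0)
    return np.abs(_perm_rhos(xr, xr))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p (exact enumeration for n <= 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    xr = sstats.rankdata(x)
    yr = sstats.rankdata(y)
    rho = _rank_corr(xr, yr)
    if n <= EXACT_P_MAX_N:
        has_ties = (len(np.unique(xr)) < n) or (len(np.unique(yr)) < n)
        null = (np.abs(_perm_rhos(xr, y)) if has_ties
                else _tie_free_null(n))
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sstats.t.sf(abs(t), df=n - 2))
    return rho, p


def correlate_features(features: pd.DataFrame,
                       min_trials: int = 3) -> pd.DataFrame:
    """Per participant x load, correlate each torque-generation feature
    (cv, coactivation, t_ref) with the matching error tau_err across the
    valid testing trials.  Cells with too few trials or a degenerate
    (constant) feature are skipped, with the skip reason recorded."""
    valid = features[features["valid"]]
    rows = []
    for (pid, load), grp in valid.groupby(["participant", "load"],
                                          sort=True):
        for feat in _FEATURES:
            sub = grp[[feat, "tau_err"]].dropna()
            row = {"participant": pid, "load": load, "feature": feat,
                   "rho": np.nan, "p_value": np.nan, "n": len(sub),
                   "note": ""}
            if len(sub) < min_trials:
                row["note"] = "insufficient trials"
            else:
                try:
                    rho, p = spearman(sub[feat].to_numpy(),
                                      sub["tau_err"].to_numpy())
                    row.update(rho=rho, p_value=p)
                except ValueError:
                    row["note"] = "constant feature"
            rows.append(row)
    return pd.DataFrame(rows)
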